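"""Generate a small synthetic cross-over cohort and inspect its structure.

Each participant completes a THC and a placebo visit with three 6-minute,
20-channel fNIRS scans (pre-dose, ~100 min, ~200 min post-dose) plus
heart-rate / DEQ-"high" series every 20 minutes.  A latent impairment
status raises the 2-back HbO response, heart rate and self-rated high.
"""

import numpy as np

from nirsimpair import CohortSpec, build_probe_layout
from nirsimpair.simulate import generate_cohort

spec = CohortSpec(n_participants=4, seed=7)
scans, vitals, truths = generate_cohort(spec)

print(f"{len(scans)} scans, {len(vitals)} vitals series, "
      f"{len(truths)} participants")
s = scans[0]
print(f"first scan: {s.key}, {s.n_samples} samples x {s.n_channels} channels "
      f"at {s.sampling_rate_hz} Hz, {len(s.events)} task blocks")
for t in truths:
    print(f"  {t.participant_id}: impaired_if_thc={t.impaired_if_thc}, "
          f"impaired scans {t.impaired_scans}, beta={t.beta_um:.3f} uM, "
          f"CCR={t.ccr}")

# impaired THC-visit vitals show the post-dose tachycardia + high trajectory
imp = next(t for t in truths if t.impaired_if_thc)
v = next(x for x in vitals
         if x.participant_id == imp.participant_id and x.visit_arm == "THC")
print("minutes:", v.minutes.astype(int).tolist())
print("HR bpm :", np.round(v.heart_rate).astype(int).tolist())
print("DEQ    :", np.round(v.deq_high).astype(int).tolist())
print("The heart-rate rise (~25 bpm) and DEQ peak (>50) around the impaired "
      "scans are what the labeling algorithm keys on.")
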