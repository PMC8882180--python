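"""Group-level HbO comparison: peak-dose vs pre-dose paired t-tests.

For each participant the post-dose scan with the higher DEQ rating is
paired with the pre-dose scan; per-timepoint paired t-tests with
Benjamini-Hochberg FDR (q=0.05) within each ROI mark where the task
response increased after dosing.
"""

from nirsimpair import ROI_ORDER, build_probe_layout
from nirsimpair.groupstats import matched_pairs, timepoint_paired_tests
from nirsimpair.pipeline import derive_cohort
from nirsimpair.simulate import CohortSpec, generate_cohort

spec = CohortSpec(n_participants=20, p_impaired_given_thc=1.0, seed=5)
scans, vitals, truths = generate_cohort(spec)
layout = build_probe_layout()
derived = derive_cohort(scans, layout)
pids = [t.participant_id for t in truths]

for arm in ("THC", "placebo"):
    vit = {v.participant_id: v for v in vitals if v.visit_arm == arm}
    print(f"\n{arm} visits:")
    for roi in ROI_ORDER:
        tcs = {k: d.timecourses[roi] for k, d in derived.items()
               if k[1] == arm}
        pre, peak, rep = matched_pairs(tcs, pids, arm, vit, roi)
        res = timepoint_paired_tests(pre, peak, roi=roi)
        frac = res.n_significant / len(res.p)
        print(f"  {roi:7s} n={rep['n_pairs']:2d} pairs, "
              f"{res.n_significant:3d}/{len(res.p)} timepoints significant "
              f"({100 * frac:.0f}%)")
print("\nAll-impaired THC visits light up every ROI around the response "
      "peak; placebo visits, where pre and peak share the same response "
      "amplitude, show no significant timepoints.")
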