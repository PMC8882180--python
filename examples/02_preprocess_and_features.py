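"""From a raw-style scan to the 95-value temporal feature map.

Shows the modified Beer-Lambert chain (optical density -> HbO/HbR), the
block-averaged ROI timecourses for the 2-back condition, and the 19
features per region that feed the boosted-trees classifier.
"""

import numpy as np

from nirsimpair import build_probe_layout
from nirsimpair.features import build_feature_vector
from nirsimpair.preprocess import (
    MBLLParams, epoch_and_block_average, hemoglobin_to_od, intensity_to_od,
    od_to_hemoglobin, preprocess_scan,
)
from nirsimpair.simulate import CohortSpec, synth_scan_timeseries

layout = build_probe_layout()
spec = CohortSpec(seed=1)
scan = synth_scan_timeseries(spec, beta_2back_um=0.5,
                             rng=np.random.default_rng(1))

# round-trip demonstration: hemoglobin -> optical density -> intensity -> back
params = MBLLParams()
od = hemoglobin_to_od(scan.series, params)
intensity = {k: np.exp(-v) for k, v in od.items()}      # unit mean intensity
od_back = {k: intensity_to_od(v) for k, v in intensity.items()}
hemo = od_to_hemoglobin(od_back, params)
drift = np.abs(hemo["hbo"] - (scan.series["hbo"]
                              - scan.series["hbo"].mean(0))).max()
print(f"MBLL round-trip max deviation (mean-centred): {drift:.2e} uM")

tcs = preprocess_scan(scan, layout)
for tc in tcs:
    print(f"{tc.roi:7s} peak {tc.hbo.max():+.3f} uM at "
          f"{tc.times[np.argmax(tc.hbo)]:5.1f} s "
          f"({tc.n_blocks_averaged} blocks averaged)")

fv = build_feature_vector(tcs, scan_key=scan.key)
print(f"feature vector: {len(fv.values)} values")
for name, val in list(zip(fv.names, fv.values))[:6]:
    print(f"  {name} = {val:+.4f}")
print("Segment means track the hemodynamic response; the peak (~10 s after "
      "block onset) reflects the simulated 0.5 uM response amplitude.")
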