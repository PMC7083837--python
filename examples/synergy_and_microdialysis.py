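"""Inhibitor-pair synergy and microdialysis transforms.

Bliss independence predicts the remaining activity under two independent
inhibitors as the product of single-agent remaining activities; observed
activity below that product means synergy.  Microdialysis traces are
normalized to the pre-perfusion baseline and summarized as area under the
curve above baseline; perfusate concentrations are corrected by the probe
membrane recovery fraction.
"""

import numpy as np

from allokin.synergy_microdialysis import (
    DialysisSeries,
    auc_window,
    bliss_expected,
    percent_of_basal,
    probe_recovery_correct,
    synergy_excess,
)

# remaining uptake activity: 89.3% under imipramine, 94% under the vestibule
# ligand, 64.8% under the combination
expected = bliss_expected(0.893, 0.94)
excess = synergy_excess(0.648, expected)
print(f"Bliss expected remaining activity: {expected * 100:.1f}%")
print(f"observed 64.8% -> excess inhibition {excess * 100:.1f} percentage points "
      "(positive = synergy)")

# a synthetic dialysate trace: 3 basal fractions then a drug response
times = np.arange(-40.0, 161.0, 20.0)
values = np.array([2.0, 2.1, 1.9, 2.5, 4.0, 6.0, 8.0, 9.5, 10.5, 11.5, 12.0])
series = DialysisSeries(times, values, n_basal=3)
pct = percent_of_basal(series)
auc = auc_window(series.times, pct, window=(20.0, 160.0))
print(f"peak 5-HT level: {pct.max():.0f}% of basal; "
      f"AUC(20–160 min) above baseline = {auc:.0f} %·min")

print(f"probe-corrected tissue concentrations: "
      f"{probe_recovery_correct(1900.0, 0.0322):.1f} nM (vestibule ligand), "
      f"{probe_recovery_correct(360.0, 0.186):.1f} nM (imipramine)")
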