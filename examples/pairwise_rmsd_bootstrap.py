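"""Ligand pose stability by bootstrap pairwise RMSD.

A ligand that occupies two poses produces a bimodal pairwise-RMSD matrix:
same-pose pairs near 0 Å, cross-pose pairs at the inter-pose distance.  We
build a two-pose ensemble (ligand displaced within a fixed binding-site
frame), bootstrap 500-frame samples, superpose every pair on the site atoms
and measure the ligand RMSD.
"""

import math

import numpy as np

from allokin.conformational_analysis import pairwise_rmsd_bootstrap
from allokin.trajectory_synth import generate_pose_ensemble

rng = np.random.default_rng(0)
site = rng.standard_normal((12, 3)) * 4.0   # binding-site anchor atoms
ligand = rng.standard_normal((8, 3))        # ligand heavy atoms
base = np.vstack([site, ligand])

theta = 1.1
rot = np.array([[math.cos(theta), -math.sin(theta), 0.0],
                [math.sin(theta), math.cos(theta), 0.0],
                [0.0, 0.0, 1.0]])
ens = generate_pose_ensemble(base, rot, np.array([0.0, 0.0, 5.0]),
                             p_alt=0.4, jitter_sd=0.3, n_frames=2000, seed=1,
                             moving_selection=np.arange(12, 20),
                             condition="two-pose ligand")

summary = pairwise_rmsd_bootstrap(ens, n_boot=10, sample_size=500,
                                  align_selection=np.arange(12),
                                  rmsd_selection=np.arange(12, 20), seed=2)
print(f"mean pairwise ligand RMSD: {summary.mean_rmsd:.2f} ± {summary.sd_rmsd:.2f} Å "
      f"(mean ± sd over {summary.n_boot} bootstraps of {summary.sample_size} frames)")
off = summary.matrices[0][np.triu_indices(summary.sample_size, k=1)]
print(f"first bootstrap: {np.mean(off < 1.0) * 100:.0f}% of pairs < 1 Å (same pose), "
      f"{np.mean(off > 3.0) * 100:.0f}% > 3 Å (cross-pose)")
print("-> a stable single-pose ligand would put ~100% of pairs near 0 Å; "
      "the bimodal split quantifies pose heterogeneity.")
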