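"""Validate docked poses against a native reference by RMSD.

Builds a native ligand pose, generates 100 docked candidates (a few small
perturbations of the native pose scoring well, plus decoys), then applies
the redocking rule: keep the ten best-scoring poses and report the three
with the lowest RMSD to the native pose.
"""

import numpy as np

from snplie import LigandPose, pose_rmsd, select_best_poses
from snplie.synth import gen_jittered_poses

rng = np.random.default_rng(4)
native = LigandPose("drug", tuple(f"C{i}" for i in range(25)),
                    rng.normal(scale=3.0, size=(25, 3)))

near = gen_jittered_poses(native, sigma=0.3, n_poses=10,
                          score_rule=lambda r, g: r + g.normal(0, 0.05), seed=5)
decoys = gen_jittered_poses(native, sigma=4.0, n_poses=90,
                            score_rule=lambda r, g: r + g.normal(0, 0.5), seed=6)

selection = select_best_poses(near + decoys, native, top_n=10, keep_k=3)
print("three lowest-RMSD poses among the ten best-scoring candidates:")
for rank, (pose, rmsd) in enumerate(selection, start=1):
    print(f"  {rank}. score {pose.score:6.3f}   RMSD {rmsd:5.2f} A")
print(f"\n(for reference, a rigidly translated decoy sits at "
      f"{pose_rmsd(native, decoys[0]):.2f} A)")
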