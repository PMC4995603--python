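"""Build ROI masks and extract both feature families.

Shows the atlas-driven strategies, the data-driven VLSM ROIs (voxels
binned by the median rounded composite score of the subjects lesioned
there), and the two feature families: voxel patterns (one probability
per mask voxel) and lesion load (damaged fraction per region).
"""

import numpy as np

import lesiondecode as ld

atlas = ld.make_atlas((32, 32, 32), n_region_pairs=10, seed=0)
probs, scores, _ = ld.simulate_cohort(atlas, n_subjects=20, seed=3)
cohort = ld.prepare_cohort(atlas, probs, scores)

for sel in ("all", "motor", "cst"):
    print(f"roi_subset({sel!r}): {ld.roi_subset(atlas, sel).mask.sum()} voxels")

# composite target: first principal component of the four scales, z-scored
fpc = ld.fpc_scores(cohort.scores.values())
y, _, _ = ld.standardize_target(fpc.train_scores)
print(f"FPC loadings (ARAT, GS, MI, NHPT): {np.round(fpc.loadings, 3)} "
      f"— explains {fpc.explained_fraction:.0%} of score variance")

rois = ld.build_vlsm_rois(cohort.lesion_masks, y)
print(f"VLSM ROI voxel counts for rounded scores -2..2: {rois.n_voxels_per_roi}")

mask = ld.roi_subset(atlas, "motor")
vp = ld.extract_voxel_patterns(cohort.probs, mask)
print(f"voxel patterns over motor mask: {vp.values.shape[0]} subjects x "
      f"{vp.values.shape[1]} voxels")
ll = ld.extract_lesion_load(cohort.lesion_masks, atlas)
print(f"lesion load over the atlas: {ll.values.shape[1]} regions, "
      f"max load {ll.values.max():.2f}")
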