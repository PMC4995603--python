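"""Simulate a synthetic stroke cohort and inspect what it contains.

Builds a mirrored atlas (motor / non-motor regions + corticospinal tract),
draws soft-edged ellipsoidal lesions of highly variable size, and derives
four correlated upper-limb motor scales (ARAT, grip strength, Motricity
Index, Nine-Hole Peg Test) from a latent damage score with noise and
floor/ceiling clipping.
"""

import numpy as np

import lesiondecode as ld

atlas = ld.make_atlas((32, 32, 32), n_region_pairs=10, seed=0)
print(f"atlas: {len(atlas.regions)} regions "
      f"({sum(r.category == 'motor' for r in atlas.regions)} motor, "
      f"{sum(r.category == 'cst' for r in atlas.regions)} CST)")

probs, scores, truth = ld.simulate_cohort(atlas, n_subjects=12, seed=1)
sizes = [(p.probabilities > 0.3).sum() for p in probs]
print(f"lesion sizes (voxels > 0.3): min {min(sizes)}, max {max(sizes)}")
print("first three subjects' motor scores:")
print(scores.scores.head(3).round(1))
print(f"latent damage scores: {np.round(truth.latent_scores[:3], 3)}")
# More damage inside the signal regions pushes the latent score down and,
# through the per-scale slopes, lowers ARAT/GS/MI and raises NHPT time.
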