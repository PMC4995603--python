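"""Lesion segmentation and canonical orientation.

Probability maps are binarized by strict thresholding (p > threshold)
followed by removal of connected components smaller than a minimum
cluster size; subjects whose segmented lesion sits predominantly in the
left hemisphere are mirrored about the mid-sagittal plane so every
lesion lies on the right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import left_half, mirror, right_half
from .synthetic import LesionProbabilityVolume

_CONNECTIVITY_ORDER = {6: 1, 18: 2, 26: 3}


@dataclass
class BinaryLesionMask:
    mask: np.ndarray  # boolean grid
    subject_id: str

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def segment_lesion(
    prob: LesionProbabilityVolume,
    threshold: float = 0.3,
    min_cluster: int = 100,
    connectivity: int = 26,
) -> BinaryLesionMask:
    """Binarize a probability map and drop small clusters.

    A voxel survives iff its probability strictly exceeds ``threshold``
    and it belongs to a connected component (under the chosen 6/18/26
    connectivity) with at least ``min_cluster`` voxels.  An empty mask is
    a valid result.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if min_cluster < 1:
        raise ValueError(f"min_cluster must be >= 1, got {min_cluster}")
    if connectivity not in _CONNECTIVITY_ORDER:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    binary = prob.probabilities > threshold
    structure = ndimage.generate_binary_structure(
        3, _CONNECTIVITY_ORDER[connectivity]
    )
    labelled, n = ndimage.label(binary, structure=structure)
    if n:
        sizes = np.bincount(labelled.ravel())
        keep = sizes >= min_cluster
        keep[0] = False
        binary = keep[labelled]
    return BinaryLesionMask(mask=binary, subject_id=prob.subject_id)


def flip_to_right(
    prob: LesionProbabilityVolume, mask: BinaryLesionMask
) -> tuple[LesionProbabilityVolume, BinaryLesionMask, bool]:
    """Mirror a subject whose segmented lesion is predominantly left.

    The decision is made on the binary mask: if the left-hemisphere lesion
    voxel count strictly exceeds the right count, both volumes are
    reflected about the mid-sagittal plane.  Ties leave the subject
    unchanged.  Applying the operation twice is the identity.
    """
    if prob.probabilities.shape != mask.mask.shape:
        raise ValueError("probability and mask grids differ in shape")
    n_left = int(left_half(mask.mask).sum())
    n_right = int(right_half(mask.mask).sum())
    if n_left > n_right:
        return (
            LesionProbabilityVolume(
                probabilities=mirror(prob.probabilities).copy(),
                subject_id=prob.subject_id,
            ),
            BinaryLesionMask(mask=mirror(mask.mask).copy(), subject_id=mask.subject_id),
            True,
        )
    return prob, mask, False


def lesion_union_mask(masks: list[BinaryLesionMask]) -> np.ndarray:
    """Voxels lesioned in at least one subject (voxelwise OR)."""
    if not masks:
        raise ValueError("lesion_union_mask needs a nonempty mask list")
    shape = masks[0].mask.shape
    out = np.zeros(shape, dtype=bool)
    for m in masks:
        if m.mask.shape != shape:
            raise ValueError("masks do not share a grid")
        out |= m.mask
    return out
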