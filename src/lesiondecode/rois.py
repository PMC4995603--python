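"""Region-of-interest construction.

Implements the mask strategies used to delimit features: atlas subsets
(all regions / motor regions / CST, and their unions), a mirrored
functional mask, the lesion-union mask, and data-driven ROIs from
voxel-based lesion-symptom mapping (VLSM): each training subject's
composite motor score is rounded to an integer in {-2,...,2}; for every
voxel lesioned in at least one training subject, the median rounded
score of the subjects lesioned there assigns the voxel to one of five
ROIs.  Data-driven masks must only ever be built from training subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import mirror
from .lesions import BinaryLesionMask
from .synthetic import AtlasLabelVolume

VLSM_SCORE_VALUES = (-2, -1, 0, 1, 2)  # ROI labels 1..5 in this order


@dataclass
class RoiMask:
    mask: np.ndarray  # boolean grid
    name: str
    provenance: str


@dataclass
class VLSMRoiSet:
    """Five score-median ROIs labelled 1..5 for rounded scores -2..2."""

    roi_labels: np.ndarray  # int grid, 0 = unlabelled
    n_voxels_per_roi: tuple[int, int, int, int, int]

    def roi_mask_for_value(self, value: int) -> np.ndarray:
        return self.roi_labels == (VLSM_SCORE_VALUES.index(value) + 1)


def roi_subset(atlas: AtlasLabelVolume, selector) -> RoiMask:
    """Boolean union of the selected atlas labels.

    ``selector`` is 'all' / 'motor' / 'nonmotor' / 'cst' or an explicit
    label list; unknown labels raise a LookupError naming the label.
    """
    labels = atlas.labels_for(selector)
    mask = np.isin(atlas.labels, labels)
    name = selector if isinstance(selector, str) else f"labels{labels}"
    prov = {"all": "atlas_all", "motor": "atlas_motor", "cst": "cst"}.get(
        name, "atlas_subset"
    )
    return RoiMask(mask=mask, name=str(name), provenance=prov)


def union_masks(a: RoiMask, b: RoiMask, name: str, provenance: str) -> RoiMask:
    if a.mask.shape != b.mask.shape:
        raise ValueError("masks do not share a grid")
    return RoiMask(mask=a.mask | b.mask, name=name, provenance=provenance)


def mirror_mask(mask: RoiMask) -> RoiMask:
    """Union of a mask with its mid-sagittal reflection (symmetric output)."""
    return RoiMask(
        mask=mask.mask | mirror(mask.mask),
        name=f"{mask.name}+mirror",
        provenance=mask.provenance,
    )


def round_scores(scores: np.ndarray) -> np.ndarray:
    """Round to the closest integer (half away from zero), clamp to [-2, 2]."""
    s = np.asarray(scores, dtype=float)
    rounded = np.sign(s) * np.floor(np.abs(s) + 0.5)
    return np.clip(rounded, -2, 2).astype(int)


def build_vlsm_rois(
    train_masks: list[BinaryLesionMask],
    train_scores: np.ndarray,
    half_median_rule: str = "toward_zero",
) -> VLSMRoiSet:
    """Score-median ROIs from training lesions and composite scores.

    For each voxel lesioned in >= 1 training subject, the median of the
    lesioned subjects' rounded scores selects one of the five ROIs.  With
    an even number of lesioned subjects the median can land on a half
    integer; it is then resolved to the bin nearer zero by default
    ('toward_zero'), or away from zero ('away_from_zero').
    """
    if len(train_masks) != len(np.atleast_1d(train_scores)):
        raise ValueError(
            f"{len(train_masks)} masks but {len(np.atleast_1d(train_scores))} scores"
        )
    if not train_masks:
        raise ValueError("need at least one training subject")
    if half_median_rule not in ("toward_zero", "away_from_zero"):
        raise ValueError(f"unknown half_median_rule {half_median_rule!r}")
    rounded = round_scores(np.atleast_1d(train_scores))
    shape = train_masks[0].mask.shape

    # Per-voxel counts of lesioned subjects at each rounded-score value;
    # the median comes from the two middle order statistics of these counts.
    counts = np.zeros((len(VLSM_SCORE_VALUES),) + shape, dtype=np.int32)
    for m, r in zip(train_masks, rounded):
        counts[VLSM_SCORE_VALUES.index(int(r))][m.mask] += 1
    total = counts.sum(axis=0)
    lesioned = total > 0

    cum = np.cumsum(counts, axis=0)
    vals = np.array(VLSM_SCORE_VALUES, dtype=float)

    def order_stat(pos: np.ndarray) -> np.ndarray:
        # value of the (pos+1)-th smallest rounded score at each voxel
        rank = pos + 1
        idx = (cum >= rank[None]).argmax(axis=0)
        return vals[idx]

    n = total.astype(np.int64)
    safe_n = np.maximum(n, 1)
    lower = order_stat((safe_n - 1) // 2)
    upper = order_stat(safe_n // 2)
    med = (lower + upper) / 2.0

    frac = med != np.floor(med)
    if half_median_rule == "toward_zero":
        resolved = np.where(frac, np.trunc(med), med)
    else:
        resolved = np.where(frac, np.sign(med) * np.ceil(np.abs(med)), med)

    roi_labels = np.zeros(shape, dtype=np.int32)
    for j, v in enumerate(VLSM_SCORE_VALUES):
        roi_labels[lesioned & (resolved == v)] = j + 1
    per_roi = tuple(int((roi_labels == j + 1).sum()) for j in range(5))
    return VLSMRoiSet(roi_labels=roi_labels, n_voxels_per_roi=per_roi)  # type: ignore[arg-type]


def vlsm_mask(rois: VLSMRoiSet) -> RoiMask:
    """Union of the five VLSM ROIs (equals the training lesion union)."""
    return RoiMask(mask=rois.roi_labels > 0, name="vlsm", provenance="vlsm")
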