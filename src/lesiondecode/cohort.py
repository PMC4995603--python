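"""Cohort container: subjects after segmentation and hemispheric alignment."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lesions import BinaryLesionMask, flip_to_right, segment_lesion
from .synthetic import AtlasLabelVolume, LesionProbabilityVolume, MotorScoreTable


@dataclass
class Cohort:
    """All per-subject inputs the cross-validation consumes.

    ``probs`` and ``lesion_masks`` are post-flip: every subject's lesion
    lies predominantly in the right hemisphere.  ``functional_mask`` is
    the raw (possibly unilateral) activation mask; it is mirrored at the
    point of use.
    """

    atlas: AtlasLabelVolume
    probs: list[LesionProbabilityVolume]
    lesion_masks: list[BinaryLesionMask]
    scores: MotorScoreTable
    functional_mask: np.ndarray | None = None
    flipped: list[bool] = field(default_factory=list)
    segmentation: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.probs)

    @property
    def subject_ids(self) -> list[str]:
        return [p.subject_id for p in self.probs]


def prepare_cohort(
    atlas: AtlasLabelVolume,
    probs: list[LesionProbabilityVolume],
    scores: MotorScoreTable,
    functional_mask: np.ndarray | None = None,
    threshold: float = 0.3,
    min_cluster: int = 100,
    connectivity: int = 26,
) -> Cohort:
    """Segment every subject, then flip left-dominant lesions rightward.

    Both steps are strictly per-subject, so they can be applied once,
    outside the cross-validation folds, without leaking information.
    """
    if list(scores.subject_ids) != [p.subject_id for p in probs]:
        raise ValueError("score table subjects do not match the volume list")
    out_probs, out_masks, flags = [], [], []
    for p in probs:
        m = segment_lesion(
            p, threshold=threshold, min_cluster=min_cluster, connectivity=connectivity
        )
        p2, m2, flipped = flip_to_right(p, m)
        out_probs.append(p2)
        out_masks.append(m2)
        flags.append(flipped)
    return Cohort(
        atlas=atlas,
        probs=out_probs,
        lesion_masks=out_masks,
        scores=scores,
        functional_mask=functional_mask,
        flipped=flags,
        segmentation={
            "threshold": threshold,
            "min_cluster": min_cluster,
            "connectivity": connectivity,
        },
    )
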