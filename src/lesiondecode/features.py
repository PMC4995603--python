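"""Feature extraction, standardization, linear kernels and the composite score.

Two feature families are supported: *voxel patterns* (the raw lesion
probability of every voxel inside a mask, one column per voxel) and
*lesion load* (per region, the fraction of its voxels covered by the
binary lesion).  Feature matrices are standardized by first normalizing
each row by its Euclidean norm and then z-scoring each column with
statistics learned on training rows only; the linear kernel C = X X^T
turns the standardized matrix into an examples-by-examples covariance.

The decoding target is the first principal component (FPC) of the four
motor scales, computed by centring the training score columns,
eigendecomposing their covariance and projecting onto the leading
eigenvector; held-out subjects are centred with the training means and
projected with the training eigenvector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .lesions import BinaryLesionMask
from .rois import RoiMask, VLSMRoiSet, VLSM_SCORE_VALUES
from .synthetic import AtlasLabelVolume, LesionProbabilityVolume, MotorScoreTable


@dataclass
class FeatureMatrix:
    """Subjects x features table with provenance.

    ``column_map`` records what each column is: flat voxel indices
    (C-order over the declared (x, y, z) axes, ascending) for voxel
    patterns, or region identifiers for lesion loads.
    """

    values: np.ndarray
    subject_ids: list[str]
    feature_kind: str  # "voxel_pattern" | "lesion_load"
    mask_provenance: str
    column_map: np.ndarray | list

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class StandardizationParams:
    mean: np.ndarray
    sd: np.ndarray  # strictly positive (constant columns stored as 1.0)


@dataclass
class CovarianceMatrix:
    values: np.ndarray
    symmetric: bool


@dataclass
class FPCResult:
    train_scores: np.ndarray
    test_scores: np.ndarray | None
    loadings: np.ndarray  # unit leading eigenvector over the 4 scales
    column_means: np.ndarray
    explained_fraction: float


class ExtractionError(ValueError):
    pass


def extract_voxel_patterns(
    probs: list[LesionProbabilityVolume], mask: RoiMask
) -> FeatureMatrix:
    """One column per mask voxel (ascending flat index), raw probabilities."""
    if not mask.mask.any():
        raise ExtractionError(f"mask {mask.name!r} is empty")
    cols = np.flatnonzero(mask.mask.ravel(order="C"))
    rows = []
    for p in probs:
        if p.probabilities.shape != mask.mask.shape:
            raise ExtractionError(f"{p.subject_id}: grid differs from mask grid")
        rows.append(p.probabilities.ravel(order="C")[cols])
    return FeatureMatrix(
        values=np.asarray(rows, dtype=float),
        subject_ids=[p.subject_id for p in probs],
        feature_kind="voxel_pattern",
        mask_provenance=mask.provenance,
        column_map=cols,
    )


def extract_lesion_load(
    lesions: list[BinaryLesionMask],
    regions: AtlasLabelVolume | list[RoiMask],
    provenance: str | None = None,
) -> FeatureMatrix:
    """Per-region fraction of voxels lesioned, in [0, 1]; one column per region."""
    if isinstance(regions, AtlasLabelVolume):
        region_masks = [
            (r.name, regions.labels == r.label) for r in regions.regions
        ]
        prov = provenance or "atlas_all"
    else:
        region_masks = [(m.name, m.mask) for m in regions]
        prov = provenance or (regions[0].provenance if regions else "regions")
    if not region_masks:
        raise ExtractionError("no regions given")
    sizes = np.array([m.sum() for _, m in region_masks], dtype=float)
    if (sizes == 0).any():
        bad = [n for (n, m), s in zip(region_masks, sizes) if s == 0]
        raise ExtractionError(f"regions with zero voxels: {bad}")
    values = np.zeros((len(lesions), len(region_masks)))
    for i, les in enumerate(lesions):
        for j, (_, m) in enumerate(region_masks):
            values[i, j] = np.logical_and(les.mask, m).sum() / sizes[j]
    return FeatureMatrix(
        values=values,
        subject_ids=[l.subject_id for l in lesions],
        feature_kind="lesion_load",
        mask_provenance=prov,
        column_map=[n for n, _ in region_masks],
    )


def vlsm_region_masks(rois: VLSMRoiSet) -> list[RoiMask]:
    """The five score-median ROIs as individual region masks (empty ones dropped)."""
    out = []
    for j, v in enumerate(VLSM_SCORE_VALUES):
        m = rois.roi_labels == j + 1
        if m.any():
            out.append(RoiMask(mask=m, name=f"vlsm_roi_{v:+d}", provenance="vlsm"))
    return out


def normalize_rows(values: np.ndarray) -> np.ndarray:
    """Divide each row by its Euclidean norm; all-zero rows pass unchanged."""
    norms = np.linalg.norm(values, axis=1, keepdims=True)
    return values / np.where(norms == 0, 1.0, norms)


def standardize(
    train: FeatureMatrix,
    test: FeatureMatrix | None = None,
    row_normalize: bool | None = None,
) -> tuple[FeatureMatrix, FeatureMatrix | None, StandardizationParams]:
    """Row-normalize, then z-score columns with training statistics.

    Column means and standard deviations come from training rows only and
    are applied unchanged to test rows.  Constant training columns are
    centred but not scaled (divisor 1), so they contribute nothing to a
    subsequent kernel.

    ``row_normalize=None`` (default) applies the per-row Euclidean
    normalization whenever the matrix has more than one column.  A
    single-column matrix is exempt: dividing a scalar feature by its own
    magnitude would collapse every nonzero value to 1, turning e.g. a
    whole-brain lesion-load feature into a binary damaged/undamaged flag.
    """
    if train.values.shape[0] < 2:
        raise ValueError("standardization needs at least 2 training rows")
    if test is not None and test.values.shape[1] != train.values.shape[1]:
        raise ValueError("test columns do not match training columns")
    if row_normalize is None:
        row_normalize = train.values.shape[1] > 1
    tr = normalize_rows(train.values) if row_normalize else np.array(
        train.values, dtype=float
    )
    mean = tr.mean(axis=0)
    sd = tr.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    params = StandardizationParams(mean=mean, sd=sd)

    def apply(fm: FeatureMatrix, vals: np.ndarray) -> FeatureMatrix:
        return FeatureMatrix(
            values=(vals - mean) / sd,
            subject_ids=fm.subject_ids,
            feature_kind=fm.feature_kind,
            mask_provenance=fm.mask_provenance,
            column_map=fm.column_map,
        )

    train_out = apply(train, tr)
    test_out = None
    if test is not None:
        te = normalize_rows(test.values) if row_normalize else np.array(
            test.values, dtype=float
        )
        test_out = apply(test, te)
    return train_out, test_out, params


def linear_kernel(A: FeatureMatrix, B: FeatureMatrix | None = None) -> CovarianceMatrix:
    """Dot-product covariance C = A B^T (C = X X^T when B is A)."""
    if B is None:
        B = A
    same = A is B
    if A.values.shape[1] != B.values.shape[1]:
        raise ValueError("feature matrices have different column counts")
    if not same:
        am, bm = np.asarray(A.column_map), np.asarray(B.column_map)
        if am.shape != bm.shape or (am != bm).any():
            raise ValueError("feature matrices have different column mappings")
    return CovarianceMatrix(values=A.values @ B.values.T, symmetric=same)


def _score_array(scores) -> np.ndarray:
    if isinstance(scores, MotorScoreTable):
        return scores.values()
    return np.asarray(scores, dtype=float)


def fpc_scores(
    train_scores, test_scores=None, degeneracy_rtol: float = 1e-9
) -> FPCResult:
    """First principal component of the four motor scales.

    Training columns are mean-centred, their covariance matrix is
    eigendecomposed, and subjects are projected onto the leading
    eigenvector.  The eigenvector sign is oriented so the sum of its
    loadings is positive ("higher FPC = better function" once the scale
    slopes are harmonized).  Near-ties of the two leading eigenvalues emit
    a degeneracy warning and keep the leading one.
    """
    Y = _score_array(train_scores)
    if Y.ndim != 2 or Y.shape[1] != 4:
        raise ValueError(f"expected an n x 4 score table, got shape {Y.shape}")
    if Y.shape[0] < 2:
        raise ValueError("FPC needs at least 2 training subjects")
    means = Y.mean(axis=0)
    centred = Y - means
    cov = centred.T @ centred / (Y.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if eigvals[0] > 0 and (eigvals[0] - eigvals[1]) <= degeneracy_rtol * eigvals[0]:
        warnings.warn(
            "leading eigenvalues of the score covariance are degenerate; "
            "keeping the first eigenvector",
            RuntimeWarning,
            stacklevel=2,
        )
    lead = eigvecs[:, 0]
    if lead.sum() < 0:
        lead = -lead
    train_fpc = centred @ lead
    test_fpc = None
    if test_scores is not None:
        T = _score_array(test_scores)
        test_fpc = (T - means) @ lead
    total = eigvals.sum()
    return FPCResult(
        train_scores=train_fpc,
        test_scores=test_fpc,
        loadings=lead,
        column_means=means,
        explained_fraction=float(eigvals[0] / total) if total > 0 else 1.0,
    )


def standardize_target(
    train_y: np.ndarray, test_y: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, tuple[float, float]]:
    """Z-score the decoding target with training mean and sd."""
    train_y = np.asarray(train_y, dtype=float)
    mu = float(train_y.mean())
    sd = float(train_y.std(ddof=0))
    if sd == 0:
        sd = 1.0
    out_test = None if test_y is None else (np.asarray(test_y, float) - mu) / sd
    return (train_y - mu) / sd, out_test, (mu, sd)
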