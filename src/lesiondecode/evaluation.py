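"""Leakage-controlled 10-fold cross-validation and model comparison.

Every quantity that pools information across subjects — the first
principal component of the motor scales, the target standardization, the
feature standardization, and the data-driven masks (lesion union, VLSM
ROIs) — is fitted on the training subjects of each fold and applied
unchanged to its held-out subjects.  Per-fold accuracy is the Pearson
correlation between predicted and actual standardized scores, and the
root mean squared error; the reported R and RMSE are the arithmetic
means across folds.  Fold RMSEs of two models are compared with a
two-sided Wilcoxon rank-sum test, exact for small samples.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata

from . import features as feat
from . import gp
from .cohort import Cohort
from .geometry import mirror
from .lesions import lesion_union_mask
from .rois import RoiMask, build_vlsm_rois, roi_subset, union_masks, vlsm_mask

MASK_STRATEGIES = (
    "whole_brain",
    "atlas_all",
    "cst",
    "atlas_plus_cst",
    "motor",
    "motor_plus_cst",
    "functional",
    "vlsm",
    "lesion_union",
)
# the eight delimitation strategies proper (whole-brain is the no-mask baseline)
GRID_STRATEGIES = MASK_STRATEGIES[1:]
FEATURE_KINDS = ("voxel_pattern", "lesion_load")


class UndefinedCorrelationError(ValueError):
    """Pearson correlation of a constant vector is undefined."""


@dataclass
class FoldPlan:
    n_subjects: int
    k: int
    assignment: np.ndarray  # per-subject fold index in [0, k)
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


@dataclass
class FeatureSpec:
    kind: str  # voxel_pattern | lesion_load
    mask_strategy: str

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.mask_strategy not in MASK_STRATEGIES:
            raise ValueError(f"unknown mask strategy {self.mask_strategy!r}")


@dataclass
class ModelSpec:
    kind: str = "gpr"  # gpr | mkl

    def __post_init__(self):
        if self.kind not in ("gpr", "mkl"):
            raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass
class FoldRecord:
    fold: int
    test_ids: list[str]
    r: float  # nan when undefined
    rmse: float
    n_features: int
    predictions: np.ndarray
    y_test: np.ndarray
    # fitted-on-training-only quantities, for leakage auditing
    fpc_loadings: np.ndarray = None
    target_mean_sd: tuple = None
    mask_sha256: str = None
    standardization_sha256: str = None
    model_params: dict = None


@dataclass
class CVResult:
    folds: list[FoldRecord]
    mean_r: float
    mean_rmse: float
    pooled_r: float  # diagnostic only: correlation over concatenated folds
    n_undefined_r: int
    feature_spec: FeatureSpec = None
    model_spec: ModelSpec = None
    fold_plan: FoldPlan = None

    def fold_rmses(self) -> np.ndarray:
        return np.array([f.rmse for f in self.folds])


def kfold_split(n: int, k: int = 10, seed: int = 0) -> FoldPlan:
    """Deal a random permutation of subjects into k near-equal folds."""
    if not (2 <= k <= n):
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for fold, size in enumerate(sizes):
        assignment[perm[start : start + size]] = fold
        start += size
    return FoldPlan(n_subjects=n, k=k, assignment=assignment, seed=seed)


def rmse(pred, actual) -> float:
    pred, actual = np.asarray(pred, float), np.asarray(actual, float)
    if pred.shape != actual.shape or pred.size == 0:
        raise ValueError("prediction and target lengths differ or are empty")
    return float(np.sqrt(np.mean((pred - actual) ** 2)))


def pearson_r(pred, actual) -> float:
    pred, actual = np.asarray(pred, float), np.asarray(actual, float)
    if pred.shape != actual.shape or pred.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    px = pred - pred.mean()
    ax = actual - actual.mean()
    denom = np.sqrt((px**2).sum() * (ax**2).sum())
    if denom == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    return float(np.clip((px * ax).sum() / denom, -1.0, 1.0))


def compare_models_wilcoxon(
    rmse_a, rmse_b, exact_limit: int = 20
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on two sets of fold RMSEs.

    Ties get midranks.  For combined sample size <= ``exact_limit`` the
    null distribution of the rank sum is enumerated exhaustively over all
    C(n_a + n_b, n_a) assignments of the observed ranks; larger samples
    use the normal approximation with tie correction.  Returns
    (rank-sum statistic of the first sample, p-value).
    """
    a, b = np.asarray(rmse_a, float), np.asarray(rmse_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    n_a, n_b = a.size, b.size
    W = float(ranks[:n_a].sum())
    if np.ptp(combined) == 0:
        return W, 1.0  # degenerate: all values identical
    N = n_a + n_b
    if N <= exact_limit:
        eps = 1e-9
        total = comb(N, n_a)
        le = ge = 0
        for idx in combinations(range(N), n_a):
            s = ranks[list(idx)].sum()
            if s <= W + eps:
                le += 1
            if s >= W - eps:
                ge += 1
        p = 2.0 * min(le, ge) / total
        return W, float(min(p, 1.0))
    mean_w = n_a * (N + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / ((N) * (N - 1))
    var_w = n_a * n_b / 12.0 * ((N + 1) - tie_term)
    z = (W - mean_w) / np.sqrt(var_w)
    from scipy.stats import norm

    return W, float(min(1.0, 2.0 * norm.sf(abs(z))))


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _fold_masks(cohort: Cohort, strategy: str, train_idx: np.ndarray,
                train_fpc_std: np.ndarray):
    """Resolve a mask strategy to (voxel mask, lesion-load region list).

    Data-driven strategies (vlsm, lesion_union) use only training-fold
    subjects.  Lesion-load regions follow the study's feature counts: the
    anatomical atlas contributes one column per region, the CST and the
    single-mask strategies one column each, VLSM five.
    """
    atlas = cohort.atlas
    if strategy == "whole_brain":
        m = RoiMask(np.ones(atlas.shape, bool), "whole_brain", "whole_brain")
        return m, [m]
    if strategy == "atlas_all":
        labs = atlas.labels_for("motor") + atlas.labels_for("nonmotor")
        m = roi_subset(atlas, labs)
        m.name, m.provenance = "atlas_all", "atlas_all"
        regions = [
            RoiMask(atlas.labels == l, atlas.region_by_label(l).name, "atlas_all")
            for l in labs
        ]
        return m, regions
    if strategy == "cst":
        m = roi_subset(atlas, "cst")
        return m, [m]
    if strategy == "atlas_plus_cst":
        labs = atlas.labels_for("motor") + atlas.labels_for("nonmotor")
        m = union_masks(
            roi_subset(atlas, labs), roi_subset(atlas, "cst"),
            "atlas_plus_cst", "atlas_plus_cst",
        )
        regions = [
            RoiMask(atlas.labels == l, atlas.region_by_label(l).name, "atlas_plus_cst")
            for l in labs
        ] + [roi_subset(atlas, "cst")]
        return m, regions
    if strategy == "motor":
        labs = atlas.labels_for("motor")
        m = roi_subset(atlas, "motor")
        regions = [
            RoiMask(atlas.labels == l, atlas.region_by_label(l).name, "atlas_motor")
            for l in labs
        ]
        return m, regions
    if strategy == "motor_plus_cst":
        labs = atlas.labels_for("motor")
        m = union_masks(
            roi_subset(atlas, "motor"), roi_subset(atlas, "cst"),
            "motor_plus_cst", "motor_plus_cst",
        )
        regions = [
            RoiMask(atlas.labels == l, atlas.region_by_label(l).name, "motor_plus_cst")
            for l in labs
        ] + [roi_subset(atlas, "cst")]
        return m, regions
    if strategy == "functional":
        if cohort.functional_mask is None:
            raise ValueError("cohort carries no functional mask")
        m = RoiMask(
            cohort.functional_mask | mirror(cohort.functional_mask),
            "functional", "functional",
        )
        return m, [m]
    if strategy == "lesion_union":
        union = lesion_union_mask([cohort.lesion_masks[i] for i in train_idx])
        m = RoiMask(union, "lesion_union", "lesion_union")
        return m, [m]
    if strategy == "vlsm":
        rois = build_vlsm_rois(
            [cohort.lesion_masks[i] for i in train_idx], train_fpc_std
        )
        m = vlsm_mask(rois)
        return m, feat.vlsm_region_masks(rois)
    raise ValueError(f"unknown mask strategy {strategy!r}")


def _mkl_sources(train_fm, test_fm, atlas):
    """Split jointly standardized voxel patterns into per-region kernels."""
    col_labels = atlas.labels.ravel(order="C")[np.asarray(train_fm.column_map)]
    names, train_ks, cross_ks = [], [], []
    for region in atlas.regions:
        sel = col_labels == region.label
        if not sel.any():
            continue
        names.append(region.name)
        Xtr = train_fm.values[:, sel]
        Xte = test_fm.values[:, sel]
        train_ks.append(feat.CovarianceMatrix(Xtr @ Xtr.T, True))
        cross_ks.append(feat.CovarianceMatrix(Xte @ Xtr.T, False))
    return gp.SourceKernelSet(train_ks, names), cross_ks


def run_cv(
    cohort: Cohort,
    feature_spec: FeatureSpec,
    model_spec: ModelSpec,
    fold_plan: FoldPlan,
) -> CVResult:
    """Full leakage-controlled cross-validation of one model configuration.

    Per fold: (1) FPC loadings and target standardization fitted on the
    training subjects; (2) data-driven masks rebuilt from training
    subjects; (3) features standardized with training statistics; (4) the
    GP (or MKL) fitted on the training kernel; (5) held-out predictions
    scored by Pearson R and RMSE.  Folds with an undefined correlation
    are excluded from the R mean and counted.
    """
    if fold_plan.n_subjects != cohort.n_subjects:
        raise ValueError("fold plan and cohort disagree on subject count")
    records: list[FoldRecord] = []
    all_preds, all_y = [], []
    scores = cohort.scores.values()
    for fold in range(fold_plan.k):
        tr = fold_plan.train_indices(fold)
        te = fold_plan.test_indices(fold)
        try:
            fpc = feat.fpc_scores(scores[tr], scores[te])
            y_tr, y_te, (mu, sd) = feat.standardize_target(
                fpc.train_scores, fpc.test_scores
            )
            mask, regions = _fold_masks(cohort, feature_spec.mask_strategy, tr, y_tr)
            if feature_spec.kind == "voxel_pattern":
                fm_tr = feat.extract_voxel_patterns(
                    [cohort.probs[i] for i in tr], mask
                )
                fm_te = feat.extract_voxel_patterns(
                    [cohort.probs[i] for i in te], mask
                )
            else:
                fm_tr = feat.extract_lesion_load(
                    [cohort.lesion_masks[i] for i in tr], regions,
                    provenance=feature_spec.mask_strategy,
                )
                fm_te = feat.extract_lesion_load(
                    [cohort.lesion_masks[i] for i in te], regions,
                    provenance=feature_spec.mask_strategy,
                )
            # row normalization applies to any multi-column matrix; the
            # single-column lesion-load models are exempt (see standardize)
            fm_tr, fm_te, std = feat.standardize(fm_tr, fm_te)
            if model_spec.kind == "mkl":
                sources, cross = _mkl_sources(fm_tr, fm_te, cohort.atlas)
                model = gp.mkl_fit(sources, y_tr)
                preds, _ = gp.gpr_predict(model, cross)
                params = {
                    "weights": model.source_weights,
                    "noise": model.noise_variance,
                    "alpha": model.alpha,
                }
            else:
                K = feat.linear_kernel(fm_tr)
                model = gp.gpr_fit(K, y_tr)
                cross = feat.CovarianceMatrix(fm_te.values @ fm_tr.values.T, False)
                preds, _ = gp.gpr_predict(model, cross)
                params = {
                    "scale": model.signal_scale,
                    "noise": model.noise_variance,
                    "alpha": model.alpha,
                }
        except Exception as e:
            raise RuntimeError(
                f"fold {fold}, stage {type(e).__name__} in "
                f"{feature_spec.kind}/{feature_spec.mask_strategy}: {e}"
            ) from e
        try:
            r = pearson_r(preds, y_te)
        except (UndefinedCorrelationError, ValueError):
            r = np.nan
        records.append(
            FoldRecord(
                fold=fold,
                test_ids=[cohort.subject_ids[i] for i in te],
                r=r,
                rmse=rmse(preds, y_te),
                n_features=fm_tr.n_features,
                predictions=preds,
                y_test=y_te,
                fpc_loadings=fpc.loadings.copy(),
                target_mean_sd=(mu, sd),
                mask_sha256=_sha(mask.mask),
                standardization_sha256=_sha(np.concatenate([std.mean, std.sd])),
                model_params=params,
            )
        )
        all_preds.append(preds)
        all_y.append(y_te)
    rs = np.array([f.r for f in records])
    n_undef = int(np.isnan(rs).sum())
    try:
        pooled = pearson_r(np.concatenate(all_preds), np.concatenate(all_y))
    except (UndefinedCorrelationError, ValueError):
        pooled = np.nan
    return CVResult(
        folds=records,
        mean_r=float(np.nanmean(rs)) if n_undef < len(rs) else np.nan,
        mean_rmse=float(np.mean([f.rmse for f in records])),
        pooled_r=pooled,
        n_undefined_r=n_undef,
        feature_spec=feature_spec,
        model_spec=model_spec,
        fold_plan=fold_plan,
    )
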