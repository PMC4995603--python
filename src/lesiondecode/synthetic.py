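"""Synthetic stroke cohort generator.

Builds a desk-scale analogue of a lesion-decoding study: a mirrored
anatomical atlas with motor, non-motor and corticospinal-tract (CST)
structures in both hemispheres; per-subject lesion-probability volumes
(soft-edged ellipsoidal blobs of highly variable size and location);
and four correlated upper-limb motor scales (ARAT, grip strength,
Motricity Index, Nine-Hole Peg Test) driven by a latent function of
lesion damage in designated signal regions, with additive noise and
floor/ceiling clipping.

Every operation is deterministic for a fixed seed and shape-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .geometry import left_half, mirror, require_even_lr

SCALE_NAMES = ("ARAT", "GS", "MI", "NHPT")

# Clinical scale bounds and affine maps from the latent damage score g
# (g is ~0 for no damage, down to about -effect_scale for heavy damage in
# signal regions).  NHPT is a timed test: more impairment -> longer time,
# hence the negative slope option is exercised by giving it slope of the
# opposite sign.
DEFAULT_SCALES = {
    # name: (floor, ceiling, slope, intercept)
    "ARAT": (0.0, 57.0, 40.0, 50.0),
    "GS": (0.0, 100.0, 60.0, 80.0),
    "MI": (0.0, 100.0, 70.0, 85.0),
    "NHPT": (0.0, 120.0, -60.0, 30.0),
}


class SizingError(ValueError):
    """Requested structures do not fit the grid."""


class CohortConfigError(ValueError):
    """Invalid cohort simulation request."""


@dataclass(frozen=True)
class Region:
    label: int
    name: str
    hemisphere: str  # "left" | "right"
    category: str  # "motor" | "nonmotor" | "cst"


@dataclass
class AtlasLabelVolume:
    """Integer-labelled grid plus a region table.

    Label 0 is background.  Every left region has a right partner whose
    voxel set is the mid-sagittal reflection of it.
    """

    labels: np.ndarray
    regions: list[Region]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def region_by_label(self, label: int) -> Region:
        for r in self.regions:
            if r.label == label:
                return r
        raise LookupError(f"label {label} not in atlas region table")

    def labels_for(self, selector) -> list[int]:
        """Resolve 'all' / 'motor' / 'nonmotor' / 'cst' or an explicit list."""
        if isinstance(selector, str):
            if selector == "all":
                return [r.label for r in self.regions]
            labs = [r.label for r in self.regions if r.category == selector]
            if not labs:
                raise LookupError(f"selector {selector!r} matches no region")
            return labs
        labs = list(selector)
        known = {r.label for r in self.regions}
        for l in labs:
            if l not in known:
                raise LookupError(f"label {l} not in atlas region table")
        return labs

    def region_mask(self, label: int) -> np.ndarray:
        self.region_by_label(label)
        return self.labels == label


@dataclass
class LesionProbabilityVolume:
    """Per-voxel likelihood in [0, 1] that tissue is part of a lesion."""

    probabilities: np.ndarray
    subject_id: str


@dataclass
class MotorScoreTable:
    """One row per subject, four clinical scales, each with declared bounds."""

    scores: pd.DataFrame  # columns = SCALE_NAMES, index = subject ids
    bounds: dict[str, tuple[float, float]]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.scores.index)

    def values(self) -> np.ndarray:
        return self.scores[list(SCALE_NAMES)].to_numpy(dtype=float)


@dataclass
class SyntheticTruth:
    """Ground truth the generator used; for recovery tests only."""

    beta_map: np.ndarray
    latent_scores: np.ndarray
    noise_sd: float
    scale_transforms: dict[str, tuple[float, float]]  # name -> (slope, intercept)
    seed: int
    signal_regions: list[int] = field(default_factory=list)


def make_atlas(
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    n_region_pairs: int = 10,
    cst_radius: float = 1.6,
    seed: int = 0,
    motor_fraction: float = 0.4,
    region_radius_range: tuple[float, float] | None = None,
) -> AtlasLabelVolume:
    """Build a mirrored synthetic atlas.

    Left-hemisphere structures are placed as spheres claiming unclaimed
    voxels, a tube-shaped CST runs inferior-superior, and the whole left
    labelling is reflected to the right, so mirror symmetry holds by
    construction.  The first ``ceil(motor_fraction * n_region_pairs)``
    pairs are flagged ``motor``, the rest ``nonmotor``.
    """
    require_even_lr(grid_shape)
    nx, ny, nz = grid_shape
    half = nx // 2
    if region_radius_range is None:
        # largest sphere that can sit fully inside one hemisphere, capped at
        # a realistic structure size relative to the default 32^3 grid
        rmax = min(4.5, 0.95 * (half - 1) / 2, 0.95 * (ny - 1) / 2,
                   0.95 * (nz - 1) / 2)
        rmin = min(2.0, 0.6 * rmax)
    else:
        rmin, rmax = region_radius_range
    if rmax < 1 or half < rmax + 1 or ny < 2 * rmax + 2 or nz < 2 * rmax + 2:
        raise SizingError(
            f"grid {grid_shape} too small along its limiting dimension "
            f"(need >= {int(2 * rmax + 2)} voxels beyond the midline split) "
            f"to place regions of radius up to {rmax}"
        )
    rng = np.random.default_rng(seed)
    left = np.zeros((half, ny, nz), dtype=np.int32)
    xs, ys, zs = np.meshgrid(
        np.arange(half), np.arange(ny), np.arange(nz), indexing="ij"
    )

    # CST: a vertical tube in the left hemisphere, label n_region_pairs + 1.
    cst_label = n_region_pairs + 1
    cx = rng.uniform(cst_radius + 1, half - cst_radius - 1)
    cy = rng.uniform(ny * 0.35, ny * 0.65)
    tube = (xs - cx) ** 2 + (ys - cy) ** 2 <= cst_radius**2
    tube &= (zs >= 1) & (zs <= nz - 2)
    left[tube] = cst_label

    n_motor = int(np.ceil(motor_fraction * n_region_pairs))
    for i in range(1, n_region_pairs + 1):
        placed = False
        for _ in range(200):
            r = rng.uniform(rmin, rmax)
            c = np.array(
                [
                    rng.uniform(r, half - 1 - r),
                    rng.uniform(r, ny - 1 - r),
                    rng.uniform(r, nz - 1 - r),
                ]
            )
            ball = (
                (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2
            ) <= r**2
            claim = ball & (left == 0)
            # require the sphere to be mostly unclaimed so regions stay blobby
            if claim.sum() >= max(4, 0.7 * ball.sum()):
                left[claim] = i
                placed = True
                break
        if not placed:
            raise SizingError(
                f"could not place region pair {i} on grid {grid_shape}; "
                "the left-right dimension is the limiting one at this "
                "region count"
            )

    labels = np.zeros(grid_shape, dtype=np.int32)
    labels[:half] = left
    offset = n_region_pairs + 1  # right labels = left label + offset
    mirrored = mirror(np.concatenate([left, np.zeros_like(left)], axis=0))
    labels[mirrored > 0] = mirrored[mirrored > 0] + offset

    regions: list[Region] = []
    for i in range(1, n_region_pairs + 1):
        cat = "motor" if i <= n_motor else "nonmotor"
        regions.append(Region(i, f"region{i:02d}_L", "left", cat))
    regions.append(Region(cst_label, "CST_L", "left", "cst"))
    for i in range(1, n_region_pairs + 1):
        cat = "motor" if i <= n_motor else "nonmotor"
        regions.append(Region(i + offset, f"region{i:02d}_R", "right", cat))
    regions.append(Region(cst_label + offset, "CST_R", "right", "cst"))
    return AtlasLabelVolume(labels=labels, regions=regions)


def simulate_lesion(
    atlas: AtlasLabelVolume,
    size_range: tuple[float, float] = (120.0, 2500.0),
    edge_softness: float = 1.0,
    seed: int = 0,
    unilateral_prob: float = 0.9,
    subject_id: str = "sub",
) -> LesionProbabilityVolume:
    """One soft-edged ellipsoidal lesion blob.

    The blob is centred at a random in-brain voxel; core probabilities sit
    near 1 and decay to 0 over roughly ``edge_softness`` voxels via a
    sigmoid of normalized distance to the ellipsoid surface.  With
    probability ``unilateral_prob`` the blob is confined to the hemisphere
    holding its centre.
    """
    lo, hi = size_range
    if lo < 1:
        raise SizingError("size_range minimum must be >= 1 voxel")
    brain = atlas.brain_mask
    if not brain.any():
        raise SizingError("atlas has no in-brain voxels")
    if hi > brain.size:
        raise SizingError(
            f"size_range maximum {hi} exceeds the grid volume {brain.size}"
        )
    rng = np.random.default_rng(seed)
    target = np.exp(rng.uniform(np.log(lo), np.log(hi)))
    # axis ratios around 1 with product 1, scaled to the target volume
    ratios = np.exp(rng.normal(0.0, 0.25, size=3))
    ratios /= ratios.prod() ** (1 / 3)
    base = (3.0 * target / (4.0 * np.pi)) ** (1 / 3)
    semi = base * ratios

    centres = np.argwhere(brain)
    centre = centres[rng.integers(len(centres))].astype(float)
    nx = atlas.shape[0]
    confine = rng.uniform() < unilateral_prob
    hemi_left = centre[0] < nx // 2

    grids = np.meshgrid(*(np.arange(s) for s in atlas.shape), indexing="ij")
    d = np.sqrt(
        sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi))
    )
    sharp = float(np.mean(semi)) / max(edge_softness, 1e-9)
    probs = expit((1.0 - d) * sharp)
    probs[probs < 1e-4] = 0.0
    if confine:
        if hemi_left:
            probs[nx // 2 :] = 0.0
        else:
            probs[: nx // 2] = 0.0
    return LesionProbabilityVolume(
        probabilities=np.clip(probs, 0.0, 1.0), subject_id=subject_id
    )


def make_functional_mask(
    atlas: AtlasLabelVolume, seed: int = 0, n_motor_regions: int = 2
) -> np.ndarray:
    """Synthetic stand-in for a task-fMRI activation mask.

    A unilateral (left) blob built from a random subset of left motor
    regions plus a one-voxel dilation; the pipeline mirrors it before use,
    as it would a file-based functional mask.
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    left_motor = [
        r.label
        for r in atlas.regions
        if r.hemisphere == "left" and r.category == "motor"
    ]
    take = rng.choice(
        left_motor, size=min(n_motor_regions, len(left_motor)), replace=False
    )
    mask = np.isin(atlas.labels, take)
    return ndimage.binary_dilation(mask, iterations=1)


def latent_damage_scores(
    beta_map: np.ndarray,
    probs: list[LesionProbabilityVolume],
    effect_scale: float,
) -> np.ndarray:
    """Latent score g_i = -effect_scale * sum_v beta(v) p_i(v)."""
    return np.array(
        [-effect_scale * float(np.sum(beta_map * p.probabilities)) for p in probs]
    )


def simulate_cohort(
    atlas: AtlasLabelVolume,
    n_subjects: int,
    signal_regions: list[int] | None = None,
    effect_scale: float = 1.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    beta_heterogeneity: float = 1.0,
    beta_mode: str = "focal",
    focal_radius: float = 2.0,
    size_range: tuple[float, float] = (120.0, 2500.0),
    edge_softness: float = 1.0,
    unilateral_prob: float = 0.9,
    scales: dict[str, tuple[float, float, float, float]] | None = None,
    clip: bool = True,
    lesions: list[LesionProbabilityVolume] | None = None,
) -> tuple[list[LesionProbabilityVolume], MotorScoreTable, SyntheticTruth]:
    """Simulate lesions plus four motor scales from a latent damage score.

    The latent score of subject i is
    ``g_i = -effect_scale * sum_v beta(v) * p_i(v)`` — more damage inside
    signal regions means a lower latent score.  Each clinical scale k is
    ``slope_k * g_i + intercept_k + N(0, noise_sd)``, clipped to that
    scale's [floor, ceiling].  ``beta`` is nonzero only inside
    ``signal_regions``.  With ``beta_mode="focal"`` (default) each signal
    region carries a compact Gaussian bump of scale ``focal_radius``
    around a random in-region locus, so the deficit depends on *where*
    within a region the lesion falls; ``"lognormal"`` spreads weight over
    the whole region.  Either way per-voxel lognormal jitter with log-sd
    ``beta_heterogeneity`` is applied (0 disables it), the map is
    mirror-symmetrized, and weights are normalized to sum to 1 so
    ``effect_scale`` sets the latent range.
    """
    if n_subjects < 2:
        raise CohortConfigError("a cohort needs at least 2 subjects")
    if signal_regions is None:
        signal_regions = atlas.labels_for("motor") + atlas.labels_for("cst")
    if len(signal_regions) == 0:
        raise CohortConfigError("signal_regions must be nonempty")
    atlas.labels_for(signal_regions)  # validates membership
    scales = dict(DEFAULT_SCALES if scales is None else scales)

    rng = np.random.default_rng(seed)
    signal = np.isin(atlas.labels, signal_regions)
    beta = np.zeros(atlas.shape, dtype=float)
    if beta_mode == "focal":
        # one compact critical locus per signal region: a Gaussian bump of
        # scale focal_radius around a random in-region voxel, emulating
        # eloquent subregions / tract bottlenecks whose damage drives the
        # deficit far more than the rest of the region
        grids = np.meshgrid(*(np.arange(s) for s in atlas.shape), indexing="ij")
        for lab in signal_regions:
            vox = np.argwhere(atlas.labels == lab)
            centre = vox[rng.integers(len(vox))]
            d2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
            bump = np.exp(-d2 / (2.0 * focal_radius**2))
            beta[atlas.labels == lab] += bump[atlas.labels == lab]
    elif beta_mode == "lognormal":
        beta[signal] = 1.0
    else:
        raise CohortConfigError(f"unknown beta_mode {beta_mode!r}")
    if beta_heterogeneity > 0:
        beta[signal] *= rng.lognormal(
            0.0, beta_heterogeneity, size=int(signal.sum())
        )
    # mirror-symmetrize: damage to a structure contributes identically from
    # either hemisphere, so the canonical right-flip leaves scores consistent
    beta = 0.5 * (beta + mirror(beta))
    beta[~signal] = 0.0  # keep support inside the signal regions
    total = beta.sum()
    if total > 0:
        beta /= total

    lesion_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    noise = rng.normal(0.0, noise_sd, size=(n_subjects, len(SCALE_NAMES)))

    if lesions is not None:
        if len(lesions) != n_subjects:
            raise CohortConfigError(
                f"{len(lesions)} supplied lesions for {n_subjects} subjects"
            )
        probs = list(lesions)
    else:
        probs = [
            simulate_lesion(
                atlas,
                size_range=size_range,
                edge_softness=edge_softness,
                seed=int(lesion_seeds[i]),
                unilateral_prob=unilateral_prob,
                subject_id=f"sub{i:03d}",
            )
            for i in range(n_subjects)
        ]
    latent = latent_damage_scores(beta, probs, effect_scale)

    table = np.zeros((n_subjects, len(SCALE_NAMES)))
    transforms: dict[str, tuple[float, float]] = {}
    bounds: dict[str, tuple[float, float]] = {}
    for k, name in enumerate(SCALE_NAMES):
        floor, ceiling, slope, intercept = scales[name]
        col = slope * latent + intercept + (noise[:, k] if noise_sd > 0 else 0.0)
        if clip:
            col = np.clip(col, floor, ceiling)
        table[:, k] = col
        transforms[name] = (slope, intercept)
        bounds[name] = (floor, ceiling)

    df = pd.DataFrame(
        table, columns=list(SCALE_NAMES), index=[p.subject_id for p in probs]
    )
    truth = SyntheticTruth(
        beta_map=beta,
        latent_scores=latent,
        noise_sd=noise_sd,
        scale_transforms=transforms,
        seed=seed,
        signal_regions=list(signal_regions),
    )
    return probs, MotorScoreTable(scores=df, bounds=bounds), truth
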