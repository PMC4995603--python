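"""Experiment configuration: strict YAML schema with validation.

Unknown keys are rejected (with a near-miss suggestion) because silent
typos corrupt scientific comparisons; every numeric parameter is range
checked and every referenced path must exist at validation time.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.problems))


_SIMULATE_KEYS = {
    "grid_shape", "n_region_pairs", "n_subjects", "effect_scale", "noise_sd",
    "beta_heterogeneity", "size_range", "edge_softness", "unilateral_prob",
    "signal_regions",
}
_PATH_KEYS = {"volumes_dir", "atlas_volume", "atlas_table", "scores_table",
              "functional_mask"}
_TOP_KEYS = {
    "simulate", "paths", "threshold", "min_cluster", "connectivity",
    "feature_kinds", "mask_strategies", "model", "cv_folds", "seed", "out_dir",
}


@dataclass
class ExperimentConfig:
    simulate: dict | None = None
    paths: dict | None = None
    threshold: float = 0.3
    min_cluster: int = 100
    connectivity: int = 26
    feature_kinds: list = field(default_factory=lambda: ["voxel_pattern", "lesion_load"])
    mask_strategies: list = field(default_factory=lambda: [
        "atlas_all", "cst", "atlas_plus_cst", "motor", "motor_plus_cst",
        "functional", "vlsm", "lesion_union",
    ])
    model: str = "gpr"
    cv_folds: int = 10
    seed: int = 0
    out_dir: str = "results"


def _suggest(key: str, valid) -> str:
    close = difflib.get_close_matches(key, list(valid), n=1)
    hint = f" (did you mean {close[0]!r}?)" if close else ""
    return f"unknown key {key!r}{hint}"


def validate_config(raw: dict) -> ExperimentConfig:
    from .evaluation import FEATURE_KINDS, MASK_STRATEGIES

    problems = []
    for key in raw:
        if key not in _TOP_KEYS:
            problems.append(_suggest(key, _TOP_KEYS))
    cfg = ExperimentConfig()
    sim = raw.get("simulate")
    paths = raw.get("paths")
    if sim is None and paths is None:
        problems.append("one of 'simulate' or 'paths' is required")
    if sim is not None and paths is not None:
        problems.append("'simulate' and 'paths' are mutually exclusive")
    if sim is not None:
        for key in sim:
            if key not in _SIMULATE_KEYS:
                problems.append("simulate: " + _suggest(key, _SIMULATE_KEYS))
        cfg.simulate = dict(sim)
    if paths is not None:
        for key in paths:
            if key not in _PATH_KEYS:
                problems.append("paths: " + _suggest(key, _PATH_KEYS))
        for key in ("volumes_dir", "atlas_volume", "atlas_table", "scores_table"):
            if key not in paths:
                problems.append(f"paths: missing required key {key!r}")
            elif not Path(paths[key]).exists():
                problems.append(f"paths.{key}: {paths[key]!r} does not exist")
        if "functional_mask" in paths and not Path(paths["functional_mask"]).exists():
            problems.append(f"paths.functional_mask: {paths['functional_mask']!r} does not exist")
        cfg.paths = dict(paths)

    def num(key, default, lo, hi, kind=float):
        val = raw.get(key, default)
        try:
            val = kind(val)
        except (TypeError, ValueError):
            problems.append(f"{key}: expected {kind.__name__}, got {val!r}")
            return default
        if not (lo <= val <= hi):
            problems.append(f"{key}: {val} outside allowed range [{lo}, {hi}]")
        return val

    cfg.threshold = num("threshold", cfg.threshold, 0.0, 0.999999)
    cfg.min_cluster = num("min_cluster", cfg.min_cluster, 1, 10**9, int)
    cfg.connectivity = num("connectivity", cfg.connectivity, 6, 26, int)
    if cfg.connectivity not in (6, 18, 26):
        problems.append(f"connectivity: {cfg.connectivity} not one of 6/18/26")
    cfg.cv_folds = num("cv_folds", cfg.cv_folds, 2, 10**6, int)
    cfg.seed = num("seed", cfg.seed, -(2**63), 2**63, int)
    cfg.model = raw.get("model", cfg.model)
    if cfg.model not in ("gpr", "mkl"):
        problems.append(f"model: {cfg.model!r} not one of 'gpr'/'mkl'")
    cfg.feature_kinds = list(raw.get("feature_kinds", cfg.feature_kinds))
    for k in cfg.feature_kinds:
        if k not in FEATURE_KINDS:
            problems.append(f"feature_kinds: {k!r} not one of {FEATURE_KINDS}")
    cfg.mask_strategies = list(raw.get("mask_strategies", cfg.mask_strategies))
    for m in cfg.mask_strategies:
        if m not in MASK_STRATEGIES:
            problems.append(f"mask_strategies: {m!r} not one of {MASK_STRATEGIES}")
    cfg.out_dir = str(raw.get("out_dir", cfg.out_dir))
    if problems:
        raise ConfigError(problems)
    return cfg


def load_config(path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(["configuration file is not a mapping"])
    return validate_config(raw)
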