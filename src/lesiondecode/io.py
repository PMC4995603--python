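"""File formats: NIfTI volumes, TSV tables, structured-text sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import (
    SCALE_NAMES,
    AtlasLabelVolume,
    LesionProbabilityVolume,
    MotorScoreTable,
    Region,
    SyntheticTruth,
)


def _affine(voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_volume(data: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(np.asarray(data), _affine(voxel_size)), str(path))


def load_volume(path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj)


def save_atlas(atlas: AtlasLabelVolume, volume_path, table_path) -> None:
    save_volume(atlas.labels.astype(np.int16), volume_path, atlas.voxel_size)
    pd.DataFrame(
        [(r.label, r.name, r.hemisphere, r.category) for r in atlas.regions],
        columns=["label", "name", "hemisphere", "category"],
    ).to_csv(table_path, sep="\t", index=False)


def load_atlas(volume_path, table_path) -> AtlasLabelVolume:
    labels = load_volume(volume_path).astype(np.int32)
    table = pd.read_csv(table_path, sep="\t")
    regions = [
        Region(int(r.label), str(r.name), str(r.hemisphere), str(r.category))
        for r in table.itertuples()
    ]
    return AtlasLabelVolume(labels=labels, regions=regions)


def save_probability_volume(vol: LesionProbabilityVolume, path) -> None:
    save_volume(vol.probabilities.astype(np.float32), path)


def load_probability_volume(path, subject_id: str) -> LesionProbabilityVolume:
    return LesionProbabilityVolume(
        probabilities=load_volume(path).astype(float), subject_id=subject_id
    )


def save_scores(table: MotorScoreTable, path) -> None:
    df = table.scores.copy()
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t")


def load_scores(path, bounds=None) -> MotorScoreTable:
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    missing = [c for c in SCALE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"score table lacks columns {missing}")
    if df.isna().any().any():
        raise ValueError("score table contains missing values")
    if bounds is None:
        bounds = {c: (-np.inf, np.inf) for c in SCALE_NAMES}
    return MotorScoreTable(scores=df[list(SCALE_NAMES)], bounds=bounds)


def save_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
        "signal_regions": list(map(int, truth.signal_regions)),
        "scale_transforms": {
            k: list(v) for k, v in truth.scale_transforms.items()
        },
        "latent_scores": [float(x) for x in truth.latent_scores],
        "beta_map_nonzero": int((truth.beta_map != 0).sum()),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
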