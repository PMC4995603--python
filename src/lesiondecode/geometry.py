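"""Grid conventions shared by every volume operation.

Volumes are 3-D arrays indexed (x, y, z) with x the left-right axis,
y posterior-anterior and z inferior-superior.  Index 0 along x is the
left-most sagittal slice.  The mid-sagittal plane lies between columns
x = L/2 - 1 and x = L/2 of an even-sized left-right axis, so mirroring
is an exact voxel permutation with no centre voxel.
"""

from __future__ import annotations

import numpy as np

LR_AXIS = 0


class GeometryError(ValueError):
    """Raised when a volume's grid is incompatible with a mirror operation."""


def require_even_lr(shape: tuple[int, ...]) -> None:
    if shape[LR_AXIS] % 2 != 0:
        raise GeometryError(
            f"left-right axis has odd size {shape[LR_AXIS]}; a mid-sagittal "
            "plane between voxel columns requires an even size"
        )


def mirror(volume: np.ndarray) -> np.ndarray:
    """Reflect a volume about the mid-sagittal plane."""
    require_even_lr(volume.shape)
    return np.flip(volume, axis=LR_AXIS)


def left_half(volume: np.ndarray) -> np.ndarray:
    """View of the left hemisphere (x < L/2)."""
    return volume[: volume.shape[LR_AXIS] // 2]


def right_half(volume: np.ndarray) -> np.ndarray:
    return volume[volume.shape[LR_AXIS] // 2 :]
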