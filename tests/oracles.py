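"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities with naive per-pixel loops so they
share no code path with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_gradient(
    d: np.ndarray, pitch: float, reduction: str = "sum"
) -> np.ndarray:
    """Generalized gradient by an explicit double loop over pixels."""
    rows, cols = d.shape
    out = np.zeros((rows, cols))
    for i in range(rows):
        for j in range(cols):
            terms = []
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < rows and 0 <= nj < cols:
                    terms.append(((d[ni, nj] - d[i, j]) / pitch) ** 2)
            total = sum(terms)
            if reduction == "mean":
                total /= len(terms)
            out[i, j] = math.sqrt(total)
    return out


def brute_force_regions(
    ref_pct: np.ndarray,
    grad: np.ndarray,
    dose_thr: float,
    grad_thr: float,
) -> dict[str, np.ndarray]:
    """Per-pixel exhaustive classification into the four regions."""
    names = (
        "high_dose_low_gradient",
        "high_dose_high_gradient",
        "low_dose_low_gradient",
        "low_dose_high_gradient",
    )
    masks = {n: np.zeros(ref_pct.shape, dtype=bool) for n in names}
    for i in range(ref_pct.shape[0]):
        for j in range(ref_pct.shape[1]):
            high = ref_pct[i, j] >= dose_thr
            low_g = grad[i, j] < grad_thr
            name = (
                "high_dose_low_gradient" if high and low_g
                else "high_dose_high_gradient" if high
                else "low_dose_low_gradient" if low_g
                else "low_dose_high_gradient"
            )
            masks[name][i, j] = True
    return masks


def axis_rotation(axis: str, deg: float) -> np.ndarray:
    """Elementary rotation matrix about a fixed axis, hand-written."""
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    raise ValueError(axis)


def compose_setup_rotation(pitch: float, roll: float, yaw: float) -> np.ndarray:
    """R = R_y(yaw) @ R_z(roll) @ R_x(pitch) as a homogeneous 4x4."""
    m = np.eye(4)
    m[:3, :3] = (
        axis_rotation("y", yaw) @ axis_rotation("z", roll) @ axis_rotation("x", pitch)
    )
    return m
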