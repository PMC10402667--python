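"""Rotational setup errors from rigid registration matrices.

Daily CBCT-to-planning-CT matching yields a rigid 4x4 registration matrix.
Couches without rotational correction leave the rotational component of the
setup error uncorrected, so it is extracted and tracked per fraction:

* pitch (theta) — rotation about the patient left-right axis (x),
* roll  (zeta)  — rotation about the superior-inferior axis (z),
* yaw   (phi)   — rotation about the vertical, anterior-posterior axis (y).

The decomposition convention is fixed: extrinsic rotations composed as
R = R_yaw @ R_roll @ R_pitch about the fixed patient axes.  Summaries are
taken over the absolute angles (maximum, mean and population standard
deviation per axis), matching how setup-error tables are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import NotRigidError

__all__ = [
    "RotationRecord",
    "RotationSummary",
    "angles_from_matrix",
    "matrix_from_angles",
    "summarize_rotations",
    "read_matrix_file",
]

# scipy Euler sequence: lowercase = extrinsic, applied left-to-right, so
# 'xzy' composes as R_y(yaw) @ R_z(roll) @ R_x(pitch).
_EULER_SEQ = "xzy"
_RIGID_TOL = 1e-6


@dataclass(frozen=True)
class RotationRecord:
    """Per-fraction rotational setup error, degrees."""

    fraction_index: int
    pitch_deg: float
    roll_deg: float
    yaw_deg: float

    def __post_init__(self) -> None:
        angles = (self.pitch_deg, self.roll_deg, self.yaw_deg)
        if not all(np.isfinite(angles)):
            raise ValueError("angles must be finite")
        if any(abs(a) >= 90 for a in angles):
            raise ValueError("setup rotations must satisfy |angle| < 90 deg")


@dataclass(frozen=True)
class RotationSummary:
    """Per-axis |angle| maximum, mean and standard deviation, degrees."""

    max_deg: dict[str, float]
    mean_deg: dict[str, float]
    std_deg: dict[str, float]


def _check_rigid(block: np.ndarray) -> None:
    if block.shape != (3, 3):
        raise NotRigidError("rotation block must be 3x3")
    if not np.allclose(block @ block.T, np.eye(3), atol=_RIGID_TOL):
        raise NotRigidError("not a rigid registration: block not orthonormal")
    if abs(np.linalg.det(block) - 1.0) > _RIGID_TOL:
        raise NotRigidError("not a rigid registration: determinant != 1")


def angles_from_matrix(
    matrix: np.ndarray, *, fraction_index: int = 1
) -> RotationRecord:
    """Decompose a 4x4 homogeneous rigid transform into pitch/roll/yaw.

    The upper-left 3x3 block must be a proper rotation (orthonormal,
    determinant 1 within 1e-6); translation is ignored.
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix, got {m.shape}")
    block = m[:3, :3]
    _check_rigid(block)
    pitch, roll, yaw = Rotation.from_matrix(block).as_euler(
        _EULER_SEQ, degrees=True
    )
    return RotationRecord(fraction_index, float(pitch), float(roll), float(yaw))


def matrix_from_angles(
    pitch_deg: float, roll_deg: float, yaw_deg: float
) -> np.ndarray:
    """Build the 4x4 homogeneous matrix for the package's convention.

    Inverse of :func:`angles_from_matrix` (zero translation).
    """
    m = np.eye(4)
    m[:3, :3] = Rotation.from_euler(
        _EULER_SEQ, [pitch_deg, roll_deg, yaw_deg], degrees=True
    ).as_matrix()
    return m


def read_matrix_file(path) -> np.ndarray:
    """Read a plain-text whitespace-delimited 4x4 registration matrix."""
    m = np.loadtxt(path)
    if m.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix, got {m.shape}")
    return m


def summarize_rotations(records: Sequence[RotationRecord]) -> RotationSummary:
    """Absolute-angle max / mean / population std per axis over a series."""
    if not records:
        raise ValueError("no rotation records to summarize")
    per_axis = {
        "pitch": np.abs([r.pitch_deg for r in records]),
        "roll": np.abs([r.roll_deg for r in records]),
        "yaw": np.abs([r.yaw_deg for r in records]),
    }
    return RotationSummary(
        max_deg={k: float(v.max()) for k, v in per_axis.items()},
        mean_deg={k: float(v.mean()) for k, v in per_axis.items()},
        std_deg={k: float(v.std(ddof=0)) for k, v in per_axis.items()},
    )
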