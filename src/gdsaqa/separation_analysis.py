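"""Body-separation change from the daily CBCT isocenter slice.

Head-and-neck patients commonly lose weight over a 30-fraction course; the
shrinking body contour reduces attenuation and drives the transit EPID
signal (and GDSA_mu) up.  This module extracts the body mask from the axial
CT slice through the treatment isocenter, measures the anterior-posterior
and lateral extents, and summarizes their change against the reference
fraction as

    Δd_AP,n  = |d_AP,ref  - d_AP,n |            (cm)
    Δd_lat,n = |d_lat,ref - d_lat,n|            (cm)
    Δd_eff,n = sqrt(Δd_lat,n · Δd_AP,n)         (cm)

The effective separation change diameter Δd_eff is the geometric mean of
the two axis changes; it is zero whenever either axis is unchanged, and a
change above 1 cm is flagged as warranting review.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .exceptions import NoBodyFoundError

__all__ = [
    "ContourSlice",
    "SeparationRecord",
    "extract_body_mask",
    "measure_separations",
    "separation_change",
    "effective_separation_change",
    "flag_separation",
    "analyze_contour_series",
    "DEFAULT_HU_THRESHOLD",
    "DEFAULT_SEPARATION_FLAG_CM",
]

DEFAULT_HU_THRESHOLD = -300.0
DEFAULT_SEPARATION_FLAG_CM = 1.0


@dataclass(frozen=True)
class ContourSlice:
    """Binary body mask on the axial isocenter slice.

    Rows run anterior -> posterior, columns patient-left -> right.
    """

    mask: np.ndarray
    row_spacing_mm: float = 1.0
    col_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or not m.any():
            raise ValueError("mask must be 2-D with at least one body pixel")
        if self.row_spacing_mm <= 0 or self.col_spacing_mm <= 0:
            raise ValueError("pixel spacings must be positive")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class SeparationRecord:
    """Per-fraction separations and their change against the reference."""

    fraction_index: int
    d_ap_cm: float
    d_lat_cm: float
    delta_ap_cm: float
    delta_lat_cm: float
    delta_eff_cm: float
    flagged: bool


def extract_body_mask(
    ct_slice: np.ndarray,
    hu_threshold: float = DEFAULT_HU_THRESHOLD,
    *,
    row_spacing_mm: float = 1.0,
    col_spacing_mm: float = 1.0,
) -> ContourSlice:
    """Threshold a CT slice at the body-surface HU and clean the mask.

    Keeps the largest 4-connected component above ``hu_threshold`` (couch
    and immobilization artifacts are smaller, disconnected blobs) and fills
    internal air cavities so the extents describe the external contour.
    """
    hu = np.asarray(ct_slice, dtype=float)
    if hu.ndim != 2 or hu.size == 0:
        raise ValueError("CT slice must be a non-empty 2-D array")
    above = hu > hu_threshold
    if not above.any():
        raise NoBodyFoundError(
            f"no body found: no pixel above {hu_threshold} HU"
        )
    labels = measure.label(above, connectivity=1)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    body = ndimage.binary_fill_holes(labels == largest)
    return ContourSlice(body, row_spacing_mm, col_spacing_mm)


def measure_separations(contour: ContourSlice) -> tuple[float, float]:
    """A-P and lateral extents of the body mask, in cm.

    Extents are bounding-box spans of the mask along the fixed image axes
    (pixel count x spacing), not chords through a specific point.
    """
    rows, cols = np.nonzero(contour.mask)
    d_ap_cm = (rows.max() - rows.min() + 1) * contour.row_spacing_mm / 10.0
    d_lat_cm = (cols.max() - cols.min() + 1) * contour.col_spacing_mm / 10.0
    return float(d_ap_cm), float(d_lat_cm)


def separation_change(
    ref: tuple[float, float], frac: tuple[float, float]
) -> tuple[float, float]:
    """Absolute per-axis change (Δd_AP, Δd_lat) in cm against the reference."""
    if min(*ref, *frac) < 0:
        raise ValueError("separations must be non-negative")
    return abs(ref[0] - frac[0]), abs(ref[1] - frac[1])


def effective_separation_change(delta_ap_cm: float, delta_lat_cm: float) -> float:
    """Effective separation change diameter: sqrt(Δd_lat x Δd_AP), cm."""
    if delta_ap_cm < 0 or delta_lat_cm < 0:
        raise ValueError("separation changes must be non-negative")
    return float(np.sqrt(delta_lat_cm * delta_ap_cm))


def flag_separation(
    delta_eff_cm: float, threshold_cm: float = DEFAULT_SEPARATION_FLAG_CM
) -> bool:
    """True when the effective change strictly exceeds the threshold."""
    if delta_eff_cm < 0:
        raise ValueError("delta_eff_cm must be non-negative")
    return delta_eff_cm > threshold_cm


def analyze_contour_series(
    contours: Sequence[ContourSlice],
    fraction_indices: Sequence[int] | None = None,
    *,
    reference_position: int = 0,
    threshold_cm: float = DEFAULT_SEPARATION_FLAG_CM,
) -> list[SeparationRecord]:
    """Per-fraction separation records for an ordered contour series."""
    if not contours:
        raise ValueError("empty contour series")
    if fraction_indices is None:
        fraction_indices = list(range(1, len(contours) + 1))
    ref = measure_separations(contours[reference_position])
    records = []
    for idx, contour in zip(fraction_indices, contours):
        d = measure_separations(contour)
        dap, dlat = separation_change(ref, d)
        deff = effective_separation_change(dap, dlat)
        records.append(
            SeparationRecord(
                fraction_index=idx,
                d_ap_cm=d[0],
                d_lat_cm=d[1],
                delta_ap_cm=dap,
                delta_lat_cm=dlat,
                delta_eff_cm=deff,
                flagged=flag_separation(deff, threshold_cm),
            )
        )
    return records
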