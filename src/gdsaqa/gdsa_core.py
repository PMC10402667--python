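"""The gradient-dose-segmented-analysis (GDSA) statistic.

The method compares each treatment fraction's composite transit EPID image
against the first fraction of the course (the reference).  The reference is
normalized to percent of its own maximum; a generalized dose-gradient map is
computed from it; pixels are segmented by a dose threshold (default 5% of
the reference maximum) and a gradient threshold (default 3 %/mm) into four
regions.  The per-fraction statistic GDSA_mu is the mean of the signed dose
difference — 100 x (comparison - reference) / max(reference) — over the
high-dose low-gradient region, a surrogate for change in the mean target
dose.  Fractions with |GDSA_mu| at or above a 3% tolerance are flagged.

The generalized gradient at pixel i is

    G_i = sqrt( sum_j (Δd_ij / Δx_ij)^2 )

over the four nearest neighbours j, with Δx_ij the pixel pitch; border
pixels sum over their existing neighbours only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .epid_io import CompositeImage, PatientSeries
from .exceptions import (
    DegenerateRoiError,
    EmptyDeliveryError,
    GeometryMismatchError,
)

__all__ = [
    "GradientMap",
    "RegionMasks",
    "GdsaResult",
    "normalize_to_percent",
    "gradient_map",
    "segment_regions",
    "dose_difference_percent",
    "gdsa_statistic",
    "analyze_series",
    "DEFAULT_DOSE_THRESHOLD_PCT",
    "DEFAULT_GRADIENT_THRESHOLD",
    "DEFAULT_FLAG_THRESHOLD_PCT",
]

DEFAULT_DOSE_THRESHOLD_PCT = 5.0
DEFAULT_GRADIENT_THRESHOLD = 3.0  # %/mm
DEFAULT_FLAG_THRESHOLD_PCT = 3.0


@dataclass(frozen=True)
class GradientMap:
    """Generalized dose-gradient magnitude, %/mm, per pixel."""

    values: np.ndarray
    pixel_pitch_mm: float


@dataclass(frozen=True)
class RegionMasks:
    """The four dose/gradient segmentation masks.

    High dose means reference dose >= ``dose_threshold_pct`` (inclusive);
    low gradient means gradient < ``gradient_threshold_pct_per_mm``
    (exclusive).  The four masks are pairwise disjoint and cover the image.
    """

    high_dose_low_gradient: np.ndarray
    high_dose_high_gradient: np.ndarray
    low_dose_low_gradient: np.ndarray
    low_dose_high_gradient: np.ndarray
    dose_threshold_pct: float = DEFAULT_DOSE_THRESHOLD_PCT
    gradient_threshold_pct_per_mm: float = DEFAULT_GRADIENT_THRESHOLD


@dataclass(frozen=True)
class GdsaResult:
    """Per-fraction GDSA outcome.

    ``note`` is non-None for fractions that could not be analyzed (geometry
    mismatch against the reference); their statistics are NaN.
    """

    fraction_index: int
    gdsa_mean_pct: float
    gdsa_std_pct: float
    roi_pixel_count: int
    flagged: bool
    note: str | None = None


def normalize_to_percent(image: CompositeImage | np.ndarray) -> np.ndarray:
    """Rescale a composite to percent of its own maximum (max -> 100)."""
    pixels = image.pixels if isinstance(image, CompositeImage) else np.asarray(image, float)
    peak = pixels.max() if pixels.size else 0.0
    if not peak > 0:
        raise EmptyDeliveryError("empty delivery: composite maximum is not positive")
    return 100.0 * pixels / peak


def gradient_map(
    reference_pct: np.ndarray,
    pixel_pitch_mm: float,
    *,
    reduction: Literal["sum", "mean"] = "sum",
) -> GradientMap:
    """Generalized gradient of the normalized reference, in %/mm.

    Root of the sum (default) or mean of squared per-neighbour gradients
    (Δd/Δx)² over the four nearest neighbours; border pixels use only the
    neighbours that exist, with no padding.
    """
    d = np.asarray(reference_pct, dtype=float)
    if d.ndim != 2 or min(d.shape) < 2:
        raise ValueError("gradient map needs a 2-D array of at least 2x2")
    if not pixel_pitch_mm > 0:
        raise ValueError("pixel pitch must be positive")

    g2 = np.zeros_like(d)
    count = np.zeros_like(d)
    # vertical neighbour pairs (rows i, i+1)
    dv = (d[1:, :] - d[:-1, :]) / pixel_pitch_mm
    g2[1:, :] += dv**2
    g2[:-1, :] += dv**2
    count[1:, :] += 1
    count[:-1, :] += 1
    # horizontal neighbour pairs (columns j, j+1)
    dh = (d[:, 1:] - d[:, :-1]) / pixel_pitch_mm
    g2[:, 1:] += dh**2
    g2[:, :-1] += dh**2
    count[:, 1:] += 1
    count[:, :-1] += 1

    if reduction == "mean":
        g2 = g2 / count
    elif reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return GradientMap(values=np.sqrt(g2), pixel_pitch_mm=pixel_pitch_mm)


def segment_regions(
    reference_pct: np.ndarray,
    grad: GradientMap,
    dose_threshold_pct: float = DEFAULT_DOSE_THRESHOLD_PCT,
    gradient_threshold: float = DEFAULT_GRADIENT_THRESHOLD,
) -> RegionMasks:
    """Segment pixels by the dose and gradient thresholds into four regions."""
    ref = np.asarray(reference_pct, dtype=float)
    if ref.shape != grad.values.shape:
        raise GeometryMismatchError(
            "reference and gradient map dimensions differ"
        )
    high_dose = ref >= dose_threshold_pct
    low_grad = grad.values < gradient_threshold
    return RegionMasks(
        high_dose_low_gradient=high_dose & low_grad,
        high_dose_high_gradient=high_dose & ~low_grad,
        low_dose_low_gradient=~high_dose & low_grad,
        low_dose_high_gradient=~high_dose & ~low_grad,
        dose_threshold_pct=dose_threshold_pct,
        gradient_threshold_pct_per_mm=gradient_threshold,
    )


def dose_difference_percent(
    reference: CompositeImage, comparison: CompositeImage
) -> np.ndarray:
    """Signed pixel difference, percent of the reference maximum.

    Positive where the comparison fraction is hotter than the reference
    (e.g. increased transmission after patient weight loss).
    """
    if reference.pixels.shape != comparison.pixels.shape or not math.isclose(
        reference.pixel_pitch_mm, comparison.pixel_pitch_mm, rel_tol=1e-9
    ):
        raise GeometryMismatchError(
            "reference and comparison composites differ in geometry"
        )
    peak = reference.pixels.max()
    if not peak > 0:
        raise EmptyDeliveryError("reference maximum is not positive")
    return 100.0 * (comparison.pixels - reference.pixels) / peak


def gdsa_statistic(
    diff_pct: np.ndarray,
    masks: RegionMasks,
    *,
    fraction_index: int = 1,
    flag_threshold_pct: float = DEFAULT_FLAG_THRESHOLD_PCT,
    std_ddof: int = 0,
) -> GdsaResult:
    """GDSA_mu and its pixel standard deviation over the high-dose
    low-gradient region.

    The standard deviation is the population form (``std_ddof=0``) of the
    same pixel distribution whose mean is GDSA_mu.
    """
    roi = masks.high_dose_low_gradient
    n = int(roi.sum())
    if n == 0:
        raise DegenerateRoiError("no high-dose low-gradient region")
    vals = np.asarray(diff_pct, dtype=float)[roi]
    mean = float(vals.mean())
    std = float(vals.std(ddof=std_ddof))
    return GdsaResult(
        fraction_index=fraction_index,
        gdsa_mean_pct=mean,
        gdsa_std_pct=std,
        roi_pixel_count=n,
        flagged=abs(mean) >= flag_threshold_pct,
    )


def analyze_series(
    series: PatientSeries,
    flag_threshold_pct: float = DEFAULT_FLAG_THRESHOLD_PCT,
    *,
    dose_threshold_pct: float = DEFAULT_DOSE_THRESHOLD_PCT,
    gradient_threshold: float = DEFAULT_GRADIENT_THRESHOLD,
    std_ddof: int = 0,
) -> list[GdsaResult]:
    """Run the GDSA over a whole treatment course.

    The gradient map and region masks are computed once from the reference
    fraction and reused for every comparison.  The reference fraction itself
    yields the trivial (0, 0) result so time-series plots stay continuous.
    At each fraction listed in ``series.rebaseline_fractions`` (a replan) the
    reference is reset to that fraction's composite.  Fractions whose
    geometry does not match the current reference are reported with NaN
    statistics and a note, not raised.
    """
    results: list[GdsaResult] = []
    reference: CompositeImage | None = None
    masks: RegionMasks | None = None
    for comp in series.fractions:
        is_ref = comp.fraction_index == series.reference_fraction or (
            comp.fraction_index in series.rebaseline_fractions
        )
        if is_ref or reference is None:
            reference = comp
            ref_pct = normalize_to_percent(reference)
            grad = gradient_map(ref_pct, reference.pixel_pitch_mm)
            masks = segment_regions(
                ref_pct, grad, dose_threshold_pct, gradient_threshold
            )
            n_roi = int(masks.high_dose_low_gradient.sum())
            if n_roi == 0:
                raise DegenerateRoiError(
                    "reference fraction has no high-dose low-gradient region"
                )
            results.append(
                GdsaResult(comp.fraction_index, 0.0, 0.0, n_roi, False)
            )
            continue
        try:
            diff = dose_difference_percent(reference, comp)
        except GeometryMismatchError as exc:
            results.append(
                GdsaResult(
                    comp.fraction_index,
                    math.nan,
                    math.nan,
                    0,
                    False,
                    note=str(exc),
                )
            )
            continue
        res = gdsa_statistic(
            diff,
            masks,
            fraction_index=comp.fraction_index,
            flag_threshold_pct=flag_threshold_pct,
            std_ddof=std_ddof,
        )
        results.append(res)
    return results
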