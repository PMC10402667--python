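"""Synthetic patients with known ground truth for every pipeline stage.

No public transit-EPID dataset accompanies the method, so validation runs on
synthetic courses whose generating parameters are known exactly:

* **Composites** — a flat high-dose plateau at D0 with a smooth Gaussian
  penumbra; the plateau guarantees a non-empty high-dose low-gradient region
  at the default thresholds.  Weight loss is modelled as a per-fraction
  multiplicative transmission gain (1 + alpha_n) applied to the reference,
  optionally graded across the field, plus optional additive Gaussian noise
  in CU.  Under zero noise the pipeline statistic has the exact closed form
  GDSA_mu = 100 * alpha_n * mean(reference over ROI) / max(reference).
* **Contours** — axis-aligned elliptical body masks whose semi-axes shrink
  by a fixed decrement per fraction, emulating gradual weight loss.
* **Registrations** — 4x4 rigid matrices composed from per-fraction true
  pitch/roll/yaw (linear drift plus seeded jitter) in the package's own
  rotation convention.

Everything is reproducible bit-for-bit from ``ScenarioConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .epid_io import CompositeImage, PatientSeries
from .gdsa_core import (
    DEFAULT_DOSE_THRESHOLD_PCT,
    DEFAULT_GRADIENT_THRESHOLD,
    RegionMasks,
    gradient_map,
    normalize_to_percent,
    segment_regions,
)
from .rotation_analysis import matrix_from_angles
from .separation_analysis import ContourSlice

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "SCENARIOS",
    "make_reference_composite",
    "make_comparison_composite",
    "make_contour_series",
    "make_registration_series",
    "generate_patient",
    "reference_roi_mask",
    "expected_gdsa_mean",
]

SCENARIOS = ("stable", "weight_loss", "replan", "rotation_drift", "mixed")


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic treatment course.

    Defaults describe a typical head-and-neck VMAT course: 30 fractions,
    256x256 composites at the 0.336 mm panel pitch, a plateau covering 40%
    of the field with a 3 mm penumbra, transmission gain 0.002/fraction
    (GDSA_mu crosses the 3% tolerance late in the course), elliptical neck
    contours of 20 cm A-P by 24 cm lateral shrinking 1 mm per fraction, and
    sub-degree-per-fraction rotational drift within the few-degree setup
    regime.  Noise defaults to zero so closed-form checks are exact.
    """

    scenario: Literal[
        "stable", "weight_loss", "replan", "rotation_drift", "mixed"
    ] = "stable"
    n_fractions: int = 30
    image_size: int = 256
    pixel_pitch_mm: float = 0.336
    plateau_fraction: float = 0.4
    penumbra_sigma_mm: float = 3.0
    d0_cu: float = 2.0
    per_fraction_transmission_gain: float = 0.002
    gain_ramp: float = 0.0
    contour_axes_cm: tuple[float, float] = (20.0, 24.0)  # (A-P, lateral)
    axis_shrink_cm_per_fraction: tuple[float, float] = (0.1, 0.1)
    contour_spacing_mm: float = 1.0
    rotation_drift_deg_per_fraction: tuple[float, float, float] = (
        0.1,
        0.05,
        0.05,
    )
    rotation_jitter_sd_deg: float = 0.0
    noise_sd_pct: float = 0.0
    replan_at: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_fractions < 1 or self.image_size < 4:
            raise ValueError("n_fractions and image_size must be positive")
        if not (0 < self.plateau_fraction < 1):
            raise ValueError("plateau_fraction must lie in (0, 1)")
        if self.noise_sd_pct < 0 or self.rotation_jitter_sd_deg < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if self.d0_cu <= 0 or self.pixel_pitch_mm <= 0:
            raise ValueError("d0_cu and pixel_pitch_mm must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Per-fraction true generating parameters, aligned with the fractions."""

    alpha: np.ndarray  # true transmission gain per fraction
    contour_axes_cm: np.ndarray  # (n, 2) true (A-P, lateral) diameters
    angles_deg: np.ndarray  # (n, 3) true (pitch, roll, yaw)
    rebaseline_fractions: tuple[int, ...] = ()


# ---------------------------------------------------------------------------
# composites


def _plateau_distance_mm(config: ScenarioConfig) -> np.ndarray:
    """Euclidean distance (mm) of each pixel outside the plateau rectangle."""
    n = config.image_size
    coords = (np.arange(n) - (n - 1) / 2.0) * config.pixel_pitch_mm
    half = config.plateau_fraction * n * config.pixel_pitch_mm / 2.0
    dy = np.maximum(np.abs(coords)[:, None] - half, 0.0)
    dx = np.maximum(np.abs(coords)[None, :] - half, 0.0)
    return np.hypot(dy, dx)


def make_reference_composite(
    config: ScenarioConfig,
    *,
    rng: np.random.Generator | None = None,
    fraction_index: int = 1,
) -> CompositeImage:
    """Reference field: plateau at D0 with a Gaussian-penumbra falloff.

    Pixels inside the centered plateau rectangle are exactly D0; outside,
    the dose decays as exp(-d^2 / 2 sigma^2) of the distance d beyond the
    plateau edge.  The flat interior has identically zero gradient, so the
    high-dose low-gradient region is non-empty at the default thresholds.
    """
    plateau_px = config.plateau_fraction * config.image_size
    if plateau_px < 3:
        raise ValueError(
            "plateau too small to contain a low-gradient pixel; "
            "increase plateau_fraction or image_size"
        )
    d = _plateau_distance_mm(config)
    pixels = config.d0_cu * np.exp(-0.5 * (d / config.penumbra_sigma_mm) ** 2)
    if config.noise_sd_pct > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        noise = rng.normal(
            0.0, config.noise_sd_pct / 100.0 * config.d0_cu, pixels.shape
        )
        pixels = np.clip(pixels + noise, 0.0, None)
    return CompositeImage(
        pixels=pixels,
        pixel_pitch_mm=config.pixel_pitch_mm,
        fraction_index=fraction_index,
        n_arcs=1,
    )


def make_comparison_composite(
    reference: CompositeImage,
    alpha_n: float,
    config: ScenarioConfig,
    *,
    rng: np.random.Generator | None = None,
    fraction_index: int = 2,
) -> CompositeImage:
    """Comparison fraction: reference scaled by (1 + alpha_n) plus noise.

    ``gain_ramp`` grades the gain linearly across columns as
    alpha_n * (1 + gain_ramp * u), u in [-1, 1], producing a nonzero ROI
    standard deviation like real fraction-to-fraction variation.
    """
    if alpha_n <= -1:
        raise ValueError("alpha_n must exceed -1")
    n_cols = reference.pixels.shape[1]
    u = np.linspace(-1.0, 1.0, n_cols)[None, :]
    gain = 1.0 + alpha_n * (1.0 + config.gain_ramp * u)
    pixels = reference.pixels * gain
    if config.noise_sd_pct > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed + fraction_index)
        noise = rng.normal(
            0.0, config.noise_sd_pct / 100.0 * config.d0_cu, pixels.shape
        )
        pixels = np.clip(pixels + noise, 0.0, None)
    return CompositeImage(
        pixels=pixels,
        pixel_pitch_mm=reference.pixel_pitch_mm,
        fraction_index=fraction_index,
        n_arcs=reference.n_arcs,
    )


def reference_roi_mask(
    reference: CompositeImage,
    *,
    dose_threshold_pct: float = DEFAULT_DOSE_THRESHOLD_PCT,
    gradient_threshold: float = DEFAULT_GRADIENT_THRESHOLD,
) -> RegionMasks:
    """Segment a generated reference exactly as the analysis pipeline does."""
    ref_pct = normalize_to_percent(reference)
    grad = gradient_map(ref_pct, reference.pixel_pitch_mm)
    return segment_regions(ref_pct, grad, dose_threshold_pct, gradient_threshold)


def expected_gdsa_mean(reference: CompositeImage, alpha_n: float) -> float:
    """Closed-form GDSA_mu for a noise-free uniform gain (1 + alpha_n).

    With comparison = (1 + alpha) * reference, the signed difference map is
    100 * alpha * reference / max(reference), so its ROI mean is
    100 * alpha * mean(reference over ROI) / max(reference).
    """
    roi = reference_roi_mask(reference).high_dose_low_gradient
    ref = reference.pixels
    return float(100.0 * alpha_n * ref[roi].mean() / ref.max())


# ---------------------------------------------------------------------------
# ground-truth schedules


def _alpha_schedule(config: ScenarioConfig) -> tuple[np.ndarray, tuple[int, ...]]:
    n = config.n_fractions
    alpha = np.zeros(n)
    rebaseline: tuple[int, ...] = ()
    if config.scenario in ("weight_loss", "mixed"):
        alpha = config.per_fraction_transmission_gain * np.arange(n)
    elif config.scenario == "replan":
        at = config.replan_at or (2 * n) // 3 + 1
        if not 1 < at <= n:
            raise ValueError("replan_at must lie within the course")
        alpha[: at - 1] = config.per_fraction_transmission_gain * np.arange(at - 1)
        alpha[at - 1 :] = config.per_fraction_transmission_gain * np.arange(
            n - at + 1
        )
        rebaseline = (at,)
    return alpha, rebaseline


def _axes_schedule(config: ScenarioConfig) -> np.ndarray:
    n = config.n_fractions
    base = np.asarray(config.contour_axes_cm, dtype=float)
    if config.scenario in ("weight_loss", "replan", "mixed"):
        shrink = np.asarray(config.axis_shrink_cm_per_fraction, dtype=float)
    else:
        shrink = np.zeros(2)
    axes = base[None, :] - np.arange(n)[:, None] * shrink[None, :]
    if np.any(axes <= 0):
        raise ValueError("shrink schedule drives a contour axis non-positive")
    return axes


def _angle_schedule(
    config: ScenarioConfig, rng: np.random.Generator
) -> np.ndarray:
    n = config.n_fractions
    if config.scenario in ("rotation_drift", "mixed"):
        drift = np.asarray(config.rotation_drift_deg_per_fraction, dtype=float)
    else:
        drift = np.zeros(3)
    angles = np.arange(n)[:, None] * drift[None, :]
    if config.rotation_jitter_sd_deg > 0:
        angles = angles + rng.normal(
            0.0, config.rotation_jitter_sd_deg, angles.shape
        )
    return angles


# ---------------------------------------------------------------------------
# series generators


def make_contour_series(config: ScenarioConfig) -> list[ContourSlice]:
    """Elliptical body masks with the configured per-fraction shrinkage.

    The grid (spacing ``contour_spacing_mm``) is sized from the unshrunk
    axes plus a margin and kept fixed across fractions.
    """
    axes_cm = _axes_schedule(config)
    sp = config.contour_spacing_mm
    n_rows = int(np.ceil(axes_cm[0, 0] * 10 / sp)) + 21
    n_cols = int(np.ceil(axes_cm[0, 1] * 10 / sp)) + 21
    y = (np.arange(n_rows) - (n_rows - 1) / 2.0) * sp
    x = (np.arange(n_cols) - (n_cols - 1) / 2.0) * sp
    slices = []
    for ap_cm, lat_cm in axes_cm:
        a = ap_cm * 10 / 2.0  # semi-axis, mm, along rows (A-P)
        b = lat_cm * 10 / 2.0  # semi-axis, mm, along columns (lateral)
        mask = (y[:, None] / a) ** 2 + (x[None, :] / b) ** 2 <= 1.0
        slices.append(ContourSlice(mask, sp, sp))
    return slices


def make_registration_series(
    config: ScenarioConfig, *, rng: np.random.Generator | None = None
) -> tuple[list[np.ndarray], np.ndarray]:
    """Rigid 4x4 matrices from the true per-fraction angle schedule.

    Returns the matrices and the (n, 3) true (pitch, roll, yaw) array.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    angles = _angle_schedule(config, rng)
    matrices = [matrix_from_angles(*row) for row in angles]
    return matrices, angles


def generate_patient(
    config: ScenarioConfig,
    *,
    patient_id: str = "SYN-001",
    site_label: str = "synthetic",
) -> tuple[PatientSeries, GroundTruth]:
    """Generate a full synthetic course: composites, contours, registrations.

    The ``replan`` scenario resets the reference composite (and the gain
    baseline) at ``replan_at``; the re-baseline fraction is recorded both in
    the series and in the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    # independent stream for rotations so image noise draws cannot shift them
    rot_rng = np.random.default_rng([config.seed, 17])
    alpha, rebaseline = _alpha_schedule(config)
    angles = _angle_schedule(config, rot_rng)
    reference = make_reference_composite(config, rng=rng, fraction_index=1)
    composites = [reference]
    current_ref = reference
    for i in range(1, config.n_fractions):
        frac_idx = i + 1
        if frac_idx in rebaseline:
            # a new plan: regenerate the delivery and re-anchor the gain
            current_ref = make_reference_composite(
                config, rng=rng, fraction_index=frac_idx
            )
            composites.append(current_ref)
            continue
        composites.append(
            make_comparison_composite(
                current_ref,
                float(alpha[i]),
                config,
                rng=rng,
                fraction_index=frac_idx,
            )
        )
    series = PatientSeries(
        patient_id=patient_id,
        site_label=site_label,
        fractions=composites,
        reference_fraction=1,
        rebaseline_fractions=rebaseline,
        contours=make_contour_series(config),
        registrations=[matrix_from_angles(*row) for row in angles],
    )
    truth = GroundTruth(
        alpha=alpha,
        contour_axes_cm=_axes_schedule(config),
        angles_deg=angles,
        rebaseline_fractions=rebaseline,
    )
    return series, truth
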