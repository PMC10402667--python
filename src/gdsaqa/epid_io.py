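"""Reading, compositing and tabulating transit EPID images.

A megavoltage imaging panel mounted opposite the treatment beam integrates
the transit signal during each VMAT arc and exports one image per arc in
Calibrated Units (CU; 1 CU delivers the same panel signal as 1 MU under a
reference 10x10 cm field).  This module reads those per-arc images (DICOM
RT Image, or a portable array format used for synthetic fixtures), sums the
arcs of a treatment fraction into a :class:`CompositeImage`, and writes the
per-fraction results table shared by the analysis modules.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, RTImageStorage, generate_uid

from .exceptions import (
    EpidReadError,
    GeometryMismatchError,
    MissingMetadataError,
)

__all__ = [
    "EpidImage",
    "CompositeImage",
    "PatientSeries",
    "FractionRecord",
    "read_epid_image",
    "write_epid_dicom",
    "write_epid_array",
    "build_composite",
    "derive_pixel_pitch",
    "project_to_isocenter",
    "write_results_table",
    "read_results_table",
]

#: Relative tolerance used when comparing pixel pitches of images that must
#: share geometry (floating-point metadata round-trips through DICOM).
_PITCH_RTOL = 1e-9


@dataclass(frozen=True)
class EpidImage:
    """One per-arc transit EPID image in Calibrated Units."""

    pixels: np.ndarray
    pixel_pitch_mm: float
    fraction_index: int
    arc_label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise EpidReadError(f"pixel data must be 2-D, got {px.ndim}-D")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel values must be finite")
        if np.any(px < 0):
            raise ValueError("CU pixel values must be non-negative")
        if not self.pixel_pitch_mm > 0:
            raise ValueError("pixel_pitch_mm must be positive")
        if self.fraction_index < 1:
            raise ValueError("fraction_index must be a positive integer")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class CompositeImage:
    """Pixel-wise sum of all arc images of one treatment fraction."""

    pixels: np.ndarray
    pixel_pitch_mm: float
    fraction_index: int
    n_arcs: int = 1

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("composite pixel data must be 2-D")
        if not self.pixel_pitch_mm > 0:
            raise ValueError("pixel_pitch_mm must be positive")
        if self.n_arcs < 1:
            raise ValueError("n_arcs must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class PatientSeries:
    """Ordered per-fraction composites for one patient.

    ``reference_fraction`` names the baseline fraction (default 1, the first
    delivered fraction); ``rebaseline_fractions`` lists fractions at which a
    new treatment plan starts and the reference is reset (a replan
    mid-course).  ``contours`` and ``registrations`` optionally carry the
    per-fraction CBCT body-contour slice and rigid setup-registration matrix
    aligned with ``fractions``.
    """

    patient_id: str
    fractions: list[CompositeImage]
    site_label: str = ""
    reference_fraction: int = 1
    rebaseline_fractions: tuple[int, ...] = ()
    contours: list | None = None
    registrations: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        idx = [f.fraction_index for f in self.fractions]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("fraction indices must be strictly increasing")
        if self.reference_fraction not in idx:
            raise ValueError(
                f"reference fraction {self.reference_fraction} not present"
            )

    def fraction(self, index: int) -> CompositeImage:
        for f in self.fractions:
            if f.fraction_index == index:
                return f
        raise KeyError(index)


# ---------------------------------------------------------------------------
# readers / writers


def read_epid_image(
    path: str | Path,
    *,
    fraction_index: int | None = None,
    arc_label: str | None = None,
) -> EpidImage:
    """Read a per-arc EPID image from DICOM RT Image or a portable array.

    Portable arrays are ``.npy`` or whitespace-delimited ``.txt`` files with
    a JSON sidecar (same stem, ``.json`` suffix) holding ``pixel_pitch_mm``,
    ``fraction_index`` and ``arc_label``.  DICOM pixel values are rescaled to
    CU with the stored slope/intercept; the pitch comes from the image-plane
    pixel spacing.  ``fraction_index`` / ``arc_label`` override metadata.
    """
    path = Path(path)
    if not path.exists():
        raise EpidReadError(f"no such file: {path}")
    if path.suffix.lower() in {".npy", ".txt"}:
        return _read_portable(path, fraction_index, arc_label)
    return _read_dicom(path, fraction_index, arc_label)


def _read_dicom(
    path: Path, fraction_index: int | None, arc_label: str | None
) -> EpidImage:
    try:
        ds = pydicom.dcmread(path, force=True)
        stored = ds.pixel_array
    except Exception as exc:  # pragma: no cover - message varies by pydicom
        raise EpidReadError(f"unreadable DICOM file {path}: {exc}") from exc
    if stored.ndim != 2:
        raise EpidReadError(f"expected a single 2-D frame, got shape {stored.shape}")

    spacing = ds.get("ImagePlanePixelSpacing") or ds.get("PixelSpacing")
    if spacing is None:
        raise MissingMetadataError(f"{path}: no image-plane pixel spacing tag")
    row_mm, col_mm = (float(spacing[0]), float(spacing[1]))
    if not math.isclose(row_mm, col_mm, rel_tol=1e-6):
        raise MissingMetadataError(
            f"{path}: anisotropic pixel spacing {row_mm} x {col_mm} mm unsupported"
        )

    slope = float(ds.get("RescaleSlope", 1.0))
    intercept = float(ds.get("RescaleIntercept", 0.0))
    pixels = stored.astype(float) * slope + intercept

    if fraction_index is None:
        fraction_index = int(ds.get("InstanceNumber", 1) or 1)
    if arc_label is None:
        arc_label = str(ds.get("RTImageLabel", "") or "")
    return EpidImage(pixels, row_mm, fraction_index, arc_label)


def _read_portable(
    path: Path, fraction_index: int | None, arc_label: str | None
) -> EpidImage:
    try:
        if path.suffix.lower() == ".npy":
            pixels = np.load(path)
        else:
            pixels = np.loadtxt(path, ndmin=2)
    except Exception as exc:
        raise EpidReadError(f"unreadable array file {path}: {exc}") from exc
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise MissingMetadataError(f"missing JSON sidecar for {path}")
    meta = json.loads(sidecar.read_text())
    if "pixel_pitch_mm" not in meta:
        raise MissingMetadataError(f"{sidecar}: no pixel_pitch_mm entry")
    return EpidImage(
        pixels=np.asarray(pixels, dtype=float),
        pixel_pitch_mm=float(meta["pixel_pitch_mm"]),
        fraction_index=(
            fraction_index
            if fraction_index is not None
            else int(meta.get("fraction_index", 1))
        ),
        arc_label=arc_label if arc_label is not None else meta.get("arc_label", ""),
    )


def write_epid_array(image: EpidImage | CompositeImage, path: str | Path) -> Path:
    """Write an image as a portable array (``.npy`` or ``.txt``) + sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        np.save(path, image.pixels)
    elif path.suffix.lower() == ".txt":
        np.savetxt(path, image.pixels)
    else:
        raise ValueError(f"unsupported portable suffix: {path.suffix}")
    meta = {
        "pixel_pitch_mm": image.pixel_pitch_mm,
        "fraction_index": image.fraction_index,
        "arc_label": getattr(image, "arc_label", ""),
    }
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def write_epid_dicom(
    image: EpidImage,
    path: str | Path,
    *,
    rescale_slope: float = 1.0,
    rescale_intercept: float = 0.0,
) -> Path:
    """Write an :class:`EpidImage` as a minimal DICOM RT Image.

    Pixels are stored as unsigned 16-bit integers; the caller-provided
    slope/intercept map CU to stored values, ``stored = (CU - b) / m``.
    The CU values must land on exact integers under that mapping.
    """
    path = Path(path)
    stored_f = (image.pixels - rescale_intercept) / rescale_slope
    stored = np.rint(stored_f).astype(np.uint16)
    if not np.allclose(stored_f, stored, atol=1e-6):
        raise ValueError("CU values do not quantize exactly under the given rescale")

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = RTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTIMAGE"
    ds.RTImageLabel = image.arc_label
    ds.InstanceNumber = image.fraction_index
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = image.pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.ImagePlanePixelSpacing = [image.pixel_pitch_mm, image.pixel_pitch_mm]
    ds.RescaleSlope = rescale_slope
    ds.RescaleIntercept = rescale_intercept
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


# ---------------------------------------------------------------------------
# compositing and panel geometry


def build_composite(arcs: Iterable[EpidImage]) -> CompositeImage:
    """Sum the arc images of one fraction into a composite.

    All arcs must share fraction index, matrix dimensions and pixel pitch;
    the composite is the pixel-wise sum in CU (the panel integrates dose, so
    the fraction total is the sum over its arcs).
    """
    arcs = list(arcs)
    if not arcs:
        raise ValueError("cannot build a composite from zero arcs")
    first = arcs[0]
    for arc in arcs[1:]:
        if arc.pixels.shape != first.pixels.shape or not math.isclose(
            arc.pixel_pitch_mm, first.pixel_pitch_mm, rel_tol=_PITCH_RTOL
        ):
            raise GeometryMismatchError(
                "mismatched geometry: arcs differ in dimensions or pixel pitch"
            )
        if arc.fraction_index != first.fraction_index:
            raise ValueError("arcs from different fractions cannot be composited")
    total = np.sum([a.pixels for a in arcs], axis=0)
    return CompositeImage(
        pixels=total,
        pixel_pitch_mm=first.pixel_pitch_mm,
        fraction_index=first.fraction_index,
        n_arcs=len(arcs),
    )


def derive_pixel_pitch(panel_size_mm: float, matrix_size: int) -> float:
    """Pixel pitch at the imager plane: physical panel size / matrix size.

    A 430 mm panel read out over 1280 pixels gives 0.3359375 ~ 0.336 mm.
    """
    if panel_size_mm <= 0 or matrix_size <= 0:
        raise ValueError("panel size and matrix size must be positive")
    return panel_size_mm / matrix_size


def project_to_isocenter(
    panel_length: float, *, sad: float = 100.0, sid: float = 154.0
) -> float:
    """Scale a length at the imager plane to the isocenter plane by SAD/SID.

    Units of ``panel_length`` carry through; ``sad`` and ``sid`` only need a
    common unit (defaults are cm for a panel at 154 cm with 100 cm SAD).
    """
    if panel_length < 0 or sad <= 0 or sid <= 0:
        raise ValueError("lengths and distances must be positive")
    return panel_length * sad / sid


# ---------------------------------------------------------------------------
# results table

RESULTS_COLUMNS = [
    "patient_id",
    "fraction",
    "gdsa_mean_pct",
    "gdsa_std_pct",
    "roi_pixels",
    "flagged",
    "delta_dap_cm",
    "delta_dlat_cm",
    "delta_deff_cm",
    "pitch_deg",
    "roll_deg",
    "yaw_deg",
]


@dataclass
class FractionRecord:
    """One row of the shared per-fraction results table.

    Measurements that were not made for a fraction stay ``None`` and are
    written as empty CSV fields.
    """

    patient_id: str
    fraction: int
    gdsa_mean_pct: float | None = None
    gdsa_std_pct: float | None = None
    roi_pixels: int | None = None
    flagged: bool | None = None
    delta_dap_cm: float | None = None
    delta_dlat_cm: float | None = None
    delta_deff_cm: float | None = None
    pitch_deg: float | None = None
    roll_deg: float | None = None
    yaw_deg: float | None = None
    extra: dict = field(default_factory=dict)


def write_results_table(
    records: Sequence[FractionRecord], path: str | Path
) -> Path:
    """Write per-fraction records as a UTF-8 CSV, one row per fraction."""
    if not records:
        raise ValueError("no records to write")
    rows = []
    for r in records:
        if not isinstance(r, FractionRecord):
            raise TypeError("records must be FractionRecord instances")
        rows.append({c: getattr(r, c) for c in RESULTS_COLUMNS})
    df = pd.DataFrame(rows, columns=RESULTS_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results CSV back into a DataFrame (empty fields become NaN)."""
    return pd.read_csv(path)
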