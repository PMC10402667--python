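"""Flagging, correlation and cohort reporting.

Assembles per-patient GDSA time-series with the separation and rotation
records, flags fractions whose |GDSA_mu| reaches the dose-accuracy
tolerance (default 3%), correlates GDSA_mu with the effective separation
change or the pitch error (ordinary-least-squares R^2), and aggregates
per-site cohort tables (patients, fractions, share of total, flagged
fractions, mean and spread of GDSA_mu).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib.figure import Figure
from scipy import stats

from .epid_io import FractionRecord, PatientSeries, write_results_table
from .gdsa_core import DEFAULT_FLAG_THRESHOLD_PCT, GdsaResult
from .rotation_analysis import RotationRecord
from .separation_analysis import SeparationRecord

__all__ = [
    "flag_series",
    "r_squared",
    "cohort_summary",
    "assemble_records",
    "export_timeseries",
    "example_cohort_counts",
    "summarize_cohort_counts",
]


def flag_series(
    results: Sequence[GdsaResult],
    threshold_pct: float = DEFAULT_FLAG_THRESHOLD_PCT,
) -> list[int]:
    """Fraction indices with |GDSA_mu| >= threshold, in fraction order."""
    return [
        r.fraction_index
        for r in results
        if np.isfinite(r.gdsa_mean_pct)
        and abs(r.gdsa_mean_pct) >= threshold_pct
    ]


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Coefficient of determination of the OLS line of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: x is constant")
    return float(stats.linregress(x, y).rvalue ** 2)


def assemble_records(
    patient_id: str,
    results: Sequence[GdsaResult],
    separations: Sequence[SeparationRecord] | None = None,
    rotations: Sequence[RotationRecord] | None = None,
) -> list[FractionRecord]:
    """Merge per-fraction GDSA, separation and rotation records by fraction."""
    sep_by_frac = {s.fraction_index: s for s in separations or ()}
    rot_by_frac = {r.fraction_index: r for r in rotations or ()}
    records = []
    for res in results:
        sep = sep_by_frac.get(res.fraction_index)
        rot = rot_by_frac.get(res.fraction_index)
        records.append(
            FractionRecord(
                patient_id=patient_id,
                fraction=res.fraction_index,
                gdsa_mean_pct=res.gdsa_mean_pct,
                gdsa_std_pct=res.gdsa_std_pct,
                roi_pixels=res.roi_pixel_count,
                flagged=res.flagged,
                delta_dap_cm=sep.delta_ap_cm if sep else None,
                delta_dlat_cm=sep.delta_lat_cm if sep else None,
                delta_deff_cm=sep.delta_eff_cm if sep else None,
                pitch_deg=rot.pitch_deg if rot else None,
                roll_deg=rot.roll_deg if rot else None,
                yaw_deg=rot.yaw_deg if rot else None,
            )
        )
    return records


def cohort_summary(
    all_series: Sequence[tuple[PatientSeries, Sequence[GdsaResult]]],
    threshold_pct: float = DEFAULT_FLAG_THRESHOLD_PCT,
) -> pd.DataFrame:
    """Per-site cohort table: patients, fractions, % of total, flags, moments.

    One row per site label, plus the derived ``pct_total`` share of all
    fractions (one decimal).  GDSA_mu moments pool every analyzable fraction
    of the site (population standard deviation).
    """
    if not all_series:
        raise ValueError("empty cohort")
    rows: dict[str, dict] = {}
    for series, results in all_series:
        site = series.site_label or "unspecified"
        row = rows.setdefault(
            site,
            {"site": site, "patients": 0, "fractions": 0, "n_flagged": 0, "_vals": []},
        )
        row["patients"] += 1
        row["fractions"] += len(results)
        vals = [r.gdsa_mean_pct for r in results if np.isfinite(r.gdsa_mean_pct)]
        row["_vals"].extend(vals)
        row["n_flagged"] += sum(
            1 for v in vals if abs(v) >= threshold_pct
        )
    total = sum(r["fractions"] for r in rows.values())
    out = []
    for row in rows.values():
        vals = np.asarray(row.pop("_vals"), dtype=float)
        row["pct_total"] = round(100.0 * row["fractions"] / total, 1)
        row["mean_gdsa_pct"] = float(vals.mean()) if vals.size else np.nan
        row["std_gdsa_pct"] = float(vals.std(ddof=0)) if vals.size else np.nan
        out.append(row)
    df = pd.DataFrame(out).sort_values("fractions", ascending=False)
    return df.reset_index(drop=True)[
        [
            "site",
            "patients",
            "fractions",
            "pct_total",
            "n_flagged",
            "mean_gdsa_pct",
            "std_gdsa_pct",
        ]
    ]


def export_timeseries(
    patient_id: str,
    results: Sequence[GdsaResult],
    out_dir: str | Path,
    *,
    separations: Sequence[SeparationRecord] | None = None,
    rotations: Sequence[RotationRecord] | None = None,
    threshold_pct: float = DEFAULT_FLAG_THRESHOLD_PCT,
    rebaseline_fractions: Sequence[int] = (),
) -> dict[str, Path]:
    """Plot GDSA_mu vs fraction and write the tidy per-fraction CSV.

    The plot shows +/-1 ROI standard deviation error bars, the flag
    threshold as a horizontal line, flagged fractions as filled red markers,
    vertical lines at any re-baseline (replan) fraction, and an optional
    secondary axis with the effective separation change or the pitch error.
    """
    if not results:
        raise ValueError("no results to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    frac = np.array([r.fraction_index for r in results])
    mean = np.array([r.gdsa_mean_pct for r in results])
    std = np.array([r.gdsa_std_pct for r in results])
    flagged = np.array([r.flagged for r in results])

    fig = Figure(figsize=(8, 4.5))
    ax = fig.add_subplot(111)
    # split the line at re-baselines so each plan segment reads separately
    cuts = sorted(f for f in rebaseline_fractions if f in set(frac))
    bounds = [frac.min()] + cuts + [frac.max() + 1]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg = (frac >= lo) & (frac < hi)
        ax.errorbar(
            frac[seg], mean[seg], yerr=std[seg], fmt="o-", ms=3,
            color="tab:blue", ecolor="lightgray", capsize=2,
        )
    ax.plot(frac[flagged], mean[flagged], "o", ms=6, color="tab:red", zorder=5)
    ax.axhline(threshold_pct, color="tab:red", ls="--", lw=1)
    ax.axhline(-threshold_pct, color="tab:red", ls="--", lw=1)
    for f in cuts:
        ax.axvline(f - 0.5, color="gray", ls=":", lw=1)
    ax.set_xlabel("fraction number")
    ax.set_ylabel(r"GDSA$_\mu$ (%)")
    ax.set_title(patient_id)

    if separations is not None:
        sep_by = {s.fraction_index: s.delta_eff_cm for s in separations}
        ax2 = ax.twinx()
        ax2.plot(
            frac, [sep_by.get(f, np.nan) for f in frac],
            "s--", ms=3, color="tab:green",
        )
        ax2.set_ylabel(r"$\Delta d_{eff}$ (cm)", color="tab:green")
    elif rotations is not None:
        rot_by = {r.fraction_index: r.pitch_deg for r in rotations}
        ax2 = ax.twinx()
        ax2.plot(
            frac, [rot_by.get(f, np.nan) for f in frac],
            "^--", ms=3, color="tab:purple",
        )
        ax2.set_ylabel("pitch (deg)", color="tab:purple")

    plot_path = out_dir / f"{patient_id}_gdsa.png"
    fig.savefig(plot_path, dpi=120, bbox_inches="tight")

    csv_path = out_dir / f"{patient_id}_timeseries.csv"
    write_results_table(
        assemble_records(patient_id, results, separations, rotations), csv_path
    )
    return {"plot": plot_path, "csv": csv_path}


# ---------------------------------------------------------------------------
# bundled example cohort

_EXAMPLE_COHORT_ROWS = [
    # site, patients, fractions, fractions with |GDSA_mu| >= 3%
    ("Larynx", 29, 641, 40),
    ("Oropharynx (p16-)", 27, 597, 26),
    ("Lip and oral cavity", 24, 530, 2),
    ("Nasal cavity and sinuses", 7, 155, 7),
    ("Unknown primary H&N tumors", 7, 155, 0),
    ("Hypopharynx", 5, 110, 1),
    ("Nasopharynx", 5, 110, 3),
    ("Salivary glands", 5, 110, 3),
    ("HPV-mediated (p16+) oropharyngeal cancer", 2, 44, 0),
    ("Lacrimal gland", 1, 22, 0),
    ("Nervous system (Misc.)", 1, 23, 0),
    ("Orbit", 1, 22, 0),
    ("Thyroid gland", 1, 22, 0),
]


def example_cohort_counts() -> pd.DataFrame:
    """Site-level tally from a one-year head-and-neck VMAT service.

    Bundled as a worked example for the cohort-summary utilities: 13
    treatment sites with patient counts, delivered fractions, and the
    number of fractions whose |GDSA_mu| reached the 3% tolerance.
    """
    return pd.DataFrame(
        _EXAMPLE_COHORT_ROWS,
        columns=["site", "patients", "fractions", "n_flagged"],
    )


def summarize_cohort_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Derive each site's share of total fractions (one decimal) and totals.

    Returns the input with a ``pct_total`` column appended plus a final
    ``Total`` row; shares are fractions-of-total x 100.
    """
    required = {"site", "patients", "fractions", "n_flagged"}
    if not required.issubset(counts.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    df = counts.copy()
    total = int(df["fractions"].sum())
    df["pct_total"] = (100.0 * df["fractions"] / total).round(1)
    total_row = pd.DataFrame(
        [
            {
                "site": "Total",
                "patients": int(df["patients"].sum()),
                "fractions": total,
                "n_flagged": int(df["n_flagged"].sum()),
                "pct_total": 100.0,
            }
        ]
    )
    return pd.concat([df, total_row], ignore_index=True)
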