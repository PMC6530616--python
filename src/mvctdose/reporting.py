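"""Organ-level dose reporting: per-fraction maxima, fractionation totals,
percent of prescription, DVHs and summary tables.

Daily MVCT imaging adds a small dose every treatment fraction; the
clinically relevant numbers are the maximum organ dose per fraction, its
total over the fractionation scheme, and that total as a percentage of
the prescribed dose.  Totals and percentages are carried unrounded
internally and rounded to two decimals only for display, since rounding
per-fraction values first does not commute with multiplying by large
fraction counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_engine import DoseGrid
from .phantoms import StructureMask

__all__ = [
    "FractionationScheme",
    "OrganDoseReport",
    "organ_max",
    "build_report",
    "summarize_reports",
    "compute_dvh",
    "reports_to_frame",
    "write_report_csv",
    "write_report_json",
    "write_dvh_csv",
    "load_organ_dose_survey",
]


@dataclass(frozen=True)
class FractionationScheme:
    """Prescription written as (fraction dose in cGy) x (number of fractions)."""

    fraction_dose: float
    n_fractions: int

    def __post_init__(self) -> None:
        if self.fraction_dose <= 0:
            raise ValueError("fraction_dose must be > 0")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")

    @property
    def prescription_total(self) -> float:
        return self.fraction_dose * self.n_fractions

    @classmethod
    def parse(cls, text: str) -> "FractionationScheme":
        """Parse '300x10' / '300 x 10' into a scheme."""
        parts = text.lower().replace(" ", "").split("x")
        if len(parts) != 2:
            raise ValueError(f"cannot parse fractionation {text!r}; expected e.g. '300x10'")
        return cls(float(parts[0]), int(parts[1]))


@dataclass(frozen=True)
class OrganDoseReport:
    organ: str
    max_per_fraction: float  # cGy
    total_max: float  # cGy, max_per_fraction * n_fractions (unrounded)
    percent_of_prescription: float  # total_max / prescription_total * 100

    @property
    def display(self) -> dict:
        return {
            "organ": self.organ,
            "max_per_fx_cGy": round(self.max_per_fraction, 2),
            "total_max_cGy": round(self.total_max, 2),
            "percent": round(self.percent_of_prescription, 2),
        }


def organ_max(dose: DoseGrid, mask: StructureMask) -> float:
    """Maximum voxel dose (cGy) over the structure."""
    if mask.member.shape != dose.dims:
        raise ValueError("mask lattice does not match the dose grid")
    if mask.voxel_count == 0:
        raise ValueError(f"structure {mask.name!r} is empty")
    return float(dose.dose[mask.member].max())


def build_report(organ: str, max_per_fraction: float, fx: FractionationScheme) -> OrganDoseReport:
    """Per-organ imaging-dose summary over the fractionation scheme."""
    if max_per_fraction <= 0:
        raise ValueError("max_per_fraction must be > 0")
    total = max_per_fraction * fx.n_fractions
    percent = total / fx.prescription_total * 100.0
    return OrganDoseReport(organ, max_per_fraction, total, percent)


def summarize_reports(reports) -> tuple[float, float]:
    """Mean of the display-rounded total doses (cGy) and percentages (%),
    each rounded to 2 decimals (table-level averaging of printed columns)."""
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to summarize")
    totals = [round(r.total_max, 2) for r in reports]
    percents = [round(r.percent_of_prescription, 2) for r in reports]
    return round(float(np.mean(totals)), 2), round(float(np.mean(percents)), 2)


def compute_dvh(
    dose: DoseGrid, mask: StructureMask, bin_width: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative dose-volume histogram of a structure.

    Returns ``(dose_edges, volume_fraction)`` where ``volume_fraction[i]``
    is the fraction of the structure's volume receiving at least
    ``dose_edges[i]`` cGy; edges run from 0 to the structure maximum in
    steps of ``bin_width``.  The curve is monotone non-increasing with
    value 1.0 at zero dose.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if mask.member.shape != dose.dims:
        raise ValueError("mask lattice does not match the dose grid")
    if mask.voxel_count == 0:
        raise ValueError(f"structure {mask.name!r} is empty")
    values = dose.dose[mask.member]
    dmax = float(values.max())
    edges = np.arange(0.0, dmax + bin_width, bin_width)
    frac = np.array([(values >= e).mean() for e in edges])
    frac[0] = 1.0  # every member receives >= 0
    return edges, frac


def reports_to_frame(reports, fx: FractionationScheme | None = None) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = dict(r.display)
        if fx is not None:
            row["prescription"] = f"{fx.fraction_dose:g} x {fx.n_fractions}"
        rows.append(row)
    return pd.DataFrame(rows)


def write_report_csv(reports, path, fx: FractionationScheme | None = None) -> None:
    reports_to_frame(reports, fx).to_csv(path, index=False)


def write_report_json(reports, path) -> None:
    Path(path).write_text(
        json.dumps([r.display for r in reports], indent=1), encoding="utf-8"
    )


def write_dvh_csv(edges: np.ndarray, frac: np.ndarray, path) -> None:
    pd.DataFrame({"dose_cGy": edges, "volume_fraction": frac}).to_csv(path, index=False)


def load_organ_dose_survey() -> pd.DataFrame:
    """Bundled example survey of maximum organ doses from normal-pitch
    MVCT delivery across five treatment sites (brain, head and neck,
    lung, abdomen, prostate; 21 organs).

    Columns: region, organ, fraction_dose_cGy, n_fractions,
    max_per_fx_cGy.  Used by the worked examples and the reproduction
    script to exercise the reporting pipeline on realistic magnitudes.
    """
    with resources.files("mvctdose.data").joinpath("organ_dose_survey.csv").open() as fh:
        return pd.read_csv(fh, comment="#")
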