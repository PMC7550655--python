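"""Caliper volumetrics, inhibition rates, and ROI summaries.

The study table is a long-format :class:`pandas.DataFrame` with columns
``animal_id, group, timepoint, quantity, value`` — one row per animal,
time point and measured quantity (caliper volume, ROI means of D, D*, f,
R2*, and the terminal pathology positive-staining rates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acquisition import ValidationError

__all__ = [
    "SummaryCell",
    "tumor_volume",
    "inhibition_rate",
    "roi_summary",
    "longitudinal_summary",
    "STUDY_COLUMNS",
]

STUDY_COLUMNS = ("animal_id", "group", "timepoint", "quantity", "value")


@dataclass(frozen=True)
class SummaryCell:
    """mean ± SD with group size n, one group × time-point cell."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd: must be non-negative")
        if self.n < 2:
            raise ValidationError("n: need at least 2 observations")

    def __str__(self) -> str:
        return f"{self.mean:g} ± {self.sd:g} (n={self.n})"


def tumor_volume(d_short: float, d_long: float) -> float:
    """Caliper tumor volume V = a²·b·0.5 in mm³.

    ``d_short`` (a) is the smaller diameter, ``d_long`` (b) the diameter
    perpendicular to it, both in mm. Swapped diameters raise rather than
    being silently reordered.
    """
    if not d_short > 0:
        raise ValidationError("d_short: must be positive")
    if d_short > d_long:
        raise ValidationError("d_short: exceeds d_long (diameters swapped?)")
    return d_short * d_short * d_long * 0.5


def inhibition_rate(v_control: float, v_treated: float) -> float:
    """Tumor inhibition rate (%) = (V_control − V_treated)/V_control · 100.

    May be negative when the treated tumors outgrow the controls.
    """
    if not v_control > 0:
        raise ValidationError("v_control: must be positive")
    return (v_control - v_treated) / v_control * 100.0


def roi_summary(values: np.ndarray, mask: np.ndarray) -> SummaryCell:
    """Mean and SD (n−1 denominator) of a parameter map over an ROI mask."""
    mask = np.asarray(mask, dtype=bool)
    values = np.asarray(values, dtype=float)
    if mask.shape != values.shape:
        raise ValidationError("mask: shape differs from map")
    sel = values[mask]
    if sel.size == 0:
        raise ValidationError("mask: empty ROI")
    if not np.all(np.isfinite(sel)):
        raise ValidationError("map: non-finite values inside ROI")
    n = int(sel.size)
    if n < 2:
        raise ValidationError("mask: ROI needs at least 2 voxels for an SD")
    return SummaryCell(mean=float(sel.mean()), sd=float(sel.std(ddof=1)), n=n)


def longitudinal_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Group × time-point mean/SD/n table per quantity.

    Input is a long study table (``STUDY_COLUMNS``); output has one row per
    (quantity, group, timepoint) with columns ``mean, sd, n``, ordered as
    the input's categorical order (first-appearance order for plain
    strings). Cells with fewer than 2 records are reported with the n they
    have rather than raised.
    """
    missing = set(STUDY_COLUMNS) - set(records.columns)
    if missing:
        raise ValidationError(f"records: missing columns {sorted(missing)}")
    out = (records
           .groupby(["quantity", "group", "timepoint"], sort=False,
                    observed=True)["value"]
           .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
           .reset_index())
    out["sd"] = out["sd"].fillna(0.0)
    return out
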