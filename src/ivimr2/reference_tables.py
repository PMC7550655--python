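"""Packaged reference summary tables of the xenograft study.

The four-group (saline control A; free doxorubicin 4 mg/kg B; targeted
nanoparticle 2 mg/kg C and 4 mg/kg D) × four-time-point (baseline, weeks
1–3), n = 8 study is distributed with the package as mean ± SD cells:
caliper tumor volumes, ROI means of the quantitative MRI parameters
(D, D*, f, R2*), and terminal pathology positive-staining rates, together
with the published one-way ANOVA F statistics for each row. These cells
seed the study simulator and are what :func:`reproduce_tables` checks the
statistics layer against.

Values are stored in display units (D and D* in 10⁻³ mm²/s, f in %,
R2* in 1/s, volume in mm³, staining rates in %).
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

from .acquisition import ValidationError
from .tumor import SummaryCell

__all__ = [
    "load_reference_tables",
    "reference_cell",
    "cell_targets",
    "GROUPS",
    "TIMEPOINTS",
    "MRI_QUANTITIES",
    "PATHOLOGY_QUANTITIES",
]

GROUPS = ("Group A", "Group B", "Group C", "Group D")
TIMEPOINTS = ("base", "week1", "week2", "week3")
MRI_QUANTITIES = ("D", "Dstar", "f", "R2star")
PATHOLOGY_QUANTITIES = ("HIF1a", "Ki67", "TUNEL", "PTEN")

_CHECKSUMS = {
    "reference_cells.csv":
        "5f0cacb27c454134388a060b6b99e6b0def33f48704711c2be5df09be7e96fa7",
    "reference_fvalues.csv":
        "d8c378604ef8f9c5d7bc4060fd4b4b8a1ff59ac1236b3c92f5dc4a3c9e63d568",
}


def _data_path(name: str) -> Path:
    return Path(resources.files("ivimr2").joinpath("data", name))  # type: ignore[arg-type]


def _verified_read(name: str) -> pd.DataFrame:
    path = _data_path(name)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise ValidationError(
            f"{name}: checksum mismatch — packaged table was modified")
    return pd.read_csv(path, keep_default_na=False, na_values=[])


def load_reference_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (cells, fvalues) with integrity verified by sha256.

    ``cells`` columns: quantity, unit, group, timepoint, mean, sd, n.
    ``fvalues`` columns: quantity, group, across, F, P — one row per
    published ANOVA (across time points within a group for volume and MRI
    quantities; across groups at the terminal time point for pathology).
    """
    cells = _verified_read("reference_cells.csv")
    fvalues = _verified_read("reference_fvalues.csv")
    return cells, fvalues


def reference_cell(quantity: str, group: str, timepoint: str) -> SummaryCell:
    """Look up one mean ± SD cell as a :class:`SummaryCell`."""
    cells, _ = load_reference_tables()
    row = cells[(cells.quantity == quantity) & (cells.group == group)
                & (cells.timepoint == timepoint)]
    if row.empty:
        raise ValidationError(
            f"cell: no reference entry for {quantity}/{group}/{timepoint}")
    r = row.iloc[0]
    return SummaryCell(mean=float(r["mean"]), sd=float(r["sd"]), n=int(r["n"]))


def cell_targets() -> dict[str, dict[tuple[str, str], SummaryCell]]:
    """All cells keyed as quantity → (group, timepoint) → SummaryCell.

    This is the default target structure for the study simulator.
    """
    cells, _ = load_reference_tables()
    out: dict[str, dict[tuple[str, str], SummaryCell]] = {}
    for r in cells.itertuples(index=False):
        out.setdefault(r.quantity, {})[(r.group, r.timepoint)] = SummaryCell(
            mean=float(r.mean), sd=float(r.sd), n=int(r.n))
    return out
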