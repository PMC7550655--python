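"""Synthetic phantoms and study tables.

Two kinds of synthetic data stand in for scanner and animal data:

* voxelwise 4D phantoms — an ellipsoidal "tumor" inside a background
  block, with per-voxel IVIM / R2* truth drawn from region-level
  mean ± SD and signals generated by the forward models in
  :mod:`ivimr2.acquisition`, optionally corrupted by Rician (magnitude
  MRI) or Gaussian noise;

* longitudinal study tables — the 4-group × 4-time-point, n = 8 design,
  with every measured quantity drawn from a Normal at its group × time
  cell target (the packaged reference cells by default).

All generators are pure functions of (spec, seed). The global seed is
expanded into independent per-component substreams so that, e.g., the
noise draw never shifts the truth-map draw.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import (DiffusionProtocol, RelaxometryProtocol,
                          ValidationError)
from .tumor import STUDY_COLUMNS, SummaryCell

__all__ = [
    "NoiseSpec",
    "RegionSpec",
    "PhantomSpec",
    "StudyDesign",
    "add_noise",
    "ellipsoid_mask",
    "generate_ivim_volume",
    "generate_gre_volume",
    "generate_study",
    "default_phantom_spec",
    "default_study_design",
]

_MAX_REDRAWS = 100


def _substream(seed: int, component: str) -> np.random.Generator:
    """Independent generator for one named component of a simulation."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(component.encode())]))


# --------------------------------------------------------------------------
# Noise

@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model: ``none``, ``gaussian`` or ``rician``.

    ``sigma`` is the per-channel noise SD in signal units. Magnitude MRI
    noise is Rician: the magnitude of a complex signal with i.i.d.
    Gaussian noise on both channels, which floors low-SNR signals upward.
    """

    model: str = "rician"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("none", "gaussian", "rician"):
            raise ValidationError(f"model: unknown noise model {self.model!r}")
        if self.sigma < 0:
            raise ValidationError("sigma: must be non-negative")


def add_noise(signal: np.ndarray, spec: NoiseSpec,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Corrupt a non-negative signal array according to a noise spec.

    Rician: ``sqrt((s + e1)^2 + e2^2)`` with e1, e2 ~ N(0, sigma²) i.i.d.
    Reproducible for a fixed ``spec.seed`` when no generator is passed.
    """
    signal = np.asarray(signal, dtype=float)
    if np.any(signal < 0):
        raise ValidationError("signal: must be non-negative")
    if spec.model == "none" or spec.sigma == 0.0:
        return signal.copy()
    if rng is None:
        rng = _substream(spec.seed, "noise")
    e1 = rng.normal(0.0, spec.sigma, size=signal.shape)
    if spec.model == "gaussian":
        return signal + e1
    e2 = rng.normal(0.0, spec.sigma, size=signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2 ** 2)


# --------------------------------------------------------------------------
# Phantom geometry and tissue

@dataclass(frozen=True)
class RegionSpec:
    """Region-level tissue parameters as mean ± SD (truth drawn voxelwise).

    D and Dstar in mm²/s, f as a fraction in [0, 1], R2star in 1/s, S0 in
    arbitrary units. An SD of 0 makes the region homogeneous.
    """

    s0_mean: float = 1000.0
    s0_sd: float = 0.0
    d_mean: float = 0.556e-3
    d_sd: float = 0.0
    dstar_mean: float = 8.53e-3
    dstar_sd: float = 0.0
    f_mean: float = 0.1675
    f_sd: float = 0.0
    r2star_mean: float = 24.74
    r2star_sd: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Ellipsoidal tumor inside a rectangular grid.

    ``grid`` is the 3D voxel dimensions; the tumor is the set of voxels
    whose centers fall inside the ellipsoid given by ``center`` and
    ``semi_axes`` (voxel units). Tumor and background tissue are each a
    :class:`RegionSpec`.
    """

    grid: tuple[int, int, int] = (18, 18, 8)
    center: tuple[float, float, float] = (8.5, 8.5, 3.5)
    semi_axes: tuple[float, float, float] = (7.0, 7.0, 3.2)
    tumor: RegionSpec = field(default_factory=lambda: RegionSpec(
        s0_sd=50.0, d_sd=0.024e-3, dstar_sd=0.57e-3, f_sd=0.0095,
        r2star_sd=0.61))
    background: RegionSpec = field(default_factory=lambda: RegionSpec(
        s0_mean=800.0, s0_sd=40.0, d_mean=1.4e-3, d_sd=0.05e-3,
        dstar_mean=15e-3, dstar_sd=1e-3, f_mean=0.05, f_sd=0.01,
        r2star_mean=30.0, r2star_sd=1.0))

    def __post_init__(self) -> None:
        if any(g < 1 for g in self.grid):
            raise ValidationError("grid: dimensions must be positive")
        if any(a <= 0 for a in self.semi_axes):
            raise ValidationError("semi_axes: must be positive")
        for c, a, g in zip(self.center, self.semi_axes, self.grid):
            if c - a < -0.5 or c + a > g - 0.5:
                raise ValidationError("semi_axes: ellipsoid exceeds grid")


def ellipsoid_mask(grid: tuple[int, int, int],
                   center: tuple[float, float, float],
                   semi_axes: tuple[float, float, float]) -> np.ndarray:
    """Boolean mask of voxels whose centers lie inside the ellipsoid."""
    idx = np.indices(grid, dtype=float)
    r2 = sum(((idx[k] - center[k]) / semi_axes[k]) ** 2 for k in range(3))
    return r2 <= 1.0


def _draw_field(rng: np.random.Generator, mean: float, sd: float,
                shape: tuple[int, ...], lo: float, hi: float,
                name: str) -> np.ndarray:
    """Normal draws redrawn into (lo, hi); clamped after _MAX_REDRAWS."""
    vals = rng.normal(mean, sd, size=shape) if sd > 0 \
        else np.full(shape, float(mean))
    for _ in range(_MAX_REDRAWS):
        bad = (vals < lo) | (vals > hi)
        if not bad.any():
            return vals
        vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    bad = (vals < lo) | (vals > hi)
    if bad.any():
        warnings.warn(f"{name}: {int(bad.sum())} draws clamped into "
                      f"[{lo:g}, {hi:g}] after {_MAX_REDRAWS} redraws")
        vals = np.clip(vals, lo, hi)
    return vals


def _truth_maps(spec: PhantomSpec, rng: np.random.Generator,
                which: tuple[str, ...]) -> tuple[dict[str, np.ndarray],
                                                 np.ndarray]:
    """Draw voxelwise truth maps for the requested parameters."""
    mask = ellipsoid_mask(spec.grid, spec.center, spec.semi_axes)
    ranges = {"S0": (1e-6, np.inf), "D": (1e-6, np.inf),
              "Dstar": (1e-6, np.inf), "f": (0.0, 1.0),
              "R2star": (0.0, np.inf)}
    attr = {"S0": "s0", "D": "d", "Dstar": "dstar", "f": "f",
            "R2star": "r2star"}
    maps: dict[str, np.ndarray] = {}
    for key in which:
        lo, hi = ranges[key]
        a = attr[key]
        m = _draw_field(rng, getattr(spec.background, f"{a}_mean"),
                        getattr(spec.background, f"{a}_sd"),
                        spec.grid, lo, hi, key)
        tum = _draw_field(rng, getattr(spec.tumor, f"{a}_mean"),
                          getattr(spec.tumor, f"{a}_sd"),
                          spec.grid, lo, hi, key)
        m[mask] = tum[mask]
        maps[key] = m
    # two-compartment identifiability: redraw Dstar wherever it fails to
    # exceed D, then clamp just above
    if "D" in maps and "Dstar" in maps:
        for _ in range(_MAX_REDRAWS):
            bad = maps["Dstar"] <= maps["D"]
            if not bad.any():
                break
            for region, rs in ((~mask, spec.background), (mask, spec.tumor)):
                sel = bad & region
                if sel.any():
                    maps["Dstar"][sel] = rng.normal(
                        rs.dstar_mean, max(rs.dstar_sd, 0.0), int(sel.sum())) \
                        if rs.dstar_sd > 0 else rs.dstar_mean
        bad = maps["Dstar"] <= maps["D"]
        if bad.any():
            warnings.warn(f"Dstar: {int(bad.sum())} voxels clamped above D")
            maps["Dstar"][bad] = maps["D"][bad] * 1.01
    return maps, mask


def generate_ivim_volume(spec: PhantomSpec, protocol: DiffusionProtocol,
                         noise: NoiseSpec
                         ) -> tuple[np.ndarray, dict[str, np.ndarray],
                                    np.ndarray]:
    """4D multi-b diffusion phantom.

    Returns ``(volume, truth, mask)`` where ``volume`` has shape
    ``grid + (len(bvalues),)``, ``truth`` maps S0/D/Dstar/f voxelwise and
    ``mask`` marks the tumor ellipsoid.
    """
    rng = _substream(noise.seed, "ivim_truth")
    maps, mask = _truth_maps(spec, rng, ("S0", "D", "Dstar", "f"))
    b = protocol.as_array()
    s0 = maps["S0"][..., None]
    d = maps["D"][..., None]
    ds = maps["Dstar"][..., None]
    f = maps["f"][..., None]
    clean = s0 * ((1.0 - f) * np.exp(-b * d) + f * np.exp(-b * ds))
    vol = add_noise(clean, noise, rng=_substream(noise.seed, "ivim_noise"))
    return vol, maps, mask


def generate_gre_volume(spec: PhantomSpec, protocol: RelaxometryProtocol,
                        noise: NoiseSpec
                        ) -> tuple[np.ndarray, dict[str, np.ndarray],
                                   np.ndarray]:
    """4D multi-echo gradient-echo phantom; truth maps S0 and R2star."""
    rng = _substream(noise.seed, "gre_truth")
    maps, mask = _truth_maps(spec, rng, ("S0", "R2star"))
    te_s = protocol.as_array() / 1000.0
    clean = maps["S0"][..., None] * np.exp(-maps["R2star"][..., None] * te_s)
    vol = add_noise(clean, noise, rng=_substream(noise.seed, "gre_noise"))
    return vol, maps, mask


def default_phantom_spec(snr: float = 50.0) -> tuple[PhantomSpec, NoiseSpec]:
    """Default tumor phantom and a Rician noise spec at the given b=0 SNR.

    Tumor region means follow the baseline ROI values of the reference
    study (D = 0.556·10⁻³ mm²/s, D* = 8.53·10⁻³ mm²/s, f = 16.75 %,
    R2* = 24.74 /s); sigma is S0_tumor / SNR.
    """
    spec = PhantomSpec()
    sigma = 0.0 if not np.isfinite(snr) else spec.tumor.s0_mean / snr
    return spec, NoiseSpec(model="rician", sigma=sigma, seed=0)


# --------------------------------------------------------------------------
# Longitudinal study tables

#: physically admissible range per measured quantity (display units)
_QUANTITY_RANGES = {
    "volume": (1e-9, np.inf),
    "D": (1e-9, np.inf),
    "Dstar": (1e-9, np.inf),
    "f": (0.0, 100.0),
    "R2star": (0.0, np.inf),
    "HIF1a": (0.0, 100.0),
    "Ki67": (0.0, 100.0),
    "TUNEL": (0.0, 100.0),
    "PTEN": (0.0, 100.0),
}


@dataclass(frozen=True)
class StudyDesign:
    """Group × time-point design with per-cell Normal targets.

    ``cell_targets`` maps quantity → (group, timepoint) → SummaryCell.
    Quantities in ``full_grid_quantities`` must cover every group × time
    cell (volumes and MRI parameters); others (terminal pathology) may
    cover a subset and are generated only where listed.
    """

    groups: tuple[str, ...] = ("Group A", "Group B", "Group C", "Group D")
    timepoints: tuple[str, ...] = ("base", "week1", "week2", "week3")
    n_per_group: int = 8
    cell_targets: dict[str, dict[tuple[str, str], SummaryCell]] = \
        field(default_factory=dict)
    full_grid_quantities: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("n_per_group: must be at least 2")
        for q in self.full_grid_quantities:
            targets = self.cell_targets.get(q, {})
            for g in self.groups:
                for t in self.timepoints:
                    if (g, t) not in targets:
                        raise ValidationError(
                            f"cell_targets: missing {q}/{g}/{t}")


def default_study_design() -> StudyDesign:
    """The reference study design: its 4×4×8 grid and published cells."""
    from .reference_tables import (MRI_QUANTITIES, cell_targets)
    return StudyDesign(cell_targets=cell_targets(),
                       full_grid_quantities=("volume",) + MRI_QUANTITIES)


def generate_study(design: StudyDesign, seed: int) -> pd.DataFrame:
    """Draw one synthetic study as a long table.

    Every quantity is drawn independently per animal from
    Normal(cell mean, cell SD), redrawn (then clamped) into its physical
    range. Animal labels are stable across time points within a group;
    no within-animal correlation over time is imposed.
    """
    rng = _substream(seed, "study")
    rows: list[tuple] = []
    for quantity in design.cell_targets:
        lo, hi = _QUANTITY_RANGES.get(quantity, (-np.inf, np.inf))
        targets = design.cell_targets[quantity]
        for group in design.groups:
            for tp in design.timepoints:
                cell = targets.get((group, tp))
                if cell is None:
                    if quantity in design.full_grid_quantities:
                        raise ValidationError(
                            f"cell_targets: missing {quantity}/{group}/{tp}")
                    continue
                vals = _draw_field(rng, cell.mean, cell.sd,
                                   (design.n_per_group,), lo, hi,
                                   f"{quantity}/{group}/{tp}")
                tag = group.split()[-1]
                for i, v in enumerate(vals):
                    rows.append((f"{tag}{i + 1:02d}", group, tp,
                                 quantity, float(v)))
    return pd.DataFrame(rows, columns=list(STUDY_COLUMNS))
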