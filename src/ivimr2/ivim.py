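"""Segmented (two-step) voxelwise IVIM fitting.

The bi-exponential IVIM decay has four parameters (S0, D, D*, f) but the
perfusion compartment only shapes the low-b portion of the curve, so the
canonical segmented strategy is used:

1. b-values at or above a boundary (default 200 s/mm², where capillary
   pseudo-diffusion has largely decayed away) are fitted with a straight
   line on the log scale, giving D and the high-b intercept
   ln[S0·(1−f)];
2. the full bi-exponential is then fitted by bounded nonlinear least
   squares with D held fixed, giving f, D* and a re-estimated S0.

With 13 b-values the perfusion compartment still contributes a few
percent of the signal at the first high-b points, which biases the
step-1 slope. The fit therefore iterates: the fitted perfusion
compartment is subtracted from the high-b signal and D is re-estimated
by a signal-weighted log-linear fit (signal weighting is the
maximum-likelihood weighting for additive constant-variance noise on the
linear scale), after which the perfusion step is repeated. At map level
the subtraction uses the ROI-median perfusion parameters — D* and f are
the unstable voxelwise estimates, and their ROI median decontaminates
the diffusion segment without injecting per-voxel perfusion noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .acquisition import DiffusionProtocol, IVIMParams, ValidationError

__all__ = ["FitConfig", "IVIMFitResult", "fit_monoexp_highb",
           "fit_perfusion", "fit_ivim_voxel", "fit_ivim_map"]


@dataclass(frozen=True)
class FitConfig:
    """Segmented-fit configuration.

    ``boundary`` (s/mm²) splits the schedule; b ≥ boundary belongs to the
    high-b (diffusion-only) segment. Bounds are in mm²/s. ``n_refine``
    is the number of perfusion-corrected re-estimations of D (0 disables
    the iteration); ``step2_all_b=False`` restricts the perfusion step to
    the low-b segment only.
    """

    boundary: float = 200.0
    d_bounds: tuple[float, float] = (1e-5, 5e-3)
    dstar_max: float = 0.5
    f_bounds: tuple[float, float] = (0.0, 1.0)
    max_iter: int = 200
    tol: float = 1e-10
    step2_all_b: bool = True
    n_refine: int = 2

    def validate_against(self, protocol: DiffusionProtocol) -> None:
        b = protocol.as_array()
        if np.sum(b >= self.boundary) < 2 or np.sum(b < self.boundary) < 2:
            raise ValidationError(
                "boundary: need at least 2 b-values on each side")


@dataclass(frozen=True)
class IVIMFitResult:
    """One voxel's segmented-fit output.

    ``params`` is None when the fit failed outright; ``converged`` is
    False whenever the optimizer did not converge or the estimates
    violate the parameter invariants.
    """

    params: IVIMParams | None
    rss: float
    n_highb: int
    n_lowb: int
    converged: bool
    boundary: float


def _model(b: np.ndarray, s0: float, f: float, d: float,
           dstar: float) -> np.ndarray:
    return s0 * ((1.0 - f) * np.exp(-b * d) + f * np.exp(-b * dstar))


def _loglinear_d(b: np.ndarray, signal: np.ndarray,
                 weighted: bool) -> tuple[float, float]:
    """Slope/intercept of ln(signal) on b; returns (D, intercept)."""
    slope, intercept = np.polyfit(b, np.log(signal), 1,
                                  w=signal if weighted else None)
    return max(-float(slope), 0.0), float(intercept)


def fit_monoexp_highb(signal: np.ndarray, protocol: DiffusionProtocol,
                      config: FitConfig = FitConfig()
                      ) -> tuple[float, float]:
    """Step 1: D and the log-intercept from the high-b segment.

    Unweighted least-squares line through (b, ln SI) over b ≥ boundary;
    the negated slope is D (clamped at 0 from below, so a constant
    signal gives D = 0) and the intercept estimates ln[S0·(1−f)].
    Non-positive signals in the segment are dropped with a warning; with
    fewer than 2 usable points both return values are NaN.
    """
    config.validate_against(protocol)
    b = protocol.as_array()
    signal = np.asarray(signal, dtype=float)
    hi = b >= config.boundary
    pos = signal > 0
    if not pos[hi].all():
        warnings.warn(f"high-b segment: dropping {int((~pos[hi]).sum())} "
                      "non-positive signals before log transform")
    sel = hi & pos
    if sel.sum() < 2:
        return float("nan"), float("nan")
    return _loglinear_d(b[sel], signal[sel], weighted=False)


def fit_perfusion(signal: np.ndarray, protocol: DiffusionProtocol,
                  d_fixed: float, config: FitConfig = FitConfig()
                  ) -> tuple[float, float, float, bool]:
    """Step 2: (f, Dstar, S0, converged) with D held fixed.

    Bounded nonlinear least squares of the full bi-exponential;
    f ∈ f_bounds, Dstar ∈ [d_fixed, dstar_max], S0 > 0. On
    non-convergence the best iterate is returned with the flag False.
    """
    if not d_fixed > 0:
        raise ValidationError("d_fixed: must be positive")
    b = protocol.as_array()
    signal = np.asarray(signal, dtype=float)
    if config.step2_all_b:
        sel = np.ones_like(b, dtype=bool)
    else:
        sel = b < config.boundary
    bb, ss = b[sel], signal[sel]
    if bb.size < 3:
        raise ValidationError("signal: need at least 3 points for step 2")

    si0 = float(signal[0])
    _, intercept = fit_monoexp_highb(signal, protocol, config)
    if np.isfinite(intercept) and si0 > 0:
        f0 = 1.0 - np.exp(intercept) / si0
    else:
        f0 = 0.1
    f0 = float(np.clip(f0, 0.01, 0.5))
    ds0 = float(np.clip(10.0 * d_fixed, d_fixed * 1.001, config.dstar_max))
    s00 = max(si0, 1e-6)

    def resid(x: np.ndarray) -> np.ndarray:
        return _model(bb, x[0], x[1], d_fixed, x[2]) - ss

    lower = [1e-12, config.f_bounds[0], d_fixed]
    upper = [np.inf, config.f_bounds[1], config.dstar_max]
    x0 = np.clip([s00, f0, ds0], lower, upper)
    res = least_squares(resid, x0, bounds=(lower, upper),
                        max_nfev=config.max_iter * 10,
                        xtol=config.tol, ftol=config.tol, gtol=config.tol)
    s0_hat, f_hat, ds_hat = (float(v) for v in res.x)
    # keep the two compartments strictly ordered for downstream invariants
    ds_hat = max(ds_hat, d_fixed * (1.0 + 1e-9))
    return f_hat, ds_hat, s0_hat, bool(res.status > 0)


def _refit_d_corrected(b: np.ndarray, signal: np.ndarray, hi: np.ndarray,
                       s0: float, f: float, dstar: float,
                       d_fallback: float, config: FitConfig) -> float:
    """Re-estimate D from the perfusion-subtracted high-b signal."""
    corrected = signal - s0 * f * np.exp(-b * dstar)
    sel = hi & (corrected > 0)
    if sel.sum() < 2:
        return d_fallback
    d, _ = _loglinear_d(b[sel], corrected[sel], weighted=True)
    return float(np.clip(d, config.d_bounds[0], config.d_bounds[1]))


def fit_ivim_voxel(signal: np.ndarray, protocol: DiffusionProtocol,
                   config: FitConfig = FitConfig()) -> IVIMFitResult:
    """Iterated segmented fit of one voxel.

    Step 1, step 2, then ``n_refine`` rounds of perfusion-corrected
    re-estimation of D (each followed by a fresh perfusion step).
    """
    b = protocol.as_array()
    signal = np.asarray(signal, dtype=float)
    if signal.shape != b.shape:
        raise ValidationError("signal: length differs from protocol")
    n_hi = int(np.sum(b >= config.boundary))
    n_lo = int(np.sum(b < config.boundary))
    if not np.any(signal > 0):
        return IVIMFitResult(None, float("nan"), n_hi, n_lo, False,
                             config.boundary)
    d_hat, _ = fit_monoexp_highb(signal, protocol, config)
    if not np.isfinite(d_hat):
        return IVIMFitResult(None, float("nan"), n_hi, n_lo, False,
                             config.boundary)
    d_used = float(np.clip(d_hat, config.d_bounds[0], config.d_bounds[1]))
    f_hat, ds_hat, s0_hat, ok = fit_perfusion(signal, protocol, d_used,
                                              config)
    hi = b >= config.boundary
    for _ in range(config.n_refine):
        d_used = _refit_d_corrected(b, signal, hi, s0_hat, f_hat, ds_hat,
                                    d_used, config)
        f_hat, ds_hat, s0_hat, ok = fit_perfusion(signal, protocol, d_used,
                                                  config)
    rss = float(np.sum((_model(b, s0_hat, f_hat, d_used, ds_hat)
                        - signal) ** 2))
    try:
        params = IVIMParams(S0=s0_hat, D=d_used, Dstar=ds_hat, f=f_hat)
    except ValidationError:
        return IVIMFitResult(None, rss, n_hi, n_lo, False, config.boundary)
    return IVIMFitResult(params, rss, n_hi, n_lo, ok, config.boundary)


def fit_ivim_map(volume4d: np.ndarray, mask: np.ndarray,
                 protocol: DiffusionProtocol,
                 config: FitConfig = FitConfig()
                 ) -> dict[str, np.ndarray]:
    """Voxelwise maps of D, Dstar, f, S0 plus QC (converged, rss).

    The refinement rounds subtract each voxel's perfusion compartment
    scaled by the ROI-median f and D* (robust across the ROI) rather
    than the voxel's own noisy estimates; for a single-voxel mask the
    median is the voxel's own estimate and the result coincides with
    :func:`fit_ivim_voxel`. Unmasked voxels carry NaN.
    """
    volume4d = np.asarray(volume4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume4d.ndim != 4:
        raise ValidationError("volume4d: expected a 4D array")
    if mask.shape != volume4d.shape[:3]:
        raise ValidationError("mask: shape differs from volume grid")
    if volume4d.shape[3] != len(protocol):
        raise ValidationError("volume4d: 4th dimension differs from protocol")
    if not mask.any():
        raise ValidationError("mask: empty")
    b = protocol.as_array()
    hi = b >= config.boundary
    base = FitConfig(boundary=config.boundary, d_bounds=config.d_bounds,
                     dstar_max=config.dstar_max, f_bounds=config.f_bounds,
                     max_iter=config.max_iter, tol=config.tol,
                     step2_all_b=config.step2_all_b, n_refine=0)
    idx = list(zip(*np.nonzero(mask)))
    state: dict = {}
    for i in idx:
        r = fit_ivim_voxel(volume4d[i], protocol, base)
        state[i] = r
    for _ in range(config.n_refine):
        good = [i for i in idx if state[i].params is not None]
        if not good:
            break
        f_med = float(np.median([state[i].params.f for i in good]))
        ds_med = float(np.median([state[i].params.Dstar for i in good]))
        for i in good:
            sig = volume4d[i]
            p = state[i].params
            d_used = _refit_d_corrected(b, sig, hi, p.S0, f_med, ds_med,
                                        p.D, config)
            f_hat, ds_hat, s0_hat, ok = fit_perfusion(sig, protocol,
                                                      d_used, config)
            rss = float(np.sum((_model(b, s0_hat, f_hat, d_used, ds_hat)
                                - sig) ** 2))
            try:
                params = IVIMParams(S0=s0_hat, D=d_used, Dstar=ds_hat,
                                    f=f_hat)
                state[i] = IVIMFitResult(params, rss, state[i].n_highb,
                                         state[i].n_lowb, ok,
                                         config.boundary)
            except ValidationError:
                state[i] = IVIMFitResult(None, rss, state[i].n_highb,
                                         state[i].n_lowb, False,
                                         config.boundary)
    grid = volume4d.shape[:3]
    maps = {k: np.full(grid, np.nan)
            for k in ("D", "Dstar", "f", "S0", "rss")}
    conv = np.zeros(grid, dtype=bool)
    for i in idx:
        r = state[i]
        conv[i] = r.converged
        maps["rss"][i] = r.rss
        if r.params is not None:
            maps["D"][i] = r.params.D
            maps["Dstar"][i] = r.params.Dstar
            maps["f"][i] = r.params.f
            maps["S0"][i] = r.params.S0
    maps["converged"] = conv
    return maps
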