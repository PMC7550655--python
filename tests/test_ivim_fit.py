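"""Segmented IVIM fit: exactness, recovery, oracles, map composition."""

import numpy as np
import pytest

from ivimr2.acquisition import (DiffusionProtocol, IVIMParams,
                                ValidationError, ivim_signal)
from ivimr2.ivim import (FitConfig, fit_ivim_map, fit_ivim_voxel,
                         fit_monoexp_highb, fit_perfusion)
from ivimr2.simulate import NoiseSpec, generate_ivim_volume


def _grid_search_rss(signal, b, d_fixed, dstar_max=0.5,
                     n_dstar=200, n_f=101):
    """Brute-force oracle: best rss over a D* × f lattice, S0 optimal
    in closed form per lattice point (linear scale parameter)."""
    dstars = np.linspace(d_fixed * (1 + 1e-9), dstar_max, n_dstar)
    fs = np.linspace(0.0, 1.0, n_f)
    best = np.inf
    slow = np.exp(-b * d_fixed)
    for ds in dstars:
        fast = np.exp(-b * ds)
        for f in fs:
            m = (1 - f) * slow + f * fast
            denom = float(m @ m)
            s0 = float(m @ signal) / denom if denom > 0 else 0.0
            if s0 <= 0:
                continue
            rss = float(np.sum((s0 * m - signal) ** 2))
            best = min(best, rss)
    return best


class TestHighBStep:
    def test_exact_monoexponential_recovered(self, dwi):
        b = dwi.as_array()
        d_true = 0.8e-3
        d, ic = fit_monoexp_highb(1234.0 * np.exp(-b * d_true), dwi)
        assert d == pytest.approx(d_true, rel=1e-12)
        assert np.exp(ic) == pytest.approx(1234.0, rel=1e-10)

    def test_constant_signal_gives_zero_d(self, dwi):
        d, _ = fit_monoexp_highb(np.full(len(dwi), 500.0), dwi)
        assert d == pytest.approx(0.0, abs=1e-15)

    def test_nonpositive_points_dropped_with_warning(self, dwi):
        b = dwi.as_array()
        sig = 1000.0 * np.exp(-b * 1e-3)
        sig[-1] = 0.0
        with pytest.warns(UserWarning, match="non-positive"):
            d, _ = fit_monoexp_highb(sig, dwi)
        assert d == pytest.approx(1e-3, rel=1e-10)

    def test_too_few_usable_points_returns_nan_not_raise(self, dwi):
        sig = np.zeros(len(dwi))
        sig[0] = 1000.0
        with pytest.warns(UserWarning):
            d, ic = fit_monoexp_highb(sig, dwi)
        assert np.isnan(d) and np.isnan(ic)

    def test_boundary_needs_two_points_each_side(self):
        proto = DiffusionProtocol((0, 50, 100, 200))
        with pytest.raises(ValidationError, match="boundary"):
            fit_monoexp_highb(np.ones(4), proto,
                              FitConfig(boundary=150.0))


class TestPerfusionStep:
    def test_zero_perfusion_detected(self, dwi):
        b = dwi.as_array()
        sig = 900.0 * np.exp(-b * 1.1e-3)
        f, ds, s0, ok = fit_perfusion(sig, dwi, 1.1e-3)
        assert ok
        assert f < 1e-6
        assert s0 == pytest.approx(900.0, rel=1e-4)

    def test_dstar_respects_lower_box_constraint(self, dwi, baseline_ivim):
        sig = ivim_signal(baseline_ivim, dwi)
        for d_fixed in (0.5e-3, 1e-3, 3e-3):
            _, ds, _, _ = fit_perfusion(sig, dwi, d_fixed)
            assert ds >= d_fixed

    def test_invalid_d_fixed_rejected(self, dwi):
        with pytest.raises(ValidationError):
            fit_perfusion(np.ones(len(dwi)), dwi, 0.0)


class TestVoxelFit:
    def test_noiseless_baseline_recovery_within_ten_percent(self, dwi,
                                                            baseline_ivim):
        r = fit_ivim_voxel(ivim_signal(baseline_ivim, dwi), dwi)
        assert r.converged and r.params is not None
        assert r.params.D == pytest.approx(baseline_ivim.D, rel=0.10)
        assert r.params.Dstar == pytest.approx(baseline_ivim.Dstar, rel=0.10)
        assert r.params.f == pytest.approx(baseline_ivim.f, rel=0.10)
        assert r.n_highb == 7 and r.n_lowb == 6

    def test_all_zero_signal_flagged_not_raised(self, dwi):
        r = fit_ivim_voxel(np.zeros(len(dwi)), dwi)
        assert not r.converged and r.params is None

    def test_rss_not_worse_than_truth_at_same_fixed_d(self, dwi,
                                                      baseline_ivim):
        """Step-2 optimality: at the fit's own D, the returned perfusion
        parameters beat the true ones in residual sum of squares."""
        sig = ivim_signal(baseline_ivim, dwi)
        r = fit_ivim_voxel(sig, dwi)
        b = dwi.as_array()
        p = r.params
        truth_at_d = baseline_ivim.S0 * (
            (1 - baseline_ivim.f) * np.exp(-b * p.D)
            + baseline_ivim.f * np.exp(-b * baseline_ivim.Dstar))
        assert r.rss <= np.sum((truth_at_d - sig) ** 2) + 1e-9

    def test_estimated_f_monotone_in_true_f(self, dwi):
        """Increasing true perfusion fraction raises its estimate."""
        ests = []
        for f_true in np.linspace(0.0, 0.3, 7):
            p = IVIMParams(S0=1000, D=0.556e-3, Dstar=8.53e-3,
                           f=float(f_true))
            r = fit_ivim_voxel(ivim_signal(p, dwi), dwi)
            ests.append(r.params.f)
        assert np.all(np.diff(ests) > 0)

    def test_boundary_choice_shifts_noiseless_d_under_3pct(self, dwi,
                                                           baseline_ivim):
        sig = ivim_signal(baseline_ivim, dwi)
        d200 = fit_ivim_voxel(sig, dwi, FitConfig(boundary=200)).params.D
        d300 = fit_ivim_voxel(sig, dwi, FitConfig(boundary=300)).params.D
        assert abs(d300 - d200) / d200 < 0.03

    def test_grid_search_oracle_matches_fit_rss(self, dwi, default_phantom):
        """Exhaustive D*×f search at the fit's D agrees with the
        optimizer's rss on noisy voxels."""
        spec, noise = default_phantom
        noise = NoiseSpec(model="rician", sigma=noise.sigma, seed=21)
        vol, truth, mask = generate_ivim_volume(spec, dwi, noise)
        b = dwi.as_array()
        coords = np.argwhere(mask)
        rng = np.random.default_rng(21)
        picks = coords[rng.choice(len(coords), size=20, replace=False)]
        for i in map(tuple, picks):
            r = fit_ivim_voxel(vol[i], dwi)
            oracle = _grid_search_rss(vol[i], b, r.params.D)
            assert r.rss <= oracle * 1.01


class TestMapFit:
    def test_single_voxel_mask_reproduces_voxel_fit(self, dwi,
                                                    baseline_ivim):
        sig = ivim_signal(baseline_ivim, dwi)
        vol = sig.reshape(1, 1, 1, -1)
        mask = np.ones((1, 1, 1), dtype=bool)
        maps = fit_ivim_map(vol, mask, dwi)
        r = fit_ivim_voxel(sig, dwi)
        assert maps["D"][0, 0, 0] == pytest.approx(r.params.D, rel=1e-12)
        assert maps["f"][0, 0, 0] == pytest.approx(r.params.f, rel=1e-12)
        assert maps["Dstar"][0, 0, 0] == pytest.approx(r.params.Dstar,
                                                       rel=1e-12)

    def test_empty_mask_rejected(self, dwi):
        vol = np.ones((2, 2, 2, len(dwi)))
        with pytest.raises(ValidationError, match="empty"):
            fit_ivim_map(vol, np.zeros((2, 2, 2), bool), dwi)

    def test_protocol_length_mismatch_rejected(self, dwi):
        vol = np.ones((2, 2, 2, 5))
        with pytest.raises(ValidationError):
            fit_ivim_map(vol, np.ones((2, 2, 2), bool), dwi)

    def test_noiseless_phantom_roi_mean_d_within_1pct(self, dwi,
                                                      default_phantom,
                                                      noiseless):
        spec, _ = default_phantom
        vol, truth, mask = generate_ivim_volume(spec, dwi, noiseless)
        maps = fit_ivim_map(vol, mask, dwi)
        assert np.nanmean(maps["D"][mask]) == pytest.approx(
            truth["D"][mask].mean(), rel=0.01)
        assert maps["converged"][mask].all()
        assert np.isnan(maps["D"][~mask]).all()
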