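import numpy as np
import pytest

from densiscale.data_io import compute_density_matrix
from densiscale.scaling import (
    ConsistencyError,
    DegenerateDesignError,
    InsufficientDataError,
    davies_test,
    fit_all_indicators,
    fit_segmented,
    fit_single,
    profile_rss,
    select_model,
)
from densiscale.synthetic import SyntheticSpec, simulate

from conftest import single_indicator_spec


def two_segment_data(n=348, beta_L=0.8, beta_H=1.4, log_psi=np.log10(27.0), intercept=2.0,
                     noise=0.0, seed=5):
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(-0.6, 2.15, n))
    y = intercept + beta_L * x + (beta_H - beta_L) * np.maximum(0.0, x - log_psi)
    if noise:
        y = y + rng.normal(0, noise, n)
    return x, y


class TestFitSingle:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 2, 5)
        fit = fit_single(x, 2.0 + 1.5 * x)
        assert fit.beta == pytest.approx(1.5, abs=1e-12)
        assert fit.log_y0 == pytest.approx(2.0, abs=1e-12)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_flat_law_gives_zero_slope(self):
        x = np.linspace(0, 2, 8)
        fit = fit_single(x, np.full(8, 3.0))
        assert fit.beta == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_single([1.0, 2.0], [1.0, 2.0])

    def test_constant_log_d_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_single(np.ones(5), np.arange(5.0))

    def test_ci_covers_planted_beta_on_synthetic_draw(self):
        spec = single_indicator_spec(seed=7, model="single", beta_L=1.0)
        dm = compute_density_matrix(simulate(spec))
        fit = fit_single(dm.log_d, dm.log_y["x"])
        lo, hi = fit.ci95["beta"]
        assert lo <= 1.0 <= hi


class TestFitSegmented:
    def test_noiseless_recovery(self):
        x, y = two_segment_data()
        fit = fit_segmented(x, y)
        assert abs(fit.log_d_star - np.log10(27.0)) < 1e-3
        assert abs(fit.beta_L - 0.8) < 1e-6
        assert abs(fit.beta_H - 1.4) < 1e-6

    def test_continuity_identity_holds(self):
        x, y = two_segment_data(noise=0.15)
        fit = fit_segmented(x, y)
        lhs = fit.log_y1
        rhs = fit.log_y0 + (fit.beta_L - fit.beta_H) * fit.log_d_star
        assert abs(lhs - rhs) < 1e-9
        # fitted curve continuous at the break
        eps = 1e-9
        below = fit.predict(fit.log_d_star - eps)
        above = fit.predict(fit.log_d_star + eps)
        assert abs(below - above) < 1e-6

    def test_segmented_rss_never_exceeds_single(self):
        # nesting: the hinge model contains the single line
        rng = np.random.default_rng(0)
        for seed in range(5):
            x = rng.uniform(-0.6, 2.15, 100)
            y = 1.0 + 1.0 * x + rng.normal(0, 0.2, 100)
            assert fit_segmented(x, y).rss <= fit_single(x, y).rss + 1e-9

    def test_refined_optimum_agrees_with_brute_force_grid(self):
        # independent oracle: 1000-point profile grid
        x, y = two_segment_data(noise=0.15, seed=11)
        fit = fit_segmented(x, y)
        grid = np.quantile(x, np.linspace(0.02, 0.98, 1000))
        rss = profile_rss(x, y, grid)
        assert abs(fit.log_d_star - grid[np.argmin(rss)]) < 0.005

    def test_base_invariance_of_exponents(self):
        # switching log base rescales both axes; beta is a ratio and unchanged
        x, y = two_segment_data(noise=0.1, seed=3)
        f10 = fit_segmented(x, y)
        scale = np.log(10.0)
        fe = fit_segmented(x * scale, y * scale)
        assert fe.beta_L == pytest.approx(f10.beta_L, abs=1e-6)
        assert fe.beta_H == pytest.approx(f10.beta_H, abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_segmented(np.arange(9.0), np.arange(9.0))


class TestDaviesTest:
    def test_strong_break_detected(self):
        x, y = two_segment_data(beta_L=0.8, beta_H=1.4, noise=0.05, seed=21)
        assert davies_test(x, y) < 0.01

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            davies_test(np.arange(9.0), np.arange(9.0))

    def test_permutation_oracle_agrees_on_strong_signal(self):
        # independent check: permuting residuals of the single fit destroys
        # the break; the observed hinge improvement should be extreme
        x, y = two_segment_data(noise=0.05, seed=22)
        single = fit_single(x, y)
        seg = fit_segmented(x, y)
        obs_gain = single.rss - seg.rss
        rng = np.random.default_rng(1)
        resid = y - single.predict(x)
        exceed = 0
        n_perm = 200
        for _ in range(n_perm):
            yp = single.predict(x) + rng.permutation(resid)
            gain = fit_single(x, yp).rss - fit_segmented(x, yp, grid_points=50).rss
            exceed += gain >= obs_gain
        p_perm = (exceed + 1) / (n_perm + 1)
        assert p_perm < 0.01
        assert davies_test(x, y) < 0.01


class TestSelectModel:
    def test_high_davies_p_keeps_single(self):
        x, y = two_segment_data(noise=0.15, seed=2)
        single, seg = fit_single(x, y), fit_segmented(x, y)
        chosen = select_model(single, seg, davies_p=0.5)
        assert chosen.model == "single"
        assert chosen.alternatives["segmented"] is seg

    def test_tiny_davies_p_with_better_bic_selects_segmented(self):
        x, y = two_segment_data(noise=0.05, seed=2)
        single, seg = fit_single(x, y), fit_segmented(x, y)
        assert seg.bic < single.bic
        assert select_model(single, seg, davies_p=1e-6).model == "segmented"

    def test_boundary_optimum_demoted(self):
        x, y = two_segment_data(noise=0.05, seed=2)
        single, seg = fit_single(x, y), fit_segmented(x, y)
        import dataclasses

        seg_b = dataclasses.replace(seg, boundary=True)
        assert select_model(single, seg_b, davies_p=1e-6).model == "single"

    def test_mismatched_fits_rejected(self):
        x, y = two_segment_data(noise=0.05, seed=2)
        single = fit_single(x[:100], y[:100])
        seg = fit_segmented(x, y)
        with pytest.raises(ConsistencyError):
            select_model(single, seg, davies_p=0.5)


class TestFitAllIndicators:
    def test_planted_models_recovered(self, default_dm):
        fits = fit_all_indicators(default_dm)
        assert len(fits) == 12
        for name in fits.fits:
            expected = "segmented" if not name.startswith("mortality") else "single"
            assert fits[name].model == expected, name
        assert fits.n_segmented == 8
        assert 23 < fits.median_d_star < 31

    def test_dstar_rank_order_data(self, default_dm):
        fits = fit_all_indicators(default_dm)
        vals = fits.d_star_values()
        assert len(vals) == fits.n_segmented
        assert vals.is_monotonic_increasing

    def test_fit_table_csv_round_trip(self, default_dm, tmp_path):
        fits = fit_all_indicators(default_dm)
        out = tmp_path / "fits.csv"
        fits.write_csv(out)
        import pandas as pd

        df = pd.read_csv(out, index_col=0)
        assert set(df.index) == set(fits.fits)
        assert {"model", "beta_L", "d_star", "davies_p", "bic_single"} <= set(df.columns)
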