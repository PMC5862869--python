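"""Linearized vs nonlinear MEE estimation, checked against independent
oracles: hand-assembled OLS normal equations and a dense grid search."""

import numpy as np
import pytest

from cisne import (
    DegenerateFitError,
    DoseEffectDataset,
    FitInfeasibleError,
    fit_linear,
    fit_nonlinear,
    initial_guess,
    load_fixture,
    predict_fa,
)
from conftest import NINE_DOSES, exact_dataset, noisy_dataset


def ols_oracle(data):
    """Normal equations for y' on x' computed from first principles."""
    keep = (data.fa > 0) & (data.fa < 1)
    xp = np.log(data.doses[keep])
    yp = np.log(data.fa[keep] / (1 - data.fa[keep]))
    n = len(xp)
    sx, sy, sxx, sxy = xp.sum(), yp.sum(), (xp * xp).sum(), (xp * yp).sum()
    m = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    b = (sy - m * sx) / n
    return m, np.exp(-b / m)


def rss(data, m, D):
    r = data.fa - predict_fa((m, D), data.doses)
    return float(r @ r)


def grid_oracle(data, n=200):
    """Dense log-spaced grid search over (m, D), refined once."""
    ms = np.geomspace(0.05, 10, n)
    Ds = np.geomspace(0.01 * data.doses.min(), 100 * data.doses.max(), n)
    best = None
    for m in ms:
        for D in Ds:
            v = rss(data, m, D)
            if best is None or v < best[0]:
                best = (v, m, D)
    # one local refinement pass around the winner
    _, m0, D0 = best
    for m in np.geomspace(m0 / 1.1, m0 * 1.1, 60):
        for D in np.geomspace(D0 / 1.1, D0 * 1.1, 60):
            v = rss(data, m, D)
            if v < best[0]:
                best = (v, m, D)
    return best


class TestLinearFit:
    @pytest.mark.parametrize("m, D", [(2.0, 10.0), (0.5, 3.0), (1.0, 42.0)])
    def test_exact_data_recovered_with_unit_correlation(self, m, D):
        p = fit_linear(exact_dataset(m, D))
        assert p.m == pytest.approx(m, rel=1e-9)
        assert p.D == pytest.approx(D, rel=1e-9)
        assert p.r == pytest.approx(1.0, abs=1e-12)
        assert p.diagnostics["perfect_fit"]

    def test_two_points_give_geometric_midpoint_D(self):
        data = DoseEffectDataset(label="t", doses=[5.0, 20.0], fa=[0.2, 0.8])
        p = fit_linear(data)
        assert p.m == pytest.approx(np.log(16) / np.log(4))
        assert p.D == pytest.approx(10.0, rel=1e-12)

    def test_matches_hand_ols_on_fixture_data(self):
        for name in ("table1", "table2"):
            for data in load_fixture(name):
                p = fit_linear(data)
                m_ref, D_ref = ols_oracle(data)
                assert p.m == pytest.approx(m_ref, rel=1e-7)
                assert p.D == pytest.approx(D_ref, rel=1e-7)

    def test_boundary_points_are_dropped_and_counted(self):
        data = DoseEffectDataset(
            label="t",
            doses=NINE_DOSES,
            fa=[-0.01, 0.05, 0.2, 0.35, 0.5, 0.65, 0.8, 0.95, 1.02],
        )
        p = fit_linear(data)
        assert p.n_dropped == 2
        assert p.n_used == 7
        assert p.n_used + p.n_dropped == len(data)

    def test_too_few_interior_points_is_infeasible(self):
        data = DoseEffectDataset(label="t", doses=[1.0, 2.0, 4.0],
                                 fa=[0.0, 0.5, 1.0])
        with pytest.raises(FitInfeasibleError):
            fit_linear(data)

    def test_decreasing_effect_is_degenerate(self):
        data = DoseEffectDataset(label="t", doses=[1.0, 10.0, 100.0],
                                 fa=[0.9, 0.5, 0.1])
        with pytest.raises(DegenerateFitError):
            fit_linear(data)

    def test_standard_errors_positive_on_noisy_data(self, rng):
        p = fit_linear(noisy_dataset(1.0, 10.0, 0.05, rng))
        assert p.se_m > 0 and p.se_D > 0
        assert p.cov[0, 1] == pytest.approx(p.cov[1, 0])
        assert np.all(np.linalg.eigvalsh(p.cov) >= -1e-15)


class TestNonlinearFit:
    @pytest.mark.parametrize("m, D", [(0.5, 10.0), (2.0, 10.0), (1.3, 0.7)])
    def test_exact_data_is_zero_residual_optimum(self, m, D):
        p = fit_nonlinear(exact_dataset(m, D))
        assert p.m == pytest.approx(m, rel=1e-8)
        assert p.D == pytest.approx(D, rel=1e-8)
        assert p.rss < 1e-20
        assert p.diagnostics["perfect_fit"]

    def test_matches_grid_search_oracle_on_fixture_data(self):
        for data in load_fixture("table2"):
            p = fit_nonlinear(data)
            best_rss, m_ref, D_ref = grid_oracle(data)
            assert p.rss <= best_rss + 1e-12
            assert p.m == pytest.approx(m_ref, rel=2e-2)
            assert p.D == pytest.approx(D_ref, rel=2e-2)

    def test_out_of_range_points_enter_the_fit(self):
        fa = [0.01, 0.03, 0.1, 0.3, 0.5, 0.7, 0.9, 0.999, 1.02]
        data = DoseEffectDataset(label="t", doses=NINE_DOSES, fa=fa)
        p = fit_nonlinear(data)
        assert p.n_used == len(data)
        assert p.n_dropped == 0

    def test_constant_response_is_degenerate(self):
        data = DoseEffectDataset(label="t", doses=[1.0, 2.0, 4.0],
                                 fa=[0.5, 0.5, 0.5])
        with pytest.raises(DegenerateFitError):
            fit_nonlinear(data)

    def test_beats_grid_on_random_noisy_datasets(self, rng):
        for _ in range(50):
            m = float(rng.uniform(0.3, 4.0))
            data = noisy_dataset(m, 10.0, 0.05, rng)
            p = fit_nonlinear(data)
            grid_rss = min(
                rss(data, mm, DD)
                for mm in np.geomspace(0.05, 10, 200)
                for DD in np.geomspace(0.01 * data.doses.min(),
                                       100 * data.doses.max(), 200)
            )
            assert p.rss <= grid_rss + 1e-12

    def test_covariance_shrinks_with_noise(self, rng):
        loose = fit_nonlinear(noisy_dataset(2.0, 10.0, 0.08, rng))
        tight = fit_nonlinear(noisy_dataset(2.0, 10.0, 0.01, rng))
        assert tight.se_m < loose.se_m
        assert tight.se_D < loose.se_D


class TestDoseUnitEquivariance:
    @pytest.mark.parametrize("fitter", [fit_linear, fit_nonlinear])
    @pytest.mark.parametrize("scale", [0.001, 7.3, 1000.0])
    def test_rescaled_doses_rescale_D_only(self, fitter, scale, rng):
        data = noisy_dataset(1.5, 10.0, 0.05, rng)
        scaled = DoseEffectDataset(label="s", doses=data.doses * scale,
                                   fa=data.fa)
        p0, p1 = fitter(data), fitter(scaled)
        assert p1.m == pytest.approx(p0.m, rel=1e-6)
        assert p1.D == pytest.approx(p0.D * scale, rel=1e-6)


class TestInitialGuess:
    def test_exact_data_returns_truth(self):
        m, D = initial_guess(exact_dataset(2.0, 10.0))
        assert m == pytest.approx(2.0, rel=1e-9)
        assert D == pytest.approx(10.0, rel=1e-9)

    def test_fallback_picks_dose_nearest_half_effect(self):
        data = DoseEffectDataset(label="t", doses=[1.0, 7.0, 50.0],
                                 fa=[0.0, 0.49, 1.0])
        assert initial_guess(data) == (1.0, 7.0)

    def test_fallback_ties_resolve_to_lower_dose(self):
        # decreasing pattern -> degenerate linear fit -> fallback; both
        # points sit 0.1 from half-effect, so the tie goes to dose 3
        data = DoseEffectDataset(label="t", doses=[3.0, 9.0],
                                 fa=[0.6, 0.4])
        assert initial_guess(data) == (1.0, 3.0)

    def test_guess_valid_on_noisy_monotone_data(self, rng):
        data = noisy_dataset(1.0, 10.0, 0.05, rng)
        m, D = initial_guess(data)
        assert m > 0
        assert data.doses.min() / 100 <= D <= data.doses.max() * 100
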