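"""Boost parameterisation, boost energy and reweighting estimators."""

import math

import numpy as np
import pytest
import sympy

from amdreweigh import (
    BoostLog,
    FrameWeights,
    boost_energy,
    compute_boost_parameters,
    compute_weights,
    kt,
    maclaurin_factors,
    reweight_histogram,
)


class TestBoostParameters:
    def test_dihedral_channel_arithmetic(self):
        # 19 residues (incl. N-terminal acetyl), a1 = a2 = 3.5, V_avg = 210
        p = compute_boost_parameters(3.5, 3.5, 0, 0, 19, 8243, 210.0, -25429.0,
                                     mode="iamd2_dihedral")
        assert p.e_dihed == pytest.approx(276.5)
        assert p.alpha_dihed == pytest.approx(13.3)
        assert p.e_total is None and p.alpha_total is None

    def test_dual_boost_total_channel_arithmetic(self):
        p = compute_boost_parameters(3.5, 3.5, 0.30, 0.30, 19, 8243, 210.0, -25429.0,
                                     mode="iamd3_dual")
        assert p.e_total == pytest.approx(-25429.0 + 0.30 * 8243)
        assert p.alpha_total == pytest.approx(0.30 * 8243)
        assert p.e_dihed == pytest.approx(276.5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(a1=0.0, a2=3.5, b1=0, b2=0, mode="iamd2_dihedral"),
            dict(a1=3.5, a2=0.0, b1=0, b2=0, mode="iamd2_dihedral"),
            dict(a1=3.5, a2=3.5, b1=0.0, b2=0.3, mode="iamd3_dual"),
            dict(a1=0.0, a2=0.0, b1=0.3, b2=0.0, mode="iamd1_total"),
        ],
    )
    def test_zero_coefficient_on_active_channel_rejected(self, kwargs):
        with pytest.raises(ValueError):
            compute_boost_parameters(
                n_res=19, n_atoms=8243, v_avg_dihed=210.0, v_avg_total=-25429.0,
                **kwargs,
            )

    def test_bad_counts_and_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            compute_boost_parameters(3.5, 3.5, 0, 0, 0, 10, 1.0, 1.0, "iamd2_dihedral")
        with pytest.raises(ValueError):
            compute_boost_parameters(-1, 3.5, 0, 0, 19, 10, 1.0, 1.0, "iamd2_dihedral")


class TestBoostEnergy:
    def test_boundary_and_closed_form_values(self):
        assert boost_energy(5.0, 5.0, 2.0) == 0.0
        assert boost_energy(6.0, 5.0, 2.0) == 0.0  # V above threshold
        # V = E - alpha gives alpha^2 / (2 alpha) = alpha / 2
        assert boost_energy(3.0, 5.0, 2.0) == pytest.approx(1.0)

    def test_matches_symbolic_form_on_grid(self):
        v_sym, e_sym, a_sym = sympy.symbols("V E alpha")
        expr = sympy.lambdify(
            (v_sym, e_sym, a_sym), (e_sym - v_sym) ** 2 / (a_sym + e_sym - v_sym)
        )
        v = np.linspace(-40.0, 4.9, 1000)
        got = boost_energy(v, 5.0, 2.0)
        assert np.max(np.abs(got - expr(v, 5.0, 2.0))) < 1e-12

    def test_nonnegative_and_monotone_below_threshold(self):
        v = np.linspace(-50, 20, 5000)
        dv = boost_energy(v, 5.0, 3.0)
        assert np.all(dv >= 0)
        assert np.all(dv[v >= 5.0] == 0)
        below = dv[v < 5.0]
        assert np.all(np.diff(below) <= 0)  # decreasing in V

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            boost_energy(1.0, 5.0, 0.0)


class TestWeights:
    def test_zero_boost_gives_unit_weights(self):
        log = BoostLog.zeros(100)
        for est, order in (("exponential", 0), ("maclaurin", 10)):
            w = compute_weights(log, estimator=est, order=max(order, 1))
            assert np.all(w.weights == 1.0)

    def test_single_frame_exponential_weight(self):
        log = BoostLog(np.array([kt()]), np.zeros(1), mode="iamd2_dihedral")
        w = compute_weights(log, estimator="exponential")
        assert w.weights[0] == pytest.approx(math.e)

    def test_maclaurin_10_close_to_exponential_at_small_boost(self):
        dv = np.full(5, 0.5 * kt())
        log = BoostLog(dv, np.zeros(5), mode="iamd2_dihedral")
        w_mac = compute_weights(log, estimator="maclaurin", order=10)
        w_exp = compute_weights(log, estimator="exponential")
        rel = np.abs(w_mac.weights / w_exp.weights - 1.0)
        assert np.max(rel) <= 1e-6

    def test_maclaurin_converges_monotonically_to_exponential(self):
        x = np.array([0.3, 1.0, 2.5])
        exact = np.exp(x)
        prev_gap = None
        for k in range(1, 15):
            gap = np.max(exact - maclaurin_factors(x, k))
            assert gap >= -1e-12  # truncation always undershoots for x > 0
            if prev_gap is not None:
                assert gap <= prev_gap + 1e-12
            prev_gap = gap

    def test_negative_boost_rejected(self):
        with pytest.raises(ValueError):
            BoostLog(np.array([-0.1]), np.zeros(1))

    def test_mode_selects_effective_boost_channel(self):
        dih = np.array([1.0, 2.0])
        tot = np.array([10.0, 20.0])
        assert np.array_equal(BoostLog(dih, tot, "iamd2_dihedral").dv, dih)
        assert np.array_equal(BoostLog(dih, tot, "iamd1_total").dv, tot)
        assert np.array_equal(BoostLog(dih, tot, "iamd3_dual").dv, dih + tot)


class TestReweightHistogram:
    def test_uniform_weights_symmetric_bins_give_flat_pmf(self):
        series = np.array([0.1] * 50 + [0.9] * 50)
        grid = reweight_histogram(series, FrameWeights.uniform(100), bins=2,
                                  hist_range=(0.0, 1.0))
        assert np.allclose(grid.pmf, [0.0, 0.0])

    def test_zero_boost_reweight_identical_to_raw_histogram(self):
        rng = np.random.default_rng(0)
        series = rng.normal(size=(500, 2))
        w = compute_weights(BoostLog.zeros(500), estimator="maclaurin", order=10)
        grid_w = reweight_histogram(series, w, bins=10)
        raw = reweight_histogram(series, FrameWeights.uniform(500), bins=10)
        assert np.array_equal(grid_w.prob, raw.prob)
        assert np.array_equal(
            np.nan_to_num(grid_w.pmf, nan=-1), np.nan_to_num(raw.pmf, nan=-1)
        )

    def test_invariant_to_weight_scaling(self):
        rng = np.random.default_rng(1)
        series = rng.normal(size=400)
        w = rng.random(400) + 0.5
        g1 = reweight_histogram(series, FrameWeights("exponential", w), bins=20)
        g2 = reweight_histogram(series, FrameWeights("exponential", 7.3 * w), bins=20)
        assert np.allclose(g1.prob, g2.prob)
        assert np.allclose(np.nan_to_num(g1.pmf), np.nan_to_num(g2.pmf))

    def test_pmf_grid_invariants(self):
        rng = np.random.default_rng(2)
        series = rng.normal(size=(2000, 2))
        w = FrameWeights("exponential", rng.random(2000) + 0.1)
        grid = reweight_histogram(series, w, bins=15)
        assert grid.prob[grid.mask].sum() == pytest.approx(1.0)
        assert np.nanmin(grid.pmf) == 0.0
        assert np.all(np.isnan(grid.pmf[~grid.mask]))

    def test_cumulant2_with_zero_boost_equals_raw(self):
        rng = np.random.default_rng(3)
        series = rng.normal(size=300)
        w = compute_weights(BoostLog.zeros(300), estimator="cumulant2")
        grid = reweight_histogram(series, w, bins=12)
        raw = reweight_histogram(series, FrameWeights.uniform(300), bins=12)
        assert np.allclose(grid.prob, raw.prob)

    def test_length_mismatch_and_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            reweight_histogram(np.zeros(10), FrameWeights.uniform(5))
        with pytest.raises(ValueError):
            reweight_histogram(
                np.zeros(4), FrameWeights("exponential", np.zeros(4))
            )


class TestRecovery:
    """Biased sampling -> weights -> histogram recovers the analytic surface."""

    @pytest.mark.parametrize(
        "estimator,order,tol",
        [("maclaurin", 10, 0.3), ("exponential", 0, 0.5), ("cumulant2", 0, 0.5)],
    )
    def test_double_well_pmf_recovery(self, well, biased_run, estimator, order, tol):
        series, log = biased_run
        w = compute_weights(log, estimator=estimator, order=max(order, 1))
        grid = reweight_histogram(
            np.column_stack([series.phi[:, 0], series.psi[:, 0]]),
            w, bins=72, hist_range=[[-180, 180], [-180, 180]],
        )
        centers = grid.centers[0]
        analytic = well.analytic_pmf(centers, grid.centers[1])
        sel = grid.mask & (analytic < 4.0)
        mae = np.mean(np.abs(grid.pmf[sel] - analytic[sel]))
        assert mae <= tol
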