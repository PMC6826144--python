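import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from telomr.errors import InsufficientData, ValidationError
from telomr.mr import (
    MRInput,
    egger_correlated,
    fdr_bh,
    finalize,
    ivw_correlated,
    maxlik_correlated,
    run_methods,
)


def _random_input(seed=0, J=5, theta=0.2, rho=None, het=0.0):
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.03, 0.12, J)
    bxse = rng.uniform(0.005, 0.02, J)
    byse = rng.uniform(0.01, 0.03, J)
    rho_m = np.eye(J) if rho is None else rho
    chol = np.linalg.cholesky(np.outer(byse, byse) * rho_m)
    by = theta * bx + chol @ rng.standard_normal(J) + het * rng.standard_normal(J)
    return MRInput(bx=bx, bxse=bxse, by=by, byse=byse, rho=rho_m)


def _corr(J, off=0.3):
    m = np.full((J, J), off)
    np.fill_diagonal(m, 1.0)
    return m


class TestIVW:
    def test_single_instrument_wald(self):
        inp = MRInput(bx=[0.5], bxse=[0.01], by=[0.1], byse=[0.02])
        res = ivw_correlated(inp)
        assert res.theta == pytest.approx(0.2, abs=1e-12)
        expected_se = np.sqrt(0.02**2 / 0.5**2 + 0.1**2 * 0.01**2 / 0.5**4)
        assert res.se == pytest.approx(expected_se, abs=1e-12)

    def test_identity_rho_matches_classical_ivw_oracle(self):
        inp = _random_input(seed=1, J=3)
        res = ivw_correlated(inp, model="fixed")
        w = 1.0 / inp.byse**2
        oracle = np.sum(w * inp.bx * inp.by) / np.sum(w * inp.bx**2)
        oracle_se = 1.0 / np.sqrt(np.sum(w * inp.bx**2))
        assert res.theta == pytest.approx(oracle, abs=1e-10)
        assert res.se == pytest.approx(oracle_se, abs=1e-10)

    def test_correlated_matches_gls_minimization_oracle(self):
        rho = _corr(4, 0.4)
        inp = _random_input(seed=2, J=4, rho=rho)
        res = ivw_correlated(inp, model="fixed")
        omega_inv = np.linalg.inv(np.outer(inp.byse, inp.byse) * rho)

        def ssr(theta):
            r = inp.by - theta * inp.bx
            return float(r @ omega_inv @ r)

        oracle = optimize.minimize_scalar(ssr, bracket=(-1, 0, 1), method="brent").x
        assert res.theta == pytest.approx(oracle, abs=1e-8)

    def test_random_effects_inflation_floored_at_one(self):
        inp = MRInput(bx=[0.1, 0.2, 0.3], bxse=[0.01] * 3,
                      by=[0.02, 0.04, 0.06], byse=[0.02] * 3)
        fixed = ivw_correlated(inp, model="fixed")
        random = ivw_correlated(inp, model="random")
        assert fixed.Q == pytest.approx(0.0, abs=1e-20)
        assert random.se == pytest.approx(fixed.se)  # no shrink below fixed

    def test_heterogeneity_inflates_se(self):
        inp = _random_input(seed=4, J=8, het=0.05)
        fixed = ivw_correlated(inp, model="fixed")
        random = ivw_correlated(inp, model="random")
        assert random.Q > inp.J - 1
        assert random.se > fixed.se

    def test_unknown_model(self):
        with pytest.raises(ValidationError):
            ivw_correlated(_random_input(), model="bayes")


class TestMaxlik:
    def test_single_instrument_equals_wald(self):
        inp = MRInput(bx=[0.5], bxse=[0.01], by=[0.1], byse=[0.02])
        assert maxlik_correlated(inp).theta == pytest.approx(0.2, abs=1e-8)

    def test_close_to_ivw_on_homogeneous_inputs(self):
        for seed in range(100):
            inp = _random_input(seed=seed, J=6)
            ml = maxlik_correlated(inp)
            ivw = ivw_correlated(inp, model="fixed")
            assert abs(ml.theta - ivw.theta) < ivw.se

    def test_close_to_ivw_with_correlation(self):
        rho = _corr(5, 0.35)
        for seed in range(20):
            inp = _random_input(seed=300 + seed, J=5, rho=rho)
            ml = maxlik_correlated(inp)
            ivw = ivw_correlated(inp, model="fixed")
            assert abs(ml.theta - ivw.theta) < ivw.se

    def test_matches_grid_oracle(self):
        """Profile -2logL minimized by brute-force grid refinement."""
        inp = _random_input(seed=7, J=4, rho=_corr(4, 0.25))
        ml = maxlik_correlated(inp)
        sx = np.outer(inp.bxse, inp.bxse) * inp.rho
        sy = np.outer(inp.byse, inp.byse) * inp.rho
        sx_inv, sy_inv = np.linalg.inv(sx), np.linalg.inv(sy)

        def neg2ll(theta):
            xi = np.linalg.solve(
                sx_inv + theta**2 * sy_inv, sx_inv @ inp.bx + theta * (sy_inv @ inp.by)
            )
            rx, ry = inp.bx - xi, inp.by - theta * xi
            return rx @ sx_inv @ rx + ry @ sy_inv @ ry

        lo, hi = ml.theta - 0.5, ml.theta + 0.5
        for _ in range(6):
            grid = np.linspace(lo, hi, 2001)
            vals = [neg2ll(t) for t in grid]
            best = grid[int(np.argmin(vals))]
            lo, hi = best - (hi - lo) / 100, best + (hi - lo) / 100
        assert ml.theta == pytest.approx(best, abs=1e-6)

    def test_sample_overlap_correlation_configurable(self):
        inp = _random_input(seed=9, J=4)
        a = maxlik_correlated(inp, psi=0.0)
        b = maxlik_correlated(inp, psi=0.3)
        assert np.isfinite(b.theta)
        assert a.theta != pytest.approx(b.theta, abs=1e-12)


class TestEgger:
    def test_exact_line(self):
        bx = np.array([0.05, 0.08, 0.11, 0.15])
        by = 0.05 + 0.2 * bx
        inp = MRInput(bx=bx, bxse=[0.01] * 4, by=by, byse=[0.02] * 4)
        res = egger_correlated(inp)
        assert res.theta == pytest.approx(0.2, abs=1e-10)
        assert res.egger_intercept == pytest.approx(0.05, abs=1e-10)
        assert res.Q == pytest.approx(0.0, abs=1e-16)

    def test_matches_wls_oracle_identity_rho(self):
        import statsmodels.api as sm

        inp = _random_input(seed=13, J=6, het=0.01)
        res = egger_correlated(inp, model="fixed")
        X = np.column_stack([np.ones(6), inp.bx])
        fit = sm.WLS(inp.by, X, weights=1.0 / inp.byse**2).fit()
        assert res.theta == pytest.approx(fit.params[1], abs=1e-10)
        assert res.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientData):
            egger_correlated(MRInput(bx=[0.1, 0.2], bxse=[0.01] * 2,
                                     by=[0.02, 0.04], byse=[0.02] * 2))

    def test_requires_nonnegative_bx(self):
        inp = MRInput(bx=[-0.1, 0.2, 0.3], bxse=[0.01] * 3,
                      by=[0.0, 0.0, 0.0], byse=[0.02] * 3)
        with pytest.raises(ValidationError):
            egger_correlated(inp)

    def test_intercept_type_one_error_calibrated(self):
        """No pleiotropy: intercept test rejects at ~5%."""
        rejections = 0
        reps = 500
        rho = _corr(8, 0.2)
        for rep in range(reps):
            inp = _random_input(seed=10000 + rep, J=8, theta=0.15, rho=rho)
            if egger_correlated(inp, model="fixed").egger_intercept_p < 0.05:
                rejections += 1
        rate = rejections / reps
        assert 0.05 - 2.5 * np.sqrt(0.05 * 0.95 / reps) < rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_detects_directional_pleiotropy(self):
        """by shifted by a constant: intercept recovered, slope unbiased."""
        intercepts, slope_cover = [], 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(20000 + rep)
            bx = rng.uniform(0.04, 0.12, 10)
            byse = np.full(10, 0.01)
            by = 0.02 + 0.0 * bx + byse * rng.standard_normal(10)
            inp = MRInput(bx=bx, bxse=np.full(10, 0.01), by=by, byse=byse)
            res = egger_correlated(inp)
            intercepts.append(res.egger_intercept)
            if res.ci95[0] <= 0.0 <= res.ci95[1]:
                slope_cover += 1
        assert np.median(intercepts) > 0.015
        assert slope_cover / reps >= 0.90


class TestInvariances:
    @settings(max_examples=20, deadline=None)
    @given(c=st.floats(0.2, 5.0), seed=st.integers(0, 100))
    def test_scale_equivariance(self, c, seed):
        inp = _random_input(seed=seed, J=5, rho=_corr(5, 0.2))
        scaled = MRInput(bx=inp.bx * c, bxse=inp.bxse * c, by=inp.by,
                         byse=inp.byse, rho=inp.rho)
        for f in (ivw_correlated, egger_correlated):
            assert f(scaled).theta == pytest.approx(f(inp).theta / c, rel=1e-9)
        assert maxlik_correlated(scaled).theta == pytest.approx(
            maxlik_correlated(inp).theta / c, rel=1e-6
        )

    def test_permutation_invariance(self):
        inp = _random_input(seed=17, J=6, rho=_corr(6, 0.3))
        perm = np.random.default_rng(0).permutation(6)
        pinp = MRInput(bx=inp.bx[perm], bxse=inp.bxse[perm], by=inp.by[perm],
                       byse=inp.byse[perm], rho=inp.rho[np.ix_(perm, perm)])
        for f in (ivw_correlated, egger_correlated):
            a, b = f(inp), f(pinp)
            assert b.theta == pytest.approx(a.theta, abs=1e-12)
            assert b.se == pytest.approx(a.se, abs=1e-12)
        # iterative optimizer: invariant up to its convergence tolerance
        a, b = maxlik_correlated(inp), maxlik_correlated(pinp)
        assert b.theta == pytest.approx(a.theta, abs=1e-7)
        assert b.se == pytest.approx(a.se, abs=1e-7)

    def test_q_zero_for_proportional_inputs(self):
        bx = np.array([0.05, 0.1, 0.2, 0.07])
        inp = MRInput(bx=bx, bxse=[0.01] * 4, by=0.3 * bx, byse=[0.02] * 4,
                      rho=_corr(4, 0.25))
        res = ivw_correlated(inp)
        assert res.Q == pytest.approx(0.0, abs=1e-16)

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            MRInput(bx=[0.1, 0.2], bxse=[0.01], by=[0.1], byse=[0.01])
        with pytest.raises(ValidationError):
            MRInput(bx=[0.1], bxse=[0.0], by=[0.1], byse=[0.01])


class TestFdrBH:
    def test_single_p(self):
        assert fdr_bh([0.03]) == pytest.approx([0.03])

    def test_uniform_ladder(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.2, 0.2, 0.2]), [0.2] * 3)

    @staticmethod
    def _brute_force(p):
        """Step-up by definition: adj_i = min_{j: p_j >= p_i} (m * p_j / rank_j), capped."""
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        for pos, i in enumerate(order):
            candidates = [m * p[order[k]] / (k + 1) for k in range(pos, m)]
            adj[i] = min(1.0, min(candidates))
        return adj

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 40))
        np.testing.assert_allclose(fdr_bh(p), self._brute_force(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(99)
        p = rng.random(25)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(fdr_bh(p), expected, atol=1e-12)

    def test_order_preserved(self):
        p = [0.04, 0.01, 0.9]
        adj = fdr_bh(p)
        assert adj[1] <= adj[0] <= adj[2]

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            fdr_bh([0.5, 1.5])


class TestFinalize:
    def _results_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "outcome": ["a", "b", "a", "b"],
                "stratum": ["60+/all"] * 2 + ["all/all"] * 2,
                "method": ["maxlik"] * 4,
                "theta": [np.log(1.2), 0.1, 0.05, 0.02],
                "se": [0.02, 0.03, 0.02, 0.03],
                "p": [0.001, 0.2, 0.5, 0.6],
            }
        )

    def test_or_rescaling(self):
        out = finalize(self._results_frame())
        assert out.loc[0, "or_250bp"] == pytest.approx(1.2 ** (250 / 650))
        assert round(out.loc[0, "or_250bp"], 2) == 1.07

    def test_beta_rescaling(self):
        import pandas as pd

        df = self._results_frame()
        df.loc[1, "theta"] = 0.1
        out = finalize(df)
        assert round(out.loc[1, "theta_250bp"], 3) == 0.038

    def test_rescale_round_trip(self):
        from telomr.panel import bp_rescale

        theta = 0.123456789
        down = bp_rescale(theta, 250)
        back = bp_rescale(down, 650, source_bp=250)
        assert back == pytest.approx(theta, abs=1e-12)

    def test_fdr_family_limited_to_primary_stratum(self):
        out = finalize(self._results_frame())
        primary = out["stratum"] == "60+/all"
        assert out.loc[primary, "p_fdr"].notna().all()
        assert out.loc[~primary, "p_fdr"].isna().all()

    def test_ci_brackets_theta(self):
        out = finalize(self._results_frame())
        assert (out["ci_low_250bp"] <= out["theta_250bp"]).all()
        assert (out["theta_250bp"] <= out["ci_high_250bp"]).all()


def test_run_methods_rescales_consistently(panel):
    rng = np.random.default_rng(5)
    by = 0.2 * panel.beta_sd + 0.01 * rng.standard_normal(panel.J)
    inp = MRInput(bx=panel.beta_sd, bxse=panel.se_sd, by=by,
                  byse=np.full(panel.J, 0.01), rho=panel.r)
    fits = run_methods(inp)
    assert set(fits) == {"ivw", "maxlik", "egger"}
    for res in fits.values():
        assert res.theta_250bp == pytest.approx(res.theta * 250 / 650, abs=1e-12)
        assert res.or_250bp == pytest.approx(np.exp(res.theta_250bp), abs=1e-12)


def test_end_to_end_null_pvalues_uniform(panel):
    """Full MR stack on null summary inputs: p-values ~ Uniform(0,1)."""
    from scipy.stats import kstest

    pvals = []
    for rep in range(500):
        rng = np.random.default_rng(41000 + rep)
        byse = np.full(panel.J, 0.02)
        chol = np.linalg.cholesky(np.outer(byse, byse) * panel.r)
        by = chol @ rng.standard_normal(panel.J)
        inp = MRInput(bx=panel.beta_sd, bxse=panel.se_sd, by=by, byse=byse, rho=panel.r)
        pvals.append(ivw_correlated(inp, model="fixed").p)
    assert kstest(pvals, "uniform").pvalue > 0.01
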