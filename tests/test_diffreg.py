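"""Mixed-model fitting, likelihood-ratio testing and BH correction."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from phoscale import diffreg
from phoscale.diffreg import (
    LmmFit,
    UntestableEvent,
    bh_adjust,
    differential_table,
    fit_random_intercept_ml,
    lrt_pvalue,
)
from phoscale.preprocess import PairMatrix, build_pair_matrix, valid_value_filter
from phoscale.simulate import simulate_pair_observations


# ---------------------------------------------------------------------------
# independent oracle: brute-force V-matrix GLS + dense grid + refinement
# ---------------------------------------------------------------------------


def oracle_loglik(y, X, groups):
    """ML log-likelihood via explicit V construction and matrix inversion,
    maximized over a dense lambda grid with scalar refinement.  Shares no
    code with the implementation's profiled closed form."""
    y = np.asarray(y, float)
    n = len(y)
    Z = (np.asarray(groups)[:, None] == np.unique(groups)[None, :]).astype(float)

    def nll_at(lam):
        V = np.eye(n) + lam * Z @ Z.T
        Vi = np.linalg.inv(V)
        A = X.T @ Vi @ X
        theta = np.linalg.solve(A, X.T @ Vi @ y)
        r = y - X @ theta
        sigma2 = max(float(r @ Vi @ r) / n, 1e-300)
        _, logdet = np.linalg.slogdet(V)
        return 0.5 * n * (np.log(2 * np.pi * sigma2) + 1) + 0.5 * logdet

    grid = np.concatenate([[0.0], np.logspace(-8, 4, 200)])
    nlls = [nll_at(g) for g in grid]
    i = int(np.argmin(nlls))
    best = -nlls[i]
    if 0 < i < len(grid) - 1:
        res = minimize_scalar(
            lambda ll: nll_at(np.exp(ll)),
            bounds=(np.log(grid[i - 1] if i > 1 else grid[1] * 1e-4), np.log(grid[i + 1])),
            method="bounded",
            options={"xatol": 1e-13},
        )
        best = max(best, -float(res.fun))
    return best


class TestFitRandomInterceptML:
    def test_constant_data_no_signal(self, balanced_labels):
        arm, bio = balanced_labels
        fit = fit_random_intercept_ml(np.full(24, 5.0), arm, bio)
        assert fit.beta == 0.0
        assert lrt_pvalue(fit) == (0.0, 1.0)

    def test_balanced_complete_beta_is_mean_difference(self, balanced_labels):
        arm, bio = balanced_labels
        rng = np.random.default_rng(1)
        for _ in range(5):
            y = rng.normal(20, 1, 24)
            fit = fit_random_intercept_ml(y, arm, bio)
            expected = y[arm == "treated"].mean() - y[arm == "control"].mean()
            assert fit.beta == pytest.approx(expected, abs=1e-10)

    def test_loglik_matches_grid_oracle(self, balanced_labels):
        arm, bio = balanced_labels
        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(24), (arm == "treated").astype(float)])
        for i in range(20):
            b = rng.normal(0, rng.uniform(0.0, 0.6), 4)
            y = 20 + 0.4 * (arm == "treated") + b[bio - 1] + rng.normal(0, 0.3, 24)
            keep = rng.random(24) > (0.25 if i % 2 else 0.0)
            if len(np.unique(bio[keep])) < 2 or len(np.unique(arm[keep])) < 2:
                continue
            fit = fit_random_intercept_ml(y[keep], arm[keep], bio[keep])
            oracle = oracle_loglik(y[keep], X[keep], bio[keep])
            assert fit.loglik_full == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_against_lme4(self, tmp_path, balanced_labels):
        """Independent cross-check against the reference mixed-model fitter."""
        arm, bio = balanced_labels
        rng = np.random.default_rng(42)
        rows, fits = [], []
        for i in range(3):
            b = rng.normal(0, 0.3, 4)
            y = 23 + 0.5 * (arm == "treated") + b[bio - 1] + rng.normal(0, 0.2, 24)
            keep = rng.random(24) > (0.2 if i else 0.0)
            fits.append(fit_random_intercept_ml(y[keep], arm[keep], bio[keep]))
            rows += [(i, yy, aa, bb) for yy, aa, bb in zip(y[keep], arm[keep], bio[keep])]
        csv = tmp_path / "d.csv"
        pd.DataFrame(rows, columns=["ds", "y", "arm", "bio"]).to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            """
            suppressMessages(library(lme4))
            d <- read.csv(commandArgs(TRUE)[1])
            for (i in unique(d$ds)) {
              s <- d[d$ds == i, ]
              m <- lmer(y ~ arm + (1 | bio), data = s, REML = FALSE)
              m0 <- lmer(y ~ 1 + (1 | bio), data = s, REML = FALSE)
              cat(sprintf("%.10f %.10f %.10f\\n", logLik(m), fixef(m)[["armtreated"]], logLik(m0)))
            }
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(csv)], capture_output=True, text=True, check=True
        )
        for fit, line in zip(fits, out.stdout.strip().splitlines()):
            ll, beta, ll0 = map(float, line.split())
            assert fit.loglik_full == pytest.approx(ll, abs=1e-5)
            assert fit.beta == pytest.approx(beta, abs=1e-6)
            assert fit.loglik_null == pytest.approx(ll0, abs=1e-5)

    def test_boundary_equals_ols(self, balanced_labels):
        """With independent data (sigma_b = 0 truth) landing at the lambda=0
        boundary, the fit must coincide with OLS exactly."""
        arm, bio = balanced_labels
        rng = np.random.default_rng(11)
        for _ in range(20):
            y = rng.normal(0, 1, 24)  # no bio-rep structure
            fit = fit_random_intercept_ml(y, arm, bio)
            if fit.lambda_hat != 0.0:
                continue
            X = np.column_stack([np.ones(24), (arm == "treated").astype(float)])
            beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
            resid = y - X @ beta_ols
            sigma2 = float(resid @ resid) / 24
            ll_ols = -0.5 * 24 * (np.log(2 * np.pi * sigma2) + 1)
            assert fit.beta == pytest.approx(beta_ols[1], abs=1e-12)
            assert fit.loglik_full == pytest.approx(ll_ols, abs=1e-10)
            break
        else:
            pytest.fail("no boundary fit encountered")

    def test_confounded_variances_flat_likelihood(self):
        """One observation per bio rep: sigma_b^2 and sigma_e^2 are
        confounded; the profiled likelihood must be flat in lambda, and the
        fit falls back to the documented lambda = 0 boundary."""
        arm = np.array(["treated", "treated", "control", "control"])
        bio = np.array([1, 2, 3, 4])
        y = np.array([1.0, 2.0, 0.5, 1.5])
        fit = fit_random_intercept_ml(y, arm, bio)
        assert fit.lambda_hat == 0.0
        prof = diffreg._ProfiledLik(
            y, np.column_stack([np.ones(4), (arm == "treated").astype(float)]), bio
        )
        lls = [prof.loglik(lam) for lam in (0.0, 0.5, 2.0, 10.0)]
        assert np.allclose(lls, lls[0], atol=1e-9)

    def test_shift_scale_equivariance(self, balanced_labels):
        arm, bio = balanced_labels
        rng = np.random.default_rng(5)
        b = rng.normal(0, 0.25, 4)
        y = 20 + 0.8 * (arm == "treated") + b[bio - 1] + rng.normal(0, 0.2, 24)
        base = fit_random_intercept_ml(y, arm, bio)
        shifted = fit_random_intercept_ml(y + 3.0, arm, bio)
        scaled = fit_random_intercept_ml(y * 2.5, arm, bio)
        assert shifted.mu == pytest.approx(base.mu + 3.0, abs=1e-8)
        assert shifted.beta == pytest.approx(base.beta, abs=1e-9)
        assert lrt_pvalue(shifted)[0] == pytest.approx(lrt_pvalue(base)[0], abs=1e-7)
        assert scaled.beta == pytest.approx(2.5 * base.beta, abs=1e-8)
        assert lrt_pvalue(scaled)[0] == pytest.approx(lrt_pvalue(base)[0], abs=1e-7)

    @pytest.mark.parametrize(
        "y,arm,bio",
        [
            (np.ones(3), ["treated", "control", "control"], [1, 2, 2]),  # n < 4
            (np.ones(6), ["treated"] * 6, [1, 1, 1, 2, 2, 2]),  # one arm
            (np.ones(6), ["treated", "treated", "treated", "control", "control", "control"], [1] * 6),
        ],
    )
    def test_precondition_violations(self, y, arm, bio):
        with pytest.raises(UntestableEvent):
            fit_random_intercept_ml(y, np.array(arm), np.array(bio))


class TestLrt:
    def test_zero_stat_p_one(self):
        fit = LmmFit(0, 0, 0, 1, loglik_full=-3.0, loglik_null=-3.0, n_obs=10, lambda_hat=0)
        assert lrt_pvalue(fit) == (0.0, 1.0)

    def test_chi2_quantile(self):
        fit = LmmFit(0, 0, 0, 1, loglik_full=0.0, loglik_null=-3.841459 / 2, n_obs=10, lambda_hat=0)
        stat, p = lrt_pvalue(fit)
        assert stat == pytest.approx(3.841459)
        assert p == pytest.approx(0.05, abs=1e-6)


class TestBhAdjust:
    def test_worked_example(self):
        q = bh_adjust([0.001, 0.008, 0.039, 0.041])
        np.testing.assert_allclose(q, [0.004, 0.016, 0.041, 0.041], atol=1e-12)

    def test_single_p(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_nan_propagates_and_excluded_from_m(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_adjust([0.01, 0.04]))

    def test_matches_reference_implementation(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(123)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            expected = statsmodels.multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_input_order_preserved(self):
        p = [0.04, 0.001, 0.02]
        q = bh_adjust(p)
        q_sorted = bh_adjust(sorted(p))
        assert sorted(q) == pytest.approx(list(q_sorted))


def _matrix_from_sim(n_events, delta, rng, pair_design):
    values, arms, bios = [], None, None
    for y, arm, bio in simulate_pair_observations(n_events, delta, rng=rng):
        values.append(y)
        arms, bios = arm, bio
    cols = pd.DataFrame(
        {"arm": arms, "bio_rep": bios, "tech_rep": np.tile([1, 2, 3], 8)},
        index=pd.Index([f"s{i}" for i in range(24)], name="sample_id"),
    )
    frame = pd.DataFrame(np.array(values), columns=cols.index)
    return PairMatrix(condition=("bic", "5min"), frame=frame, columns=cols)


class TestDifferentialTable:
    def test_planted_event_detected(self, pair_design):
        rng = np.random.default_rng(99)
        delta = np.zeros(100)
        delta[17] = 3.0
        m = _matrix_from_sim(100, delta, rng, pair_design)
        table = differential_table(m)
        assert bool(table["regulated"].iloc[17])
        assert table["log2fc"].iloc[17] == pytest.approx(3.0, abs=0.5)
        assert table["direction"].iloc[17] == "up"

    def test_pure_noise_regulated_fraction_near_zero(self, pair_design):
        rng = np.random.default_rng(100)
        m = _matrix_from_sim(300, 0.0, rng, pair_design)
        table = differential_table(m, fdr_threshold=0.01)
        assert table["regulated"].mean() <= 0.01

    def test_empty_matrix(self, pair_design):
        m = _matrix_from_sim(1, 0.0, np.random.default_rng(0), pair_design)
        m = PairMatrix(m.condition, m.frame.iloc[:0], m.columns)
        table = differential_table(m)
        assert len(table) == 0

    def test_untestable_events_reported_not_dropped(self, pair_design):
        rng = np.random.default_rng(5)
        m = _matrix_from_sim(3, 0.0, rng, pair_design)
        values = m.frame.to_numpy()
        values[1, m.arms == "treated"] = np.nan  # one arm gone
        m = PairMatrix(m.condition, pd.DataFrame(values, columns=m.frame.columns), m.columns)
        table = differential_table(m)
        assert len(table) == 3
        assert bool(table["untestable"].iloc[1])
        assert np.isnan(table["p"].iloc[1])
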