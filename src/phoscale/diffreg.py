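"""Random-intercept mixed-model testing of treatment effects.

For each phospho-event (or protein) and condition the model

    y_ij = mu + beta * 1[treated] + b_i + e_ij,
    b_i ~ N(0, sigma_b^2),   e_ij ~ N(0, sigma_e^2)

is fitted by maximum likelihood, with the biological replicate ``i`` as the
single random effect and the technical replicates as residual-level
observations.  The treatment effect is tested by a likelihood-ratio test
against the no-treatment null (same random-effect structure), with the LRT
statistic referred to chi-square(1); ML (not REML) is used throughout
because the compared models differ in their fixed effects.

Computationally, for a given variance ratio ``lambda = sigma_b^2 /
sigma_e^2`` the fixed effects and the residual variance have closed-form
generalized-least-squares solutions, so the likelihood is profiled down to
a 1-D function of ``log lambda``, maximized over a log-spaced grid refined
by a bounded scalar optimizer, always comparing against the exact
``lambda = 0`` boundary (where the fit coincides with OLS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .preprocess import PairMatrix

LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-8, 4, 25)])
OPTIMIZER_TOL = 1e-10
FDR_THRESHOLD = 0.01

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class LmmFit:
    """Maximum-likelihood fit of the random-intercept model and its null."""

    beta: float  # log2 fold change, treated - control
    mu: float
    sigma_b2: float
    sigma_e2: float
    loglik_full: float
    loglik_null: float
    n_obs: int
    lambda_hat: float


class UntestableEvent(ValueError):
    """The observation pattern violates the model's preconditions."""


class _ProfiledLik:
    """Closed-form GLS profile of the likelihood at fixed variance ratio.

    V = I + lam * Z Z' is block diagonal over bio-rep groups, so
    V^{-1} = I - c_g J within group g with c_g = lam / (1 + lam * n_g),
    and log|V| = sum_g log(1 + lam * n_g).  All data-dependent sums are
    precomputed once; each lambda evaluation is O(#groups).
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        _, gidx, ng = np.unique(groups, return_inverse=True, return_counts=True)
        self.n, self.p = X.shape
        self.ng = ng.astype(float)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        G = len(ng)
        self.Sy = np.bincount(gidx, weights=y, minlength=G)
        self.Sx = np.stack(
            [np.bincount(gidx, weights=X[:, j], minlength=G) for j in range(self.p)], axis=1
        )

    def __call__(self, lam: float):
        """Return (loglik, theta, sigma_e2) at this lambda."""
        c = lam / (1.0 + lam * self.ng)
        A = self.XtX - (c[:, None] * self.Sx).T @ self.Sx
        b = self.Xty - (c * self.Sy) @ self.Sx
        yVy = self.yty - float(c @ (self.Sy**2))
        if self.p == 1:
            theta = np.array([b[0] / A[0, 0]])
        else:
            det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
            theta = np.array(
                [(A[1, 1] * b[0] - A[0, 1] * b[1]) / det, (A[0, 0] * b[1] - A[1, 0] * b[0]) / det]
            )
        rss = max(yVy - float(b @ theta), 1e-300)  # guard: perfect fit
        sigma_e2 = rss / self.n
        loglik = -0.5 * self.n * (_LOG2PI + np.log(sigma_e2) + 1.0) - 0.5 * float(
            np.log1p(lam * self.ng).sum()
        )
        return loglik, theta, sigma_e2

    def loglik(self, lam: float) -> float:
        return self(lam)[0]


def _ml_fit(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """Maximize the profiled likelihood over lambda >= 0.

    Grid search over ``LAMBDA_GRID`` (which includes the exact 0 boundary),
    then bounded 1-D refinement on log lambda in the bracket around the
    grid optimum; the boundary fit is always compared exactly.
    """
    prof = _ProfiledLik(y, X, groups)
    lls = np.array([prof.loglik(lam) for lam in LAMBDA_GRID])
    i = int(np.argmax(lls))
    best_lam, best_ll = float(LAMBDA_GRID[i]), float(lls[i])
    # bracket on the positive axis around the grid optimum
    if i <= 1:
        lo, hi = float(LAMBDA_GRID[1]) * 1e-4, float(LAMBDA_GRID[2])
    elif i == len(LAMBDA_GRID) - 1:
        lo, hi = float(LAMBDA_GRID[i - 1]), float(LAMBDA_GRID[i]) * 10.0
    else:
        lo, hi = float(LAMBDA_GRID[i - 1]), float(LAMBDA_GRID[i + 1])
    res = minimize_scalar(
        lambda loglam: -prof.loglik(float(np.exp(loglam))),
        bounds=(float(np.log(lo)), float(np.log(hi))),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if -float(res.fun) > best_ll:
        best_lam, best_ll = float(np.exp(res.x)), -float(res.fun)
    # prefer the exact lambda = 0 boundary (OLS) whenever it is not worse
    # than the interior optimum beyond tolerance — in particular when the
    # profiled likelihood is flat (variances confounded)
    if lls[0] >= best_ll - OPTIMIZER_TOL:
        best_lam = 0.0
    ll, theta, sigma_e2 = prof(best_lam)
    return best_lam, ll, theta, sigma_e2


def fit_random_intercept_ml(
    y: np.ndarray, arm: np.ndarray, bio_rep: np.ndarray
) -> LmmFit:
    """Fit the random-intercept model (full and null) by ML.

    Parameters
    ----------
    y : observed log2 intensities (no NaN)
    arm : per-observation arm label, "treated" or "control"
    bio_rep : per-observation biological-replicate label

    Raises
    ------
    UntestableEvent
        fewer than 2 distinct biological replicates, an unobserved arm, or
        fewer than 4 observations.
    """
    y = np.asarray(y, dtype=float)
    arm = np.asarray(arm)
    bio_rep = np.asarray(bio_rep)
    treated = arm == "treated"
    n = len(y)
    if n < 4:
        raise UntestableEvent(f"n_obs={n} < 4")
    if len(np.unique(bio_rep)) < 2:
        raise UntestableEvent("fewer than 2 biological replicates observed")
    if treated.all() or (~treated).all():
        raise UntestableEvent("only one arm observed")

    if np.ptp(y) == 0.0:
        # perfectly constant data: no signal, no test
        return LmmFit(
            beta=0.0, mu=float(y[0]), sigma_b2=0.0, sigma_e2=1e-300,
            loglik_full=0.0, loglik_null=0.0, n_obs=n, lambda_hat=0.0,
        )

    X_full = np.column_stack([np.ones(n), treated.astype(float)])
    X_null = np.ones((n, 1))
    lam_f, ll_f, theta_f, sig_f = _ml_fit(y, X_full, bio_rep)
    _, ll_n, _, _ = _ml_fit(y, X_null, bio_rep)
    ll_n = min(ll_n, ll_f)  # nested models: numerical guard
    return LmmFit(
        beta=float(theta_f[1]),
        mu=float(theta_f[0]),
        sigma_b2=float(lam_f * sig_f),
        sigma_e2=float(sig_f),
        loglik_full=float(ll_f),
        loglik_null=float(ll_n),
        n_obs=n,
        lambda_hat=float(lam_f),
    )


def lrt_pvalue(fit: LmmFit) -> tuple[float, float]:
    """Likelihood-ratio statistic and its chi-square(1) upper-tail p."""
    stat = max(0.0, 2.0 * (fit.loglik_full - fit.loglik_null))
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    NaN p-values propagate to NaN q-values and do not count toward the
    number of tests.  Ties are handled by a stable sort on input order.
    """
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.minimum(qv, 1.0)
    out = np.empty(m)
    out[order] = qv
    q[valid] = out
    return q


def differential_table(matrix: PairMatrix, fdr_threshold: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Fit and test every event of a valid-value-filtered pairwise matrix.

    Returns one row per event with columns ``log2fc, lrt_stat, p, q,
    regulated, direction, untestable``; BH correction is applied within the
    condition, over testable events only.  Events violating the model
    preconditions are retained with ``untestable=True`` and NaN statistics.
    """
    values = matrix.frame.to_numpy()
    arm = matrix.arms
    bio = matrix.bio_reps
    n_events = values.shape[0]
    log2fc = np.full(n_events, np.nan)
    lrt = np.full(n_events, np.nan)
    pvals = np.full(n_events, np.nan)
    untestable = np.zeros(n_events, dtype=bool)
    for i in range(n_events):
        obs = ~np.isnan(values[i])
        try:
            fit = fit_random_intercept_ml(values[i, obs], arm[obs], bio[obs])
        except UntestableEvent:
            untestable[i] = True
            continue
        log2fc[i] = fit.beta
        lrt[i], pvals[i] = lrt_pvalue(fit)
    q = bh_adjust(pvals)
    regulated = (q < fdr_threshold) & ~np.isnan(q)
    direction = np.where(log2fc >= 0, "up", "down")
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "lrt_stat": lrt,
            "p": pvals,
            "q": q,
            "regulated": regulated,
            "direction": direction,
            "untestable": untestable,
        },
        index=matrix.frame.index,
    )
    out.loc[~regulated & np.isnan(log2fc), "direction"] = "NA"
    return out
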