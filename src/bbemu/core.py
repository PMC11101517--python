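"""Shared numerical machinery: time grid, errors, design matrices, and the
weighted (grouped-binomial) logistic solver that powers both the treatment /
censoring weight models and the pooled discrete-time hazard models.

The analysis time grid is fixed: follow-up is discretized into 30.4375-day
"months" (365.25 / 12), with a 60-interval (five-year) horizon.  Interval
``t`` covers days ``[(t-1)*MONTH_DAYS, t*MONTH_DAYS)`` since time zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MONTH_DAYS: float = 30.4375
HORIZON: int = 60

ARM_TREATED = "beta_blocker"
ARM_CONTROL = "no_beta_blocker"

BB_CLASSES = ("metoprolol", "bisoprolol")


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class BbemuError(Exception):
    """Base class for package errors."""


class ConfigurationError(BbemuError):
    pass


class EstimationError(BbemuError):
    pass


class PositivityError(BbemuError):
    pass


class ImputationError(BbemuError):
    pass


class AlignmentError(BbemuError):
    pass


# ---------------------------------------------------------------------------
# dates and intervals
# ---------------------------------------------------------------------------

def to_days(dates) -> np.ndarray:
    """Convert a datetime-like Series/array to int64 days since 1970-01-01.

    NaT maps to the minimum int64 sentinel; callers should mask separately.
    """
    arr = pd.to_datetime(pd.Series(dates)).to_numpy(dtype="datetime64[D]")
    return arr.astype("int64")


def from_days(days) -> pd.Series:
    return pd.Series(np.asarray(days, dtype="int64").astype("datetime64[D]"))


def day_to_interval(days_since_t0) -> np.ndarray:
    """Map days since time zero (day of an event) to its 1-based interval."""
    return np.floor(np.asarray(days_since_t0, dtype=float) / MONTH_DAYS).astype(int) + 1


def complete_intervals(days_since_t0) -> np.ndarray:
    """Number of fully observed intervals before a censoring day (floor rule)."""
    return np.floor(np.asarray(days_since_t0, dtype=float) / MONTH_DAYS).astype(int)


def interval_mid_day(t) -> np.ndarray:
    """Representative (mid-interval) day offset used when synthesizing dates."""
    return np.round((np.asarray(t, dtype=float) - 0.5) * MONTH_DAYS).astype(int)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def build_design(df: pd.DataFrame, covariates: list[str],
                 add_intercept: bool = True,
                 reference_levels: dict | None = None):
    """Expand covariates to a numeric design matrix.

    Categorical columns (object/category dtype) are expanded to indicator
    columns with the most frequent level as reference.  Returns
    ``(X, names, reference_levels)`` so a fitted design can be re-applied.
    """
    cols, names = [], []
    refs = dict(reference_levels) if reference_levels else {}
    if add_intercept:
        cols.append(np.ones(len(df)))
        names.append("intercept")
    for cov in covariates:
        s = df[cov]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            s = s.astype(str)
            if cov in refs:
                ref, levels = refs[cov]
            else:
                counts = s.value_counts()
                ref = counts.index[0]
                levels = [lv for lv in sorted(counts.index) if lv != ref]
                refs[cov] = (ref, levels)
            for lv in levels:
                cols.append((s == lv).to_numpy(dtype=float))
                names.append(f"{cov}[{lv}]")
        else:
            v = s.to_numpy(dtype=float)
            if np.isnan(v).any():
                raise ImputationError(
                    f"covariate '{cov}' contains missing values; impute first")
            cols.append(v)
            names.append(cov)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names, refs


# ---------------------------------------------------------------------------
# logistic solver
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    params: np.ndarray
    names: list[str]
    cov_params: np.ndarray
    converged: bool
    n_iter: int
    loglik: float
    warnings: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = X @ self.params
        return expit(eta)

    def summary_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_params))
        return pd.DataFrame({"coef": self.params, "se": se}, index=self.names)


def expit(eta):
    # clipped for numerical safety in extreme tails
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -35.0, 35.0)))


def fit_logistic(X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None,
                 names: list[str] | None = None, max_iter: int = 60,
                 tol: float = 1e-10, ridge: float = 0.0) -> LogisticFit:
    """Weighted maximum-likelihood logistic regression by Newton-Raphson.

    Accepts fractional responses with case weights, so grouped-binomial data
    (y = events/trials, weight = trials) fit identically to the expanded
    Bernoulli rows.  Raises :class:`EstimationError` on non-convergence or
    (quasi-)separation, naming the worst-offending columns.

    ``ridge`` adds an L2 penalty (excluding the intercept) used for sparse
    censoring-event models, where quasi-separation is routine and an
    unpenalized MLE may not exist.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise EstimationError("weights must be finite and nonnegative")
    keep = w > 0
    if not keep.all():
        X, y, w = X[keep], y[keep], w[keep]
        n = len(y)
    if n == 0 or p == 0:
        raise EstimationError("empty design matrix")

    pen = np.full(p, float(ridge))
    if names[0] == "intercept":
        pen[0] = 0.0

    def _penll(b, mu):
        ll = float(np.sum(w * (y * np.log(np.clip(mu, 1e-300, None))
                               + (1 - y) * np.log(np.clip(1 - mu, 1e-300, None)))))
        return ll - 0.5 * float(np.sum(pen * b * b))

    beta = np.zeros(p)
    ybar = np.clip(np.average(y, weights=w), 1e-12, 1 - 1e-12)
    if names[0] == "intercept":
        beta[0] = np.log(ybar / (1 - ybar))
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        ll = _penll(beta, mu)
        g = X.T @ (w * (y - mu)) - pen * beta
        s = w * mu * (1 - mu)
        H = (X * s[:, None]).T @ X + np.diag(pen)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), g)
        except np.linalg.LinAlgError:
            raise EstimationError("singular information matrix; collinear columns: "
                                  + ", ".join(names))
        # step-halving on likelihood decrease
        new = beta + step
        for _ in range(25):
            ll_new = _penll(new, expit(X @ new))
            if ll_new >= ll - 1e-12:
                break
            new = (beta + new) / 2.0
        beta = new
        if abs(ll_new - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            ll = ll_new
            break
        ll_old = ll_new
        ll = ll_new

    eta = X @ beta
    if np.max(np.abs(eta)) > 30.0 or not converged:
        worst = [names[j] for j in np.argsort(-np.abs(beta))[:3]]
        raise EstimationError(
            "logistic fit did not converge (possible separation); "
            "largest coefficients: " + ", ".join(worst))
    mu = expit(eta)
    s = w * mu * (1 - mu)
    H = (X * s[:, None]).T @ X + np.diag(pen)
    cov = np.linalg.inv(H + 1e-12 * np.eye(p))
    return LogisticFit(params=beta, names=list(names), cov_params=cov,
                       converged=converged, n_iter=it, loglik=ll)


def cluster_robust_cov(X, y, w, fit: LogisticFit, clusters) -> np.ndarray:
    """Sandwich covariance with scores summed within clusters (persons)."""
    mu = fit.predict(X)
    resid = (w * (y - mu))[:, None] * X
    df = pd.DataFrame(resid)
    df["_c"] = np.asarray(clusters)
    sc = df.groupby("_c").sum().to_numpy()
    meat = sc.T @ sc
    s = w * mu * (1 - mu)
    bread = np.linalg.inv((X * s[:, None]).T @ X + 1e-12 * np.eye(X.shape[1]))
    return bread @ meat @ bread


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------

def spawn_rngs(seed: int, *labels: str) -> dict[str, np.random.Generator]:
    """Fan a global seed out to named, independent substreams."""
    ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(len(labels))
    return {lab: np.random.default_rng(ch) for lab, ch in zip(labels, children)}
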