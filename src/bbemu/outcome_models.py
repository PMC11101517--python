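"""Discrete-time hazard modelling and effect estimation.

The estimator is an IP-weighted pooled logistic regression on person-interval
data: event indicator on assigned arm, a restricted cubic spline of follow-up
interval (knots at 6, 12, 24 and 48 months by default), and arm x spline
product terms.  Cumulative risks follow the product-limit recursion
``risk(t) = 1 - prod_{s<=t} (1 - hazard(s))``; risks at five years are
compared via differences and ratios, and an average hazard ratio comes from
the same model refit without the product terms on person-time truncated at
the horizon of interest.  Inference is by nonparametric bootstrap (resampling
persons, re-estimating weights inside each replicate) with percentile
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (HORIZON, ARM_TREATED, ARM_CONTROL, ConfigurationError,
                   EstimationError, build_design, fit_logistic, expit,
                   cluster_robust_cov)

__all__ = ["SplineSpec", "rcs_basis", "PooledLogisticFit",
           "fit_pooled_logistic", "RiskCurve", "risk_curves",
           "EffectEstimates", "effect_estimates", "bootstrap_cis",
           "km_risk_from_intervals"]


@dataclass(frozen=True)
class SplineSpec:
    knots: tuple = (6.0, 12.0, 24.0, 48.0)
    basis: str = "restricted_cubic"

    def __post_init__(self):
        if len(self.knots) < 3:
            raise ConfigurationError("restricted cubic spline needs >= 3 knots")
        if not np.all(np.diff(self.knots) > 0):
            raise ConfigurationError("spline knots must be strictly increasing")


def rcs_basis(t, spec: SplineSpec | None = None) -> np.ndarray:
    """Restricted (natural) cubic spline basis ``[t, b_1(t), ..., b_{K-2}(t)]``.

    Truncated-cubic construction normalized by ``(k_K - k_1)^2``; every
    nonlinear column is exactly zero below the first knot and the whole basis
    is linear in ``t`` beyond the last knot.
    """
    spec = spec or SplineSpec()
    k = np.asarray(spec.knots, dtype=float)
    K = len(k)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    cols = [t]
    denom = (k[K - 1] - k[0]) ** 2

    def cube(x):
        return np.clip(x, 0.0, None) ** 3

    for j in range(K - 2):
        bj = (cube(t - k[j])
              - cube(t - k[K - 2]) * (k[K - 1] - k[j]) / (k[K - 1] - k[K - 2])
              + cube(t - k[K - 1]) * (k[K - 2] - k[j]) / (k[K - 1] - k[K - 2]))
        cols.append(bj / denom)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# pooled logistic fit
# ---------------------------------------------------------------------------

@dataclass
class PooledLogisticFit:
    kind: str                      # "spline" | "saturated"
    params: np.ndarray | None
    names: list | None
    cov_robust: np.ndarray | None
    spline: SplineSpec | None
    interaction: bool
    extra_covariates: list
    design_refs: dict
    converged: bool
    warnings: list
    horizon: int
    # saturated-time representation: hazard per (arm, t)
    saturated_hazards: pd.DataFrame | None = None
    # per-person covariate frame for g-formula standardization
    standardization_frame: pd.DataFrame | None = None

    def hazard(self, arm_indicator: float, t: np.ndarray,
               extra_row: pd.Series | None = None) -> np.ndarray:
        if self.kind == "saturated":
            h = self.saturated_hazards
            col = ARM_TREATED if arm_indicator == 1 else ARM_CONTROL
            return h.set_index("t").loc[t, col].to_numpy()
        X = _hazard_design(self, arm_indicator, t, extra_row)
        return expit(X @ self.params)


def _hazard_design_base(fit: PooledLogisticFit, arm: float,
                        t: np.ndarray) -> np.ndarray:
    """Design columns for (arm, t) only — the non-extra-covariate part."""
    tb = rcs_basis(t, fit.spline)
    cols = [np.ones(len(t)), np.full(len(t), arm), tb]
    if fit.interaction:
        cols.append(arm * tb)
    return np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])


def _hazard_design(fit: PooledLogisticFit, arm: float, t: np.ndarray,
                   extra_row: pd.Series | None) -> np.ndarray:
    tb = rcs_basis(t, fit.spline)
    cols = [np.ones(len(t)), np.full(len(t), arm)]
    cols.append(tb)
    if fit.interaction:
        cols.append(arm * tb)
    if fit.extra_covariates:
        if extra_row is None:
            raise ConfigurationError("model has extra covariates; supply a "
                                     "covariate row for prediction")
        Xe, _, _ = build_design(pd.DataFrame([extra_row]),
                                fit.extra_covariates, add_intercept=False,
                                reference_levels=fit.design_refs)
        cols.append(np.repeat(Xe, len(t), axis=0))
    return np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])


def fit_pooled_logistic(person_intervals: pd.DataFrame,
                        weights: pd.Series | None = None,
                        spline: SplineSpec | None = None,
                        include_treatment_time_interaction: bool = True,
                        extra_covariates: list | None = None,
                        saturated_time: bool = False,
                        event_col: str = "event",
                        horizon: int = HORIZON,
                        robust_variance: bool = False) -> PooledLogisticFit:
    """Weighted ML fit of the discrete-time hazard model.

    With ``saturated_time`` the time axis is fully stratified by (arm, t); the
    MLE on that design equals the weighted event proportion in each cell and
    is computed directly (cells without events give hazard 0, which the
    coefficient parameterization can only reach in the limit).

    When the design depends only on (arm, t) the rows are aggregated to
    grouped-binomial cells before fitting, which makes bootstrap refits cheap.
    """
    spline = spline or SplineSpec()
    extra_covariates = list(extra_covariates or [])
    df = person_intervals
    y = df[event_col].to_numpy(dtype=float)
    if y.sum() < 1:
        raise EstimationError("no events in the person-interval data")
    w = (np.ones(len(df)) if weights is None
         else np.asarray(weights.reindex(df.index) if isinstance(weights, pd.Series)
                         else weights, dtype=float))
    if not np.all(np.isfinite(w)):
        raise EstimationError("weights must be finite")
    arm = (df["arm"] == ARM_TREATED).to_numpy(dtype=float)
    t = df["t"].to_numpy(dtype=float)
    warnings = []
    for arm_label, m in ((ARM_TREATED, arm == 1), (ARM_CONTROL, arm == 0)):
        if m.any() and y[m].sum() == 0:
            warnings.append(f"zero events in arm {arm_label}")

    if saturated_time:
        cells = pd.DataFrame({"arm": df["arm"].to_numpy(), "t": t.astype(int),
                              "ev": w * y, "n": w})
        g = cells.groupby(["arm", "t"]).sum().reset_index()
        g["hazard"] = g["ev"] / g["n"]
        tab = g.pivot(index="t", columns="arm", values="hazard").fillna(0.0)
        for lab in (ARM_TREATED, ARM_CONTROL):
            if lab not in tab:
                tab[lab] = 0.0
        tab = tab.reindex(range(1, int(t.max()) + 1), fill_value=0.0)
        sat = tab.reset_index().rename(columns={"index": "t"})
        return PooledLogisticFit(kind="saturated", params=None, names=None,
                                 cov_robust=None, spline=None,
                                 interaction=True, extra_covariates=[],
                                 design_refs={}, converged=True,
                                 warnings=warnings, horizon=horizon,
                                 saturated_hazards=sat)

    tb = rcs_basis(t, spline)
    tnames = ["t"] + [f"rcs{j}" for j in range(1, tb.shape[1])]
    names = ["intercept", "arm"] + tnames
    cols = [np.ones(len(df)), arm, tb]
    if include_treatment_time_interaction:
        cols.append(arm[:, None] * tb)
        names += [f"arm:{nm}" for nm in tnames]
    refs = {}
    std_frame = None
    if extra_covariates:
        Xe, enames, refs = build_design(df, extra_covariates,
                                        add_intercept=False)
        cols.append(Xe)
        names += enames
        std_frame = (df.drop_duplicates("person_id")
                       .loc[:, ["person_id"] + extra_covariates]
                       .reset_index(drop=True))
        X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])
        fit = fit_logistic(X, y, weights=w, names=names)
    else:
        # aggregate to (arm, t) grouped-binomial cells
        key = (arm.astype(np.int64) * (int(t.max()) + 1) + t.astype(np.int64))
        order = np.argsort(key, kind="mergesort")
        uk, inv = np.unique(key, return_inverse=True)
        ev = np.bincount(inv, weights=w * y)
        tot = np.bincount(inv, weights=w)
        cell_arm = (uk // (int(t.max()) + 1)).astype(float)
        cell_t = (uk % (int(t.max()) + 1)).astype(float)
        ctb = rcs_basis(cell_t, spline)
        ccols = [np.ones(len(uk)), cell_arm, ctb]
        if include_treatment_time_interaction:
            ccols.append(cell_arm[:, None] * ctb)
        X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in ccols])
        fit = fit_logistic(X, ev / np.clip(tot, 1e-300, None), weights=tot,
                           names=names)

    cov_robust = None
    if robust_variance:
        try:
            Xfull_cols = [np.ones(len(df)), arm, tb]
            if include_treatment_time_interaction:
                Xfull_cols.append(arm[:, None] * tb)
            if extra_covariates:
                Xfull_cols.append(Xe)
            Xfull = np.column_stack([c if c.ndim == 2 else c[:, None]
                                     for c in Xfull_cols])
            cov_robust = cluster_robust_cov(Xfull, y, w, fit,
                                            df["person_id"].to_numpy())
        except Exception:  # robust covariance is reporting-only
            warnings.append("cluster-robust covariance unavailable")

    return PooledLogisticFit(kind="spline", params=fit.params, names=names,
                             cov_robust=cov_robust, spline=spline,
                             interaction=include_treatment_time_interaction,
                             extra_covariates=extra_covariates,
                             design_refs=refs, converged=fit.converged,
                             warnings=warnings, horizon=horizon,
                             standardization_frame=std_frame)


# ---------------------------------------------------------------------------
# risk curves
# ---------------------------------------------------------------------------

@dataclass
class RiskCurve:
    curves: pd.DataFrame     # arm | t | hazard | risk
    outcome: str = ""
    contrast: str = ""
    weighted: bool = False

    def risk_at(self, arm: str, t: int) -> float:
        c = self.curves
        row = c[(c["arm"] == arm) & (c["t"] == t)]
        return float(row["risk"].iloc[0])


def risk_curves(model: PooledLogisticFit, spec: SplineSpec | None = None,
                horizon: int = HORIZON, outcome: str = "",
                contrast: str = "") -> RiskCurve:
    """Cumulative risk per arm by the product-limit recursion.

    With extra covariates in the model, risks are standardized over the
    cohort's empirical covariate distribution (parametric g-formula): the
    per-subject cumulative risks are averaged, not the hazards.
    """
    if model.kind == "spline" and not model.interaction:
        raise ConfigurationError("risk curves require the treatment-time "
                                 "interaction model")
    if model.kind == "spline" and horizon > model.horizon:
        raise ConfigurationError(f"horizon {horizon} beyond fitted support "
                                 f"{model.horizon}")
    tgrid = np.arange(1, horizon + 1, dtype=float)
    rows = []
    for arm_label, a in ((ARM_TREATED, 1.0), (ARM_CONTROL, 0.0)):
        if model.extra_covariates:
            frame = model.standardization_frame
            Xe, _, _ = build_design(frame, model.extra_covariates,
                                    add_intercept=False,
                                    reference_levels=model.design_refs)
            n_extra = Xe.shape[1]
            base_eta = _hazard_design_base(model, a, tgrid) @ model.params[:-n_extra]
            offset = Xe @ model.params[-n_extra:]
            hmat = expit(base_eta[None, :] + offset[:, None])
            risks = (1.0 - np.cumprod(1.0 - hmat, axis=1)).mean(axis=0)
            # implied marginal hazard from the averaged survival
            surv = 1.0 - risks
            h = 1.0 - surv / np.concatenate([[1.0], surv[:-1]])
        else:
            h = model.hazard(a, tgrid)
            risks = 1.0 - np.cumprod(1.0 - h)
        for t, hz, r in zip(tgrid.astype(int), h, risks):
            rows.append((arm_label, t, hz, r))
    return RiskCurve(curves=pd.DataFrame(rows, columns=["arm", "t", "hazard",
                                                        "risk"]),
                     outcome=outcome, contrast=contrast)


def km_risk_from_intervals(person_intervals: pd.DataFrame,
                           event_col: str = "event") -> pd.DataFrame:
    """Nonparametric product-limit risk per arm on the interval grid.

    Independent of the model machinery; used as an oracle cross-check of the
    saturated-time fit.
    """
    rows = []
    for arm, sub in person_intervals.groupby("arm"):
        tmax = int(sub["t"].max())
        risks = []
        surv = 1.0
        for t in range(1, tmax + 1):
            at_risk = (sub["t"] == t).sum()
            ev = sub.loc[sub["t"] == t, event_col].sum()
            h = ev / at_risk if at_risk else 0.0
            surv *= (1.0 - h)
            risks.append((arm, t, h, 1.0 - surv))
        rows.extend(risks)
    return pd.DataFrame(rows, columns=["arm", "t", "hazard", "risk"])


# ---------------------------------------------------------------------------
# effect estimates
# ---------------------------------------------------------------------------

@dataclass
class EffectEstimates:
    outcome: str
    contrast: str
    estimates: dict                   # name -> point estimate
    cis: dict = field(default_factory=dict)    # name -> (lo, hi)
    n_boot: int = 0
    seed: int | None = None
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, v in self.estimates.items():
            lo, hi = self.cis.get(k, (np.nan, np.nan))
            rows.append((self.outcome, self.contrast, k, v, lo, hi))
        return pd.DataFrame(rows, columns=["outcome", "contrast", "estimate",
                                           "value", "ci_lower", "ci_upper"])


def _average_hr(person_intervals: pd.DataFrame, weights, spline: SplineSpec,
                horizon: int, extra_covariates: list | None = None) -> float:
    sub = person_intervals[person_intervals["t"] <= horizon]
    w = None
    if weights is not None:
        w = weights.reindex(sub.index) if isinstance(weights, pd.Series) else \
            pd.Series(np.asarray(weights), index=person_intervals.index).reindex(sub.index)
    fit = fit_pooled_logistic(sub, weights=w, spline=spline,
                              include_treatment_time_interaction=False,
                              extra_covariates=extra_covariates,
                              horizon=horizon)
    return float(np.exp(fit.params[fit.names.index("arm")]))


def effect_estimates(curves: RiskCurve, horizons=(36, 48, 60),
                     person_intervals: pd.DataFrame | None = None,
                     weights=None, spline: SplineSpec | None = None,
                     extra_covariates: list | None = None,
                     risk_horizon: int = HORIZON) -> EffectEstimates:
    """Risks, risk difference/ratio at five years, and average hazard ratios.

    Risks and the RD are reported in percent.  The average HR at each horizon
    comes from a no-interaction refit on person-time truncated there.
    """
    spline = spline or SplineSpec()
    r1 = curves.risk_at(ARM_TREATED, risk_horizon)
    r0 = curves.risk_at(ARM_CONTROL, risk_horizon)
    est = {"risk_treated": 100.0 * r1, "risk_control": 100.0 * r0,
           "rd": 100.0 * (r1 - r0)}
    est["rr"] = r1 / r0 if r0 > 0 else np.nan
    if r0 <= 0:
        est["rr_undefined"] = 1.0
    if person_intervals is not None:
        for h in horizons:
            est[f"hr_{h}m"] = _average_hr(person_intervals, weights, spline, h,
                                          extra_covariates)
        ev = person_intervals[person_intervals["event"] == 1]
        est["events_treated"] = float((ev["arm"] == ARM_TREATED).sum())
        est["events_control"] = float((ev["arm"] == ARM_CONTROL).sum())
    return EffectEstimates(outcome=curves.outcome, contrast=curves.contrast,
                           estimates=est)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_cis(analysis, n_persons: int, n_boot: int = 500,
                  seed: int = 0, alpha: float = 0.05) -> tuple[dict, int]:
    """Percentile bootstrap over persons.

    ``analysis(indices, replicate_rng)`` maps an integer index array (a
    with-replacement resample of ``range(n_persons)``) to a dict of point
    estimates.  Failed replicates (EstimationError) are dropped and counted;
    more than 5% failures is an error.  Returns ``(cis, n_failed)``.
    """
    if n_boot < 2:
        raise ConfigurationError("n_boot must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    draws = {}
    n_failed = 0
    for b in range(n_boot):
        idx = rng.integers(0, n_persons, size=n_persons)
        try:
            res = analysis(idx, rng)
        except (EstimationError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        for k, v in res.items():
            draws.setdefault(k, []).append(v)
    if n_failed > 0.05 * n_boot:
        raise EstimationError(f"{n_failed}/{n_boot} bootstrap replicates "
                              "failed to converge")
    cis = {}
    for k, vals in draws.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        if len(arr) == 0:
            cis[k] = (np.nan, np.nan)
        else:
            cis[k] = (float(np.percentile(arr, 100 * alpha / 2)),
                      float(np.percentile(arr, 100 * (1 - alpha / 2))))
    return cis, n_failed
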