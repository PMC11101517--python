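"""Stabilized inverse-probability weights and covariate-balance diagnostics.

Baseline treatment weights: stabilized by the marginal arm probability,
``sw_i = P(A = a_i) / P(A = a_i | L_i)`` with the denominator from a
maximum-likelihood logistic regression of arm on baseline covariates.

Per-protocol censoring weights: within each arm separately, a pooled
logistic model for remaining uncensored per interval; the denominator model
uses baseline + time-varying covariates + a restricted cubic spline of
interval, the numerator drops the time-varying covariates.  The cumulative
weight at ``t`` is the product over ``s <= t`` of numerator(s)/denominator(s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (ARM_TREATED, ARM_CONTROL, ConfigurationError,
                   EstimationError, PositivityError, build_design,
                   fit_logistic, LogisticFit)
from .outcome_models import SplineSpec, rcs_basis

__all__ = ["WeightSet", "BalanceTable", "baseline_ip_weights",
           "censoring_ip_weights", "truncate_weights", "balance_table"]

# weak L2 penalty for censoring-hazard models: censoring events are sparse
# per interval, so quasi-separation is routine and an unpenalized MLE may
# not exist; the penalty is negligible for identified coefficients
CENSOR_RIDGE = 1.0


@dataclass
class WeightSet:
    baseline: pd.Series | None = None          # per person_id
    censoring: pd.Series | None = None         # per person-interval row
    combined: pd.Series | None = None          # per person-interval row
    truncated: bool = False
    truncation_percentile: float | None = None
    model_summaries: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def summary(self) -> dict:
        out = {}
        for name in ("baseline", "censoring", "combined"):
            s = getattr(self, name)
            if s is not None and len(s):
                out[name] = {"min": float(s.min()), "max": float(s.max()),
                             "mean": float(s.mean())}
        return out


@dataclass
class BalanceTable:
    table: pd.DataFrame  # covariate | smd_unweighted | smd_weighted | missing_pct

    def max_smd(self, weighted: bool = True) -> float:
        col = "smd_weighted" if weighted else "smd_unweighted"
        return float(self.table[col].max())


def baseline_ip_weights(subjects: pd.DataFrame,
                        covariates: list[str]) -> WeightSet:
    """Stabilized baseline inverse-probability-of-treatment weights."""
    arms = subjects["arm"].to_numpy()
    a = (arms == ARM_TREATED).astype(float)
    if a.sum() == 0 or a.sum() == len(a):
        raise PositivityError("one arm is empty; cannot estimate assignment "
                              "probabilities")
    X, names, _ = build_design(subjects, covariates)
    fit = fit_logistic(X, a, names=names)
    p1 = fit.predict(X)
    marg = a.mean()
    pa = np.where(a == 1, p1, 1 - p1)
    sw = np.where(a == 1, marg, 1 - marg) / np.clip(pa, 1e-12, None)
    if not np.all(np.isfinite(sw)):
        raise PositivityError("non-finite baseline weights (propensity at 0/1)")
    baseline = pd.Series(sw, index=pd.Index(subjects["person_id"],
                                            name="person_id"))
    ws = WeightSet(baseline=baseline)
    ws.model_summaries["assignment"] = fit.summary_frame()
    return ws


def censoring_ip_weights(person_intervals: pd.DataFrame,
                         baseline_covariates: list[str],
                         timevarying_covariates: list[str],
                         spline: SplineSpec | None = None,
                         baseline_weights: pd.Series | None = None) -> WeightSet:
    """Time-varying stabilized inverse-probability-of-censoring weights.

    ``person_intervals`` must carry ``artificially_censored`` flags; rows
    after a person's censoring do not exist by construction.  An arm with no
    censoring events gets weights identically 1 (logged, not an error).
    """
    spline = spline or SplineSpec()
    df = person_intervals
    uncens = 1.0 - df["artificially_censored"].to_numpy(dtype=float)
    w = np.ones(len(df))
    summaries, notes = {}, []
    tb = rcs_basis(df["t"].to_numpy(dtype=float), spline)
    tnames = [f"rcs_t{j}" for j in range(tb.shape[1])]
    for arm in (ARM_TREATED, ARM_CONTROL):
        m = (df["arm"] == arm).to_numpy()
        if not m.any():
            continue
        if df.loc[m, "artificially_censored"].sum() == 0:
            notes.append(f"no artificial censoring in arm {arm}; weights = 1")
            continue
        sub = df.loc[m]
        Xb, nb, refs = build_design(sub, baseline_covariates)
        Xt, nt, _ = build_design(sub, timevarying_covariates,
                                 add_intercept=False)
        Xden = np.column_stack([Xb, tb[m], Xt])
        Xnum = np.column_stack([Xb, tb[m]])
        fit_den = fit_logistic(Xden, uncens[m], names=nb + tnames + nt,
                               ridge=CENSOR_RIDGE)
        fit_num = fit_logistic(Xnum, uncens[m], names=nb + tnames,
                               ridge=CENSOR_RIDGE)
        p_den = np.clip(fit_den.predict(Xden), 1e-12, None)
        p_num = fit_num.predict(Xnum)
        ratio = pd.Series(p_num / p_den, index=sub.index)
        cum = ratio.groupby(sub["person_id"].to_numpy()).cumprod()
        w[m] = cum.to_numpy()
        summaries[f"censoring_denominator[{arm}]"] = fit_den.summary_frame()
        summaries[f"censoring_numerator[{arm}]"] = fit_num.summary_frame()
    cens = pd.Series(w, index=df.index, name="censor_weight")
    ws = WeightSet(censoring=cens, model_summaries=summaries, notes=notes)
    if baseline_weights is not None:
        base_per_row = baseline_weights.reindex(df["person_id"]).to_numpy()
        ws.baseline = baseline_weights
        ws.combined = pd.Series(base_per_row * w, index=df.index,
                                name="combined_weight")
    return ws


def truncate_weights(weights: WeightSet,
                     percentile: float | None) -> WeightSet:
    """Cap combined weights at the given upper percentile and its mirror."""
    if percentile is None:
        return weights
    if not (50.0 < percentile <= 100.0):
        raise ConfigurationError("truncation percentile must be in (50, 100]")
    target = weights.combined if weights.combined is not None else weights.baseline
    if target is None:
        raise ConfigurationError("no weights to truncate")
    hi = np.percentile(target, percentile)
    lo = np.percentile(target, 100.0 - percentile)
    clipped = target.clip(lower=lo, upper=hi)
    out = WeightSet(baseline=weights.baseline, censoring=weights.censoring,
                    combined=None, truncated=True,
                    truncation_percentile=percentile,
                    model_summaries=dict(weights.model_summaries),
                    notes=list(weights.notes))
    if weights.combined is not None:
        out.combined = clipped
    else:
        out.baseline = clipped
    return out


# ---------------------------------------------------------------------------
# balance diagnostics
# ---------------------------------------------------------------------------

def _wmean(x, w):
    return np.sum(w * x) / np.sum(w)


def _wvar(x, w):
    m = _wmean(x, w)
    return np.sum(w * (x - m) ** 2) / np.sum(w)


def _smd_binary(p1, p0):
    denom = np.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2.0)
    if denom == 0:
        return 0.0 if p1 == p0 else np.inf
    return abs(p1 - p0) / denom


def _smd_continuous(m1, m0, v1, v0):
    denom = np.sqrt((v1 + v0) / 2.0)
    if denom == 0:
        return 0.0 if m1 == m0 else np.inf
    return abs(m1 - m0) / denom


def balance_table(subjects: pd.DataFrame, weights: WeightSet | None,
                  covariates: list[str],
                  missing_flags: bool = True) -> BalanceTable:
    """Standardized mean differences before and after IP weighting.

    Categorical covariates contribute one row per level (indicator SMD); the
    weighted column uses the baseline weights.
    """
    t_mask = (subjects["arm"] == ARM_TREATED).to_numpy()
    c_mask = ~t_mask
    if weights is not None and weights.baseline is not None:
        w = weights.baseline.reindex(subjects["person_id"]).to_numpy()
    else:
        w = np.ones(len(subjects))
    ones = np.ones(len(subjects))
    rows = []
    for cov in covariates:
        s = subjects[cov]
        miss_col = f"missing_{cov}"
        miss_pct = (100.0 * subjects[miss_col].mean()
                    if (missing_flags and miss_col in subjects) else 0.0)
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            for level in sorted(s.astype(str).unique()):
                x = (s.astype(str) == level).to_numpy(dtype=float)
                m1, m0 = (_wmean(x[t_mask], ones[t_mask]),
                          _wmean(x[c_mask], ones[c_mask]))
                smd_u = _smd_binary(m1, m0)
                smd_w = _smd_binary(_wmean(x[t_mask], w[t_mask]),
                                    _wmean(x[c_mask], w[c_mask]))
                rows.append((f"{cov}[{level}]", m1, m0, smd_u, smd_w,
                             miss_pct))
        else:
            x = s.to_numpy(dtype=float)
            uniq = np.unique(x[~np.isnan(x)])
            m1, m0 = (_wmean(x[t_mask], ones[t_mask]),
                      _wmean(x[c_mask], ones[c_mask]))
            if len(uniq) <= 2 and set(uniq).issubset({0.0, 1.0}):
                smd_u = _smd_binary(m1, m0)
                smd_w = _smd_binary(_wmean(x[t_mask], w[t_mask]),
                                    _wmean(x[c_mask], w[c_mask]))
            else:
                smd_u = _smd_continuous(m1, m0,
                                        _wvar(x[t_mask], ones[t_mask]),
                                        _wvar(x[c_mask], ones[c_mask]))
                smd_w = _smd_continuous(_wmean(x[t_mask], w[t_mask]),
                                        _wmean(x[c_mask], w[c_mask]),
                                        _wvar(x[t_mask], w[t_mask]),
                                        _wvar(x[c_mask], w[c_mask]))
            rows.append((cov, m1, m0, smd_u, smd_w, miss_pct))
    table = pd.DataFrame(rows, columns=["covariate", "mean_treated",
                                        "mean_control", "smd_unweighted",
                                        "smd_weighted", "missing_pct"])
    return BalanceTable(table=table)
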