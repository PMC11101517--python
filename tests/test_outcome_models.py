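"""Spline basis, pooled logistic fits, risk curves (vs the product-limit
estimator and lifelines), effect arithmetic and bootstrap contracts."""

import numpy as np
import pandas as pd
import pytest

import bbemu
from bbemu.outcome_models import (SplineSpec, rcs_basis, fit_pooled_logistic,
                                  risk_curves, effect_estimates,
                                  bootstrap_cis, km_risk_from_intervals,
                                  PooledLogisticFit)
from bbemu import ConfigurationError, EstimationError


# ---------------------------------------------------------------------------
# restricted cubic spline
# ---------------------------------------------------------------------------

def test_rcs_zero_nonlinear_below_first_knot():
    basis = rcs_basis(np.array([0.0, 3.0, 5.0, 5.999]), SplineSpec())
    assert np.all(basis[:, 1:] == 0.0)


def test_rcs_linear_beyond_last_knot():
    spec = SplineSpec()
    t = np.array([55.0, 56.0, 57.0, 70.0, 71.0, 72.0])
    basis = rcs_basis(t, spec)
    for j in range(basis.shape[1]):
        second_diff = np.diff(basis[:3, j], n=2)
        assert np.all(np.abs(second_diff) < 1e-9)
        second_diff = np.diff(basis[3:, j], n=2)
        assert np.all(np.abs(second_diff) < 1e-9)


def test_rcs_closed_form_at_t12():
    k = (6.0, 12.0, 24.0, 48.0)
    t = 12.0
    denom = (k[3] - k[0]) ** 2

    def cube(x):
        return max(x, 0.0) ** 3

    expected = []
    for j in range(2):
        bj = (cube(t - k[j])
              - cube(t - k[2]) * (k[3] - k[j]) / (k[3] - k[2])
              + cube(t - k[3]) * (k[2] - k[j]) / (k[3] - k[2])) / denom
        expected.append(bj)
    got = rcs_basis(np.array([t]), SplineSpec(knots=k))[0]
    np.testing.assert_allclose(got, [t] + expected, atol=1e-12)


def test_rcs_requires_three_knots():
    with pytest.raises(ConfigurationError):
        SplineSpec(knots=(6.0, 12.0))


# ---------------------------------------------------------------------------
# pooled logistic
# ---------------------------------------------------------------------------

def _toy_intervals(n=200, seed=3, hazard=0.02, arm_split=0.5, horizon=24):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        arm = bbemu.ARM_TREATED if i < n * arm_split else bbemu.ARM_CONTROL
        for t in range(1, horizon + 1):
            ev = rng.random() < hazard
            rows.append((i, t, arm, int(ev)))
            if ev:
                break
    return pd.DataFrame(rows, columns=["person_id", "t", "arm", "event"])


def test_identical_event_patterns_zero_arm_coefficient():
    df = _toy_intervals()
    # mirror arm-0 data into arm 1 exactly
    a = df[df["arm"] == bbemu.ARM_TREATED].copy()
    b = a.copy()
    b["arm"] = bbemu.ARM_CONTROL
    b["person_id"] += 10_000
    both = pd.concat([a, b], ignore_index=True)
    fit = fit_pooled_logistic(both, include_treatment_time_interaction=False)
    assert abs(fit.params[fit.names.index("arm")]) < 1e-6


def test_weight_scale_invariance():
    df = _toy_intervals()
    f1 = fit_pooled_logistic(df, weights=pd.Series(1.0, index=df.index))
    f2 = fit_pooled_logistic(df, weights=pd.Series(2.0, index=df.index))
    np.testing.assert_allclose(f1.params, f2.params, atol=1e-9)


def test_saturated_fit_equals_cell_proportions():
    df = _toy_intervals(n=150, horizon=10)
    fit = fit_pooled_logistic(df, saturated_time=True)
    cells = df.groupby(["arm", "t"])["event"].mean()
    sat = fit.saturated_hazards.set_index("t")
    for (arm, t), p in cells.items():
        assert abs(sat.loc[t, arm] - p) < 1e-12


def test_km_equivalence_against_lifelines(km_fixture):
    from lifelines import KaplanMeierFitter
    subjects, expanded = km_fixture
    fit = fit_pooled_logistic(expanded, saturated_time=True)
    curve = risk_curves(fit, horizon=int(expanded["t"].max()))
    for arm in (bbemu.ARM_TREATED, bbemu.ARM_CONTROL):
        sub = expanded[expanded["arm"] == arm]
        last = sub.groupby("person_id").agg(T=("t", "max"), E=("event", "max"))
        kmf = KaplanMeierFitter().fit(last["T"], last["E"])
        tg = np.array(sorted(sub["t"].unique()), dtype=float)
        ll = 1 - kmf.survival_function_at_times(tg).to_numpy()
        mine = (curve.curves[curve.curves["arm"] == arm]
                .set_index("t").loc[tg.astype(int), "risk"].to_numpy())
        np.testing.assert_allclose(mine, ll, atol=1e-10)


def test_no_events_is_estimation_error():
    df = _toy_intervals(hazard=0.0)
    with pytest.raises(EstimationError):
        fit_pooled_logistic(df)


def test_zero_event_arm_attaches_warning():
    df = _toy_intervals(n=300, hazard=0.03)
    df.loc[df["arm"] == bbemu.ARM_CONTROL, "event"] = 0
    fit = fit_pooled_logistic(df)
    assert any("zero events" in w for w in fit.warnings)


# ---------------------------------------------------------------------------
# risk curves and effects
# ---------------------------------------------------------------------------

def _constant_hazard_fit(h=0.01):
    tab = pd.DataFrame({"t": range(1, 61),
                        bbemu.ARM_TREATED: h, bbemu.ARM_CONTROL: h})
    return PooledLogisticFit(kind="saturated", params=None, names=None,
                             cov_robust=None, spline=None, interaction=True,
                             extra_covariates=[], design_refs={},
                             converged=True, warnings=[], horizon=60,
                             saturated_hazards=tab)


def test_constant_hazard_risk_closed_form():
    curve = risk_curves(_constant_hazard_fit(0.01))
    r = curve.risk_at(bbemu.ARM_TREATED, 60)
    assert abs(r - (1 - 0.99 ** 60)) < 1e-12
    assert abs(r - 0.4528) < 1e-3


def test_risk_curves_monotone_bounded(small_cohort):
    cfg, bundle, subjects, _ = small_cohort
    out = bbemu.itt_analysis(bundle, subjects, cfg.study_end)
    for arm, grp in out.curve.curves.groupby("arm"):
        r = grp.sort_values("t")["risk"].to_numpy()
        assert (np.diff(r) >= -1e-12).all()
        assert ((r >= 0) & (r <= 1)).all()


def test_effect_arithmetic_from_given_risks():
    tab = pd.DataFrame({"t": range(1, 61),
                        bbemu.ARM_TREATED: np.nan, bbemu.ARM_CONTROL: np.nan})
    # build a curve object directly with the target 5-year risks
    rows = []
    for arm, r in ((bbemu.ARM_TREATED, 0.102), (bbemu.ARM_CONTROL, 0.119)):
        for t in range(1, 61):
            rows.append((arm, t, np.nan, r * t / 60 if t < 60 else r))
    curve = bbemu.RiskCurve(curves=pd.DataFrame(
        rows, columns=["arm", "t", "hazard", "risk"]))
    eff = effect_estimates(curve)
    assert abs(eff.estimates["rd"] - (-1.7)) < 1e-12
    assert round(eff.estimates["rr"], 2) == 0.86


def test_identical_curves_null_effects():
    curve = risk_curves(_constant_hazard_fit(0.005))
    eff = effect_estimates(curve)
    assert eff.estimates["rd"] == 0.0
    assert eff.estimates["rr"] == 1.0


def test_average_hr_recovers_conditional_or_in_rare_outcome_cohort():
    """Constant multiplicative hazard contrast: no-interaction fit should
    recover the odds ratio."""
    rng = np.random.default_rng(9)
    rows = []
    for i in range(4000):
        arm = bbemu.ARM_TREATED if i % 2 else bbemu.ARM_CONTROL
        h = 0.004 * (0.75 if arm == bbemu.ARM_TREATED else 1.0)
        for t in range(1, 61):
            ev = rng.random() < h
            rows.append((i, t, arm, int(ev)))
            if ev:
                break
    df = pd.DataFrame(rows, columns=["person_id", "t", "arm", "event"])
    fit = fit_pooled_logistic(df, include_treatment_time_interaction=False)
    hr = float(np.exp(fit.params[fit.names.index("arm")]))
    assert abs(hr - 0.75) < 0.08


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_deterministic_and_degenerate():
    def const_stat(idx, rng):
        return {"x": 1.23}

    cis1, nf1 = bootstrap_cis(const_stat, n_persons=50, n_boot=40, seed=4)
    cis2, _ = bootstrap_cis(const_stat, n_persons=50, n_boot=40, seed=4)
    assert cis1 == cis2
    assert cis1["x"] == (1.23, 1.23)
    with pytest.raises(ConfigurationError):
        bootstrap_cis(const_stat, 50, n_boot=1, seed=0)


def test_bootstrap_failure_budget():
    calls = {"n": 0}

    def flaky(idx, rng):
        calls["n"] += 1
        if calls["n"] % 2 == 0:
            raise EstimationError("boom")
        return {"x": float(idx.mean())}

    with pytest.raises(EstimationError, match="replicates"):
        bootstrap_cis(flaky, 50, n_boot=40, seed=1)
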