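"""Generator contracts: determinism, confounded assignment, missingness,
counterfactual oracle against an independent risk recursion."""

import numpy as np
import pandas as pd
import pytest

import bbemu
from bbemu.core import expit, to_days
from bbemu.synthetic_registry import (CovariateDef, OutcomeModel,
                                      _draw_covariates, _draw_renal_onset,
                                      validate_config)
from bbemu import ConfigurationError


def _bundle_digest(bundle):
    parts = [getattr(bundle, t).to_csv(index=False)
             for t in ("persons", "dispensations", "diagnoses", "outcomes")]
    return "".join(parts)


def test_empty_cohort_yields_empty_tables():
    cfg = bbemu.default_config(n_persons=0)
    b = bbemu.generate_registry(cfg)
    assert len(b.persons) == 0 and len(b.dispensations) == 0
    assert len(b.diagnoses) == 0 and len(b.outcomes) == 0


def test_determinism_same_seed_identical_bundles():
    cfg = bbemu.default_config(n_persons=500, seed=9)
    b1 = bbemu.generate_registry(cfg)
    b2 = bbemu.generate_registry(cfg)
    assert _bundle_digest(b1) == _bundle_digest(b2)


def test_different_seed_differs():
    b1 = bbemu.generate_registry(bbemu.default_config(n_persons=300, seed=1))
    b2 = bbemu.generate_registry(bbemu.default_config(n_persons=300, seed=2))
    assert _bundle_digest(b1) != _bundle_digest(b2)


def test_assignment_coefficient_raises_prevalence_by_over_ten_points():
    # binary covariate L with +2.0 log-odds on prescription
    cfg = bbemu.default_config(
        n_persons=10_000, seed=3,
        covariate_spec=[CovariateDef("L", "binary", {"p": 0.5})],
        assignment_model=OutcomeModel(0.0, {"L": 2.0}),
        event_model={"death": OutcomeModel(-7.0, {"L": 0.3}),
                     "mi": OutcomeModel(-7.0, {})},
        missingness={})
    b = bbemu.generate_registry(cfg)
    subj, _ = bbemu.prepare_cohort(b)
    # tabulate prescription by L directly on the generated cohort
    tab = subj.groupby("L")["arm"].apply(
        lambda s: (s == bbemu.ARM_TREATED).mean())
    assert tab[1.0] - tab[0.0] > 0.10


def test_monotone_confounding_in_assignment_coefficient():
    assocs = []
    for coef in (0.0, 1.0, 2.0):
        cfg = bbemu.default_config(
            n_persons=6000, seed=4,
            covariate_spec=[CovariateDef("L", "binary", {"p": 0.4})],
            assignment_model=OutcomeModel(0.0, {"L": coef}),
            event_model={"death": OutcomeModel(-7.0, {"L": 0.3}),
                         "mi": OutcomeModel(-7.0, {})},
            missingness={})
        b = bbemu.generate_registry(cfg)
        subj, _ = bbemu.prepare_cohort(b)
        treated = (subj["arm"] == bbemu.ARM_TREATED).astype(float)
        assocs.append(np.corrcoef(subj["L"], treated)[0, 1])
    assert assocs[0] < assocs[1] < assocs[2]


def test_prebaseline_history_spans_full_lookback(small_registry):
    # dispensation/diagnosis dates may reach (but not exceed) 3 years back
    cfg, bundle = small_registry
    ang = bundle.persons.set_index("person_id")["angiography_date"]
    dx = bundle.diagnoses.merge(ang.rename("ang"), left_on="person_id",
                                right_index=True)
    back = (dx["ang"] - dx["date"]).dt.days
    assert back.max() <= 3 * 366
    assert (back > 2 * 365).any()  # history populated deep into the window


def test_invalid_configs_name_the_field():
    with pytest.raises(ConfigurationError, match="prior_bb_fraction"):
        validate_config(bbemu.default_config(prior_bb_fraction=1.5))
    with pytest.raises(ConfigurationError, match="undeclared covariate"):
        validate_config(bbemu.default_config(
            assignment_model=OutcomeModel(0.0, {"nonexistent": 1.0})))
    with pytest.raises(ConfigurationError, match="recruitment_window"):
        validate_config(bbemu.default_config(
            recruitment_window=("2017-01-01", "2010-01-01")))


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def test_inject_missingness_rates():
    cfg = bbemu.default_config(n_persons=10_000, seed=6,
                               missingness={"ldl": 0.155, "creatinine": 0.0})
    b = bbemu.generate_registry(cfg)
    out = bbemu.inject_missingness(b, cfg)
    assert out.persons["creatinine"].notna().all()
    frac = out.persons["ldl"].isna().mean()
    tol = 3 * np.sqrt(0.155 * 0.845 / 10_000)
    assert abs(frac - 0.155) < tol
    # rate 1 blanks everything; untouched tables identical
    cfg1 = bbemu.default_config(n_persons=500, seed=6, missingness={"ldl": 1.0})
    b1 = bbemu.generate_registry(cfg1)
    out1 = bbemu.inject_missingness(b1, cfg1)
    assert out1.persons["ldl"].isna().all()
    assert out1.dispensations.equals(b1.dispensations)


# ---------------------------------------------------------------------------
# counterfactual oracle
# ---------------------------------------------------------------------------

def test_oracle_null_effect_gives_zero_rd():
    cfg = confounded_null = bbemu.default_config(
        n_persons=1000, seed=8,
        event_model={"death": OutcomeModel(-7.0, {}, 0.0),
                     "mi": OutcomeModel(-7.0, {}, 0.0)})
    oracle = bbemu.compute_true_effects(cfg, 40_000, seed=8)
    for outcome in ("composite", "death", "mi"):
        assert abs(oracle.true_rd_5y[outcome]) < 3 * oracle.mc_se[outcome]


def test_oracle_constant_hazard_closed_form():
    # MI hazard 0.01/interval, no deaths: risk(60) = 1 - 0.99^60
    cfg = bbemu.default_config(
        n_persons=1000, seed=8,
        event_model={"death": OutcomeModel(-40.0, {}, 0.0),
                     "mi": OutcomeModel(float(np.log(0.01 / 0.99)), {}, 0.0)},
        renal_onset_rate=0.0, renal_baseline_rate=0.0)
    oracle = bbemu.compute_true_effects(cfg, 50_000, seed=9)
    expected = 1 - 0.99 ** 60
    got = oracle.true_risk_5y[("mi", bbemu.ARM_TREATED)]
    assert abs(got - expected) < 3 * oracle.mc_se["mi"]
    assert abs(expected - 0.4528) < 5e-4  # sanity on the closed form itself


def test_oracle_matches_independent_risk_recursion():
    """MC oracle vs an analytic per-person interval recursion."""
    cfg = effect_cfg = bbemu.default_config(n_persons=1000, seed=5)
    n = 50_000
    oracle = bbemu.compute_true_effects(cfg, n, seed=11)

    # independent recursion: draw the covariate/renal sample the same way,
    # then compute exact discrete-time risks instead of simulating events
    from bbemu.core import spawn_rngs
    rngs = spawn_rngs(11, "oracle_cov", "oracle_renal", "oracle_events")
    covs = _draw_covariates(cfg, n, rngs["oracle_cov"])
    onset = _draw_renal_onset(cfg, n, rngs["oracle_renal"])
    defs = cfg.cov_defs()

    def lp(model):
        eta = np.zeros(n)
        for name, coef in model.coef.items():
            if name == "renal_tv":
                continue
            d = defs[name]
            x = covs[name]
            if d.kind == "continuous":
                eta = eta + coef * (x - d.params["mean"]) / d.params["sd"]
            elif d.kind == "binary":
                eta = eta + coef * x
            else:
                for lv, v in coef.items():
                    eta = eta + v * (x == lv)
        return eta

    tgrid = np.arange(1, 61)
    renal = tgrid[None, :] >= onset[:, None]
    for arm, a in ((bbemu.ARM_TREATED, 1.0), (bbemu.ARM_CONTROL, 0.0)):
        md, mm = cfg.event_model["death"], cfg.event_model["mi"]
        hd = expit((md.intercept + lp(md) + md.treatment_logor * a)[:, None]
                   + md.coef.get("renal_tv", 0.0) * renal)
        hm = expit((mm.intercept + lp(mm) + mm.treatment_logor * a)[:, None]
                   + mm.coef.get("renal_tv", 0.0) * renal)
        surv_d = np.cumprod(1 - hd, axis=1)
        surv_m = np.cumprod(1 - hm, axis=1)
        # death is a marginal process; MI competes with earlier death
        death_risk = 1 - surv_d.mean(axis=0)
        prev_m = np.concatenate([np.ones((n, 1)), surv_m[:, :-1]], axis=1)
        prev_d = np.concatenate([np.ones((n, 1)), surv_d[:, :-1]], axis=1)
        mi_risk = np.cumsum(prev_m * hm * prev_d, axis=1).mean(axis=0)
        comp_risk = 1 - (surv_d * surv_m).mean(axis=0)
        got = oracle.risks[oracle.risks["arm"] == arm]
        for outcome, truth in (("death", death_risk), ("mi", mi_risk),
                               ("composite", comp_risk)):
            g = got[got["outcome"] == outcome].sort_values("t")["risk"].to_numpy()
            se = np.sqrt(np.maximum(truth * (1 - truth), 1e-9) / n)
            assert np.all(np.abs(g - truth) <= 4 * se + 1e-4), outcome


def test_oracle_risks_monotone_and_composite_dominates():
    oracle = bbemu.compute_true_effects(bbemu.default_config(), 5000, seed=2)
    piv = oracle.risks.pivot_table(index="t", columns=["outcome", "arm"],
                                   values="risk")
    for col in piv:
        assert (np.diff(piv[col]) >= -1e-12).all()
        assert piv[col].between(0, 1).all()
    for arm in (bbemu.ARM_TREATED, bbemu.ARM_CONTROL):
        assert (piv[("composite", arm)] >= piv[("mi", arm)] - 1e-12).all()
        assert (piv[("composite", arm)] >= piv[("death", arm)] - 1e-12).all()


def test_crude_itt_matches_oracle_without_confounding_or_deviation():
    """With no covariate links to assignment or adherence, the crude risk in
    the generated cohort converges to the oracle risk."""
    from bbemu.synthetic_registry import AdherenceModel
    cfg = bbemu.default_config(
        n_persons=50_000, seed=21,
        recruitment_window=("2010-09-01", "2011-09-01"),
        study_end="2017-12-31",
        assignment_model=OutcomeModel(0.5, {}),
        window_event_rate=0.0)
    oracle = bbemu.compute_true_effects(cfg, 50_000, seed=22)
    b = bbemu.generate_registry(cfg)
    b = bbemu.inject_missingness(b, cfg)
    subj, _ = bbemu.prepare_cohort(b)
    exp = bbemu.expand_person_time(subj, b.outcomes, None, cfg.study_end)
    from bbemu.outcome_models import km_risk_from_intervals
    km = km_risk_from_intervals(exp)
    for arm in (bbemu.ARM_TREATED, bbemu.ARM_CONTROL):
        got = km[(km["arm"] == arm) & (km["t"] == 60)]["risk"].iloc[0]
        truth = oracle.true_risk_5y[("composite", arm)]
        n_arm = (subj["arm"] == arm).sum()
        se = np.sqrt(truth * (1 - truth) * (1 / n_arm + 1 / 50_000))
        assert abs(got - truth) < 3 * se
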