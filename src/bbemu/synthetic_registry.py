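"""Synthetic registry generator with a counterfactual oracle.

Emulates the statistical structure a beta-blocker-after-MI target-trial
emulation has to cope with on real registry data:

* confounded prescribing — assignment to a beta blocker within the 30-day
  window follows a logistic model on baseline covariates;
* informative non-adherence — refill sequences in the treated arm stop
  (discontinuation) or gap, and untreated persons cross over, at rates that
  may depend on covariates including time-varying renal disease;
* contraindication / new-indication diagnoses that excuse deviations under
  the per-protocol adherence rule;
* competing death and new-MI hazards on a discrete monthly grid with a
  configurable treatment effect (the effect of the assigned strategy);
* pre-baseline (3-year lookback) diagnosis and dispensation history so every
  eligibility rule has persons to fire on;
* missingness in continuous labs.

Event histories are simulated on the analysis grid itself (30.4375-day
intervals), so the oracle recursion for true risks is exact on that grid.
Event dates are synthesized at the mid-interval day, which maps back to the
generating interval under the analysis' flooring rule.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (MONTH_DAYS, HORIZON, ARM_TREATED, ARM_CONTROL,
                   ConfigurationError, to_days, from_days, interval_mid_day,
                   expit, spawn_rngs)

__all__ = [
    "CovariateDef", "OutcomeModel", "AdherenceModel", "GeneratorConfig",
    "RegistryBundle", "TrueEffectOracle", "default_config",
    "generate_registry", "inject_missingness", "compute_true_effects",
    "write_bundle", "read_bundle",
]

CONTRAINDICATION_CODES = ("bradycardia", "av_block_2_3", "hypotension",
                          "syncope", "asthma", "copd", "stroke")
INDICATION_CODES = ("chronic_heart_failure", "atrial_flicker_flutter")
COMPLIANCE_CODES = ("psychiatric_disorder", "dementia")
NEW_INDICATION_CODES = ("hypertension_dx", "angina", "arrhythmia", "heart_failure")
OTHER_DRUG_CLASSES = ("arb", "ace_inhibitor", "ccb", "diuretic", "nitrate",
                      "diabetes_tx")


@dataclass
class CovariateDef:
    name: str
    kind: str  # "binary" | "categorical" | "continuous"
    params: dict


@dataclass
class OutcomeModel:
    """Per-interval logistic hazard: intercept + covariates (+ renal_tv) +
    treatment log-odds-ratio for the assigned strategy."""
    intercept: float
    coef: dict = field(default_factory=dict)
    treatment_logor: float = 0.0


@dataclass
class AdherenceModel:
    """Per-interval deviation hazards.

    ``discontinuation`` applies in the treated arm (stop refilling),
    ``crossover`` in the untreated arm (initiate a beta blocker).
    ``long_gap_prob`` is the per-refill probability of a >180-day refill
    delay that is later resumed; ``contra_before_discontinuation_prob`` /
    ``new_indication_before_crossover_prob`` control how often a deviation is
    preceded by a diagnosis that excuses it under the adherence rule.
    """
    discontinuation: OutcomeModel = field(
        default_factory=lambda: OutcomeModel(-4.4, {"renal_tv": 1.0}))
    crossover: OutcomeModel = field(
        default_factory=lambda: OutcomeModel(-4.85, {}))
    long_gap_prob: float = 0.004
    contra_before_discontinuation_prob: float = 0.3
    new_indication_before_crossover_prob: float = 0.5


def default_covariates() -> list[CovariateDef]:
    return [
        CovariateDef("age", "continuous", {"mean": 65.0, "sd": 10.0}),
        CovariateDef("female", "binary", {"p": 0.21}),
        CovariateDef("smoking", "categorical",
                     {"levels": ["never", "ex", "current"],
                      "probs": [0.42, 0.35, 0.23]}),
        CovariateDef("hypertension", "binary", {"p": 0.31}),
        CovariateDef("diabetes", "binary", {"p": 0.11}),
        CovariateDef("prev_mi", "binary", {"p": 0.045}),
        CovariateDef("prev_hf", "binary", {"p": 0.03}),
        CovariateDef("nstemi", "binary", {"p": 0.57}),
        CovariateDef("heart_rate", "continuous", {"mean": 72.0, "sd": 14.0}),
        CovariateDef("sbp", "continuous", {"mean": 146.0, "sd": 22.0}),
        CovariateDef("ldl", "continuous", {"mean": 3.3, "sd": 0.9}),
        CovariateDef("creatinine", "continuous", {"mean": 80.0, "sd": 18.0}),
    ]


@dataclass
class GeneratorConfig:
    n_persons: int = 10_000
    recruitment_window: tuple[str, str] = ("2010-09-01", "2017-09-10")
    study_end: str = "2017-12-31"
    covariate_spec: list[CovariateDef] = field(default_factory=default_covariates)
    assignment_model: OutcomeModel = field(default_factory=lambda: OutcomeModel(
        2.3, {"age": -0.35, "smoking": {"current": 0.35}, "prev_mi": -0.6,
              "prev_hf": -0.4, "nstemi": -0.35, "heart_rate": 0.55,
              "sbp": 0.15}))
    event_model: dict = field(default_factory=lambda: {
        "death": OutcomeModel(-7.1, {"age": 0.6, "diabetes": 0.35,
                                     "prev_mi": 0.4, "creatinine": 0.25,
                                     "renal_tv": 0.8},
                              treatment_logor=float(np.log(0.90))),
        "mi": OutcomeModel(-7.1, {"age": 0.25, "diabetes": 0.3,
                                  "prev_mi": 0.5, "ldl": 0.2,
                                  "renal_tv": 0.4},
                           treatment_logor=float(np.log(0.75))),
    })
    adherence_model: AdherenceModel = field(default_factory=AdherenceModel)
    renal_onset_rate: float = 0.002          # per interval
    renal_baseline_rate: float = 0.013
    contraindication_rate: float = 0.0008    # per interval, post-baseline
    new_indication_rate: float = 0.0008
    contraindication_history_rate: float = 0.05   # per person, 3-y lookback
    indication_history_rate: float = 0.03
    compliance_history_rate: float = 0.03
    window_event_rate: float = 0.01
    missing_angiography_rate: float = 0.02
    prior_bb_fraction: float = 0.10
    prior_bb_admission_agreement: float = 0.9
    statin_antithrombotic_fraction: float = 0.94
    bb_discharge_only_fraction: float = 0.03
    discharge_offset_days: int = 3
    bisoprolol_fraction: float = 0.2
    other_drug_user_fractions: dict = field(default_factory=lambda: {
        "arb": 0.18, "ace_inhibitor": 0.69, "ccb": 0.17, "diuretic": 0.125,
        "nitrate": 0.5, "diabetes_tx": 0.11})
    missingness: dict = field(default_factory=lambda: {"ldl": 0.155,
                                                       "creatinine": 0.044})
    seed: int = 0

    # -- helpers ----------------------------------------------------------
    def cov_defs(self) -> dict[str, CovariateDef]:
        return {c.name: c for c in self.covariate_spec}

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "covariate_spec" in d:
            d["covariate_spec"] = [CovariateDef(**c) if isinstance(c, dict) else c
                                   for c in d["covariate_spec"]]
        for key in ("assignment_model",):
            if key in d and isinstance(d[key], dict):
                d[key] = OutcomeModel(**d[key])
        if "event_model" in d:
            d["event_model"] = {k: (OutcomeModel(**v) if isinstance(v, dict) else v)
                                for k, v in d["event_model"].items()}
        if "adherence_model" in d and isinstance(d["adherence_model"], dict):
            am = dict(d["adherence_model"])
            for key in ("discontinuation", "crossover"):
                if isinstance(am.get(key), dict):
                    am[key] = OutcomeModel(**am[key])
            d["adherence_model"] = AdherenceModel(**am)
        if "recruitment_window" in d:
            d["recruitment_window"] = tuple(d["recruitment_window"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RegistryBundle:
    persons: pd.DataFrame
    dispensations: pd.DataFrame
    diagnoses: pd.DataFrame
    outcomes: pd.DataFrame
    meta: dict = field(default_factory=dict)


@dataclass
class TrueEffectOracle:
    """Marginal counterfactual risks under sustained treatment vs none."""
    risks: pd.DataFrame        # columns: outcome, arm, t, risk
    true_risk_5y: dict         # {(outcome, arm): risk at HORIZON}
    true_rd_5y: dict           # {outcome: treated - control}
    true_rr_5y: dict
    n_oracle: int
    mc_se: dict                # {outcome: binomial SE at HORIZON}


def default_config(**overrides) -> GeneratorConfig:
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

_EXTRA_MODEL_COVS = {"renal_tv"}


def validate_config(cfg: GeneratorConfig) -> None:
    if cfg.n_persons < 0:
        raise ConfigurationError("n_persons must be nonnegative")
    start, end = (pd.Timestamp(cfg.recruitment_window[0]),
                  pd.Timestamp(cfg.recruitment_window[1]))
    if start > end:
        raise ConfigurationError("recruitment_window start after end")
    if pd.Timestamp(cfg.study_end) < end:
        raise ConfigurationError("study_end precedes recruitment_window end")
    declared = set(cfg.cov_defs())
    for label, model in [("assignment_model", cfg.assignment_model),
                         *[(f"event_model[{k}]", m) for k, m in cfg.event_model.items()],
                         ("adherence_model.discontinuation", cfg.adherence_model.discontinuation),
                         ("adherence_model.crossover", cfg.adherence_model.crossover)]:
        for name in model.coef:
            if name not in declared and name not in _EXTRA_MODEL_COVS:
                raise ConfigurationError(
                    f"{label} coefficient references undeclared covariate '{name}'")
    for pname in ("contraindication_rate", "new_indication_rate",
                  "renal_onset_rate", "renal_baseline_rate",
                  "prior_bb_fraction", "statin_antithrombotic_fraction",
                  "window_event_rate", "missing_angiography_rate",
                  "bb_discharge_only_fraction", "bisoprolol_fraction",
                  "prior_bb_admission_agreement"):
        v = getattr(cfg, pname)
        if not (0.0 <= v <= 1.0):
            raise ConfigurationError(f"{pname} must be in [0, 1], got {v}")
    for name, rate in cfg.missingness.items():
        if not (0.0 <= rate <= 1.0):
            raise ConfigurationError(f"missingness[{name}] must be in [0, 1]")
        if name not in declared:
            raise ConfigurationError(f"missingness references undeclared covariate '{name}'")


# ---------------------------------------------------------------------------
# covariates and linear predictors
# ---------------------------------------------------------------------------

def _draw_covariates(cfg: GeneratorConfig, n: int, rng) -> dict[str, np.ndarray]:
    out = {}
    for c in cfg.covariate_spec:
        if c.kind == "binary":
            out[c.name] = (rng.random(n) < c.params["p"]).astype(float)
        elif c.kind == "continuous":
            out[c.name] = c.params["mean"] + c.params["sd"] * rng.standard_normal(n)
        elif c.kind == "categorical":
            levels = np.asarray(c.params["levels"], dtype=object)
            probs = np.asarray(c.params["probs"], dtype=float)
            out[c.name] = levels[rng.choice(len(levels), size=n, p=probs / probs.sum())]
        else:
            raise ConfigurationError(f"unknown covariate kind '{c.kind}' for {c.name}")
    return out


def _linpred(model: OutcomeModel, covs: dict[str, np.ndarray],
             defs: dict[str, CovariateDef], n: int) -> np.ndarray:
    """Linear predictor excluding intercept, treatment and renal_tv terms.

    Continuous covariates enter standardized by their marginal (mean, sd), so
    coefficients are per-SD log-odds.
    """
    eta = np.zeros(n)
    for name, coef in model.coef.items():
        if name in _EXTRA_MODEL_COVS:
            continue
        d = defs[name]
        x = covs[name]
        if d.kind == "continuous":
            eta += coef * (x - d.params["mean"]) / d.params["sd"]
        elif d.kind == "binary":
            eta += coef * x
        else:  # categorical: coef is {level: value}
            for level, v in coef.items():
                eta += v * (x == level)
    return eta


def _renal_gamma(model: OutcomeModel) -> float:
    return float(model.coef.get("renal_tv", 0.0))


# ---------------------------------------------------------------------------
# discrete-time event engine (shared by the registry and the oracle)
# ---------------------------------------------------------------------------

def _first_hit(rng, eta_base: np.ndarray, gamma_renal: float,
               renal_onset: np.ndarray, horizon: int) -> np.ndarray:
    """First interval (1-based) where a per-interval Bernoulli with logistic
    hazard fires; HORIZON+999 if never within the horizon.

    ``renal_onset`` is the 1-based interval from which the renal indicator is
    on (0 = prevalent at baseline, inf/large = never).
    """
    n = len(eta_base)
    tgrid = np.arange(1, horizon + 1)
    renal_on = tgrid[None, :] >= renal_onset[:, None]
    p = expit(eta_base[:, None] + gamma_renal * renal_on)
    hit = rng.random((n, horizon)) < p
    any_hit = hit.any(axis=1)
    first = np.where(any_hit, hit.argmax(axis=1) + 1, horizon + 999)
    return first


def _simulate_events(cfg: GeneratorConfig, covs: dict, treated: np.ndarray,
                     renal_onset: np.ndarray, rng,
                     horizon: int = HORIZON) -> tuple[np.ndarray, np.ndarray]:
    """Death and first-MI intervals under the assigned sustained strategy.

    MI can only occur while alive; an MI in the same interval as death is
    allowed (the analysis resolves the tie per outcome).  Returns 1-based
    intervals, HORIZON+999 when the event does not occur within the horizon.
    """
    defs = cfg.cov_defs()
    n = len(treated)
    md, mm = cfg.event_model["death"], cfg.event_model["mi"]
    eta_d = md.intercept + _linpred(md, covs, defs, n) + md.treatment_logor * treated
    eta_m = mm.intercept + _linpred(mm, covs, defs, n) + mm.treatment_logor * treated

    tgrid = np.arange(1, horizon + 1)
    renal_on = tgrid[None, :] >= renal_onset[:, None]
    p_d = expit(eta_d[:, None] + _renal_gamma(md) * renal_on)
    p_m = expit(eta_m[:, None] + _renal_gamma(mm) * renal_on)
    hit_d = rng.random((n, horizon)) < p_d
    hit_m = rng.random((n, horizon)) < p_m

    death_t = np.where(hit_d.any(1), hit_d.argmax(1) + 1, horizon + 999)
    alive_mask = tgrid[None, :] <= death_t[:, None]   # MI allowed through death interval
    hit_m = hit_m & alive_mask
    mi_t = np.where(hit_m.any(1), hit_m.argmax(1) + 1, horizon + 999)
    return death_t, mi_t


def _draw_renal_onset(cfg: GeneratorConfig, n: int, rng,
                      horizon: int = HORIZON) -> np.ndarray:
    """1-based onset interval; 0 for prevalent-at-baseline; BIG for never."""
    onset = np.full(n, horizon + 999, dtype=float)
    prevalent = rng.random(n) < cfg.renal_baseline_rate
    onset[prevalent] = 0
    if cfg.renal_onset_rate > 0:
        g = rng.geometric(cfg.renal_onset_rate, size=n)  # >= 1
        incident = (~prevalent) & (g <= horizon)
        onset[incident] = g[incident]
    return onset


# ---------------------------------------------------------------------------
# registry generation
# ---------------------------------------------------------------------------

def generate_registry(config: GeneratorConfig) -> RegistryBundle:
    """Generate the four registry tables. Deterministic given (config, seed)."""
    validate_config(config)
    cfg = config
    n = cfg.n_persons
    rngs = spawn_rngs(cfg.seed, "covariates", "history", "assignment",
                      "events", "adherence", "drugs", "window")
    empty = RegistryBundle(
        persons=pd.DataFrame(columns=["person_id", "index_hospitalization_date",
                                      "angiography_date",
                                      "admission_record_prior_bb",
                                      "bb_at_discharge"]),
        dispensations=pd.DataFrame(columns=["person_id", "drug_class",
                                            "dispense_date", "pill_count",
                                            "pill_dose_mg"]),
        diagnoses=pd.DataFrame(columns=["person_id", "condition_code", "date",
                                        "source"]),
        outcomes=pd.DataFrame(columns=["person_id", "event", "date"]),
        meta={"config_hash": cfg.config_hash(), "seed": cfg.seed, "n_persons": 0})
    if n == 0:
        return empty

    pid = np.arange(1, n + 1)
    start_day, end_day = (int(to_days([cfg.recruitment_window[0]])[0]),
                          int(to_days([cfg.recruitment_window[1]])[0]))
    admin_day = int(to_days([cfg.study_end])[0])

    rng = rngs["covariates"]
    index_day = rng.integers(start_day, end_day + 1, size=n)
    angio_day = index_day + rng.integers(0, 3, size=n)
    angio_missing = rng.random(n) < cfg.missing_angiography_rate
    covs = _draw_covariates(cfg, n, rng)
    defs = cfg.cov_defs()

    # -- assignment (confounded prescribing) ------------------------------
    rng = rngs["assignment"]
    am = cfg.assignment_model
    p_treat = expit(am.intercept + _linpred(am, covs, defs, n))
    treated = rng.random(n) < p_treat
    t0_day = angio_day + 30

    disp_rows = []   # (pid, class, day, count, dose)
    diag_rows = []   # (pid, code, day, source)
    out_rows = []    # (pid, event, day)

    # -- 3-year lookback history ------------------------------------------
    rng = rngs["history"]
    lookback = 1095  # days

    def _lookback_dx(rate, codes, source_pool):
        has = rng.random(n) < rate
        idx = np.nonzero(has)[0]
        if len(idx) == 0:
            return
        days = angio_day[idx] - rng.integers(1, lookback, size=len(idx))
        codes_arr = np.asarray(codes, dtype=object)[rng.integers(0, len(codes), size=len(idx))]
        src = np.asarray(source_pool, dtype=object)[rng.integers(0, len(source_pool), size=len(idx))]
        for i, d, c, s in zip(pid[idx], days, codes_arr, src):
            diag_rows.append((i, c, d, s))

    _lookback_dx(cfg.contraindication_history_rate, CONTRAINDICATION_CODES,
                 ["inpatient", "outpatient"])
    _lookback_dx(cfg.indication_history_rate, INDICATION_CODES, ["registry"])
    _lookback_dx(cfg.compliance_history_rate, COMPLIANCE_CODES,
                 ["registry", "inpatient"])

    # prior beta-blocker use: dispensation trail + admission-record flag with
    # imperfect agreement (both sensitivity-2 signals)
    prior_bb = rng.random(n) < cfg.prior_bb_fraction
    agree = cfg.prior_bb_admission_agreement
    admission_flag = np.where(prior_bb, rng.random(n) < agree,
                              rng.random(n) < 0.02)
    idx = np.nonzero(prior_bb)[0]
    for i, a in zip(pid[idx], angio_day[idx]):
        d1 = a - rng.integers(200, 1000)
        disp_rows.append((i, "metoprolol", d1, 100, 100.0))
        disp_rows.append((i, "metoprolol", d1 + 100, 100, 100.0))

    # statins + antithrombotics at baseline for most otherwise-eligible persons
    both = rng.random(n) < cfg.statin_antithrombotic_fraction
    statin_only = (~both) & (rng.random(n) < 0.5)
    for i, a, b, so in zip(pid, angio_day, both, statin_only):
        if b or so:
            disp_rows.append((i, "statin", a - rng.integers(5, 300), 100, 20.0))
        if b:
            disp_rows.append((i, "antithrombotic", a - rng.integers(5, 300), 100, 75.0))

    # baseline-prevalent renal disease diagnoses
    renal_onset = _draw_renal_onset(cfg, n, rngs["events"])
    idx = np.nonzero(renal_onset == 0)[0]
    for i, a in zip(pid[idx], angio_day[idx]):
        diag_rows.append((i, "renal_disease", a - rng.integers(30, 1000), "inpatient"))

    # -- events in the assignment window (eligibility criterion 6) --------
    rng = rngs["window"]
    wevent = rng.random(n) < cfg.window_event_rate
    wdeath = wevent & (rng.random(n) < 0.4)
    wmi = wevent & ~wdeath
    wday = angio_day + rng.integers(1, 31, size=n)
    for i, d in zip(pid[wdeath], wday[wdeath]):
        out_rows.append((i, "death", d))
    for i, d in zip(pid[wmi], wday[wmi]):
        out_rows.append((i, "mi", d))

    # -- post-baseline events under the assigned strategy ------------------
    death_t, mi_t = _simulate_events(cfg, covs, treated.astype(float),
                                     renal_onset, rngs["events"])
    death_t = np.where(wdeath, 0, death_t)       # window deaths preempt
    death_day = np.where(death_t >= 1, t0_day + interval_mid_day(np.maximum(death_t, 1)),
                         wday)
    death_day = np.where(wdeath, wday, death_day)
    has_death = (death_t <= HORIZON) | wdeath
    obs_death = has_death & (death_day <= admin_day)
    has_mi = (mi_t <= HORIZON) & ~wdeath
    mi_day = t0_day + interval_mid_day(np.maximum(mi_t, 1))
    obs_mi = has_mi & (mi_day <= admin_day)
    for i, d in zip(pid[obs_death & ~wdeath], death_day[obs_death & ~wdeath]):
        out_rows.append((i, "death", d))
    for i, d in zip(pid[obs_mi], mi_day[obs_mi]):
        out_rows.append((i, "mi", d))

    # renal-disease onset diagnoses during follow-up
    inc = (renal_onset >= 1) & (renal_onset <= HORIZON)
    rdx_day = t0_day + interval_mid_day(np.maximum(renal_onset, 1).astype(int))
    stop_day_all = np.where(obs_death, death_day, admin_day)
    inc &= rdx_day <= stop_day_all
    for i, d in zip(pid[inc], rdx_day[inc]):
        diag_rows.append((i, "renal_disease", int(d), "inpatient"))

    # background contraindication / new-indication diagnoses post-baseline
    rng = rngs["window"]
    for rate, codes in ((cfg.contraindication_rate, CONTRAINDICATION_CODES),
                        (cfg.new_indication_rate, NEW_INDICATION_CODES)):
        if rate <= 0:
            continue
        g = rng.geometric(rate, size=n)
        hit = g <= HORIZON
        dxd = t0_day + interval_mid_day(np.maximum(g, 1))
        hit &= dxd <= stop_day_all
        codes_arr = np.asarray(codes, dtype=object)[rng.integers(0, len(codes), size=n)]
        for i, d, c in zip(pid[hit], dxd[hit], codes_arr[hit]):
            diag_rows.append((i, c, int(d), "outpatient"))

    # -- beta-blocker refill engine (treated arm) --------------------------
    rng = rngs["adherence"]
    amod = cfg.adherence_model
    eta_disc = (amod.discontinuation.intercept
                + _linpred(amod.discontinuation, covs, defs, n))
    disc_t = _first_hit(rng, eta_disc, _renal_gamma(amod.discontinuation),
                        renal_onset, HORIZON)
    disc_day = t0_day + interval_mid_day(np.maximum(disc_t, 1))
    disc_day = np.where(disc_t > HORIZON, admin_day + 10_000, disc_day)

    is_bb = treated & ~wdeath & ~angio_missing
    discharge_only = is_bb & (rng.random(n) < cfg.bb_discharge_only_fraction)
    window_disp = is_bb & ~discharge_only
    first_day = np.where(window_disp, angio_day + rng.integers(1, 31, size=n),
                         angio_day + cfg.discharge_offset_days)
    biso = rng.random(n) < cfg.bisoprolol_fraction
    stop_day = np.minimum(np.minimum(disc_day, np.where(obs_death, death_day,
                                                        admin_day + 10_000)),
                          admin_day)

    cur = first_day.astype(float)
    prev_end = np.full(n, -1e18)
    active = is_bb.copy()
    last_end = np.full(n, np.nan)
    max_refills = int(np.ceil((HORIZON + 4) * MONTH_DAYS / 30)) + 2
    for _ in range(max_refills):
        act = active & (cur <= stop_day)
        if not act.any():
            break
        # pill menus: metoprolol 90/100 pills at 50/100 mg; bisoprolol 5 mg
        u = rng.random(n)
        count = np.where(biso, np.where(u < 0.8, 100, 30),
                         np.where(u < 0.5, 100, np.where(u < 0.75, 100, 90)))
        dose = np.where(biso, 5.0, np.where(u < 0.5, 100.0,
                                            np.where(u < 0.75, 50.0, 100.0)))
        daily = np.where(biso, 5.0, 100.0)
        dur = np.floor(count * dose / daily)
        drug = np.where(biso, "bisoprolol", "metoprolol")
        for i, d, c, do, dg in zip(pid[act], cur[act].astype(int), count[act],
                                   dose[act], drug[act]):
            disp_rows.append((i, dg, d, int(c), float(do)))
        seg_start = np.maximum(cur, prev_end + 1)
        seg_end = seg_start + dur - 1
        prev_end = np.where(act, seg_end, prev_end)
        last_end = np.where(act, seg_end, last_end)
        delay = rng.uniform(-15, 15, size=n)
        long_gap = rng.random(n) < amod.long_gap_prob
        delay = np.where(long_gap, 190 + rng.uniform(0, 100, size=n), delay)
        cur = np.where(act, seg_end + 1 + np.round(delay), cur)
        active = act

    # contraindication preceding a discontinuation excuses the terminal gap
    disc_obs = is_bb & (disc_day <= stop_day + 1) & np.isfinite(last_end)
    excused = disc_obs & (rng.random(n) < amod.contra_before_discontinuation_prob)
    cdx_day = np.maximum(last_end - 10, angio_day + 31)
    codes_arr = np.asarray(CONTRAINDICATION_CODES, dtype=object)[
        rng.integers(0, len(CONTRAINDICATION_CODES), size=n)]
    for i, d, c in zip(pid[excused], cdx_day[excused], codes_arr[excused]):
        diag_rows.append((i, c, int(d), "inpatient"))

    # -- crossover initiation (untreated arm) ------------------------------
    eta_x = (amod.crossover.intercept + _linpred(amod.crossover, covs, defs, n))
    cross_t = _first_hit(rng, eta_x, _renal_gamma(amod.crossover),
                         renal_onset, HORIZON)
    cross_day = t0_day + interval_mid_day(np.maximum(cross_t, 1))
    is_ctrl = ~treated & ~wdeath
    crossed = is_ctrl & (cross_t <= HORIZON) & (cross_day <= stop_day)
    newind = crossed & (rng.random(n) < amod.new_indication_before_crossover_prob)
    ni_codes = np.asarray(NEW_INDICATION_CODES, dtype=object)[
        rng.integers(0, len(NEW_INDICATION_CODES), size=n)]
    for i, d, c in zip(pid[newind], cross_day[newind] - 20, ni_codes[newind]):
        diag_rows.append((i, c, int(d), "outpatient"))
    for i, d in zip(pid[crossed], cross_day[crossed]):
        disp_rows.append((i, "metoprolol", int(d), 100, 100.0))

    # -- concomitant drug classes (time-varying covariates) ----------------
    rng = rngs["drugs"]
    for cls, frac in cfg.other_drug_user_fractions.items():
        users = np.nonzero(rng.random(n) < frac)[0]
        if len(users) == 0:
            continue
        ustart = angio_day[users] - rng.integers(0, 180, size=len(users))
        ustop = stop_day_all[users]
        step = rng.integers(80, 121, size=len(users))
        max_r = int(np.ceil((180 + (HORIZON + 2) * MONTH_DAYS) / 80)) + 1
        for r in range(max_r):
            day_r = ustart + r * step
            ok = day_r <= ustop
            if not ok.any():
                break
            for i, d in zip(pid[users[ok]], day_r[ok]):
                disp_rows.append((i, cls, int(d), 100, 1.0))

    # -- assemble tables ----------------------------------------------------
    persons = pd.DataFrame({"person_id": pid,
                            "index_hospitalization_date": from_days(index_day),
                            "angiography_date": from_days(angio_day)})
    persons.loc[angio_missing, "angiography_date"] = pd.NaT
    for name in defs:
        persons[name] = covs[name]
    persons["admission_record_prior_bb"] = admission_flag.astype(bool)
    persons["bb_at_discharge"] = (discharge_only | (treated & ~angio_missing
                                                    & ~wdeath
                                                    & (rng.random(n) < 0.5))).astype(bool)

    dispensations = pd.DataFrame(disp_rows, columns=["person_id", "drug_class",
                                                     "dispense_date",
                                                     "pill_count",
                                                     "pill_dose_mg"])
    dispensations["dispense_date"] = from_days(dispensations["dispense_date"]
                                               .to_numpy()).to_numpy()
    diagnoses = pd.DataFrame(diag_rows, columns=["person_id", "condition_code",
                                                 "date", "source"])
    diagnoses["date"] = from_days(diagnoses["date"].to_numpy()).to_numpy()
    outcomes = pd.DataFrame(out_rows, columns=["person_id", "event", "date"])
    outcomes["date"] = from_days(outcomes["date"].to_numpy()).to_numpy()

    for df, keys in ((dispensations, ["person_id", "dispense_date", "drug_class"]),
                     (diagnoses, ["person_id", "date", "condition_code"]),
                     (outcomes, ["person_id", "date", "event"])):
        df.sort_values(keys, inplace=True, kind="mergesort")
        df.reset_index(drop=True, inplace=True)

    meta = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "n_persons": n}
    return RegistryBundle(persons=persons, dispensations=dispensations,
                          diagnoses=diagnoses, outcomes=outcomes, meta=meta)


def inject_missingness(bundle: RegistryBundle,
                       config: GeneratorConfig) -> RegistryBundle:
    """Blank continuous covariates independently at the configured rates."""
    validate_config(config)
    persons = bundle.persons.copy()
    rng = spawn_rngs(config.seed, "missingness")["missingness"]
    for name, rate in config.missingness.items():
        mask = rng.random(len(persons)) < rate
        persons.loc[mask, name] = np.nan
    return RegistryBundle(persons=persons, dispensations=bundle.dispensations,
                          diagnoses=bundle.diagnoses, outcomes=bundle.outcomes,
                          meta=dict(bundle.meta))


# ---------------------------------------------------------------------------
# counterfactual oracle
# ---------------------------------------------------------------------------

def compute_true_effects(config: GeneratorConfig, n_oracle: int,
                         seed: int) -> TrueEffectOracle:
    """Simulate both counterfactual histories per oracle person.

    Adherence is forced perfect, so the oracle risk is the marginal risk of
    the sustained strategy: always treated from time zero vs never treated.
    There is no administrative censoring in the counterfactual world.
    """
    validate_config(config)
    if n_oracle < 1000:
        raise ConfigurationError("n_oracle must be >= 1000")
    rngs = spawn_rngs(seed, "oracle_cov", "oracle_renal", "oracle_events")
    covs = _draw_covariates(config, n_oracle, rngs["oracle_cov"])
    renal_onset = _draw_renal_onset(config, n_oracle, rngs["oracle_renal"])

    rows = []
    risk5, rd, rr, mcse = {}, {}, {}, {}
    per_arm = {}
    for arm_label, a in ((ARM_TREATED, 1.0), (ARM_CONTROL, 0.0)):
        treated = np.full(n_oracle, a)
        death_t, mi_t = _simulate_events(config, covs, treated, renal_onset,
                                         rngs["oracle_events"])
        comp_t = np.minimum(death_t, mi_t)
        per_arm[arm_label] = {}
        for outcome, ev_t in (("composite", comp_t), ("death", death_t),
                              ("mi", mi_t)):
            cum = np.array([(ev_t <= t).mean() for t in range(1, HORIZON + 1)])
            per_arm[arm_label][outcome] = cum
            for t, r in enumerate(cum, start=1):
                rows.append((outcome, arm_label, t, r))
    for outcome in ("composite", "death", "mi"):
        r1 = per_arm[ARM_TREATED][outcome][-1]
        r0 = per_arm[ARM_CONTROL][outcome][-1]
        risk5[(outcome, ARM_TREATED)] = r1
        risk5[(outcome, ARM_CONTROL)] = r0
        rd[outcome] = r1 - r0
        rr[outcome] = r1 / r0 if r0 > 0 else np.nan
        mcse[outcome] = float(np.sqrt(r1 * (1 - r1) / n_oracle
                                      + r0 * (1 - r0) / n_oracle))
    risks = pd.DataFrame(rows, columns=["outcome", "arm", "t", "risk"])
    return TrueEffectOracle(risks=risks, true_risk_5y=risk5, true_rd_5y=rd,
                            true_rr_5y=rr, n_oracle=n_oracle, mc_se=mcse)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_TABLES = ("persons", "dispensations", "diagnoses", "outcomes")


def write_bundle(bundle: RegistryBundle, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        df = getattr(bundle, name).copy()
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.strftime("%Y-%m-%d")
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(json.dumps(bundle.meta, indent=2))


def read_bundle(indir) -> RegistryBundle:
    indir = Path(indir)
    tables = {}
    for name in _TABLES:
        df = pd.read_csv(indir / f"{name}.tsv", sep="\t")
        for col in df.columns:
            if col.endswith("date") or col == "date":
                df[col] = pd.to_datetime(df[col])
        tables[name] = df
    meta = {}
    mf = indir / "manifest.json"
    if mf.exists():
        meta = json.loads(mf.read_text())
    return RegistryBundle(meta=meta, **tables)
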