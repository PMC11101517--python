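"""Sensitivity analyses around the main emulation.

Variants: (1) covariate-adjusted outcome model instead of IP weighting;
(2a/2b) prior-beta-blocker eligibility reformulations; (3a/3b) missing-data
strategies (complete case; "missing" categories); (4) a clone-censor-weight
analysis that moves time zero back to angiography with a grace period for
initiation; and the 90-day-gap per-protocol variant.

The clone-censor recipe: every person eligible at angiography contributes
one clone per strategy with time zero at angiography.  The initiation clone
is censored at the end of the grace period if no beta-blocker dispensation
occurred by then; the no-initiation clone is censored at the first
dispensation inside the grace window.  The grace window is modelled as a
single nonparametric discrete interval (weighted event proportion per clone
arm, with inverse-probability-of-censoring weights from baseline covariates)
and composed with a pooled logistic fit on the post-window person-time,
which runs on the same interval grid as the main landmark analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (HORIZON, ARM_TREATED, ARM_CONTROL, BB_CLASSES,
                   ConfigurationError, PositivityError, build_design,
                   fit_logistic, to_days, from_days)
from .cohort_builder import (EligibilityConfig, apply_eligibility, assign_arm,
                             impute_baseline)
from .adherence_censoring import AdherenceConfig, expand_person_time
from .outcome_models import (SplineSpec, fit_pooled_logistic, risk_curves,
                             effect_estimates, EffectEstimates)

__all__ = ["SensitivityGrid", "covariate_adjusted_analysis",
           "prior_bb_variants", "missingness_variants",
           "clone_censor_analysis", "pp_gap_variant", "run_sensitivity_suite"]


@dataclass
class SensitivityGrid:
    entries: list = field(default_factory=list)   # (label, EffectEstimates)
    config_deltas: dict = field(default_factory=dict)
    base_hash: str = ""

    def add(self, label: str, effects: EffectEstimates, delta: str):
        if label in self.config_deltas:
            raise ConfigurationError(f"duplicate sensitivity label '{label}'")
        self.entries.append((label, effects))
        self.config_deltas[label] = delta

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for label, eff in self.entries:
            f = eff.to_frame()
            f.insert(0, "variant", label)
            f["config_delta"] = self.config_deltas[label]
            frames.append(f)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def covariate_adjusted_analysis(person_intervals: pd.DataFrame,
                                covariates: list,
                                spline: SplineSpec | None = None
                                ) -> EffectEstimates:
    """Outcome-model adjustment: unweighted pooled logistic with baseline
    covariates as regressors; risks standardized over the empirical covariate
    distribution (parametric g-formula)."""
    spline = spline or SplineSpec()
    fit = fit_pooled_logistic(person_intervals, weights=None, spline=spline,
                              extra_covariates=covariates)
    curve = risk_curves(fit, spline, contrast="itt")
    eff = effect_estimates(curve, person_intervals=person_intervals,
                           weights=None, spline=spline,
                           extra_covariates=covariates)
    eff.contrast = "itt"
    return eff


def _prior_bb_dispensation_flag(bundle, subjects: pd.DataFrame,
                                lookback_days: int = 1096) -> np.ndarray:
    disp = bundle.dispensations
    bb = disp[disp["drug_class"].isin(BB_CLASSES)]
    ang = pd.Series(to_days(subjects["angiography_date"]),
                    index=subjects["person_id"])
    flagged = np.zeros(len(subjects), dtype=float)
    if len(bb):
        bb = bb.merge(ang.rename("anchor"), left_on="person_id",
                      right_index=True, how="inner")
        d = to_days(bb["dispense_date"])
        anchor = bb["anchor"].to_numpy()
        ids = set(bb.loc[(d <= anchor) & (d > anchor - lookback_days),
                         "person_id"])
        flagged = subjects["person_id"].isin(ids).to_numpy(dtype=float)
    return flagged


def _run_itt(bundle, subjects, covariates, admin_end, spline,
             outcome_kind="composite") -> EffectEstimates:
    from .pipeline import itt_analysis
    out = itt_analysis(bundle, subjects, admin_end, covariates,
                       outcome_kind=outcome_kind, spline=spline)
    return out.effects


def prior_bb_variants(bundle, eligibility: EligibilityConfig,
                      covariates: list, admin_end,
                      spline: SplineSpec | None = None,
                      imputation: str = "median") -> list:
    """Variants 2a (keep prior users, adjust for either-source indicator) and
    2b (exclude on the admission record only, adjust for dispensation
    history)."""
    spline = spline or SplineSpec()
    out = []

    cfg_2a = replace(eligibility, exclude_prior_bb=False)
    elig, _ = apply_eligibility(bundle, cfg_2a)
    subj = assign_arm(bundle, elig, cfg_2a)
    disp_flag = _prior_bb_dispensation_flag(bundle, subj)
    subj["prior_bb_any"] = np.maximum(
        disp_flag, subj["admission_record_prior_bb"].to_numpy(dtype=float))
    subj = impute_baseline(subj, imputation)
    eff = _run_itt(bundle, subj, covariates + ["prior_bb_any"], admin_end,
                   spline)
    out.append(("2a_include_prior_bb", eff,
                "exclude_prior_bb=False; +prior_bb_any covariate"))

    cfg_2b = replace(eligibility, prior_bb_source="admission_record_only")
    elig, _ = apply_eligibility(bundle, cfg_2b)
    subj = assign_arm(bundle, elig, cfg_2b)
    subj["prior_bb_dispensation"] = _prior_bb_dispensation_flag(bundle, subj)
    subj = impute_baseline(subj, imputation)
    eff = _run_itt(bundle, subj, covariates + ["prior_bb_dispensation"],
                   admin_end, spline)
    out.append(("2b_admission_record_only", eff,
                "prior_bb_source=admission_record_only; "
                "+prior_bb_dispensation covariate"))
    return out


def missingness_variants(bundle, eligibility: EligibilityConfig,
                         covariates: list, admin_end,
                         spline: SplineSpec | None = None) -> list:
    """Variants 3a (complete case) and 3b (continuous covariates binned with
    a "missing" category)."""
    spline = spline or SplineSpec()
    elig, _ = apply_eligibility(bundle, eligibility)
    raw = assign_arm(bundle, elig, eligibility)
    out = []
    cc = impute_baseline(raw, "complete_case")
    if len(cc) == 0:
        raise ConfigurationError("complete-case cohort is empty")
    out.append(("3a_complete_case",
                _run_itt(bundle, cc, covariates, admin_end, spline),
                "imputation=complete_case"))
    mc = impute_baseline(raw, "missing_category")
    out.append(("3b_missing_category",
                _run_itt(bundle, mc, covariates, admin_end, spline),
                "imputation=missing_category"))
    return out


# ---------------------------------------------------------------------------
# clone-censor-weight analysis
# ---------------------------------------------------------------------------

def clone_censor_analysis(bundle, eligibility: EligibilityConfig | None = None,
                          grace_days: int = 30,
                          covariates: list | None = None, admin_end=None,
                          spline: SplineSpec | None = None,
                          imputation: str = "median",
                          outcome_kind: str = "composite"):
    """Clone-censor-weight analysis with time zero at angiography.

    Returns ``(EffectEstimates, clones)`` where ``clones`` records one row
    per clone with its censoring day (days since angiography) or NaN.

    Intended for the composite outcome: for a single-component outcome, a
    window event of the other type would leave a clone with an outcome
    record preceding its post-window time zero, which the expansion rejects
    as misaligned.
    """
    from .pipeline import DEFAULT_COVARIATES
    eligibility = eligibility or EligibilityConfig()
    covariates = covariates or DEFAULT_COVARIATES
    spline = spline or SplineSpec()
    # eligibility must be determinable at angiography: drop the two criteria
    # that post-date it
    cfg = replace(eligibility, require_statin_antithrombotic=False,
                  exclude_window_events=False)
    elig, _ = apply_eligibility(bundle, cfg)
    subj = assign_arm(bundle, elig, cfg)
    subj = impute_baseline(subj, imputation)
    n = len(subj)
    ang = to_days(subj["angiography_date"])

    # first beta-blocker dispensation after angiography (any time)
    disp = bundle.dispensations
    bb = disp[disp["drug_class"].isin(BB_CLASSES)]
    first_bb = np.full(n, np.inf)
    if len(bb):
        bb = bb.merge(pd.DataFrame({"person_id": subj["person_id"],
                                    "_ang": ang}), on="person_id", how="inner")
        d = to_days(bb["dispense_date"])
        rel = d - bb["_ang"].to_numpy()
        bb = bb.assign(_rel=rel)
        bb = bb[bb["_rel"] > 0]
        firsts = bb.groupby("person_id")["_rel"].min()
        pos = {p: i for i, p in enumerate(subj["person_id"])}
        for p, r in firsts.items():
            first_bb[pos[p]] = r
    init_in_grace = first_bb <= grace_days

    # first outcome after angiography
    oc = bundle.outcomes.merge(pd.DataFrame({"person_id": subj["person_id"],
                                             "_ang": ang}),
                               on="person_id", how="inner")
    od = to_days(oc["date"]) - oc["_ang"].to_numpy()
    event_rel = np.full(n, np.inf)
    death_rel = np.full(n, np.inf)
    pos = {p: i for i, p in enumerate(subj["person_id"])}
    for p, ev, r in zip(oc["person_id"], oc["event"], od):
        if r <= 0:
            continue
        i = pos[p]
        if ev == "death":
            death_rel[i] = min(death_rel[i], r)
        if outcome_kind == "composite" or outcome_kind == ev:
            event_rel[i] = min(event_rel[i], r)

    # per-clone-arm window events: an event on or before the clone's
    # deviation day counts for that clone (the event resolves first)
    we_treated = event_rel <= grace_days
    we_control = (event_rel <= grace_days) & (event_rel <= first_bb)

    bb_censored = (~init_in_grace) & ~we_treated
    bb_censor_day = np.where(bb_censored, float(grace_days), np.nan)
    ctrl_censored = init_in_grace & (first_bb < event_rel)
    ctrl_censor_day = np.where(ctrl_censored, first_bb, np.nan)
    if not (init_in_grace | we_treated).any():
        raise PositivityError(
            f"no clone initiates within the {grace_days}-day grace window; "
            "the initiation arm is empty")
    assert not np.any(bb_censored & (bb_censor_day == 0) & ctrl_censored
                      & (ctrl_censor_day == 0)), \
        "both clones censored at time zero"

    clones = pd.DataFrame({
        "person_id": np.tile(subj["person_id"].to_numpy(), 2),
        "clone_arm": np.repeat([ARM_TREATED, ARM_CONTROL], n),
        "censor_day": np.concatenate([bb_censor_day, ctrl_censor_day]),
        "grace_days": grace_days})

    # window interval: weighted event proportion per clone arm.
    # censoring weights from baseline covariates, fit per clone arm.
    X, names, _ = build_design(subj, covariates)
    r_window = {}
    w_post = {}
    for arm_label, censored, wevent in ((ARM_TREATED, bb_censored, we_treated),
                                        (ARM_CONTROL, ctrl_censored, we_control)):
        uncens = 1.0 - censored.astype(float)
        if censored.sum() == 0:
            p_unc = np.ones(n)
        else:
            f = fit_logistic(X, uncens, names=names, ridge=1e-8)
            p_unc = np.clip(f.predict(X), 1e-12, None)
        w = 1.0 / p_unc
        ev_w = np.where(wevent, 1.0, w)  # events complete the window
        num = float(np.sum(ev_w * wevent))
        den = float(np.sum(np.where(wevent, ev_w,
                                    np.where(~censored, w, 0.0))))
        r_window[arm_label] = num / den if den > 0 else 0.0
        w_post[arm_label] = w
    # post-window landmark expansion per clone arm
    est = {}
    for arm_label in (ARM_TREATED, ARM_CONTROL):
        if arm_label == ARM_TREATED:
            mask = init_in_grace & ~we_treated
        else:
            mask = (~init_in_grace) & ~we_control
        sub = subj.loc[mask].copy()
        if len(sub) == 0:
            raise PositivityError(f"no clones survive the grace window "
                                  f"uncensored in arm {arm_label}")
        sub["arm"] = arm_label
        sub["time_zero"] = from_days(ang[mask] + grace_days).to_numpy()
        wvec = pd.Series(w_post[arm_label][mask],
                         index=pd.Index(sub["person_id"], name="person_id"))
        expanded = expand_person_time(sub, bundle.outcomes, None, admin_end,
                                      outcome_kind=outcome_kind,
                                      diagnoses=bundle.diagnoses,
                                      dispensations=bundle.dispensations)
        est[arm_label] = (expanded, wvec)
    both = pd.concat([est[ARM_TREATED][0], est[ARM_CONTROL][0]],
                     ignore_index=True)
    wboth = pd.concat([est[ARM_TREATED][1], est[ARM_CONTROL][1]])
    wrow = pd.Series(wboth.reindex(both["person_id"]).to_numpy(),
                     index=both.index)
    fit = fit_pooled_logistic(both, weights=wrow, spline=spline)
    curve = risk_curves(fit, spline, outcome=outcome_kind,
                        contrast="clone_censor")
    r1_post = curve.risk_at(ARM_TREATED, HORIZON)
    r0_post = curve.risk_at(ARM_CONTROL, HORIZON)
    r1 = 1.0 - (1.0 - r_window[ARM_TREATED]) * (1.0 - r1_post)
    r0 = 1.0 - (1.0 - r_window[ARM_CONTROL]) * (1.0 - r0_post)
    eff = EffectEstimates(outcome=outcome_kind, contrast="clone_censor",
                          estimates={"risk_treated": 100 * r1,
                                     "risk_control": 100 * r0,
                                     "rd": 100 * (r1 - r0),
                                     "rr": (r1 / r0) if r0 > 0 else np.nan,
                                     "window_risk_treated":
                                         100 * r_window[ARM_TREATED],
                                     "window_risk_control":
                                         100 * r_window[ARM_CONTROL]})
    return eff, clones


def pp_gap_variant(bundle, subjects, admin_end, covariates=None,
                   adherence: AdherenceConfig | None = None,
                   gap_days: int = 90,
                   spline: SplineSpec | None = None) -> EffectEstimates:
    """Per-protocol analysis with a tightened refill-gap rule."""
    from .pipeline import pp_analysis
    adherence = adherence or AdherenceConfig()
    variant = replace(adherence, gap_days=gap_days)
    out = pp_analysis(bundle, subjects, admin_end, covariates,
                      adherence=variant, spline=spline)
    out.effects.contrast = f"pp_gap{gap_days}"
    return out.effects


def run_sensitivity_suite(bundle, subjects, run_config) -> SensitivityGrid:
    """All variants plus the main analyses, each with its config delta."""
    from .pipeline import itt_analysis, pp_analysis
    rc = run_config
    admin_end = rc.generator.study_end
    grid = SensitivityGrid(base_hash=rc.generator.config_hash())

    itt = itt_analysis(bundle, subjects, admin_end, rc.covariates,
                       spline=rc.spline)
    grid.add("main_itt", itt.effects, "none")
    pp = pp_analysis(bundle, subjects, admin_end, rc.covariates, rc.adherence,
                     spline=rc.spline)
    grid.add("main_pp", pp.effects, "none")

    adj = covariate_adjusted_analysis(itt.expanded, rc.covariates, rc.spline)
    grid.add("1_covariate_adjusted", adj,
             "outcome-model adjustment instead of IP weights")

    for label, eff, delta in prior_bb_variants(bundle, rc.eligibility,
                                               rc.covariates, admin_end,
                                               rc.spline, rc.imputation):
        grid.add(label, eff, delta)
    for label, eff, delta in missingness_variants(bundle, rc.eligibility,
                                                  rc.covariates, admin_end,
                                                  rc.spline):
        grid.add(label, eff, delta)

    clone_eff, _ = clone_censor_analysis(bundle, rc.eligibility,
                                         grace_days=30,
                                         covariates=rc.covariates,
                                         admin_end=admin_end,
                                         spline=rc.spline,
                                         imputation=rc.imputation)
    grid.add("4_clone_censor", clone_eff,
             "time zero at angiography; 30-day grace; clone-censor weights")

    pp90 = pp_gap_variant(bundle, subjects, admin_end, rc.covariates,
                          rc.adherence, 90, rc.spline)
    grid.add("pp_gap90", pp90, "gap_days=90")
    return grid
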