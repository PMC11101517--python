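"""Eligibility, treatment-strategy assignment and baseline imputation.

Time zero is a landmark at angiography + 30 days for both arms; persons with
a death or new MI inside that window are excluded, and assignment is read off
the dispensation record (first beta-blocker dispensation strictly after
angiography and no later than time zero), falling back on the
beta-blocker-at-discharge record when no dispensation exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (ARM_TREATED, ARM_CONTROL, BB_CLASSES, AlignmentError,
                   ConfigurationError, ImputationError, to_days, from_days)

__all__ = ["EligibilityConfig", "FlowchartCounts", "apply_eligibility",
           "assign_arm", "impute_baseline"]

DEFAULT_CONTRAINDICATIONS = frozenset({"bradycardia", "av_block_2_3",
                                       "hypotension", "syncope", "asthma",
                                       "copd", "stroke"})
DEFAULT_INDICATIONS = frozenset({"chronic_heart_failure",
                                 "atrial_flicker_flutter"})
DEFAULT_COMPLIANCE = frozenset({"psychiatric_disorder", "dementia"})


@dataclass
class EligibilityConfig:
    assignment_window_days: int = 30
    lookback_years: int = 3
    contraindication_codes: frozenset = DEFAULT_CONTRAINDICATIONS
    indication_codes: frozenset = DEFAULT_INDICATIONS
    compliance_exclusion_codes: frozenset = DEFAULT_COMPLIANCE
    vital_thresholds: dict = field(default_factory=lambda: {
        "heart_rate": 120.0, "sbp": 180.0, "dbp": 120.0})
    require_statin_antithrombotic: bool = True
    exclude_prior_bb: bool = True
    prior_bb_source: str = "both"  # "both" | "admission_record_only"
    # the clone-censor analysis evaluates eligibility at angiography and must
    # not condition on what happens during the assignment window
    exclude_window_events: bool = True

    def __post_init__(self):
        if self.assignment_window_days < 1:
            raise ConfigurationError("assignment_window_days must be >= 1")
        if self.lookback_years < 1:
            raise ConfigurationError("lookback_years must be >= 1")
        if self.prior_bb_source not in ("both", "admission_record_only"):
            raise ConfigurationError("prior_bb_source must be 'both' or "
                                     "'admission_record_only'")
        for k, v in self.vital_thresholds.items():
            if v <= 0:
                raise ConfigurationError(f"vital threshold {k} must be positive")


@dataclass
class FlowchartCounts:
    steps: list  # ordered (label, n_remaining)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["criterion", "n_remaining"])

    def render(self) -> str:
        lines = []
        for j, (label, n) in enumerate(self.steps):
            pad = "  " * j
            lines.append(f"{pad}{label}: n = {n}")
        return "\n".join(lines)


def _lookback_days(config: EligibilityConfig) -> int:
    return int(round(config.lookback_years * 365.25))


def _persons_with_dx(diagnoses: pd.DataFrame, codes, anchor_days: pd.Series,
                     lookback: int) -> pd.Series:
    """Person ids with a listed diagnosis dated in (anchor - lookback, anchor]."""
    if len(diagnoses) == 0:
        return pd.Series(False, index=anchor_days.index)
    dx = diagnoses[diagnoses["condition_code"].isin(codes)]
    if len(dx) == 0:
        return pd.Series(False, index=anchor_days.index)
    dx = dx.merge(anchor_days.rename("anchor"), left_on="person_id",
                  right_index=True, how="inner")
    d = to_days(dx["date"])
    hit = (d <= dx["anchor"].to_numpy()) & (d > dx["anchor"].to_numpy() - lookback)
    flagged = set(dx.loc[hit, "person_id"])
    return pd.Series(anchor_days.index.isin(flagged), index=anchor_days.index)


def apply_eligibility(bundle, config: EligibilityConfig | None = None):
    """Apply the eligibility criteria in their fixed declared order.

    Returns ``(eligible_person_ids, FlowchartCounts)``.  A missing
    angiography date fails criterion 1 rather than raising.
    """
    config = config or EligibilityConfig()
    persons = bundle.persons
    lookback = _lookback_days(config)
    window = config.assignment_window_days

    steps = [("persons with index hospitalization", len(persons))]
    ok = persons["angiography_date"].notna().to_numpy()
    if "index_hospitalization_date" in persons:
        idx_days = to_days(persons["index_hospitalization_date"])
        ang_days = to_days(persons["angiography_date"].fillna(
            persons["index_hospitalization_date"]))
        ok &= (ang_days >= idx_days) & (ang_days <= idx_days + window)
    cur = persons.loc[ok].set_index("person_id")
    steps.append(("angiography within window of index MI", len(cur)))

    anchor = pd.Series(to_days(cur["angiography_date"]), index=cur.index)

    # (2) contraindications in lookback
    contra = _persons_with_dx(bundle.diagnoses, config.contraindication_codes,
                              anchor, lookback)
    cur = cur.loc[~contra]
    anchor = anchor.loc[cur.index]
    steps.append(("no contraindication in lookback", len(cur)))

    # (3) beta-blocker indication: prior use, vitals, indication diagnoses
    excl = pd.Series(False, index=cur.index)
    if config.exclude_prior_bb:
        excl |= cur["admission_record_prior_bb"].astype(bool)
        if config.prior_bb_source == "both":
            disp = bundle.dispensations
            bb = disp[disp["drug_class"].isin(BB_CLASSES)]
            if len(bb):
                bb = bb.merge(anchor.rename("anchor"), left_on="person_id",
                              right_index=True, how="inner")
                d = to_days(bb["dispense_date"])
                hit = (d <= bb["anchor"].to_numpy()) & (d > bb["anchor"].to_numpy() - lookback)
                prior_ids = set(bb.loc[hit, "person_id"])
                excl |= pd.Series(cur.index.isin(prior_ids), index=cur.index)
    for vital, threshold in config.vital_thresholds.items():
        if vital in cur.columns:
            excl |= cur[vital].to_numpy() >= threshold
    excl |= _persons_with_dx(bundle.diagnoses, config.indication_codes,
                             anchor, lookback)
    cur = cur.loc[~excl]
    anchor = anchor.loc[cur.index]
    steps.append(("no beta-blocker indication", len(cur)))

    # (4) compliance-limiting conditions
    comp = _persons_with_dx(bundle.diagnoses, config.compliance_exclusion_codes,
                            anchor, lookback)
    cur = cur.loc[~comp]
    anchor = anchor.loc[cur.index]
    steps.append(("no compliance-limiting condition", len(cur)))

    # (5) statins AND antithrombotics dispensed by time zero within lookback
    if config.require_statin_antithrombotic:
        disp = bundle.dispensations
        onboth = pd.Series(False, index=cur.index)
        have = {}
        for cls in ("statin", "antithrombotic"):
            sub = disp[disp["drug_class"] == cls]
            if len(sub):
                sub = sub.merge(anchor.rename("anchor"), left_on="person_id",
                                right_index=True, how="inner")
                d = to_days(sub["dispense_date"])
                hit = (d <= sub["anchor"].to_numpy() + window) & \
                      (d > sub["anchor"].to_numpy() - lookback)
                have[cls] = set(sub.loc[hit, "person_id"])
            else:
                have[cls] = set()
        onboth = pd.Series([i in have["statin"] and i in have["antithrombotic"]
                            for i in cur.index], index=cur.index)
        cur = cur.loc[onboth]
        anchor = anchor.loc[cur.index]
    steps.append(("on statins and antithrombotics at baseline", len(cur)))

    # (6) event-free through the assignment window
    outc = bundle.outcomes
    if len(outc) and config.exclude_window_events:
        oc = outc.merge(anchor.rename("anchor"), left_on="person_id",
                        right_index=True, how="inner")
        d = to_days(oc["date"])
        hit = (d > oc["anchor"].to_numpy()) & (d <= oc["anchor"].to_numpy() + window)
        wids = set(oc.loc[hit, "person_id"])
        cur = cur.loc[~cur.index.isin(wids)]
    steps.append(("no death or MI in assignment window", len(cur)))

    return list(cur.index), FlowchartCounts(steps)


def assign_arm(bundle, eligible: list, config: EligibilityConfig | None = None
               ) -> pd.DataFrame:
    """Assign each eligible person to a strategy from dispensation data.

    Returns the subjects table: one row per person with arm, assignment date,
    time zero, baseline covariates and missingness flags.
    """
    config = config or EligibilityConfig()
    window = config.assignment_window_days
    persons = bundle.persons.set_index("person_id").loc[eligible]
    ang = pd.Series(to_days(persons["angiography_date"]), index=persons.index)

    disp = bundle.dispensations
    bb = disp[disp["drug_class"].isin(BB_CLASSES)]
    first_in_window = pd.Series(np.nan, index=persons.index)
    if len(bb):
        bb = bb.merge(ang.rename("anchor"), left_on="person_id",
                      right_index=True, how="inner")
        d = to_days(bb["dispense_date"])
        anchor = bb["anchor"].to_numpy()
        if config.exclude_prior_bb and config.prior_bb_source == "both":
            lookback = _lookback_days(config)
            bad = (d <= anchor) & (d > anchor - lookback)
            if bad.any():
                offenders = sorted(set(bb.loc[bad, "person_id"]))[:5]
                raise AlignmentError(
                    "beta-blocker dispensation on/before angiography for "
                    f"persons marked eligible under exclude_prior_bb: {offenders}")
        inwin = bb.loc[(d > anchor) & (d <= anchor + window)]
        if len(inwin):
            firsts = inwin.groupby("person_id")["dispense_date"].min()
            first_in_window.loc[firsts.index] = to_days(firsts)

    arm = np.where(first_in_window.notna(), ARM_TREATED, ARM_CONTROL)
    assignment_day = first_in_window.copy()
    # fallback: discharge record indicates a beta blocker but no dispensation
    fallback = first_in_window.isna() & persons["bb_at_discharge"].astype(bool)
    # discharge date modeled as angiography + 3 days
    assignment_day.loc[fallback] = ang.loc[fallback] + 3
    arm = np.where(fallback, ARM_TREATED, arm)

    covariate_cols = [c for c in persons.columns
                      if c not in ("index_hospitalization_date",
                                   "angiography_date",
                                   "admission_record_prior_bb",
                                   "bb_at_discharge")]
    subjects = pd.DataFrame({"person_id": persons.index,
                             "arm": arm,
                             "angiography_date": persons["angiography_date"].to_numpy(),
                             "assignment_date": from_days(
                                 assignment_day.fillna(0)).to_numpy(),
                             "time_zero": from_days(ang + window).to_numpy()})
    subjects.loc[assignment_day.isna().to_numpy(), "assignment_date"] = pd.NaT
    for c in covariate_cols:
        subjects[c] = persons[c].to_numpy()
    for c in covariate_cols:
        if pd.api.types.is_float_dtype(subjects[c]):
            subjects[f"missing_{c}"] = subjects[c].isna()
    subjects["admission_record_prior_bb"] = persons["admission_record_prior_bb"].to_numpy()
    return subjects.reset_index(drop=True)


def impute_baseline(subjects: pd.DataFrame, strategy: str = "median",
                    covariates: list[str] | None = None) -> pd.DataFrame:
    """Handle missing baseline covariates.

    ``median``           continuous missings -> cohort median; categorical
                         missings -> a "missing" level.
    ``complete_case``    drop subjects missing any analysis covariate.
    ``missing_category`` continuous covariates binned into quintiles plus a
                         "missing" level (they become categorical).
    """
    if strategy not in ("median", "complete_case", "missing_category"):
        raise ConfigurationError(f"unknown imputation strategy '{strategy}'")
    out = subjects.copy()
    if covariates is None:
        covariates = [c for c in out.columns
                      if c not in ("person_id", "arm", "angiography_date",
                                   "assignment_date", "time_zero",
                                   "admission_record_prior_bb")
                      and not c.startswith("missing_")]
    if strategy == "complete_case":
        mask = np.ones(len(out), dtype=bool)
        for c in covariates:
            if pd.api.types.is_float_dtype(out[c]):
                mask &= out[c].notna().to_numpy()
            else:
                mask &= out[c].notna().to_numpy()
        return out.loc[mask].reset_index(drop=True)

    for c in covariates:
        col = out[c]
        if pd.api.types.is_float_dtype(col):
            miss = col.isna()
            if strategy == "median":
                if miss.all():
                    raise ImputationError(f"all values missing for covariate '{c}'")
                if miss.any():
                    out[c] = col.fillna(col.median())
            else:  # missing_category: quintiles + missing level
                nonmiss = col.dropna()
                if len(nonmiss) == 0:
                    raise ImputationError(f"all values missing for covariate '{c}'")
                qs = np.unique(np.quantile(nonmiss, [0.2, 0.4, 0.6, 0.8]))
                binned = np.digitize(col.to_numpy(dtype=float), qs)
                lab = pd.Series([f"q{b + 1}" for b in binned], index=out.index,
                                dtype=object)
                lab[miss] = "missing"
                out[c] = lab
        else:
            if col.isna().any():
                out[c] = col.astype(object).where(col.notna(), "missing")
    return out
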