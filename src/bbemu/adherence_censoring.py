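"""Dispensation coverage, per-protocol censoring dates, and expansion of the
cohort into the discrete person-interval dataset.

Conventions (all configurable or documented in docs/methods.md):

* a dispensation's intended duration is ``floor(pill_count * pill_dose /
  daily_dose)`` days;
* early refills extend coverage (stockpiling) — a refill's coverage starts at
  ``max(dispense_date, previous_end + 1)``;
* the non-adherence (artificial censoring) date in the treated arm is the
  last covered day before a violating gap plus ``gap_days`` — the first day
  on which the gap criterion is violated;
* a person censored mid-interval contributes only complete intervals (floor
  rule); events always close the interval in which they occur;
* in the MI total-effect expansion, death neither ends follow-up nor counts
  as an event, and artificial censoring is only applied while alive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (MONTH_DAYS, HORIZON, ARM_TREATED, ARM_CONTROL, BB_CLASSES,
                   AlignmentError, ConfigurationError, to_days,
                   complete_intervals, day_to_interval)

__all__ = ["AdherenceConfig", "CoverageSegment", "dispensation_coverage",
           "nonadherence_date", "censoring_dates", "expand_person_time",
           "adherence_proportions", "TIMEVARYING_DRUG_CLASSES"]

TIMEVARYING_DRUG_CLASSES = ("arb", "ace_inhibitor", "ccb", "diuretic",
                            "nitrate", "diabetes_tx")

DEFAULT_NEW_INDICATIONS = frozenset({"hypertension_dx", "angina",
                                     "arrhythmia", "heart_failure"})
DEFAULT_CONTRAINDICATIONS = frozenset({"bradycardia", "av_block_2_3",
                                       "hypotension", "syncope", "asthma",
                                       "copd", "stroke"})


@dataclass
class AdherenceConfig:
    daily_dose_mg: dict = field(default_factory=lambda: {"metoprolol": 100.0,
                                                         "bisoprolol": 5.0})
    gap_days: int = 180
    new_indication_codes: frozenset = DEFAULT_NEW_INDICATIONS
    contraindication_codes: frozenset = DEFAULT_CONTRAINDICATIONS
    stockpiling: bool = True

    def __post_init__(self):
        if self.gap_days < 1:
            raise ConfigurationError("gap_days must be >= 1")
        for k, v in self.daily_dose_mg.items():
            if v <= 0:
                raise ConfigurationError(f"daily dose for {k} must be positive")


@dataclass
class CoverageSegment:
    person_id: object
    start_day: int          # days since epoch
    end_day: int
    source_ids: list


def dispensation_coverage(dispensations: pd.DataFrame,
                          config: AdherenceConfig | None = None
                          ) -> list[CoverageSegment]:
    """Merge one person's beta-blocker dispensations into coverage segments.

    Input rows must be beta-blocker class and date-ordered.  Adjacent or
    overlapping segments are merged; with stockpiling on, an early refill's
    coverage starts the day after the previous segment ends.
    """
    config = config or AdherenceConfig()
    if len(dispensations) == 0:
        return []
    days = to_days(dispensations["dispense_date"])
    if not np.all(np.diff(days) >= 0):
        raise AlignmentError("dispensations must be date-ordered")
    segments: list[CoverageSegment] = []
    for i, row in enumerate(dispensations.itertuples(index=True)):
        cls = row.drug_class
        if cls not in config.daily_dose_mg:
            raise ConfigurationError(f"no daily dose configured for drug '{cls}'")
        dur = int(np.floor(row.pill_count * row.pill_dose_mg
                           / config.daily_dose_mg[cls]))
        if dur < 1:
            continue
        d = int(days[i])
        if segments and config.stockpiling:
            start = max(d, segments[-1].end_day + 1)
        else:
            start = d
        end = start + dur - 1
        if segments and start <= segments[-1].end_day + 1:
            prev = segments[-1]
            prev.end_day = max(prev.end_day, end)
            prev.source_ids.append(row.Index)
        else:
            segments.append(CoverageSegment(person_id=row.person_id,
                                            start_day=start, end_day=end,
                                            source_ids=[row.Index]))
    return segments


def nonadherence_date(arm: str, time_zero_day: int,
                      coverage: list[CoverageSegment],
                      diagnosis_days_by_code: dict[str, np.ndarray],
                      bb_dispense_days: np.ndarray,
                      config: AdherenceConfig) -> float:
    """First day the person deviates from the assigned strategy, or nan.

    Treated arm: the censor date is ``coverage_end + gap_days`` for the first
    refill gap of at least ``gap_days`` (coverage exhaustion counts as an
    infinite gap), unless a contraindication diagnosis occurred on or before
    that coverage end.  Untreated arm: the first beta-blocker dispensation
    strictly after time zero, unless preceded by a new-indication diagnosis.
    """
    if arm == ARM_TREATED:
        contra_days = np.concatenate(
            [diagnosis_days_by_code.get(c, np.empty(0))
             for c in config.contraindication_codes]) \
            if diagnosis_days_by_code else np.empty(0)
        if not coverage:
            # never covered: deviation clock runs from time zero
            return float(time_zero_day + config.gap_days)
        for j, seg in enumerate(coverage):
            nxt = coverage[j + 1].start_day if j + 1 < len(coverage) else None
            gap = np.inf if nxt is None else nxt - seg.end_day - 1
            if gap >= config.gap_days:
                excused = contra_days.size and (contra_days <= seg.end_day).any()
                if not excused:
                    return float(seg.end_day + config.gap_days)
        return np.nan
    elif arm == ARM_CONTROL:
        after = bb_dispense_days[bb_dispense_days > time_zero_day]
        if after.size == 0:
            return np.nan
        first = int(after.min())
        ni_days = np.concatenate(
            [diagnosis_days_by_code.get(c, np.empty(0))
             for c in config.new_indication_codes]) \
            if diagnosis_days_by_code else np.empty(0)
        if ni_days.size and (ni_days <= first).any():
            return np.nan
        return float(first)
    raise ConfigurationError(f"unknown arm '{arm}'")


def censoring_dates(subjects: pd.DataFrame, dispensations: pd.DataFrame,
                    diagnoses: pd.DataFrame,
                    config: AdherenceConfig | None = None) -> pd.Series:
    """Per-protocol deviation day for every subject (nan = always adherent).

    Returns a float Series of days-since-epoch indexed by person_id.
    """
    config = config or AdherenceConfig()
    bb = dispensations[dispensations["drug_class"].isin(BB_CLASSES)].copy()
    bb["_day"] = to_days(bb["dispense_date"])
    bb.sort_values(["person_id", "_day"], inplace=True, kind="mergesort")
    bb_by_person = dict(tuple(bb.groupby("person_id")))

    relevant_codes = set(config.contraindication_codes) | set(config.new_indication_codes)
    dx = diagnoses[diagnoses["condition_code"].isin(relevant_codes)].copy()
    if len(dx):
        dx["_day"] = to_days(dx["date"])
    dx_by_person = dict(tuple(dx.groupby("person_id"))) if len(dx) else {}

    t0 = to_days(subjects["time_zero"])
    out = {}
    for i, row in enumerate(subjects.itertuples(index=False)):
        p = row.person_id
        pdx = dx_by_person.get(p)
        dxd = ({c: g["_day"].to_numpy(dtype=float)
                for c, g in pdx.groupby("condition_code")} if pdx is not None
               else {})
        pbb = bb_by_person.get(p)
        bb_days = pbb["_day"].to_numpy(dtype=float) if pbb is not None else np.empty(0)
        if row.arm == ARM_TREATED:
            cov = dispensation_coverage(pbb if pbb is not None
                                        else bb.iloc[0:0], config)
            out[p] = nonadherence_date(ARM_TREATED, int(t0[i]), cov, dxd,
                                       bb_days, config)
        else:
            out[p] = nonadherence_date(ARM_CONTROL, int(t0[i]), [], dxd,
                                       bb_days, config)
    return pd.Series(out, name="censor_day", dtype=float)


# ---------------------------------------------------------------------------
# person-time expansion
# ---------------------------------------------------------------------------

def expand_person_time(subjects: pd.DataFrame, outcomes: pd.DataFrame,
                       censor_dates: pd.Series | None, admin_end,
                       horizon: int = HORIZON, outcome_kind: str = "composite",
                       total_effect: bool = True,
                       diagnoses: pd.DataFrame | None = None,
                       dispensations: pd.DataFrame | None = None
                       ) -> pd.DataFrame:
    """Expand subjects into the discrete person-interval dataset.

    One row per person-interval with event indicators, adherence state,
    artificial-censoring flag and time-varying covariates.  ``censor_dates``
    (days-since-epoch Series indexed by person_id) enables the per-protocol
    truncation; pass None for intention-to-treat.
    """
    if outcome_kind not in ("composite", "death", "mi"):
        raise ConfigurationError(f"unknown outcome_kind '{outcome_kind}'")
    n = len(subjects)
    pid = subjects["person_id"].to_numpy()
    t0 = to_days(subjects["time_zero"])
    admin_day = int(to_days([admin_end])[0])

    BIG = 10 ** 9
    death_day = np.full(n, BIG, dtype=float)
    mi_day = np.full(n, BIG, dtype=float)
    if len(outcomes):
        oc = outcomes.merge(pd.DataFrame({"person_id": pid, "_t0": t0}),
                            on="person_id", how="inner")
        od = to_days(oc["date"])
        rel = od - oc["_t0"].to_numpy()
        pos = {p: k for k, p in enumerate(pid)}
        for p, ev, r, d in zip(oc["person_id"], oc["event"], rel, od):
            if r < 0:
                raise AlignmentError(
                    f"outcome before time zero for person {p}; window events "
                    "should have been excluded upstream")
            if d > admin_day:
                continue
            k = pos[p]
            if ev == "death":
                death_day[k] = min(death_day[k], r)
            elif ev == "mi":
                mi_day[k] = min(mi_day[k], r)

    comp_day = np.minimum(death_day, mi_day)
    if outcome_kind == "composite":
        event_day = comp_day
    elif outcome_kind == "death":
        event_day = death_day
    else:
        event_day = mi_day

    censor_rel = np.full(n, np.inf)
    if censor_dates is not None:
        cvals = censor_dates.reindex(pid).to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            censor_rel = np.where(np.isnan(cvals), np.inf, cvals - t0)
        censor_rel = np.maximum(censor_rel, 0.0)
        # artificial censoring applies only while alive
        censor_rel = np.where(death_day < censor_rel, np.inf, censor_rel)

    admin_rel = np.maximum(admin_day - t0, 0).astype(float)

    # number of complete intervals available absent the event
    n_cens = np.minimum(complete_intervals(np.minimum(censor_rel, 1e15)),
                        horizon)
    n_admin = np.minimum(complete_intervals(admin_rel), horizon)
    n_nonevent = np.minimum(n_cens, n_admin)

    ev_t = day_to_interval(np.minimum(event_day, 1e15))
    # for the MI total effect, death does not end follow-up
    if outcome_kind == "mi" and total_effect:
        stop_nonevent = n_nonevent
    elif outcome_kind == "mi" and not total_effect:
        d_t = day_to_interval(np.minimum(death_day, 1e15))
        stop_nonevent = np.minimum(n_nonevent, np.maximum(d_t - 1, 0))
    elif outcome_kind == "death":
        stop_nonevent = n_nonevent
    else:
        stop_nonevent = n_nonevent

    # event counts if its day precedes every censoring day and its interval
    # is within the horizon
    event_happens = ((event_day <= np.minimum(censor_rel, admin_rel))
                     & (ev_t <= horizon))
    n_int = np.where(event_happens, ev_t, stop_nonevent).astype(int)
    cens_flag_at = np.where((~event_happens)
                            & (censor_rel <= admin_rel)
                            & np.isfinite(censor_rel)
                            & (n_int == n_cens) & (n_int >= 1)
                            & (n_int < horizon),
                            n_int, 0)

    keep = n_int >= 1
    reps = n_int[keep]
    row_pid = np.repeat(pid[keep], reps)
    row_t = np.concatenate([np.arange(1, m + 1) for m in reps]) \
        if keep.any() else np.empty(0, dtype=int)
    row_last = np.concatenate([np.arange(1, m + 1) == m for m in reps]) \
        if keep.any() else np.empty(0, dtype=bool)

    def _per_row(values):
        return np.repeat(values[keep], reps)

    df = pd.DataFrame({"person_id": row_pid, "t": row_t})
    df["arm"] = _per_row(subjects["arm"].to_numpy())
    ev_row = row_last & _per_row(event_happens)
    d_t_all = day_to_interval(np.minimum(death_day, 1e15))
    m_t_all = day_to_interval(np.minimum(mi_day, 1e15))
    df["event_death"] = (row_t == _per_row(d_t_all)).astype(np.int8)
    df["event_mi"] = (row_t == _per_row(m_t_all)).astype(np.int8)
    df["event_composite"] = (row_t == _per_row(day_to_interval(
        np.minimum(comp_day, 1e15)))).astype(np.int8)
    df["event"] = ev_row.astype(np.int8)
    df["artificially_censored"] = (row_t == _per_row(cens_flag_at)).astype(np.int8)

    adherent_through = np.where(np.isfinite(censor_rel),
                                complete_intervals(np.minimum(censor_rel, 1e15)),
                                horizon + 1)
    df["adherent"] = (row_t <= _per_row(adherent_through)).astype(np.int8)

    # time-varying covariates
    row_t0 = _per_row(t0)
    if diagnoses is not None and len(diagnoses):
        renal = diagnoses[diagnoses["condition_code"] == "renal_disease"]
        first_renal = renal.groupby("person_id")["date"].min()
        fr = pd.Series(to_days(first_renal), index=first_renal.index) \
            if len(first_renal) else pd.Series(dtype=float)
        fr_rel = fr.reindex(pid).to_numpy(dtype=float) - t0
        fr_safe = np.nan_to_num(fr_rel, nan=1e15)
        onset_t = np.where(np.isnan(fr_rel), BIG,
                           np.where(fr_rel <= 0, 0,
                                    day_to_interval(np.maximum(fr_safe, 0))))
        df["renal_disease"] = (row_t >= _per_row(onset_t)).astype(np.int8) \
            if keep.any() else np.int8(0)
        df.loc[_per_row(onset_t) == 0, "renal_disease"] = 1
    else:
        df["renal_disease"] = np.int8(0)

    if dispensations is not None and len(dispensations):
        dsp = dispensations[dispensations["drug_class"]
                            .isin(TIMEVARYING_DRUG_CLASSES)].copy()
        if len(dsp):
            dsp = dsp.merge(pd.DataFrame({"person_id": pid, "_t0": t0}),
                            on="person_id", how="inner")
            rel = to_days(dsp["dispense_date"]) - dsp["_t0"].to_numpy()
            dsp["_t"] = day_to_interval(np.maximum(rel, 0))
            dsp = dsp[(rel > 0)]
            # integer-encode (person, interval) pairs for fast membership
            codes, _ = pd.factorize(np.concatenate([df["person_id"].to_numpy(),
                                                    dsp["person_id"].to_numpy()]))
            row_code = codes[:len(df)].astype(np.int64) * (HORIZON + 2) + row_t
            dsp_code = (codes[len(df):].astype(np.int64) * (HORIZON + 2)
                        + dsp["_t"].to_numpy())
            for cls in TIMEVARYING_DRUG_CLASSES:
                sub_code = dsp_code[(dsp["drug_class"] == cls).to_numpy()]
                df[cls] = np.isin(row_code, sub_code).astype(np.int8)
        else:
            for cls in TIMEVARYING_DRUG_CLASSES:
                df[cls] = np.int8(0)
    else:
        for cls in TIMEVARYING_DRUG_CLASSES:
            df[cls] = np.int8(0)

    # carry baseline covariates forward
    base_cols = [c for c in subjects.columns
                 if c not in ("person_id", "arm", "angiography_date",
                              "assignment_date", "time_zero")
                 and not c.startswith("missing_")]
    for c in base_cols:
        df[c] = _per_row(subjects[c].to_numpy())
    return df


def adherence_proportions(subjects: pd.DataFrame,
                          person_intervals: pd.DataFrame) -> dict[str, float]:
    """Fraction of each arm never artificially censored during follow-up."""
    cens = person_intervals.loc[person_intervals["artificially_censored"] == 1,
                                "person_id"].unique()
    out = {}
    for arm in (ARM_TREATED, ARM_CONTROL):
        ids = subjects.loc[subjects["arm"] == arm, "person_id"]
        if len(ids) == 0:
            out[arm] = np.nan
        else:
            out[arm] = 1.0 - np.isin(ids.to_numpy(), cens).mean()
    return out
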