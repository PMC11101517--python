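"""Coverage arithmetic, censoring rules with overrides, person-time
expansion conventions."""

import numpy as np
import pandas as pd
import pytest

import bbemu
from bbemu.adherence_censoring import (AdherenceConfig, dispensation_coverage,
                                       nonadherence_date, censoring_dates,
                                       expand_person_time)
from bbemu.core import to_days, MONTH_DAYS
from conftest import make_bundle, clean_person, D


def _disp(days_counts, drug="metoprolol", dose=100.0, pid=1, origin="2012-01-01"):
    rows = [(pid, drug, D(origin) + pd.Timedelta(days=d), c, dose)
            for d, c in days_counts]
    df = pd.DataFrame(rows, columns=["person_id", "drug_class",
                                     "dispense_date", "pill_count",
                                     "pill_dose_mg"])
    return df


@pytest.mark.parametrize("drug,count,dose,expected_days", [
    ("metoprolol", 100, 50.0, 50),   # 100 * 50 / 100
    ("metoprolol", 100, 100.0, 100),
    ("bisoprolol", 30, 5.0, 30),     # 30 * 5 / 5
    ("bisoprolol", 100, 5.0, 100),
])
def test_dispensation_duration_formula(drug, count, dose, expected_days):
    segs = dispensation_coverage(_disp([(0, count)], drug=drug, dose=dose))
    assert len(segs) == 1
    assert segs[0].end_day - segs[0].start_day + 1 == expected_days


def test_stockpiling_merges_early_refills():
    # two 50-day dispensations on days 0 and 20 -> single segment days 0-99
    segs = dispensation_coverage(_disp([(0, 100), (20, 100)], dose=50.0))
    assert len(segs) == 1
    origin = to_days([D("2012-01-01")])[0]
    assert segs[0].start_day == origin
    assert segs[0].end_day == origin + 99


def test_refill_reset_mode_does_not_stockpile():
    cfg = AdherenceConfig(stockpiling=False)
    segs = dispensation_coverage(_disp([(0, 100), (20, 100)], dose=50.0), cfg)
    assert len(segs) == 1           # overlapping, still merged
    origin = to_days([D("2012-01-01")])[0]
    assert segs[0].end_day == origin + 20 + 49   # resets from dispense date


def test_coverage_conservation():
    disp = _disp([(0, 100), (70, 90), (300, 100)], dose=100.0)
    segs = dispensation_coverage(disp)
    covered = sum(s.end_day - s.start_day + 1 for s in segs)
    dispensed = int(np.floor(disp["pill_count"] * disp["pill_dose_mg"] / 100.0).sum())
    assert covered <= dispensed
    assert covered == dispensed  # nothing runs past any boundary here


# ---------------------------------------------------------------------------
# non-adherence dates
# ---------------------------------------------------------------------------

def _t0_day():
    return int(to_days([D("2012-01-31")])[0])


def test_gap_under_180_is_continuous():
    # coverage ends day 200, next dispensation day 370: gap 169 < 180, so the
    # only censoring comes from terminal exhaustion (day 469 + 180), not the gap
    disp = _disp([(0, 100), (101, 100), (370, 100)])
    segs = dispensation_coverage(disp)
    d = nonadherence_date(bbemu.ARM_TREATED, _t0_day(), segs, {},
                          np.array([]), AdherenceConfig())
    origin = to_days([D("2012-01-01")])[0]
    assert d == origin + 469 + 180


def test_coverage_exhaustion_censors_at_end_plus_gap():
    disp = _disp([(0, 100), (101, 100)])  # coverage days 0..200
    segs = dispensation_coverage(disp)
    d = nonadherence_date(bbemu.ARM_TREATED, _t0_day(), segs, {},
                          np.array([]), AdherenceConfig())
    origin = to_days([D("2012-01-01")])[0]
    assert d == origin + 200 + 180


def test_contraindication_before_gap_suppresses_censoring():
    disp = _disp([(0, 100), (101, 100)])
    segs = dispensation_coverage(disp)
    origin = to_days([D("2012-01-01")])[0]
    dx = {"stroke": np.array([origin + 150], dtype=float)}
    d = nonadherence_date(bbemu.ARM_TREATED, _t0_day(), segs, dx,
                          np.array([]), AdherenceConfig())
    assert np.isnan(d)


def test_control_arm_crossover_censors_unless_new_indication():
    t0 = _t0_day()
    bb_days = np.array([t0 + 400], dtype=float)
    d = nonadherence_date(bbemu.ARM_CONTROL, t0, [], {}, bb_days,
                          AdherenceConfig())
    assert d == t0 + 400
    dx = {"heart_failure": np.array([t0 + 380], dtype=float)}
    d2 = nonadherence_date(bbemu.ARM_CONTROL, t0, [], dx, bb_days,
                           AdherenceConfig())
    assert np.isnan(d2)


def test_gap_monotonicity_90_never_later_than_180(small_cohort):
    cfg, bundle, subjects, _ = small_cohort
    c180 = censoring_dates(subjects, bundle.dispensations, bundle.diagnoses,
                           AdherenceConfig(gap_days=180))
    c90 = censoring_dates(subjects, bundle.dispensations, bundle.diagnoses,
                          AdherenceConfig(gap_days=90))
    both = pd.concat([c180.rename("d180"), c90.rename("d90")], axis=1)
    m = both["d180"].notna()
    assert both.loc[m, "d90"].notna().all()
    assert (both.loc[m, "d90"] <= both.loc[m, "d180"]).all()


# ---------------------------------------------------------------------------
# person-time expansion
# ---------------------------------------------------------------------------

def _one_subject(arm=bbemu.ARM_TREATED):
    return pd.DataFrame({"person_id": [1], "arm": [arm],
                         "angiography_date": [D("2012-01-01")],
                         "assignment_date": [D("2012-01-05")],
                         "time_zero": [D("2012-01-31")]})


def _outcomes(rows):
    df = pd.DataFrame(rows, columns=["person_id", "event", "date"])
    df["date"] = pd.to_datetime(df["date"])
    return df


ADMIN = "2030-12-31"


def test_event_day70_falls_in_third_interval():
    out = _outcomes([(1, "mi", D("2012-01-31") + pd.Timedelta(days=70))])
    exp = expand_person_time(_one_subject(), out, None, ADMIN,
                             outcome_kind="composite")
    assert list(exp["t"]) == [1, 2, 3]
    assert list(exp["event"]) == [0, 0, 1]


def test_total_effect_keeps_person_after_death():
    out = _outcomes([(1, "death", D("2012-01-31") + pd.Timedelta(days=100))])
    exp = expand_person_time(_one_subject(), out, None, ADMIN,
                             outcome_kind="mi", total_effect=True)
    assert len(exp) == 60
    assert exp["event"].sum() == 0


def test_mi_without_total_effect_truncates_at_death():
    out = _outcomes([(1, "death", D("2012-01-31") + pd.Timedelta(days=100))])
    exp = expand_person_time(_one_subject(), out, None, ADMIN,
                             outcome_kind="mi", total_effect=False)
    assert exp["t"].max() <= 4 and exp["event"].sum() == 0


def test_censor_day_380_contributes_12_complete_intervals():
    cd = pd.Series({1: float(to_days([D("2012-01-31")])[0] + 380)})
    exp = expand_person_time(_one_subject(), _outcomes([]), cd, ADMIN,
                             outcome_kind="composite")
    assert list(exp["t"]) == list(range(1, 13))      # 380/30.4375 = 12.48
    assert exp["artificially_censored"].to_list() == [0] * 11 + [1]
    assert exp["event"].sum() == 0


def test_artificial_censoring_only_applies_while_alive():
    out = _outcomes([(1, "death", D("2012-01-31") + pd.Timedelta(days=100))])
    cd = pd.Series({1: float(to_days([D("2012-01-31")])[0] + 380)})
    exp = expand_person_time(_one_subject(), out, cd, ADMIN,
                             outcome_kind="mi", total_effect=True)
    assert len(exp) == 60
    assert exp["artificially_censored"].sum() == 0


def test_event_before_time_zero_is_alignment_error():
    out = _outcomes([(1, "mi", "2012-01-15")])
    with pytest.raises(bbemu.AlignmentError):
        expand_person_time(_one_subject(), out, None, ADMIN)


def test_same_day_death_and_mi_resolution():
    day = D("2012-01-31") + pd.Timedelta(days=70)
    out = _outcomes([(1, "death", day), (1, "mi", day)])
    comp = expand_person_time(_one_subject(), out, None, ADMIN, outcome_kind="composite")
    assert comp["event"].sum() == 1                        # single event
    mi = expand_person_time(_one_subject(), out, None, ADMIN, outcome_kind="mi")
    assert mi.loc[mi["t"] == 3, "event"].iloc[0] == 1      # counts as MI
    de = expand_person_time(_one_subject(), out, None, ADMIN, outcome_kind="death")
    assert de.loc[de["t"] == 3, "event"].iloc[0] == 1      # and as death


def test_itt_expansion_invariant_to_post_t0_dispensations(small_cohort):
    cfg, bundle, subjects, _ = small_cohort
    sub = subjects.head(150)
    e1 = expand_person_time(sub, bundle.outcomes, None, cfg.study_end)
    t0 = sub.set_index("person_id")["time_zero"]
    disp = bundle.dispensations.merge(t0.rename("t0"), left_on="person_id",
                                      right_index=True, how="left")
    pre_only = bundle.dispensations[~(disp["dispense_date"] > disp["t0"]).fillna(False)]
    b2 = bbemu.RegistryBundle(persons=bundle.persons, dispensations=pre_only,
                              diagnoses=bundle.diagnoses,
                              outcomes=bundle.outcomes)
    e2 = expand_person_time(sub, b2.outcomes, None, cfg.study_end)
    pd.testing.assert_frame_equal(e1, e2)


def test_interval_count_is_min_of_event_censor_admin_horizon(small_cohort):
    cfg, bundle, subjects, _ = small_cohort
    cd = censoring_dates(subjects, bundle.dispensations, bundle.diagnoses)
    exp = expand_person_time(subjects, bundle.outcomes, cd, cfg.study_end)
    t0 = to_days(subjects.set_index("person_id")["time_zero"])
    admin = to_days([cfg.study_end])[0]
    n_by_person = exp.groupby("person_id")["t"].max()
    pids = subjects["person_id"].to_numpy()
    adm_n = np.floor((admin - t0) / MONTH_DAYS).astype(int)
    for p, nadm in list(zip(pids, adm_n))[:300]:
        got = n_by_person.get(p, 0)
        assert got <= min(nadm, 60)
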