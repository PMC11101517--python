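"""Shared fixtures: hand-built registry bundles and the simulation scenarios
used by the statistical acceptance checks (fixed study conditions)."""

import numpy as np
import pandas as pd
import pytest

import bbemu
from bbemu.synthetic_registry import (OutcomeModel, AdherenceModel,
                                      RegistryBundle)

D = pd.Timestamp  # shorthand for dates


# ---------------------------------------------------------------------------
# hand-built bundle machinery
# ---------------------------------------------------------------------------

def make_bundle(persons_rows, disp_rows=(), diag_rows=(), out_rows=()):
    """Assemble a RegistryBundle from plain tuples.

    persons: (person_id, index_date, angio_date, covariate dict,
              admission_prior_bb, bb_at_discharge)
    """
    precs = []
    base_cov = {"age": 60.0, "female": 0.0, "smoking": "never",
                "hypertension": 0.0, "diabetes": 0.0, "prev_mi": 0.0,
                "prev_hf": 0.0, "nstemi": 1.0, "heart_rate": 70.0,
                "sbp": 140.0, "ldl": 3.0, "creatinine": 80.0}
    for pid, idx, ang, cov, prior, discharge in persons_rows:
        row = {"person_id": pid, "index_hospitalization_date": D(idx),
               "angiography_date": (D(ang) if ang is not None else pd.NaT),
               **base_cov, **(cov or {}),
               "admission_record_prior_bb": prior,
               "bb_at_discharge": discharge}
        precs.append(row)
    persons = pd.DataFrame(precs)
    disp = pd.DataFrame(list(disp_rows), columns=["person_id", "drug_class",
                                                  "dispense_date",
                                                  "pill_count",
                                                  "pill_dose_mg"])
    if len(disp):
        disp["dispense_date"] = pd.to_datetime(disp["dispense_date"])
    diag = pd.DataFrame(list(diag_rows), columns=["person_id",
                                                  "condition_code", "date",
                                                  "source"])
    if len(diag):
        diag["date"] = pd.to_datetime(diag["date"])
    outc = pd.DataFrame(list(out_rows), columns=["person_id", "event", "date"])
    if len(outc):
        outc["date"] = pd.to_datetime(outc["date"])
    return RegistryBundle(persons=persons, dispensations=disp, diagnoses=diag,
                          outcomes=outc)


def clean_person(pid, ang="2012-01-10", with_statins=True):
    """A person passing every eligibility criterion, plus their statin and
    antithrombotic dispensations."""
    persons = [(pid, ang, ang, None, False, False)]
    disp = []
    if with_statins:
        a = D(ang)
        disp = [(pid, "statin", a - pd.Timedelta(days=30), 100, 20.0),
                (pid, "antithrombotic", a - pd.Timedelta(days=30), 100, 75.0)]
    return persons, disp


# ---------------------------------------------------------------------------
# scenario configurations (fixed study conditions)
# ---------------------------------------------------------------------------

def confounded_null_config(n=20_000, seed=42):
    """Strong baseline confounding, exactly null treatment effect."""
    events = {
        "death": OutcomeModel(-7.1, {"age": 0.8, "diabetes": 0.5,
                                     "prev_mi": 0.8, "heart_rate": -0.5,
                                     "creatinine": 0.3, "renal_tv": 0.8},
                              treatment_logor=0.0),
        "mi": OutcomeModel(-7.1, {"age": 0.6, "diabetes": 0.4, "prev_mi": 0.8,
                                  "heart_rate": -0.3, "ldl": 0.2,
                                  "renal_tv": 0.4}, treatment_logor=0.0),
    }
    return bbemu.default_config(
        n_persons=n, seed=seed,
        assignment_model=OutcomeModel(1.0, {"age": -0.8, "diabetes": -0.6,
                                            "prev_mi": -1.0,
                                            "heart_rate": 0.5,
                                            "smoking": {"current": 0.4}}),
        event_model=events)


def effect_recovery_config(n=50_000, seed=7):
    """Balanced arms, moderate confounding, known protective effects."""
    events = {
        "death": OutcomeModel(-7.1, {"age": 0.6, "diabetes": 0.35,
                                     "prev_mi": 0.4, "creatinine": 0.25,
                                     "renal_tv": 0.8},
                              treatment_logor=float(np.log(0.80))),
        "mi": OutcomeModel(-7.1, {"age": 0.25, "diabetes": 0.3, "prev_mi": 0.5,
                                  "ldl": 0.2, "renal_tv": 0.4},
                           treatment_logor=float(np.log(0.70))),
    }
    return bbemu.default_config(
        n_persons=n, seed=seed,
        assignment_model=OutcomeModel(0.0, {"age": -0.5, "heart_rate": 0.5,
                                            "prev_mi": -0.5,
                                            "diabetes": -0.4}),
        event_model=events)


def informative_censoring_config(n=20_000, seed=31):
    """Per-protocol censoring driven by measured renal-disease onset, which
    also raises the event hazards; no baseline confounding."""
    events = {
        "death": OutcomeModel(-7.1, {"age": 0.4, "renal_tv": 1.5},
                              treatment_logor=float(np.log(0.85))),
        "mi": OutcomeModel(-7.1, {"age": 0.3, "renal_tv": 1.5},
                           treatment_logor=float(np.log(0.75))),
    }
    adh = AdherenceModel(
        discontinuation=OutcomeModel(-6.0, {"renal_tv": 3.5}),
        crossover=OutcomeModel(-6.5, {}),
        long_gap_prob=0.0,
        contra_before_discontinuation_prob=0.0,
        new_indication_before_crossover_prob=0.0)
    return bbemu.default_config(
        n_persons=n, seed=seed,
        assignment_model=OutcomeModel(1.0, {}),
        event_model=events, adherence_model=adh,
        renal_onset_rate=0.012, renal_baseline_rate=0.0,
        contraindication_rate=0.0, new_indication_rate=0.0)


def clone_agreement_config(n=6000, seed=55, window_event_rate=0.0):
    """No misalignment: everyone on statins/antithrombotics, no window
    events, no discharge-record-only assignment, no prior users."""
    return bbemu.default_config(
        n_persons=n, seed=seed,
        statin_antithrombotic_fraction=1.0,
        window_event_rate=window_event_rate,
        missing_angiography_rate=0.0, prior_bb_fraction=0.0,
        bb_discharge_only_fraction=0.0)


def coverage_config(n=2000, seed=100):
    """Coverage-simulation conditions: balanced arms, moderate confounding,
    default effect sizes."""
    return bbemu.default_config(
        n_persons=n, seed=seed,
        assignment_model=OutcomeModel(0.0, {"age": -0.5, "heart_rate": 0.5,
                                            "prev_mi": -0.5}))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_registry():
    cfg = bbemu.default_config(n_persons=2000, seed=1)
    bundle = bbemu.inject_missingness(bbemu.generate_registry(cfg), cfg)
    return cfg, bundle


@pytest.fixture(scope="session")
def small_cohort(small_registry):
    cfg, bundle = small_registry
    subjects, flowchart = bbemu.prepare_cohort(bundle)
    return cfg, bundle, subjects, flowchart


@pytest.fixture(scope="session")
def km_fixture():
    """200-person cohort with its ITT person-interval expansion."""
    cfg = bbemu.default_config(n_persons=400, seed=12)
    bundle = bbemu.inject_missingness(bbemu.generate_registry(cfg), cfg)
    subjects, _ = bbemu.prepare_cohort(bundle)
    subjects = subjects.head(200).reset_index(drop=True)
    expanded = bbemu.expand_person_time(subjects, bundle.outcomes, None,
                                        cfg.study_end)
    return subjects, expanded
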