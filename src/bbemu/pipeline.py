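"""End-to-end orchestration: simulate -> build cohort -> expand -> weight ->
fit -> bootstrap -> sensitivity -> report.

The intention-to-treat and per-protocol runners here are also the building
blocks the sensitivity suite re-runs under config deltas.  Bootstrap
replicates resample persons, re-estimate every weight model inside the
replicate, and reuse pre-expanded person-interval blocks so a replicate costs
milliseconds for the weighted ITT analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (HORIZON, ARM_TREATED, ARM_CONTROL, ConfigurationError,
                   EstimationError, build_design, fit_logistic, expit,
                   to_days, spawn_rngs)
from . import synthetic_registry as sr
from .cohort_builder import (EligibilityConfig, apply_eligibility, assign_arm,
                             impute_baseline)
from .adherence_censoring import (AdherenceConfig, censoring_dates,
                                  expand_person_time, adherence_proportions,
                                  TIMEVARYING_DRUG_CLASSES)
from .weighting import (baseline_ip_weights, censoring_ip_weights,
                        truncate_weights, balance_table, WeightSet,
                        CENSOR_RIDGE)
from .outcome_models import (SplineSpec, rcs_basis, fit_pooled_logistic,
                             risk_curves, effect_estimates, bootstrap_cis,
                             EffectEstimates, RiskCurve)

log = logging.getLogger("bbemu")

DEFAULT_COVARIATES = ["age", "female", "smoking", "hypertension", "diabetes",
                      "prev_mi", "prev_hf", "nstemi", "heart_rate", "sbp",
                      "ldl", "creatinine"]
TIMEVARYING_COVARIATES = ["renal_disease", *TIMEVARYING_DRUG_CLASSES]
OUTCOME_KINDS = ("composite", "death", "mi")


@dataclass
class RunConfig:
    generator: sr.GeneratorConfig = field(default_factory=sr.GeneratorConfig)
    registry_dir: str | None = None          # read instead of simulating
    eligibility: EligibilityConfig = field(default_factory=EligibilityConfig)
    adherence: AdherenceConfig = field(default_factory=AdherenceConfig)
    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    imputation: str = "median"
    spline: SplineSpec = field(default_factory=SplineSpec)
    truncation_percentile: float | None = None
    n_boot: int = 500
    pp_n_boot: int | None = None             # default: same as n_boot
    outcomes: tuple = OUTCOME_KINDS
    sensitivity: bool = True
    oracle_n: int = 0                        # >0: add a recovery panel
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        if "generator" in raw:
            kw["generator"] = sr.GeneratorConfig.from_dict(raw.pop("generator"))
        if "eligibility" in raw:
            e = raw.pop("eligibility")
            for k in ("contraindication_codes", "indication_codes",
                      "compliance_exclusion_codes"):
                if k in e:
                    e[k] = frozenset(e[k])
            kw["eligibility"] = EligibilityConfig(**e)
        if "adherence" in raw:
            a = raw.pop("adherence")
            for k in ("new_indication_codes", "contraindication_codes"):
                if k in a:
                    a[k] = frozenset(a[k])
            kw["adherence"] = AdherenceConfig(**a)
        if "spline" in raw:
            kw["spline"] = SplineSpec(knots=tuple(raw.pop("spline")["knots"]))
        kw.update(raw)
        return cls(**kw)


# ---------------------------------------------------------------------------
# cohort preparation
# ---------------------------------------------------------------------------

def prepare_cohort(bundle, eligibility: EligibilityConfig | None = None,
                   imputation: str = "median"):
    """Eligibility -> assignment -> imputation. Returns (subjects, flowchart)."""
    eligibility = eligibility or EligibilityConfig()
    eligible, flowchart = apply_eligibility(bundle, eligibility)
    subjects = assign_arm(bundle, eligible, eligibility)
    subjects = impute_baseline(subjects, imputation)
    log.info("cohort: %d eligible (%s treated)", len(subjects),
             int((subjects["arm"] == ARM_TREATED).sum()))
    return subjects, flowchart


# ---------------------------------------------------------------------------
# fast bootstrap machinery
# ---------------------------------------------------------------------------

class _BlockTable:
    """Person-blocked view of an expanded person-interval table.

    Stores per-person contiguous row ranges plus the numeric columns needed
    to refit models after resampling persons, without touching pandas in the
    replicate loop.
    """

    def __init__(self, subjects: pd.DataFrame, expanded: pd.DataFrame,
                 extra_arrays: dict | None = None):
        pid = subjects["person_id"].to_numpy()
        pos = {p: i for i, p in enumerate(pid)}
        rows_pos = expanded["person_id"].map(pos).to_numpy()
        # rows are emitted in subjects order and contiguous per person
        lens = np.bincount(rows_pos, minlength=len(pid))
        starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
        self.starts, self.lens = starts, lens
        self.t = expanded["t"].to_numpy(dtype=np.int64)
        self.event = expanded["event"].to_numpy(dtype=float)
        self.arm1 = (subjects["arm"] == ARM_TREATED).to_numpy(dtype=float)
        self.n_persons = len(pid)
        self.extra = extra_arrays or {}

    def gather(self, idx: np.ndarray):
        sel_starts = self.starts[idx]
        sel_len = self.lens[idx]
        total = int(sel_len.sum())
        if total == 0:
            return (np.empty(0, dtype=np.int64),) * 2 + (np.empty(0),)
        starts_rep = np.repeat(sel_starts, sel_len)
        offs = np.cumsum(sel_len)
        within = np.arange(total) - np.repeat(offs - sel_len, sel_len)
        rows = starts_rep + within
        boot_pid = np.repeat(np.arange(len(idx)), sel_len)
        return rows, boot_pid, sel_len


def _stabilized_itw(Xw: np.ndarray, a: np.ndarray) -> np.ndarray:
    if a.sum() == 0 or a.sum() == len(a):
        raise EstimationError("an arm is empty in this replicate")
    fit = fit_logistic(Xw, a)
    p1 = fit.predict(Xw)
    marg = a.mean()
    pa = np.where(a == 1, p1, 1 - p1)
    return np.where(a == 1, marg, 1 - marg) / np.clip(pa, 1e-12, None)


class _CellModel:
    """Pre-built design matrices on the (arm, t) cell grid."""

    def __init__(self, spline: SplineSpec, horizon: int = HORIZON):
        self.horizon = horizon
        self.spline = spline
        t = np.tile(np.arange(1, horizon + 1, dtype=float), 2)
        a = np.repeat([0.0, 1.0], horizon)
        tb = rcs_basis(t, spline)
        self.cell_arm, self.cell_t = a, t
        self.X_int = np.column_stack([np.ones(len(t)), a, tb, a[:, None] * tb])
        self.X_noint = np.column_stack([np.ones(len(t)), a, tb])
        g1 = rcs_basis(np.arange(1, horizon + 1, dtype=float), spline)
        self.Xpred1 = np.column_stack([np.ones(horizon), np.ones(horizon), g1, g1])
        self.Xpred0 = np.column_stack([np.ones(horizon), np.zeros(horizon), g1,
                                       np.zeros_like(g1)])

    def aggregate(self, arm_row, t_row, y, w):
        key = (arm_row * (self.horizon + 1) + t_row).astype(np.int64)
        size = 2 * (self.horizon + 1)
        ev = np.bincount(key, weights=w * y, minlength=size)
        tot = np.bincount(key, weights=w, minlength=size)
        cell_key = (self.cell_arm * (self.horizon + 1) + self.cell_t).astype(np.int64)
        return ev[cell_key], tot[cell_key]

    def fit_risks(self, ev, tot):
        m = tot > 0
        fit = fit_logistic(self.X_int[m], ev[m] / tot[m], weights=tot[m],
                           names=[f"c{j}" for j in range(self.X_int.shape[1])])
        h1 = expit(self.Xpred1 @ fit.params)
        h0 = expit(self.Xpred0 @ fit.params)
        return 1 - np.cumprod(1 - h1), 1 - np.cumprod(1 - h0)

    def fit_hr(self, ev, tot, horizon: int):
        m = (tot > 0) & (self.cell_t <= horizon)
        fit = fit_logistic(self.X_noint[m], ev[m] / tot[m], weights=tot[m],
                           names=["intercept", "arm"]
                           + [f"t{j}" for j in range(self.X_noint.shape[1] - 2)])
        return float(np.exp(fit.params[1]))


def _itt_estimates_from_replicate(prep: _BlockTable, cells: _CellModel,
                                  Xw: np.ndarray, idx: np.ndarray,
                                  weighted: bool, hr_horizons=(36, 48, 60),
                                  curve_risks: bool = False) -> dict:
    a = prep.arm1[idx]
    sw = _stabilized_itw(Xw[idx], a) if weighted else np.ones(len(idx))
    rows, boot_pid, _ = prep.gather(idx)
    w_row = sw[boot_pid]
    arm_row = a[boot_pid]
    ev, tot = cells.aggregate(arm_row, prep.t[rows], prep.event[rows], w_row)
    r1, r0 = cells.fit_risks(ev, tot)
    out = {"risk_treated": 100 * r1[-1], "risk_control": 100 * r0[-1],
           "rd": 100 * (r1[-1] - r0[-1]),
           "rr": r1[-1] / r0[-1] if r0[-1] > 0 else np.nan}
    for h in hr_horizons:
        out[f"hr_{h}m"] = cells.fit_hr(ev, tot, h)
    if curve_risks:
        for t in range(1, cells.horizon + 1):
            out[f"curve_treated_{t}"] = 100 * r1[t - 1]
            out[f"curve_control_{t}"] = 100 * r0[t - 1]
    return out


# ---------------------------------------------------------------------------
# ITT analysis
# ---------------------------------------------------------------------------

@dataclass
class AnalysisOutput:
    effects: EffectEstimates
    curve: RiskCurve
    weights: WeightSet | None
    expanded: pd.DataFrame | None = None


def itt_analysis(bundle, subjects: pd.DataFrame, admin_end,
                 covariates: list | None = None, outcome_kind: str = "composite",
                 spline: SplineSpec | None = None, weighted: bool = True,
                 truncation_percentile: float | None = None,
                 n_boot: int = 0, seed: int = 0,
                 curve_cis: bool = False) -> AnalysisOutput:
    """Weighted intention-to-treat analysis for one outcome."""
    spline = spline or SplineSpec()
    covariates = covariates or DEFAULT_COVARIATES
    expanded = expand_person_time(subjects, bundle.outcomes, None, admin_end,
                                  outcome_kind=outcome_kind,
                                  diagnoses=bundle.diagnoses,
                                  dispensations=bundle.dispensations)
    ws = None
    weight_series = None
    if weighted:
        ws = baseline_ip_weights(subjects, covariates)
        if truncation_percentile is not None:
            ws = truncate_weights(ws, truncation_percentile)
        weight_series = pd.Series(
            ws.baseline.reindex(expanded["person_id"]).to_numpy(),
            index=expanded.index)
    fit = fit_pooled_logistic(expanded, weights=weight_series, spline=spline,
                              robust_variance=False)
    curve = risk_curves(fit, spline, outcome=outcome_kind, contrast="itt")
    eff = effect_estimates(curve, person_intervals=expanded,
                           weights=weight_series, spline=spline)
    eff.outcome, eff.contrast = outcome_kind, "itt"

    if n_boot > 0:
        Xw, _, _ = build_design(subjects, covariates)
        prep = _BlockTable(subjects, expanded)
        cells = _CellModel(spline)

        def analysis(idx, rng):
            return _itt_estimates_from_replicate(prep, cells, Xw, idx,
                                                 weighted,
                                                 curve_risks=curve_cis)

        cis, n_failed = bootstrap_cis(analysis, len(subjects), n_boot, seed)
        eff.cis = {k: v for k, v in cis.items() if not k.startswith("curve_")}
        eff.n_boot, eff.seed, eff.n_failed = n_boot, seed, n_failed
        if curve_cis:
            band = []
            for t in range(1, HORIZON + 1):
                band.append((t, *cis.get(f"curve_treated_{t}", (np.nan,) * 2),
                             *cis.get(f"curve_control_{t}", (np.nan,) * 2)))
            curve.curves = curve.curves.merge(
                pd.DataFrame(band, columns=["t", "treated_lo", "treated_hi",
                                            "control_lo", "control_hi"]),
                on="t", how="left")
    return AnalysisOutput(effects=eff, curve=curve, weights=ws,
                          expanded=expanded)


# ---------------------------------------------------------------------------
# per-protocol analysis
# ---------------------------------------------------------------------------

def pp_analysis(bundle, subjects: pd.DataFrame, admin_end,
                covariates: list | None = None,
                adherence: AdherenceConfig | None = None,
                outcome_kind: str = "composite",
                spline: SplineSpec | None = None,
                truncation_percentile: float | None = None,
                n_boot: int = 0, seed: int = 0) -> AnalysisOutput:
    """Per-protocol analysis: artificial censoring at deviation plus
    time-varying inverse-probability-of-censoring weights."""
    spline = spline or SplineSpec()
    covariates = covariates or DEFAULT_COVARIATES
    adherence = adherence or AdherenceConfig()
    cdates = censoring_dates(subjects, bundle.dispensations, bundle.diagnoses,
                             adherence)
    expanded = expand_person_time(subjects, bundle.outcomes, cdates, admin_end,
                                  outcome_kind=outcome_kind,
                                  diagnoses=bundle.diagnoses,
                                  dispensations=bundle.dispensations)
    base_ws = baseline_ip_weights(subjects, covariates)
    ws = censoring_ip_weights(expanded, covariates, TIMEVARYING_COVARIATES,
                              spline=spline, baseline_weights=base_ws.baseline)
    if truncation_percentile is not None:
        ws = truncate_weights(ws, truncation_percentile)
    fit = fit_pooled_logistic(expanded, weights=ws.combined, spline=spline)
    curve = risk_curves(fit, spline, outcome=outcome_kind, contrast="pp")
    eff = effect_estimates(curve, person_intervals=expanded,
                           weights=ws.combined, spline=spline)
    eff.outcome, eff.contrast = outcome_kind, "pp"

    if n_boot > 0:
        cis, n_failed = _pp_bootstrap(bundle, subjects, expanded, covariates,
                                      spline, n_boot, seed)
        eff.cis, eff.n_boot, eff.seed, eff.n_failed = cis, n_boot, seed, n_failed
    return AnalysisOutput(effects=eff, curve=curve, weights=ws,
                          expanded=expanded)


def _pp_bootstrap(bundle, subjects, expanded, covariates, spline,
                  n_boot, seed):
    """Person-resampled bootstrap for the per-protocol estimator.

    Weight models (assignment and censoring) are refit inside each replicate
    on pre-built design-matrix rows gathered per resampled person.
    """
    Xw, _, _ = build_design(subjects, covariates)
    prep = _BlockTable(subjects, expanded)
    cells = _CellModel(spline)
    tb = rcs_basis(expanded["t"].to_numpy(dtype=float), spline)
    Xb, _, _ = build_design(expanded, covariates)
    Xt, _, _ = build_design(expanded, TIMEVARYING_COVARIATES,
                            add_intercept=False)
    X_den = np.column_stack([Xb, tb, Xt])
    X_num = np.column_stack([Xb, tb])
    uncens = 1.0 - expanded["artificially_censored"].to_numpy(dtype=float)
    arm_row_full = (expanded["arm"] == ARM_TREATED).to_numpy(dtype=float)

    def analysis(idx, rng):
        a = prep.arm1[idx]
        sw = _stabilized_itw(Xw[idx], a)
        rows, boot_pid, _ = prep.gather(idx)
        u = uncens[rows]
        armr = arm_row_full[rows]
        cw = np.ones(len(rows))
        for aval in (1.0, 0.0):
            m = armr == aval
            if not m.any() or (1 - u[m]).sum() == 0:
                continue
            fd = fit_logistic(X_den[rows[m]], u[m], ridge=CENSOR_RIDGE)
            fn = fit_logistic(X_num[rows[m]], u[m], ridge=CENSOR_RIDGE)
            ratio = fn.predict(X_num[rows[m]]) / np.clip(
                fd.predict(X_den[rows[m]]), 1e-12, None)
            # cumulative product within each resampled person's block
            s = pd.Series(ratio).groupby(boot_pid[m]).cumprod().to_numpy()
            cw[m] = s
        w_row = sw[boot_pid] * cw
        ev, tot = cells.aggregate(armr, prep.t[rows], prep.event[rows], w_row)
        r1, r0 = cells.fit_risks(ev, tot)
        out = {"risk_treated": 100 * r1[-1], "risk_control": 100 * r0[-1],
               "rd": 100 * (r1[-1] - r0[-1]),
               "rr": r1[-1] / r0[-1] if r0[-1] > 0 else np.nan}
        for h in (36, 48, 60):
            out[f"hr_{h}m"] = cells.fit_hr(ev, tot, h)
        return out

    return bootstrap_cis(analysis, len(subjects), n_boot, seed)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write tables + manifests under out_dir."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = replace(config.generator, seed=_substream(config.seed, 0))
    stage_log = []

    def manifest(stage, **info):
        rec = {"stage": stage, "seed": config.seed,
               "config_hash": gen.config_hash(), **info}
        stage_log.append(rec)
        log.info("stage %s: %s", stage, info)

    if config.registry_dir:
        bundle = sr.read_bundle(config.registry_dir)
    else:
        bundle = sr.generate_registry(gen)
        bundle = sr.inject_missingness(bundle, gen)
        sr.write_bundle(bundle, out / "registry")
    manifest("simulate", persons=len(bundle.persons),
             dispensations=len(bundle.dispensations))

    subjects, flowchart = prepare_cohort(bundle, config.eligibility,
                                         config.imputation)
    flowchart.to_frame().to_csv(out / "flowchart.tsv", sep="\t", index=False)
    (out / "flowchart.txt").write_text(flowchart.render() + "\n")
    manifest("build_cohort", eligible=len(subjects))

    admin_end = gen.study_end
    results = {"flowchart": flowchart, "effects": {}, "curves": {}}

    ws_balance = baseline_ip_weights(subjects, config.covariates)
    bal = balance_table(subjects, ws_balance, config.covariates)
    bal.table.to_csv(out / "balance.tsv", sep="\t", index=False)
    results["balance"] = bal
    manifest("weight", max_smd_after=bal.max_smd(weighted=True))

    effect_rows = []
    pp_boot = config.pp_n_boot if config.pp_n_boot is not None else config.n_boot
    for kind in config.outcomes:
        itt = itt_analysis(bundle, subjects, admin_end, config.covariates,
                           outcome_kind=kind, spline=config.spline,
                           truncation_percentile=config.truncation_percentile,
                           n_boot=config.n_boot,
                           seed=_substream(config.seed, 1),
                           curve_cis=(kind == "composite"))
        results["effects"][(kind, "itt")] = itt.effects
        results["curves"][(kind, "itt")] = itt.curve
        effect_rows.append(itt.effects.to_frame())

        pp = pp_analysis(bundle, subjects, admin_end, config.covariates,
                         config.adherence, outcome_kind=kind,
                         spline=config.spline,
                         truncation_percentile=config.truncation_percentile,
                         n_boot=pp_boot, seed=_substream(config.seed, 2))
        results["effects"][(kind, "pp")] = pp.effects
        results["curves"][(kind, "pp")] = pp.curve
        effect_rows.append(pp.effects.to_frame())
        if kind == "composite":
            results["adherence"] = adherence_proportions(subjects, pp.expanded)
            manifest("adherence", **{k: round(v, 4)
                                     for k, v in results["adherence"].items()})
    effects_df = pd.concat(effect_rows, ignore_index=True)
    effects_df.to_csv(out / "effects.tsv", sep="\t", index=False)
    _write_shaped_tables(effects_df, out)
    curves_df = pd.concat([c.curves.assign(outcome=c.outcome, contrast=c.contrast)
                           for c in results["curves"].values()],
                          ignore_index=True)
    curves_df.to_csv(out / "risk_curves.tsv", sep="\t", index=False)
    manifest("fit", outcomes=list(config.outcomes))

    if config.oracle_n:
        oracle = sr.compute_true_effects(gen, config.oracle_n,
                                         _substream(config.seed, 3))
        panel = []
        for kind in config.outcomes:
            est = results["effects"][(kind, "itt")].estimates
            panel.append((kind, est["rd"], 100 * oracle.true_rd_5y[kind],
                          abs(est["rd"] - 100 * oracle.true_rd_5y[kind]),
                          est["rr"], oracle.true_rr_5y[kind],
                          abs(est["rr"] - oracle.true_rr_5y[kind])))
        rec = pd.DataFrame(panel, columns=["outcome", "rd_est", "rd_true",
                                           "rd_abs_err", "rr_est", "rr_true",
                                           "rr_abs_err"])
        rec.to_csv(out / "oracle_recovery.tsv", sep="\t", index=False)
        results["oracle"] = oracle
        results["oracle_recovery"] = rec
        manifest("oracle", n_oracle=config.oracle_n)

    if config.sensitivity:
        from .sensitivity_suite import run_sensitivity_suite
        grid = run_sensitivity_suite(bundle, subjects, config)
        grid.to_frame().to_csv(out / "sensitivity.tsv", sep="\t", index=False)
        results["sensitivity"] = grid
        manifest("sensitivity", variants=[lab for lab, _ in grid.entries])

    (out / "manifest.json").write_text(json.dumps(stage_log, indent=2,
                                                  default=str))
    manifest("report", out_dir=str(out))
    return results


def _substream(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(int(seed)).spawn(8)[k]
               .generate_state(1)[0] % (2 ** 31))


def _write_shaped_tables(effects_df: pd.DataFrame, out: Path) -> None:
    """Risk/RD/RR table and HR-by-horizon table layouts."""
    risks = effects_df[effects_df["estimate"].isin(
        ["events_treated", "events_control", "risk_treated", "risk_control",
         "rd", "rr"])]
    risks = risks.pivot_table(index=["contrast", "outcome"],
                              columns="estimate", values=["value", "ci_lower",
                                                          "ci_upper"],
                              aggfunc="first")
    risks.to_csv(out / "table_risks.tsv", sep="\t")
    hrs = effects_df[effects_df["estimate"].str.startswith("hr_")]
    hrs.to_csv(out / "table_hazard_ratios.tsv", sep="\t", index=False)


def render_report(results_dir) -> str:
    """Assemble a plain-text report (plus an SVG risk-curve figure) from the
    artifacts a pipeline run wrote.  Missing artifacts are noted, not fatal."""
    results_dir = Path(results_dir)
    lines = ["# Target-trial emulation report", ""]

    def section(title, fname, formatter=None):
        path = results_dir / fname
        lines.append(f"## {title}")
        if not path.exists():
            lines.append(f"[missing artifact: {fname}]")
            lines.append("")
            return None
        df = pd.read_csv(path, sep="\t")
        lines.append(df.to_string(index=False))
        lines.append("")
        return df

    fc = results_dir / "flowchart.txt"
    lines.append("## Cohort selection")
    lines.append(fc.read_text() if fc.exists()
                 else "[missing artifact: flowchart.txt]")
    lines.append("")
    section("Covariate balance", "balance.tsv")
    section("Risks, risk differences and ratios", "effects.tsv")
    section("Oracle recovery", "oracle_recovery.tsv")
    section("Sensitivity analyses", "sensitivity.tsv")

    curves_path = results_dir / "risk_curves.tsv"
    if curves_path.exists():
        try:
            _plot_curves(pd.read_csv(curves_path, sep="\t"),
                         results_dir / "risk_curves.svg")
            lines.append("Risk-curve figure: risk_curves.svg")
        except Exception as e:  # plotting is best-effort
            lines.append(f"[risk-curve figure unavailable: {e}]")
    report = "\n".join(lines)
    (results_dir / "report.txt").write_text(report)
    return report


def _plot_curves(curves: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = curves[(curves["outcome"] == "composite")
                 & (curves["contrast"] == "itt")]
    fig, ax = plt.subplots(figsize=(6, 4))
    for arm, color in ((ARM_TREATED, "tab:blue"), (ARM_CONTROL, "tab:red")):
        s = sub[sub["arm"] == arm]
        ax.plot(s["t"], 100 * s["risk"], color=color, label=arm)
        lo = f"{'treated' if arm == ARM_TREATED else 'control'}_lo"
        hi = f"{'treated' if arm == ARM_TREATED else 'control'}_hi"
        if lo in s and s[lo].notna().any():
            ax.fill_between(s["t"], s[lo], s[hi], color=color, alpha=0.2)
    ax.set_xlabel("months since time zero")
    ax.set_ylabel("cumulative risk (%)")
    ax.set_title("Composite outcome, intention-to-treat")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
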