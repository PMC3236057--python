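"""End-to-end analysis: cohort -> normalised visits -> stages -> tables.

``analyze_cohort`` produces the long analysis table every downstream
operation consumes; ``run_pipeline`` strings the full study analysis
together: stage prevalence per visit, cut-off calibration on the stable
patients, per-measurement contingency counts and operating characteristics,
predictive-ability counts for the single and combined criteria, and the
abnormal-occasion histogram over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .evaluation import (
    ContingencyCounts,
    CutoffSpec,
    calibrate_cutoff,
    bos0p_predictor_stats,
    operating_characteristics,
    tabulate_counts,
)
from .io import config_hash, read_visit_table, write_report_tsv
from .normalization import ReferenceSet, normalize_timeline
from .prediction import PredictionCriterion, combined_abnormal_timeline, predictive_ability
from .staging import PatientOutcome, StageRules, Stage, stage_timeline, stage_visit
from .synthetic import CohortConfig, PatientTimeline, generate_cohort

__all__ = ["RunConfig", "CohortAnalysis", "ReportBundle", "analyze_cohort", "run_pipeline",
           "default_cutoff_templates", "write_tables"]


#: The cut-off battery evaluated by default: (variable, dimension, direction,
#: fixed value or None for calibration).  FEV1 percent-of-baseline < 90 is the
#: definition of potential BOS and therefore fixed, not calibrated.
DEFAULT_CUTOFF_TEMPLATES: tuple[tuple[str, str, str, float | None], ...] = (
    ("fev1", "pct_baseline", "less", 90.0),
    ("fvc", "pct_baseline", "less", None),
    ("n2_slope", "pct_baseline", "greater", None),
    ("fev1", "pct_predicted", "less", None),
    ("fvc", "pct_predicted", "less", None),
    ("n2_slope", "pct_predicted", "greater", None),
)


def default_cutoff_templates() -> tuple[tuple[str, str, str, float | None], ...]:
    return DEFAULT_CUTOFF_TEMPLATES


@dataclass
class CohortAnalysis:
    """Normalised, staged view of a cohort."""

    analysis: pd.DataFrame  # long: one row per measurement, with diagnostic_state
    staged: pd.DataFrame  # one row per FEV1 measurement with stage/confirmed/state
    outcomes: dict[str, PatientOutcome]

    @property
    def excluded_patients(self) -> set[str]:
        """Patients ending follow-up in unresolved potential BOS."""
        return {pid for pid, o in self.outcomes.items() if o.terminal_bos0p}

    @property
    def stable_patients(self) -> set[str]:
        """Never BOS, never potential BOS: the cut-off calibration pool."""
        return {
            pid
            for pid, o in self.outcomes.items()
            if o.bos_onset is None and not o.ever_bos0p
        }


def analyze_cohort(
    timelines: Sequence[PatientTimeline],
    refset: ReferenceSet | None = None,
    rules: StageRules | None = None,
) -> CohortAnalysis:
    refset = refset or ReferenceSet.default()
    rules = rules or StageRules()
    norm_frames = []
    staged_frames = []
    outcomes: dict[str, PatientOutcome] = {}
    for tl in timelines:
        norm = normalize_timeline(tl, refset)
        if norm.empty:
            outcomes[tl.patient_id] = PatientOutcome(patient_id=tl.patient_id)
            continue
        staged, outcome = stage_timeline(norm, rules)
        outcomes[tl.patient_id] = outcome

        confirmed_0p_months = set(
            staged.loc[
                (staged["diagnostic_state"] == "BOS0p"), "months_post_tx"
            ].tolist()
        )
        onset = outcome.bos_onset

        def state_of(month: float) -> str:
            if onset is not None and month >= onset:
                return "BOS"
            if month in confirmed_0p_months:
                return "BOS0p"
            return "NoBOS"

        norm = norm.copy()
        norm["diagnostic_state"] = norm["months_post_tx"].map(state_of)
        norm_frames.append(norm)
        staged_frames.append(staged)

    analysis = (
        pd.concat(norm_frames, ignore_index=True)
        if norm_frames
        else pd.DataFrame(
            columns=[
                "patient_id", "months_post_tx", "variable", "value",
                "pct_predicted", "pct_baseline", "provisional", "diagnostic_state",
            ]
        )
    )
    staged_df = (
        pd.concat(staged_frames, ignore_index=True)
        if staged_frames
        else pd.DataFrame(
            columns=[
                "patient_id", "months_post_tx", "fev1_pct_baseline",
                "stage", "confirmed", "diagnostic_state",
            ]
        )
    )
    return CohortAnalysis(analysis=analysis, staged=staged_df, outcomes=outcomes)


def stage_prevalence_table(
    cohort: CohortAnalysis, months: Iterable[float] = (6, 9, 12, 18, 24, 36)
) -> pd.DataFrame:
    """Patients per BOS stage at each scheduled visit (one column per month).

    A patient contributes to the column of a month only if seen at that
    month.  BOS visits are graded into stages 1-3 by the concurrent FEV1
    percent-of-baseline (never shallower than stage 1 once diagnosed).
    """
    months = [float(m) for m in months]
    rows = {name: [] for name in ("NoBOS", "BOS0p", "BOS1", "BOS2", "BOS3")}
    staged = cohort.staged
    for m in months:
        at_m = staged[staged["months_post_tx"] == m]
        counts = dict.fromkeys(rows, 0)
        for _, rec in at_m.iterrows():
            state = rec["diagnostic_state"]
            if state == "BOS":
                sub = stage_visit(rec["fev1_pct_baseline"])
                sub = max(sub, Stage.BOS1)
                counts[sub.name] += 1
            elif state == "BOS0p":
                counts["BOS0p"] += 1
            else:
                counts["NoBOS"] += 1
        for name in rows:
            rows[name].append(counts[name])
    out = pd.DataFrame(rows, index=[f"{m:g}" for m in months]).T
    out.index.name = "stage"
    return out.reset_index()


@dataclass
class ReportBundle:
    """Everything one pipeline run produces."""

    cutoffs: list[CutoffSpec]
    table_stage_prevalence: pd.DataFrame
    table_counts: pd.DataFrame
    table_operating: pd.DataFrame
    table_prediction: pd.DataFrame
    figure_histogram: pd.DataFrame
    staged: pd.DataFrame
    summary: dict[str, float | int | None]
    meta: dict


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_path`` (a long-format visit TSV) or ``cohort``
    (synthesis settings) must be given.
    """

    input_path: str | None = None
    cohort: CohortConfig | None = None
    reference_path: str | None = None
    rules: StageRules = field(default_factory=StageRules)
    evaluation_window: tuple[float, float] = (6.0, 36.0)
    prediction_window: tuple[float, float] = (6.0, 24.0)
    target_specificity: float = 95.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.cohort is None):
            raise ConfigurationError("give exactly one of input_path or cohort settings")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ConfigurationError(f"input path does not exist: {self.input_path}")


def run_pipeline(config: RunConfig) -> ReportBundle:
    refset = (
        ReferenceSet.from_tsv(config.reference_path)
        if config.reference_path
        else ReferenceSet.default()
    )
    if config.input_path is not None:
        timelines = read_visit_table(config.input_path)
        seed = config.seed
    else:
        cohort_cfg = config.cohort
        if cohort_cfg.seed != config.seed:
            cohort_cfg = CohortConfig(
                **{**cohort_cfg.__dict__, "seed": config.seed}
            )
        timelines = generate_cohort(cohort_cfg, refset).timelines
        seed = cohort_cfg.seed

    cohort = analyze_cohort(timelines, refset, config.rules)
    excluded = cohort.excluded_patients
    stable = cohort.stable_patients
    win = config.evaluation_window

    # calibrate the battery on the stable pool
    cutoffs: list[CutoffSpec] = []
    stable_mask = cohort.analysis["patient_id"].isin(stable)
    in_window = cohort.analysis["months_post_tx"].between(win[0], win[1])
    for variable, dimension, direction, fixed in DEFAULT_CUTOFF_TEMPLATES:
        if fixed is not None:
            cutoffs.append(
                CutoffSpec(variable=variable, dimension=dimension, direction=direction,
                           value=fixed, source="fixed")
            )
            continue
        sel = cohort.analysis[
            stable_mask & in_window & (cohort.analysis["variable"] == variable)
        ]
        vals = sel[dimension]
        if dimension == "pct_baseline":
            vals = vals[~sel["provisional"].astype(bool)]
        vals = vals.dropna().to_numpy()
        if vals.size == 0:
            continue  # variable absent from this data set
        cutoffs.append(
            calibrate_cutoff(vals, variable, dimension, direction, config.target_specificity)
        )

    # contingency counts and operating characteristics per cut-off
    count_rows = []
    oc_rows = []
    for spec in cutoffs:
        counts = tabulate_counts(cohort.analysis, spec, win, excluded)
        count_rows.append(
            {
                "criterion": spec.label(),
                "variable": spec.variable,
                "dimension": spec.dimension,
                "direction": spec.direction,
                "cutoff": spec.value,
                "source": spec.source,
                **counts.__dict__,
            }
        )
        oc = operating_characteristics(counts).rounded()
        oc_rows.append({"criterion": spec.label(), **oc})
    table_counts = pd.DataFrame(count_rows)
    table_operating = pd.DataFrame(oc_rows)

    # predictive ability: FEV1 %basal, N2 %pred, and the combination
    by_key = {(s.variable, s.dimension): s for s in cutoffs}
    pred_rows = []
    hist = pd.DataFrame(columns=["months_post_tx", "n_abnormal", "n_preceding_bos"])
    fev1_spec = by_key.get(("fev1", "pct_baseline"))
    n2_spec = by_key.get(("n2_slope", "pct_predicted"))
    criteria: list[tuple[str, PredictionCriterion]] = []
    if fev1_spec:
        criteria.append(("fev1", PredictionCriterion((fev1_spec,))))
    if n2_spec:
        criteria.append(("n2_slope", PredictionCriterion((n2_spec,))))
    if fev1_spec and n2_spec:
        criteria.append(("combined", PredictionCriterion((fev1_spec, n2_spec))))
    for name, criterion in criteria:
        counts = predictive_ability(
            cohort.analysis, cohort.outcomes, criterion,
            config.prediction_window, excluded,
        )
        pred_rows.append(
            {
                "criterion": name,
                "definition": criterion.label(),
                "total_results": counts.total_results,
                "total_abnormal": counts.total_abnormal,
                "abnormal_preceding_bos": counts.abnormal_preceding_bos,
                "predictive_value_pct": counts.predictive_value_rounded,
            }
        )
        if name == "combined":
            hist = combined_abnormal_timeline(
                cohort.analysis, cohort.outcomes, criterion,
                config.prediction_window, excluded,
            )
    table_prediction = pd.DataFrame(pred_rows)

    prevalence = stage_prevalence_table(
        cohort, [m for m in sorted({*cohort.staged["months_post_tx"]}) if m >= win[0]]
    )
    stats = bos0p_predictor_stats(cohort.outcomes.values())

    summary: dict[str, float | int | None] = {
        "n_patients": len(timelines),
        "n_excluded_terminal_bos0p": len(excluded),
        "n_stable": len(stable),
        "n_bos": stats.n_bos,
        "bos0p_sensitivity_pct": None if stats.sensitivity is None else round(stats.sensitivity, 1),
        "bos0p_specificity_pct": None if stats.specificity is None else round(stats.specificity, 1),
        "bos0p_ppv_pct": None if stats.ppv is None else round(stats.ppv, 1),
    }
    for row in pred_rows:
        summary[f"predictive_value_{row['criterion']}_pct"] = row["predictive_value_pct"]

    meta = {
        "seed": seed,
        "config_hash": config_hash(
            {
                "input_path": config.input_path,
                "cohort": None if config.cohort is None else repr(config.cohort),
                "rules": repr(config.rules),
                "evaluation_window": config.evaluation_window,
                "prediction_window": config.prediction_window,
                "target_specificity": config.target_specificity,
            }
        ),
    }
    return ReportBundle(
        cutoffs=cutoffs,
        table_stage_prevalence=prevalence,
        table_counts=table_counts,
        table_operating=table_operating,
        table_prediction=table_prediction,
        figure_histogram=hist,
        staged=cohort.staged,
        summary=summary,
        meta=meta,
    )


def write_tables(bundle: ReportBundle, out_dir: str | Path) -> list[Path]:
    """Write every table of a bundle as TSV files under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "stage_prevalence.tsv": bundle.table_stage_prevalence,
        "contingency_counts.tsv": bundle.table_counts,
        "operating_characteristics.tsv": bundle.table_operating,
        "predictive_ability.tsv": bundle.table_prediction,
        "abnormal_histogram.tsv": bundle.figure_histogram,
        "staged_visits.tsv": bundle.staged,
    }
    for name, df in tables.items():
        path = out_dir / name
        write_report_tsv(df, path, bundle.meta)
        written.append(path)
    summary_df = pd.DataFrame(
        [(k, "" if v is None else v) for k, v in bundle.summary.items()],
        columns=["key", "value"],
    )
    path = out_dir / "summary.tsv"
    write_report_tsv(summary_df, path, bundle.meta)
    written.append(path)
    return written
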