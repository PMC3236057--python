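"""Predictive ability of an abnormal test result for later BOS.

This statistic is deliberately different from a conventional positive
predictive value: it only pools measurement occasions at which the patient
is *not yet* diagnosed with BOS, and asks what fraction of the abnormal
occasions precede a BOS diagnosis within follow-up.  It therefore reads as
"given an abnormal result today in a patient without BOS, what is the
probability this heralds BOS?".

A criterion may combine several components (e.g. FEV1 < 90 % of baseline
*and* N2-slope > a calibrated percent-predicted cut-off); an occasion is
abnormal only if every component is abnormal, and occasions at which any
component is missing are dropped from the pool entirely -- both tests must
be evaluable simultaneously.  Patients whose potential-BOS appears only at
the final visit (unresolved outcome) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .errors import AnalysisError
from .evaluation import CutoffSpec, is_abnormal
from .staging import PatientOutcome

__all__ = [
    "PredictionCriterion",
    "PredictionCounts",
    "predictive_ability",
    "combined_abnormal_timeline",
]


@dataclass(frozen=True)
class PredictionCriterion:
    """One or more cut-off components, all of which must be abnormal."""

    components: tuple[CutoffSpec, ...]

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise AnalysisError("a prediction criterion needs at least one component")

    def label(self) -> str:
        return " + ".join(c.label() for c in self.components)


@dataclass(frozen=True)
class PredictionCounts:
    """Occasion counts behind one predictive-ability figure."""

    total_results: int
    total_abnormal: int
    abnormal_preceding_bos: int

    def __post_init__(self) -> None:
        if not 0 <= self.abnormal_preceding_bos <= self.total_abnormal <= self.total_results:
            raise AnalysisError(
                "need abnormal_preceding_bos <= total_abnormal <= total_results"
            )

    @property
    def predictive_value(self) -> float | None:
        """Raw percentage; None (undefined) when no abnormal occasion exists."""
        if self.total_abnormal == 0:
            return None
        return 100.0 * self.abnormal_preceding_bos / self.total_abnormal

    @property
    def predictive_value_rounded(self) -> int | None:
        pv = self.predictive_value
        return None if pv is None else round_half_up(pv)


def _occasion_table(
    analysis: pd.DataFrame,
    outcomes: Mapping[str, PatientOutcome] | Iterable[PatientOutcome],
    criterion: PredictionCriterion,
    window: tuple[float, float],
    excluded_patients: Iterable[str],
) -> pd.DataFrame:
    """One row per pre-diagnosis occasion with all components evaluable.

    Columns: patient_id, months_post_tx, abnormal (all components),
    precedes_bos.
    """
    if not isinstance(outcomes, Mapping):
        outcomes = {o.patient_id: o for o in outcomes}
    excluded = set(excluded_patients)

    per_component = []
    for idx, comp in enumerate(criterion.components):
        df = analysis[
            (analysis["variable"] == comp.variable)
            & (analysis["months_post_tx"] >= window[0])
            & (analysis["months_post_tx"] <= window[1])
            & ~analysis["patient_id"].isin(excluded)
        ]
        vals = df[comp.dimension]
        keep = vals.notna()
        if comp.dimension == "pct_baseline" and "provisional" in df.columns:
            keep &= ~df["provisional"].astype(bool)
        df = df[keep]
        per_component.append(
            pd.DataFrame(
                {
                    "patient_id": df["patient_id"].to_numpy(),
                    "months_post_tx": df["months_post_tx"].to_numpy(),
                    f"abn_{idx}": is_abnormal(df[comp.dimension].to_numpy(), comp),
                }
            )
        )
    merged = per_component[0]
    for extra in per_component[1:]:
        merged = merged.merge(extra, on=["patient_id", "months_post_tx"], how="inner")

    abn_cols = [c for c in merged.columns if c.startswith("abn_")]
    merged["abnormal"] = merged[abn_cols].all(axis=1)

    onset = merged["patient_id"].map(
        lambda pid: outcomes[pid].bos_onset if pid in outcomes else None
    )
    onset = onset.astype(float)  # None -> NaN
    # keep only occasions before diagnosis (or of never-diagnosed patients)
    not_yet = onset.isna() | (merged["months_post_tx"] < onset)
    merged = merged[not_yet].copy()
    onset = onset[not_yet]
    merged["precedes_bos"] = (~onset.isna()) & (merged["months_post_tx"] < onset)
    return merged[["patient_id", "months_post_tx", "abnormal", "precedes_bos"]]


def predictive_ability(
    analysis: pd.DataFrame,
    outcomes: Mapping[str, PatientOutcome] | Iterable[PatientOutcome],
    criterion: PredictionCriterion,
    window: tuple[float, float] = (6.0, 24.0),
    excluded_patients: Iterable[str] = (),
) -> PredictionCounts:
    """Count pre-diagnosis occasions, abnormal ones, and those preceding BOS.

    ``analysis`` is the long normalised-and-staged table (see
    :func:`n2bos.pipeline.analyze_cohort`); ``outcomes`` per-patient
    outcome records.  "Precedes BOS" requires an onset strictly later than
    the occasion and within observed follow-up.
    """
    occ = _occasion_table(analysis, outcomes, criterion, window, excluded_patients)
    return PredictionCounts(
        total_results=len(occ),
        total_abnormal=int(occ["abnormal"].sum()),
        abnormal_preceding_bos=int((occ["abnormal"] & occ["precedes_bos"]).sum()),
    )


def combined_abnormal_timeline(
    analysis: pd.DataFrame,
    outcomes: Mapping[str, PatientOutcome] | Iterable[PatientOutcome],
    criterion: PredictionCriterion,
    window: tuple[float, float] = (6.0, 24.0),
    excluded_patients: Iterable[str] = (),
) -> pd.DataFrame:
    """Histogram of abnormal occasions by visit month.

    Returns a DataFrame with columns ``months_post_tx``, ``n_abnormal``,
    ``n_preceding_bos``; its column sums equal the corresponding
    :class:`PredictionCounts` of the same criterion.
    """
    occ = _occasion_table(analysis, outcomes, criterion, window, excluded_patients)
    occ = occ[occ["abnormal"]]
    if occ.empty:
        return pd.DataFrame(columns=["months_post_tx", "n_abnormal", "n_preceding_bos"])
    grouped = occ.groupby("months_post_tx", sort=True).agg(
        n_abnormal=("abnormal", "sum"), n_preceding_bos=("precedes_bos", "sum")
    )
    out = grouped.reset_index()
    out["n_abnormal"] = out["n_abnormal"].astype(int)
    out["n_preceding_bos"] = out["n_preceding_bos"].astype(int)
    return out
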