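"""Loader for the packaged published-cohort worked example.

The package ships the printed normal/abnormal measurement counts,
prediction-occasion counts and patient-level outcome counts of a published
follow-up study of 61 double lung transplant recipients.  These counts are
*inputs*: the operating characteristics and predictive-ability percentages
are always recomputed from them by the same functions that analyse any
cohort, which makes the published tables a zero-synthesis worked example
for the whole reporting surface.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass

from .evaluation import Bos0pPredictorStats, ContingencyCounts, CutoffSpec
from .prediction import PredictionCounts

__all__ = ["PublishedCohortCounts", "load_published_counts"]


@dataclass(frozen=True)
class PublishedCohortCounts:
    n_recipients: int
    contingency: tuple[tuple[CutoffSpec, ContingencyCounts], ...]
    prediction: tuple[tuple[str, PredictionCounts], ...]
    patient_outcomes: Bos0pPredictorStats


def load_published_counts() -> PublishedCohortCounts:
    ref = importlib.resources.files("n2bos.data") / "published_cohort_counts.json"
    raw = json.loads(ref.read_text())
    contingency = []
    for row in raw["contingency"]:
        spec = CutoffSpec(
            variable=row["variable"],
            dimension=row["dimension"],
            direction=row["direction"],
            value=float(row["cutoff"]),
            source="fixed",
        )
        counts = ContingencyCounts(
            nobos_normal=row["nobos_normal"],
            nobos_abnormal=row["nobos_abnormal"],
            bos_normal=row["bos_normal"],
            bos_abnormal=row["bos_abnormal"],
            bos0p_normal=row["bos0p_normal"],
            bos0p_abnormal=row["bos0p_abnormal"],
        )
        contingency.append((spec, counts))
    prediction = tuple(
        (
            row["criterion"],
            PredictionCounts(
                total_results=row["total_results"],
                total_abnormal=row["total_abnormal"],
                abnormal_preceding_bos=row["abnormal_preceding_bos"],
            ),
        )
        for row in raw["prediction"]
    )
    outcomes = Bos0pPredictorStats(**raw["patient_outcomes"])
    return PublishedCohortCounts(
        n_recipients=raw["n_recipients"],
        contingency=tuple(contingency),
        prediction=prediction,
        patient_outcomes=outcomes,
    )
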