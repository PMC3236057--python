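"""BOS staging from FEV1 percent-of-baseline and per-patient onset detection.

Bronchiolitis obliterans syndrome (BOS) is diagnosed functionally: a
sustained fall of FEV1 to <= 80 % of the post-transplant baseline defines
BOS, a sustained fall into the 81-90 % band defines "potential BOS"
(BOS 0-p), and the depth of the fall grades the syndrome (stage 1: 66-80 %,
stage 2: 51-65 %, stage 3: <= 50 %).  "Sustained" means confirmed by a
second measurement at least 3 weeks later that also lies at or below the
relevant threshold; the FEF25-75 criterion of the staging system is not
used here.

Conventions of this implementation:

* a potential-BOS (81-90 %) value is confirmed when the next measurement
  >= 3 weeks later is also <= 90 %; a <= 80 % value is confirmed when the
  next measurement >= 3 weeks later is also <= 80 % (the substage may
  deepen between the pair -- onset is defined by crossing 80 %);
* BOS onset is dated at the first measurement of the earliest confirmed
  run at <= 80 % (switchable to the confirming measurement);
* an unconfirmed qualifying value at the final visit yields terminal
  flags, not an onset -- such patients' relation to BOS is unresolved;
* visits whose baseline is still provisional are recorded as NoBOS.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import weeks_to_months
from .errors import ConfigurationError

__all__ = ["Stage", "StageRules", "StagedVisit", "PatientOutcome", "stage_visit",
           "confirm_stages", "stage_timeline"]


class Stage(enum.IntEnum):
    NoBOS = 0
    BOS0p = 1
    BOS1 = 2
    BOS2 = 3
    BOS3 = 4

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class StageRules:
    """Staging thresholds and the confirmation rule.

    The bands are contiguous percentages of baseline FEV1: NoBOS > 90,
    BOS 0-p 81-90, stage 1 66-80, stage 2 51-65, stage 3 <= 50.
    ``onset_dating`` chooses whether onset is dated at the first ("first")
    or the confirming ("confirming") measurement of the pair.
    """

    bos0p_band: tuple[float, float] = (81.0, 90.0)
    bos_threshold: float = 80.0
    substage_bounds: dict = field(
        default_factory=lambda: {"BOS1": (66.0, 80.0), "BOS2": (51.0, 65.0), "BOS3": (0.0, 50.0)}
    )
    confirmation_separation_weeks: float = 3.0
    use_fef2575: bool = False
    onset_dating: str = "first"

    def __post_init__(self) -> None:
        if self.use_fef2575:
            raise ConfigurationError("FEF25-75-based staging is not supported")
        if self.onset_dating not in ("first", "confirming"):
            raise ConfigurationError("onset_dating must be 'first' or 'confirming'")
        if abs(self.bos_threshold - (self.bos0p_band[0] - 1.0)) > 1e-9:
            raise ConfigurationError(
                "bos_threshold must be the integer just below the BOS 0-p band"
            )


@dataclass(frozen=True)
class StagedVisit:
    months_post_tx: float
    fev1_pct_baseline: float
    stage: Stage
    confirmed: bool
    #: diagnostic state used for contingency tables: "NoBOS", "BOS0p" or "BOS"
    diagnostic_state: str


@dataclass(frozen=True)
class PatientOutcome:
    patient_id: str | None = None
    bos_onset: float | None = None  # months, None if never diagnosed
    ever_bos0p: bool = False
    bos0p_before_bos: bool = False
    terminal_bos0p: bool = False


def stage_visit(fev1_pct_baseline: float, rules: StageRules | None = None) -> Stage:
    """Monotone step function of the FEV1 percent-of-baseline.

    The band bounds are stated as integer percentages (0-p: 81-90, stage 1:
    66-80, ...); on the continuous scale each band extends down to just
    above the next bound, so 80.5 % is still potential BOS -- BOS proper
    requires crossing the 80 % threshold.
    """
    rules = rules or StageRules()
    pct = float(fev1_pct_baseline)
    if pct > rules.bos0p_band[1]:
        return Stage.NoBOS
    if pct > rules.bos_threshold:
        return Stage.BOS0p
    if pct > rules.substage_bounds["BOS2"][1]:
        return Stage.BOS1
    if pct > rules.substage_bounds["BOS3"][1]:
        return Stage.BOS2
    return Stage.BOS3


def confirm_stages(
    months: Sequence[float],
    fev1_pct_baseline: Sequence[float],
    rules: StageRules | None = None,
    patient_id: str | None = None,
) -> tuple[list[StagedVisit], PatientOutcome]:
    """Apply the confirmation rule to a chronological timeline.

    ``months`` and ``fev1_pct_baseline`` are the non-provisional staging
    inputs, in chronological order.  Returns the per-visit staged record
    (with diagnostic state) and the patient's outcome summary.
    """
    rules = rules or StageRules()
    months = [float(m) for m in months]
    pct = [float(p) for p in fev1_pct_baseline]
    if any(b <= a for a, b in zip(months, months[1:])):
        raise ConfigurationError("visits must be supplied in strictly increasing time order")
    sep = weeks_to_months(rules.confirmation_separation_weeks)
    n = len(months)
    stages = [stage_visit(p, rules) for p in pct]

    def next_at_separation(i: int) -> int | None:
        for j in range(i + 1, n):
            if months[j] - months[i] + 1e-9 >= sep:
                return j
        return None

    confirmed = [False] * n
    for i in range(n):
        if stages[i] == Stage.NoBOS:
            continue
        j = next_at_separation(i)
        if j is None:
            continue
        threshold = rules.bos0p_band[1] if stages[i] == Stage.BOS0p else rules.bos_threshold
        confirmed[i] = pct[j] <= threshold

    bos_onset: float | None = None
    for i in range(n):
        if pct[i] <= rules.bos_threshold and confirmed[i]:
            if rules.onset_dating == "first":
                bos_onset = months[i]
            else:
                j = next_at_separation(i)
                bos_onset = months[j] if j is not None else months[i]
            break

    # terminal flags: a qualifying unconfirmed value at the final visit
    terminal_bos0p = (
        bos_onset is None
        and n > 0
        and stages[-1] == Stage.BOS0p
        and not confirmed[-1]
    )
    confirmed_bos0p_visits = [
        months[i] for i in range(n) if stages[i] == Stage.BOS0p and confirmed[i]
    ]
    ever_bos0p = bool(confirmed_bos0p_visits) or terminal_bos0p
    bos0p_before_bos = bos_onset is not None and any(
        m < bos_onset for m in confirmed_bos0p_visits
    )

    visits = []
    for i in range(n):
        if bos_onset is not None and months[i] >= bos_onset:
            state = "BOS"
        elif stages[i] == Stage.BOS0p and confirmed[i]:
            state = "BOS0p"
        elif terminal_bos0p and i == n - 1:
            # diagnosed potential BOS at the final visit, outcome unresolved
            state = "BOS0p"
        else:
            state = "NoBOS"
        visits.append(
            StagedVisit(
                months_post_tx=months[i],
                fev1_pct_baseline=pct[i],
                stage=stages[i],
                confirmed=confirmed[i],
                diagnostic_state=state,
            )
        )
    outcome = PatientOutcome(
        patient_id=patient_id,
        bos_onset=bos_onset,
        ever_bos0p=ever_bos0p,
        bos0p_before_bos=bos0p_before_bos,
        terminal_bos0p=terminal_bos0p,
    )
    return visits, outcome


def stage_timeline(
    normalized: pd.DataFrame, rules: StageRules | None = None
) -> tuple[pd.DataFrame, PatientOutcome]:
    """Stage one patient's normalised long table (as from ``normalize_timeline``).

    Only non-provisional FEV1 percent-of-baseline rows enter the confirmation
    machinery; visits with a provisional (or absent) baseline are recorded as
    NoBOS with ``confirmed=False``.  Returns a staged DataFrame (one row per
    FEV1 measurement) and the patient outcome.
    """
    rules = rules or StageRules()
    fev1 = normalized[normalized["variable"] == "fev1"].sort_values("months_post_tx")
    pid = fev1["patient_id"].iloc[0] if len(fev1) else None
    usable = fev1[~fev1["provisional"] & fev1["pct_baseline"].notna()]
    staged, outcome = confirm_stages(
        usable["months_post_tx"].tolist(),
        usable["pct_baseline"].tolist(),
        rules,
        patient_id=pid,
    )
    by_month = {v.months_post_tx: v for v in staged}
    rows = []
    for _, rec in fev1.iterrows():
        m = float(rec["months_post_tx"])
        v = by_month.get(m)
        if v is None:  # provisional-baseline visit
            rows.append(
                {
                    "patient_id": pid,
                    "months_post_tx": m,
                    "fev1_pct_baseline": rec["pct_baseline"],
                    "stage": Stage.NoBOS.name,
                    "confirmed": False,
                    "diagnostic_state": "NoBOS",
                }
            )
        else:
            rows.append(
                {
                    "patient_id": pid,
                    "months_post_tx": m,
                    "fev1_pct_baseline": v.fev1_pct_baseline,
                    "stage": v.stage.name,
                    "confirmed": v.confirmed,
                    "diagnostic_state": v.diagnostic_state,
                }
            )
    staged_df = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "months_post_tx",
            "fev1_pct_baseline",
            "stage",
            "confirmed",
            "diagnostic_state",
        ],
    )
    return staged_df, outcome
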