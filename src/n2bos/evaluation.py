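"""Cut-off calibration and per-measurement operating characteristics.

A cut-off for a test variable is either *fixed* (the FEV1 < 90 %-of-baseline
criterion is the definition of potential BOS, so it is never recalibrated --
which is why its specificity is 90 %, not 95 %) or *calibrated*: chosen so
that a target fraction (default 95 %) of all pooled measurements of the
stable patients between 6 and 36 months are classified normal.  The
calibrated cut-off is the conservative empirical order statistic
(``numpy.quantile`` method ``higher``), which guarantees at least the target
specificity on the calibration pool itself; abnormality requires a strict
inequality beyond the cut-off, so borderline values count as normal.

Each measurement is then classified normal/abnormal and binned by the
patient's *current* diagnostic state at that visit (NoBOS, BOS 0-p, or BOS
-- pre-onset visits of eventual BOS patients count as NoBOS), yielding a
3 x 2 contingency table from which sensitivity, specificity and the
predictive values are computed.  The BOS-only positive and negative
predictive values compare BOS against NoBOS measurements (the potential-BOS
column enters only the combined "BOS + BOS 0-p" variants); percentages are
rounded half-up to integers for reporting, with raw values retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .errors import AnalysisError
from .staging import PatientOutcome

__all__ = [
    "CutoffSpec",
    "ContingencyCounts",
    "OperatingCharacteristics",
    "Bos0pPredictorStats",
    "calibrate_cutoff",
    "is_abnormal",
    "tabulate_counts",
    "operating_characteristics",
    "bos0p_predictor_stats",
]

DIMENSIONS = ("pct_baseline", "pct_predicted")
DIRECTIONS = ("less", "greater")  # abnormal-if-less / abnormal-if-greater


@dataclass(frozen=True)
class CutoffSpec:
    """One abnormality criterion: variable, scale, direction, threshold."""

    variable: str
    dimension: str  # "pct_baseline" | "pct_predicted"
    direction: str  # "less" | "greater"
    value: float
    source: str = "fixed"  # "fixed" | "calibrated"

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise AnalysisError(f"dimension must be one of {DIMENSIONS}")
        if self.direction not in DIRECTIONS:
            raise AnalysisError(f"direction must be one of {DIRECTIONS}")
        if not self.value > 0:
            raise AnalysisError("cut-off value must be positive")

    def label(self) -> str:
        sign = "<" if self.direction == "less" else ">"
        dim = "% basal" if self.dimension == "pct_baseline" else "% pred."
        return f"{self.variable} {dim} {sign} {self.value:g}"


def calibrate_cutoff(
    stable_results: Sequence[float] | np.ndarray,
    variable: str,
    dimension: str,
    direction: str,
    target_specificity: float = 95.0,
) -> CutoffSpec:
    """Choose a cut-off so the stable pool attains the target specificity.

    ``stable_results`` is the pooled set of measurements (on the requested
    scale) of patients with no graft complication.  The cut-off is the
    order statistic closest to the target percentile that still classifies
    at least the target fraction of the pool as normal (abnormality being a
    strict inequality beyond it): for "abnormal if greater" the smallest
    observed value with >= target fraction of the pool at or below it, and
    mirror-image for "abnormal if less".  The realised specificity on the
    pool therefore always lies in [target, target + 100/n].
    """
    values = np.asarray(stable_results, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise AnalysisError("empty calibration pool")
    if values.size < 20:
        warnings.warn(
            f"calibration pool has only {values.size} values; the empirical "
            "percentile is unstable",
            stacklevel=2,
        )
    q = target_specificity / 100.0
    if direction == "greater":
        cutoff = float(np.quantile(values, q, method="inverted_cdf"))
    else:
        cutoff = float(-np.quantile(-values, q, method="inverted_cdf"))
    return CutoffSpec(
        variable=variable,
        dimension=dimension,
        direction=direction,
        value=cutoff,
        source="calibrated",
    )


def is_abnormal(values, cutoff: CutoffSpec):
    """Strictly beyond the cut-off in the abnormal direction."""
    arr = np.asarray(values, dtype=float)
    result = arr < cutoff.value if cutoff.direction == "less" else arr > cutoff.value
    if np.isscalar(values) or arr.ndim == 0:
        return bool(result)
    return result


@dataclass(frozen=True)
class ContingencyCounts:
    """Normal/abnormal measurement counts by current diagnostic state."""

    nobos_normal: int = 0
    nobos_abnormal: int = 0
    bos_normal: int = 0
    bos_abnormal: int = 0
    bos0p_normal: int = 0
    bos0p_abnormal: int = 0

    def __post_init__(self) -> None:
        for f in (
            self.nobos_normal,
            self.nobos_abnormal,
            self.bos_normal,
            self.bos_abnormal,
            self.bos0p_normal,
            self.bos0p_abnormal,
        ):
            if f < 0:
                raise AnalysisError("counts must be non-negative")

    @property
    def total(self) -> int:
        return (
            self.nobos_normal
            + self.nobos_abnormal
            + self.bos_normal
            + self.bos_abnormal
            + self.bos0p_normal
            + self.bos0p_abnormal
        )


def tabulate_counts(
    analysis: pd.DataFrame,
    cutoff: CutoffSpec,
    window: tuple[float, float] = (6.0, 36.0),
    excluded_patients: Iterable[str] = (),
) -> ContingencyCounts:
    """Classify every in-window measurement and bin by diagnostic state.

    ``analysis`` is a long table with columns ``patient_id``,
    ``months_post_tx``, ``variable``, the measurement scales
    (``pct_baseline``/``pct_predicted``), ``provisional`` and
    ``diagnostic_state``.  Measurements of excluded patients (e.g. those
    ending follow-up in unresolved potential BOS) are dropped; so are
    percent-of-baseline values still flagged provisional.
    """
    excluded = set(excluded_patients)
    df = analysis[
        (analysis["variable"] == cutoff.variable)
        & (analysis["months_post_tx"] >= window[0])
        & (analysis["months_post_tx"] <= window[1])
        & ~analysis["patient_id"].isin(excluded)
    ]
    vals = df[cutoff.dimension]
    keep = vals.notna()
    if cutoff.dimension == "pct_baseline" and "provisional" in df.columns:
        keep &= ~df["provisional"].astype(bool)
    df = df[keep]
    abnormal = is_abnormal(df[cutoff.dimension].to_numpy(), cutoff)
    counts = {}
    for state, key in (("NoBOS", "nobos"), ("BOS", "bos"), ("BOS0p", "bos0p")):
        in_state = (df["diagnostic_state"] == state).to_numpy()
        counts[f"{key}_abnormal"] = int(np.sum(in_state & abnormal))
        counts[f"{key}_normal"] = int(np.sum(in_state & ~abnormal))
    return ContingencyCounts(**counts)


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Per-measurement operating characteristics of one cut-off.

    All fields are raw percentages (not rounded); metrics with an undefined
    denominator are ``None``.  ``rounded()`` applies half-up integer
    rounding for tabular reporting.
    """

    specificity: float | None
    sensitivity_bos: float | None
    sensitivity_bos0p: float | None
    ppv_bos: float | None
    ppv_bos_plus_0p: float | None
    npv_bos: float | None
    npv_bos_plus_0p: float | None

    def rounded(self) -> dict[str, int | None]:
        return {
            name: (None if value is None else round_half_up(value))
            for name, value in self.__dict__.items()
        }


def _ratio(num: float, denom: float) -> float | None:
    return None if denom == 0 else 100.0 * num / denom


def operating_characteristics(counts: ContingencyCounts) -> OperatingCharacteristics:
    """Sensitivity, specificity and predictive values from a 3 x 2 table.

    Specificity is computed on NoBOS measurements; sensitivities on the BOS
    and potential-BOS columns separately.  The BOS-only predictive values
    contrast BOS with NoBOS measurements; the "+ BOS 0-p" variants include
    the potential-BOS column in both numerator (PPV) and denominator.
    """
    c = counts
    return OperatingCharacteristics(
        specificity=_ratio(c.nobos_normal, c.nobos_normal + c.nobos_abnormal),
        sensitivity_bos=_ratio(c.bos_abnormal, c.bos_normal + c.bos_abnormal),
        sensitivity_bos0p=_ratio(c.bos0p_abnormal, c.bos0p_normal + c.bos0p_abnormal),
        ppv_bos=_ratio(c.bos_abnormal, c.nobos_abnormal + c.bos_abnormal),
        ppv_bos_plus_0p=_ratio(
            c.bos_abnormal + c.bos0p_abnormal,
            c.nobos_abnormal + c.bos_abnormal + c.bos0p_abnormal,
        ),
        npv_bos=_ratio(c.nobos_normal, c.nobos_normal + c.bos_normal),
        npv_bos_plus_0p=_ratio(
            c.nobos_normal, c.nobos_normal + c.bos_normal + c.bos0p_normal
        ),
    )


@dataclass(frozen=True)
class Bos0pPredictorStats:
    """Patient-level value of the potential-BOS stage as a predictor of BOS."""

    n_bos: int
    n_bos_preceded_by_bos0p: int
    n_never_bos: int
    n_never_bos_never_bos0p: int
    n_bos0p_patients: int
    n_bos0p_progressed: int

    @property
    def sensitivity(self) -> float | None:
        return _ratio(self.n_bos_preceded_by_bos0p, self.n_bos)

    @property
    def specificity(self) -> float | None:
        return _ratio(self.n_never_bos_never_bos0p, self.n_never_bos)

    @property
    def ppv(self) -> float | None:
        """Fraction of ever-potential-BOS patients who progressed to BOS.

        Patients whose potential-BOS appears only at the final visit are
        counted in the denominator under the assumption that they did not
        progress; ``ppv_if_progressed(k)`` gives the counterfactual when
        ``k`` of them in fact did.
        """
        return _ratio(self.n_bos0p_progressed, self.n_bos0p_patients)

    def ppv_if_progressed(self, extra: int) -> float | None:
        return _ratio(self.n_bos0p_progressed + extra, self.n_bos0p_patients)


def bos0p_predictor_stats(outcomes: Iterable[PatientOutcome]) -> Bos0pPredictorStats:
    """Patient-level 2 x 2 of potential BOS preceding BOS.

    Sensitivity: BOS patients whose onset was preceded by a confirmed
    potential-BOS stage, over all BOS patients.  Specificity: never-BOS
    patients never staged potential BOS, over never-BOS patients.  PPV:
    ever-potential-BOS patients who progressed to BOS, over all
    ever-potential-BOS patients (terminal, unresolved ones included in the
    denominator).
    """
    outcomes = list(outcomes)
    bos = [o for o in outcomes if o.bos_onset is not None]
    never = [o for o in outcomes if o.bos_onset is None]
    bos0p = [o for o in outcomes if o.ever_bos0p]
    return Bos0pPredictorStats(
        n_bos=len(bos),
        n_bos_preceded_by_bos0p=sum(o.bos0p_before_bos for o in bos),
        n_never_bos=len(never),
        n_never_bos_never_bos0p=sum(not o.ever_bos0p for o in never),
        n_bos0p_patients=len(bos0p),
        n_bos0p_progressed=sum(o.bos_onset is not None for o in bos0p),
    )
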