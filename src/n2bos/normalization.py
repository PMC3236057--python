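"""Percent-of-predicted and percent-of-baseline normalisation.

Every lung-function measurement is expressed on two scales:

* **percent predicted** -- 100 x value / predicted normal, where the
  predicted value comes from a configurable table of sex-specific linear
  reference equations (intercept + age term + height term).  The table the
  package ships is a *synthetic default* with physiologically plausible
  coefficients; studies should substitute the reference equations of their
  own laboratory.

* **percent of the latest baseline** -- the post-transplant baseline of a
  variable is the mean of the two highest qualifying values, where
  qualifying means measured at or after 4.5 months post transplantation and
  at least 3 weeks apart.  The "latest" baseline is recomputed at every
  visit from all eligible visits up to and including that visit, so it can
  only rise as follow-up accrues.  Before two eligible visits exist the
  single value is used and flagged *provisional*; provisional percentages
  are excluded from staging.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import weeks_to_months
from .errors import AnalysisError, ConfigurationError, ValidationError

__all__ = [
    "ReferenceSet",
    "BaselineState",
    "VisitRecord",
    "percent_predicted",
    "update_baseline",
    "percent_of_baseline",
    "normalize_timeline",
]


@dataclass(frozen=True)
class ReferenceSet:
    """Sex-specific linear reference equations, one row per (variable, sex).

    predicted = intercept + age_coef * age_years + height_coef * height_cm
    """

    coefficients: Mapping[tuple[str, str], tuple[float, float, float]]

    def predicted(self, variable: str, sex: str, age_years: float, height_cm: float) -> float:
        try:
            intercept, age_coef, height_coef = self.coefficients[(variable, sex)]
        except KeyError:
            raise ConfigurationError(
                f"no reference equation for variable={variable!r}, sex={sex!r}"
            ) from None
        pred = intercept + age_coef * age_years + height_coef * height_cm
        if pred <= 0:
            raise ConfigurationError(
                f"reference equation for {variable}/{sex} predicts a non-positive "
                f"value ({pred:.3g}) at age {age_years}, height {height_cm}"
            )
        return pred

    @property
    def variables(self) -> set[str]:
        return {var for var, _ in self.coefficients}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceSet":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"variable", "sex", "intercept", "age_coef", "height_coef"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"reference table {path} must have columns {sorted(required)}"
            )
        coef = {
            (row.variable, row.sex): (
                float(row.intercept),
                float(row.age_coef),
                float(row.height_coef),
            )
            for row in df.itertuples()
        }
        return cls(coefficients=coef)

    @classmethod
    def default(cls) -> "ReferenceSet":
        """The packaged synthetic default reference table."""
        ref = importlib.resources.files("n2bos.data") / "reference_equations.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)


def percent_predicted(
    value: float,
    variable: str,
    demographics: Mapping[str, object],
    refset: ReferenceSet,
) -> float:
    """100 x value / predicted(variable; sex, age, height)."""
    pred = refset.predicted(
        variable,
        str(demographics["sex"]),
        float(demographics["age_years"]),
        float(demographics["height_cm"]),
    )
    return 100.0 * value / pred


@dataclass(frozen=True)
class BaselineState:
    """Running baseline of one variable.

    ``eligible`` holds every qualifying (months, value) pair seen so far;
    ``baseline`` is the best achievable pair mean (or the single value while
    provisional); ``contributors`` are the pair realising it.
    """

    eligible: tuple[tuple[float, float], ...] = ()
    baseline: float | None = None
    provisional: bool = True
    contributors: tuple[tuple[float, float], ...] = ()
    min_separation_weeks: float = 3.0
    earliest_months: float = 4.5

    def _recompute(self) -> "BaselineState":
        if not self.eligible:
            return replace(self, baseline=None, provisional=True, contributors=())
        min_sep = weeks_to_months(self.min_separation_weeks)
        best: float | None = None
        best_pair: tuple = ()
        pts = self.eligible
        for a in range(len(pts)):
            for b in range(a + 1, len(pts)):
                if abs(pts[b][0] - pts[a][0]) + 1e-9 >= min_sep:
                    mean = 0.5 * (pts[a][1] + pts[b][1])
                    if best is None or mean > best:
                        best = mean
                        best_pair = (pts[a], pts[b])
        if best is None:
            # no qualifying pair yet: highest single value, provisional
            top = max(pts, key=lambda p: p[1])
            return replace(self, baseline=top[1], provisional=True, contributors=(top,))
        return replace(self, baseline=best, provisional=False, contributors=best_pair)

    def updated(self, months: float, value: float) -> "BaselineState":
        """State after observing ``value`` at ``months`` post transplant."""
        if not np.isfinite(value):
            return self
        if value <= 0:
            raise ValidationError(f"measured values must be positive, got {value}")
        if months < self.earliest_months:
            return self  # ineligible visit leaves the state unchanged
        new = replace(self, eligible=self.eligible + ((float(months), float(value)),))
        return new._recompute()


def update_baseline(
    state: BaselineState,
    months: float,
    value: float,
    min_separation_weeks: float | None = None,
    earliest_months: float | None = None,
) -> BaselineState:
    """Functional wrapper around :meth:`BaselineState.updated`."""
    if min_separation_weeks is not None or earliest_months is not None:
        state = replace(
            state,
            min_separation_weeks=min_separation_weeks
            if min_separation_weeks is not None
            else state.min_separation_weeks,
            earliest_months=earliest_months
            if earliest_months is not None
            else state.earliest_months,
        )
    return state.updated(months, value)


def percent_of_baseline(value: float, state: BaselineState) -> tuple[float, bool]:
    """100 x value / baseline, with a flag marking provisional baselines.

    Returns ``(percent, provisional)``; a provisional percentage must be
    excluded from staging.  Raises if no baseline exists at all.
    """
    if state.baseline is None:
        raise AnalysisError("no baseline established yet")
    if state.baseline <= 0:
        raise AnalysisError("baseline must be positive")
    return 100.0 * value / state.baseline, state.provisional


@dataclass(frozen=True)
class VisitRecord:
    """One patient-visit with raw values and both normalised scales."""

    patient_id: str
    months_post_tx: float
    values: Mapping[str, float]
    pct_predicted: Mapping[str, float] = field(default_factory=dict)
    pct_baseline: Mapping[str, float] = field(default_factory=dict)
    baseline_provisional: Mapping[str, bool] = field(default_factory=dict)


def normalize_timeline(
    timeline,
    refset: ReferenceSet | None = None,
    min_separation_weeks: float = 3.0,
    earliest_months: float = 4.5,
) -> pd.DataFrame:
    """Normalise one patient timeline onto both scales.

    ``timeline`` is any object with ``patient_id``, ``sex``, ``age_years``,
    ``height_cm`` and a ``visits`` DataFrame (index months, one column per
    variable).  Returns a long DataFrame with columns ``patient_id``,
    ``months_post_tx``, ``variable``, ``value``, ``pct_predicted``,
    ``pct_baseline``, ``provisional``.  The baseline used at each visit
    includes that visit's own value (the "latest baseline").
    """
    refset = refset or ReferenceSet.default()
    demo = {
        "sex": timeline.sex,
        "age_years": timeline.age_years,
        "height_cm": timeline.height_cm,
    }
    states: dict[str, BaselineState] = {
        var: BaselineState(
            min_separation_weeks=min_separation_weeks, earliest_months=earliest_months
        )
        for var in timeline.visits.columns
    }
    rows = []
    for months, visit in timeline.visits.sort_index().iterrows():
        for var in timeline.visits.columns:
            value = visit[var]
            if pd.isna(value):
                continue
            states[var] = states[var].updated(float(months), float(value))
            pct_pred = percent_predicted(float(value), var, demo, refset)
            if states[var].baseline is not None:
                pct_base, provisional = percent_of_baseline(float(value), states[var])
            else:
                pct_base, provisional = np.nan, True
            rows.append(
                {
                    "patient_id": timeline.patient_id,
                    "months_post_tx": float(months),
                    "variable": var,
                    "value": float(value),
                    "pct_predicted": pct_pred,
                    "pct_baseline": pct_base,
                    "provisional": bool(provisional),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "months_post_tx",
            "variable",
            "value",
            "pct_predicted",
            "pct_baseline",
            "provisional",
        ],
    )
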