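"""Seeded synthetic cohorts and synthetic washout tracings.

Real follow-up data for double lung transplant recipients are not
redistributable, so every downstream stage of the pipeline is exercised on
synthetic cohorts with the longitudinal structure the analysis assumes:

* a fixed visit schedule (default 1, 2, 3, 4.5, 6, 9, 12, 18, 24, 36 months
  post transplantation);
* most patients stable, fluctuating around a personal plateau for each
  lung-function variable;
* a subset destined for bronchiolitis obliterans syndrome (BOS), whose FEV1
  declines past 80 % of baseline at an assigned onset visit and keeps
  deteriorating, and whose N2-slope starts rising a configurable lead time
  *before* the FEV1 decline;
* a small group ending follow-up with an unconfirmed 10-19 % FEV1 fall
  (terminal "potential BOS", outcome unresolved);
* deaths/dropout truncating some timelines.

The trajectory model is deliberately the simplest one reproducing that
qualitative structure: piecewise-constant-then-linear decline on FEV1 as a
fraction of the patient's true plateau, a multiplicative N2-slope rise, and
lognormal measurement noise (lung-function variability is relative).
Multi-compartment gas-mixing physiology is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .normalization import ReferenceSet
from .tracing import WashoutTracing

__all__ = [
    "VARIABLES",
    "CohortConfig",
    "TracingParams",
    "PatientTimeline",
    "SyntheticCohort",
    "generate_cohort",
    "generate_washout_tracing",
]

#: Lung-function variables carried by a visit table.  Units: litres BTPS for
#: the volumes, mmol.min-1.kPa-1 for CO uptake, %N2 per litre for the slope.
VARIABLES = ("fev1", "fvc", "tlc", "frc", "rv", "co_uptake", "n2_slope")

# Personal plateau as a typical fraction of predicted normal, emulating the
# post-transplant state (reduced CO uptake, roughly doubled N2-slope), and
# the between-patient lognormal spread of that fraction.
_PLATEAU_FRACTION = {
    "fev1": 0.85,
    "fvc": 0.80,
    "tlc": 0.88,
    "frc": 0.90,
    "rv": 1.00,
    "co_uptake": 0.55,
    "n2_slope": 2.00,
}
_PLATEAU_SIGMA = {
    "fev1": 0.12,
    "fvc": 0.12,
    "tlc": 0.10,
    "frc": 0.12,
    "rv": 0.15,
    "co_uptake": 0.15,
    "n2_slope": 0.50,
}

#: Default per-visit probability that a measurement is missing; emulates the
#: unequal measurement counts across variables seen in practice (washout
#: tracings are obtained less often than spirometry).
_DEFAULT_MISSING = {
    "n2_slope": 0.12,
    "tlc": 0.07,
    "frc": 0.07,
    "rv": 0.07,
    "co_uptake": 0.05,
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic transplant cohort.

    ``fraction_bos`` of the patients progress to BOS at an onset drawn from
    the scheduled visits inside ``bos_onset_range``;
    ``fraction_terminal_bos0p`` end follow-up with an unconfirmed 81-90 %
    value at the final visit; the rest are stable.
    ``n2_lead_time_months`` is the mean lead by which the N2-slope rise
    precedes the FEV1-defined onset.  ``measurement_cv`` is the relative
    within-patient measurement noise, a scalar or a per-variable mapping;
    variables absent from the mapping default to 5 %.  The washout slope is
    noticeably less repeatable than spirometry, hence its larger default.  ``fraction_prodrome`` of BOS patients
    pass through the 81-90 % band at the visit before onset (a detectable
    potential-BOS stage); it only applies when onset is late enough for the
    baseline to be established first.
    """

    n_patients: int = 61
    visit_schedule: tuple[float, ...] = (1, 2, 3, 4.5, 6, 9, 12, 18, 24, 36)
    fraction_bos: float = 15 / 61
    fraction_terminal_bos0p: float = 3 / 61
    bos_onset_range: tuple[float, float] = (9.0, 24.0)
    n2_lead_time_months: float = 6.0
    measurement_cv: float | Mapping[str, float] = field(
        default_factory=lambda: {"n2_slope": 0.15}
    )
    missing_prob: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_MISSING))
    dropout_hazard: float = 0.015
    fraction_prodrome: float = 4 / 15
    n2_onset_factor: float = 3.0
    n2_max_factor: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if len(self.visit_schedule) == 0:
            raise ConfigurationError("visit_schedule must not be empty")
        sched = tuple(float(m) for m in self.visit_schedule)
        if any(b <= a for a, b in zip(sched, sched[1:])):
            raise ConfigurationError("visit_schedule must be strictly increasing")
        object.__setattr__(self, "visit_schedule", sched)
        for name in ("fraction_bos", "fraction_terminal_bos0p", "dropout_hazard", "fraction_prodrome"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {val}")
        if self.fraction_bos + self.fraction_terminal_bos0p > 1.0 + 1e-12:
            raise ConfigurationError("fraction_bos + fraction_terminal_bos0p must be <= 1")
        if self.n2_lead_time_months <= 0:
            raise ConfigurationError("n2_lead_time_months must be positive")

    def cv_for(self, variable: str) -> float:
        if isinstance(self.measurement_cv, Mapping):
            return float(self.measurement_cv.get(variable, 0.05))
        return float(self.measurement_cv)


@dataclass(frozen=True)
class TracingParams:
    """Waveform parameters of one synthetic single-breath washout tracing.

    ``closing_volume`` is measured upward from residual volume, so the
    closing point sits at expired volume ``vital_capacity - closing_volume``.
    ``n2_start`` is the concentration at the onset of the alveolar plateau.
    """

    vital_capacity: float = 4.5  # L BTPS
    tlc: float = 6.0  # L BTPS
    dead_space: float = 0.15  # L
    phase3_slope: float = 1.5  # %N2 per L
    closing_volume: float = 0.9  # L above RV
    phase4_slope: float = 8.0  # %N2 per L
    n2_start: float = 25.0  # % at plateau onset
    noise_sd: float = 0.0  # %N2
    sample_spacing: float = 0.01  # L
    seed: int = 0

    # expired volume over which phase II (the sigmoid front) completes
    _PHASE2_WIDTH = 0.4

    def __post_init__(self) -> None:
        if self.vital_capacity <= 0 or self.sample_spacing <= 0:
            raise ConfigurationError("vital_capacity and sample_spacing must be positive")
        if self.tlc < self.vital_capacity:
            raise ConfigurationError("tlc must be >= vital_capacity")
        if not 0 <= self.dead_space < self.vital_capacity:
            raise ConfigurationError("dead_space must lie in [0, vital_capacity)")
        if not 0 <= self.closing_volume < self.vital_capacity:
            raise ConfigurationError("closing_volume must lie in [0, vital_capacity)")
        if not 0 <= self.phase3_slope <= self.phase4_slope:
            raise ConfigurationError("need 0 <= phase3_slope <= phase4_slope")
        if not 0 < self.n2_start < 100:
            raise ConfigurationError("n2_start must lie in (0, 100) %")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        plateau_start = self.dead_space + self._PHASE2_WIDTH
        closing_point = self.vital_capacity - self.closing_volume
        if closing_point <= plateau_start:
            raise ConfigurationError(
                "closing point falls before the alveolar plateau begins "
                f"({closing_point:.3f} <= {plateau_start:.3f} L expired)"
            )


@dataclass
class PatientTimeline:
    """One patient's longitudinal lung-function record."""

    patient_id: str
    sex: str  # "M" | "F"
    age_years: float
    height_cm: float
    visits: pd.DataFrame  # index: months_post_tx; columns: VARIABLES (NaN = missing)

    @property
    def months(self) -> np.ndarray:
        return self.visits.index.to_numpy()


@dataclass
class SyntheticCohort:
    """Generated timelines plus the ground-truth sidecar used in recovery tests."""

    timelines: list[PatientTimeline]
    truth: pd.DataFrame  # patient_id, group, bos_onset_months, n2_rise_start_months,
    #                       prodrome, last_visit_month
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.timelines)


def _fev1_trajectory(schedule: np.ndarray, onset: float, prodrome: bool) -> np.ndarray:
    """FEV1 as a fraction of the personal plateau for a BOS-destined patient.

    1.0 until the decline starts, 0.88 at the prodrome visit (if any), 0.75
    at onset, then a further 0.10 per visit down to a floor of 0.40 -- the
    typical deepening from stage 1 through stage 3.
    """
    frac = np.ones_like(schedule, dtype=float)
    onset_idx = int(np.nonzero(schedule == onset)[0][0])
    if prodrome and onset_idx >= 1:
        frac[onset_idx - 1] = 0.88  # centred in the 81-90 % band once noise is added
    for j in range(onset_idx, len(schedule)):
        frac[j] = max(0.40, 0.75 - 0.10 * (j - onset_idx))
    return frac


def _n2_trajectory(
    schedule: np.ndarray, onset: float, lead: float, onset_factor: float, max_factor: float
) -> np.ndarray:
    """Multiplicative N2-slope rise starting ``lead`` months before onset."""
    rise_start = onset - lead
    rate = (onset_factor - 1.0) / lead  # per month
    factor = 1.0 + np.maximum(0.0, schedule - rise_start) * rate
    return np.minimum(factor, max_factor)


def generate_cohort(config: CohortConfig, refset: ReferenceSet | None = None) -> SyntheticCohort:
    """Generate a seeded synthetic cohort.

    Identical ``config`` (including seed) gives a bit-identical cohort.  Each
    patient draws from an independent random stream, so changing a trajectory
    parameter (e.g. the N2 lead time) alters no random draw of any patient.
    """
    refset = refset or ReferenceSet.default()
    schedule = np.asarray(config.visit_schedule, dtype=float)
    n = config.n_patients

    n_bos = int(round(config.fraction_bos * n))
    n_term = int(round(config.fraction_terminal_bos0p * n))
    if n_bos + n_term > n:
        raise ConfigurationError("rounded group sizes exceed n_patients")

    eligible_onsets = [
        m
        for i, m in enumerate(schedule)
        if config.bos_onset_range[0] <= m <= config.bos_onset_range[1] and i < len(schedule) - 1
    ]
    if n_bos > 0:
        if not eligible_onsets:
            raise ConfigurationError(
                "no scheduled visit inside bos_onset_range (excluding the final visit)"
            )
        for m in eligible_onsets:
            prior = [t for t in schedule if 4.5 <= t < m]
            if len(prior) < 2:
                raise ConfigurationError(
                    f"onset at {m} months leaves fewer than two baseline visits"
                )

    root = np.random.SeedSequence(config.seed)
    cohort_ss, *patient_ss = root.spawn(n + 1)
    cohort_rng = np.random.default_rng(cohort_ss)

    # cohort-level draws happen before and independently of per-patient ones
    onsets = (
        cohort_rng.choice(eligible_onsets, size=n_bos) if n_bos else np.empty(0)
    )
    prodrome_draws = cohort_rng.random(n_bos) < config.fraction_prodrome

    timelines: list[PatientTimeline] = []
    truth_rows: list[dict] = []
    n_visits = len(schedule)

    for i in range(n):
        rng = np.random.default_rng(patient_ss[i])
        pid = f"P{i + 1:03d}"

        # demographics (exercise the percent-predicted machinery only)
        sex = "M" if rng.random() < 0.5 else "F"
        age = float(rng.uniform(18.0, 60.0))
        height = float(rng.normal(178.0, 7.0) if sex == "M" else rng.normal(165.0, 6.0))
        height = float(np.clip(height, 150.0, 198.0))

        # personal plateaus around predicted normal
        plateau_z = rng.standard_normal(len(VARIABLES))
        plateaus = {}
        for j, var in enumerate(VARIABLES):
            pred = refset.predicted(var, sex, age, height)
            plateaus[var] = pred * _PLATEAU_FRACTION[var] * float(
                np.exp(_PLATEAU_SIGMA[var] * plateau_z[j])
            )

        # noise and missingness drawn up front, independent of group/parameters
        noise_z = rng.standard_normal((n_visits, len(VARIABLES)))
        miss_u = rng.random((n_visits, len(VARIABLES)))
        dropout_u = rng.random(n_visits)

        if i < n_bos:
            group = "bos"
            onset = float(onsets[i])
            onset_idx = int(np.nonzero(schedule == onset)[0][0])
            # a prodrome needs a pre-onset visit after the baseline window
            prodrome = bool(prodrome_draws[i]) and schedule[onset_idx - 1] >= 9.0
            fev1_frac = _fev1_trajectory(schedule, onset, prodrome)
            n2_frac = _n2_trajectory(
                schedule,
                onset,
                config.n2_lead_time_months,
                config.n2_onset_factor,
                config.n2_max_factor,
            )
            fvc_frac = np.array(
                [max(0.65, 1.0 - 0.06 * (j - onset_idx + 1)) if j >= onset_idx else 1.0
                 for j in range(n_visits)]
            )
            rv_frac = np.array(
                [min(1.5, 1.0 + 0.15 * (j - onset_idx)) if j >= onset_idx else 1.0
                 for j in range(n_visits)]
            )
            co_frac = np.array(
                [max(0.80, 1.0 - 0.04 * (j - onset_idx)) if j >= onset_idx else 1.0
                 for j in range(n_visits)]
            )
            n2_rise_start = onset - config.n2_lead_time_months
        elif i < n_bos + n_term:
            group = "terminal_bos0p"
            onset = np.nan
            prodrome = False
            fev1_frac = np.ones(n_visits)
            fev1_frac[-1] = 0.87  # inside the 81-90 % band, final visit only
            n2_frac = np.ones(n_visits)
            fvc_frac = rv_frac = co_frac = np.ones(n_visits)
            n2_rise_start = np.nan
        else:
            group = "stable"
            onset = np.nan
            prodrome = False
            fev1_frac = n2_frac = fvc_frac = rv_frac = co_frac = np.ones(n_visits)
            n2_rise_start = np.nan

        traj = {
            "fev1": fev1_frac,
            "fvc": fvc_frac,
            "tlc": np.ones(n_visits),
            "frc": np.ones(n_visits),
            "rv": rv_frac,
            "co_uptake": co_frac,
            "n2_slope": n2_frac,
        }

        values = np.empty((n_visits, len(VARIABLES)))
        for j, var in enumerate(VARIABLES):
            cv = config.cv_for(var)
            sigma = float(np.sqrt(np.log1p(cv**2)))  # lognormal with the requested CV
            noise = np.exp(sigma * noise_z[:, j]) if sigma > 0 else np.ones(n_visits)
            values[:, j] = plateaus[var] * traj[var] * noise
            miss = miss_u[:, j] < config.missing_prob.get(var, 0.0)
            values[miss, j] = np.nan

        # dropout: never before a BOS patient's onset is confirmable, never
        # for terminal potential-BOS patients (they need their final visit)
        last_idx = n_visits - 1
        if config.dropout_hazard > 0 and group != "terminal_bos0p":
            if group == "bos":
                at_risk_from = int(np.nonzero(schedule == onset)[0][0]) + 2
            else:
                at_risk_from = int(np.searchsorted(schedule, 12.0, side="right"))
            for j in range(at_risk_from, n_visits):
                if dropout_u[j] < config.dropout_hazard:
                    last_idx = j
                    break

        visits = pd.DataFrame(
            values[: last_idx + 1], index=schedule[: last_idx + 1], columns=list(VARIABLES)
        )
        visits.index.name = "months_post_tx"
        timelines.append(
            PatientTimeline(
                patient_id=pid, sex=sex, age_years=age, height_cm=height, visits=visits
            )
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "group": group,
                "bos_onset_months": onset,
                "n2_rise_start_months": n2_rise_start,
                "prodrome": prodrome,
                "last_visit_month": float(schedule[last_idx]),
            }
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id",
            "group",
            "bos_onset_months",
            "n2_rise_start_months",
            "prodrome",
            "last_visit_month",
        ],
    )
    return SyntheticCohort(timelines=timelines, truth=truth, config=config)


def generate_washout_tracing(params: TracingParams) -> WashoutTracing:
    """Synthesise one single-breath washout tracing.

    Piecewise construction over expired volume 0..VC: ~0 % N2 over the dead
    space (phase I), a raised-cosine sigmoid front (phase II), a linear
    alveolar plateau with ``phase3_slope`` (phase III), and a steeper linear
    rise with ``phase4_slope`` from the closing point (phase IV).  Beyond
    phase II the noiseless curve is exactly piecewise linear, which is what
    makes closed-form slope-recovery checks possible.
    """
    v = np.arange(0.0, params.vital_capacity + params.sample_spacing / 2, params.sample_spacing)
    ds = params.dead_space
    p3_start = ds + params._PHASE2_WIDTH
    closing_point = params.vital_capacity - params.closing_volume

    c = np.zeros_like(v)
    front = (v >= ds) & (v < p3_start)
    c[front] = params.n2_start * 0.5 * (1.0 - np.cos(np.pi * (v[front] - ds) / (p3_start - ds)))
    plateau = v >= p3_start
    c[plateau] = params.n2_start + params.phase3_slope * (v[plateau] - p3_start)
    c += np.maximum(0.0, v - closing_point) * (params.phase4_slope - params.phase3_slope)

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        c = c + rng.normal(0.0, params.noise_sd, size=c.shape)
    c = np.clip(c, 0.0, 100.0)

    return WashoutTracing(
        expired_volume=v, n2=c, vital_capacity=params.vital_capacity, tlc=params.tlc
    )
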