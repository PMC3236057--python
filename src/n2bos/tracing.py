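"""Phase-III (alveolar) slope extraction from single-breath nitrogen washout tracings.

A single-breath N2 washout starts with a vital-capacity inhalation of pure
oxygen to total lung capacity (TLC) followed by a slow full expiration while
expired N2 concentration is recorded against expired volume.  The tracing
shows four classical phases: dead-space gas (I), a sigmoid transition (II),
the alveolar plateau (III) whose slope indexes ventilation-distribution
inhomogeneity, and a steep terminal rise (IV) beyond the closing point where
dependent airways close.

The slope algorithm implemented here is deliberately mechanical so that no
reader judgement enters the result: the analysis window runs from a fixed
proximal offset (default 0.825 L of expired volume, i.e. lung volume
TLC - 0.825 L BTPS) to the closing point; the closing point itself is found
by exhaustive two-segment piecewise-linear least squares; and the reported
slope is the difference in N2 concentration between the closing point and
the proximal end of the window, read off a least-squares line fitted over
the window, divided by the corresponding volume.  On a noiseless piecewise
linear tracing this reduces exactly to the true phase-III slope.

Volume convention: the volume axis is *expired* volume in litres BTPS, zero
at the start of expiration (TLC); lung volume = TLC - expired volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import AnalysisError, ConfigurationError, ValidationError

__all__ = [
    "WashoutTracing",
    "SlopeConfig",
    "SlopeResult",
    "detect_closing_point",
    "compute_n2_slope",
    "average_recordings",
    "read_tracing",
    "write_tracing",
]


@dataclass(frozen=True)
class WashoutTracing:
    """Sampled expired-volume vs. N2-concentration curve of one manoeuvre.

    Parameters
    ----------
    expired_volume : array of float
        Expired volume in L BTPS, strictly increasing from ~0.
    n2 : array of float
        N2 concentration in %, same length, within [0, 100].
    vital_capacity : float
        Expired vital capacity in L BTPS.
    tlc : float, optional
        Total lung capacity in L BTPS.  Only used for reporting; the
        analysis window is defined on the expired-volume axis, which is
        anchored at TLC whether or not TLC itself is known.
    """

    expired_volume: np.ndarray
    n2: np.ndarray
    vital_capacity: float
    tlc: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.expired_volume, dtype=float)
        c = np.asarray(self.n2, dtype=float)
        object.__setattr__(self, "expired_volume", v)
        object.__setattr__(self, "n2", c)
        if v.ndim != 1 or v.shape != c.shape:
            raise ValidationError("expired_volume and n2 must be 1-D arrays of equal length")
        if len(v) >= 2 and not np.all(np.diff(v) > 0):
            raise ValidationError("expired_volume must be strictly increasing")
        if len(c) and (c.min() < 0.0 or c.max() > 100.0):
            raise ValidationError("n2 concentrations must lie within [0, 100] %")
        if not self.vital_capacity > 0:
            raise ValidationError("vital_capacity must be positive")

    def __len__(self) -> int:
        return len(self.expired_volume)


@dataclass(frozen=True)
class SlopeConfig:
    """Settings of the slope algorithm.

    ``proximal_offset`` is the expired volume (L BTPS) at which the analysis
    window starts, i.e. lung volume TLC minus that offset; the default
    0.825 L clears the dead space and phase II.  ``closing_detection``
    selects the breakpoint method ("two_segment" is the only built-in).
    A phase IV is declared only when the distal segment is steeper than the
    proximal one by both the multiplicative ``phase4_factor`` and the
    additive ``min_slope_excess`` (%N2/L), which suppresses spurious
    breakpoints on noisy plateaus without a real terminal rise.
    """

    proximal_offset: float = 0.825
    closing_detection: str = "two_segment"
    min_window: float = 0.5
    breakpoint_tolerance: float = 0.05
    phase4_factor: float = 2.0
    min_slope_excess: float = 0.5

    def __post_init__(self) -> None:
        if not self.proximal_offset > 0:
            raise ConfigurationError("proximal_offset must be positive")
        if self.closing_detection != "two_segment":
            raise ConfigurationError(
                f"unknown closing_detection method {self.closing_detection!r}"
            )
        if self.min_window <= 0:
            raise ConfigurationError("min_window must be positive")


@dataclass(frozen=True)
class SlopeResult:
    """Alveolar slope of one (or the average of several) washout recordings."""

    slope: float  # %N2 per L
    closing_point_volume: float  # L expired
    window: tuple[float, float]  # (start, end) L expired
    n_samples_used: int
    n_recordings: int = 1


def _fit_line(v: np.ndarray, c: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line c = a*v + b; returns (slope, intercept, rss)."""
    if len(v) < 2:
        raise AnalysisError("need at least 2 samples for a line fit")
    vm = v.mean()
    cm = c.mean()
    dv = v - vm
    denom = float(dv @ dv)
    if denom == 0.0:
        raise AnalysisError("degenerate volume axis in fit window")
    a = float(dv @ (c - cm)) / denom
    b = cm - a * vm
    resid = c - (a * v + b)
    return a, b, float(resid @ resid)


def _window_samples(tracing: WashoutTracing, config: SlopeConfig) -> tuple[np.ndarray, np.ndarray]:
    mask = tracing.expired_volume >= config.proximal_offset
    v = tracing.expired_volume[mask]
    c = tracing.n2[mask]
    if len(v) < 4:
        raise AnalysisError(
            f"only {len(v)} samples beyond the proximal offset "
            f"({config.proximal_offset} L); need >= 4"
        )
    if v[-1] - v[0] < config.min_window:
        raise AnalysisError(
            f"analysis window {v[-1] - v[0]:.3f} L shorter than min_window "
            f"{config.min_window} L (tracing truncated?)"
        )
    return v, c


def detect_closing_point(tracing: WashoutTracing, config: SlopeConfig | None = None) -> float:
    """Locate the closing point (phase IV onset) as an expired volume in L.

    Runs an exhaustive two-segment piecewise-linear least-squares scan over
    the analysis window: every admissible split of the samples into a
    proximal and a distal segment (each with >= 2 points) is fitted with two
    independent lines and the split minimising the total residual sum of
    squares is taken.  A phase IV is declared only if the distal slope
    exceeds the proximal slope by the configured factor and absolute excess;
    otherwise the end of expiration (``vital_capacity``) is returned,
    meaning "no detectable closing point".
    """
    config = config or SlopeConfig()
    v, c = _window_samples(tracing, config)
    n = len(v)

    best_rss = np.inf
    best_k = None
    for k in range(2, n - 1):  # distal segment starts at index k
        # the proximal segment must span a usable phase-III window,
        # otherwise a 2-point "plateau" fit is pure noise
        if v[k] - v[0] < config.min_window:
            continue
        _, _, rss_p = _fit_line(v[:k], c[:k])
        _, _, rss_d = _fit_line(v[k:], c[k:])
        rss = rss_p + rss_d
        if rss < best_rss - 1e-15:
            best_rss = rss
            best_k = k
    if best_k is None:
        return tracing.vital_capacity

    slope_p, _, _ = _fit_line(v[:best_k], c[:best_k])
    slope_d, _, _ = _fit_line(v[best_k:], c[best_k:])
    has_phase4 = (
        slope_d > config.phase4_factor * max(slope_p, 0.0)
        and slope_d - slope_p > config.min_slope_excess
    )
    if not has_phase4:
        return tracing.vital_capacity
    return float(v[best_k])


def compute_n2_slope(tracing: WashoutTracing, config: SlopeConfig | None = None) -> SlopeResult:
    """Alveolar (phase III) N2 slope in %N2 per litre.

    The slope is the difference in N2 concentration between the closing
    point and the proximal end of the window (lung volume TLC minus
    ``proximal_offset``) divided by the corresponding volume difference.
    Both endpoint concentrations are read off the least-squares line fitted
    over the window, so the ratio equals the fitted slope; on noiseless
    data this is exact, on noisy data it is robust to single-sample error.
    """
    config = config or SlopeConfig()
    closing = detect_closing_point(tracing, config)
    if closing - config.proximal_offset <= 0:
        raise AnalysisError(
            f"closing point ({closing:.3f} L) does not exceed the proximal "
            f"offset ({config.proximal_offset} L)"
        )
    mask = (tracing.expired_volume >= config.proximal_offset) & (
        tracing.expired_volume <= closing + 1e-12
    )
    v = tracing.expired_volume[mask]
    c = tracing.n2[mask]
    if len(v) < 2:
        raise AnalysisError("fewer than 2 samples in the phase-III window")
    slope, _, _ = _fit_line(v, c)
    return SlopeResult(
        slope=slope,
        closing_point_volume=closing,
        window=(float(v[0]), float(v[-1])),
        n_samples_used=len(v),
    )


def average_recordings(results: Sequence[SlopeResult] | Iterable[SlopeResult]) -> SlopeResult:
    """Arithmetic mean of the slopes of several acceptable recordings.

    Duplicate manoeuvres are routinely recorded and their average used for
    analysis; the window and closing point of the first recording are
    retained for reporting.
    """
    results = list(results)
    if not results:
        raise AnalysisError("no recordings to average")
    first = results[0]
    return SlopeResult(
        slope=float(np.mean([r.slope for r in results])),
        closing_point_volume=first.closing_point_volume,
        window=first.window,
        n_samples_used=first.n_samples_used,
        n_recordings=len(results),
    )


# -- tracing text format ----------------------------------------------------
#
# Two numeric columns (expired_volume_L, n2_percent) preceded by a single
# metadata header line of key=value pairs, e.g.
#   # vc=4.500000 tlc=6.000000 sample_spacing=0.010000


def write_tracing(tracing: WashoutTracing, path: str | Path) -> None:
    path = Path(path)
    meta = f"# vc={tracing.vital_capacity:.6g}"
    if tracing.tlc is not None:
        meta += f" tlc={tracing.tlc:.6g}"
    if len(tracing) >= 2:
        meta += f" sample_spacing={tracing.expired_volume[1] - tracing.expired_volume[0]:.6g}"
    lines = [meta, "expired_volume_L\tn2_percent"]
    for v, c in zip(tracing.expired_volume, tracing.n2):
        lines.append(f"{v:.6f}\t{c:.6f}")
    path.write_text("\n".join(lines) + "\n")


def read_tracing(path: str | Path) -> WashoutTracing:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValidationError(f"{path}: missing metadata header line")
    meta: dict[str, float] = {}
    for token in lines[0].lstrip("#").split():
        key, _, val = token.partition("=")
        meta[key] = float(val)
    if "vc" not in meta:
        raise ValidationError(f"{path}: header must record vc=<vital capacity>")
    data = np.loadtxt(lines[2:], delimiter="\t", ndmin=2)
    return WashoutTracing(
        expired_volume=data[:, 0],
        n2=data[:, 1],
        vital_capacity=meta["vc"],
        tlc=meta.get("tlc"),
    )
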