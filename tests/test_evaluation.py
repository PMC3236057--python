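"""Cut-off calibration, contingency counts, operating characteristics."""

import numpy as np
import pandas as pd
import pytest

from n2bos import (
    AnalysisError,
    Bos0pPredictorStats,
    ContingencyCounts,
    CutoffSpec,
    PatientOutcome,
    bos0p_predictor_stats,
    calibrate_cutoff,
    is_abnormal,
    operating_characteristics,
    tabulate_counts,
)
from n2bos._util import round_half_up


def test_round_half_up():
    assert round_half_up(54.5) == 55
    assert round_half_up(99.6) == 100
    assert round_half_up(26.67) == 27
    assert round_half_up(43.4) == 43


@pytest.mark.parametrize("direction", ["greater", "less"])
def test_calibration_on_1_to_100(direction):
    """A 95 % target on the pool 1..100 leaves exactly 5 values abnormal."""
    values = np.arange(1.0, 101.0)
    spec = calibrate_cutoff(values, "n2_slope", "pct_predicted", direction)
    abnormal = is_abnormal(values, spec)
    assert abnormal.sum() == 5
    expected_tail = values[-5:] if direction == "greater" else values[:5]
    assert set(values[abnormal]) == set(expected_tail)


def test_calibration_degenerate_pool():
    values = np.full(20, 7.0)
    spec = calibrate_cutoff(values, "n2_slope", "pct_predicted", "greater")
    assert spec.value >= 7.0
    assert is_abnormal(values, spec).sum() == 0


def test_calibration_small_pool_warns():
    with pytest.warns(UserWarning, match="unstable"):
        calibrate_cutoff(np.arange(1.0, 11.0), "fev1", "pct_predicted", "less")


def test_calibration_empty_pool_raises():
    with pytest.raises(AnalysisError):
        calibrate_cutoff(np.array([]), "fev1", "pct_predicted", "less")


@pytest.mark.parametrize("n", [50, 500, 5000])
@pytest.mark.parametrize("direction", ["greater", "less"])
def test_calibration_self_consistency(n, direction):
    """Applying a calibrated cut-off to its own pool gives specificity in
    [target, target + 100/n]."""
    rng = np.random.default_rng(n)
    values = rng.lognormal(mean=5.0, sigma=0.4, size=n)
    spec = calibrate_cutoff(values, "n2_slope", "pct_predicted", direction, 95.0)
    specificity = 100.0 * (~is_abnormal(values, spec)).mean()
    assert 95.0 - 1e-9 <= specificity <= 95.0 + 100.0 / n + 1e-9


def _analysis_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "months_post_tx", "variable",
            "pct_baseline", "pct_predicted", "provisional", "diagnostic_state",
        ],
    )


def test_tabulate_counts_perfect_separation():
    rows = []
    for m in (6, 9, 12):
        rows.append(("A", m, "fev1", 100.0, 90.0, False, "NoBOS"))
        rows.append(("B", m, "fev1", 60.0, 50.0, False, "BOS"))
    cutoff = CutoffSpec("fev1", "pct_baseline", "less", 90.0)
    counts = tabulate_counts(_analysis_frame(rows), cutoff)
    assert (counts.nobos_normal, counts.nobos_abnormal) == (3, 0)
    assert (counts.bos_normal, counts.bos_abnormal) == (0, 3)
    assert (counts.bos0p_normal, counts.bos0p_abnormal) == (0, 0)


def test_tabulate_counts_window_exclusions_and_provisional():
    rows = [
        ("A", 3.0, "fev1", 85.0, 80.0, False, "NoBOS"),   # before window
        ("A", 6.0, "fev1", 85.0, 80.0, True, "NoBOS"),    # provisional baseline
        ("A", 9.0, "fev1", 85.0, 80.0, False, "NoBOS"),
        ("C", 9.0, "fev1", 70.0, 60.0, False, "BOS"),     # excluded patient
    ]
    cutoff = CutoffSpec("fev1", "pct_baseline", "less", 90.0)
    counts = tabulate_counts(_analysis_frame(rows), cutoff, excluded_patients={"C"})
    assert counts.total == 1 and counts.nobos_abnormal == 1
    empty = tabulate_counts(_analysis_frame(rows), cutoff, window=(40.0, 50.0))
    assert empty.total == 0


def test_tabulate_matches_direct_reclassification(default_analysis):
    """Vectorised binning equals a plain per-row loop on a real cohort."""
    cutoff = CutoffSpec("n2_slope", "pct_predicted", "greater", 400.0)
    excluded = default_analysis.excluded_patients
    counts = tabulate_counts(default_analysis.analysis, cutoff, (6.0, 36.0), excluded)
    tally = {}
    for _, r in default_analysis.analysis.iterrows():
        if (
            r["variable"] != "n2_slope"
            or not 6.0 <= r["months_post_tx"] <= 36.0
            or r["patient_id"] in excluded
            or pd.isna(r["pct_predicted"])
        ):
            continue
        key = (r["diagnostic_state"], r["pct_predicted"] > 400.0)
        tally[key] = tally.get(key, 0) + 1
    assert counts.nobos_abnormal == tally.get(("NoBOS", True), 0)
    assert counts.nobos_normal == tally.get(("NoBOS", False), 0)
    assert counts.bos_abnormal == tally.get(("BOS", True), 0)
    assert counts.bos_normal == tally.get(("BOS", False), 0)
    assert counts.bos0p_abnormal == tally.get(("BOS0p", True), 0)
    assert counts.bos0p_normal == tally.get(("BOS0p", False), 0)


def test_operating_characteristics_perfect_test():
    counts = ContingencyCounts(10, 0, 0, 10, 0, 0)
    oc = operating_characteristics(counts)
    assert oc.specificity == pytest.approx(100.0)
    assert oc.sensitivity_bos == pytest.approx(100.0)
    assert oc.ppv_bos == pytest.approx(100.0)
    assert oc.sensitivity_bos0p is None  # no potential-BOS measurements


def test_operating_characteristics_undefined_denominators():
    oc = operating_characteristics(ContingencyCounts(0, 0, 0, 0, 0, 0))
    assert all(v is None for v in oc.rounded().values())


def test_bos0p_predictor_stats_from_outcomes():
    outcomes = []
    # 4 BOS preceded by potential BOS, 11 BOS not preceded
    for i in range(4):
        outcomes.append(PatientOutcome(f"B{i}", bos_onset=12.0, ever_bos0p=True,
                                       bos0p_before_bos=True))
    for i in range(11):
        outcomes.append(PatientOutcome(f"C{i}", bos_onset=18.0))
    # 43 clean stable, 3 terminal potential BOS
    for i in range(43):
        outcomes.append(PatientOutcome(f"S{i}"))
    for i in range(3):
        outcomes.append(PatientOutcome(f"T{i}", ever_bos0p=True, terminal_bos0p=True))
    stats = bos0p_predictor_stats(outcomes)
    assert stats.n_bos == 15 and stats.n_bos_preceded_by_bos0p == 4
    assert round_half_up(stats.sensitivity) == 27
    assert round_half_up(stats.specificity) == 93
    assert stats.n_bos0p_patients == 7 and stats.n_bos0p_progressed == 4
    assert round_half_up(stats.ppv) == 57
    assert round_half_up(stats.ppv_if_progressed(1)) == 71
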