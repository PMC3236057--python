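# n2bos

Single-breath nitrogen washout analysis for lung-transplant follow-up:
from the raw washout tracing to the alveolar (phase III) N₂-slope, from
longitudinal FEV₁ to bronchiolitis obliterans syndrome (BOS) staging, and
from pooled measurements to specificity-calibrated cut-offs, operating
characteristics and the predictive ability of an abnormal result obtained
*before* diagnosis.

## The problem

Bronchiolitis obliterans — progressive obstruction of the small peripheral
airways — is the main limit on long-term survival after double lung or
heart-lung transplantation. Because transbronchial biopsy is insensitive,
the syndrome is diagnosed functionally: BOS is a sustained fall of FEV₁ to
≤ 80 % of the post-transplant baseline, and "potential BOS" (BOS 0-p) a
sustained fall into the 81–90 % band. By the time FEV₁ has fallen, however,
much of the damage is done. The slope of the alveolar plateau of the
single-breath nitrogen washout (ΔN₂/ΔV over phase III, in %N₂ per litre) is
a sensitive index of ventilation-distribution inhomogeneity in exactly
those peripheral airways, and tends to rise months before FEV₁ declines.
This package implements, as a tested and reusable pipeline, the analysis
that evaluates the N₂-slope as a diagnostic and predictive test for BOS.
It is aimed at clinical-physiology and biostatistics users working with
longitudinal lung-function data.

## What it computes

* **Slope extraction** (`n2bos.tracing`). The analysis window runs from a
  fixed proximal offset (expired volume 0.825 L, i.e. lung volume
  TLC − 0.825 L BTPS) to the closing point, located by exhaustive
  two-segment piecewise-linear least squares. The reported slope is the N₂
  concentration difference between the closing point and the window start,
  read off the fitted line, divided by the corresponding volume — exact on
  noiseless piecewise-linear tracings.
* **Normalisation** (`n2bos.normalization`). Every measurement is expressed
  as percent of predicted normal (configurable reference-equation table)
  and as percent of the *latest baseline*: the mean of the two highest
  values measured ≥ 4.5 months post transplant and ≥ 3 weeks apart,
  recomputed as follow-up accrues.
* **Staging** (`n2bos.staging`). NoBOS > 90 %, BOS 0-p 81–90 %, BOS 1
  66–80 %, BOS 2 51–65 %, BOS 3 ≤ 50 % of baseline FEV₁, each confirmed by
  a second measurement ≥ 3 weeks later; onset is dated at the first
  measurement of the earliest confirmed run at ≤ 80 %.
* **Test evaluation** (`n2bos.evaluation`). Cut-offs calibrated so that
  95 % of pooled stable-patient results are normal; 3 × 2 contingency
  counts by current diagnostic state; sensitivity, specificity, predictive
  values with half-up integer rounding.
* **Prediction** (`n2bos.prediction`). The *predictive ability* of a
  criterion: among abnormal results obtained while the patient is not yet
  diagnosed, the percentage that precede a BOS diagnosis — deliberately
  different from a conventional PPV, which mixes in post-diagnosis results.
  Criteria can be combined (all components abnormal simultaneously).
* **Synthetic cohorts** (`n2bos.synthetic`). Seeded generators for washout
  tracings and for 61-recipient cohorts (visit schedule 1–36 months, ~15
  patients progressing to BOS, 3 ending in unresolved potential BOS,
  N₂-slope rising ~6 months before the FEV₁ decline) so the whole pipeline
  is testable without patient data.

## Worked example

The package ships the printed measurement counts of a published follow-up
study of double lung transplant recipients; all percentages are recomputed
from those counts at run time:

```sh
python examples/04_published_worked_example.py
```

```
operating characteristics (percent, rounded):
criterion                      spec sens BOS sens 0-p      PPV   PPV+0p      NPV   NPV+0p
fev1 % basal < 90                90      100      100       57       61      100      100
fvc % basal < 90                 96       77       17       71       72       97       96
n2_slope % basal > 299           95       52       43       52       57       95       94
fev1 % pred. < 49                95       67        0       63       63       96       94
fvc % pred. < 52                 95       29        0       43       43       92       90
n2_slope % pred. > 478           93       96      100       57       63      100      100

predictive ability of a pre-diagnosis abnormal result:
  fev1        11 of  28 abnormal results precede BOS -> 39 %
  n2_slope    12 of  22 abnormal results precede BOS -> 55 %
  combined     9 of  12 abnormal results precede BOS -> 75 %

potential BOS (0-p) as a patient-level predictor of BOS:
  sensitivity 27 %  specificity 93 %  PPV 57 % (71 % if one unresolved patient progressed)
```

Reading the numbers: the N₂-slope in percent predicted identifies BOS
measurements almost as reliably as the FEV₁ criterion that defines the
syndrome (sensitivity 96 % vs 100 %), and an abnormal N₂-slope seen before
diagnosis heralds BOS more often than an abnormal FEV₁ (55 % vs 39 %);
when both are abnormal simultaneously, three out of four such occasions
precede BOS.

The other examples cover slope extraction from a tracing
(`01_washout_slope.py`), baseline tracking and staging on a hand-written
timeline (`02_baseline_and_staging.py`), cut-off calibration
(`03_cutoff_calibration.py`) and the full pipeline on a synthetic cohort
(`05_synthetic_cohort_report.py`). A thin CLI wraps the same functions:

```sh
n2bos synth --seed 1 --out work/
n2bos report --input work/cohort.tsv --seed 1 --out work/report/
n2bos slope my_tracing.tsv
```

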