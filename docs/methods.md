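# Methods

This note records the models, conventions and design choices behind the
package, in the order data flows through the pipeline.

## Volume convention

All volumes are litres BTPS. The washout volume axis is *expired* volume,
zero at the start of expiration (total lung capacity, TLC); lung volume =
TLC − expired volume. The proximal end of the slope window, stated as lung
volume TLC − 0.825 L, is therefore simply expired volume 0.825 L whether or
not TLC itself was measured.

## Slope extraction

A single-breath N₂ washout is a full expiration after a vital-capacity
inspiration of pure O₂. The alveolar (phase III) slope is computed as the
difference in N₂ concentration between the closing point and the proximal
window start divided by the corresponding volume. Two numerical choices:

* **Closing-point detection.** Exhaustive two-segment piecewise-linear
  least squares over the window: every split into a proximal and a distal
  segment (each ≥ 2 samples, proximal spanning at least `min_window`,
  default 0.5 L) is fitted with two independent lines; the split minimising
  the total residual sum of squares wins. A phase IV is declared only when
  the distal slope exceeds the proximal slope both by a factor (default 2×)
  and by an absolute excess (default 0.5 %N₂/L); otherwise the end of
  expiration is returned ("no detectable closing point"). The factor/excess
  gate suppresses spurious breakpoints on noisy plateaus; the proximal-span
  floor prevents a two-point "plateau" fit that would be pure noise. The
  method is objective and reproducible — no reader judgement enters.
* **Endpoint concentrations from the fitted line, not raw samples.** The
  difference of the fitted line's endpoints divided by the volume equals
  the fitted slope, so the formula is preserved exactly in the noiseless
  limit while being robust to single-sample noise. On noiseless piecewise
  linear tracings recovery is exact to ~1e-15 %N₂/L and the detected
  closing point is within one sample spacing of the true breakpoint; with
  0.2 %N₂ analyser noise the mean estimate over 50 tracings is within a few
  thousandths of the true slope.

Duplicate manoeuvres are averaged arithmetically (`average_recordings`),
retaining the first recording's window for reporting.

The proximal offset (0.825 L) clears the series dead space and the phase II
front; it is configurable, as is the breakpoint method tag, so a different
published detection algorithm can be substituted without API change.

## Normalisation

Percent predicted divides by a sex-specific linear reference equation
(intercept + age + height terms) read from a TSV table. The packaged table
contains *synthetic defaults* — physiologically plausible, invented
coefficients covering ages 18–65 and heights 145–200 cm — because published
reference coefficients are licensed to their sources; laboratories should
substitute their own. No headline result of the package depends on these
coefficients.

The post-transplant baseline of each variable is the mean of the two
highest qualifying values: measured ≥ 4.5 months post transplant and ≥ 3
weeks apart (weeks converted at 365.25/12 days per month). The "latest
baseline" is recomputed at every visit from all eligible visits up to and
including that visit, so the established baseline never decreases. Before
two qualifying visits exist the single highest eligible value is used and
flagged *provisional*; provisional percentages are excluded from staging
and from the evaluation pools. The same pairing rule is applied to every
variable uniformly, including the N₂-slope — for which "two highest" is the
conservative reading, since a rising slope drags its own baseline up and
thereby weakens percent-of-baseline abnormality, a behaviour visible in the
lower sensitivity of the percent-of-baseline N₂ criterion. Visits missing a
variable simply do not update that variable's baseline.

## Staging and onset

Stages are a monotone step function of FEV₁ percent-of-baseline: NoBOS
> 90, BOS 0-p > 80–90, BOS 1 > 65–80, BOS 2 > 50–65, BOS 3 ≤ 50. The bands
are conventionally written as integer ranges (81–90, 66–80, ...); on the
continuous scale each band extends down to just above the next bound so the
function has no gaps. A potential-BOS value is confirmed when the *next*
measurement ≥ 3 weeks later is also ≤ 90 %; a ≤ 80 % value when the next
measurement ≥ 3 weeks later is also ≤ 80 % — the substage may deepen within
the pair, since onset is defined by crossing 80 %. Onset is dated at the
first measurement of the earliest confirmed run (switchable to the
confirming measurement, `onset_dating="confirming"`). An unconfirmed
qualifying value at the final visit yields terminal flags instead of an
onset; patients ending follow-up in unresolved potential BOS are excluded
from the evaluation and prediction pools, and the per-visit FEF₂₅–₇₅
criterion of the staging system is not used.

## Cut-off calibration and operating characteristics

Calibrated cut-offs use the pooled in-window (6–36 months) measurements of
the *stable* patients (never BOS, never potential BOS). The cut-off is the
inverted-CDF order statistic: the smallest observed value with at least the
target fraction (default 95 %) of the pool at or below it (mirrored for
abnormal-if-less). Abnormality is a strict inequality beyond the cut-off,
so borderline values count as normal and the realised pool specificity
always lies in [target, target + 100/n]. Linear-interpolation quantiles
were rejected because they can leave the pool specificity *below* the
target for small pools. The FEV₁ < 90 %-of-baseline criterion is fixed, not
calibrated — it is the definition of potential BOS — which is why its
specificity on a NoBOS pool is ~90 % rather than 95 %. Calibration warns
below 20 pool values.

Measurements are binned by the patient's *current* diagnostic state:
pre-onset visits of eventual BOS patients count as NoBOS, and potential-BOS
visits of eventual BOS patients stay in the 0-p column (current-state
binning). The evaluation pool (all non-excluded patients' NoBOS visits) is
a superset of the calibration pool (stable patients only), so tabulated
specificity can differ from the calibration target. Of the 3 × 2 table, the
BOS-only predictive values contrast BOS with NoBOS measurements — the
potential-BOS column enters only the "+ BOS 0-p" variants — and all
reported percentages are rounded half-up to integers (raw values retained;
an undefined denominator yields an absent metric, never 0).

## Predictive ability

For each criterion, the pool is every measurement occasion inside the
prediction window (default 6–24 months) at which the patient is not yet
diagnosed with BOS and *all* components of the criterion are evaluable; an
occasion with any missing component is dropped entirely (both tests must be
abnormal *simultaneously*, so both must exist — this is why the combined
pool is smaller than the FEV₁ pool). The predictive value is the percentage
of abnormal occasions whose patient's onset lies strictly later, within
observed follow-up. The companion histogram keys abnormal occasions by
visit month; its totals equal the criterion's counts by construction.

## Synthetic data

The cohort generator emulates the longitudinal *structure* of a transplant
follow-up programme, not gas-mixing physiology. Defaults: 61 patients,
visits at 1, 2, 3, 4.5, 6, 9, 12, 18, 24 and 36 months, 15/61 progressing
to BOS with onsets on scheduled visits between 9 and 24 months, 3/61 ending
in unresolved potential BOS at the final visit, N₂-slope rise starting 6
months before onset, and per-visit dropout hazard 1.5 % (producing a
handful of deaths over three years). Each patient has a personal plateau
per variable (a lognormal multiple of predicted normal: FEV₁ ~85 %, CO
uptake ~55 %, N₂-slope ~200 % of predicted, matching the typical
post-transplant state). Trajectories are piecewise constant-then-linear on
FEV₁ fraction-of-plateau (0.75 at onset, −0.10 per subsequent visit, floor
0.40), with 4/15 of BOS patients passing through the 81–90 % band at the
visit before onset; the N₂-slope rises multiplicatively (to 3× its plateau
at onset, capped at 6×). Measurement noise is lognormal with CV 5 % (15 %
for the N₂-slope, whose repeatability is poorer; the distribution of
stable-patient slope variability is a free parameter, flagged in the
config). Missingness (e.g. 12 % for washout tracings) emulates unequal
measurement counts across variables. Each patient draws from an independent
seeded stream, with group assignment, onsets and noise drawn before and
independently of the trajectory parameters — so changing, say, the N₂ lead
time alters no random draw, which is what makes lead-time monotonicity
testable.

What the generator does **not** emulate: infection- or
anastomosis-driven FEV₁ dips, re-transplantation, seasonal drift, and any
correlation between variables beyond the shared trajectory. Passing tests
on synthetic cohorts therefore demonstrate the correctness of the
*computations* under the assumed structure, not the clinical performance of
the N₂-slope on real patients. One emergent behaviour is worth noting:
5 % measurement noise against a two-highest-pair baseline makes transient
(even confirmed) potential-BOS episodes relatively common among stable
synthetic patients, so patient-level 0-p specificity on synthetic cohorts
runs below what a real cohort with exactly three such patients shows —
abnormal results among stable patients are precisely why calibrated
specificity matters.

Tracings are built piecewise: ~0 %N₂ over the dead space, a raised-cosine
phase II front completing well before the 0.825 L window start, then an
exactly linear plateau and (optionally) an exactly linear phase IV from the
closing point, plus Gaussian analyser noise, clipped to [0, 100] %. The
exact piecewise-linear construction beyond phase II is what makes
closed-form recovery checks possible.

## Problem sizes and determinism

All worked-example computations are desk-scale (< 1 s): the published
counts are 3 × 2 tables. The property checks run on 61-patient cohorts,
50-tracing Monte-Carlo batches and calibration pools up to n = 5000 —
sizes chosen so the full suite completes in seconds while the binomial
bands being asserted are still sharp. Every stochastic component is seeded;
identical seeds give bit-identical cohorts, tracings and report files.

## Known limitations

* The closing-point detector is one reasonable published-style algorithm;
  laboratory-specific algorithms may place the breakpoint differently on
  noisy phase IVs (the method tag allows substitution).
* Reference equations are synthetic placeholders; percent-predicted values
  are only meaningful once a laboratory's own table is supplied.
* Onset dating at the first measurement of a confirmed run is a choice;
  dating at the confirming measurement shifts onsets one visit later and
  correspondingly reclassifies the measurements in between.
* The predictive-ability statistic conditions on outcome within the
  observed follow-up: patients who would have developed BOS after the last
  visit count against the criterion.
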