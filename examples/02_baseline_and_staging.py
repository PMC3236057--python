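"""Baseline tracking and BOS staging on one hand-written patient timeline.

The FEV1 baseline is the mean of the two highest values measured at or
after 4.5 months post transplant and at least 3 weeks apart; a sustained
fall to <= 80 % of it defines BOS, 81-90 % defines potential BOS (0-p).
"""

import pandas as pd

from n2bos import ReferenceSet, normalize_timeline, stage_timeline
from n2bos.synthetic import PatientTimeline

visits = pd.DataFrame(
    {"fev1": [2.6, 2.9, 3.0, 3.0, 3.1, 2.7, 2.3, 2.2, 2.0, 1.8]},
    index=[1, 2, 3, 4.5, 6, 9, 12, 18, 24, 36],
)
visits.index.name = "months_post_tx"
patient = PatientTimeline("P001", sex="F", age_years=38.0, height_cm=166.0, visits=visits)

norm = normalize_timeline(patient, ReferenceSet.default())
staged, outcome = stage_timeline(norm)

print(staged.to_string(index=False, float_format=lambda x: f"{x:.1f}"))
print()
print(f"BOS onset            : {outcome.bos_onset} months post transplant")
print(f"potential BOS before : {outcome.bos0p_before_bos}")
# The 9-month value (2.7 L, ~88 % of the 3.05 L baseline) is potential BOS,
# confirmed by the next visit; BOS proper starts where FEV1 stays <= 80 %.
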