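"""Recompute a published transplant cohort's diagnostic tables from its counts.

The package ships the printed normal/abnormal counts of a published
follow-up study of double lung transplant recipients.  The operating
characteristics and the predictive-ability percentages are recomputed here
from those counts -- the same functions run on any cohort.
"""

from n2bos import load_published_counts, operating_characteristics
from n2bos._util import round_half_up

published = load_published_counts()

print("operating characteristics (percent, rounded):")
header = ("criterion", "spec", "sens BOS", "sens 0-p", "PPV", "PPV+0p", "NPV", "NPV+0p")
print(f"{header[0]:<26}" + "".join(f"{h:>9}" for h in header[1:]))
for spec, counts in published.contingency:
    oc = operating_characteristics(counts).rounded()
    cells = (oc["specificity"], oc["sensitivity_bos"], oc["sensitivity_bos0p"],
             oc["ppv_bos"], oc["ppv_bos_plus_0p"], oc["npv_bos"], oc["npv_bos_plus_0p"])
    print(f"{spec.label():<26}" + "".join(f"{c:>9}" for c in cells))

print("\npredictive ability of a pre-diagnosis abnormal result:")
for name, counts in published.prediction:
    print(f"  {name:<10} {counts.abnormal_preceding_bos:>3} of {counts.total_abnormal:>3} "
          f"abnormal results precede BOS -> {counts.predictive_value_rounded} %")

stats = published.patient_outcomes
print("\npotential BOS (0-p) as a patient-level predictor of BOS:")
print(f"  sensitivity {round_half_up(stats.sensitivity)} %  "
      f"specificity {round_half_up(stats.specificity)} %  "
      f"PPV {round_half_up(stats.ppv)} % "
      f"({round_half_up(stats.ppv_if_progressed(1))} % if one unresolved patient progressed)")
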