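"""Calibrate an abnormality cut-off to 95 % specificity on stable patients.

The cut-off is the order statistic of the pooled stable measurements that
classifies at least 95 % of them as normal; abnormality requires a strict
inequality beyond it, so the realised pool specificity always lands in
[95, 95 + 100/n] %.
"""

import numpy as np

from n2bos import calibrate_cutoff, is_abnormal

rng = np.random.default_rng(0)
# pooled N2-slope results (percent of predicted) of stable recipients
stable_pool = rng.lognormal(mean=np.log(200.0), sigma=0.5, size=500)

cutoff = calibrate_cutoff(stable_pool, "n2_slope", "pct_predicted", "greater",
                          target_specificity=95.0)
specificity = 100.0 * (~is_abnormal(stable_pool, cutoff)).mean()

print(f"calibrated criterion : abnormal if {cutoff.label()}")
print(f"pool specificity     : {specificity:.2f} % (target 95, n = {stable_pool.size})")
print(f"abnormal in pool     : {int(is_abnormal(stable_pool, cutoff).sum())} of {stable_pool.size}")
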