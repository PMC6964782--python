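"""The audit's nonparametric statistics, stand-alone.

Exact Wilcoxon signed-rank test (is the correction a systematic shift?)
and the distribution-free order-statistic confidence interval for a
median of 12 institutional values.
"""

import numpy as np

from smallfield_audit.stats import PairedSample, median_ci, wilcoxon_signed_rank

# paired uncorrected/corrected output factors for 8 institutions at 5 mm
keys = [(f"inst{i:02d}", 5.0) for i in range(1, 9)]
of_det = np.array([0.574, 0.571, 0.569, 0.576, 0.573, 0.570, 0.538, 0.556])
omega = np.array([0.545, 0.542, 0.540, 0.547, 0.544, 0.541, 0.546, 0.545])

res = wilcoxon_signed_rank(PairedSample(tuple(keys), of_det, omega))
print(f"Wilcoxon signed-rank: n={res.n}, W={res.statistic:g}, "
      f"p={res.p_value:.4f} ({res.method})")
print("Small p: the correction shifts the values systematically — the "
      "uncorrected readings are detector-biased, not just noisy.\n")

rng = np.random.default_rng(0)
values = 0.545 * (1 + 0.01 * rng.standard_normal(12))
ci = median_ci(values)
print(f"median of 12 values: {ci.median:.4f}")
print(f"95% CI from order statistics: ({ci.low:.4f}, {ci.high:.4f}) "
      f"= sample ranks ({ci.rank}, {12 + 1 - ci.rank})")
print(f"achieved coverage {ci.achieved_coverage:.4f} (conservative, "
      "from the binomial(12, 1/2) distribution; no normality assumed)")
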