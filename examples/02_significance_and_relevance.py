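"""From SSEs to p-value, fold change, relevance score and a class label.

Walks one fitted curve through the statistics stack: the recalibrated
F-statistic, its shifted-F p-value with effective degrees of freedom,
the s0-adjusted relevance score, and the final classification.
"""

import numpy as np

from doseresp import (
    Boundary,
    CurveData,
    LogisticParams,
    adjusted_f,
    effective_dfd,
    f_value,
    fit_loglogistic,
    fold_change,
    loglogistic_eval,
    p_value,
    relevance_score,
)

rng = np.random.default_rng(2)
x = np.linspace(-9.0, -4.0, 10)
truth = LogisticParams(7.0, 1.0, 1.0, 0.5)  # saturated log2 fold change = -1
y = loglogistic_eval(truth, x) + rng.normal(0.0, 0.05, x.size)
fit = fit_loglogistic(CurveData("c", x, y))

n = fit.n
F = f_value(fit.sse_m0, fit.sse_m1, n)
p = p_value(F, n)
cfc = fold_change(fit.params, fit.x_min, fit.x_max)

boundary = Boundary(alpha_asymptote=0.05, fc_asymptote=0.45)
s0 = boundary.s0_for_n(n)
fadj = adjusted_f(F, cfc, s0)
score = relevance_score(fadj, n)

print(f"n = {n} points -> effective dfd = {effective_dfd(n):.3f}")
print(f"F = {F:.2f}   p = {p:.3g}")
print(f"curve fold change = {cfc:+.2f} log2 units")
print(f"s0 = {s0:.3f}   F_adj = {fadj:.2f}   relevance score = {score:.2f}")
print(f"decision threshold = {boundary.relevance_threshold:.2f} "
      f"-> {'regulated' if score >= boundary.relevance_threshold else 'not called'}")
print()
print("The relevance score folds the effect size into the significance:")
print("a curve with tiny |fold change| is pushed below the threshold even")
print("when its raw p-value is very small.")
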