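"""Knockdown dose-response curves of the four degradation laws.

Evaluates each model's steady-state knockdown ratio (treated over
negative control) on the standard 14-dose transfection grid, using
reference fitted parameter values for an EGFP-mRNA silencing experiment.
A ratio of 1 means no silencing; the Hill model (model4) flattens out at
dm/(dm + d4) instead of silencing completely.
"""

from rnaifit import (
    MODEL_IDS,
    SharedRates,
    knockdown_ratio,
    make_params,
    standard_dose_grid,
)

shared = SharedRates()  # km = 1 a.u./min, dm = ln(2)/40 per min
params = {
    "model1": make_params("model1", k1=1.38e-4),
    "model2": make_params("model2", k2=5.00e-3, h2=0.126),
    "model3": make_params("model3", k3h3=1.40e-4, c3_over_km=1.33e3),
    "model4": make_params("model4", d4=8.1e-3, theta4=0.105, h4=4.47),
}

doses = standard_dose_grid()
print(f"{'dose (pmol)':>12}" + "".join(f"{m:>10}" for m in MODEL_IDS))
for i, dose in enumerate(doses):
    row = [knockdown_ratio(m, params[m], shared, dose) for m in MODEL_IDS]
    print(f"{dose:>12g}" + "".join(f"{r:>10.3f}" for r in row))

floor = shared.dm / (shared.dm + params["model4"].d4)
print(f"\nHill-model saturation floor dm/(dm+d4) = {floor:.3f}: even at "
      "200 pmol the Hill curve cannot drop below this, while the other "
      "three laws keep silencing as the dose grows.")
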