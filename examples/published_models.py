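"""Evaluating the packaged published resistance models.

Seven rational models relate resistance % to the mutant allele
frequencies C (F1534C), G (V1016G), P (S989P) and their sums.  The
transcribed coefficients are evaluated in exact decimal arithmetic; at
predictor 0 every denominator is 1, so the value is the model's
constant term.
"""

from kdrfit import evaluate_printed_model, rank_models
from kdrfit.models import PRINTED_UNIFORM_ERRORS, ModelSummary, PREDICTOR_SPECS

print("model  predictor  value at 0      published uniform error")
for spec in PREDICTOR_SPECS:
    at_zero = evaluate_printed_model(spec.model_id, 0.0)
    err = PRINTED_UNIFORM_ERRORS[spec.model_id]
    print(f"{spec.model_id:>5}  {spec.label:<9}  {at_zero:<14.6g}  {err:g}")

summaries = [
    ModelSummary(mid, PREDICTOR_SPECS[mid - 1].label, err, None, "ok")
    for mid, err in PRINTED_UNIFORM_ERRORS.items()
]
print("\nranked by ascending uniform error:", rank_models(summaries))
# Models 1 (C alone) and 7 (C+G+P) carry uniform errors below 1e-3 —
# the single-locus F1534C frequency and the three-locus sum are the
# strongest phenotype predictors in this set.
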