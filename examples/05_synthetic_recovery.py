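"""Validate the inference pipeline on data with known ground truth.

Generates factorial tables from a known linear-plus-interaction surface with
Gaussian noise, refits the model, and checks coefficient bias and 95%
confidence-interval coverage.
"""

from extractopt.synthetic_data import (
    DPPH_LIKE_COEFFICIENTS,
    SyntheticSpec,
    recovery_experiment,
)

spec = SyntheticSpec(DPPH_LIKE_COEFFICIENTS, noise_sd=48.41, seed=42)
out = recovery_experiment(spec, reps=2000)

print(f"reps = {out['reps']}")
print("per-term bias and CI coverage:")
for term in out["terms"]:
    print(f"  {term:28s} bias {out['bias'][term]:+7.3f}   coverage {out['coverage'][term]:.3f}")
print(f"overall coverage: {out['overall_coverage']:.4f}  (nominal 0.95)")

# Reading: near-zero bias and ~0.95 coverage confirm the OLS estimates and
# their t-intervals are calibrated at the noise level of the antioxidant
# response; curvature in the truth (quad_amplitude > 0) would break this.
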