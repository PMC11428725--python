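"""Fit the factorial regression to the antioxidant-activity response.

Loads the packaged 27-run wood-chip extraction dataset, fits the 8-term
linear-with-interactions model on coded factors to the DPPH response, and
prints the fitted equation, per-term significance and adequacy diagnostics.
"""

from extractopt import ffd_model, study_table

table = study_table()
fit = ffd_model.fit_response(table, "dpph")

print(ffd_model.regression_equation(fit))
print()
print(ffd_model.term_pvalues(fit).round(4))
print()
s = ffd_model.fit_statistics(fit)
print(f"R2 = {s.r2:.4f}   adj R2 = {s.adj_r2:.4f}   pred R2 = {s.pred_r2:.4f}")
print(f"adequate precision = {s.adequate_precision:.4f}  (> 4 means usable)")

# Reading: temperature and ethanol fraction carry the signal (p < 0.0001);
# extraction time is flat for this response.  The coefficients are effects
# per coded unit, i.e. per half-range of each factor.
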