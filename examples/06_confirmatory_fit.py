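"""Confirmatory factor analysis of an exploratory-derived pattern.

An EFA solution on one half of the data is thresholded (|loading| >
0.45) into an indicator pattern; the CFA fits that fixed pattern to
the other half's correlation matrix and reports chi^2, CFI, TLI,
RMSEA (with 90% CI) and SRMR.
"""

import numpy as np

import latentdomains as ld

L = ld.block_loadings(4, 6, 0.7)
spec = ld.SyntheticSpec(1200, L, 1.0 - (L**2).sum(axis=1), seed=13)
table, _ = ld.generate_factor_data(spec)
X = table.values.to_numpy()
discovery, replication = X[:600], X[600:]

sol = ld.fit_efa(discovery, 4)
sol.variable_names = table.variables
pattern = ld.pattern_from_efa(sol, threshold=0.45)
print(f"indicators per factor: {pattern.free_mask.sum(axis=0)}, "
      f"dropped variables: {pattern.dropped_variables}")
print(f"free parameters: {pattern.n_free_parameters}, df: {pattern.degrees_of_freedom()}")

S = np.corrcoef(replication, rowvar=False)
fit = ld.fit_cfa(S, pattern, n_obs=600)
lo, hi = fit.rmsea_ci90
print(f"chi^2 = {fit.chi_square:.2f} (df {fit.df}), CFI = {fit.cfi:.3f}, TLI = {fit.tli:.3f}")
print(f"RMSEA = {fit.rmsea:.3f} (90% CI {lo:.3f}-{hi:.3f}), SRMR = {fit.srmr:.3f}")
# CFI/TLI near 1 and RMSEA/SRMR well under 0.08 confirm that the
# structure discovered on one half generalizes to the other.
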