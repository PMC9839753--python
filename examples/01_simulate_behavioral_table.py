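"""Generate a behavioral-style table from a planted factor model.

Four latent domains, ten variables each, with age/gender confound
effects, sparse missingness and family structure — the kind of table
the rest of the pipeline consumes.
"""

import numpy as np

import latentdomains as ld

L = ld.block_loadings(4, 10, 0.7, jitter=0.05, rng=np.random.default_rng(0))
spec = ld.SyntheticSpec(
    n_subjects=600,
    loadings=L,
    uniquenesses=1.0 - (L**2).sum(axis=1),
    confound_effects=np.column_stack([np.full(40, 0.02), np.full(40, 0.3)]),
    missing_rate=0.03,
    family_sizes=ld.default_family_sizes(600, seed=1),
    seed=42,
)
table, truth = ld.generate_factor_data(spec)

print(f"table: {table.n_subjects} subjects x {table.n_variables} variables")
print(f"missing fraction: {table.missing_mask.to_numpy().mean():.3f}")
print(f"families: {table.family_id.nunique()}")
print(f"planted factors: {spec.n_factors}, block sizes 10")
print("first rows:")
print(table.values.iloc[:3, :4].round(2))
# The planted loadings and factor scores in `spec`/`truth` are the ground
# truth every downstream stage is validated against.
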