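"""Flow of variance across factor solutions (Sankey data).

Solutions with 1..k factors form levels; Bartlett factor scores are
correlated between consecutive levels, and |r| is the flow of variance
from a parent factor to a child. A broad factor splitting into two
narrower ones appears as two strong outgoing edges.
"""

import numpy as np

import latentdomains as ld

# one general factor over 20 variables, plus two specific sub-factors
g = np.full(20, 0.65)
s1 = np.concatenate([np.full(10, 0.3), np.zeros(10)])
s2 = np.concatenate([np.zeros(10), np.full(10, 0.3)])
L = np.column_stack([g, s1, s2])
spec = ld.SyntheticSpec(1000, L, 1.0 - (L**2).sum(axis=1), seed=21)
table, _ = ld.generate_factor_data(spec)

flow = ld.build_hierarchy(table.values.to_numpy(), k_max=3)
print("nodes (percent variance per factor and level):")
print(flow.nodes_frame().round(2).to_string(index=False))
print("\nedges level 1 -> 2 (the broad factor splitting in two):")
print(flow.edges.query("level == 1").round(3).to_string(index=False))
# Two comparable weights out of the single level-1 factor show its
# variance dividing between the two sub-domains at the next level.
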