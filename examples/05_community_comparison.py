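"""Compare communities grown on different EPS sources.

Builds a small relative-abundance table, computes Bray-Curtis
dissimilarities, log2 fold changes versus the inoculum (absences masked),
and a Ward clustering of the fold-change rows.
"""

import numpy as np
import pandas as pd

import epsdigest as ed

rng = np.random.default_rng(7)
species = [f"sp{i:02d}" for i in range(8)]
table = pd.DataFrame(
    rng.dirichlet(np.ones(8), size=4).T,
    index=species,
    columns=["inoculum", "eps_a", "eps_b", "eps_c"],
)
table.loc["sp03", "eps_b"] = 0.0  # species lost on one EPS source
table = table / table.sum(axis=0)

for a, b in [("eps_a", "eps_b"), ("eps_a", "eps_c"), ("eps_b", "eps_c")]:
    d = ed.bray_curtis(table[a], table[b])
    print(f"Bray-Curtis {a} vs {b}: {d:.2f}")

fc = ed.fold_changes(table, "inoculum")
print("\nlog2 fold change vs inoculum (NaN = not detected):")
print(fc.values.round(2).to_string())

Z, leaf_order = ed.ward_cluster(fc)
print("\nWard leaf order for the heatmap:", leaf_order)
print("top-3 summary with remainder:")
print(ed.top_n(table, n=3).round(3).to_string())
# Dissimilarities near 0 mean near-identical communities, near 1 disjoint
# ones; masked cells mark species absent after growth on that EPS.
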