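"""Classify ion temporal profiles and measure cross-digest sharing.

Runs the decreased / bell / increased classifier on a simulated digest,
shows the m/z-binned category distribution, then aligns increased ions
across digests (8 ppm, 0.1 min) and reports how sharing falls with mass.
"""

import math

import epsdigest as ed

table, truth = ed.generate_dataset(ed.default_scenario(noise_cv=0.2, seed=42))
result = ed.classify_table(table)

print("overall category counts:", result.counts_overall)
print("\ncategory fractions by m/z bin:")
print(ed.mz_category_distribution(result).to_string(index=False))

increased = result.per_ion.loc[result.per_ion["category"] == "increased", "ion_id"]
features = (
    table[table["ion_id"].isin(increased)]
    .groupby(["ion_id", "digest"])
    .agg(mz=("mz", "first"), rt_min=("rt_min", "first"), mode=("mode", "first"))
    .reset_index()
)
aligned = ed.align_ions(features, ppm_tol=8.0, rt_tol=0.1)
sharing = ed.sharing_by_mz(aligned, bin_edges=[50, 200, 1400, math.inf])
print("\nfraction of terminal products detected in >1 digest, by m/z:")
print(sharing.to_string(index=False))
# Low-mass terminal monomers are broadly shared across digests; high-mass
# resistant oligomers stay digest-specific - the signature of sequential
# depolymerization into increasingly generic products.
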