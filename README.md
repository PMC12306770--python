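# epsdigest

Analytics for the sequential degradation of extracellular polymeric
substances (EPS) — the secreted mixture of polysaccharides, proteins, and
humic-like material that microbes release while breaking down polymers such
as chitin. The package is aimed at microbial-ecology and metabolomics
researchers who want to (i) quantify how much carbon a degrader exports as
EPS versus low-molecular-weight (LMW) metabolites, (ii) follow in vitro
enzyme digests of EPS by untargeted LC–MS over 24 h, and (iii) relate the
released products to the microbial communities they feed.

## What it computes

**Degradation kinetics.** A digest is modelled as linear chains of
irreversible first-order cleavages with rates k₁ … k₍ₙ₋₁₎ (h⁻¹) and an
absorbing terminal product. For distinct rates the Bateman closed form gives
stage *i*'s amount

N_i(t) = N₀ (∏_{j<i} k_j) Σ_{j≤i} e^{−k_j t} / ∏_{l≤i, l≠j}(k_l − k_j),

with numerical integration as the degenerate-rate fallback. A synthetic
generator turns such chains into realistic multi-digest ion tables
(log-normal intensity noise, detection-floor censoring, an instrument m/z
window, [M−H]⁻ adducts) with planted ground truth.

**Ion temporal classes.** Each ion's 0–24 h trace is classified as
*increased* (log₂ fold change of the final versus initial timepoint ≥ 10 —
terminal products appearing from a censored baseline), *bell* (a transient
intermediate whose interior maximum exceeds both endpoints at least
2-fold), or *decreased* (log₂ FC ≤ −1). Features are aligned across digests
within 8 ppm / 0.1 min, and cross-digest sharing is summarised per m/z bin.

**Exact-mass annotation.** All 10,625 peptide compositions of ≤4 residues
(168,420 ordered sequences), amino-sugar monomers and glycosidic dimers,
and user compound tables are matched to ions at 5 ppm via the
protonation/deprotonation adducts.

**Carbon budgets and composition.** Closed carbon balances
(biomass + EPS + LMW + CO₂ = 100%), dry-mass EPS yields, MW-weighted
monosaccharide fractions, mock-medium formulation, and Coble peak M/C
extraction from excitation–emission fluorescence matrices.

**Community response.** Bray–Curtis dissimilarity, log₂ fold changes
versus an inoculum with a read-depth detection floor and explicit masking
of absent species, Ward clustering, and top-N community summaries.

## Worked example

```python
import epsdigest as ed

table, truth = ed.generate_dataset(ed.default_scenario(noise_cv=0.2, seed=42))
result = ed.classify_table(table)
print(result.counts_overall)
# {'decreased': 333, 'bell': 282, 'increased': 222, 'unclassified': 0}

b = ed.carbon_budget(33.0, 4.1, 11.0)
print(round(b.co2_pct, 1), round(b.eps_share_of_exudate, 1))
# 51.9 27.2
```

The first block simulates three enzyme digests (~840 ion features) and
recovers the planted temporal classes: 333 substrate-like decreasing ions,
282 transient intermediates, 222 accumulating terminal products. The second
closes a carbon budget in which 33% of substrate carbon went to biomass,
4.1% to EPS and 11% to LMW metabolites: 51.9% is unrecovered (respired
CO₂), and EPS is 27.2% of the exuded carbon. The scripts in `examples/`
walk through each capability (simulation, classification and sharing,
annotation, budgets, community comparison) and print annotated output.

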