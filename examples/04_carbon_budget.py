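"""Close a carbon budget and formulate a mock EPS medium.

Partitions input substrate carbon into biomass / EPS / LMW / CO2, derives
the EPS share of exuded carbon, computes monosaccharide weight fractions,
and prints a defined medium mimicking a measured EPS composition.
"""

import epsdigest as ed

for biomass, eps, lmw in [(33.0, 4.1, 11.0), (36.0, 4.5, 14.0)]:
    b = ed.carbon_budget(biomass, eps, lmw)
    print(
        f"biomass {b.biomass_pct}%  EPS {b.eps_pct}%  LMW {b.lmw_pct}%  "
        f"-> CO2 {b.co2_pct:.1f}%,  EPS share of exudate {b.eps_share_of_exudate:.1f}%"
    )
# The two recovery endpoints put respiration at 45.5-51.9% of substrate
# carbon and EPS at 24.3-27.2% of the exuded carbon (~one quarter).

mg_per_g, pct = ed.eps_yield(90.0, 2.0)
print(f"\nEPS yield: {mg_per_g:.0f} mg/g substrate ({pct:.1f}% w/w)")

fractions = ed.monosaccharide_mass_fractions(
    {"glucose": 20.0, "galactose": 13.0, "galacturonic acid": 17.0, "glucosamine": 22.0}
)
print("\nmonosaccharide weight fractions:")
print(fractions.round(3).to_string())

recipe = ed.mock_medium(
    {"galactose": 13.0, "galacturonic acid": 17.0, "glucosamine": 22.0,
     "glucose": 20.0, "ribose": 0.4},
    protein_mg_per_L=150.0,
)
print("\nmock medium (sugars >= 1 uM + protein):")
print(recipe.to_string(index=False))
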