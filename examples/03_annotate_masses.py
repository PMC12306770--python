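"""Annotate ions by exact mass against peptide and amino-sugar catalogs.

Enumerates all <=4-residue peptide compositions and the amino-sugar
mono/dimer catalog, then matches two observed m/z values at 5 ppm.
"""

import epsdigest as ed

catalog = ed.MassCatalog.combine(ed.enumerate_peptides(max_len=4), ed.sugar_masses())
print(f"catalog size: {len(catalog)} neutral masses "
      f"({(catalog.entries['source'] == 'peptide').sum()} peptide compositions)")

hits = ed.annotate_ions([133.06077], "positive", catalog, ppm_tol=5.0)
print("\n[M+H]+ at m/z 133.06077:")
print(hits.head(5).to_string(index=False))

hits = ed.annotate_ions([423.16204], "negative", catalog, ppm_tol=5.0)
print("\n[M-H]- at m/z 423.16204:")
print(hits.head(5).to_string(index=False))
# The positive-mode ion matches diglycine (neutral 132.05349 Da); the
# negative-mode ion matches the N-acetylhexosamine glycosidic dimer
# (424.16932 Da). Matches are putative: exact mass cannot separate isomers.
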