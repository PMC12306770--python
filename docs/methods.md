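# Methods

## Degradation model

EPS breakdown is modelled as linear chains of irreversible first-order
cleavages: substrate → intermediate(s) → terminal product, with rate
constants k₁ … k₍ₙ₋₁₎ in h⁻¹ and the terminal rate fixed at 0 (the last
tracked product is not cleaved further). The model tracks one species per
stage and conserves the summed amount — it is a bookkeeping abstraction of
depolymerization, not enzyme kinetics: no enzyme saturation
(Michaelis–Menten), no chain-length distribution, and no stoichiometric
fan-out (a cleavage of a large polymer in reality yields several fragments;
here the `stoichiometry` field can scale daughter amounts but defaults
to 1). Distinct-rate chains are evaluated with the Bateman closed form;
chains with repeated rates are flagged `degenerate` at construction and
integrated with LSODA (rtol 1e-10). The analytic and numerical routes agree
to better than 1e-4 of the initial amount on random chains of up to six
stages, and the interior stage of a three-stage chain peaks at
t\* = ln(k₂/k₁)/(k₂−k₁), which the simulated trajectories reproduce to
within one grid step.

## Synthetic digest generator

`default_scenario` emulates three parallel 24 h enzyme digests sampled
hourly (the sampling cadence of continuous autosampler acquisition is a
free parameter; hourly keeps ~25 points per trace and runs in milliseconds).
Per digest, 111 chains:

* ~85% are three-stage: substrate 1,450–1,650 Da, digest-specific
  intermediate 600–1,400 Da, terminal monomer 120–390 Da. 70% of terminal
  masses come from a pool shared across digests — small monomers
  (amino acids, monosaccharides) are generic products — while intermediates
  are digest-specific, as oligomer structure varies with the parent EPS.
* ~15% are two-stage with a cleavage-resistant high-mass terminal product
  (1,400–1,640 Da), mostly digest-specific (15% from a small shared pool).
  These reproduce the observed pattern that accumulating high-mass ions are
  rarely shared across digests while low-mass ones are broadly shared.

Rates: k₁ ∈ [0.15, 0.45] h⁻¹ and k₂ = k₁ + [0.35, 0.9] h⁻¹, so
intermediates peak at 2–5 h and are near-exhausted by 24 h, and substrates
retain 2–3% of their signal at 24 h — well clear of both the bell and the
increased rule for the wrong class.

Observation model: intensity = amount × 10⁶ counts, multiplied by
mean-one log-normal noise with CV 0.2 (the standard shape of LC–MS
intensity error; CV is configurable). Intensities below the detection
floor are censored — the row is absent, which is what produces the huge
log₂ fold changes of terminal products whose baseline is unobserved. The
floor defaults to 10⁻⁴ of the initial substrate signal: a terminal product
formed in full yield then sits ~2¹³ above the floor, comfortably past the
2¹⁰ increased threshold, whereas a floor of 10⁻³ would cap the achievable
fold change at ~2^9.97 and make full-yield products unclassifiable in
principle. m/z is the [M−H]⁻ adduct (neutral − 1.007276 Da) by default,
matching negative-mode acquisition; ions outside the 50–1,700 m/z window
are dropped entirely. Retention times are a deterministic hash of the
neutral mass (same compound, same elution in every digest) plus ±0.02 min
digest jitter, well inside the 0.1 min alignment tolerance.

What the generator does **not** emulate: chromatographic peak shapes,
isotope envelopes, adduct multiplicity, ion suppression, chemical noise
features, or mass-dependent response factors. Passing the recovery tests
therefore shows the classifier implements its rules correctly under
realistic intensity noise and censoring — not that it would achieve the
same accuracy on raw instrument data.

## Temporal classification

Rules are evaluated per digest on that digest's full timepoint grid, with
missing values imputed at the 1% quantile of the digest's nonzero
intensities, then combined across digests (a rule firing in ≥1 digest
assigns the ion; conflicts resolve by increased > bell > decreased, since
the increased rule is the only one with a hard quantitative definition).
Order within a digest: increased (log₂(I₂₄/I₀) ≥ 10), then bell, then
decreased (log₂ FC ≤ −1, i.e. 2-fold; the bell prominence is 2-fold over
both endpoints). The decrease and prominence thresholds are the package's
defaults for "steady decrease" and "transient rise" — minimal fold changes
distinguishable above 20% multiplicative noise — and are configurable via
`ClassifierParams`; they are reported in the result object.

Bell detection median-smooths the trace (window 3) to reject
single-timepoint spikes, but only when the series has at least
`smooth_window + 2` points: a three-point series is its own interior, and
smoothing it would erase any single-point maximum by construction.
Endpoints are compared unsmoothed.

Alignment is exact single-linkage: two features co-cluster when their m/z
difference is within 8 ppm of their mean m/z and their retention times are
within 0.1 min, closed transitively via union–find over an m/z-sorted
sliding window (the ppm bound is monotone in the sorted order, so the scan
is exhaustive). Cluster labels follow ascending (m/z, RT) of each
cluster's first member, making the output independent of row order.

## Mass annotation

All masses are monoisotopic (exact-mass matching on a Q-TOF); residue and
formula masses come from pyteomics. Peptides are enumerated as residue
multisets (mass is order-independent): 10,625 compositions at ≤4 residues
versus 168,420 ordered sequences. The 20 canonical residues only — no
modifications. Amino sugars: hexosamine (C₆H₁₃NO₅, 179.07937 Da),
N-acetylhexosamine (C₈H₁₅NO₆, 221.08994 Da), and the three glycosidic
dimers (sum of monomers − water). Only [M+H]⁺/[M−H]⁻ adducts are
implemented; the 5 ppm default tolerance matches the export tolerance of
the MS² workflow the class-prediction filter serves. The filter keeps rows
with intensity explained ≥ 0.5, isotope score ≥ 5 *when present*, and most
specific class probability ≥ 0.75 (inclusive).

## Budgets and composition

Carbon budgets treat CO₂ as the closing remainder, so
biomass + EPS + LMW + CO₂ = 100 exactly; the EPS share of exudate is
100·eps/(eps+lmw) and is NaN (flagged `degenerate`) when nothing was
exuded. Carbon-percent budgets and dry-mass yields (mg EPS per g substrate)
are kept as separate quantities: converting between them needs a
carbon-content assumption the package does not make. Monosaccharide weight
fractions use free-monosaccharide monoisotopic masses by default (the
quantified analytes are released monomers); anhydro (in-polymer residue)
masses are available via a flag. The bundled mass table covers the 17
standards of a PMP-derivatization LC–MS panel plus the six structural
classes. Mock-medium formulation includes sugars at or above 1 µM and an
optional protein supplement in mg/L (bovine serum albumin by default; a
source document's "150 mg/mL" variant of that value is treated as a
typographical inconsistency for "150 mg/L").

Coble peaks are rectangular excitation/emission windows — M: Ex 290–310 /
Em 370–410 nm (marine humic-like), C: Ex 320–360 / Em 420–460 nm (visible
humic-like) — with inclusive bounds on the 5 nm acquisition grid. The
statistic is the window *mean* so values are comparable across window
sizes; the sum is available via `statistic="sum"`. Both the 50–1,700 m/z
acquisition range and an 1,800 m/z upper bin edge appear in source
descriptions of the LC–MS method; the package accepts either as a window
configuration and defaults the bin edges to 50, 200, …, 1,800 with
half-open [low, high) bins and open-ended ranges like [1,400, ∞) for
">1,400 m/z".

## Community comparison

Abundance tables are renormalized per sample on load. Fold changes versus
the inoculum use FC = log₂(a_cond / max(a_inoc, floor)) with floor
1/30,000 — one read at the typical filtered 16S read depth per sample — so
species absent from the inoculum get large finite enrichments; species
absent from a *condition* are masked (NaN), not scored as −∞ or zero,
matching the grayed-out cells of a fold-change heatmap. Fold changes are
computed on relative abundances (read counts would need the per-sample
depths, which the tables do not carry). For Ward clustering, masked cells
are imputed at the matrix minimum (absent ≈ most depleted; `impute="zero"`
is available), and rows feed Euclidean distances into SciPy's Ward
linkage — Ward's variance criterion presumes squared-Euclidean geometry.
Top-N summaries break abundance ties lexicographically by species name.

## Problem sizes and determinism

The default test and acceptance workloads use the default scenario
(3 digests × 111 chains ≈ 840 unique ion features, hourly grid), 20 random
chains for the kinetic cross-checks, 1,000 random m/z values for the
annotation oracle, 100 features for the alignment oracle, and ≤8 rows for
the exhaustive Ward oracle; the complete suite runs in a few seconds. All
randomness flows through `numpy.random.default_rng` seeds; identical seeds
give byte-identical generated tables.

## Known limitations

One tracked species per stage (observed ions, not stoichiometry); no
branching chains; single-adduct annotation; no isomer disambiguation; Ward
tie-breaks below floating-point resolution follow SciPy's merge order; the
classifier assumes a common timepoint grid per digest and imputes all
missingness as censoring (not as dropout at high intensity).
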