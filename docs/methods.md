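# Methods

## Mass calculus

All masses are monoisotopic. Residue masses come from pyteomics
(Unimod/IUPAC values); water = 18.010565 Da, proton = 1.007276 Da. A
peptidoform's neutral mass is the sum of residue masses plus water plus
the modification deltas; precursor m/z at charge z is (M + z·1.007276)/z.
The modification registry ships γ-carboxylation (+43.98983 on Glu),
methyl ester (+14.01565 on free carboxyls), propionamide (+71.03711 on
Cys, from acrylamide alkylation), Asp oxidation/β-hydroxylation
(+15.99491), deamidation (+0.98402 on Asn/Gln), Tyr sulfation (+79.95682)
and phosphorylation (+79.96633 on Ser/Thr/Tyr). Sulfation and
phosphorylation at the same site differ by only 0.0095 Da and are modeled
as two distinct definitions; nothing in the package adjudicates between
them, mirroring the ambiguity inherent in low-resolution CID data.
Glycans are compositions (counts of Hex, HexNAc, Fuc, NeuAc, NeuGc, Xyl)
without topology; their mass is the count-weighted residue sum and the
integer-rounded value gives the "+656"/"+947" shorthand used in variant
labels.

Fragment ladders follow standard b/y arithmetic (b_i = Σ residues(1..i) +
z·proton; y_i adds water), with the a-series (b − CO) available; localized
modification masses ride with the fragment that spans their site, and
unlocalized (count-based) modifications are applied only at the whole-
peptide level since they cannot be placed on partial fragments. Optional
neutral-loss ladders subtract SO3 from fragments spanning a sulfation
site and CO2 from fragments spanning a γ-carboxyl, the dominant CID
behaviour of both modification types. Glycopeptide Y ions are built by
stripping all glycans (Y0 = protonated peptide, non-glycan modifications
retained) and re-attaching monosaccharides core-first: HexNAc, then Hex,
then distal residues (NeuAc, NeuGc, Fuc, Xyl) — the order consistent with
the Y1/Y2 values of mucin-type O-glycopeptides. Immonium m/z is residue
mass − 26.98763 plus modification deltas.

Digestion is fully specific. Trypsin cleaves C-terminal of Lys/Arg with
the classical not-before-Pro suppression enabled by default (a
`trypsin/p` rule without suppression is provided); GluC cleaves after
Glu, AspN before Asp, chymotrypsin after Phe/Trp/Tyr/Leu (not before
Pro). Peptides carry 1-based coordinates in the parent protein. The
digestion routine is tested against a brute-force enumeration over all
boundary-consistent substrings on random sequences.

## Carboxyform and methylform families

Quantification treats γ-carboxyforms by count k, not by site combination:
all same-k site placements are isobaric and co-extracted, so one
representative per k is enumerated (site-resolved placements remain
available internally for mass computation). Methanolic derivatization
esterifies free carboxyl groups; the inventory per peptidoform is
(#Asp) + (#non-carboxylated Glu) + 2·(#Gla) + 1 for a free C-terminus,
and methylforms are enumerated from 0 up to the inventory, capped at a
configurable 6 — beyond which variants are too sparse to be individually
useful. Methyl counts are modeled unlocalized because esterification is
chemically non-specific.

## Ion libraries and isolation windows

A SWATH scheme is a deterministic list of [low, high) windows from
(start, end, width, stride); the last window is clipped at the range end.
The default global geometry is width 26, stride 25 (1 m/z overlap),
first edge 399.5, across 400–1250 m/z — the simplest geometry consistent
with the two documented co-isolation pairs (603.3461²⁺ with 621.309³⁺,
and 879.8644²⁺ with 887.8618²⁺); exact vendor boundaries are not
recoverable, so the geometry is configurable. The narrow scheme for
derivatized GLA peptides uses 6.2 m/z non-overlapping windows across
400–917 m/z.

Conflict groups are connected components of the graph linking entries
that share at least one window and elute within rt_tolerance (default
1.0 min — "similar RT" is inherently a tuning choice). Groups are pooled
and quantified as one merged class; per-member deconvolution is out of
scope. Identification confidence gates library import (default 0.99);
measurement-level FDR gates quantities — the two thresholds act at
different stages and are deliberately separate parameters.

## Quantification

Transition summation takes, per sample and (merged) peptidoform class,
the top-N transition intensities whose observed RT lies within ±w/2 of
the library reference. Three presets mirror the acquisition modes:
`global` (N = 6, w = 2 min) for protein-level work, `ptm` (all
transitions, 2 min) for PTM variants, and `gla-methyl` (all transitions,
6 min, except 2 min for the early-eluting CSFEEAR family) for
derivatized GLA peptides. Peptides with FDR > 0.01 are eliminated;
protein intensity is the sum of passing peptides. Shared peptides are
excluded from the rollup by default (which makes total intensity
conservation testable); an assign-to-all option exists. Normalization
divides by the intensity of the trypsin autolysis peptide VATVSLPR in
the same sample, cancelling loading and response factors; samples
missing the reference are flagged and excluded rather than silently
normalized by zero.

## Stoichiometry

Carboxyform profiles sum intensities over all variants sharing a
carboxyl count (marginalizing methyl and glycan states) and report
percentages of the family total. Zero-total families are flagged
undefined, not reported as 0%. Percentages are conditional on detectable
forms: where a family's fully carboxylated variants escape detection
(underivatized positive-mode data), the profile describes the detectable
subset, and output metadata should be read accordingly. PTM variant
series divide variant intensity by total product abundance per sample;
time-course matrices keep missing values explicit (NaN, never imputed
zero), with optional log10 transform and per-row max scaling for display.

## Statistics

Per-variant comparisons use a pooled-variance two-sample t-test,
one-tailed in a direction that must be declared per comparison. When both
groups are degenerate (zero variance, equal means) the symmetric-null
convention p = 0.5 is returned with a flag. Time-course screening runs a
t-test per day and applies the two-stage linear step-up procedure
(stage 1: BH at q/(1+q) to estimate the null count m0; stage 2: BH at
that level scaled by m/m0) at Q = 0.01. The implementation is
cross-checked in the test suite against statsmodels' independent
`fdr_tsbky` routine. Note the two-stage procedure does not universally
dominate plain BH: when stage 1 rejects fewer than m·q/(1+q) hypotheses
it can discover less; dominance is asserted only under that condition.

Protein-level differential abundance is a deliberate simplification of
mixed-model summarization frameworks: feature intensities (transition- or
peptide-level) are log2 transformed, summarized to run level by Tukey
median polish, compared with an equal-variance t-test, and BH-adjusted
across proteins with significance at a configurable alpha (default
1e-5). Proteins observed in only one group receive the ±infinite
fold-change convention and are excluded from testing. Because analysis is
on the log scale, all results are invariant to unit rescaling.

## Synthetic fed-batch generator

The generator emulates the statistical structure the analysis assumes,
not bioreactor mechanism. Two conditions run n_days = 13. Product
abundance is the cumulative sum of a per-day secretion trajectory;
secreted HCPs accumulate proportionally to culture day; intracellular
HCPs appear as lysis_coefficient × cumulative viability loss — the
linear-in-viability-loss release model is an assumption, chosen as the
simplest monotone coupling. Per-family class distributions (over
carboxyl counts or PTM variants) interpolate linearly between a day-1
and a final-day probability vector. Derivatized carboxyform classes are
split over methyl counts by a binomial esterification model (p = 0.8 per
free carboxyl, mass above the cap collapsed onto the cap). Purification
re-weights family shares by per-class retention probabilities —
increasing in k for three GLA families (0.10→0.85), flat for the
single-site TTEFWK family, whose carboxylation does not drive
anion-exchange binding — concentrates the product, and carries HCPs over
at 0.02 (secreted), 0.05 (intracellular) and 0.20 (calcium binders,
which co-bind the resin).

The default "h1h2-like" scenario gives condition A a final viability of
0.93, a yield plateau after day 8, and high carboxyform occupancy;
condition B a final viability of 0.77, continued secretion (higher final
yield), doubled lysis release, a larger glycan/sialylation load, and
lower carboxyform occupancy. Trajectory numbers are fixture choices that
reproduce this qualitative design, not measured values. Abundance units
are scaled so that day-13 supernatant classes sit well above the
censoring limit; early-day, low-share classes may censor, as real
low-abundance variants do.

Rendering draws, per transition, intensity = protein abundance × class
share × normalized library relative intensity × LogNormal(0, σ) +
baseline, censored below a limit (σ default 0.2; the multiplicative
log-normal with censoring is the simplest model under which FDR
filtering and normalization are genuinely exercised). Relative
intensities are normalized within each entry so the summed transition
signal equals the true class intensity — the assumption targeted
extraction itself makes. Rendered-true entries receive FDR scores below
0.01, injected decoys above it. Reference RTs are copied from the
library with no drift model, since extraction uses generous RT windows.
All randomness flows from a single seed and a manifest (scenario hash,
seed) accompanies every rendered dataset.

What the generator does *not* emulate: interference between co-eluting
analytes beyond declared conflict groups, retention-time drift,
saturation or detector nonlinearity, missed-cleavage leakage across
families, and mechanistic CHO metabolism. Passing recovery tests
therefore shows the pipeline is correct under its own assumptions, not
that those assumptions hold for any particular instrument.

## Problem sizes and numerical choices

Tests run the default scenario (7 product families → 93 product
peptidoform classes, 40 HCPs, 161 library entries) with 3 replicate
renders at σ = 0.1 for recovery checks, a 100-protein panel for the
differential-abundance power check, and 50 null simulations of 200
proteins for the type-I bound. m/z assertions use 0.002–0.003 absolute
tolerance at z ≤ 2 (scaled for higher charge and composite targets),
consistent with single-digit-ppm mass accuracy. Probability vectors are
validated to sum to 1 within 1e-9; percentage sums to 100 within 1e-9.
Ties in top-N transition selection resolve by stable sort order, making
outputs deterministic.

## Known limitations

Absolute occupancy requires labeled standards and is out of scope; all
stoichiometry is relative. The immonium constant reproduces the
theoretical phosphotyrosine value (216.042); published observed values
scatter by a few mDa around it. Site-resolved carboxyform quantification
(distinguishing same-k placements) would require resolving isobaric
species and is not attempted. MSstats-grade mixed modeling, search-engine
FDR estimation, and spectrum-level (mzML) processing are explicitly not
reimplemented.
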