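# Methods

## Scope and model

`mmpscreen` analyses single-concentration phenotypic screens in which an
annotated compound library is tested on a proteolytic disease cell model and
read out as fluorescence from a quenched gelatin substrate cleaved by
secreted MMPs. The computational object is the funnel

screened compounds → (viability triage) → assayed → (control-anchored
calling) → hits → (pIC50 filter + frequency/enrichment ranking) → candidate
target,

plus set-algebra utilities for off-target uniqueness within a chemical
series. Wet-lab concerns (differentiation protocols, zymography, image
quantification) are outside scope; the package starts at a per-well
fluorescence table and a per-compound target/pIC50 table.

## Hit calling

Activity is normalized per compound as mean treated fluorescence over
replicates divided by the mean MFS_DMSO (untreated disease line) baseline.
Replicate aggregation is the arithmetic mean: with n = 2 technical
replicates, per-compound variances are too unstable to drive the call, so
per-role SDs enter only through the control band. The default threshold is

  max over reference roles {CORR, REFERENCE_DRUG} of (mean + k·SD),  k = 2,

on the normalized scale, with SD taken as 0 for a singleton control. This
encodes "reduced MMP activity to a level comparable to the healthy
controls" while remaining tunable; the comparison is inclusive (≤) so
boundary compounds are called deterministically, and a fixed-fraction rule
is available for sensitivity analysis. Toxicity triage uses mean well
viability < 0.5 by default, or an externally supplied triage list for
screens where toxicity was scored by eye; compounds with neither viability
data nor a flag are assayed. No plate-effect correction (B-score, spatial
detrending) is applied — the model is a single plate per readout.

## Occupancy model and potency filter

Target engagement at the screening concentration C is modelled as
single-site occupancy C / (C + IC50) = 1 / (1 + 10^(−pIC50) / C). At
C = 1 µM, pIC50 = 6 gives occupancy 0.5; the deconvolution filter therefore
drops annotations with pIC50 < 6 (inclusive cut: ≥ 6 is retained).
Annotations without a pIC50 are retained in the table but excluded from any
potency-filtered analysis, with the exclusion counted in the load/filter
reports. Duplicate (compound, target) records keep the maximum pIC50 —
the conservative choice for a ≥-threshold filter — and target symbols are
canonicalized (trimmed, uppercased, Greek letters transliterated) so that
records from differently formatted sources unify.

## Ranking and enrichment

Targets are ranked by distinct-hit-compound frequency, then BH q, then
lexicographic id (all tie-breaks deterministic). Mean pIC50 over hit
annotations measures specificity; primary-target counts use the library's
design-target flag (at most one per compound). Enrichment is the one-sided
exact hypergeometric tail P[X ≥ k] for K annotated among N assayed
compounds and k among the n hits — over-representation among hits is the
scientific question, so no two-sided Fisher test — with BH FDR applied
separately within each hypothesis family (targets; categories). Category
overrepresentation takes a user-supplied target→category map; database
lookups are deliberately excluded because their term lists depend on
database versions. The hit/non-hit frequency comparison reports Spearman's
ρ over the target union (missing counts = 0) and standardized residuals
from the least-squares line through the rank-rank scatter; large positive
residuals flag targets unusually frequent among hits. Rank-based statistics
were chosen because target frequencies are heavy-tailed (a few promiscuous
targets dominate).

## Synthetic screens

The generator emulates the study conditions rather than idealized ones:
1,022 compounds by default, ~5 annotations per compound
(Poisson, minimum 1) over a 200-decoy universe, decoy pIC50 ~ N(6, 1.2)
truncated to [3, 11] (centred at the informativeness boundary so roughly
half the decoy annotations survive the filter), causal annotations in 5 %
of compounds at pIC50 ~ N(8, 0.7) (near-complete 1 µM occupancy), shared
Emax 0.8, multiplicative log-normal noise with CV 0.1, duplicate technical
replicates, and a 0.714 toxicity rate. The causal pIC50 distribution has
its own parameters (`causal_pic50_mean/sd`) because the planted signal and
the decoy background are different populations. The effect model is
single-hit: expected signal reduction = Emax × max occupancy over a
compound's causal annotations (max, not sum — no synergy), and 0 without a
causal annotation. Toxicity is independent of annotation: the emulated
screen gives no mechanism for its triaged compounds, and the quantitative
viability proxy (uniform draws below/above the cut) is a stand-in for a
visual call. Control wells sit at the baseline, 0.40× (corrected line) and
0.45× (reference drug) levels with the same noise. All randomness derives
from one root seed via `SeedSequence([seed, stage])` child streams, so the
library and the plate are independently reproducible; with noise CV 0 the
pipeline is deterministic end-to-end and the hit set equals exactly the
compounds whose planted reduction crosses the control band.

What passing synthetic tests does *not* show: the generator has no plate
spatial effects, no compound cross-reactivity structure (decoy targets are
sampled independently), no dose-response curvature, and toxicity carries no
signal; real screens violate all four, so recovery rates here are an upper
bound on real-data behaviour.

## Numerical choices

Hypergeometric tails come from `scipy.stats.hypergeom.sf` (exact,
log-space) and are cross-checked in tests against full enumeration with
`math.comb` for every admissible parameter combination with N ≤ 12; BH
q-values come from `statsmodels` and are cross-checked against the step-up
definition. Tables round-trip exactly: floats are written as `repr`,
absent values as empty cells. Normalized tables are kept sorted by
(compound, target) so duplicate collapse is independent of input row
order. In the rank-residual analysis, residuals below 1e−9 (relative to
the rank scale) are treated as zero so that an exact rank agreement yields
all-zero standardized residuals instead of amplified floating-point noise.

## Problem sizes

The test suite exercises the documented scales: exhaustive enumeration to
N = 12; 200 random tables (≤ 50 compounds × 20 targets) against
nested-loop oracles; 100 random instances for the monotonicity suite; and
100 seeded 1,000-compound replicate screens for planted-target recovery
(the full suite runs in about a minute). The acceptance script uses a
1,022-compound screen and the same 100-replicate recovery scenario.

## Known limitations

The frequency/enrichment ranking inherits library composition bias: a
target annotated on many library compounds can rank high without being
causal (the enrichment q, which conditions on K, is the guard). The
control-band threshold pools reference roles via max rather than modelling
them jointly; with a single control well the band collapses to its mean.
The Excel adapter assumes one row per (compound, target) record; matrix-
or pivot-shaped workbooks must be reshaped upstream. Identifier
normalization is typographic only — no synonym mapping against gene
databases.
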