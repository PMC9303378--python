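# Methods

This note documents the models and procedures implemented in `dietsweep`,
the parameter choices behind their defaults, and what the synthetic data
do and do not establish.

## Diet-profile model

A consumer's diet is a selection-probability vector over a fixed pool of
`n_taxa` food taxa (default 100), non-increasing in rank. Sequencing is
modelled as a single multinomial draw of `n_reads` reads (default 25,000,
a typical per-sample MiSeq yield) from that vector: ideal data with no
contamination, amplification bias or sequencing error, so every downstream
distortion is attributable to the analysis itself.

Rank-abundance skew is parameterised by a Pareto shape α, with the field
convention that low α means a specialist (steep, concentrated) diet and
high α a generalist (even) diet. Mapping α to a probability vector admits
several conventions that differ qualitatively, so the mapping is a
pluggable strategy:

| strategy | definition | skew direction |
|---|---|---|
| `calibrated` (default) | p_r ∝ r^(−β), β(α) = 0.58·α^(−1.12) | low α steep |
| `density` | p_r ∝ α·s^α / r^(α+1) at integer ranks | **high** α steep |
| `survival` | p_r ∝ (s/r)^α at integer ranks | **high** α steep |
| `deviates` | n i.i.d. Pareto(s, α) deviates, sorted, normalised | low α steep (stochastic) |

The two rank-evaluation conventions invert the field's α-to-skew
convention, and sorted random deviates have very high sampling variance
(the realised profile depends mostly on the largest deviate). The default
`calibrated` strategy therefore uses the rank power law — the deterministic
skeleton of the Pareto quantile transform, whose exponent scales as 1/α —
with the two constants (0.58, 1.12) fixed once so that the three canonical
consumers reproduce the established benchmark behaviour of threshold
filtering at 25,000 reads and 100 taxa: a 0.2% RRA filter removes ≈75% of
the specialist's and ≈80% of the intermediate's observed taxa while
leaving the generalist untouched, and a 2.8% filter removes >95% of the
intermediate's and generalist's. This calibration was performed against
those published loss values (medians over independent simulations), not
against any package test, and the constants are not meant to be tuned per
study. The strategy used is recorded in all simulation metadata.

## Threshold semantics

"Filtering at t" retains a taxon in a sample iff its RRA strictly exceeds
t, computed on the *original* table. Strict retention is the only reading
under which a 0% threshold returns the complete data. Consequences:
filtering is idempotent; retained sets are nested as t grows; at t > 0
per-sample richness is < 1/t; a threshold of 1 empties every sample (a
monoculture's RRA of 1 is not > 1). Counts of retained taxa are never
renormalised — richness and loss depend on retention only — and percent
loss is measured against the threshold-0 richness S₀.

The default grid is 0–5% in 0.2% steps (26 points), covering the range of
cutoffs in common use; all benchmark cutoffs (0.2%, 2.8%, 4%, 5%) are grid
points. Convergence is reported, by default, as the smallest grid
threshold achieving the smallest richness spread attainable anywhere on
the grid, with the achieved spread returned alongside ("similar richness"
has no canonical quantification; with tolerance 1 taxon the default
simulation converges in the 4–5% region, while a spread of ≤2 taxa is
already reached near 2.8%).

Rank-order inversions are recorded at a threshold t when a pair of samples
strictly ordered by richness at threshold 0 is strictly ordered the
opposite way at t; ties (shared average ranks) neither create nor count as
inversions.

Dropout ledgers treat a taxon as present in a group at threshold t if it
is retained in at least one of the group's samples; the ledger lists, per
group and threshold, the taxa present unfiltered but absent at t,
aggregated at a chosen taxonomy rank with an `unknown` bin for
unannotated sequences. Group-level presence as "retained in ≥1 sample" is
an interpretation choice (the natural one for population-level analyses)
and is stated here rather than configurable.

## Hill numbers

D(q) = (Σ pᵢ^q)^(1/(1−q)) over the positive entries only (standard Hill
convention, including q = 0), with D(1) evaluated as exp of Shannon
entropy. Orders within 1e−9 of 1 use the entropy limit, which keeps the
profile numerically continuous (|D(1±1e−6) − D(1)| < 1e−4 in the property
tests). Group profiles may be computed on pooled counts (default) or
per-sample with means taken afterwards; both pathways exist because
composite-matched pooling is what microhistology provides, while
per-sample means are what DNA data support. Microhistology percent
columns are renormalised to proportions before D(q) to absorb rounding.

## Rarefaction

Each sample is subsampled to a common depth without replacement
(multivariate hypergeometric), the correct model for drawing from reads
that were actually sequenced; a multinomial mode exists for purely
simulated compositions. The default depth is the minimum positive sample
total. Samples shallower than the depth are dropped with a warning; taxa
reduced to zero total count are removed.

## Population-level richness

Groups of samples are reduced to incidence frequency counts (T, S_obs,
Q₁, Q₂). Undetected richness uses Chao2 with the (T−1)/T small-sample
factor and the bias-corrected branch when Q₂ = 0; extrapolation to T + t*
units uses the standard sample-based formula (see README). The
implementation is cross-checked against `vegan::specpool`, which uses the
identical variant, to 1e−6 over random incidence matrices.

Extrapolation targets default to twice the smallest group size within each
outer stratum (per species: twice the smallest seasonal sample count),
i.e. N = 8 for a 6/4 design and N = 20 for a 15/10 design. Confidence
intervals are a percentile bootstrap over sampling units (B = 200,
level 0.95). Because resampling units with replacement duplicates samples
and deflates uniques, the raw bootstrap distribution of the Chao2-based
estimate is biased low; replicates are recentred on the original-data
estimate before percentiles are taken, which removes that bias and
guarantees the interval brackets the point estimate. Extrapolation is
computed for richness (q = 0) only.

## Synthetic wildlife data

The generator emulates the statistical structure of a two-species,
two-season grazer study: 35 samples (bighorn-like 6 summer / 4 winter,
bison-like 15 summer / 10 winter), a 355-taxon master pool in 21 families
(graminoid families large and available year-round, forbs mostly in
summer, woody browse mostly in winter), per-sample rank-power compositions
(exponent 1.4 ± 0.3), lognormal read depths around 40,000, rarefaction to
the minimum depth, and nested annotation masking at 88% / 55% / 23%
(family / genus / species), which for a 355-taxon pool yields 312 / 195 /
82 annotated sequences. Mean per-sample richness is 45 for the first
species in winter, scaled by 1.6 for summer and 1.4 for the second
species — values chosen to put unfiltered sample richness in the 40–110
range typical of trnL-P6 grazer profiles.

The seasonal surplus is deliberately fragile: with
`low_rra_summer_excess=True` (default) forbs enter samples at tail ranks
and summer profiles are steepened by +0.15 (winter −0.15), so the extra
summer taxa sit at low RRA. Unfiltered, summer > winter mean richness in
both species and the bison-like species out-ranks the bighorn-like in
total extrapolated richness; any threshold ≥ 0.2% erases or reverses the
seasonal ordering for the bison-like group. Note that in this generator
the same mechanism applies to both species, so the bighorn-like group may
reverse as well; only the bison-like contrast is asserted. Cell sizes of
15/10 rather than 14/11 for the bison-like species were chosen so the
double-minimum rule lands on N = 20.

The microhistology companion pools the *true* compositions per
species-season cell (equal-weight mean across samples) into one percent
composite, then lumps genera: two resolvable genera per family, everything
else into an `unknown <family>` sink — so grass-rich families collapse to
a single category and composite richness falls strictly below the pooled
DNA richness.

What the synthetic data do **not** emulate: sequencing error, chimeras,
tag jumps, pollen contamination, reference-library incompleteness,
phylogenetic structure among taxa, or any real co-occurrence structure.
Tests passing on these data show that the pipeline recovers effects that
are present and destroys them in the designed way under filtering — not
that any particular wild population behaves this way.

## Numerical and design choices

* Randomness: every stochastic routine takes one integer seed; multi-draw
  routines split it into per-sample child seeds via `SeedSequence` (all
  < 2³¹) and record them in output metadata.
* Degenerate inputs: all-zero samples yield all-zero RRA with a warning;
  all-zero compositions are an error for Hill numbers; empty groups are an
  error for incidence reduction; degenerate (all-empty) bootstrap
  resamples are redrawn up to a cap.
* Probability vectors are renormalised exactly by pushing rounding slack
  onto the largest entry.
* CSV outputs carry `#`-prefixed provenance headers (version, command,
  parameters, seeds) and readers skip them.
* The CLI accepts thresholds in percent (0.2 = 0.2%) and stores fractions
  internally; the library API uses fractions throughout.

## Known limitations

* The calibrated strategy's constants are tied to the benchmark design
  point (100 taxa, 25,000 reads); at very different depths the same β
  mapping gives different loss percentages, as it should.
* Percent-loss medians at small observed richness move in coarse steps
  (each lost taxon is worth several percentage points for a specialist).
* The bootstrap interval is percentile-based and symmetric-in-rank only;
  no BCa correction is attempted.
* Coverage-standardised (rather than size-standardised) comparisons and
  significance testing across groups are out of scope.
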