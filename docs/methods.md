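# Methods

## The measurement and its conventions

A BONLAC experiment labels nascent proteins in acute hippocampal slices
with AHA (for click-chemistry enrichment) while simultaneously applying
medium/heavy SILAC labels to the two genotypes in the same run. MaxQuant
reports one normalized H/M ratio per protein group per replicate; this
package takes those ratios as given (it never re-normalizes) and works at
the protein-group level, keyed by the group's leading accession, with the
gene symbol carried as annotation.

All ratios are oriented as **affected over control** (APP/PS1 : WT).
Because label assignment alternates between biological replicates, each
replicate carries an orientation flag in the label design; swapped
replicates are inverted element-wise at ingestion and nowhere else. Empty
cells, `NaN`, and `0` in ratio columns all denote a failed quantification
(a zero SILAC ratio is non-physical); decoy (`REV__`), potential
contaminant, and only-identified-by-site rows are dropped and counted.
Site-only removal is configurable, since published pipelines differ on it.

## The coincidence-detection screen

Per protein, with `n` replicates and oriented ratios `r_1..r_n` (some
missing), three filters must coincide:

1. **Majority detection.** At least ⌊n/2⌋+1 ratios present (3/5, 4/7);
   `min_detected` may instead fix an explicit floor (e.g. 5/7). Proteins
   below the floor are `insufficient` and excluded from the screened
   denominator.
2. **Average fold change.** The mean ratio over detected replicates is
   ≥ 1.2 (up) or ≤ 0.8 (down). The default is the arithmetic mean,
   mirroring the original procedure; a geometric mode is provided as the
   log-symmetric alternative, and under it (with reciprocal thresholds)
   inverting every ratio exactly swaps up and down calls — a property the
   arithmetic mean only approximates.
3. **Direction consistency.** Strictly more detected replicates shift in
   the called direction than against it; ratios exactly 1 count toward
   neither side, and a tie yields `unchanged`.

No multiple-testing correction or outlier statistic is layered on top: the
three filters are the screen. Cohort summaries report counts and
percentages of the screened set, rounded half-up to one decimal.

Cross-cohort concordance considers only proteins called up or down in
*both* cohorts; the overlap partitions into both-up, both-down, and
reversed, reported both as counts and in `k/overlap` style. Matching is by
protein-group identifier; gene symbols never affect it.

## Fold-change clustering

Proteins majority-detected in every cohort enter a matrix of cohort mean
ratios (same averaging convention as the screen), log-transformed (base 2
by default) and centered. Per-protein (row) centering is the default
reading of "mean-normalized": colors then encode each protein's deviation
from its own cross-cohort mean; per-cohort and uncentered modes are
available, as is a broad fold-change window annotation (e.g. 0.85–1.15)
that marks near-unchanged proteins without filtering them.

Rows are clustered agglomeratively with **unweighted average linkage
(UPGMA)** on Euclidean distances. The merge loop is implemented in the
package rather than delegated because determinism under distance ties is
part of the contract: tied merges resolve toward the pair whose combined
sorted member-index tuple is lexicographically smallest. Inter-cluster
distances follow the unweighted Lance–Williams update
`d(k, i∪j) = (|i|·d(k,i) + |j|·d(k,j)) / (|i|+|j|)`, which equals the mean
over all cross-cluster leaf pairs; the test suite checks equivalence
against an exhaustive O(n³)-per-step recomputation (merge order exactly,
heights to 1e-9 relative — the two routes differ only in summation order)
and cross-checks heights against an independent library implementation on
tie-free inputs. Average linkage is inversion-free, so merge heights are
non-decreasing and a flat cut into k clusters removes exactly the k−1
highest merges. Trees export to Newick with ultrametric branch lengths
(leaf depth = final merge height / 2).

## Validation statistics

Western-blot band densities are normalized in-lane (band / lane total
protein) and expressed relative to the mean of the blot's WT lanes, making
the WT mean exactly 1 within each blot and values comparable across blots.
Group comparisons use **Student's pooled-variance** two-sample t-test with
df = n₁+n₂−2 — the form consistent with integer degrees of freedom in
legend-style reporting — with the 95% CI from the pooled SE and the
central-t quantile, and the effect reported as mean difference ± its SE.
The effect (and the sign of t) is mean(second) − mean(first), so calling
with (control, affected) reads as the affected-relative-to-control shift.
p-values are rounded half-up to four decimals and reported as `< 0.0001`
below that resolution. Degenerate inputs: two constant equal groups give
t = 0, p = 1; two constant unequal groups are flagged and report p at a
floor rather than 0. Regression is ordinary least squares with
r² = 1 − SSres/SStot and the slope's t-test at n−2 df.

## The synthetic-data generator

`simulate_experiment` emulates the statistical structure the screen
assumes, with a truth table for every protein:

- **Effects.** A fraction of proteins carries a fixed true fold change
  (default 4% up at 1.6, 6% down at 0.625 — approximately the young
  cohort's observed candidate rates and a ±40–60% effect size detectable
  by blot); the rest are null at 1.0.
- **Noise.** Multiplicative log-normal noise on ratios (default sd 0.25 on
  the log2 scale, a typical biological replicate spread for SILAC ratios),
  split evenly between the two isotope channels so that channel-level
  dropout can act on realized channel abundances.
- **Label swaps.** The default pattern alternates forward/swapped across
  replicates; raw H/M ratios are emitted per flag so ingestion's
  orientation step is always exercised. Flipping every flag in generator
  and design together changes oriented values only by reciprocal rounding
  (≤ 1 ulp) and no downstream call — asserted as a property.
- **Missing-not-at-random dropout.** Each protein has a latent log10
  abundance (default N(7, 1), an intensity-like scale); each channel drops
  out with probability logistic in its realized log-abundance (midpoint 6,
  slope 2 per decade), and the ratio is missing if either channel fails.
  The affected genotype's channel is scaled by `global_synthesis_scale`
  (default 0.8, matching a ~20% global synthesis deficit), shifting it
  toward dropout. The logistic parameters are free knobs — the
  dropout-vs-abundance relationship is not quantified by data — chosen so
  that roughly a third of ratio cells are missing and two thirds of
  proteins pass majority detection, comparable to the detected/screened
  proportions in real cohorts.

One seed sequence per experiment spawns per-protein sub-streams, so
identical configs are byte-identical and per-protein draws are stable.

**What the generator shows — and does not.** Under the default conditions
the screened null proteins show an excess of *up* calls. Three mechanisms
contribute in the same direction: the ±20% band is asymmetric on the log
scale (1.2 is easier to reach than 0.8 from symmetric log-noise), the
arithmetic mean of log-normal ratios is biased above 1, and channel-level
MNAR dropout preferentially removes low-affected-channel observations. At
realistic noise the third effect is small for nulls but strong for true
downregulation: proteins synthesized less in the affected genotype fail to
yield ratios at all more often than upregulated ones (also asserted as a
property), which is the substantive detection bias of ratio-based de novo
proteomics. The generator does not simulate peptide-level evidence,
intensity-dependent ratio precision, shared-peptide protein-group
ambiguity, or correlated replicate batch effects, so passing tests show
the *procedure* behaves correctly under the stated statistical model, not
that real cohorts satisfy that model.

`simulate_blot` draws normalized relative densities Gaussian around 1 (WT)
and the true ratio (TG) — the additive model under which the downstream
pooled t-test has the textbook noncentral-t power, used as a closed-form
oracle — and folds them into band/total densities with varying lane totals
to exercise in-lane normalization.

## Problem sizes and numerical choices

Test and acceptance runs use 200–2000 proteins × 5–7 replicates, 20 seeds
for recovery estimates, 200 random matrices (≤ 8 rows) for the clustering
oracle, and 500–1000 blot simulations for power calibration — sizes at
which Monte-Carlo bands are tight enough for the asserted tolerances while
the whole suite stays interactive. Percentages and p-values round half-up
(`decimal`), never banker's rounding, to match legend-style reporting.
Screen calls are emitted in sorted protein-id order; clustering tie-breaks
are lexicographic; both make every pipeline output order-independent and
platform-deterministic.

## Known limitations

- The arithmetic screen mean is kept as the default for fidelity to the
  original procedure even though the geometric mean is the principled
  choice for ratios; both are exposed.
- The aged-cohort generator settings (shallower proteome, up-shifted
  candidate mix) are descriptive choices for the analysis narrative, not
  estimates fit to data.
- Western-blot simulation clips normalized densities away from zero;
  at plausible noise levels the clip is unreachable.
- The Newick export encodes an ultrametric dendrogram; branch lengths are
  halves of merge-height differences, not evolutionary distances.
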