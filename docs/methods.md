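# Methods

This note records the models the package implements, the parameters that
matter, what the synthetic-data generator does and does not emulate, and the
design choices made where the design was genuinely open.

## Synthetic data generator

The generator produces inputs with the statistical structure every downstream
stage assumes, as pure functions of a configuration and a seed (one seeded
`numpy` generator per call, no global state).

**Upstream sequences.** Promoters are fixed-length (default 500 bp) strings
drawn i.i.d. per position from an order-0 background parameterized only by GC
content (default 0.43, a Drosophila-like value).  An order-0 background keeps
the enrichment null analytically checkable — the exact PWM score distribution
and the HMM background model both assume it.  Real promoters are not order-0
(CpG avoidance, microsatellites, TATA positioning), so passing enrichment
tests here demonstrates correctness of the statistics, not robustness to
compositional structure.

**Site planting.** Each promoter receives a Poisson(rate) number of sites
sampled column-wise from the matrix; `affinity_jitter` (default 0.1) mixes
each column toward uniform, broadening the affinity spectrum.  Sites are
placed at uniform positions on a uniformly chosen strand and never overlap;
a site that cannot be placed after 100 attempts is dropped with a warning,
keeping the annotation table an exact ground truth (every annotated substring
equals the planted text at the recorded position — asserted in tests).
Defaults plant 2 sites per target promoter versus 0.2 per background
promoter.

**Two-channel arrays.** Channel 2 carries a common reference, channel 1 the
sample of each array; arrays alternate mutant / control within two contrast
pairs (default 22 arrays, mirroring the emulated design; power analyses use
8).  On the log2 scale, intensities are
`base + dye bias + print-tip distortion + genotype effect + noise`, then
exponentiated.  Per-gene abundance is N(10, 1.5²); each gene appears as 2
duplicate elements (kept un-averaged downstream); per-channel noise SD
defaults to 0.25 (so the log-ratio noise SD is 0.25·√2).  The dye bias is a
single additive constant per array (SD 0.3) — the simplest structure
within-array normalization must remove.  The print-tip distortion is a
smooth per-tip curve `c₁·z + c₂·(z²−1)/√2` in the standardized abundance z,
with coefficients N(0, 0.3) and z clipped to ±2: real print-tip trends are a
few tenths of a log2 unit across the intensity range, and without the clip a
quadratic in an unbounded z produces multi-log2-unit artifacts at abundance
extremes that no within-array normalization (and no real scanner) would
exhibit.  A chosen fraction of genes (default 10%) carries ±`de_log2_effect`
(default 1.0) on mutant arrays, signs recorded in a truth table.  Spot
morphology, saturation, and spatial artifacts beyond the print-tip structure
are not modelled.

**Crosses.** Wing severities are multinomial draws from the control class
law exponentially tilted by `exp(shift·class)`; shift 0 reproduces the
control law, positive shift moves mass toward severe classes, and classes
with zero control probability stay empty.  Bristle outcomes are binomial.
Vial-level structure is flattened (results were pooled across vials in the
emulated protocol), and no sex-ratio structure is simulated.

## Expression screen

Filtering discards an element, per array, when it is below the per-array
median in **both** channels (strict inequality, so ties survive); no other
background correction is applied.  Filter flags are computed from raw
intensities; filtered observations are excluded from the loess fit and from
the ANOVA but still pass through normalization, so arrays keep complete
element sets for the quantile step.

Print-tip loess uses the tricube locally-linear smoother with span 0.3 and
three robustifying iterations, fitted per (array, print-tip) group and
evaluated at every element; groups need at least 10 elements.  Quantile
normalization maps each of the 2·n_arrays log2 channel vectors onto the mean
of the across-column order statistics (ties get the interpolated mean, which
makes the transform idempotent), then recomputes M and A.  Quantile
normalization mildly compresses true effects when the differential fraction
is asymmetric between arrays — a known property of the method, visible in the
recovery simulations as a few-percent shrink of estimated log2 effects.

The per-gene model is ordinary least squares `M ~ contrast_pair + genotype`
with a partial F-test (1 df) on the genotype term; whether array or dye
should enter as covariates is not derivable from the emulated protocol, so
the minimal model was chosen and recorded in the output metadata.  Genes with
fewer than 2 unfiltered observations in either genotype class are reported
with missing p and excluded from FDR correction rather than imputed.  A gene
with zero residual and zero effect is reported as F = 0, p = 1.  Direction is
the sign of the genotype coefficient (down = lower in mutants); an exactly
zero coefficient (measure-zero) is excluded from selection.  FDR correction
is Benjamini–Hochberg throughout the package (validated in tests against an
independently written step-up rule).

Because the low-intensity filter censors genes by abundance — on synthetic
data roughly the bottom half of genes, since both channels reflect the same
latent abundance — the power analyses of spike-in recovery run the
normalization + ANOVA + selection chain without the filter: the synthetic
intensities contain no low-intensity artifact for the filter to remove, and
recovery of a gene the filter has discarded is undefined rather than a
property of the selection machinery.  The filter is exercised by its own
unit tests and remains part of the standard pipeline.

## Binding-site enrichment

**Scores on a grid.** Window log-odds scores, the exact null distribution,
and hit thresholds all live on one integer grid of 0.01 log2 units
(`SCORE_GRID`); per-column log-odds are rounded to the grid before any use,
so the dynamic-programming convolution over columns is *exact* for the score
function actually scanned, and the threshold's tail probability is the exact
per-window false-hit rate.  Zero-probability bases (pseudocount 0) are
floored at −100 log2 units per column rather than −∞, which keeps arithmetic
finite while guaranteeing such windows can never reach a hit threshold.
Windows containing N are skipped and counted, not scored.

**Threshold scan.** The hit threshold is the smallest grid score whose exact
upper-tail probability is at most 1 − quantile (default quantile 0.999).
Both strands are scanned — binding sites are double-stranded features — and
reported positions are forward-strand 0-based starts.  Set-level
significance is the upper-tail hypergeometric probability of the target hit
count, with the target set a subset of the background set.  The
hypergeometric test is discrete and therefore conservative at these sample
sizes; null calibration lands slightly below the nominal rate.

**HMM topology.** One background state B plus match states M1..MW;
B→B (1−τ), B→M1 (τ), Mi→Mi+1 (1), MW→B (1); the initial distribution mirrors
B's outgoing probabilities so a site may begin at base 1, and the forward sum
runs over all end states so a partial site may abut the 3' end.  τ defaults
to 1/promoter-length (one expected site per promoter).  The topology, τ and
the set-level p-value mechanism were open choices; this left-to-right block
with background return is the minimal model that supports several sites of
varying affinity per promoter, and the set-versus-background comparison is a
one-sided rank-sum test (normal approximation with tie correction; exact
enumeration when both sets have ≤ 8 promoters) of target scores against the
scores of the remaining background promoters.  With match emissions equal to
the background the likelihood ratio collapses to the total path weight, 1,
for every sequence — scores are exactly 0, a closed form asserted in tests.
N bases are emitted with probability 1 in every state and in the background
model, cancelling in the ratio.

Background base frequencies default to the empirical frequencies of the
supplied background promoter set, not uniform.  Both strands are scored and
the larger taken, which makes scores invariant under reverse-complementing
the input.  Whether a single-stranded DNA binder like SSDP warrants
single-strand scoring is not decidable from the emulated protocol;
both-strand scanning is applied uniformly and is configurable.  FDR strata:
correction runs across the matrix library within each method × gene-set
stratum, mirroring a screen of one constructed site against a full matrix
library.

The packaged single-site sequence (`CTCTTTCTTTCTCT`) is a synthetic
poly-pyrimidine placeholder of realistic width and composition — the
canonical SSDP site sequence is not distributed here, and any user site can
be supplied instead.  The "flexibility" softening of indicator matrices is a
symmetric pseudocount, default 0.1 (observed base (1+ε)/(1+4ε)).

## Genetic screens

The wing comparison is implemented as the rank-sum (Mann–Whitney) test with
tie correction over per-fly ordinal classes: the emulated protocol names the
Wilcoxon signed-rank test, but that statistic requires paired data and these
are two independent fly populations; the output metadata keeps the original
naming.  Direction (enhancer = stochastically more severe) comes from the
rank mean; two identical samples return p = 1.  Significance threshold for
calling is α = 0.05 (configurable — none is derivable from the protocol), and
no multiplicity correction is applied to the wing screen (only the bristle
screen's protocol specifies FDR); a flag enables it.  The concordance rule
for the final call: all significant results must agree in direction, and
either every allele is significant in both sexes, or one allele is
significant in both sexes and every other allele in at least one sex.
The dominant-*ap* assay's 2-class control / 3-class test scheme is handled by
the same machinery with per-assay class schemes mapped to their printed
order.

The bristle test computes both exact binomial tails at the plug-in control
rate p̂ = (d+1)/(n+1) and reports the smaller with its direction (the
protocol does not fix a tail).  Two consequences, both visible in
simulations and documented rather than patched: taking the minimum tail
roughly doubles the effective false-positive rate relative to a one-sided
test (the FDR simulations land near 0.09 at a q < 0.05 threshold, within the
≤ 0.1 design bound), and treating p̂ as known ignores control-cross sampling
error, which inflates the false-discovery proportion substantially when the
control cross is small — the package therefore reports p̂ alongside the
calls so users can judge the control's precision.

The packaged screen-table replica summarizes to: per column, tested (≠ n),
interacting (+ or −), enhancers and suppressors; combined over the two
bristle sensitizers, role counts are distinct genes per role — a gene
enhancing one sensitizer and suppressing the other carries both roles — next
to distinct-gene counts.  The number of genes non-zero in *both* bristle
columns is reported from the table codes (6) with an explanatory note, since
the accompanying narrative arithmetic (5) cannot be reconciled with the
table itself.

## Problem sizes and validation scale

The test suite validates the scoring engines exhaustively (all 4⁸ sequences
against brute-force path enumeration; all 4^W windows for W ≤ 5; all C(12,5)
target subsets), and the statistical properties at simulation scales chosen
to keep the full suite at a few minutes: null calibration over 1000
motif × seed strata and 1000 wing crosses; motif power over 50 seeded
replicates of 100 target / 1000 background promoters; expression recovery
pooled over 20 seeded experiments of 2000 genes × 8 arrays.  The 3-SD
binomial bounds used in calibration assertions make the tests' own false
alarm rate ≈ 0.3% per check.

## Known limitations

* Order-0 sequence background and additive log-normal array noise are
  idealisations; calibration on real data will be worse than on these
  simulations.
* The hypergeometric stage is conservative for small gene sets; the HMM
  rank-sum stage assumes exchangeability of promoters within a set.
* The plug-in bristle test understates uncertainty from small control
  crosses (see above).
* Quantile normalization compresses effects when differential expression is
  unbalanced across arrays; estimated log2 effects are mildly biased toward
  zero.
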