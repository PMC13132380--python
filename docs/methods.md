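# Methods

## Promoter model and coordinates

All intervals are 0-based half-open (BED-native); any 1-based dialect must
be converted at the reader boundary. A promoter is the strand-aware window
TSS − upstream / + downstream (defaults 1,000 bp each side), clamped at
position 0 rather than dropped so that the gene universe stays identical
across marks and conditions. One TSS per gene is required; collapsing
multi-TSS genes is the caller's responsibility. Peak-to-promoter assignment
is any-overlap (≥ 1 bp under half-open semantics): a peak ending exactly at
a promoter start does not overlap. When several scored peaks overlap a
promoter, its intensity is the maximum overlapping score — the conservative
single-number summary of per-peak height.

## Bona fide bivalency

Bivalency calls are gene-level set operations: separate-ChIP bivalency
requires ≥ 1 peak of each mark in the window, sequential-ChIP bivalency
requires ≥ 1 re-ChIP peak, and the bona fide set is their intersection. No
minimum overlap width and no IgG subtraction are applied; a gene with
several qualifying peaks counts once. The protein-coding restriction is a
biotype filter applied when the promoter set is built, not in the calling
step. Co-occupancy of a factor at bivalent promoters is the fraction of
bivalent genes whose window carries ≥ 1 factor peak; it is undefined (an
error) on an empty bivalent set.

## Differential marking

The between-condition comparison follows the classic M–A normalization plus
exact count test design. For each gene, M = log₂((x₁+c)/(x₂+c)) and
A = ½(log₂(x₁+c) + log₂(x₂+c)). The normalization model M = a + b·A is fitted
by ordinary least squares on the *common* promoters (both raw intensities
strictly positive), with one optional robust pass removing points whose
residual exceeds 3 scaled MADs (on by default; the MAD is normalised by
1.4826 for consistency with a Gaussian σ). Condition 2 is rescaled as
x₂′ = x₂·2^(a+bA). The fit uses pseudocount 0 — common promoters are
strictly positive, and this makes the model exact on noise-free
proportionally scaled data (a global 2× scale is recovered to machine
precision, and re-fitting already-normalized data returns a ≈ b ≈ 0);
reported M/A values use the configured pseudocount (default 1).

The fit assumes most common promoters are unchanged. When a large fraction
of genes genuinely changes in one direction (heavy planted switching in the
simulator, or a drastic perturbation in real data), part of the shift is
absorbed into the model and the post-normalization median M on common
promoters drifts from 0; the scaler warns when it exceeds ±0.05 rather than
failing.

Significance: normalized intensities are rounded half-to-even to counts and
tested with the exact conditional count test. Under the shared-rate null,
P(y|x) = (x+y)!/(x!y!2^(x+y+1)); conditional on the total t = x₁+x₂ this is
(half of) the Binomial(t, ½) likelihood, and the two-sided p-value doubles
the smaller conditional-binomial tail (capped at 1). The tails are evaluated
at the smaller of the two counts so that p(x₁,x₂) = p(x₂,x₁) holds exactly,
not merely to rounding. Two-sided testing is the default. A gene is called
changed when p < 0.05 (strict) and |log₂FC| ≥ 0.58 (inclusive — 0.58 ≈
log₂ 1.5). No multiple-testing correction is applied by default, matching
the raw-p convention of the analysis this reproduces; a Benjamini–Hochberg
flag is available as a clearly separate extension. On equal-mean Poisson
counts around 50 the realised type-I error at p < 0.05 is ≈ 0.04 (the test
is mildly conservative through discreteness); power for 2-fold changes
rises steeply with counts, from ≈ 0.70 at counts of 20 to > 0.95 at 50 —
the power benchmark therefore draws base intensities log-uniformly from
[20, 200], a representative promoter fragment-count range.

## Bivalency states and transitions

Bivalent promoters are labelled by the pseudocounted intensity ratio
r = (k4+c)/(k27+c), c = 0.5: cluster I when r ≥ 1.5, cluster II when
1/r ≥ 1.5, cluster III otherwise. Both boundaries are inclusive (a ratio of
exactly 1.5 is cluster I), the two high conditions are mutually exclusive
for any threshold > 1, and swapping the marks swaps I ↔ II while fixing
III. The deterministic threshold rule is the primary classifier; a k-means
(k = 3, 50 restarts, fixed seed) on (log₂ k4, log₂ k27) is provided only as
a diagnostic cross-check and agrees with the rule on ≥ 90% of genes under
the default simulation.

Transitions between two conditions are cross-tabulated over the union of
the two gene universes, with genes absent from one side recorded as
nonbivalent there; row sums therefore conserve the per-condition label
counts. "Bivalency resolution" switches are II→I and III→I by default. The
switch-up fraction counts switch genes with expression log₂FC > 0 and
errors when no gene switches. The mark/expression relationship is a Pearson
correlation (two-sided t-test p, n−2 df) over all bona fide bivalent genes
by default (configurable to switch genes only); expression change enters as
a precomputed per-gene log₂FC table — upstream RNA-seq differential
expression is out of scope.

## Meta-programs

Per-sample NMF (scikit-learn, Frobenius objective, coordinate-descent
solver, NNDSVD-A initialisation, ≤ 500 iterations, fixed seed — fully
deterministic) is run at k = 4…9 after log1p and per-gene clipping at the
99.9th quantile (no centering; NMF requires non-negativity). Each factor
yields a program instance: the top-90 genes by loading. Clustering then
(1) keeps only instances recurring within their sample at ≥ 2 distinct
ranks with Jaccard ≥ 0.2; (2) seeds a cluster from the most-partnered
instance, ranking candidates by the *sum* of Jaccard similarity over
cross-sample partners so that a program strongly shared across samples
outranks a diffuse factor with many weak links (ties broken by
(sample, k, factor) key); (3) absorbs every instance at Jaccard ≥ 0.2 to the
seed, with the consensus being the 90 most frequent genes across members
(ties by summed loading, then gene id); (4) repeats until no seed has a
cross-sample partner; and (5) drops clusters supported by < 2 distinct
samples. Clustering is hard (each instance joins ≤ 1 meta-program) and
deterministic. The recurrence thresholds are config-exposed.

## Synthetic data generator

The generator emulates the statistical structure the pipeline consumes, not
the sequencing process. Each gene is planted in one of five states —
three bivalent (H3K4me3-high, H3K27me3-high, equal) and two non-bivalent
(active, silent) — with default fractions (0.10, 0.10, 0.10, 0.35, 0.35),
i.e. 30% bivalent; counts follow largest-remainder rounding (ties by state
enumeration order). Default state mean intensities (μ_K4, μ_K27) are
(8, 2), (2, 8), (5, 5), (8, 0.5) and (0.5, 0.5), separated enough that the
1.5-fold ratio rule is unambiguous under the noise model. Intensities are
the state means times a shared per-gene, per-condition log-normal factor
exp(ε), ε ~ N(0, σ²) with σ = 0.3 by default — promoter-level
efficiency/accessibility noise that preserves the within-promoter
K4/K27 ratio. Mark-specific technical noise (independent per IP) is *not*
modelled; under such noise the equal-state ratio would cross the 1.5-fold
boundary far more often, so state-recovery results here bound real-data
performance from above. A mark's peak is emitted when its intensity exceeds
twice the silent-state mean; sequential peaks are emitted exactly at
bivalent promoters. Between conditions, a configurable fraction (default
0.5) of the cluster-II/III genes resolves to cluster I; switching genes
receive positive expression log₂FC with the coupling probability (default
0.85, magnitudes Exponential(1)), others draw N(0, 1).

The meta-program simulator adds, per sample, additive blocks
(amplitude 5) on program genes × a random 25% cell subset over gamma
baseline noise (mean 0.5). The default planted study uses 5 disjoint
90-gene programs shared by 8 samples of 150 cells over a 2,000-gene
universe — the typical highly-variable-gene count of an scRNA-seq input.
With a much smaller gene universe, chance top-90 overlap between baseline
noise factors can exceed the 0.2 Jaccard threshold and create spurious
two-sample meta-programs; a realistic gene count keeps chance overlap near
0.03.

All generators are bit-reproducible given their seed. What passing tests on
this data do *not* show: robustness to per-mark technical noise, to peak
callers' boundary errors, to copy-number or mappability artifacts, or to
scRNA count-depth variation — none of which the generator models.

## Numerical and design choices

- Intensities are rounded half-to-even before the exact test; M/A reporting
  uses pseudocount 1, the CBS ratio pseudocount 0.5.
- Problem sizes in the test-suite benchmarks: 1,000–2,000 genes for
  calling/classification oracles, 5,000 × 10 null pairs for calibration,
  25,000 genes for the switch-coupling study (≥ 2,000 switch genes), and
  8 × (2,000 × 150) matrices for meta-program recovery — small enough to run
  on a laptop in well under a minute per stage while keeping binomial
  sampling error far below the tolerances asserted.
- The pipeline writes JSON with sorted keys and explicitly rounded floats,
  which is what makes re-runs byte-identical.

## Known limitations

- The normalization is the linear M–A rescaling; hierarchical
  mean–variance modelling across replicates is out of scope.
- Signal "intensity" is whatever non-negative per-promoter number the
  caller supplies (summit height, mean coverage, area …); the package is
  agnostic and no attempt is made to convert between conventions.
- Meta-program functional annotation (GO/GSEA) and upstream single-cell QC
  are out of scope.
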