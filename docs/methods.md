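# Methods

This note documents the models behind each stage, the defaults and why,
what the synthetic cohorts do and do not emulate, and the numerical and
design choices made where the design was genuinely open.

## Data model and conventions

All internal coordinates are 0-based half-open. On disk, BEDPE and BED are
0-based half-open and SEG and the mutation table are 1-based inclusive,
matching each format's prevailing convention. The breakpoint position of a
BEDPE end interval is its start coordinate: end intervals are typically
1 bp, and a single representative point is needed to order the two ends of
an event. Sex chromosomes are accepted in the data but excluded from the
fraction-of-genome-altered denominator by default (`include_sex` flips
this); the autosome-only denominator is the common convention and the
choice is reported in output metadata.

## Rearrangement classification and the burden mixture

Same-chromosome breakpoint pairs are typed by the strand pair of their
position-sorted ends: (+,−) deletion, (−,+) tandem duplication, (+,+)/(−,−)
inversion; different chromosomes give an interchromosomal event. This is
the common paired-end SV convention; callers differ in dialect, so the
strand map is a replaceable argument.

Per-sample burden counts span orders of magnitude across tumors, so the
subpopulation decomposition fits a two-component Gaussian mixture to
log10(count + 1) (the +1 guards zeros) by EM:

- initialization by quantile split (lower/upper halves of the sorted data
  seed the components) — deterministic, no restarts needed in 1-D;
- convergence when the log-likelihood gain drops below 1e-8, cap 500
  iterations; a variance floor of 1e-6 guards collapse onto a point mass;
- components are reported sorted by mean, so "high" is always component 1;
- a one-component Gaussian fit is computed alongside and compared by BIC
  (ΔBIC = BIC₁ − BIC₂ > 0 favors two components). Degenerate inputs (all
  counts equal) therefore yield a one-component-preferred flag instead of a
  failure.

Per-sample labels are arg-max responsibility with ties assigned low. The
default decomposition uses total counts; the burden table also carries the
intra/inter channels so either can be decomposed. Whether the original
cohort's two subpopulations were delineated visually or by model is not
recorded anywhere we know of; the mixture model is this package's explicit,
documented choice.

## Fraction of genome altered

FGA = (summed length of segments with |log2| ≥ t) / (total length of
included chromosomes). Uncovered genome counts as unaltered, gains and
losses both count ("altered", not "deleted"), and the default t = 0.2 is
the conventional array-CN cutoff; all three choices are configuration with
the defaults stated in output. Histogram bins are `<0.01`, then left-closed
interior bins at 0.05/0.1/0.2/0.3/0.4, then `≥0.5`; only the two extreme
bin labels are canonical, the interior edges are this package's choice.

## The rank-sum engine

One Wilcoxon–Mann–Whitney implementation backs both the FGA class
comparison and every lesion–burden association. When both groups have ≤ 8
values the tail probabilities are computed by exhaustive enumeration over
all C(n, n₁) group assignments of the pooled midranks (exact under ties);
otherwise the tie-corrected normal approximation with continuity correction
is used. Three p-values are exposed:

- `p_greater` / `p_less`: fixed-direction tails. These are the calibrated
  objects — under the null each is uniform, rejecting at nominal rate.
- `p_one`: the tail in the direction of the observed shift, the number
  conventionally quoted next to a directed finding. Being a min of two
  tails it is *not* uniform under the null and is never used for
  calibration claims.
- `p_two` = min(1, 2·min tail): the reported association p-value. It
  inherits mild conservativeness from discreteness and the continuity
  correction.

## Lesion matrix, association, exclusivity

A lesion is a gene point mutation (present iff the sample has ≥ 1 mutation
in the gene) or a region deletion (present iff any segment overlapping the
supplied region has log2 ≤ −0.2). Lesions in fewer than `min_recurrence`
(default 3) samples are dropped as non-recurrent; region discovery
(GISTIC-like peak calling) is out of scope — regions are inputs.
Associations compare burden between carriers and non-carriers per channel
(intra, inter, total) with the engine above; Benjamini–Hochberg q-values
are computed across lesions within each channel. Raw −log10 p is emitted
alongside q for conventional association plots.

Mutual exclusivity of two lesions is the one-tail Fisher test:
P(overlap ≤ observed) under the hypergeometric null with fixed margins; a
zero margin returns p = 1 with a degenerate flag.

## Clonality and precedence

The CCF model assumes a well-mixed tumor/normal specimen of purity p where
carrier tumor cells hold m mutated copies at a locus of total tumor copy
number CN, so the expected VAF is v = m·CCF·p / (p·CN + 2(1−p)). The
estimator inverts this at the observed VAF with m = round(v·(p·CN +
2(1−p))/p) clamped to [1, CN] — the simplest multiplicity rule that is
exact at the clonal extremes. The 95% interval propagates a Jeffreys
Beta(alt+½, ref+½) interval on VAF through the same linear map; estimates
and interval ends are clamped to [0, 1].

Deletion clonality assumes mono-allelic loss: the length-weighted mean log
ratio L over the region satisfies 2·2^L = 2 − p·c, i.e. c = 2(1 − 2^L)/p.
An implied c > 1 before clamping suggests bi-allelic loss and is flagged;
L > 0 is flagged not-a-deletion with CCF 0. The interval propagates the
length-weighted standard error of the per-segment log ratios through the
same map (a single covering segment gives a degenerate interval).

Precedence A → B is a one-sided binomial sign test across samples carrying
both lesions: a win for A is ccf_A ≥ ccf_B + δ with δ = 0.1 (the tie zone
absorbs estimation noise; within-δ samples are ignored), edge iff the
binomial tail p < α = 0.05, requiring ≥ 3 co-occurring samples. The
evolution graph runs this for every ordered pair; any cycle is resolved by
repeatedly deleting the cycle edge with the largest p, so the output is
always acyclic and deterministic given the estimates. δ, α and the
co-occurrence floor are configuration.

## Signature segregation

Samples are clustered on the signature genes only, with distance
1 − Pearson correlation between sample profiles and average linkage —
the most common transcriptome-dendrogram default, both configurable.
Samples are processed in lexicographic order so the dendrogram is invariant
to input column order. The tree is cut at its root into exactly two
clusters (cluster 1 = smaller, ties broken toward the lexicographically
first sample). The segregation statistic is the minimum over the two
clusters of the hypergeometric upper-tail probability of labeled-sample
enrichment; its permutation p keeps the clustering fixed and permutes the
labels, realized exactly by sampling the cluster-1 carrier count from its
hypergeometric distribution, with p = (1 + #{null ≤ observed})/(B + 1).
Expression values are used as given — upstream normalization is the
caller's responsibility — and the test definition is recorded in output
metadata since segregation p-values in the literature rarely name their
test.

## Synthetic cohorts: what they emulate

`CohortConfig` defaults are the study conditions for all recovery
properties:

| parameter | default | rationale |
|---|---|---|
| n_samples | 100 | desk-scale cohort of the order of published WGS series |
| p_high | 0.2 | high-rearrangement class is the rarer one |
| intra_rate_low / high | 20 / 200 | ten-fold separation; bimodal on log scale |
| inter_rate | 15 | class-independent, as translocations showed no class link |
| dispersion | 10 | negative binomial; burden is heavily overdispersed |
| driver_baseline / driver_or | 0.05 / 20 | ~5% carriers in the stable class, strongly enriched in the unstable class, ~10% overall |
| driver_ccf | 1.0 | the driver is clonal |
| deletion ccf bounds | (0.4, 0.8) | deletions subclonal, below the driver |
| fga beta low / high | (2,38) / (5,15) | FGA centered at 0.05 vs 0.25 per class |
| depth / purity | 100× / U(0.4, 0.9) | typical WGS depth and clinical purity range |

The generator plants: negative-binomial intra counts per class and
class-independent inter counts; uniform breakpoints with subtype-consistent
strands on a ten-autosome ~1.5 Gb toy genome; per-sample segment profiles
hitting a Beta-drawn FGA target within ±0.02, with deletion-lesion segments
at log2 = log2(1 − p·c/2); binomial read counts from the expected-VAF
formula; and the clonal hierarchy (deletion CCFs capped below the driver's
in co-occurring samples). Four class-independent passenger point lesions
make the "driver is the top point-mutation association" property
non-vacuous and exercise multiplicity control.

Deliberately *not* emulated: breakpoint clustering and complex events
(chromoplexy/chromothripsis), mutational signatures, allele-specific copy
number, whole-genome doubling, subclonal population structure beyond one
CCF per lesion, and read-level artifacts. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated generative
model, not robustness to every artifact of real cohorts. Note one
realistic consequence of purity dilution: a subclonal deletion at low
purity can sit above the −0.2 call threshold and be missed, exactly as in
real segmented data, so detected co-occurrence counts are below the planted
ones.

Synthetic expression places the two label classes at symmetric
signature-gene means (±effect/2 per gene, alternating sign across genes —
a signature mixes up- and down-regulated genes, and a same-sign shift would
cancel in a Pearson profile comparison); effect 0 gives a structureless
null.

## Problem sizes and known limitations

Recovery properties run at the sizes stated in the test suite and
acceptance script: mixture recovery on a 400-tumor cohort; association
recovery on 100 replicate 200-tumor cohorts; evolution-graph recovery on 50
replicate 200-tumor cohorts (configured with p_high 0.3 and driver baseline
0.15 so every replicate has ≥ 10 detected co-occurring carrier pairs);
calibration on 2000 rank-sum and 1000 segregation null replicates.

Three quantitative limits are worth stating plainly, because they are
properties of the statistics, not implementation defects:

- **CCF noise floor.** At 100× depth the binomial sampling noise on VAF
  maps to sd(CCF) ≈ (2/p)·√(v(1−v)/100) ≈ 0.08–0.14 over the default
  purity/CCF range, so the mean absolute error of any VAF-inverting point
  estimate is ~0.06–0.08. Interval coverage is the reliable guarantee at
  this depth; sub-0.05 point accuracy requires deeper sequencing.
- **False-positive floor of BH.** Under a global null, Benjamini–Hochberg
  at level q makes at least one rejection with probability ≈ q for
  independent near-uniform p-values. A null burden channel therefore shows
  some q < 0.1 lesion in roughly 8–10% of cohorts; "no hits" cannot be
  guaranteed in more than ~90–92% of replicates.
- **Discreteness of the segregation p.** The min-hypergeometric statistic
  takes few values once the clustering is fixed (root cuts of unstructured
  data are often 1-vs-rest), so its permutation p is valid but
  conservative, not uniform, under the null: it errs toward missing
  segregation, never toward inventing it.
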