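# Methods

`vpaglio` re-implements, as a tested pipeline over synthetic data, the
statistical chain used to characterize the transcriptional and
chromatin-level response of glioma cell lines to valproic acid (VPA), a
class I/IIa HDAC inhibitor: per-line differential expression without
replicates, promoter euchromatinization from ChIP-enriched regions,
cross-line consensus signatures, gene-family over-representation, gene
set enrichment analysis, transcriptional subtype scoring, and
temozolomide dose-response pharmacology.

## Study design being modelled

Fourteen glioma cell lines — seven established adherent glioblastoma
lines and seven primary stem-like lines — are each profiled RNA-Seq and
H3ac ChIP-Seq once VPA-naive and once VPA-treated.  There are no
replicates: every differential comparison is one library against one
library, which dictates the choice of test (below) and rules out
replicate-based models (negative-binomial GLMs are an explicit
non-goal).  Differential ChIP region calling is treated as an upstream
input: the pipeline consumes per-line BED files of treated-condition
enriched regions and never calls peaks itself.

## Differential expression for unreplicated counts

For a gene observed `x` times among `N1` mapped reads in the naive
library and `y` times among `N2` in the treated library, the
Audic–Claverie conditional law under equal underlying expression is

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) )

This is exactly the negative-binomial law with `x+1` successes and
success probability `N1/(N1+N2)`.  The implementation uses that
identity: the point mass is evaluated in log space (`lgamma`), and the
tail probabilities through the regularized incomplete beta function —
exact, vectorized over all genes, and immune to factorial overflow or
truncation error.  The up-tail `P(Y >= y | x)` is the default test for
"up-regulated" calls since up- and down-regulated gene lists are
reported separately; `down` and `two_sided` (2·min of the tails, capped
at 1) are available.  Tails that underflow double precision are floored
at the smallest normal float so p-values stay in (0, 1].

Multiple testing uses Benjamini–Hochberg within each cell line
(`statsmodels`), with the q < 0.01 threshold as the default call level.
The adjustment procedure is recorded in output provenance because it is
a package choice, not something the upstream tooling of this study
design pins down.

Fold changes are computed on the counts-per-million scale with a
pseudo-count: `fc = (CPM_y + c) / (CPM_x + c)`, default `c = 0.5` CPM.
The pseudo-count keeps zero counts defined; it shrinks fold changes of
weakly expressed genes toward 1 (a gene at 1 CPM needs a true 6.5-fold
change to show a measured 4.3-fold), which is deliberate conservatism at
the expression floor.

RPKM is `count * 1e9 / (exonic_length * library_size)` with library
sizes taken from sample metadata (total mapped reads), not column sums,
because annotated genes need not exhaust the library.  PCA runs on
log2(RPKM+1) of the 1,800 most variable genes (variance ties broken
lexicographically by gene id), centered, with the sign convention that
each component's largest-magnitude loading is positive.

## Promoter euchromatinization

The promoter of a gene is the 1,000 bp window immediately 5' of its
transcription start site, half-open and excluding the TSS base: on the
plus strand `[TSS-1000, TSS)`, on the minus strand `[TSS, TSS+1000)`,
clipped at the chromosome origin.  One TSS per gene is assumed.  A
promoter is "euchromatinized" in a cell line when any treated-condition
enriched region overlaps it by at least `min_overlap_bp` (default 1 bp)
under half-open semantics — touching intervals do not overlap.  The
overlap routine sorts regions by start per chromosome, narrows
candidates by binary search plus a running maximum of region ends, and
verifies overlap lengths exactly on the surviving slice; it is tested
against an all-pairs brute-force scan.

## Consensus signatures and family enrichment

A gene enters the VPA-response signature at fold-change tier `t` iff it
is called up (q < 0.01, fc >= t, fc > 1) in at least 4 of the 7 adherent
lines AND at least 4 of the 7 stem lines.  The same 4-of-7-per-lineage
majority rule applies to the euchromatinization call matrix when
intersecting the RNA and ChIP layers.  Genes absent from a line's table
count as non-supporting.  Tiers are evaluated at cutoffs 5, 4, 3, 2 by
default; signatures at stricter cutoffs are subsets of looser ones by
construction.

Family over-representation uses Fisher's exact test on the table

    [[k, n-k], [K, N-K]]

i.e. the candidate list (k family members of n genes) is compared
against the whole N-gene universe (K family members) as an independent
reference column — the universe margin is **not** reduced by the list.
With the reference inputs k=16, n=497, K=397, N=46,111 this yields
p = 1.178e-5 one-sided.  (The alternative convention of treating the
list as a draw from the universe, `hypergeom.sf(k-1, N, K, n)`, gives
8.24e-6 on the same counts; the package uses the independent-column
convention throughout.)  One-sided (greater) is the default; the
two-sided variant sums point probabilities at or below the observed
one.  The gene universe size is user input since no annotation catalog
ships with the package.

## Gene set enrichment analysis

The ranked list is the mean log2 fold change across all 14 lines
(descending; ties broken by gene id).  The enrichment score is the
signed extremum of the running sum that increments by the hit gene's
|metric|^p normalized over hits and decrements by `1/(N - N_hits)` at
misses, weighting exponent `p = 1` by default.

Because the design has no phenotype replicates to permute, the null is
gene-set permutation: `n_perm` random same-size sets drawn from the
ranked universe (vectorized; extrema of the running sum are evaluated
only at hit boundaries, O(k) per permutation).  NES divides the ES by
the mean magnitude of same-signed null scores.  The nominal p uses the
add-one rule against null scores at least as extreme **in magnitude**,

    p = (1 + #{ |ES_null| >= |ES| }) / (n_perm + 1)

which floors at `1/(n_perm+1)`, is never zero, and is calibrated: over
500 random sets the rejection rate at alpha = 0.05 lies in [0.03, 0.07]
(counting only same-signed nulls against the full denominator would be
about twice anti-conservative).  The FDR q pools sign-matched null NES
values across sets and compares the null exceedance fraction to the
observed one, clipped to [0, 1].

## Subtype scoring

No per-sample enrichment rule is canonical for two-signature subtype
scoring, so the package uses the simplest monotone choice: a sample's
signature score is the mean over signature genes of the per-gene
z-scored log2(RPKM+1); the subtype call is the argmax of the
mesenchymal and proneural scores (`indeterminate` on exact ties).
Signature gene lists are user input via GMT; the packaged ones are
synthetic.

Paired naive/treated score shifts per lineage (n = 7 pairs) use an
exact two-sided Wilcoxon signed-rank test: zero differences are
dropped, tied absolute differences get mid-ranks, and the null
distribution of the positive-rank sum is built exactly by convolution
(mid-ranks doubled to stay integral — identical to enumerating all 2^n
sign assignments, feasible to n = 25).  Beyond n = 25 a normal
approximation with continuity and tie correction takes over.  The
two-sided p is `2·min(P(W <= w), P(W >= w))` capped at 1; with n = 7
uniformly positive shifts this gives 2/128 = 0.015625, the granularity
at which per-lineage shifts of a 7-line panel can be significant.

## Dose-response pharmacology

Fluorescence readings are normalized to the intra-plate no-drug control
mean (control = 100%) and fitted with the four-parameter logistic on
log10 concentration:

    response(x) = bottom + (top - bottom) / (1 + 10^((log_ic50 - x) * hill))

All replicate points are fitted, not their means.  Because the response
is control-normalized, the plateaus are constrained to meaningful
ranges — bottom in [0, 50] %, top in [50, 150] %, hill negative
(inhibition), midpoint within one decade of the tested concentration
span.  This matters quantitatively: a local information (Cramér–Rao)
analysis of the unconstrained 4-parameter fit at the emulated plate
design (8 doses spanning 1–8,000 µM, triplicates, 5% Gaussian noise)
gives an intrinsic ~22% standard deviation on the IC50 through
plateau/slope trade-offs, while the anchored fit recovers the midpoint
with ~9% median error.  All bounds are exposed as parameters.
Optimization is `scipy.optimize.least_squares` from a deterministic
multi-start grid (hill in {-0.5, -1, -2} × two midpoint guesses); the
best residual sum of squares wins.  A fit whose midpoint lands on the
search boundary is unidentifiable from the data and reported
non-converged — this covers flat curves.  Both the curve midpoint IC50
and the absolute IC50 (concentration at 50% of control, from the fitted
curve in closed form) are reported, since "50% growth reduction versus
control" is the absolute variant while variable-slope fitting
conventionally yields the midpoint.

Sensitization is `1 - IC50_treated/IC50_naive` (positive = leftward
curve shift).  The siRNA rescue ratio divides each siRNA's VPA-induced
TMZ effect, `[m(vpa+,tmz+)/m(vpa+,tmz-)] / [m(vpa-,tmz+)/m(vpa-,tmz-)]`,
by the control siRNA's, so siCTRL is exactly 1, values > 1 mean the
knockdown weakened the VPA-induced sensitization (rescue), and the
statistic is invariant to per-siRNA scaling.  qPCR fold changes use
2^(-ddCt) with a reference transcript and calibrator sample.

## Synthetic data generator

Every generator is a pure function of (parameters, seed) and writes a
`TruthManifest` (JSON) recording exactly what was planted.  Defaults,
chosen once as the emulated study conditions:

| parameter | default | meaning |
|---|---|---|
| lines | 7 adherent + 7 stem × {naive, vpa} | the 28-library design |
| n_genes | 5,000 | annotation size for end-to-end runs |
| library sizes | U[20M, 50M] | total mapped reads per library |
| noise | negative binomial, dispersion 0.1 | `var = mu + 0.1 mu^2`; `poisson` mode available |
| frac_up | 0.02 | fraction of genes planted as treatment-up-regulated |
| effect | log2FC ~ U[2, 3] | 4- to 8-fold planted effects |
| family | 30 genes, 12 planted | the designated transporter-like family |
| support | 7 of 7 per lineage | lines carrying each planted effect (configurable to probe the 4-of-7 boundary) |
| planted baseline | U[1, 50] CPM (log-uniform) | keeps planted genes detectable |
| subtype blocks | 50 + 50 genes; lineage boost 1.5 log2; treatment shift 0.5 log2 | adherent lines score mesenchymal, stem lines proneural; VPA boosts the opposite signature without flipping calls |
| ChIP concordance | 0.9 per line | probability a planted gene's promoter gets an overlapping region |
| background regions | 50 per chromosome | uniform decoy intervals |
| dose-response | 8 doses 1–8,000 µM, triplicates, 5% noise | 4PL truth per curve with planted IC50 reductions |

Gene bodies are non-overlapping with >= 2 kb gaps, so neighbouring 1 kb
promoter windows never collide, and concordant ChIP regions are placed
strictly inside the promoter window — with concordance 1 and no
background the derived call matrix equals the planted set exactly,
which the tests exploit.

Negative-binomial noise at dispersion 0.1 deliberately violates the
Poisson sampling the count test assumes, as real RNA-Seq does; this
inflates single-line false positive rates (roughly a thousand up-calls
per line at q < 0.01 on 5,000 null-majority genes), and the cross-line
consensus rule is what restores specificity — the same structure the
analysis relies on for real data.  The Poisson mode exists for exact
calibration studies (null false-positive rates, the 4-of-7 boundary,
sensitivity/FDR of planted recovery), where the test's assumptions hold
by construction.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: line-to-line baseline heterogeneity
(all lines share one baseline expression vector, so the dominant PCA
axis is the treatment effect rather than cell type), gene length/GC
biases, mappability, multiple or alternative TSSs, correlated gene
modules beyond the planted blocks, and ChIP signal strength (regions
are binary presence/absence).

## Determinism and numerical conventions

All randomness flows from one top-level seed expanded via
`numpy.random.SeedSequence` into per-stage seeds, which are logged.
Identical seeds and inputs give bit-identical outputs; GSEA results
carry their seed and permutation count in every output row.  Tie-breaks
are lexicographic by gene id everywhere a ranking is needed (PCA
variance ranking, GSEA metric ties).  Degenerate inputs fail loudly
with typed errors: empty count matrices, constant expression for PCA,
all-zero Wilcoxon differences, flat dose-response curves, inconsistent
enrichment counts.

## Problem sizes in the test suite

The packaged verification runs at sizes chosen to exercise every rule
while staying quick: oracle grids to x, y <= 200 (exact rational
arithmetic to 30), 400–1,500-gene datasets for unit-level planted-truth
checks, 20 random datasets for tier nesting, 100 random interval
instances up to 10^3 × 10^3, 500 random gene sets for GSEA calibration,
and five full 5,000-gene simulate→run-all cycles for end-to-end family
recovery.

## Known limitations

- The count test is anti-conservative per line under overdispersion by
  design of the original method; only consensus-level outputs are
  calibrated against the NB generator.
- Single-TSS promoters; alternative promoters would need an expanded
  annotation format.
- The enrichment universe size is an input; results are only as
  meaningful as that choice.
- The subtype score is one of several defensible per-sample enrichment
  statistics; ranks are stable across monotone variants but absolute
  scores are not comparable across datasets.
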