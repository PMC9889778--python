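# Methods

This note documents the statistical models and procedures implemented in
`fibroscape`, the synthetic data they are validated against, the numerical
choices behind each stage, and the limits of what the synthetic
validation demonstrates.

## Synthetic data model

All validation rests on generators whose statistical structure mirrors the
assumptions of the analyses.

**Counts.** Gene counts are negative binomial with mean/inverse-dispersion
parameterisation, variance `mu + mu^2/theta`, `theta = 10` by default
(moderate overdispersion typical of droplet data). Relative gene
abundances are lognormal(0, 1), scaled so a cell's expected total is
`lib_size_mean` (default 5000) times a lognormal(0, 0.3) library-size
factor. The log-normalized layer scales each cell to 10,000 counts before
`log1p` — the de facto standard the pipelines assume.

**Batch effects.** Each patient applies a multiplicative `2^N(0,
batch_sd)` effect to a random 30 % of genes (`batch_sd` 0.5 on the log2
scale by default). This makes group-dependent structure detectable by the
kNN-overlap score while leaving most genes unperturbed.

**Cell-type signatures.** Each planted type elevates a disjoint block of
signature genes by a configured log2 fold change. Signature blocks are
assigned from the most-expressed genes so the planted effects are not
drowned by shot noise — matching the fact that curated marker genes are
well-detected genes.

**Trajectories.** Cells get a branch (Bernoulli 1/2) and a pseudotime `t ~
U[0, 1]`. Four gene modules multiply their genes' means by
`2^(amplitude * bump(t))` within overlapping activation windows
([0, .4], [.15, .6], [.4, .85], [.6, 1] by default). Interior windows are
raised-cosine bumps; windows touching a boundary are monotone half-bumps
with full amplitude at the boundary. Two properties of this design are
load-bearing: the endpoint states must differ (otherwise the expression
manifold closes into a loop and pseudotime is unidentifiable by
construction), and the windows must overlap (otherwise the manifold has
near-stationary gaps where ordering is unrecoverable at realistic noise).
Branch-identity genes (40 per branch, log2FC 2) hold near-full effect
until half of the convergence time `terminal_t` (default 0.75) and decay
smoothly to zero there; cells past `terminal_t` share one terminal state
and carry the truth label `terminal`. Replicate datasets share the module
truth but draw independent cells and patient batch effects.

**Survival.** Event times follow a Weibull proportional-hazards model
(shape 1.2, scale 60 months) with subject hazard multiplied by
`exp(beta * score)` for a continuous score in [0, 100] (or by a step
hazard above a cutpoint, for cutpoint-recovery experiments). Censoring is
the minimum of an administrative horizon (120 months) and a uniform
random censoring draw.

## Stage-by-stage procedures and choices

**Module scores.** Genes are ranked into 25 equal-occupancy bins by mean
log-normalized expression; each signature gene draws 100 control genes
from its bin (excluding signature genes, with replacement when the bin is
small); the score is mean(signature) − mean(pooled controls) per cell.
Control sampling is seeded; across seeds, per-cell scores correlate at
r ≥ 0.95 on cohorts of realistic size.

**Stromal demarcation.** Fibroblast when `s_fib − s_mural > margin
(0.1)` and `s_fib > 0`; the mural branch is the mirror image; cells
satisfying neither remain `unassigned` rather than being force-assigned —
ambiguous cells are excluded, not guessed.

**Batch QC.** For a group of size m, the observed statistic per member
cell is the count of its k nearest neighbours inside the group. The null
pools the same per-cell statistic over random m-subsets of all cells
(1000 draws by default; exhaustive enumeration available for tiny
graphs). z-scores use the pooled null mean and SD; a group is flagged when
its median z exceeds 1.96. Neighbours are found on the top 30 PCs of
log-normalized data by default; both k and the embedding are exposed
because the reference procedure states neither.

**Sample-level markers.** Pseudo-sample profiles are per-(sample, cluster)
means of log-normalized expression (pairs under 3 cells dropped). A
parallel layer of arithmetic means on the linear (expm1) scale backs the
fold-change estimate: averaging log values is a geometric mean and
understates how much a mixed rest group dilutes a marker, which would let
noise-split sibling clusters keep "passing" markers. The cluster-vs-rest
contrast compares each sample's cluster profile against the cell-weighted
mean of its other clusters. p-values come from the *exact* Mann-Whitney
null by default: with ~12 samples per side, the normal approximation
floors attainable p-values too high to survive Bonferroni correction over
thousands of genes, and the exact paired signed-rank is floored at
`2^-(n-1)` — which is why `paired` is an explicit switch rather than the
default. A marker passes when sample-level average log2FC > 1,
Bonferroni-adjusted p < 0.01 and the gene is expressed (profile > 0) in at
least half the target samples.

**Resolution sweep.** The SNN graph weights kNN edges by neighbour-list
Jaccard overlap (pruned below 1/15) and is partitioned by seeded Leiden
modularity optimisation at each resolution. A resolution is supported when
every cluster retains at least `marker_min` passing markers; the chosen
resolution is the largest supported one. The validation benchmark uses
`marker_min = 10` — genuine subpopulations carry tens of sample-validated
markers, while noise-splits of a homogeneous population fall below the
fold-change threshold once the sibling cluster dilutes the rest group.

**Diffusion pseudotime.** The kernel is Gaussian on the kNN graph with
per-cell bandwidth equal to the distance to the ⌈k/2⌉-th neighbour;
neighbourhoods are distance-thresholded (ties included) so duplicated
cells embed identically; density normalization divides by the product of
kernel row sums. Components come from the symmetric conjugate's
eigendecomposition; expression input is first reduced to 5 PCs of the 800
most variable genes (mean-binned normalized dispersion), scaled to unit
variance — trajectory manifolds are low-dimensional, and restricting to
variable genes keeps correlated biological programs above the flat
technical noise of the remaining genes. `dpt` is Euclidean distance from
the root in the space of eigenvectors scaled by `lambda/(1-lambda)`,
min-max normalized. Branch assignment works on geodesics of the kNN graph
in that space: the second progenitor tip maximizes geodesic distance from
the root; the terminal tip maximizes the *sum* of distances to both
progenitor tips (constant along the arms of a tree geodesic, growing only
past the junction — a farthest-point or max-min rule can capture a
mid-branch outlier instead); cells with both path-additivity residuals
under 5 % of the inter-progenitor geodesic lie past the junction and are
terminal, the rest join the branch with the smaller residual. This is a
deliberately simplified branching rule, adequate for a single
convergence point; it is not a general multi-branch triangulation.

**Pseudotime differential expression.** Local quadratic regression with
tricube weights, span 0.5 (fraction of cells per neighbourhood). The
smoother matrix depends only on the pseudotime vector, so it is built
once and applied to all genes. The test against the intercept-only model
uses the analysis-of-variance construction for local regression:
`F = ((RSS0 − RSS1)/nu1) / (RSS1/delta1)` with degrees of freedom from
the first and second traces of the residual quadratic forms. Measured
size at the 5 % level is 0.047–0.055 on 2000 null genes. Constant genes
return p = 1 and a flat profile.

**Meta-analysis and modules.** Stouffer combination
`Z = sum(Phi^-1(1-p_d))/sqrt(D)` over the datasets where a gene was
testable; Bonferroni adjustment over genes; significance requires
adjusted meta-p < 1e-10 and nominal p < 0.05 in ≥ 3 datasets. Fitted
profiles are z-scaled per dataset before the pointwise median across
datasets, so datasets with different depth contribute equally; modules
come from Ward clustering on `1 − r` between median profiles, cut at
k = 4, and are named progenitor / early-activation /
proto-differentiation / differentiation by ascending peak position.

**Deconvolution.** The signature matrix holds per-type mean linear-scale
expression over the union of per-type top-50 fold-change genes
(one-vs-rest rank-sum, Bonferroni p < 0.01), after downsampling each type
to ≤ 500 cells. Pseudobulk samples draw 1000 cells from 3 random
patients and top fibroblast content up/down to a uniform 1–50 % target;
mixtures are counts-per-million. Scoring is non-negative least squares of
each mixture on the signature columns; within-fibroblast percentages
rescale the three fibroblast subpopulation scores to 100 — prognostic
cutpoints are defined on that scale.

**Survival.** The log-rank statistic is the standard hypergeometric
tabulation; the cutpoint sweep evaluates the signed standardized
statistic `U/sqrt(Var)` at every cutpoint keeping both groups above 10 %
of subjects (vectorized jointly over event times and candidates; verified
identical to per-candidate evaluation). The sweep is returned
*uncorrected*: the maximally selected statistic is anti-conservative
under the null (a property the test suite demonstrates rather than
corrects), and significance of a chosen cutpoint should come from
applying it to independent validation cohorts. Cox models maximize the
Efron- (default) or Breslow-tied partial likelihood via statsmodels'
proportional-hazards regression; an optional horizon administratively
censors follow-up (e.g. 48 months for 4-year analyses); Wald 95 % CIs.
Stage enters as an ordinal covariate by default.

**Histo-cytometry.** `pif8(v) = min(256, ceil(v/1.5 * 256))`, kept exactly
as specified by the upstream imaging pipeline even though the cap of 256
exceeds the 8-bit range — values are stored in wider integer containers.
Background is the mean over a `window x window` (default 151)
neighbourhood with edge-replicated padding, computed with an integer
summed-area table so threshold ties resolve exactly for integer
channels; pixels under `background + 5` are zeroed, and red pixels must
also reach 0.43 of the brown registration signal (the two chromogens have
similar colour profiles). Cell-level positivity uses a coverage floor of
0.01 to exclude single-pixel noise; exact coverage ties between
fibroblast markers are broken by the fixed priority CD34 > AOC3 > POSTN >
ACTA2 and flagged.

## Validation conditions, and what they do and do not show

Benchmarks for clustering, markers, trajectories and deconvolution run on
cohorts *without* within-dataset patient batch effects, representing the
state after batch correction: the correction step itself (anchor-based
integration, reference/mixture batch adjustment) is a pluggable hook, not
part of this package. Batch effects stay on where they are the subject
(batch QC) and across trajectory replicate datasets (the meta-analysis
must survive them). With batch effects left uncorrected, NNLS
deconvolution R² degrades (observed 0.71–0.97 across simulations versus
~0.99 without), which is precisely the gap the external service's S-mode
correction addresses — uncorrected inputs are a documented limitation of
the NNLS stand-in.

Problem sizes follow the study-condition descriptions (6000-cell
demarcation cohorts, 12-sample marker cohorts, 500–600-cell trajectories
with 4 x 50 module genes across 3 replicate datasets, 200 pseudobulk
samples, 2000 null replicates for test calibration, 200 replicates for
coefficient recovery).

The generators emulate planted, block-structured effects with NB noise.
They do not emulate ambient RNA, doublets, dropout beyond NB sampling,
continuous within-type heterogeneity, correlated gene programs outside
the planted ones, or read-level artefacts. Passing these benchmarks shows
the procedures recover the structures they claim to recover at realistic
noise and depth; it does not certify performance on real tissue, where
the unmodelled effects above and the quality of upstream correction
dominate. The centroid-correlation softmax classifier and the NNLS
deconvolution are transparent stand-ins for anchor-based label transfer
and for the external digital-cytometry service respectively; both expose
plug-points for the original tools' outputs.
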