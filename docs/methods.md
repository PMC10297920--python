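# Methods

This note documents the models and procedures implemented in `ovimyo`, the
parameter choices that matter, what the synthetic-data generators emulate,
and the package's known limitations. It states no result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Fiber morphometry

**Pipeline.** RGB images are converted to luminance (ITU-R BT.601 weights),
smoothed with a Gaussian (`gaussian_sigma_px`, default 1.0; 0 disables
smoothing), and binarized. Because the boundary network is the bright
structure in WGA-stained material, foreground = pixels *below* the
threshold (Otsu by default, fixed threshold available). Morphological
opening with a disk (radius `adhesion_opening_radius_px`, default 3 px)
severs thin bridges between adhered fibers; holes are filled; connected
components are labeled with 4-connectivity.

**Filtering.** Every region carries area (px), perimeter, circularity and a
status. Checks run in a fixed order — border_touching, too_small,
too_large, non_circular — and the first failure is the single recorded
reason, so rejection reasons are mutually exclusive and reproducible.
Bounds are closed intervals: area in [1400, 80 000] px, circularity in
[0.2, 1.0]. Border-touching regions are rejected because their true CSA
cannot be measured. All filters operate in pixel units; µm² areas are
reported only when a `um_per_px` calibration is supplied.

**Circularity** is the isoperimetric ratio 4πA/P² (ImageJ's definition; the
quantity is named but not defined in common histology protocols, so the
standard form is adopted). The perimeter uses the Crofton estimator by
default (`perimeter_method="classic"` switches to the boundary-walk
estimator). Digitization makes near-circular regions overshoot 1 slightly;
values are clipped to [0, 1.05] and the same 0.05 slack is granted above
the upper filter bound, which never affects the nominal [0.2, 1.0] check.

**Statistics.** `summarize` reports mean/SD of CSA over accepted fibers
only; the hypertrophy fraction is #(CSA > threshold)/n with a *strict*
inequality, making it a non-increasing step function of the threshold with
endpoints 1 and 0. The CSA grade used as a hypertrophy threshold is a
required caller parameter (the pipeline config defaults to 14.2877, in
whatever units the caller's CSA values carry — the correction behind that
conventional grade is not part of this package). Group comparisons use the
independent-sample t-test (equal-variance by default, Welch available) or
one-way ANOVA; fully degenerate inputs return p = 1 with a warning instead
of NaN.

**Fiber typing.** ATPase-like images are trimodal (dark slow fibers, grey
fast fibers, light background), so binarization uses the upper threshold of
a three-class multi-Otsu split (falling back to two-class Otsu when the
image has fewer grey levels). Accepted fibers are split into slow/fast at
the midpoint of the largest gap in their sorted mean interior intensities —
more robust than Otsu on small samples of near-discrete means. If the
largest gap is below `min_separation` (30 grey levels) the distribution is
treated as unimodal: a warning is raised and all fibers are assigned to one
class, dark (slow) iff their mean is below 60% of the background mean.

## Synthetic images

Fiber geometry is a seeded Voronoi tessellation: seeds are drawn uniformly,
then Lloyd-relaxed (seed → cell centroid) until the cell-area coefficient
of variation reaches the requested `area_cv` (unrelaxed Voronoi sits near
CV 0.55; relaxation monotonically tightens it; a cap of 30 iterations bounds
run time, so very small targets saturate). The boundary band is the
thick inter-cell boundary dilated to `boundary_width_px`, plus a frame so
no fiber touches the image border. Ground truth is exact: the interior
label map partitions all non-boundary pixels and each recorded area equals
the label's pixel count. The canvas auto-sizes so the mean *interior* area
matches `mean_area_px` (cell side solves s² − 4sw = mean_area); an
explicitly given shape too small for the request raises a packing error
rather than silently generating fewer fibers. Rendering adds Gaussian noise
(`noise_sd`, default 8 grey levels — modest shot noise; realistic optics,
PSF blur and multi-channel fluorescence are deliberately not modeled, so
segmentation results here do not certify performance on real micrographs
with uneven illumination or out-of-focus boundaries).

Recovery tests and the demo use `area_cv = 0.15` (and the ATPase generator
defaults to mean 4000 px, CV 0.15) so that every generated fiber lies
within the standard 1400–80 000 px filter bounds — the stated precondition
for exact-count recovery; the corresponding test asserts that precondition
on the generated truth before checking recovery. Real sections show wider
area dispersion; with wider CV the filters correctly reject out-of-bound
fibers and exact-count identity no longer applies.

## Count simulation

Counts are negative binomial with mean
μ(g,s) = depth(s) · baseline(g) · 2^effect(g, group(s)) and variance
μ + αμ², the standard RNA-seq parameterization. Baselines are log-uniform
on [50, 500] (moderately expressed genes); the default dispersion α = 0.05
is typical of tissue RNA-seq. The default design is the study layout:
breeds H/HD/D with 6/5/3 replicates at stages D3, M3, M6, M12.

Planted structure: (a) fold-changes between named groups; (b) co-expression
modules — each module's genes share a per-sample latent profile (plus
per-gene log2 noise, default SD 0.3); latent profiles of different modules
are QR-orthogonalized because independent Gaussian profiles can correlate
above the module-merge threshold by chance at small sample counts, in which
case merging them is correct behavior and the planted condition would not
be "k distinct modules"; (c) bias scenarios — the D breed is shifted by
`bias_log2fc` (default 2) relative to H and the crossbred HD tracks D, H,
the midpoint, or no breed effect exists ("unbiased"). Bias simulations
plant biased genes as a small share of the transcriptome (several percent),
mirroring real data; planting a large share would shift the D samples'
rank distribution and distort the quantile-normalization reference itself.

## Expression core

**Size factors** are median-of-ratios: per sample, the median over
reference genes (nonzero in all samples) of count/geometric-mean ratios,
rescaled to geometric mean 1. A matrix with no reference gene raises an
error advising filtering.

**Differential expression.** Genes with total count below 10 across the
contrast samples are excluded from testing and from the BH family (few-count
dispersion estimates are unstable at desk scale). Per-gene dispersions are
method-of-moments on normalized counts, pooled within groups, then shrunk
in log space toward a fitted mean–dispersion trend α(μ) = a₀ + a₁/μ
(weight 0.7 on the trend; modes for trend-only or raw gene-wise estimates
exist). Group means are NB maximum likelihood with size-factor offsets
(vectorized Newton; exact Σk/Σs in the Poisson limit; all-zero groups are
floored at half a normalized count to keep fold-changes finite). The Wald
statistic uses the Fisher information Σ sμ/(1+αsμ) per group and a normal
reference; log2FC of contrast (A, B) is log2(μ_A/μ_B). This is an
approximation of the DESeq2-style analysis, not a numerical replica: the
normal-reference Wald with moment dispersions runs mildly anticonservative
at n = 5 vs 5 (measured ~0.055–0.065 at nominal 0.05 in the calibration
tests), which is accepted and documented rather than patched with an ad hoc
reference distribution. The printed significance rule applies `lfc_min` to
|log2FC| (default 0, i.e. padj alone), since a one-sided threshold on
signed fold-change would discard all down-regulated genes, contradicting
the up/down DEG accounting this workflow is meant to support. Contrasts are
single-factor; stage or sex covariates are not adjusted for.

**Enrichment** is the upper-tail hypergeometric test P[X ≥ overlap] per
gene set (sets intersected with the universe first; sets that become empty
are skipped with a note), BH-corrected across tested sets.

## Co-expression

Unsigned adjacency |cor|^β (β user-set, default 6; scale-free-fit
diagnostics for automatic β are out of scope), TOM similarity
(L + A)/(min(k_i,k_j) + 1 − a), average-linkage clustering of TOM
dissimilarity. A *static* cut replaces WGCNA's dynamic tree cut: default
cut height 0.95 on the [0, 1] dissimilarity scale, chosen so that
between-module merges (near 1) are severed while within-module structure
(well below) survives; clusters under `min_module_size` go to "grey".
Eigengenes are the first principal component of the standardized module
block, unit variance, sign-oriented to positive mean member correlation.
Modules whose eigengenes correlate above 1 − merge_height (default
merge_height 0.25) are merged iteratively. The unsigned network was chosen
because modules are expected to carry both positively and negatively
trait-correlated members.

Hub screening: kME(g) = cor(g, eigengene), GS(g) = |cor(g, trait)|;
hubs satisfy kME > 0.6 and GS > 0.8. GS is thresholded on the correlation
scale (consistent with a 0–1 threshold of 0.8); a −log10(p) reporting
variant is a column, not the thresholded quantity. The network-screening
weight criterion is approximated by a BH q-value on each gene's
trait-correlation test and is off by default; WGCNA's internal weighting is
not replicated.

## Trends and crossbred bias

**Correction.** Expression is quantile-normalized (columns mapped onto the
mean sorted reference; ties averaged by rank interpolation), which is the
"NB → approximately normal" correction used before interval-based
classification. Per-gene z-scoring is applied on top for trend clustering
(`standardize=True`), but note that z-scoring each gene breaks the
equal-column-means property of plain quantile normalization.

**Fuzzy c-means.** Minimizes Σᵢⱼ uᵢⱼ^m ‖xᵢ − cⱼ‖² with the standard
alternating updates; defaults m = 2, tol 1e-6 on max |ΔU|, 500 iterations
max, k-means++-style seeding from the passed seed (Mfuzz's fuzzifier
estimation heuristic is out of scope; m is configurable). A point
coinciding with a center receives membership 1 there (standard singularity
rule). The objective is non-increasing by construction and the trace is
returned. Six clusters is the default pattern count for stage trends;
per-breed clusters are correlated with the breed's CSA trajectory, each
gene inherits its hard cluster's correlation sign, and a gene is
"discordant" when its sign in the reference breed differs from any other
breed.

**Confidence intervals and bias calls.** Intervals are the t-based
mean ± t₍(1+level)/2, n−1₎·s/√n (level default 0.95). The default "two_ci"
mode builds one interval per parent breed: HD inside the D interval only →
toward_D; inside H only → toward_H; inside both → unbiased; inside neither
→ toward the nearer breed mean, with ties declared ambiguous. A "pooled_ci"
mode (one interval from pooled H+D values) exists because the procedure's
description admits either reading; two_ci is the default since intervals
are computed per parent breed. HD is summarized by its group mean by
default; a per-animal voting mode is available. A gene's overall call is
the majority across stages, ties → ambiguous. Calls are scale-equivariant
(affine transforms of all values leave them unchanged) and monotone in the
level: raising the level can only move genes toward "unbiased".

**Known limitation of the CI classifier.** A t-interval covers the *true*
group mean at the nominal level, but the comparison is against an
independent, noisy HD group mean. At the study's group sizes (H 6, D 3,
HD 5) the per-stage probability that a truly unbiased gene falls outside at
least one parent interval is ~20% (dominated by the narrow H interval).
Aggregation across stages absorbs most of this: at the gene level, definite
directional false calls measure ≈ 2–8% in the recovery simulations, and
"ambiguous" is an abstention rather than a bias claim. Users should read
per-stage bias calls with this inflation in mind; the gene-level majority
call is the supported output. This package classifies breed-level
expression proximity — it is not allele-resolved ASE and supports no
parent-of-origin inference.

## Pipeline, determinism and problem sizes

One seed determines all stochastic behavior; all generators draw from
explicit `numpy.random.Generator` instances and never touch global state.
`run_demo` regenerates data, runs every stage and emits a sorted-key JSON
report that is byte-identical across runs with the same seed. Verification
problem sizes were chosen as the smallest at which the recovery and
calibration properties are statistically meaningful: 10 noiseless
100-fiber mosaics for segmentation, 10 000 region stubs for filter
fidelity, 2000-gene null and 200-gene planted-effect simulations for DE
calibration and power, 3 × 50-gene modules at 12 samples for module
recovery, 100 repetitions for hub ranking, and 250 planted bias scenarios
within a 2500-gene transcriptome for the CI classifier.
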