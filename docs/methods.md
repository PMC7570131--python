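# Methods

`hmpenrich` implements the downstream statistical analysis of a bulk RNA-seq
study with a four-genotype sibling design: one wild-type reference group and
three mutant groups (here labelled `eofad_het`, `null_het` and `trans_het`,
after the zebrafish *sorl1* study design the package emulates, with group
sizes 8/6/4/6), plus sex and rearing-tank nuisance factors. The scientific
regime of interest is *subtle* transcriptome change: few genes pass a
per-gene differential-expression threshold, but coordinated shifts across
functional gene sets are detectable — and a single enrichment algorithm is
not trusted on its own.

## Pipeline model

### Counts

Transcript-level estimated counts (kallisto-style `est_counts`) are summed to
gene level over each gene's mature transcripts; transcripts flagged as
unspliced (intron-retaining, ID suffix `.unspliced`) are excluded. Estimated
counts are fractional and are kept fractional everywhere; no rounding is
applied, and the negative-binomial likelihood is evaluated in its
gamma-function form, which is continuous in the response.

Genes are called undetectable when their CPM falls below 0.66 in at least
half the libraries (`ceil(n/2)`, i.e. 12 of 24; both threshold and count are
configurable) and removed; CPM for this rule uses the raw pre-normalization
library sizes, since filtering precedes normalization in the pipeline order.
Between-sample scaling uses the trimmed mean of M-values (TMM): reference
sample = the one whose upper-quartile CPM is closest to the mean
upper-quartile; genes zero in either sample excluded; 30% two-sided trim on
M-values and 5% on A-values; inverse asymptotic binomial variances as
weights; factors rescaled to geometric mean 1.

### Removal of unwanted variation (RUVg, k = 1)

An initial NB-GLM fit *without* latent factors provides a joint (ANOVA-type)
p-value per gene over all genotype coefficients. The genes with the largest
joint p-values (default 5000) become negative controls; the first k = 1
left singular vector(s) of their row-centred log(count + 1) matrix, taken on
the sample side, give the factor W1 that enters the second, final design.
W columns are unit-norm (scale is absorbed by the regression coefficient)
and sign-fixed so the largest-magnitude coordinate is positive. The two
passes are packaged as one operation (`ruv_two_pass`) so controls can never
accidentally be selected from a fit that already contains W.

### Differential expression

Per gene: NB GLM, log link, offset log(library size x TMM factor). Design:
intercept = wild type, one coefficient per mutant genotype, sex (female
reference), tank (tank 1 reference), plus W1. Dispersions are estimated by
maximising the Cox–Reid adjusted profile likelihood (APL) on a 19-point
log-spaced grid spanning 1e-4 to 10, with quadratic interpolation between
grid points. The abundance trend is the moving average of APL curves over
genes ordered by average logCPM (window 10% of genes), and the per-gene
estimate maximises `APL_g + (prior_df / residual_df) * APL_trend_g`
(weighted-likelihood empirical Bayes, prior_df default 10). All-zero or
otherwise uninformative genes fall back to the trend value and are flagged.

Tests are likelihood-ratio chi-square: one per genotype coefficient (df 1)
and one joint test over the three genotype coefficients (df 3; it is this
joint test that drives negative-control selection). Quasi-likelihood F-tests
are not implemented; LRT was chosen as the simpler, oracle-checkable
variant. IRLS runs to a relative deviance tolerance of 1e-8 with at most 50
iterations and step-halving; non-converged genes are reported with p = 1
(conservative) and flagged. BH adjustment is applied per contrast, and a
gene is "DE" when the adjusted p is below 0.05.

### Enrichment: three independent algorithms

All three consume the same filtered universe and the same final design.

**Rotation (self-contained, roast/fry family).** The design is reordered so
the tested coefficient is last and a QR effects transform isolates one
coordinate per gene carrying that coefficient plus `n - p` residual
coordinates. Moderated t = effect coordinate / posterior sd, with the
empirical-Bayes variance prior (d0, s0^2) fitted by moments on the log
residual variances. The set statistic is the mean moderated t of members;
the Monte-Carlo null projects every gene's coordinate vector onto a shared
random direction of the unit sphere (equivalent to a full random rotation
for this statistic), preserving inter-gene correlation exactly. Two-sided
directional p = (b + 1) / (n_rot + 1). The analytic infinite-rotation
approximation is not implemented; Monte-Carlo rotations were chosen because
they can be verified against an explicit rotation-matrix oracle.

**Competitive (camera family).** Moderated t statistics are mapped through
the t CDF to standard-normal z. Per set, the variance inflation factor is
computed from unit-normalised residual rows as `VIF = ||sum of unit
rows||^2 / m` (equivalently `1 + (m - 1) * rho_bar` with rho_bar the mean
inter-gene residual correlation). The two-sample statistic
`(mean z_set - mean z_rest) / (sd * sqrt(VIF/m + 1/(N - m)))` is referred to
a t distribution with `n - p` degrees of freedom — the df of the VIF
estimate (a normal reference ignores that estimation noise and is
anti-conservative). Negative correlation estimates are kept; an optional
`rho_floor` can impose the fixed prior correlation (0.01) some
implementations default to, at the cost of conservatism on uncorrelated
sets. Sets of size < 2 use VIF = 1.

**Preranked GSEA.** Ranking statistic: sign(logFC) x (-log10 p) from the DE
fit (zero p capped at magnitude 300); ties broken by gene ID so the order is
total and deterministic. ES is the signed extremum of the weighted
Kolmogorov–Smirnov running sum (hit increments proportional to |stat|^w,
w = 1 by default; miss decrements 1/(N - m)). The null draws random
same-size gene sets from the ranked list: one shared batch of ordered
random samples of the largest set size, whose length-m prefixes serve every
smaller set. Draws come in antithetic mirrored pairs (each sample plus its
rank-reversed image), making the null exactly symmetric under negation of
the ranking statistic. p is one-tailed on the matching ES sign with the +1
correction; NES = ES / mean |ES| of same-sign null draws; the leading edge
is the members at or before (after, for negative ES) the extremum. The
multilevel refinement of the fast GSEA algorithm is out of scope, so very
small p-values are floored at 1/(n_perm + 1).

### Consensus and validation

Per set and contrast the three p-values are combined by the harmonic mean
p-value, HMP = (Σ w_i) / (Σ w_i / p_i), equal weights by default. The raw
HMP is used — no Landau-tail recalibration — because a BH FDR step across
all sets in the contrast follows immediately; the asymptotically exact
transform is available as `hmp_exact` for users who want marginal HMP
p-values. A set is significant when the FDR-adjusted HMP is below 0.05. BH
is applied across all sets tested together in a contrast; targeted families
(e.g. an IRE collection) can be adjusted separately by passing them as their
own collection.

The permutation-label null re-runs enrichment + consensus after randomly
reassigning gene identifiers to expression rows. This breaks gene–set
membership while leaving the expression matrix — and therefore the entire
distribution of per-gene statistics — untouched, which is the property that
makes it a null for *set-level* inference. Shuffles are sampled uniformly
over non-identity permutations. Shuffling gene labels against rows is
equivalent to shuffling set membership; both interpretations of
"permuting the gene labels" coincide for this null.

Leading-edge overlaps are reported upset-style: each gene is assigned to the
exact combination of (significant) leading edges containing it, and
combinations of 2+ sets with at least `min_shared` (default 3) genes are
reported.

## Synthetic data

The generator emulates the study conditions: 24 samples in groups 8/6/4/6,
alternating sexes, three tanks cycling across samples; library sizes uniform
on a configurable range (default 0.5–1.0 M for fast tests; a realistic
13–23 M range is one flag away and scales linearly in cost); log-normal
baseline abundances (sdlog 1.6); NB dispersion following
`phi = 0.05 + 2/mu`; a latent factor w correlated with log library size
(rho = 0.8) loading on half the genes (N(0, 0.3) loadings), reproducing the
"PC1 tracks library size" confound; a handful of large individual effects
(|log2FC| = 2); and planted *subtle* coordinated shifts: |log2FC| <= 0.3 on
80% of the members of selected sets — the "few DE genes, detectable
set-level signal" regime. Gene counts are NB draws; each gene's count is
split across 1–3 mature transcripts by fixed Dirichlet usage weights (so
transcript counts are fractional, like EM-distributed multi-mapping reads,
but sum exactly to the gene draw), and every gene carries one low-count
unspliced transcript (Poisson, 5% of the gene mean) that aggregation must
discard.

What the generator does *not* emulate: GC/length bias, read-level noise,
isoform switching, batch structure beyond one latent factor, compositional
(mRNA-total) effects, and outlier samples. Passing tests therefore show
correctness and calibration of the statistical machinery under the NB model
with one confounder — not robustness to every artefact of real libraries.
One consequence to keep in mind: when the latent factor is active, its
*imperfect* removal by estimated W1 leaves mild residual inter-sample
structure that can nudge per-set type-I error above nominal; the shipped
calibration experiments therefore measure size on confounder-free null
simulations, and the permutation-label experiment measures the end-to-end
false-positive behaviour with the confounder present. That residual
sensitivity is a property of one-factor RUV with estimated controls, not of
the implementation.

## Problem sizes used for validation

Experiments are sized to run on a laptop-class single core: the full-scale
fixture is ~12 000 genes x 24 samples x 100 sets with 999
rotations/resamples and 100 label permutations (the permutation loop reuses
the label-invariant linear fit and GSEA null distributions, which makes the
full experiment cheap); calibration uses 500 null sets at 4000 genes;
consensus recall uses 50 replicate simulations at 1500 genes x 15 sets (two
planted sets each, |log2FC| 0.3 over 80% of members, 499 resamples).
Dispersion-recovery checks use 1000 genes at phi = 0.1.

## Numerical choices

- IRLS: deviance tolerance 1e-8, max 50 iterations, up to six step-halvings,
  linear predictor clipped at ±45, 1e-10 ridge on the Fisher solve.
- Dispersion grid 1e-4–10 (19 points); quadratic interpolation in log phi.
- Log pseudo-count 1 for the RUV factor transform (the published RUVg
  default); logCPM uses prior count 0.5.
- Ranking-statistic cap 300 for p = 0; GSEA weight 1; tie-breaks by gene ID
  everywhere a total order is needed.
- Degenerate genes (no variation beyond the nuisance fit) are forced to
  t = 0 in the rotation test rather than dividing rounding noise by a
  near-zero variance.
- All randomness flows from a single top-level seed through named
  substreams, so stages are decoupled and reruns are byte-identical.

## Known limitations

- LRT p-values (not quasi-likelihood F) can be mildly liberal for very low
  counts; the detection filter removes most of that regime.
- The competitive test estimates VIF per set from `n - p` residual
  dimensions; for very small sets the estimate is noisy, which the t
  reference only partly absorbs.
- GSEA p-values are floored at 1/(n_perm + 1); at the default resampling
  depth the consensus inherits a floor of roughly 3x that when the other
  two methods saturate.
- The permutation-label experiment re-runs only enrichment + consensus (the
  DE statistics are label-invariant by construction), so it validates
  set-level inference, not the DE stage itself.
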