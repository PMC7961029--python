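# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the known limitations of
`braintx`. Everything empirical stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external
results.

## Study design being modeled

The package targets small matched post-mortem cohorts: ~7 case and ~8
comparison subjects, each contributing tissue from four brain regions —
two orbitofrontal cortical areas (BA11, BA47) that are nearly replicate
measurements of one another, and two striatal regions (caudate,
nucleus accumbens). Subjects carry demographic and tissue covariates
(sex, age, post-mortem interval, pH, RNA integrity number). Analyses
run at two scopes: *global* (all regions jointly, with a region factor)
and *regional* (per region).

## Quality control

CPM normalization divides each count column by its library total and
scales to 10⁶. The expression floor keeps gene g iff some region r has
≥ ⌈n_r/2⌉ samples with CPM ≥ 1 ("at least half" uses the ceiling at odd
n_r). The variability filter computes CV_j = sd_j/mean_j per gene over
all samples and keeps CV_j < T with T = mean(CV) + 3·sd(CV), computed
once over the input genes. The filter is deliberately *not* iterated:
re-applying it would recompute T on the trimmed set and remove more
genes each pass, like any iterated outlier trim. Degenerate cases:
sd(CV) = 0 (identical CVs, or one gene) keeps everything; zero-mean
genes are excluded from the CV computation with a warning.

### Consensus correlation

Defined as the median over subjects of the Pearson correlation, across
genes, between a subject's two regional profiles, computed on log₂
expression *centered per gene within region*. Centering matters: raw
between-sample correlations over genes are dominated by the common
baseline-abundance profile (any two brain samples correlate near 1) and
carry no information about region similarity. After centering, the
statistic measures shared subject-level deviation, which is what
justifies treating BA11/BA47 as one region. The median (rather than the
mean) is used because n = 7–8 subjects makes the estimate sensitive to
a single outlying subject; both are reported in the pipeline's QC
block. Merging is config-driven: regions are averaged (per gene and
subject) into a pseudo-region when their consensus correlation exceeds
a threshold (default 0.5).

### Cohort table

Pooled-variance two-sample t per covariate with df = n₁ + n₂ − 2,
computed at the subject level. The t *magnitude* is reported with a
two-sided p, the convention of demographic tables. The same computation
is exposed from group summaries (`pooled_two_sample_t`) so printed
(mean, SD, n) rows can be checked directly; computing from summaries
and from raw values agrees to 1e-12.

## Differential expression

Per gene, ordinary least squares of y = log₂(CPM + 1) on an intercept,
diagnosis (comparison = 0, case = 1, so β > 0 means higher expression
in cases), region dummies (global scope only), sex, pH, and any
screened-in candidate covariate. Gaussian OLS on log-scale CPM is the
simplest member of the generalized-linear-regression family appropriate
here and keeps closed-form oracles: with no covariates the fit reduces
exactly to the pooled two-sample t-test, which the tests assert at
1e-10. Fits are vectorized — the projection (X'X)⁻¹X' is formed once
per design and applied to all genes — and agree with per-gene
statsmodels OLS to 1e-8.

Covariate screening (`select_model`): a candidate (age, PMI, RIN) is
promoted if it correlates with any of the top 5 expression principal
components at p < 0.01. Under pure noise a candidate is retained with
probability ≈ 1 − 0.99⁵ ≈ 5%, which the tests bound empirically.
Near-collinear designs (condition number > 1e8) are rejected with the
offending pair named.

BH adjustment is applied within scope (global separately from each
region), since DEG counts are reported per scope. Direction calls:
up/down at q < α (default 0.05), else ns; the ±0.26 log₂FC volcano
guide line only annotates effect-size exceedance and never affects
significance.

### Calibration and its limits

The cohort design is repeated-measures: each subject contributes
several regional samples, and the generator (below) gives them shared
subject-level variance. Fixed-effects OLS ignores that dependence, so
for the between-subject diagnosis contrast its p-values are mildly
anti-conservative under the full correlated design (measured fraction
of p < 0.05 ≈ 0.09 at the defaults instead of 0.05). This is a known
property of fitting such cohorts with per-sample fixed-effects
regression, not an implementation artifact; the package documents it
rather than silently switching to a mixed model. Calibration tests
(type-I error, KS uniformity, empirical FDR, end-to-end null) therefore
run on null configurations with the shared latents at zero (or a single
region), where the independence assumptions hold exactly — measured
type-I error 0.0505, KS p = 0.32 at 2000 genes. Regional fits use one
sample per subject and are calibrated under all configurations.

## Gene-set enrichment and the co-occurrence network

Enrichment p is the hypergeometric upper tail P(X ≥ k) for the 2×2
table (in-set/DE vs not), identical to the one-sided Fisher exact test;
only over-representation is tested. Sets are intersected with the
analysis background first; overlaps below `min_overlap` (default 3,
guarding degenerate tables) are skipped and logged; BH runs across the
tested sets of one collection, and separate collections are corrected
separately.

Set–set similarity is the Jaccard index on the DEG universe ("fraction
of shared genes out of the unique genes in either set"); an
overlap-coefficient variant (min-size denominator) is available by
flag. Clustering is average-linkage agglomeration on distance 1 − J
with a fixed-k cut (default 4), a reproducible stand-in for a by-eye
dendrogram cut; set names are sorted internally so the partition is
invariant to input order. Edges are emitted for every pair with J > 0
and flagged *strong* at J ≥ 0.5 ("at least half the genes
co-occurring").

Directionality: each enriched set's DEG overlap is tabulated into
n_up/n_down and frac_down = n_down/(n_up + n_down). The focal cluster
(in practice the most down-biased) is compared to all remaining sets by
pooled two-sample t (df = n₁ + n₂ − 2); a one-way ANOVA runs across
clusters (df = (k−1, n−k)); and each cluster with ≥ 2 sets gets a
two-sided one-sample t of frac_down against 0.5, Bonferroni-corrected
over tested clusters. The one-sample form was chosen so that a
down-biased cluster yields a positive t and an up-biased cluster a
negative one; this realization of the per-cluster test is an
interpretive choice, as is reading "fraction of genes present in two
pathways given the total number of unique genes in both" as Jaccard.

## Cell-type deconvolution

The convolution model: bulk expression of marker gene g in sample s is
Σ_k f_sk · S_gk, with S the linear-scale mean expression of cell type k
(linearity requires the linear scale; a log signature would break
additivity). Markers are chosen per type by the ratio of the type's
mean to the maximum of the other types' means (top n with ratio > 1,
default 10; fewer available markers warns). Fractions are estimated by
nonnegative least squares followed by sum-to-one renormalization — a
transparent, analyzable solver whose behaviour is validated by recovery
simulation (exact on noiseless full-rank mixtures; mean absolute error
< 0.05 at 5% additive noise) rather than by identity with any published
deconvolution package. Estimates are invariant to positive rescaling of
a bulk sample.

Region panels: cortical samples are solved without medium spiny neurons
and striatal samples without excitatory neurons (7 types each of 8);
excluded types are NaN in the output, never zero, so across-region
subject averages use only the regions where a type exists. Group
comparison is OLS of the fraction on diagnosis + covariates (sex, pH
default — mirroring the expression model, since the covariate set for
this comparison is otherwise unspecified); raw p is the primary
readout with BH q alongside, and fractions are compared on the raw
scale (logit behind a flag).

## Cross-study concordance

Matching is an inner join on gene id. The correlation p-value uses the
exact t transform t = r√(n−2)/√(1−r²) on n − 2 df, two-sided (the
two-sided convention reproduces the printed significance of the
correlation sizes this transform is checked against).

The beta-uniform mixture has density f(p) = λ + (1−λ)·a·p^(a−1) on
(0, 1], 0 < λ, a < 1. Maximum likelihood runs L-BFGS-B within the box
(1e-4, 1−1e-4) from five fixed starts; the fitted log-likelihood
dominates a 50×50 grid oracle in tests. Two signal summaries are
exposed: `beta_fraction` = 1 − λ̂, the fitted weight of the Beta
component (the "fraction of observations drawn from the Beta"), and
`signal_fraction` = 1 − π̂ with π̂ = λ̂ + (1−λ̂)â, the conservative
complement of the null-proportion upper bound. On strongly enriched
p-vectors λ̂ hits the box floor and beta_fraction saturates near 1
while signal_fraction stays lower; both behaviours are tested.

The FDR threshold inverts FDR(τ) = π̂τ/F(τ), F(τ) = λ̂τ + (1−λ̂)τ^â,
giving τ = ((π̂ − q·λ̂)/(q·(1−λ̂)))^(1/(â−1)) for target FDR q; the
round trip recovers q to 1e-9. Note the limit: as â → 1 (everything
looks uniform) τ → 0 — no cutoff can attain the requested FDR, so
nothing passes. Since π̂ ≥ λ̂, the guard branch π̂ − q·λ̂ ≤ 0 (τ = 1)
is unreachable for interior fits and exists only for robustness.
p-values of exactly 0 are clamped to machine ε with a warning (the
power-law density diverges at 0); exact 1s are retained. Congruence
requires strict sign equality of the two log₂FCs; zero fold changes
count as non-congruent.

## Synthetic-data generator

The generator is the package's test bed: it emulates the study design
with known truth, and its defaults are the study conditions (7/8
subjects, regions BA11/BA47/caudate/NAcc, 15,000 genes, 900 planted
global DE genes plus 30 caudate / 200 NAcc extras at ±1 log₂FC,
40M-read-scale libraries, NB dispersion 0.1).

Counts: gene baselines are log-normal (log₂ SD 3.2, giving a realistic
left tail of genes below the CPM floor — roughly a fifth of genes fail
QC at study scale); library sizes are uniform over the configured
range; counts are negative binomial with mean
lib_s · prop_g · 2^Δ_gs. The log₂ shift Δ collects: the planted
diagnosis effect (global effects in all regions, regional effects in
their region only, signs random), per-gene covariate coefficients
(N(0, σ_c) per gene, times the standardized covariate — so the default
DE model is correctly specified), a subject-level latent shared across
all of a subject's samples, an additional latent shared by the cortical
pair, and independent per-sample noise (SD 0.25). The two latent
variances are calibrated analytically from the target correlations:
with v_ind the independent log-scale variance (biological SD² plus the
mean NB counting variance (1/μ + φ)/ln²2 over expressed genes),
v_global = ρ_b/(1−ρ_b)·v_ind and the cortical extra brings the total to
ρ_c/(1−ρ_c)·v_ind. Measured consensus correlations land within ±0.03
of the 0.7 cortical target and near 0.2–0.3 for other pairs, inside the
±0.15 band the tests enforce.

Demographic covariates are drawn from the matched-cohort summary
statistics (means/SDs per group for age, PMI, pH, RIN), clipped to
plausible ranges; sexes alternate within group to emulate matching. No
claim of distributional fidelity beyond those summaries is made.

Gene sets: planted sets draw a configurable fraction (default 0.7) of
their members from the planted DE genes, each from the downregulated
pool with probability `down_bias` (1.0 forces a purely downregulated
overlap); the filler for planted sets avoids DE genes so the planted
overlap is exactly the drawn members; non-planted sets are uniform. The
pipeline plants both a down-biased and a smaller up-biased group
(default ¼ of planted sets) so cluster directionality has a contrast to
find.

Cell types: the synthetic reference gives each of 8 broad types planted
marker genes at 8-fold specificity over a shared per-gene baseline with
mild (lognormal SD 0.2) type noise, so marker selection is
deterministic by construction. True fractions are Dirichlet
(concentration 60) around a realistic composition, with the
case-group mean of one type (medium spiny neurons, −0.08 by default)
shifted *after* rescaling the other types, so the planted shift
survives the sum-to-one constraint; region-inappropriate types get
fraction 0. Mixtures add truncated-Gaussian noise, keeping NNLS
recovery analyzable.

Partner study: a configurable fraction of the reported genes are
planted DE genes (sign agreeing with truth with probability
`sign_agreement`, default 0.9), the rest null genes with small effects;
all reported p < 0.01, emulating a published nominally-significant DEG
table. The true sharing fraction of the emulated external study is
unknown; the pipeline default of 0.6 represents a moderately concordant
partner, and the acceptance script additionally reports the
full-overlap analog, where the fitted beta_fraction saturates near 1.

### What the generator does not emulate

Read-level artifacts (no FASTQ, mapping, or transcript quantification),
batch and library-preparation effects, gene–gene correlation beyond the
shared latents, medication/comorbidity structure, and sample swaps.
Passing tests therefore demonstrate correctness of the statistical
machinery under a faithful but idealized design, not robustness to
every failure mode of real post-mortem data.

## Problem sizes and determinism

Unit and property tests run at 400–3000 genes with the seed counts
stated per test (20-seed calibration bands, 50-seed power checks,
200-rep null uniformity); the acceptance script runs the full 15,000
gene study once, in a few seconds. Every generator takes an explicit
seed and uses a private `numpy.random.Generator`; the pipeline derives
stable per-stage sub-seeds (crc32 of the stage name mixed with the run
seed, kept below 2³¹), so identical config + seed yields byte-identical
reports — asserted by test.

## Known limitations

- Fixed-effects OLS on repeated-measures designs is anti-conservative
  for between-subject effects (quantified above); a mixed model would
  be the remedy but is out of scope.
- The NNLS-based deconvolution is validated behaviourally, not
  identical to any published reference-based method.
- The BUM mixture's `beta_fraction` is an optimistic summary (any
  decreasing p-density pushes λ̂ to the floor); `signal_fraction` is
  the conservative counterpart. Report both.
- GMT collections are corrected separately; cross-collection multiplicity
  is the user's responsibility.
- The CV filter's cutoff depends on the input gene pool (CPM filter
  first, then CV filter — the ordering is an assumption, stated here).
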