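# Methods

`invadiv` reimplements, as one tested library, the statistical workflow
used to ask how an introduced bird population diverges from — and within —
its new range: how much microsatellite diversity the introduction retained,
whether expansion left bottleneck signatures or isolation by distance, and
whether phenotypic divergence among sites exceeds what neutral genetic
drift can explain.

## Genetic diversity

Per (population, locus) cell the package reports the allele count Na,
observed heterozygosity Ho, Nei's unbiased gene diversity
UHe = (2n/(2n−1))(1 − Σp²) with 2n non-missing gene copies, and
F_IS = 1 − Ho/UHe. F_IS is deliberately the Nei form rather than the
Weir–Cockerham small-sample f; the two differ at these sample sizes, which
is documented rather than hidden. Missing genotypes are excluded cell-wise;
a genotype is either complete or absent (half-calls are rejected at parse
time).

Allelic richness is standardised by hypergeometric rarefaction to g gene
copies: Ar_g = Σ_i [1 − C(N−N_i, g)/C(N, g)]. Private allelic richness
multiplies each allele's presence probability in the focal population's
rarefied sample by the probability of absence from every other
population's independent rarefied sample (Kalinowski's definition). The
rarefaction unit is *gene copies* — "28 alleles" equals 14 diploids — and
g should be taken from the observed minimum cell size, not the nominal
sample size, because a single partially typed individual lowers the
attainable g. Both quantities are validated against exhaustive enumeration
of all C(N, g) subsamples on small instances.

Hardy–Weinberg testing uses the exact conditional (Levene) distribution of
genotype tables given allele counts. Tables are enumerated exactly while
the table count stays below a configurable bound (default 10⁶; the
pipeline uses a smaller bound for speed), beyond which a seeded Monte-Carlo
shuffle of gene copies is used. The two-sided p aggregates tables no more
probable than the observed one; the one-sided tests use the heterozygote
count as statistic. The null-allele frequency estimator is Brookfield's
first: r = (UHe − Ho)/(1 + UHe), floored at zero.

Diversity-vs-time uses Pearson correlation of an index against time since
colonisation (reference year minus arrival year, default 2012); group
contrasts (introduced vs native sites) use Wilcoxon rank-sum tests with
exact small-sample distributions.

## Bottleneck test

A recent bottleneck removes rare alleles faster than heterozygosity, so
observed UHe exceeds the equilibrium heterozygosity Heq implied by the
observed allele count k. Heq is sampled with a standard neutral coalescent
of the n sampled gene copies: inter-coalescence times Exp(C(m,2)) in units
of 2N generations, mutations Poisson(θ/2 · branch length). Each mutation
moves the allele size ±1 repeat unit with probability `p_single` (default
0.95) or by a symmetric geometric multi-step whose variance is
`variance_multi`. Published descriptions of the two-phase model's
"variance" are ambiguous between a proportion (0.12) and squared repeat
units (12); both are supported (`variance_mode`), the proportion reading
being the default, and neither asserted as canonical. θ is tuned by
bisection so E[k] matches the observation, then simulations are retained
only when the realised allele count equals k exactly (rejection capped at
10⁶ attempts). Under the strict stepwise model E[k] saturates below n
because different mutational paths can reach the same size; when the
target expectation is unattainable the tuner settles for the largest θ as
long as exact-count simulations still occur. Net size displacement per
branch is drawn in closed form (binomial for the ± balance of single
steps, negative binomial for summed geometric magnitudes), which keeps
memory and time independent of θ.

Per locus the report gives the mean, sd and median of the simulated Heq,
the standardised difference DH = (UHe − mean Heq)/sd Heq, and the tail
probability P(Heq ≥ UHe). The population-level one-tailed excess test is a
Wilcoxon signed-rank over per-locus differences between UHe and the
**median** of the simulated Heq distribution. The median, not the mean, is
used deliberately: He given k is left-skewed, so mean-centred differences
have a positive median under the null and the nominal 5% test rejects at
roughly 11% in calibration simulations (200 equilibrium replicates at both
θ = 2 and θ = 12, strict stepwise model; the standardised-DH variant is
equally inflated). Median-centred differences give 3.5–4.5% — the
correctly sized test. DH itself remains mean/sd-standardised, as is
conventional for the per-locus effect size.

## Differentiation

θ (F_ST) follows the Weir–Cockerham (1984) moment estimator: per allele
and locus the a (among-population), b (among-individual) and c
(within-individual) components with the unequal-sample-size n̄, n_c, p̄,
s², h̄ corrections; multi-locus θ = Σa / Σ(a+b+c). Significance permutes
whole multilocus genotypes among populations (preserving within-individual
allele pairing), one-sided with the +1/(n_perm+1) correction; the 95% CI
bootstraps loci with replacement (undefined with a single locus). The
implementation is checked to 1e-10 against a second, independent
transcription of the published formulas on randomised small instances.

D_est uses Nei & Chesser's sample-size-corrected H_S and H_T (harmonic
mean sample size, Ho correction) with the k/(k−1) scaling. The multi-locus
summary is the harmonic mean of per-locus values, excluding non-positive
loci (they are counted and reported; an arithmetic-mean option exists
because the original web tool's handling of non-positive loci is not
documented).

R_ST treats allele sizes (converted to repeat units when a motif length is
declared, raw bp otherwise) by a two-level unequal-n ANOVA over gene
copies grouped by population; R_ST = σ²_among/(σ²_among + σ²_within),
components summed over loci. Per-locus standardisation (centre/scale by
the global mean and sd) is on by default, matching the convention of the
standardisation-based R_ST calculator the field uses; a flag disables it.

Geographic distances are haversine great circles on a sphere of radius
6371.0 km. Mantel tests correlate the n(n−1)/2 unordered off-diagonal
pairs and permute one matrix's site labels; the default one-sided p is
taken in the sign of the observed r (a two-sided option exists), and
isolation-by-distance tests use natural-log distances (r is invariant to
the log base). Bonferroni thresholds are α/n_tests.

With the published pairwise matrices for the six Brazilian sites, the
cross-statistic Mantel correlations and IBD statistics reproduce the
printed values (r ≈ 0.79 for θ vs D_est, 0.70 for θ vs R_ST, −0.11 and
0.03 against log distance). The θ-vs-log-distance correlation does *not*
reproduce the printed −0.38 under haversine distances (we obtain −0.49);
the distance convention of the original software run is unrecoverable, so
both numbers are reported by the pipeline and neither is asserted.

## Phenotypes and colorimetry

Replicate reflectance spectra are linearly interpolated to the 1-nm grid
300–700 nm (401 points), averaged per sample × patch, and clipped at zero.
Brightness is the mean % reflectance — equivalent to trapezoid area
divided by bandwidth on this uniform grid — so the anchors hold exactly
(flat 0% → 0 = black, flat 100% → 100 = white). UV-chroma is the share of
summed reflectance in 300–400 nm with both endpoints inclusive (101 of the
401 points); the inclusive convention is a documented choice the source
descriptions leave open. Whether reflectance should be rescaled by the
white standard's own spectrum is likewise unstated; raw % reflectance
relative to the standard is assumed.

Multivariate outliers are screened per sex by robust Mahalanobis distances
from a minimum-covariance-determinant fit against the χ² 0.975 quantile.
Site-centroid divergence is tested per sex by one-way MANOVA using the
Pillai trace V = tr[H(H+E)⁻¹] with the standard s/m/n approximate F;
the implementation is cross-checked against an eigen-decomposition oracle
and against statsmodels' MANOVA.

## P_ST–F_ST sensitivity

For each trait (per sex) a one-way ANCOVA with site as factor — body
length as covariate for every trait except body length itself — yields
σ²_W (residual mean square) and σ²_B = max(0, (MS_site − MS_res)/n0) with
n0 = (N − Σn_i²/N)/(k−1); the raw, untruncated value is retained. Then

    P_ST(r) = r·σ²_B / (r·σ²_B + 2·σ²_W),  r = c/h²,

traced on the grid r ∈ [0, 2] in steps of 0.01. Confidence intervals take
P_ST approximately normal with t critical values at df = k − 1. The SE is,
by default, a delta-method propagation of the ANOVA mean squares
(Var MS = 2·MS²/df per stratum, with the induced covariance between
components). A stratified bootstrap over individuals within sites is
available behind `ci_method="bootstrap"`, but it is *not* the default on
empirical grounds: resampling within sites conditions on the realised site
effects and omits the χ²_{k−1} between-site sampling term, and in
coverage simulations at the generator's conditions (σ²_B = 1, σ²_W = 2,
6 sites × 25 individuals) its 95% CI covers the true P_ST at c/h² = 1 in
only ~73/100 replicates versus ~92/100 for the delta method. Whether the
original analysis was parametric or resampling-based is not recoverable;
both remain configurable.

The critical ratio is the smallest grid value at which the lower 95% bound
of P_ST exceeds the upper bound of the neutral F_ST interval (taken from
the bootstrap-over-loci θ CI); P_ST is strictly increasing in r whenever
σ²_B > 0, so once cleared the bound stays cleared. Small critical ratios
(≪ 1) mean divergence would be attributed to drift only if between-
population additive effects were implausibly weak relative to within-
population heritability — robust evidence for divergent selection.

## Synthetic data

The genotype generator is a forward-time Wright–Fisher simulation of
diploid demes with per-gamete stepwise or two-phase mutation on repeat
counts, bounded to [5, 60] with reflecting boundaries (configurable; at
the default mutation rates the bound is never hit, which was verified by
widening it with identical output). Forward time was chosen over the
coalescent because arbitrary founder schedules are trivial forward at desk
scale. Island mode exchanges migrants at a per-gamete rate each
generation; founder-expansion mode grows daughter demes logistically from
scheduled propagules.

Two canonical scenarios are exported. `equilibrium_config` is the
bottleneck test's null condition: one deme of 50 diploids, stepwise
mutation at μ = 0.01 (θ = 4Nμ = 2), 1500 generations (≫ 4N), 15 diploids
sampled; its output was verified to match an independent coalescent
simulation at θ = 2 (mean k ≈ 3.5, He ≈ 0.55). `study_founder_config` is a
desk-scale introduction: a source deme of 500 diploids burnt in for 2000
generations (He ≈ 0.8, strongly polymorphic loci), five daughters founded
at 6-generation intervals with propagules of 100 and rapid logistic
growth, sampled 15 per deme shortly after. This regime reproduces the
qualitative field finding — θ among daughters of a few percent (median
≈ 0.026 across seeds, comparable to the published global 0.028) and no
allelic-richness-vs-time trend.

The phenotype generator draws site effects once (variance σ²_B) and adds
within-site Gaussian noise (σ²_W) plus an optional body-length covariate
slope; heritability is carried as ground-truth metadata only, since the
phenotypic variance decomposition is what the P_ST machinery consumes.
The spectra generator builds two-segment flat spectra whose processed
brightness/UV-chroma equal the requested targets exactly at zero noise.

What the generators deliberately do not emulate: linkage between loci,
selection on genotypes, mutation-rate heterogeneity among loci, real
sparrow demography or geography, measurement error structure beyond iid
Gaussian noise, and sexual dimorphism in the variance components. Passing
tests therefore demonstrate the estimators' correctness and calibration
under idealised neutral conditions, not robustness to those real-data
complications.

## Problem sizes and numerics

Simulation-based checks use desk-scale sizes chosen once: 100 replicates
for the bottleneck type-I error (n_iter = 200 per locus) and the P_ST
coverage check, 20 replicates for the founder-expansion summary, and ≤ 30
randomised small instances per oracle comparison (tolerance 1e-10).
Permutation and bootstrap counts default to 1000 in the pipeline.
Degenerate inputs are defined rather than left to chance: monomorphic
cells report F_IS and HWE as missing, all-zero spectra have undefined
UV-chroma, single-locus datasets report no bootstrap CI, non-positive
distances refuse the log transform, and negative variance components are
truncated at zero (raw values logged). All stochastic stages take explicit
seeds; pipeline stage seeds are spawned deterministically from one config
seed, and identical configs produce byte-identical outputs.
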