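# Methods

`flightdiff` implements the statistical machinery needed to ask whether
sympatric, temporally separated flights of a univoltine butterfly are
genetically and phenotypically differentiated: Bayesian allele-frequency
inference from reduced-representation read counts, Nei's G_ST with
credible intervals, model-based admixture with Evanno's ΔK, nucleotide
diversity, landmark-based wing-shape analysis, and wing-melanization
statistics.  Every analysis is exercisable end to end on synthetic data
whose generating parameters are retained, so each estimator is tested as a
parameter-recovery problem.

## Genotype and allele-frequency model

Reads at a biallelic site are a noisy channel on the diploid genotype
g ∈ {0, 1, 2} (copies of the alternate allele).  With per-read miscall
rate ε, an alternate read occurs with probability e(0) = ε, e(1) = 0.5,
e(2) = 1 − ε, so the read likelihood is binomial,
L(g) = C(d, a) e(g)^a (1 − e(g))^(d − a) for a alternate among d reads.
Zero depth gives the flat triple (1, 1, 1).  Within each population,
genotypes follow Hardy–Weinberg proportions given the population allele
frequency p, which carries a Beta(1, 1) prior.

Inference is Gibbs sampling: each genotype is drawn from the categorical
posterior ∝ L(g)·HWE(g | p), then each population–locus p from its
conjugate Beta update.  Defaults are 100,000 steps with 10,000 burn-in
(thinning 10 for the stored p draws); the scaled-down schedule used in the
recovery experiments is 10,000/2,000.  The genotype posterior is the
empirical frequency of sampled genotypes over all post-burn-in steps.
ε defaults to 0.005 and is a configuration knob — typical short-read
miscall rates are a few per mille, and the inference is insensitive to the
exact value at moderate depth.

The samplers draw ~10⁹ variates per chain, so they run as numba kernels
over a counter-based splitmix64 PRNG (uniforms), with Marsaglia polar
normals, Marsaglia–Tsang gammas, and gamma-ratio betas.  Genotype draws
are branchless.  Every chain is a pure function of its integer seed.

A 20-iteration EM over the same model (E-step: genotype posterior given p;
M-step: p ← Σ E[g]/2N) provides the point estimates behind the diversity
statistics: a site is variable when the EM estimate is farther than 1e-6
from 0 and 1; per variable site π = 2p̂(1−p̂)·2n/(2n−1); θ_W = S/a_{2n−1}
with a_m the m-th harmonic number, reported for the variable-site set and
per assayed site.

## Filtering

Sites are dropped, in order: more than two alleles (when per-site allele
counts are supplied), coverage (≥1 read) in fewer than 25% of
individuals, or fewer than 15 total reads in any population sample; then
individuals missing more than 98% of retained loci are removed.  The
"25% coverage" denominator is all individuals, and the 15-read rule sums
reads per population per site — the thresholds are conventions of the
GBS-style workflow this package reimplements.  Every removal is logged
with the rule that fired.

## Differentiation and ordination

For each pair of populations and each retained MCMC draw, per-locus
H_S is the mean of 2p_k(1−p_k) over the pair and H_T = 2p̄(1−p̄) with p̄
their mean frequency; the multi-locus G_ST is the ratio of sums
Σ(H_T − H_S)/ΣH_T, which is stable at nearly monomorphic loci.  The point
estimate is the posterior mean over draws and the 95% credible interval
the 2.5/97.5 percentiles; draws are paired across populations at matched
iterations (chains are independent, so no cross-population dependence is
imposed).

Two properties of this estimator matter for interpreting the recovery
experiments and are derived in closed form (and confirmed by simulation):

1. **Two-deme estimand.**  Under the F-model generator (below), the
   population frequencies have Var(p) = F·p0(1−p0).  With k demes,
   E[H_T − H_S] = 2·(k−1)/k·F·p0q0 and E[H_T] = 2p0q0(1 − F/k), so the
   pairwise (k = 2) multi-locus G_ST converges to **F/(2−F)**, not F:
   0.015 at F = 0.03, 0.031 at F = 0.06, 0.29 at F = 0.45.  The shortfall
   comes from H_T using the two-deme sample mean instead of the ancestral
   frequency.  Recovery experiments that compare the estimate against F
   itself therefore fail by construction at the larger F, and the honest
   comparison is against the realized multi-locus G_ST of the true
   frequencies.
2. **Estimation-noise inflation.**  Posterior draws scatter around the
   true frequencies with variance σ² set by sample size and depth
   (σ² ≈ 0.005 at n = 25 diploids, 8× coverage), which adds ≈ σ² to the
   per-locus numerator: at 8× the estimator is biased upward by roughly
   +0.01–0.02.  The bias shrinks with depth and sample size.

PCA of genetic structure operates on the individuals × (3·loci) matrix of
genotype posterior probabilities: columns are mean-centered, never scaled,
missing cells are imputed with the column mean, and scores/variance
fractions come from the covariance eigendecomposition.

The G_ST matrix is summarized by non-metric MDS: SMACOF majorization with
pool-adjacent-violators monotone regression of configuration distances on
dissimilarity ranks, Kruskal stress-1 as the loss, a classical-scaling
start plus random restarts (default 8), and the per-iteration stress trace
exposed (it is non-increasing).  Three dimensions by default.

## Admixture

Individuals are reduced to pseudo-haploid calls — one read sampled per
individual-locus in proportion to the read counts (missing at zero depth)
— sidestepping genotype calling at low depth.  The admixture model is the
classic mixture: each non-missing call draws a latent cluster of origin
z ~ Categorical(q_i · f), with conjugate Dirichlet(α + counts) updates of
q_i (α = 1 fixed, configurable) and Beta(1 + counts) updates of the
cluster frequencies.  Missing calls contribute nothing.  Defaults are the
desk-scale 10,000/5,000 schedule; the full-scale 100,000/50,000 schedule
is a configuration flag.

The marginal likelihood per K is the harmonic-approximation estimator
mean(lnL) − var(lnL)/2 over the retained trace, and K is chosen by the
second-order ΔK statistic |L̄(K+1) − 2L̄(K) + L̄(K−1)|/sd(L(K)) across
replicate runs (sample sd; undefined at the K-range endpoints and at zero
sd, by the statistic's definition).  Replicate runs are label-aligned by
optimal assignment (Hungarian) on the summed absolute Q difference to the
first run — optimal assignment dominates greedy matching under the same
cost and guarantees the alignment never increases the mismatch cost.

Posterior-mean admixture proportions are intentionally *not* hard
assignments: at modest divergence (F ≈ 0.1) and ~10³ pseudo-haploid calls
per individual, the posterior mean for a pure individual sits near 0.9
with oracle cluster frequencies and lower when frequencies are estimated
from ~30 samples per cluster.  This softness is a property of the
posterior, not a mixing failure (retained-window analyses show stable
means), and it bounds how small a Q recovery error these conditions can
produce.  ΔK model choice is robust at the same signal level.

## Geometric morphometrics

Twelve 2-D landmarks per wing.  Generalized Procrustes analysis: center,
scale to unit centroid size (CS = root summed squared distances to the
centroid), rotate onto the iteratively re-estimated mean with
rotation-only orthogonal Procrustes (reflections are never fitted; left
wings are mirrored explicitly beforehand via the side flag).  Convergence
tolerance 1e-10 on the mean, 100 iterations maximum, non-convergence
flagged rather than raised.

Aligned shapes are then projected onto the tangent plane at the mean
(disable with `tangent_projection=False`).  The projection is what makes
the dimension accounting exact: centering and the 2-D rotation criterion
are linear constraints, and projection linearizes the unit-size
constraint, so shape variation spans at most 2·12 − 4 = 20 dimensions and
the covariance PCA has at most 20 nonzero eigenvalues.  Without
projection, the size constraint is a sphere and eigenvalue 21 is of order
(shape scatter)² relative to eigenvalue 1.

Allometry is removed by OLS of each Procrustes coordinate on raw centroid
size (not log size); residuals (exactly uncorrelated with size) feed the
covariance PCA, per-PC one-way ANOVA + Tukey HSD on PC1–PC3, and CVA.
CVA projects onto the nonzero-variance principal components first
(eigenvalue > 1e-12 × largest, a rank guard), solves the generalized
eigenproblem of among-group (divided by g−1) versus pooled within-group
(divided by N−g) covariance, scales scores to unit pooled within-group
variance per axis, and returns at most g−1 axes.  At two groups this is
Fisher's discriminant, which the tests verify against an independent
direct solve and scikit-learn's LDA.

Group differences in shape are tested by the Procrustes distance between
group mean aligned shapes with a label-permutation test (default 10,000
permutations, +1/(N+1) continuity correction).  95% confidence ellipses
of group means use the eigendecomposition of (sample covariance)/n with
chi-square 2-df scaling (5.991); that scaling is asymptotic — coverage is
~91.5% at n = 20 and within 2% of nominal by n ≈ 200.

## Melanization

Wing images (single-channel, dark = melanin) are binarized with the
isodata/intermeans threshold (or a fixed value for reproducibility).
Black area is the filled black region; enclosed white area is the white
pixels not connected to the image border (the holes); total melanization
is black minus enclosed white — numerically the raw black pixel area.
Subtracting *all* white would give negative values and is rejected as a
reading.  Duplicate measurements are averaged before analysis.  Because
melanization correlates with wing size, it is regressed on wing area
(Pearson R with a t-test p-value is reported) and the residuals enter a
one-way ANOVA with Tukey–Kramer HSD (studentized-range p-values; the
two-group identity q² = 2F is verified numerically).

## Synthetic data

The generators define the conditions every recovery experiment runs
under:

- **F-model frequencies** — ancestral p0 ~ Uniform(0.05, 0.95) per locus;
  each population's p ~ Beta(p0(1−F)/F, (1−p0)(1−F)/F), i.e. mean p0 and
  variance F·p0(1−p0).  F is the single divergence dial.
- **Reads** — HWE genotypes Binomial(2, p); depth Poisson(coverage 8 by
  default) zeroed with probability `missing_rate` (default 0.1,
  i.i.d. per cell — real GBS missingness is structured by locus and
  library, a known mismatch); alternate reads Binomial(depth, e(g)) with
  ε = 0.005.  Experiments whose stated condition is bare "8× coverage"
  simulate with missing_rate = 0 so the observed mean depth is 8.
- **Admixed individuals** — each of the two allele copies per
  individual-locus draws its cluster of origin from q (rows on the
  simplex, or symmetric Dirichlet), then its allele from that cluster's
  frequency.
- **Wing shapes** — in unit-size shape space: template + group effect +
  allometric vector × (CS − mean CS) + i.i.d. Gaussian digitization noise
  (default 0.005 shape units); scaled to CS ~ Uniform(22, 28) mm
  (a realistic forewing size), then randomly rotated and translated.  A
  per-specimen digitization scale factor is carried as TPS-style SCALE
  metadata rather than corrupting the coordinates, matching how landmark
  software handles image scale; reflections are never applied, matching
  the no-reflection GPA convention.
- **Melanization** — slope·area + group offset + Gaussian noise,
  truncated at zero, area ~ Uniform(90, 150) mm², slope 0.2 by default;
  duplicate "measurements" add small noise.  Rendered wing blobs have
  exactly known filled and hole pixel counts, with the scale bar outside
  the measurement region.

What passing recovery tests on these data do **not** show: robustness to
structured missingness, linked loci, selection, misidentified landmarks,
or photographic segmentation error — none of which the generators
emulate.

## Problem sizes of the recovery experiments

Chosen as the package's own desk-scale experiment design (the full-scale
MCMC schedules remain available by configuration):

- G_ST recovery: F ∈ {0.03, 0.06, 0.45}, L = 2000 loci, n = 25/population,
  8× coverage, ε = 0.005, 10,000-step/2,000-burn-in chains; 24 seeded
  replicates for credible-interval coverage (the coverage bar is the same
  ≥90% proportion at any replicate count).
- Admixture: K = 3 truth (30/cluster + 10 symmetric admixed, L = 1000);
  ΔK over K = 1..6 with 10 runs per K in each of 10 seeded experiments,
  800-step/400-burn-in chains (well-separated synthetic clusters mix
  within tens of sweeps; longer chains change ΔK results only through
  smaller replicate scatter); the Q-recovery run uses the 10,000/5,000
  default.
- Type-I error of the ANOVA: 8 groups × 25, 2000 null replicates.
- Ellipse coverage: n = 200, 2000 replicates.

## Known limitations

- The allele-frequency and admixture samplers assume unlinked biallelic
  loci and within-population HWE.
- Pairwise G_ST inherits the two-deme estimand F/(2−F) and the upward
  estimation-noise bias at low depth described above; no deme-count or
  sample-size (Nei–Chesser-style) corrections are applied, matching the
  plain estimator this package set out to implement.
- ΔK is undefined at the endpoints of the K range and cannot select K = 1.
- No thin-plate-spline deformation grids, semilandmarks, or 3-D
  landmarks; no wing segmentation from photographs.
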