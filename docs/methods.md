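# Methods

## The question and the estimand

Given amplicon count tables from a drought experiment (ambient / mild /
severe watering, pretreatment T1 and post-treatment T2, bulk and rhizosphere
soil, five replicates per post-treatment cell), the pipeline asks three
questions: (i) does drought restructure the community (beta diversity,
dispersion); (ii) is the per-taxon drought response phylogenetically
structured; (iii) does the community covary with root exudate composition.

The central derived quantity is the per-ZOTU **response ratio**.  For a
drought level and the ambient control, replicates are paired by sorted
sample id and

r_i = (t_i − a_i)/(t_i + a_i),  RR = mean over the five pairs.

r_i is set to 0 when both counts are 0 (no information, neutral by
convention) and is bounded in [−1, 1], antisymmetric under swapping the
groups and invariant to common scaling of a pair — properties the test
suite asserts.  The "total count" in the denominator is the pair total; a
dataset-wide denominator variant is not implemented because it destroys the
bounded tri-level interpretation used for tree colouring.  Pairing by
replicate index is the default; `pairing="mean"` (single ratio of group
sums) handles unbalanced designs.  RRs are always computed on rarefied
counts so depth differences cannot masquerade as responses.

The per-ZOTU null shuffles the pooled group labels, re-forms pairs and
recomputes the mean RR (999 permutations by default, two-sided, with the
(1 + exceedances)/(1 + B) convention; all permutation p-values in the
package use it, giving a reportable floor of 1/(B+1)).  Small contrasts can
request `exhaustive=True`, which enumerates every relabelling and returns
the exact fraction (the identity counts itself); the same option exists for
PERMANOVA and Mantel and is pinned against independent enumeration oracles
in the tests.

## Phylogenetic signal

All three statistics operate on the observed RR as a tip trait.

**Pagel's λ** scales the off-diagonal Brownian-motion covariance:
V(λ) = λ·V with the diagonal restored.  The mean and rate are profiled
analytically (GLS), λ is maximised on [0, 1] by bounded scalar search
(tolerance 1e-8; for ultrametric trees λ≤1 keeps V(λ) positive definite,
since V(λ) = (1−λ)·diag(V) + λ·V is then a PD combination), and the test is
a likelihood-ratio against λ=0 referred to χ²₁.  The implementation
reproduces `phytools::phylosig` to ≈1e-5 in λ̂ and ≈1e-4 in log-likelihood
on a frozen fixture (a unit test).  A caveat the acceptance suite measures
explicitly: at the λ=0 boundary the χ²₁ LRT is **conservative** — most
null fits land exactly on λ̂=0 with LR=0 — so its type-I error falls below
1% rather than near the nominal 5%.  The test never over-rejects; users
should simply not interpret a null result as evidence against weak signal.

**Blomberg's K** uses the phylogenetically weighted mean
â = (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹x, MSE₀ = (x−â)ᵀ(x−â)/(n−1),
MSE = (x−â)ᵀV⁻¹(x−â)/(n−1), and
K = (MSE₀/MSE) / [(tr V − n/1ᵀV⁻¹1)/(n−1)], which has expectation ≈1 for BM
traits (the recovery test finds mean K within [0.85, 1.15] over 200 BM
draws).  The p-value permutes trait values across tips, one-sided high.

**Abouheif's C_mean** is Moran autocorrelation of the n-standardised trait
under a topological proximity: A_ij = 1/Π dd(v) over the internal nodes on
the nodal path between tips i and j taken as the union of their ancestor
chains up to and including the root, dd(v) = number of direct descendants;
rows of A are normalised to sum to one and C_mean = zᵀWz/n.  On the
three-tip tree ((A,B),C) every off-diagonal proximity is 1/(2·2) = 0.25;
this hand value and an explicit double-sum loop pin the variant in the
tests (proximity conventions differ between software packages, so the
matrix definition above — not a package name — is the specification of
what this function computes).  One-sided permutation test, as for K.

Practical ordering of power on recovered (count-noisy) response-ratio
traits is C_mean > λ > K; the end-to-end acceptance test requires C_mean to
reject in ≥80% of 50 full simulate→rarefy→RR→test chains at λ_true = 0.9
and to stay within the 1–12% band at λ_true = 0.

## Clade-level response tests

Within each rank, every clade with ≥5 members (configurable) whose member
RRs have nonzero variance gets a two-sided one-sample t-test against 0, BH
correction across clades within the rank, and a direction call when the
adjusted p clears α.  Members never observed in any contrast sample are
excluded first: their conventional r=0 values carry no information and only
dilute the clade mean.  Because relative abundances close to one, a large
planted increase in one clade *genuinely* depresses all others — flags in
other clades under a planted-effect simulation are compositional reality,
not false positives — so the false-flag rate is measured under a matching
no-shift null generator.

The clade-recovery acceptance experiment plants a δ=2 log2-fold-change
shift (a 4σ shift against a background per-taxon effect SD of 0.5) into a
random 8–30-tip clade of a 150-tip tree, with baseline log-SD 1.5, mean
depth 10,000 and Dirichlet-multinomial θ=0.01, and requires BH-q<0.05
detection in ≥80% of 50 runs.  With a background effect SD of 1 — background
taxa individually responding half as strongly as the planted clade shift —
detection drops well below that threshold at any clade size we tested:
bounded pair ratios attenuate sharply under count noise, which is the main
cost of this statistic's robustness.

## Community statistics

Alpha diversity: richness, Shannon (natural log) and Faith's PD including
the path to the root.  Unweighted UniFrac (presence/absence) comes from
scikit-bio and is verified against a per-branch shared/unshared tally
oracle.  PCoA is the classical Gower double-centering eigendecomposition,
implemented in-package because the dispersion test needs the
negative-eigenvalue axes that standard wrappers discard.

PERMANOVA is multi-factor with **sequential (Type I) sums of squares**:
an orthonormal basis is grown term by term (factor dummies and interaction
products, rank-checked), SS per term is the increment of tr(H·G) on the
Gower-centered inner-product matrix, pseudo-F uses the residual MS, and
sample labels are permuted freely (999 default).  Term order follows the
formula as written — treatment, timepoint, microhabitat, then interactions —
so treatment is credited first, mirroring how such tables are usually
printed.  Restricted/strata permutation is out of scope.  Beta dispersion
embeds samples by PCoA with negative axes entering squared distances
negatively (floored at 0), computes distances to group centroids, and
permutes those distances across groups for a one-way F test; singleton
groups are excluded with a warning.

The T1-vs-ambient-T2 comparison is a per-clade rank test on relative
abundances with BH correction.  The groups are unpaired (15 vs 5
replicates), so the default is the two-sample Mann-Whitney form; a paired
signed-rank variant exists for genuinely paired designs.

## SparCC and differential networks

SparCC estimates correlations between latent basis abundances from
compositions: per Dirichlet draw of fractions (posterior with unit prior;
`n_dirichlet=0` uses posterior-mean fractions, deterministic and exactly
invariant to sample order), the log-ratio variance matrix
t_ij = var(log f_i/f_j) is mapped to basis variances via the sparsity
approximation t_ij ≈ ω_i + ω_j (a linear system over included pairs), then
ρ_ij = (ω_i + ω_j − t_ij)/(2√(ω_iω_j)) clipped to [−1,1]; the most strongly
correlated pair above 0.1 is excluded and the system re-solved, up to 10
iterations (never isolating a node; exactly singular exclusion patterns
fall back to least squares), and ρ is averaged over 20 draws.  Defaults
follow the original estimator's reference settings.  Fewer than 25 taxa
triggers a sparsity warning; below 4 is an error.

The differential comparison builds a network per group at class level
(kingdom-tagged tables concatenated sample-wise for cross-kingdom edges),
ranks candidate edges by max(|ρ₁|,|ρ₂|), and tests each selected edge by
permuting the pooled group assignment and recomputing both networks, BH
within the selected set, with sign-pattern labels (always-positive,
always-negative, and the two flip directions).  A selection effect worth
knowing about, quantified in the calibration tests: under a global null,
the top-k-by-magnitude edges have inflated raw p-values (selection favours
pairs whose two group estimates happened to diverge), while the per-edge
test over *all* pairs is calibrated (type-I ≈ 4–5%) and BH-adjusted calls
within a selected set are conservative.  Type-I calibration is therefore
measured without magnitude pre-selection; the top-50 workflow is for
prioritising and display.

## Exudate coupling

envfit regresses each (centered) compound on the leading two PCoA axes
(r², unit arrow, permutation p, BH across compounds).  Mantel correlates
upper triangles of the community distance matrix and the Euclidean distance
on z-scored concentrations (one-sided high); both r and r² are reported
because squared Mantel statistics circulate in the applied literature.
Best-subset search scores every compound subset up to size 5 (>15 compounds
requires greedy forward selection) by Mantel r and attaches a permutation p
to the winner; subset search means the top subset's r need not dominate the
full set's r, and no such ordering is asserted anywhere.

## The synthetic generator

What it emulates: the 3×2×2 study design (60 samples: 15+15 pretreatment
carrying their future treatment labels, 5 replicates per post-treatment
cell); drought severity as a scalar dose s ∈ {0, 0.5, 1} multiplying each
taxon's log2-fold-change effect (dose 0 at T1); phylogenetic structure in
the effect via N(0, σ²V(λ)) plus additive shifts in planted responder
clades; log-normal baseline abundances (default log-SD 2, several orders of
magnitude, so presence/absence UniFrac carries the treatment signal as in
real ZOTU tables); log-normal depth variation (±15%) around 10,000 reads;
and Dirichlet-multinomial count noise with total concentration 1/θ
(θ=0.01 default, multinomial at θ=0).  Trees are unit-height Yule trees;
taxonomies cut them at depths (0.2, 0.5, 0.65, 0.8, 0.9) into monophyletic
phyla…genera (≈16–19 classes at 150–200 tips, matching the class-level
network scale).  Exudates: ten named compounds, two of which track two
rotated mixtures of the community's own top-2 PCoA plane (slope 1.5, noise
SD 0.7), the rest pure noise — rotated mixtures make the *pair* jointly
optimal for the subset search rather than mutually redundant.  A separate
log-normal-basis generator with plantable pairwise correlations and group
latent factors exercises the compositional network estimators.

What it does not emulate: sequencing-error ZOTU inflation and chimeras,
taxonomy misclassification, sample cross-contamination, spatial or temporal
autocorrelation between pots, non-neutral tree shapes, or realistic GC-MS
measurement structure in the exudates.  Passing recovery tests therefore
demonstrate the statistics behave correctly under the stated stochastic
model at ~100–200-taxon scale, not that any real dataset satisfies that
model; real ZOTU tables are 50–100× larger, where clade tests have far more
members per clade and correspondingly higher power.

## Numerical choices and degenerate inputs

Rarefaction is multivariate-hypergeometric (without replacement), seeded;
samples below an explicit depth are dropped with a warning, and
depth="min" uses the shallowest sample.  Zero-variance traits, zero-sum
samples, constant distance matrices, singleton dispersion groups and
all-zero taxa raise or warn explicitly rather than propagating NaNs.
Cholesky factorisation backs all GLS algebra (a 1e-12 jitter stabilises
trait simulation); BH uses statsmodels.  Ties in permutation tests count as
exceedances.  Problem sizes used by the acceptance suite — 100–200 taxa,
60 samples, 50–200 replicate runs, 99–999 permutations — were chosen to
keep each recovery or calibration study at seconds to a couple of minutes
on one core.

## Known limitations

Pagel's λ p-values are conservative at the boundary (above); the RR
statistic attenuates toward 0 under heavy count noise, so clade effects in
rare taxa need large clades or more replicates; sequential-SS PERMANOVA
makes term order matter in unbalanced designs; SparCC assumes sparse true
correlation structure and weakens below a few dozen taxa; and the
select-then-test differential workflow is for edge prioritisation, with
calibrated inference available by testing all pairs.
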