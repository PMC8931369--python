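# Methods

## The model

Traits are analysed on the log10 scale, so an allometry is a straight
line and a clade-specific scaling regime ("grade") is a (θ, β) pair. Two
complementary machines share one substrate, the time-calibrated tree:

**Multiregime OU regression (shift detection).** Branches are painted
into regimes by a set of shift points; each shift sits at the rootward
origin of its branch and is inherited by all descendant branches until a
nested shift overrides it (at most one shift per branch; K = shifts + 1).
Conditional on the painting, a tip's expectation is the regime-weight
mixture E[yᵢ] = Σₖ W[i,k](θₖ + βₖxᵢ), where W[i,k] is the exponentially
discounted time tip *i*'s lineage spent under regime *k*
(Σ over regime-k segments of e^(−α(Tᵢ−t_end)) − e^(−α(Tᵢ−t_start))), with
the residual weight e^(−αTᵢ) assigned to the root regime. Residuals are
multivariate normal with the fixed-root OU covariance
V[i,j] = σ²/(2α)·e^(−2α(T−tₐ))·(1−e^(−2αtₐ)), tₐ the MRCA height. The
fixed-root convention (root state = root-regime expectation, no
stationarity) is the default; it is the convention under which W rows sum
exactly to one. The predictor x is treated as error-free and
time-invariant per tip — the model is conditional on x, not a joint
process.

**PGLS with Pagel's λ (grade confirmation).** y = Xβ + ε,
ε ~ N(0, σ²C(λ)), C(λ) the BM covariance with off-diagonals scaled by
λ ∈ [0,1]. λ is profiled by bounded searches on the five grid intervals
{0, .25, .5, .75, 1} with ties resolved toward larger λ; REML is the
reporting scale, ML available throughout. Grade models use cell-means
coding (one intercept and one slope per grade, shared λ and σ²).

## Priors and sampler

Priors on the shift model: α, σ² ~ half-Cauchy(scale 0.1); shift count ~
Poisson with mean 2 % of the branch count, truncated at 20 %; shift
locations uniform over branches (at most one per branch, so the location
mass of m shifts is 1/C(B, m)); θ ~ N(mean y, 1.5·SD y);
β ~ N(PGLS slope, 0.3).

The sampler is Metropolis–Hastings within reversible jump with uniform
move choice among: birth, death, relocation of a shift; log-scale random
walks on α and σ² (with Jacobian); Gaussian walks on each θₖ and βₖ; and
a joint "line-pivot" move that shears (θₖ, βₖ) along the direction that
keeps the line fixed at the mean predictor — without it the strong θ–β
anticorrelation (x̄ far from 0) makes scalar walks mix very slowly. Birth
proposals draw (θ, β) from an equal mixture of the prior and a normal
centred on the candidate clade's own OLS line (precomputed per branch);
the exact mixture density enters the Hastings ratio, so detailed balance
holds, verified by the prior-only run reproducing the truncated Poisson.
Step sizes adapt toward 30 % acceptance during burn-in only and are
frozen afterwards. Chains are bit-reproducible from the seed.

Implementation note: the OU covariance factors as σ²·M(α) and W as a
regime-aggregation of per-segment exponentials E(α), so only α updates
pay for a Cholesky; every other move reuses the cached factor. Default
run scale is 4 chains × 200,000 iterations, thinned by 100, burn-in
fraction 0.2 — published analyses of this kind run 10M iterations, which
is the same call with a larger `n_iter`; every iteration count here is
configuration, not a constant.

Shift summarization pools post-burn-in samples across chains: a branch's
pp is the fraction of samples in which it carries a shift; accepted
shifts need pp > 0.7 and a clade of at least 4 tips (the "more than three
species" rule). R̂ ≥ 1.1 on α, σ² or the shift count flags, but does not
block, the summary.

### Identifiability caveats

Two shift configurations can be exactly or nearly likelihood-equivalent:
a shift on a root child is symmetric with a shift on its sibling plus a
different root line, and two sister clades sharing one line are dominated
by a single shift on their covering parent (fewer shifts, higher prior).
Posterior mass then spreads over the equivalent configurations and no
single branch need clear the 0.7 threshold — a property of the model, not
a sampler defect. The planted-shift test scenario therefore places its
shifts on branches that are locally distinct (sibling and both children
carry ≥ 3 tips) and have no small covering clade.

## Grade cascade

Starting from the grouping induced by accepted shifts, each putative
grade is merged into the ancestral grade and the merge is adopted when
the richer model is *not* significantly better (p > 0.05); retained
grades are then merged pairwise to detect convergence. The default
comparison is an exact F test of the nested GLS designs conditional on λ
estimated by REML under the simpler model. We did not use the chi-square
LRT with λ re-profiled per model: in simulations at n = 64 it rejected a
true merge ~20–30 % of the time at α = 0.05 (λ-estimation noise leaks
into the statistic), while the conditional F test held the nominal 5 %
level. LRT variants (`criterion="ml"`/`"reml"`) remain available.

## Derived quantities

*Relative measures* are residuals from a single-line PGLS within the
scope of interest (relative brain size: brain on body; relative neuron
density: neurons on structure mass — identical residuals to density on
mass, since log density = log neurons − log mass). *Fold change* between
two grades is 10^(mean vertical distance between the two fitted lines
evaluated at the observed predictor values of all included species);
for parallel lines this is exactly 10^Δθ and F(A,B) = 1/F(B,A) always.

*Ancestral states* use Gaussian message passing (upward subtree
aggregation, downward out-of-subtree information), which equals the joint
ML/GLS solution with the root profiled; estimation variances are the
conditional variances scaled by the ML BM rate. Zero-length pendant
branches collapse exactly to the tip value. Ancestral relative brain size
reconstructs brain and body independently and takes the node's departure
from the tip-level PGLS line.

*Rates.* Group rates for the grade-level comparison come from a
fixed-painting multi-rate BM ML fit (branch lengths scaled per regime) —
a deliberate approximation of branch-wise multiple-variance BM MCMC,
adequate because only group-level rates are interpreted. The bootstrap
group comparison uses the cheaper per-group GLS mean-square statistic
(subtree covariance submatrix) for both the observed and the 10,000
simulated single-rate null datasets, so observed and null are exchangeable
under H₀; p = (1 + #{null ≥ observed})/(1 + n_sim), keeping p ∈ (0, 1].
The trait-rate test compares common-rate vs per-trait-rate BM likelihoods
(LR = n·Σ log(σ̂²_common/σ̂²_t)) with traits treated as evolutionarily
independent given their rates; among-trait covariance is a known
limitation.

## Synthetic data

Trees are pure-birth (uniformly chosen lineage splits), rescaled to a
depth of 300 My to evoke the amniote radiation. Log10 body mass evolves
by BM with diffusion set so the tip SD is span/4 (default span 5 decades
— amniote-like). Responses follow regime lines with residuals that are
either λ-structured (PGLS generative model; tip regime = terminal-branch
regime) or OU-structured (W-weighted means and V_OU residuals; the shift
detector's generative model). The "amniote-like" preset plants three base
grades plus two nested convergent sub-grades (ancestral θ 6.8/β 0.45;
shifted 8.1/0.55 twice; nested 8.6/0.60 twice), echoing the
reptile → bird/mammal → landbird/primate structure; the planted-shift
scenario plants two convergent shifts of Δθ = 0.6, Δβ = 0.15 at αT = 2
with stationary SD 0.15. What the generators do **not** emulate:
measurement error, missing data, non-birth–death tree shape, body-mass
selection, or correlated evolution of predictor and response beyond the
regime structure — so passing recovery tests demonstrates correctness of
the estimators under their own assumptions, not robustness on real data.

## Problem sizes and numerical choices

Recovery and calibration tests run at 48–200 tips with seed-derandomised
replicates (50 for λ recovery, 10 seeds × 4 chains × 100k iterations for
the planted-shift scenario, 200 repetitions at n_sim = 500 for null
calibration); the acceptance script uses slightly smaller replicate
counts at the same per-dataset sizes. Covariance factorizations add a
jitter of 1e−10·trace/n only on Cholesky failure; exact-fit PGLS
likelihoods floor the residual sum at 1e−280 to avoid infinities;
ultrametricity is declared within a relative tolerance of 1e−6.
Polytomies are resolved to zero-length bifurcations in input order, which
fixes the 2n−2 branch count the shift prior depends on. Shifts live at
branch origins; mid-branch positions are not supported.
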