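# Methods

This note documents the statistical machinery in `ecocausal`, the design
choices that were genuinely open, and what the synthetic validation does and
does not establish.

## The inference problem

Given one cross-sectional observation per species of abundance and
generalism (degree or normalized degree in a bipartite interaction network),
decide which variable causes the other. Selection-type community assembly
implies generalism → abundance; drift-type assembly implies the reverse.
Bivariate causal discovery from observational data is impossible without
assumptions; the three methods here each exploit a different asymmetry and
are therefore useful as independent cross-checks.

## Formal-logic Δ statistic

Species are probabilistically binarized: abundant with probability
p_A,i and generalist with probability p_G,i, where the probabilities come
from normalizing each marginal to [0, 1]. The four expected joint-category
proportions are computed analytically (means over species of the per-species
Bernoulli products; a Monte-Carlo binarization oracle verifies them in the
tests), and

Δ = P(abundant ∧ specialist) − P(rare ∧ generalist).

**Variants.** `original` uses the raw min–max rescale as the probability;
`refined` applies ordered-quantile normalization first — normal scores
Φ⁻¹((r − ½)/n) with average ranks for ties — then min–max. The plotting
position (r − ½)/n is one of several standard choices in the
ordered-quantile family; it is fixed here and documented. After the affine
min–max step the normal's location and scale are irrelevant, and the
symmetry of normal scores balances the "small" and "large" proportions
(sample mean ≈ 0.5), which is the stated purpose of the refinement.

**An algebraic degeneracy worth knowing about.** By inclusion–exclusion,
for *any* joint classification scheme,

P(abundant ∧ specialist) − P(rare ∧ generalist) = P(abundant) − P(generalist),

so Δ is a functional of the two marginal probability vectors alone — it
never sees the joint pairing of the two variables. Two consequences:

* The original variant compares marginal skewness. A convex causal link
  (y ~ x², which concentrates the effect near small values) flips its
  verdict even though the causal direction is unchanged — this bias is
  reproduced quantitatively by the test suite on the null models below.
* Rank normalization maps every tie-free marginal to the *same* multiset of
  scores, so the refined Δ is identically zero (up to float roundoff
  ~1e-16) on continuous data. The refined variant is informative only when
  the two marginals differ in tie/discreteness structure. Integer degrees
  from a right-skewed (truncated power-law) distribution have a large tied
  group at low degree whose average-rank score is pulled toward the center;
  after min–max its mean falls below ½, while a continuous abundance
  marginal keeps mean ≈ ½, yielding Δ > 0. On real network data the refined
  Δ therefore measures the asymmetry in marginal discreteness between
  degree and abundance — users should interpret it with that caveat, and
  lean on the ANM and IGCI methods for independent evidence.

**Significance.** The species-level nonparametric bootstrap (resample
species with replacement, recompute the transforms and Δ per resample;
percentile CI; two-sided sign-crossing p-value, doubled, floored at
1/n_boot) treats species as the exchangeable unit. It is a documented
interpretation, not a canonical procedure; measured null rejection at
α = 0.05 is ≈ 5% (test suite, 100–200 replicates).

## Additive-noise model

Y = f(X) + ε, ε ⫫ X, is identifiable outside the linear-Gaussian family.
Both directions are fitted with a univariate penalized cubic B-spline GAM
(basis size min(10, #distinct − 1), intercept included). The penalty weight
is selected by minimizing GCV(λ) = n·RSS/(n − edf)² over a fixed 15-point
log-spaced grid spanning 1e-4..1e6, making the fit deterministic; the
selected weight, effective degrees of freedom and basis are recorded in
`smoothing_info`. Degenerate designs (< 5 distinct predictor values) fall
back to a low-order polynomial; a noiseless response inside the spline span
falls back to the unpenalized basis regression.

Residual–predictor independence is tested with the biased V-statistic HSIC
(Gaussian kernels; bandwidth = median pairwise distance), reported as
n·HSIC_b. P-values: permutation (smoothed (c + 1)/(n_perm + 1)) or a
moment-matched gamma approximation of the permutation null (default; the
two agree within 0.1 on independent data in the tests, and the permutation
test's type-I error at α = 0.05 sits inside the binomial 95% band over 500
replicates). The decision applies one α (default 0.05) to both directions
and returns *inconclusive* when both or neither direction passes; both raw
p-values are always reported.

For abundance data the ANM should be run on the log scale (the
`--log-abundance` flag / `y_transform=np.log`): abundance noise is
multiplicative, and the log transform puts it in the additive regime the
model assumes.

## Information-geometric inference

Both marginals are linearly rescaled to [0, 1]; differential entropy is
estimated by the spacing estimator
Ĥ = ψ(m) − ψ(1) + (1/(m−1)) Σ log(x₍ᵢ₊₁₎ − x₍ᵢ₎) (natural logs; the
ψ-correction is exact only in nats). Zero spacings (ties) contribute 0 and
m counts all points including ties — a literal reading of the estimator's
stated convention; note that with heavily tied data this inflates Ĥ, which
is precisely why tied integer degrees receive a much larger entropy than a
continuous skewed abundance marginal. The decision is H(X) > H(Y) ⇒ X
causes Y, with an equality band of 1e-12 (a floating-point guard: affine
pairs are equal to ~1e-13 after rescaling roundoff) returning
*inconclusive*. The entropy gap |Ĥ(X) − Ĥ(Y)| is exposed as an effect-size
diagnostic; no confidence measure is attached.

## Synthetic generators

**Null models.** x ~ U(0, 1), y = x^d + Normal(0, g(x)) with g
monotonically decreasing: g(x) = max(floor, σ₀(1 − x)) by default
(an exponential form is also provided). Defaults σ₀ = 0.1, floor = 0.01.
The scale matters: the construction is meant to make large-x/small-y pairs
rare while the d = 2 case keeps a right-skewed effect marginal ("more small
than large values"). Much larger σ₀ makes the low-x noise dominate the
min–max range and reverses the skew of the rescaled marginal, destroying
the very property the null model exists to exhibit; σ₀ = 0.1 preserves it
(measured y-skewness ≈ +0.5 at d = 2, and the original Δ variant reverses
direction in ~97% of replicates).

**Ensemble.** Each point draws its own exponent d ~ U(0.5, 1);
y = x^d + white noise — a heterogeneous monotone cause–effect cloud.

**Truncated power law.** p(k) ∝ k^(−γ)e^(−k/k_c) on 1..k_max, sampled from
the directly normalized mass function. The decaying cutoff e^(−k/k_c) is
the normalizable, conventional form. Defaults γ = 1, k_c = 10.

**Communities.** n = 100 species per guild by default. Selection mode:
degrees k ~ truncated power law; a latent effect score
t = ρ·z(k) + σ·√(1 − ρ²)·ε (z = standardized cause, coupling ρ = 0.8,
σ = 1) is rank-remapped onto an exact lognormal(0, 1) abundance sample.
Drift mode mirrors the construction (log-abundance first, degrees
remapped). Rank-remapping guarantees both marginals exactly while the
generative order defines the ground truth, so marginal shape and causal
direction vary independently. The interaction matrix realizes the degree
sequence by letting each species pick its partners uniformly without
replacement; partner-guild abundances are independent draws. When the
latent link is deterministic (ρ = 1, σ = 0), ties in the integer degree
marginal still cap the Spearman correlation slightly below 1 (≈ 0.97);
among species with distinct degrees the ordering is exact.

**What the synthetic validation does not show.** The generators emulate
marginal shapes and a monotone stochastic link; they do not contain
sampling effort effects, measurement error in degree (unsampled
pollinators), bidirectional feedback, or confounding by environment — all
present in real data. Passing the benchmarks demonstrates that each method
detects the asymmetry it is designed for at realistic sample sizes, not
that real communities satisfy the methods' assumptions. On these
communities the ANM recovers the selection direction in ~80% of replicates
at n = 100 (the rank-remap distorts additivity; inconclusive verdicts make
up most of the remainder), and IGCI agrees with the selection label
essentially always — though for the tie-convention reasons above its
verdict on (degree, abundance) pairs is driven by the marginals and does
not flip in drift mode.

## Numerical choices and limitations

* Δ = 0 exactly → inconclusive; no tie-break.
* IGCI equality band 1e-12; spacing ties contribute 0.
* Replicate seeds in the benchmark harness are base_seed + index.
* Bootstrap resamples with a constant marginal are redrawn (bounded), as
  they carry no rank information.
* Problem sizes used by the test suite and the acceptance script (e.g.
  100 replicates of n = 1000 null models; 500 replicates for test size;
  50 communities of 100 species) are chosen so the whole validation runs
  in minutes on a laptop while keeping Monte-Carlo error well below the
  asserted margins.
* Known limitations: no confounder adjustment (no instrumental variables
  or deconfounding), no heteroscedastic or post-nonlinear ANM variants, no
  slope-based IGCI reference measures, no visitation-weighted generalism
  indices, and the marginal-only nature of Δ discussed above.
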