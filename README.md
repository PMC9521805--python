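# ecocausal

Bivariate causal discovery for cross-sectional ecological data.

A ubiquitous pattern in community ecology is that abundant species tend to be
generalists — they interact with more partners. But which way does the causal
arrow point? If communities are structured by **selection** (niche-based
processes), generalists gain a competitive advantage and generalism drives
abundance. If they are structured by **drift** (neutral processes), abundant
populations simply encounter more partners by chance and abundance drives
generalism. `ecocausal` answers this question for any paired species-level
dataset (abundance plus an independent measure of generalism such as degree in
a bipartite interaction network) using three methods with independent
theoretical foundations:

1. **Formal-logic Δ statistic.** Each species is classified *abundant* with
   probability equal to its normalized abundance and *generalist* with
   probability equal to its normalized generalism. With the four joint
   categories, the decision statistic is

   Δ = P(abundant ∧ specialist) − P(rare ∧ generalist),

   with Δ > 0 indicating generalism → abundance. The *original* variant
   normalizes by min–max rescaling; the *refined* variant first removes
   marginal skew with ordered-quantile (rank-based inverse-normal)
   normalization, which protects the statistic from confusing marginal
   skewness with causal asymmetry. A species-level bootstrap supplies
   confidence intervals and p-values.

2. **Additive-noise model (ANM).** Assumes Y = f(X) + ε with ε ⫫ X. Both
   directions are fitted by a penalized cubic-spline GAM (GCV-selected
   smoothing) and the residuals are tested for independence from the putative
   cause with the Hilbert–Schmidt independence criterion (Gaussian kernels,
   median-heuristic bandwidths; permutation or gamma-approximation p-values).
   The direction whose residuals pass the test is causal.

3. **Information-geometric causal inference (IGCI).** For (near-)
   deterministic nonlinear relations, the effect's marginal loses entropy
   relative to the cause. After rescaling both marginals to [0, 1], the
   criterion is H(X) ≥ H(Y) when X causes Y, with differential entropy
   estimated from order-statistic spacings,
   Ĥ = ψ(m) − ψ(1) + (1/(m−1)) Σᵢ log(x₍ᵢ₊₁₎ − x₍ᵢ₎).

The package also ships the validation apparatus: null-model simulators
(y = x^d + heteroscedastic noise with decreasing scale), a community-scale
generator with lognormal abundance marginals, truncated power-law degree
distributions p(k) ∝ k^(−γ)e^(−k/k_c) and a selectable ground-truth causal
direction, plus a benchmark harness measuring direction-recovery rates.

## Worked example

Generate a selection-mode community (100 species, generalism → abundance by
construction) and run all three methods:

```python
import numpy as np
from ecocausal import (CommunityConfig, simulate_community,
                       paired_sample_from_community, fort_direction,
                       fort_significance, igci_direction, anm_direction,
                       PairedSample)

ds = simulate_community(CommunityConfig(n_species=100,
                                        causal_mode="selection", seed=7))
s = paired_sample_from_community(ds)          # x = degree, y = abundance

v = fort_direction(s, "refined")
sig = fort_significance(s, "refined", n_boot=1000, seed=7)
print(v.direction, v.statistics["delta"], sig["ci"], sig["p_value"])

print(igci_direction(s).direction, igci_direction(s).statistics)

log_s = PairedSample(s.ids, s.x, np.log(s.y))  # additive noise on log scale
print(anm_direction(log_s, seed=7).direction, anm_direction(log_s, seed=7).p_values)
```

Output:

```
x_causes_y 0.2431 (0.1832, 0.2776) 0.001
x_causes_y {'h_x': 4.6834, 'h_y': -0.9846, 'entropy_gap': 5.668}
x_causes_y {'p_xy': 0.4153, 'p_yx': 0.0}
```

All three methods agree that generalism causes abundance here: the Δ
statistic is positive (more abundant-specialist than rare-generalist mass,
bootstrap CI excluding 0), generalism's marginal has the higher spacing
entropy, and only the generalism → log-abundance regression leaves residuals
independent of the predictor (p = 0.42 vs p < 10⁻³ for the reverse).

The same analyses run from the shell:

```sh
ecocausal simulate --model community --seed 7 --out sim/
ecocausal discover --method fort-refined --input table.csv \
    --x-col degree --y-col abundance --boot 1000 --seed 7 --out report.json
ecocausal benchmark --method anm --generator eq2 --replicates 100 --n 500 --seed 7
ecocausal analyze --communities dir/ --covariates covs.csv --out fig_table.tsv
```

## Caveats

The Δ statistic is algebraically a difference of *marginal* classification
means; after rank normalization of tie-free continuous marginals it is
identically zero, so the refined variant is informative only when the
marginals carry discreteness/tie structure (as integer degree data do). See
`docs/methods.md` for the full discussion, the generator design, and known
limitations.
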