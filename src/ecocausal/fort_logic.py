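"""Formal-logic causal discovery via probabilistic binarization.

Each species is classified "abundant" with probability equal to its
normalized abundance and "generalist" with probability equal to its
normalized generalism (independently). The expected proportions of the
four joint categories are computed analytically, and the decision
statistic is

    delta = P(abundant & specialist) - P(rare & generalist).

A positive delta indicates that generalism drives abundance (selection),
a negative one that abundance drives generalism (drift).

Two variants differ only in the normalization: ``original`` uses the raw
min-max rescale, ``refined`` first removes marginal skew with the
ordered-quantile normal transform. Note an algebraic property with real
consequences: the two cross-category proportions always differ by
``mean(p_abundant) - mean(p_generalist)``, so delta is a functional of
the two marginals alone. After rank normalization of tie-free continuous
marginals the two probability multisets coincide and delta vanishes; the
refined variant is therefore informative only when the marginals carry
tie/discreteness structure (as integer degree data do). See the methods
note for discussion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import CausalVerdict, PairedSample
from .errors import ConfigurationError, DataError
from .transforms import TransformSpec, to_probability

__all__ = ["FortResult", "fort_proportions", "fort_direction", "fort_significance"]

_VARIANT_SPEC = {
    "original": TransformSpec(kind="minmax"),
    "refined": TransformSpec(kind="orq_then_minmax"),
}


@dataclass
class FortResult:
    """Per-species classification probabilities and the four joint proportions."""

    p_large_x: np.ndarray
    p_large_y: np.ndarray
    prop_abundant_specialist: float
    prop_rare_generalist: float
    prop_abundant_generalist: float
    prop_rare_specialist: float
    delta: float
    variant: str = "refined"

    @property
    def proportions(self) -> dict:
        return {
            "abundant_specialist": self.prop_abundant_specialist,
            "rare_generalist": self.prop_rare_generalist,
            "abundant_generalist": self.prop_abundant_generalist,
            "rare_specialist": self.prop_rare_specialist,
        }


def fort_proportions(p_large_x, p_large_y, variant: str = "refined") -> FortResult:
    """Expected joint-category proportions under independent Bernoulli classification.

    ``p_large_x`` is the per-species probability of being a generalist and
    ``p_large_y`` of being abundant. The four proportions are means over
    species of the per-species joint probabilities; they sum to 1 exactly.
    """
    px = np.asarray(p_large_x, dtype=float)
    py = np.asarray(p_large_y, dtype=float)
    if px.shape != py.shape or px.ndim != 1:
        raise DataError("probability vectors must be 1-d and equal-length")
    if len(px) < 3:
        raise DataError("need at least 3 species")
    for name, p in (("p_large_x", px), ("p_large_y", py)):
        if (p < 0).any() or (p > 1).any():
            raise DataError(f"{name} has entries outside [0, 1]")
    prop_as = float(np.mean(py * (1.0 - px)))
    prop_rg = float(np.mean(px * (1.0 - py)))
    prop_ag = float(np.mean(px * py))
    prop_rs = float(np.mean((1.0 - px) * (1.0 - py)))
    return FortResult(px, py, prop_as, prop_rg, prop_ag, prop_rs,
                      delta=prop_as - prop_rg, variant=variant)


def _direction_from_delta(delta: float) -> str:
    if delta > 0:
        return "x_causes_y"
    if delta < 0:
        return "y_causes_x"
    return "inconclusive"


def fort_direction(sample: PairedSample, variant: str = "refined") -> CausalVerdict:
    """Infer the causal direction between x (generalism) and y (abundance)."""
    if variant not in _VARIANT_SPEC:
        raise ConfigurationError(f"variant must be 'original' or 'refined', got {variant!r}")
    spec = _VARIANT_SPEC[variant]
    result = fort_proportions(to_probability(sample.x, spec),
                              to_probability(sample.y, spec), variant=variant)
    verdict = CausalVerdict(
        method=f"fort_{variant}",
        direction=_direction_from_delta(result.delta),
        statistics={"delta": result.delta, **result.proportions},
        diagnostics=f"x={sample.x_name}, y={sample.y_name}, n={len(sample)}",
    )
    verdict.fort_result = result
    return verdict


def fort_significance(sample: PairedSample, variant: str = "refined",
                      n_boot: int = 1000, seed: int = 0,
                      ci_level: float = 0.95) -> dict:
    """Species-level nonparametric bootstrap of delta.

    Species are resampled with replacement; probabilities and delta are
    recomputed per resample. Returns the observed delta, a percentile
    confidence interval and a two-sided sign-crossing p-value (doubled
    smaller tail fraction, floored at 1/n_boot and capped at 1).
    """
    if n_boot < 200:
        raise ConfigurationError("n_boot must be at least 200")
    if len(sample) < 10:
        raise DataError("need at least 10 species for the bootstrap")
    spec = _VARIANT_SPEC[variant]
    observed = fort_proportions(to_probability(sample.x, spec),
                                to_probability(sample.y, spec)).delta
    rng = np.random.default_rng(seed)
    n = len(sample)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = sample.x[idx], sample.y[idx]
        # degenerate resamples (constant marginal) carry no information: redraw
        attempts = 0
        while (np.unique(xb).size < 2 or np.unique(yb).size < 2) and attempts < 100:
            idx = rng.integers(0, n, size=n)
            xb, yb = sample.x[idx], sample.y[idx]
            attempts += 1
        deltas[b] = fort_proportions(to_probability(xb, spec),
                                     to_probability(yb, spec)).delta
    lo = (1.0 - ci_level) / 2.0
    ci = (float(np.quantile(deltas, lo)), float(np.quantile(deltas, 1.0 - lo)))
    p = 2.0 * min(float(np.mean(deltas <= 0.0)), float(np.mean(deltas >= 0.0)))
    p = min(1.0, max(p, 1.0 / n_boot))
    return {"delta": float(observed), "ci": ci, "p_value": p,
            "bootstrap_deltas": deltas, "variant": variant, "n_boot": n_boot}
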