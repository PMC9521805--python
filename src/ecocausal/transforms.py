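"""Marginal rescaling and normalization.

Two routes to a per-species classification probability in [0, 1]:

* ``minmax`` — the raw affine rescale (value - min) / (max - min), the
  binarization probability of the original formal-logic method;
* ``orq_then_minmax`` — ordered-quantile (rank-based inverse normal)
  normalization followed by the same affine rescale. Because normal
  scores are symmetric, the rescaled scores balance the proportions of
  "small" and "large" values (sample mean ~= 0.5) for any skewed input,
  which is the bias correction of the refined method.

The ordered-quantile transform depends on the data only through ranks
(ties averaged), so it is invariant under any strictly increasing
transformation of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .errors import DegenerateInputError

__all__ = ["TransformSpec", "minmax_rescale", "orq_transform", "to_probability"]


@dataclass(frozen=True)
class TransformSpec:
    """Which normalization route to use when converting values to probabilities."""

    kind: str = "orq_then_minmax"  # or "minmax"
    tie_policy: str = "average_rank"
    target_mean: float = 0.5

    def __post_init__(self):
        if self.kind not in {"minmax", "orq_then_minmax"}:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.tie_policy != "average_rank":
            raise ValueError("only 'average_rank' tie policy is supported")


def _as_vector(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-d vector")
    if not np.isfinite(v).all():
        raise ValueError("vector must be finite")
    return v


def minmax_rescale(v) -> np.ndarray:
    """Affine map of ``v`` onto [0, 1]: min -> 0, max -> 1, order preserved."""
    v = _as_vector(v)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise DegenerateInputError("constant vector cannot be min-max rescaled")
    return (v - lo) / (hi - lo)


def orq_transform(v, spec: TransformSpec | None = None) -> np.ndarray:
    """Ordered-quantile normal scores: Phi^-1((rank - 0.5) / n), ties averaged.

    Distribution-free: the output depends on ``v`` only through its ranks,
    hence is identical for ``v`` and ``m(v)`` for any strictly increasing m.
    """
    v = _as_vector(v)
    if len(v) < 3:
        raise DegenerateInputError("need at least 3 values for normal scores")
    if np.unique(v).size < 2:
        raise DegenerateInputError("constant vector cannot be normalized")
    ranks = rankdata(v, method="average")
    return norm.ppf((ranks - 0.5) / len(v))


def to_probability(v, spec: TransformSpec | None = None) -> np.ndarray:
    """Convert raw values into per-species classification probabilities.

    ``minmax``: the rescaled value itself; ``orq_then_minmax``: the rescaled
    normal score. The result is interpreted as the probability that the
    species belongs to the "large" category (abundant / generalist).
    """
    spec = spec or TransformSpec()
    if spec.kind == "minmax":
        return minmax_rescale(v)
    return minmax_rescale(orq_transform(v, spec))
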