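"""Computed ABC analysis: item categorization on the cumulative-value curve.

Given a vector of nonnegative importances, the items are sorted in descending
order and the curve of cumulative item fraction ("effort") against cumulative
value fraction ("yield") is formed.  Three disjoint sets are cut out of the
sorted sequence:

* set A ("the important few"): the prefix up to the curve point closest
  (Euclidean) to the ideal point (0, 1);
* set B: up to the break-even point, where the interpolated curve's slope
  first drops to <= 1 (i.e. items whose value falls below the mean stop
  paying for their effort), never before the A|B boundary;
* set C ("the trivial many"): the rest.

The partition is invariant to positive rescaling and to input permutation
(up to ties, which are broken by stable input order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ABCResult:
    order: np.ndarray  # item indices, by descending value (stable)
    effort: np.ndarray  # cumulative item fraction, starting at 0
    yield_: np.ndarray  # cumulative value fraction, starting at 0
    ab_boundary: int  # items order[:ab_boundary] form set A
    bc_boundary: int  # items order[ab_boundary:bc_boundary] form set B
    labels: np.ndarray  # per input item, one of "A"/"B"/"C"

    @property
    def set_a(self) -> np.ndarray:
        return self.order[: self.ab_boundary]

    @property
    def set_b(self) -> np.ndarray:
        return self.order[self.ab_boundary : self.bc_boundary]

    @property
    def set_c(self) -> np.ndarray:
        return self.order[self.bc_boundary :]


def abc_analysis(values) -> ABCResult:
    """Partition nonnegative item values into sets A/B/C (see module docs)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("need a 1-d vector of at least 3 items")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if np.any(v < 0):
        raise ValueError("values must be nonnegative")
    total = v.sum()
    if total <= 0:
        raise ValueError("at least one value must be positive")

    n = v.size
    order = np.argsort(-v, kind="stable")
    sorted_v = v[order]
    effort = np.arange(n + 1) / n
    yield_ = np.concatenate(([0.0], np.cumsum(sorted_v) / total))

    # A|B: curve point (excluding the origin) nearest to the ideal (0, 1)
    dist2 = effort[1:] ** 2 + (1.0 - yield_[1:]) ** 2
    ab = int(np.argmin(dist2)) + 1

    # B|C: boundary before the first segment whose slope drops to <= 1;
    # segment i (item i) has slope (v_i/total)/(1/n) = n * v_i / total
    slopes = n * sorted_v / total
    below = np.nonzero(slopes <= 1.0 + 1e-12)[0]
    bc = int(below[0]) if below.size else n
    bc = max(bc, ab)

    labels = np.empty(n, dtype=object)
    labels[order[:ab]] = "A"
    labels[order[ab:bc]] = "B"
    labels[order[bc:]] = "C"
    return ABCResult(order=order, effort=effort, yield_=yield_,
                     ab_boundary=ab, bc_boundary=bc, labels=labels)


def abc_set_a(values) -> np.ndarray:
    """Indices of the items in ABC set A (convenience projection)."""
    return abc_analysis(values).set_a
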