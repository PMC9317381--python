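"""Scoring rules for the olfactory test battery.

Turns raw instrument responses into the analysis variables:

* dilution-sorting tasks (PEA/EUG): Spearman-footrule error score, optionally
  time-corrected (errors per second);
* Sniffin' Sticks: TDI composite and the anosmia/hyposmia/normosmia diagnosis;
* peanut-butter distance test: per-nostril mean detection distance;
* lateralization and enantiomer tasks: correct-trial counts;
* importance-of-olfaction questionnaire: three 6-item subscale sums
  (association, application, consequence); lie/aggravation items are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

N_SORT_ITEMS = 5

# diagnosis cut-offs on the TDI composite
ANOSMIA_MAX = 16.5  # TDI < 16.5 -> anosmia
NORMOSMIA_MIN = 30.5  # TDI > 30.5 -> normosmia; [16.5, 30.5] -> hyposmia


@dataclass(frozen=True)
class SortingResponse:
    """One dilution-sorting trial.

    ``assigned_order[p]`` is the true dilution rank (1..5) of the jar the
    subject placed at position ``p+1``; a perfect sort is (1, 2, 3, 4, 5).
    """

    assigned_order: tuple[int, ...]
    duration: float  # seconds

    def __post_init__(self) -> None:
        if sorted(self.assigned_order) != list(range(1, N_SORT_ITEMS + 1)):
            raise ValueError(
                f"assigned_order must be a permutation of 1..{N_SORT_ITEMS}, "
                f"got {self.assigned_order}"
            )
        if not self.duration > 0:
            raise ValueError("task duration must be positive")


def footrule_sort_score(response: SortingResponse | Sequence[int]) -> int:
    """Spearman-footrule error of a sorting response.

    Sum over positions of |assigned rank - true rank|.  An item one slot off
    contributes 1; the strongest dilution placed first contributes 4.  The
    score is always an even integer in [0, 12] for five items (0 = perfect).
    """
    order = response.assigned_order if isinstance(response, SortingResponse) else tuple(response)
    if sorted(order) != list(range(1, N_SORT_ITEMS + 1)):
        raise ValueError(f"not a permutation of 1..{N_SORT_ITEMS}: {order}")
    return int(sum(abs(rank - pos) for pos, rank in enumerate(order, start=1)))


def time_corrected_score(score: float, duration: float) -> float:
    """Sorting errors per second of task time."""
    if not duration > 0:
        raise ValueError("duration must be positive seconds")
    if score < 0:
        raise ValueError("score must be nonnegative")
    return score / duration


@dataclass(frozen=True)
class SniffinScores:
    """Sniffin' Sticks subtest scores (threshold / discrimination / identification)."""

    olfthresh: float  # dilution-step threshold in [1, 16]
    olfdis: int  # correct discriminations in [0, 16]
    olfident: int  # correct identifications in [0, 16]

    def __post_init__(self) -> None:
        if not 1 <= self.olfthresh <= 16:
            raise ValueError("olfthresh out of [1, 16]")
        if not 0 <= self.olfdis <= 16:
            raise ValueError("olfdis out of [0, 16]")
        if not 0 <= self.olfident <= 16:
            raise ValueError("olfident out of [0, 16]")


def tdi_and_diagnosis(scores: SniffinScores) -> tuple[float, str]:
    """TDI composite (sum of the three subtests, range 1..48) and its diagnosis.

    anosmia: TDI < 16.5; hyposmia: 16.5 <= TDI <= 30.5 (closed interval);
    normosmia: TDI > 30.5.
    """
    tdi = float(scores.olfthresh + scores.olfdis + scores.olfident)
    if tdi < ANOSMIA_MAX:
        return tdi, "anosmia"
    if tdi <= NORMOSMIA_MIN:
        return tdi, "hyposmia"
    return tdi, "normosmia"


PEANUT_START_DISTANCE = 30.0  # cm; the jar starts 30 cm below the nostril


def peanut_summary(
    trials_left: Sequence[float], trials_right: Sequence[float]
) -> tuple[float, float]:
    """Mean peanut-butter detection distance (cm) per nostril over 3 trials."""

    def _mean(trials: Sequence[float], side: str) -> float:
        if len(trials) != 3:
            raise ValueError(f"expected 3 {side} trials, got {len(trials)}")
        arr = np.asarray(trials, dtype=float)
        if np.any(arr < 0) or np.any(arr > PEANUT_START_DISTANCE):
            raise ValueError(f"{side} distances must lie in [0, {PEANUT_START_DISTANCE}] cm")
        return float(arr.mean())

    return _mean(trials_left, "left"), _mean(trials_right, "right")


def count_correct(trials: Iterable[bool], expected_trials: int | None = None) -> int:
    """Number of correct trials (lateralization: 40 trials; enantiomers: 4)."""
    trials = list(trials)
    if expected_trials is not None and len(trials) != expected_trials:
        raise ValueError(f"expected {expected_trials} trials, got {len(trials)}")
    return int(sum(bool(t) for t in trials))


SUBSCALES = ("association", "application", "consequence")
ITEMS_PER_SUBSCALE = 6
ITEM_MAX = 3

#: Default item layout: six items per main subscale, in instrument order,
#: followed by any lie/aggravation items.
DEFAULT_SUBSCALE_MAP = tuple(
    scale for scale in SUBSCALES for _ in range(ITEMS_PER_SUBSCALE)
)


@dataclass(frozen=True)
class QuestionnaireResponse:
    """Importance-of-olfaction questionnaire: 4-point items (0..3) with a
    subscale map assigning each item to association/application/consequence or
    the discarded lie scale."""

    items: tuple[int, ...]
    subscale_map: tuple[str, ...] = DEFAULT_SUBSCALE_MAP

    def __post_init__(self) -> None:
        if len(self.items) != len(self.subscale_map):
            raise ValueError("items and subscale_map lengths differ")
        if any((i < 0 or i > ITEM_MAX) for i in self.items):
            raise ValueError(f"items must lie in [0, {ITEM_MAX}]")
        for scale in SUBSCALES:
            n = sum(1 for s in self.subscale_map if s == scale)
            if n != ITEMS_PER_SUBSCALE:
                raise ValueError(f"subscale {scale!r} must have {ITEMS_PER_SUBSCALE} items, got {n}")
        unknown = {s for s in self.subscale_map} - set(SUBSCALES) - {"lie"}
        if unknown:
            raise ValueError(f"unknown subscales: {sorted(unknown)}")


def importance_subscales(q: QuestionnaireResponse) -> dict[str, int]:
    """Per-subscale sums (0..18 each); lie items contribute nowhere."""
    sums = {scale: 0 for scale in SUBSCALES}
    for item, scale in zip(q.items, q.subscale_map):
        if scale in sums:
            sums[scale] += item
    return sums
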