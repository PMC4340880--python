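"""Iterative short-form subscale construction.

Mirrors the instrument-development pipeline: starting from a candidate
item pool, repeatedly calibrate, compute infit/outfit mean squares, and
eliminate the single worst-fitting item (max MSQ >= 1.3) until the
remaining items conform to the Rasch model or a floor is reached.
High-severity items can be protected from elimination even when they
overfit, since redundancy does not threaten validity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .fitstats import (
    MSQ_UPPER,
    AndersenResult,
    andersen_lr_test,
    flag_items,
    item_fit,
)
from .rasch import ItemBank, ResponseMatrix, estimate_item_difficulties, test_information

__all__ = ["BuildTrace", "build_subscale", "information_window", "best_subset"]


@dataclass
class BuildTrace:
    """Audit trail of a subscale build."""

    steps: list  # (eliminated item, reason, {item: (infit, outfit)})
    final_bank: ItemBank
    final_fit: list
    andersen: AndersenResult | None
    information_window: tuple
    status: str  # "ok" or "floor_reached_with_misfit"
    classifications: dict = field(default_factory=dict)


def _flip_reverse(pool: ResponseMatrix, reverse) -> ResponseMatrix:
    if not reverse:
        return pool
    vals = pool.values.copy()
    for item in reverse:
        j = pool.items.index(item)
        vals[:, j] = 1.0 - vals[:, j]
    return ResponseMatrix(pool.persons, pool.items, vals, pool.ages)


def build_subscale(pool: ResponseMatrix, protect=(), min_items: int = 4,
                   reverse=(), partition=None,
                   msq_upper: float = MSQ_UPPER) -> BuildTrace:
    """Greedy one-at-a-time elimination of misfitting items.

    Each round recalibrates the remaining pool by conditional ML, computes
    item fits, and removes the item with the largest max(infit, outfit)
    if that maximum is >= ``msq_upper`` and the item is not protected.
    Ties break on larger outfit, then lexical item id. Reverse-scored
    items are flipped before entering the pool. If the pool would drop
    below ``min_items`` while misfit remains, the trace is returned with
    a failure status rather than raising.
    """
    protect = set(protect)
    if not protect <= set(pool.items):
        raise ValueError("protect set contains items not in the pool")
    if pool.n_items < min_items + 1:
        raise ValueError("pool must exceed min_items")

    work = _flip_reverse(pool, reverse)
    steps = []
    status = "ok"
    while True:
        bank = estimate_item_difficulties(work, method="conditional_ml")
        fits = item_fit(work, bank)
        worst = None
        for f in sorted(fits, key=lambda f: (-max(f.infit_msq, f.outfit_msq),
                                             -f.outfit_msq, str(f.item_id))):
            if max(f.infit_msq, f.outfit_msq) >= msq_upper and f.item_id not in protect:
                worst = f
                break
        if worst is None:
            break
        if work.n_items <= min_items:
            status = "floor_reached_with_misfit"
            break
        steps.append((worst.item_id, "msq_misfit",
                      {f.item_id: (f.infit_msq, f.outfit_msq) for f in fits}))
        work = work.subset_items([i for i in work.items if i != worst.item_id])

    andersen = andersen_lr_test(work, partition) if partition is not None else None
    window = information_window(bank)
    return BuildTrace(steps=steps, final_bank=bank, final_fit=fits,
                      andersen=andersen, information_window=window,
                      status=status, classifications=flag_items(fits))


def information_window(bank: ItemBank, threshold_fraction: float = 0.5,
                       grid=(-6.0, 6.0, 0.01)) -> tuple:
    """Contiguous theta interval where test information >= fraction of max.

    Scanned on a fixed grid and rounded outward to integers, matching the
    reporting convention "most informative between logit scores X-Y".
    """
    lo, hi, step = grid
    thetas = np.arange(lo, hi + step / 2, step)
    ti = test_information(thetas, bank)
    cutoff = threshold_fraction * ti.max()
    peak = int(np.argmax(ti))
    left = peak
    while left > 0 and ti[left - 1] >= cutoff:
        left -= 1
    right = peak
    while right < ti.size - 1 and ti[right + 1] >= cutoff:
        right += 1
    return (float(np.floor(thetas[left])), float(np.ceil(thetas[right])))


def best_subset(pool: ResponseMatrix, size: int, reverse=()) -> list:
    """Exhaustive search for the best-fitting item subset of a given size.

    Ranks subsets by the largest max-MSQ among their items (smaller is
    better; ties on the sum of |MSQ - 1|). Exponential in pool size —
    intended for small candidate pools as an oracle for the greedy path.
    """
    work = _flip_reverse(pool, reverse)
    best = None
    for combo in combinations(work.items, size):
        sub = work.subset_items(list(combo))
        try:
            bank = estimate_item_difficulties(sub, method="conditional_ml")
        except ValueError:
            continue
        fits = item_fit(sub, bank)
        worst = max(max(f.infit_msq, f.outfit_msq) for f in fits)
        spread = sum(abs(f.infit_msq - 1) + abs(f.outfit_msq - 1) for f in fits)
        key = (worst, spread)
        if best is None or key < best[0]:
            best = (key, list(combo))
    if best is None:
        raise ValueError("no calibratable subset of the requested size")
    return best[1]
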