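"""Collector's (rarefaction) curves of category richness versus effort.

Reads are subsampled without replacement at increasing effort fractions
(seeded, replicated); richness is the number of distinct categories (gene
accessions or functional groups) observed.  The curve at full effort equals
the total category count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np


@dataclass
class RarefactionCurve:
    effort_fractions: list[float]
    mean_richness: list[float]
    replicate_sd: list[float]
    n_reps: int
    seed: int
    total_richness: int
    n_reads: int


def collectors_curve(
    read_categories: Mapping[str, str],
    fractions: Sequence[float],
    n_reps: int = 10,
    seed: int = 0,
) -> RarefactionCurve:
    """Subsample ``floor(f * N)`` reads per fraction and count distinct
    categories, averaged over ``n_reps`` seeded replicates.

    Each replicate draws one permutation of the reads; richness at a cutoff
    is the number of categories whose first occurrence falls within it, which
    is equivalent to independent without-replacement subsampling at every
    fraction and makes each replicate's curve non-decreasing by construction.
    """
    if not read_categories:
        raise ValueError("empty category table")
    fractions = list(fractions)
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if sorted(fractions) != fractions:
        raise ValueError("fractions must be sorted increasing")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    rids = sorted(read_categories)
    cats = np.array([read_categories[r] for r in rids])
    _, codes = np.unique(cats, return_inverse=True)
    n = len(codes)
    k_total = int(codes.max()) + 1
    cutoffs = [max(1, int(np.floor(f * n))) for f in fractions]

    rng = np.random.default_rng(seed)
    richness = np.empty((n_reps, len(fractions)))
    for rep in range(n_reps):
        perm = codes[rng.permutation(n)]
        # first-occurrence position of each category in this ordering
        first = np.full(k_total, n, dtype=np.int64)
        idx = np.arange(n - 1, -1, -1)
        first[perm[::-1]] = idx  # last assignment wins = first occurrence
        first.sort()
        # a category is seen in the first c reads iff its first occurrence
        # (0-based) lies strictly below the cutoff c
        richness[rep] = np.searchsorted(first, cutoffs, side="left")
    mean = richness.mean(axis=0)
    sd = richness.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(len(fractions))
    return RarefactionCurve(
        effort_fractions=fractions,
        mean_richness=[float(m) for m in mean],
        replicate_sd=[float(s) for s in sd],
        n_reps=n_reps,
        seed=seed,
        total_richness=k_total,
        n_reads=n,
    )


def effort_at_richness(curve: RarefactionCurve, target_fraction: float = 0.8) -> float:
    """Smallest effort fraction reaching ``target_fraction`` of total richness.

    Linearly interpolates between adjacent curve points; the curve must cover
    effort up to 1.0.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must lie in (0, 1]")
    if not curve.effort_fractions or curve.effort_fractions[-1] != 1.0:
        raise ValueError("curve must cover effort up to 1.0")
    target = target_fraction * curve.total_richness
    fr = curve.effort_fractions
    mr = curve.mean_richness
    if mr[0] >= target:
        return fr[0]
    for (f0, r0), (f1, r1) in zip(zip(fr, mr), zip(fr[1:], mr[1:])):
        if r1 >= target:
            if r1 == r0:
                return f1
            return f0 + (target - r0) / (r1 - r0) * (f1 - f0)
    return 1.0
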