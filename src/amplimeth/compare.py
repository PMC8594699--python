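"""Cross-condition pattern-set analyses: Venn regions, pooled groups, levels.

Pattern identity across conditions is bit-string equality; a pattern present
in several conditions lands in exactly one Venn region (the set of conditions
that share it). Pooled comparisons (e.g. nurses vs foragers, young vs old)
apply the frequency cutoff within each member library first, then take the
union per group.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .estimate import PatternDistribution, apply_cutoff, estimate_distribution
from .patterns import PatternCountTable, per_cpg_levels

__all__ = [
    "ConditionComparison",
    "PooledComparison",
    "venn_counts",
    "compare_conditions",
    "pooled_comparison",
    "cumulative_pooled",
    "overall_level",
    "region_label",
]


def region_label(subset: frozenset[str], order: Sequence[str]) -> str:
    return "&".join(c for c in order if c in subset)


def venn_counts(sets: Mapping[str, set[str]]) -> dict[frozenset[str], int]:
    """Count patterns exclusive to every nonempty subset of 2-5 named sets.

    A pattern contributes to exactly one region: the subset of conditions
    containing it. Region counts therefore sum to |union of all sets|.
    """
    names = list(sets)
    if not 2 <= len(names) <= 5:
        raise ValueError("venn_counts requires between 2 and 5 sets")
    lengths = {len(p) for s in sets.values() for p in s}
    if len(lengths) > 1:
        raise ValueError("patterns of unequal length cannot be compared")
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[frozenset(combo)] = 0
    for pattern in set().union(*sets.values()):
        member = frozenset(n for n in names if pattern in sets[n])
        regions[member] += 1
    return regions


@dataclass(frozen=True)
class ConditionComparison:
    """Venn-style comparison of retained pattern sets across conditions."""

    conditions: tuple[str, ...]
    cutoff: float
    sets: dict[str, set[str]]
    region_counts: dict[frozenset[str], int]

    def labelled_counts(self) -> list[tuple[str, int]]:
        items = sorted(
            self.region_counts.items(),
            key=lambda kv: (len(kv[0]), region_label(kv[0], self.conditions)),
        )
        return [(region_label(s, self.conditions), c) for s, c in items]


def compare_conditions(
    dists: Mapping[str, PatternDistribution],
    cutoff: float,
) -> ConditionComparison:
    """Apply the frequency cutoff per condition and count Venn regions."""
    amplicons = {d.amplicon for d in dists.values()}
    if len(amplicons) > 1:
        raise ValueError(f"conditions span multiple amplicons: {sorted(amplicons)}")
    sets = {cond: apply_cutoff(d, cutoff)[1] for cond, d in dists.items()}
    return ConditionComparison(
        conditions=tuple(dists),
        cutoff=cutoff,
        sets=sets,
        region_counts=venn_counts(sets),
    )


@dataclass(frozen=True)
class PooledComparison:
    """2-way comparison of two pooled condition groups for one amplicon."""

    amplicon: str
    cutoff: float
    set_a: frozenset[str]
    set_b: frozenset[str]

    @property
    def a_only(self) -> int:
        return len(self.set_a - self.set_b)

    @property
    def b_only(self) -> int:
        return len(self.set_b - self.set_a)

    @property
    def shared(self) -> int:
        return len(self.set_a & self.set_b)


def _pool(group: Sequence[PatternDistribution], cutoff: float, mode: str) -> frozenset[str]:
    if mode == "per_member":
        out: set[str] = set()
        for d in group:
            out |= apply_cutoff(d, cutoff)[1]
        return frozenset(out)
    if mode == "reestimate":
        # alternative pooling: sum raw counts, re-estimate, then cut
        counts: dict[str, int] = {}
        for d in group:
            for p, c in d.observed_counts.items():
                counts[p] = counts.get(p, 0) + c
        table = PatternCountTable(
            amplicon=group[0].amplicon,
            sample="pooled",
            counts=counts,
            n_called=sum(counts.values()),
        )
        pooled = estimate_distribution(table, group[0].error_model)
        return frozenset(apply_cutoff(pooled, cutoff)[1])
    raise ValueError(f"unknown pooling mode {mode!r}")


def pooled_comparison(
    group_a: Sequence[PatternDistribution],
    group_b: Sequence[PatternDistribution],
    cutoff: float,
    mode: str = "per_member",
) -> PooledComparison:
    """Compare two groups of libraries from the same amplicon.

    Each group's pattern set is the union over members of patterns passing
    the cutoff within that member (``mode="per_member"``, the default), or
    the cutoff applied to a re-estimated pool of the raw counts
    (``mode="reestimate"``).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    amplicons = {d.amplicon for d in list(group_a) + list(group_b)}
    if len(amplicons) > 1:
        raise ValueError(f"groups span multiple amplicons: {sorted(amplicons)}")
    return PooledComparison(
        amplicon=amplicons.pop(),
        cutoff=cutoff,
        set_a=_pool(group_a, cutoff, mode),
        set_b=_pool(group_b, cutoff, mode),
    )


def cumulative_pooled(results: Sequence[PooledComparison]) -> dict[str, int]:
    """Sum 2-way pooled counts over amplicons (the 'cumulative' comparison)."""
    return {
        "a_only": sum(r.a_only for r in results),
        "b_only": sum(r.b_only for r in results),
        "shared": sum(r.shared for r in results),
    }


def overall_level(dist) -> float:
    """Overall methylation: the mean over CpGs of the per-CpG combined levels."""
    return float(np.mean(per_cpg_levels(dist)))
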