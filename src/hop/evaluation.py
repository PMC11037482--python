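"""Benchmark metrics: truth rank, cumulative top-K curves, baselines.

A spike-in benchmark exome has one known causal combination. Its position
in the output ranking is the *truth rank*; ties on the final score are
resolved pessimistically (the truth takes the worst position among tied
records), so reported recovery never benefits from tie luck. Across many
exomes the cumulative curve CDF(K) = fraction of exomes with truth rank
<= K summarizes performance, conventionally reported at K = 1, 10, 20, 50.

Single-variant prioritizers are compared by aggregating their per-variant
ranks: a combination's rank is the maximum of its member variants' ranks,
i.e. the number of variants one must examine down the list to have seen
the whole combination; it is top-1 only when every member variant sits at
the very top.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from hop.ranking import RankingRecord
from hop.variant_pipeline import DigenicCombination

__all__ = [
    "NOT_FOUND",
    "ExomeResult",
    "CdfTable",
    "truth_rank",
    "cdf_topk",
    "single_variant_combination_rank",
]

SUMMARY_KS = (1, 10, 20, 50)

NOT_FOUND = None  # sentinel: truth combination absent from the ranking


@dataclass(frozen=True)
class ExomeResult:
    """Outcome of one benchmark exome."""

    exome_id: str
    truth_combination_id: str
    truth_rank: int | None  # None when the truth never appeared
    total_combinations: int

    def __post_init__(self) -> None:
        if self.truth_rank is not None and not (
            1 <= self.truth_rank <= self.total_combinations
        ):
            raise ValueError(
                f"truth rank {self.truth_rank} outside 1..{self.total_combinations}"
            )


@dataclass
class CdfTable:
    """Fraction of exomes with truth rank <= K, for K = 1..K_max."""

    fractions: dict[int, float]
    summary: dict[int, float]

    def __getitem__(self, k: int) -> float:
        return self.fractions[k]


def truth_rank(ranking: Sequence[RankingRecord], truth_id: str) -> int | None:
    """Worst-case 1-based rank of the truth combination, or None if absent.

    Records tied with the truth on the final score all count as ranked
    above it: the returned rank is the number of records whose final score
    is >= the truth's. This is the conservative reading -- a user scanning
    the list might inspect every tied record before the truth.
    """
    truth = next((r for r in ranking if r.combination_id == truth_id), None)
    if truth is None:
        return NOT_FOUND
    return sum(1 for r in ranking if r.FS >= truth.FS)


def cdf_topk(results: Sequence[ExomeResult], k_max: int = 50) -> CdfTable:
    """Cumulative recovery curve over benchmark exomes.

    CDF(K) = |{exomes: truth_rank <= K}| / |exomes|; an exome whose truth
    was never ranked counts as not recovered at any K.
    """
    if not results:
        raise ValueError("cdf_topk requires at least one exome result")
    n = len(results)
    ranks = [r.truth_rank for r in results]
    fractions = {
        k: sum(1 for r in ranks if r is not None and r <= k) / n
        for k in range(1, k_max + 1)
    }
    summary = {k: fractions[k] for k in SUMMARY_KS if k <= k_max}
    return CdfTable(fractions=fractions, summary=summary)


def single_variant_combination_rank(
    variant_ranks: Mapping, combination: DigenicCombination
) -> int | None:
    """Rank of a combination under a single-variant prioritizer.

    The combination's rank is the maximum of its member variants' ranks:
    the minimum list depth at which every member has been seen. A missing
    variant yields None (not found). The result is 1 only if every member
    variant is ranked at the top of the list.

    ``variant_ranks`` may be keyed by Variant objects or by variant id
    strings (``chrom:pos:ref:alt``).
    """
    ranks = []
    for v in combination.variants:
        rank = variant_ranks.get(v)
        if rank is None:
            rank = variant_ranks.get(v.variant_id)
        if rank is None:
            return NOT_FOUND
        ranks.append(int(rank))
    return max(ranks)
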