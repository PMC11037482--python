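"""Score fusion and per-exome ranking.

PS (pathogenicity) and DS (disease relevance) live on incomparable
scales, so both are min-max scaled *within one exome*: the best
combination of each kind maps to 1, the worst to 0, giving the two
signals equal weight. The final score is their mean (alternative
aggregation operators are selectable), and combinations are ranked in
decreasing final score. Scaling is never performed across a cohort.

Ties are broken deterministically (higher scaled PS first, then
lexicographic combination id) so repeated runs produce byte-identical
rankings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FUSION_OPERATORS",
    "RankingRecord",
    "minmax_scale",
    "fuse_scores",
    "rank_exome",
    "write_ranking_tsv",
    "read_ranking_tsv",
]

FUSION_OPERATORS = ("mean", "product", "min", "max")

RANKING_COLUMNS = (
    "rank",
    "combination_id",
    "gene_a",
    "gene_b",
    "PS",
    "DS",
    "PS_scaled",
    "DS_scaled",
    "FS",
)


@dataclass(frozen=True)
class RankingRecord:
    """One ranked combination with raw, scaled and fused scores."""

    combination_id: str
    gene_pair: tuple[str, str]
    PS: float
    DS: float
    PS_scaled: float
    DS_scaled: float
    FS: float
    rank: int


def minmax_scale(values: Sequence[float]) -> np.ndarray:
    """Map values affinely onto [0, 1]; a constant sequence maps to 0.5.

    The degenerate all-equal case maps to 0.5 so a constant score neither
    dominates nor vanishes when averaged with the other signal.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot min-max scale an empty sequence")
    if not np.all(np.isfinite(arr)):
        raise ValueError("min-max scaling requires finite values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.full_like(arr, 0.5)
    return (arr - lo) / (hi - lo)


def fuse_scores(ps_scaled: float, ds_scaled: float, operator: str = "mean") -> float:
    """Combine the two scaled scores with the selected operator."""
    if operator == "mean":
        return (ps_scaled + ds_scaled) / 2.0
    if operator == "product":
        return ps_scaled * ds_scaled
    if operator == "min":
        return min(ps_scaled, ds_scaled)
    if operator == "max":
        return max(ps_scaled, ds_scaled)
    raise ValueError(
        f"unknown fusion operator {operator!r}; expected one of {FUSION_OPERATORS}"
    )


def rank_exome(
    records: Sequence[tuple[str, tuple[str, str], float, float]],
    operator: str = "mean",
) -> list[RankingRecord]:
    """Scale, fuse and rank one exome's combinations.

    Parameters
    ----------
    records
        Tuples ``(combination_id, gene_pair, PS, DS)`` for every
        combination in one exome.
    operator
        Fusion operator for the scaled scores (default mean).

    Returns
    -------
    list of RankingRecord sorted by rank 1..N (decreasing final score;
    ties by decreasing scaled PS, then combination id).
    """
    if not records:
        raise ValueError("cannot rank an empty exome")
    ps_scaled = minmax_scale([r[2] for r in records])
    ds_scaled = minmax_scale([r[3] for r in records])
    fused = [
        (cid, pair, ps, ds, float(pss), float(dss), fuse_scores(float(pss), float(dss), operator))
        for (cid, pair, ps, ds), pss, dss in zip(records, ps_scaled, ds_scaled)
    ]
    fused.sort(key=lambda t: (-t[6], -t[4], t[0]))
    return [
        RankingRecord(
            combination_id=cid,
            gene_pair=pair,
            PS=ps,
            DS=ds,
            PS_scaled=pss,
            DS_scaled=dss,
            FS=fs,
            rank=i,
        )
        for i, (cid, pair, ps, ds, pss, dss, fs) in enumerate(fused, start=1)
    ]


def read_ranking_tsv(path) -> list[RankingRecord]:
    """Read a ranking TSV written by :func:`write_ranking_tsv`."""
    records: list[RankingRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != RANKING_COLUMNS:
            raise ValueError(f"unexpected ranking columns in {path}: {header}")
        for line in fh:
            rank, cid, ga, gb, ps, ds, pss, dss, fs = line.rstrip("\n").split("\t")
            records.append(
                RankingRecord(
                    combination_id=cid,
                    gene_pair=(ga, gb),
                    PS=float(ps),
                    DS=float(ds),
                    PS_scaled=float(pss),
                    DS_scaled=float(dss),
                    FS=float(fs),
                    rank=int(rank),
                )
            )
    return records


def write_ranking_tsv(records: Sequence[RankingRecord], path) -> None:
    """Write the ranking as a TSV sorted by rank, with stable formatting."""
    with open(path, "w") as fh:
        fh.write("\t".join(RANKING_COLUMNS) + "\n")
        for r in sorted(records, key=lambda x: x.rank):
            fh.write(
                "\t".join(
                    (
                        str(r.rank),
                        r.combination_id,
                        r.gene_pair[0],
                        r.gene_pair[1],
                        f"{r.PS:.10g}",
                        f"{r.DS:.10g}",
                        f"{r.PS_scaled:.10g}",
                        f"{r.DS_scaled:.10g}",
                        f"{r.FS:.10g}",
                    )
                )
                + "\n"
            )
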