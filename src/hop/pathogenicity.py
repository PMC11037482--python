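"""Pathogenicity-score contract, bundled scorers, and grouped CV folds.

The pathogenicity score (PS) of a variant combination is the probability,
in [0, 1], that the combination is disease causing. The trained gene-pair
classifier that produces it in production is external to this package;
here it is a pluggable contract with two bundled implementations:

* :class:`TableScorer` -- looks PS up in a precomputed TSV keyed by
  combination id (the adapter for externally computed model output);
* :class:`SurrogateScorer` -- a deterministic, platform-stable hash of the
  combination id mapped to [0, 1), with per-gene-pair overrides, used by
  the synthetic benchmark to plant a known high-scoring truth pair.

Fold assignment for cross-validating a retrainable scorer is grouped by
gene pair: all combinations sharing a gene pair land in the same fold, so
a model never sees its test pair during training.
"""

from __future__ import annotations

import hashlib
import logging
from abc import ABC, abstractmethod
from collections import defaultdict

import numpy as np
import pandas as pd

from hop.variant_pipeline import DigenicCombination

__all__ = [
    "PathogenicityScorer",
    "TableScorer",
    "SurrogateScorer",
    "table_scorer",
    "surrogate_scorer",
    "assign_grouped_folds",
]

logger = logging.getLogger(__name__)


class PathogenicityScorer(ABC):
    """Scorer contract: deterministic map combination -> PS in [0, 1]."""

    name: str = "abstract"

    @abstractmethod
    def score(self, combination: DigenicCombination) -> float:
        """Return the pathogenicity score of one combination."""


class TableScorer(PathogenicityScorer):
    """Lookup scorer backed by a TSV with columns combination_id, ps.

    ``mode='strict'`` raises on a missing id; ``'lenient'`` scores missing
    ids 0 and emits one aggregated warning at the end of the run.
    """

    def __init__(self, table: dict[str, float], mode: str = "strict") -> None:
        if mode not in ("strict", "lenient"):
            raise ValueError(f"mode must be strict or lenient, got {mode!r}")
        bad = {k: v for k, v in table.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(
                f"pathogenicity scores outside [0, 1] for {len(bad)} id(s), "
                f"e.g. {next(iter(bad.items()))}"
            )
        self._table = table
        self._mode = mode
        self._missing: set[str] = set()
        self.name = f"table[{mode}]"

    @classmethod
    def from_tsv(cls, path, mode: str = "strict") -> "TableScorer":
        df = pd.read_csv(path, sep="\t", dtype={"combination_id": str, "ps": float})
        for col in ("combination_id", "ps"):
            if col not in df.columns:
                raise ValueError(f"score table {path} lacks column {col!r}")
        return cls(dict(zip(df["combination_id"], df["ps"])), mode=mode)

    def score(self, combination: DigenicCombination) -> float:
        cid = combination.combination_id
        if cid in self._table:
            return self._table[cid]
        if self._mode == "strict":
            raise KeyError(f"no pathogenicity score for combination {cid}")
        if not self._missing:
            logger.warning("score table misses some combinations; scoring them 0")
        self._missing.add(cid)
        return 0.0


class SurrogateScorer(PathogenicityScorer):
    """Deterministic pseudo-random scorer for benchmarks and tests.

    PS is a SHA-256 hash of ``seed:combination_id`` scaled to [0, 1), so
    scores are identical across runs, platforms and process boundaries
    and approximately uniform over random ids. Gene pairs listed in
    ``overrides`` always receive the override value, which is how a
    planted truth pair gets a known near-maximal PS.
    """

    def __init__(
        self,
        seed: int = 0,
        overrides: dict[tuple[str, str], float] | None = None,
    ) -> None:
        self._seed = int(seed)
        self._overrides: dict[tuple[str, str], float] = {}
        for pair, value in (overrides or {}).items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"override for {pair} outside [0, 1]: {value}")
            self._overrides[tuple(sorted(pair))] = value
        self.name = f"surrogate[seed={seed}]"

    def score(self, combination: DigenicCombination) -> float:
        pair = tuple(sorted(combination.gene_pair))
        if pair in self._overrides:
            return self._overrides[pair]
        digest = hashlib.sha256(
            f"{self._seed}:{combination.combination_id}".encode()
        ).digest()
        return int.from_bytes(digest[:8], "big") / 2**64


def table_scorer(score_table_path, mode: str = "strict") -> TableScorer:
    """Load a :class:`TableScorer` from a TSV of precomputed scores."""
    return TableScorer.from_tsv(score_table_path, mode=mode)


def surrogate_scorer(
    seed: int = 0, overrides: dict[tuple[str, str], float] | None = None
) -> SurrogateScorer:
    """Construct the deterministic surrogate scorer."""
    return SurrogateScorer(seed=seed, overrides=overrides)


def assign_grouped_folds(
    combinations: list[DigenicCombination], k: int, seed: int
) -> dict[str, int]:
    """Assign combinations to k folds, keeping each gene pair in one fold.

    Gene-pair groups are shuffled with ``seed`` and greedily placed into
    the currently smallest fold, so fold sizes differ by at most the
    largest group size (exactly balanced when all groups are singletons).

    Returns a mapping ``combination_id -> fold label`` with labels 1..k.

    Raises
    ------
    ValueError
        If k < 2 or there are fewer distinct gene pairs than folds.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    groups: dict[tuple[str, str], list[str]] = defaultdict(list)
    for c in combinations:
        groups[c.gene_pair].append(c.combination_id)
    if len(groups) < k:
        raise ValueError(
            f"need at least k={k} distinct gene pairs, got {len(groups)}"
        )
    rng = np.random.default_rng(seed)
    order = sorted(groups)
    rng.shuffle(order)

    fold_sizes = [0] * k
    assignment: dict[str, int] = {}
    for pair in order:
        fold = int(np.argmin(fold_sizes))  # ties -> lowest label
        for cid in groups[pair]:
            assignment[cid] = fold + 1
        fold_sizes[fold] += len(groups[pair])
    return assignment
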