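"""Random walk with restart and gene-pair disease-relevance scoring.

A walker starts on the seed nodes (phenotype terms and/or panel genes,
uniform initial mass), follows graph edges with probability ``1 - r`` and
teleports back to the seeds with probability ``r``::

    p(t+1) = (1 - r) * W @ p(t) + r * p0

The stationary distribution scores every node's proximity to the seeds:
guilt by association, with both local and global topology taken into
account. The disease-relevance score of a gene pair is the mean of the two
gene scores; genes absent from the walk index (not in the graph, or
isolated) contribute 0 so a whole-exome run never aborts on an
unannotated gene.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from hop.graph_store import TransitionMatrix

__all__ = [
    "GENE_PREFIX",
    "HPO_PREFIX",
    "gene_node",
    "hpo_node",
    "SeedSet",
    "RWRConfig",
    "NodeScoreVector",
    "SeedResolutionError",
    "build_seed_vector",
    "random_walk_restart",
    "pair_disease_score",
]

logger = logging.getLogger(__name__)

GENE_PREFIX = "GENE:"
HPO_PREFIX = "HPO:"


def gene_node(symbol: str) -> str:
    """Namespaced graph id for a gene symbol."""
    return symbol if symbol.startswith(GENE_PREFIX) else GENE_PREFIX + symbol


def hpo_node(term: str) -> str:
    """Namespaced graph id for an HPO term id such as ``HP:0000118``."""
    return term if term.startswith(HPO_PREFIX) else HPO_PREFIX + term


class SeedResolutionError(ValueError):
    """No requested seed could be resolved against the graph index."""


@dataclass
class RWRConfig:
    """Restart-walk parameters.

    r : restart probability in (0, 1]; 0.3 by default. Higher values keep
        the walker near the seeds, lower values let it diffuse further.
    tol : L1 convergence tolerance on successive iterates.
    max_iter : iteration cap; convergence is geometric at rate (1 - r),
        so the defaults terminate in a few dozen steps.
    """

    r: float = 0.3
    tol: float = 1e-9
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.r <= 1.0:
            raise ValueError(f"restart probability must be in (0, 1], got {self.r}")
        if self.tol <= 0:
            raise ValueError(f"tolerance must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")


@dataclass
class SeedSet:
    """Resolved seeds with their uniform initial probability vector."""

    requested_ids: list[str]
    resolved_ids: list[str]
    p0: np.ndarray

    @property
    def unresolved_ids(self) -> list[str]:
        return [i for i in self.requested_ids if i not in set(self.resolved_ids)]


@dataclass
class NodeScoreVector:
    """Stationary distribution of the walk plus convergence metadata."""

    scores: dict[str, float]
    iterations_used: int
    converged: bool
    raw: np.ndarray = field(repr=False, default=None)

    def get(self, node_id: str, default: float = 0.0) -> float:
        return self.scores.get(node_id, default)


def build_seed_vector(
    graph_index: dict[str, int],
    hpo_ids: list[str] | None = None,
    panel_genes: list[str] | None = None,
) -> SeedSet:
    """Resolve phenotype/panel seeds and build the initial vector ``p0``.

    HPO ids and panel gene symbols are namespaced, deduplicated, resolved
    against the walk index, and given equal probability summing to 1.
    Unresolved ids are logged as warnings; if *none* resolves,
    :class:`SeedResolutionError` lists every offender.
    """
    hpo_ids = hpo_ids or []
    panel_genes = panel_genes or []
    if not hpo_ids and not panel_genes:
        raise SeedResolutionError("at least one HPO term or panel gene is required")

    requested: list[str] = []
    for raw, namespace in itertools.chain(
        ((t, hpo_node) for t in hpo_ids), ((g, gene_node) for g in panel_genes)
    ):
        # an id already present verbatim (any namespace) is taken as-is
        nid = raw if raw in graph_index else namespace(raw)
        if nid not in requested:
            requested.append(nid)

    resolved = [nid for nid in requested if nid in graph_index]
    unresolved = [nid for nid in requested if nid not in graph_index]
    if not resolved:
        raise SeedResolutionError(
            "no seed resolves against the graph: " + ", ".join(unresolved)
        )
    if unresolved:
        logger.warning(
            "%d seed id(s) absent from the graph and ignored: %s",
            len(unresolved),
            ", ".join(unresolved),
        )

    p0 = np.zeros(len(graph_index))
    mass = 1.0 / len(resolved)
    for nid in resolved:
        p0[graph_index[nid]] = mass
    return SeedSet(requested_ids=requested, resolved_ids=resolved, p0=p0)


def random_walk_restart(
    W: TransitionMatrix, seeds: SeedSet, cfg: RWRConfig | None = None
) -> NodeScoreVector:
    """Iterate the restart walk to its stationary distribution.

    Power iteration from ``p0`` until the L1 difference of successive
    iterates drops below ``cfg.tol`` or ``cfg.max_iter`` is reached.
    Column-stochasticity of ``W`` conserves total mass, so the output
    always sums to 1. Non-convergence is flagged and logged, not fatal.
    """
    cfg = cfg or RWRConfig()
    if seeds.p0.shape[0] != W.n_nodes:
        raise ValueError(
            f"seed vector length {seeds.p0.shape[0]} does not match "
            f"walk index size {W.n_nodes}"
        )
    p = seeds.p0.copy()
    if cfg.r == 1.0:
        # walk degenerates to the restart distribution itself
        return _finish(W, seeds.p0.copy(), iterations=1, converged=True)

    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        p_next = (1.0 - cfg.r) * (W.W @ p) + cfg.r * seeds.p0
        gap = float(np.abs(p_next - p).sum())
        p = p_next
        if gap < cfg.tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "restart walk did not converge in %d iterations (r=%.3g, tol=%.1e)",
            cfg.max_iter,
            cfg.r,
            cfg.tol,
        )
    return _finish(W, p, iterations=iterations, converged=converged)


def _finish(W: TransitionMatrix, p: np.ndarray, iterations: int, converged: bool) -> NodeScoreVector:
    scores = {nid: float(p[idx]) for nid, idx in W.node_index.items()}
    return NodeScoreVector(scores=scores, iterations_used=iterations, converged=converged, raw=p)


_missing_logged: set[str] = set()


def pair_disease_score(scores: NodeScoreVector, gene_a: str, gene_b: str) -> float:
    """Disease-relevance score of a gene pair: mean of the two gene scores.

    ``gene_a``/``gene_b`` accept bare symbols or namespaced ids. A gene
    missing from the walk index contributes 0 (logged once per gene).
    Symmetric in its arguments.
    """
    total = 0.0
    for g in (gene_a, gene_b):
        nid = gene_node(g)
        if nid in scores.scores:
            total += scores.scores[nid]
        elif nid not in _missing_logged:
            _missing_logged.add(nid)
            logger.info("gene %s absent from walk index; scored 0", nid)
    return total / 2.0
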