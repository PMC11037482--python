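"""Heterogeneous knowledge-graph store and transition-matrix preparation.

The disease-relevance propagation runs over a multiplex-heterogeneous
network: typed nodes (genes, phenotype terms, diseases, ...) connected by
undirected edges grouped into named layers (protein interactions,
gene-phenotype annotations, ...). Node identifiers are namespaced by type
(``GENE:BRCA1``, ``HPO:HP:0000118``) so gene symbols can never collide
with ontology ids.

For the walk itself the layers are flattened into a single unweighted
simple graph -- an edge exists between two nodes iff at least one layer
connects them -- and the adjacency matrix is column-normalized. Edge
weights and edge direction in source data are deliberately ignored: the
propagation measures proximity, not directed flow. The layer field is kept
on every edge record for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "HeteroGraph",
    "TransitionMatrix",
    "GraphValidationError",
    "load_graph",
    "remove_node_type",
    "flatten_and_normalize",
]


class GraphValidationError(ValueError):
    """Raised when a graph file or in-memory graph violates the schema."""


@dataclass
class HeteroGraph:
    """Typed, layered, undirected node/edge store.

    Parameters
    ----------
    nodes
        Mapping ``node_id -> node_type``. Ids must be namespaced by type.
    edges
        Undirected edge records ``(source_id, target_id, layer)``. The same
        node pair may appear in several layers (distinct records); within a
        layer duplicates are collapsed on load.
    layer_names
        Declared layer names, in first-seen order.
    """

    nodes: dict[str, str]
    edges: list[tuple[str, str, str]]
    layer_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        offenders = []
        for src, dst, _layer in self.edges:
            if src == dst:
                raise GraphValidationError(f"self-loop edge on node {src!r}")
            if src not in self.nodes:
                offenders.append(src)
            if dst not in self.nodes:
                offenders.append(dst)
        if offenders:
            unique = sorted(set(offenders))
            raise GraphValidationError(
                "edge endpoints missing from node table: " + ", ".join(unique)
            )

    @property
    def node_types(self) -> set[str]:
        return set(self.nodes.values())

    def nodes_of_type(self, node_type: str) -> list[str]:
        return [n for n, t in self.nodes.items() if t == node_type]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"HeteroGraph({len(self.nodes)} nodes, {len(self.edges)} edge records, "
            f"{len(self.layer_names)} layers)"
        )


@dataclass
class TransitionMatrix:
    """Column-stochastic walk matrix over an ordered node index.

    ``W[i, j]`` is the probability of stepping to node ``i`` from node
    ``j``; every column over a retained node sums to 1. Nodes isolated
    after layer flattening are excluded from the index (they can never be
    reached nor left) and listed in ``isolated_nodes``.
    """

    W: sp.csc_matrix
    node_index: dict[str, int]
    isolated_nodes: list[str] = field(default_factory=list)

    @property
    def node_ids(self) -> list[str]:
        """Node ids in column order."""
        return sorted(self.node_index, key=self.node_index.__getitem__)

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.node_index


def _read_tsv(path, expected_cols: tuple[str, ...], what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise GraphValidationError(f"cannot parse {what} file {path}: {exc}") from exc
    missing = [c for c in expected_cols if c not in df.columns]
    if missing:
        raise GraphValidationError(
            f"{what} file {path} lacks required columns {missing}; "
            f"found {list(df.columns)}"
        )
    bad = df[list(expected_cols)].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = [int(i) + 2 for i in df.index[bad][:10]]
        raise GraphValidationError(
            f"{what} file {path}: malformed row(s) with missing fields "
            f"at line(s) {lines}"
        )
    return df


def load_graph(edge_list_path, node_table_path) -> HeteroGraph:
    """Load and validate a heterogeneous graph from TSV exports.

    The node table has columns ``node_id``/``node_type``; the edge list has
    ``source_id``/``target_id``/``layer``. Duplicate edges within a layer
    (either orientation) are collapsed to one record; the same node pair
    listed in several layers yields one record per layer.

    Raises
    ------
    GraphValidationError
        On malformed rows, duplicate node ids, or edges referencing
        undeclared nodes (the offending ids are listed).
    """
    node_df = _read_tsv(node_table_path, ("node_id", "node_type"), "node table")
    edge_df = _read_tsv(edge_list_path, ("source_id", "target_id", "layer"), "edge list")

    dup = node_df["node_id"].duplicated()
    if dup.any():
        raise GraphValidationError(
            "duplicate node ids in node table: "
            + ", ".join(sorted(node_df["node_id"][dup].unique()))
        )
    nodes = dict(zip(node_df["node_id"], node_df["node_type"]))

    seen: set[tuple[str, str, str]] = set()
    edges: list[tuple[str, str, str]] = []
    layer_names: list[str] = []
    for src, dst, layer in edge_df[["source_id", "target_id", "layer"]].itertuples(
        index=False
    ):
        a, b = sorted((src, dst))
        key = (a, b, layer)
        if key in seen:
            continue
        seen.add(key)
        edges.append(key)
        if layer not in layer_names:
            layer_names.append(layer)

    return HeteroGraph(nodes=nodes, edges=edges, layer_names=layer_names)


def convert_knowledge_graph_export(export_dir, edge_list_path, node_table_path):
    """Converter stub for a published knowledge-graph export.

    A real multiplex-heterogeneous knowledge graph (e.g. the BOCK export
    on Zenodo, doi 10.5281/zenodo.7185679) can drop into this package
    once mapped to the two-file schema consumed by :func:`load_graph`:

    * node table -- one row per node, ``node_id`` namespaced by type
      (``GENE:<symbol>``, ``HPO:<HP:id>``, ``DISEASE:<id>``,
      ``OLIGOGENIC:<id>``, ...) and ``node_type`` in lower case;
    * edge list -- one row per (undirected) edge per layer, endpoints as
      namespaced ids and ``layer`` naming the source network (ppi,
      coexpression, gene_hpo, ...). Edge weights and directions in the
      export are dropped: the walk treats the graph as unweighted and
      undirected.

    The mapping depends on the export's own column naming, so this
    function is intentionally left unimplemented; the synthetic graph
    generator provides the same schema for all tests.
    """
    raise NotImplementedError(
        "map the export's node/edge tables to the TSV schema described in "
        "this function's docstring, then load with load_graph()"
    )


def remove_node_type(graph: HeteroGraph, node_type: str) -> HeteroGraph:
    """Drop every node of ``node_type`` and all edges touching one.

    Used to excise the oligogenic-interaction nodes before propagation:
    those nodes encode exactly the associations the prioritizer is meant
    to rediscover, so leaving them in would leak the answer into the walk.
    Removing an absent type is a no-op.
    """
    removed = {n for n, t in graph.nodes.items() if t == node_type}
    if not removed:
        return graph
    nodes = {n: t for n, t in graph.nodes.items() if n not in removed}
    edges = [e for e in graph.edges if e[0] not in removed and e[1] not in removed]
    layer_names = [l for l in graph.layer_names if any(e[2] == l for e in edges)]
    return HeteroGraph(nodes=nodes, edges=edges, layer_names=layer_names)


def flatten_and_normalize(graph: HeteroGraph) -> TransitionMatrix:
    """Flatten layers to a simple unweighted graph and column-normalize.

    Two nodes are adjacent iff at least one layer connects them; multiple
    layers contribute a single unit of degree. Columns of the returned
    matrix each sum to 1 over nodes of degree >= 1; isolated nodes are
    dropped from the index and reported on the result.

    Raises
    ------
    GraphValidationError
        If no edges remain after flattening.
    """
    pairs = sorted({(e[0], e[1]) for e in graph.edges})
    if not pairs:
        raise GraphValidationError("graph has no edges after flattening")

    connected = sorted({n for pair in pairs for n in pair})
    node_index = {n: i for i, n in enumerate(connected)}
    isolated = sorted(set(graph.nodes) - set(connected))

    n = len(connected)
    rows = np.empty(2 * len(pairs), dtype=np.int64)
    cols = np.empty(2 * len(pairs), dtype=np.int64)
    for k, (a, b) in enumerate(pairs):
        ia, ib = node_index[a], node_index[b]
        rows[2 * k], cols[2 * k] = ia, ib
        rows[2 * k + 1], cols[2 * k + 1] = ib, ia
    adj = sp.csc_matrix(
        (np.ones(2 * len(pairs)), (rows, cols)), shape=(n, n), dtype=np.float64
    )
    degree = np.asarray(adj.sum(axis=0)).ravel()
    W = adj @ sp.diags(1.0 / degree)
    return TransitionMatrix(W=sp.csc_matrix(W), node_index=node_index, isolated_nodes=isolated)
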