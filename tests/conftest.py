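"""Shared fixtures: toy graphs, random graphs, and small exome bundles."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from hop.graph_store import HeteroGraph, flatten_and_normalize
from hop.variant_pipeline import Variant


def write_graph_files(tmp_path: Path, nodes, edges, suffix="") -> tuple[Path, Path]:
    """Write node/edge TSVs from (id, type) and (src, dst, layer) tuples."""
    node_path = tmp_path / f"nodes{suffix}.tsv"
    edge_path = tmp_path / f"edges{suffix}.tsv"
    node_path.write_text(
        "node_id\tnode_type\n" + "".join(f"{n}\t{t}\n" for n, t in nodes)
    )
    edge_path.write_text(
        "source_id\ttarget_id\tlayer\n" + "".join(f"{a}\t{b}\t{l}\n" for a, b, l in edges)
    )
    return edge_path, node_path


def random_hetero_graph(rng: np.random.Generator, max_nodes: int = 50) -> HeteroGraph:
    """Random mixed-type graph with at least one edge."""
    n = int(rng.integers(3, max_nodes + 1))
    types = ["gene", "hpo", "disease"]
    nodes = {
        f"{types[i % 3].upper()}:N{i}": types[i % 3] for i in range(n)
    }
    ids = list(nodes)
    edges = set()
    p = float(rng.uniform(0.05, 0.3))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add((ids[i], ids[j], "L1"))
    if not edges:  # guarantee at least one edge
        edges.add((ids[0], ids[1], "L1"))
    return HeteroGraph(nodes=nodes, edges=sorted(edges), layer_names=["L1"])


def make_variant(gene="G1", pos=100, chrom="1", ref="A", alt="T", **kw) -> Variant:
    defaults = dict(zygosity="het", maf=0.001, consequence="missense")
    defaults.update(kw)
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, **defaults)


@pytest.fixture
def triangle_matrix():
    """Column-normalized matrix of the triangle A-B-C."""
    g = HeteroGraph(
        nodes={"GENE:A": "gene", "GENE:B": "gene", "GENE:C": "gene"},
        edges=[
            ("GENE:A", "GENE:B", "L1"),
            ("GENE:A", "GENE:C", "L1"),
            ("GENE:B", "GENE:C", "L1"),
        ],
        layer_names=["L1"],
    )
    return flatten_and_normalize(g)


@pytest.fixture
def two_node_matrix():
    g = HeteroGraph(
        nodes={"GENE:A": "gene", "GENE:B": "gene"},
        edges=[("GENE:A", "GENE:B", "L1")],
        layer_names=["L1"],
    )
    return flatten_and_normalize(g)
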