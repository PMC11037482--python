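"""End-to-end orchestration: filter, combine, score, propagate, fuse, rank.

One call runs the whole prioritization for one patient exome:

1. read the VCF and its annotation sidecar, apply the variant filters;
2. enumerate digenic candidate combinations (<= 2 variants per gene);
3. score each combination's pathogenicity (PS) with the configured scorer;
4. propagate the patient's phenotype/panel seeds through the knowledge
   graph by random walk with restart and score each gene pair (DS);
5. min-max scale PS and DS within the exome, average them, rank.

Defaults reproduce the reference configuration: restart probability 0.3,
mean fusion, MAF <= 3.5% / intronic / synonymous-distance filters, and
removal of oligogenic-interaction nodes from the graph before the walk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from hop.graph_store import HeteroGraph, flatten_and_normalize, load_graph, remove_node_type
from hop.pathogenicity import PathogenicityScorer, surrogate_scorer, table_scorer
from hop.propagation import (
    NodeScoreVector,
    RWRConfig,
    build_seed_vector,
    pair_disease_score,
    random_walk_restart,
)
from hop.ranking import RankingRecord, rank_exome, write_ranking_tsv
from hop.variant_pipeline import (
    FilterConfig,
    apply_variant_filters,
    count_combinations,
    generate_combinations,
    read_annotated_variants,
)

__all__ = ["RunConfig", "run_hop", "prepare_graph", "propagate_seeds"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full configuration of one prioritization run."""

    vcf: Path
    annotation: Path
    edge_list: Path
    node_table: Path
    hpo_ids: list[str] = field(default_factory=list)
    panel_genes: list[str] = field(default_factory=list)
    out_dir: Path = Path(".")
    sample: str | None = None
    scorer: str = "surrogate"  # "surrogate" | "table"
    score_table: Path | None = None
    score_table_mode: str = "strict"
    surrogate_seed: int = 0
    ps_threshold: float | None = None  # optional pre-ranking PS cutoff, off by default
    removed_node_type: str = "oligogenic"
    filters: FilterConfig = field(default_factory=FilterConfig)
    rwr: RWRConfig = field(default_factory=RWRConfig)
    operator: str = "mean"

    def __post_init__(self) -> None:
        if not self.hpo_ids and not self.panel_genes:
            raise ValueError(
                "at least one disease prior is required: HPO terms and/or a gene panel"
            )
        for path, what in (
            (self.vcf, "vcf"),
            (self.annotation, "annotation"),
            (self.edge_list, "edge_list"),
            (self.node_table, "node_table"),
        ):
            if not Path(path).exists():
                raise FileNotFoundError(f"{what} file not found: {path}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "filters" in raw and isinstance(raw["filters"], dict):
            raw["filters"] = FilterConfig(**raw["filters"])
        if "rwr" in raw and isinstance(raw["rwr"], dict):
            raw["rwr"] = RWRConfig(**raw["rwr"])
        return cls(**raw)

    def build_scorer(self) -> PathogenicityScorer:
        if self.scorer == "surrogate":
            return surrogate_scorer(seed=self.surrogate_seed)
        if self.scorer == "table":
            if self.score_table is None:
                raise ValueError("scorer 'table' requires score_table")
            return table_scorer(self.score_table, mode=self.score_table_mode)
        raise ValueError(f"unknown scorer {self.scorer!r}; expected surrogate or table")


def prepare_graph(edge_list, node_table, removed_node_type: str = "oligogenic"):
    """Load the knowledge graph, excise the leak-prone node type, normalize."""
    graph: HeteroGraph = load_graph(edge_list, node_table)
    graph = remove_node_type(graph, removed_node_type)
    return flatten_and_normalize(graph)


def propagate_seeds(
    matrix, hpo_ids, panel_genes, rwr: RWRConfig | None = None
) -> NodeScoreVector:
    """Resolve seeds and run the restart walk; returns the node scores."""
    seeds = build_seed_vector(matrix.node_index, hpo_ids, panel_genes)
    return random_walk_restart(matrix, seeds, rwr or RWRConfig())


def run_hop(
    config: RunConfig,
    scorer: PathogenicityScorer | None = None,
    node_scores: NodeScoreVector | None = None,
) -> tuple[list[RankingRecord], dict]:
    """Execute the full pipeline and write ranking + run report.

    ``scorer`` and ``node_scores`` may be supplied directly (e.g. a scorer
    with benchmark overrides, or a propagation result shared across many
    exomes with identical seeds); otherwise both are built from config.

    Returns the ranked records and the run report. The ranking TSV and a
    JSON report land in ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scorer = scorer or config.build_scorer()

    variants = read_annotated_variants(config.vcf, config.annotation, sample=config.sample)
    kept, filter_report = apply_variant_filters(variants, config.filters)

    if node_scores is None:
        matrix = prepare_graph(config.edge_list, config.node_table, config.removed_node_type)
        node_scores = propagate_seeds(matrix, config.hpo_ids, config.panel_genes, config.rwr)

    pair_ds: dict[tuple[str, str], float] = {}
    scored: list[tuple[str, tuple[str, str], float, float]] = []
    n_thresholded = 0
    for combo in generate_combinations(kept):
        ps = scorer.score(combo)
        if config.ps_threshold is not None and ps < config.ps_threshold:
            n_thresholded += 1
            continue
        pair = combo.gene_pair
        if pair not in pair_ds:
            pair_ds[pair] = pair_disease_score(node_scores, *pair)
        scored.append((combo.combination_id, pair, ps, pair_ds[pair]))

    if not scored:
        raise RuntimeError(
            "ranking stage received no combinations "
            "(fewer than two genes with kept variants, or threshold removed all)"
        )
    records = rank_exome(scored, operator=config.operator)

    report = {
        "filter": filter_report.as_dict(),
        "n_genes_with_variants": len({v.gene for v in kept}),
        "n_combinations": count_combinations(kept),
        "n_ranked": len(records),
        "n_below_ps_threshold": n_thresholded,
        "rwr_iterations": node_scores.iterations_used,
        "rwr_converged": node_scores.converged,
        "scorer": scorer.name,
        "operator": config.operator,
        "restart_probability": config.rwr.r,
    }
    write_ranking_tsv(records, out_dir / "ranking.tsv")
    (out_dir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return records, report
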