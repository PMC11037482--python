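"""Synthetic benchmark fixtures: template exomes, spike-ins, graphs.

Real benchmark material for oligogenic prioritization -- patient exomes
with a known causal digenic combination, and a curated knowledge graph --
cannot ship with a test suite, so this module generates structurally
faithful stand-ins:

* *template exomes*: single-sample VCFs with randomized variants whose
  annotations (MAF, consequence, exon-edge distance) exercise every
  filter rule;
* *spike-ins*: a known pathogenic combination inserted into a template,
  with a truth manifest recording its id and the patient's phenotype
  terms and gene panel;
* *synthetic graphs*: multiplex-heterogeneous networks (gene, HPO and
  disease node types over several layers) with Erdos-Renyi background
  edges plus planted edges connecting chosen disease genes to chosen
  seed nodes, so planted genes sit provably close to the seeds.

The fixtures use a 2-contig artificial genome; coordinates correspond to
no real assembly and no reference FASTA is ever needed. All randomness
flows through explicit seeds and output files are byte-deterministic.
These fixtures emulate the *shape* of real data, not its biology: no
linkage disequilibrium, no ancestry structure, no realistic gene length
or network degree distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hop.propagation import gene_node, hpo_node
from hop.variant_pipeline import (
    ANNOTATION_COLUMNS,
    DigenicCombination,
    FilterConfig,
    Variant,
    apply_variant_filters,
)

__all__ = [
    "SpikeInSpec",
    "SyntheticGraphSpec",
    "generate_template_exome",
    "insert_combination",
    "generate_synthetic_graph",
]

CONTIGS = ("1", "2")
CONTIG_LENGTH = 50_000_000

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##source=hop-synthetic-fixtures\n"
    + "".join(f"##contig=<ID={c},length={CONTIG_LENGTH}>\n" for c in CONTIGS)
    + '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE1\n"
)

_BASES = ("A", "C", "G", "T")


@dataclass
class SpikeInSpec:
    """Recipe for inserting a known causal combination into a template.

    The inserted variants must pass the default variant filters --
    otherwise the truth combination could never appear in the candidate
    stream and the benchmark would be unwinnable by construction.
    """

    template_vcf: Path
    template_annotation: Path
    combination: DigenicCombination
    patient_hpo: list[str] = field(default_factory=list)
    patient_panel: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        kept, _ = apply_variant_filters(list(self.combination.variants), FilterConfig())
        dropped = set(self.combination.variants) - set(kept)
        if dropped:
            raise ValueError(
                "inserted variant(s) would be removed by the default filters: "
                + ", ".join(v.variant_id for v in sorted(dropped))
            )


@dataclass
class SyntheticGraphSpec:
    """Recipe for a multiplex-heterogeneous graph with a planted module.

    Background edges are Erdos-Renyi per layer; every planted gene is
    additionally connected to every planted seed id, so the planted
    module is adjacent to the seeds regardless of the background draw.
    """

    n_genes: int = 60
    n_hpo: int = 30
    n_disease: int = 10
    background_edge_prob: float = 0.05
    planted_genes: list[str] = field(default_factory=list)
    planted_seed_ids: list[str] = field(default_factory=list)
    layers: tuple[str, ...] = ("ppi", "gene_hpo", "gene_disease")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_hpo, self.n_disease) < 1:
            raise ValueError("node counts must be positive")
        if not 0.0 <= self.background_edge_prob <= 1.0:
            raise ValueError("background_edge_prob must be in [0, 1]")

    def gene_symbols(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    def hpo_terms(self) -> list[str]:
        return [f"HP:{9000000 + i:07d}" for i in range(1, self.n_hpo + 1)]

    def disease_ids(self) -> list[str]:
        return [f"D{i:04d}" for i in range(1, self.n_disease + 1)]


def _format_record(chrom: str, pos: int, ref: str, alt: str, gt: str) -> str:
    return f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n"


def _maf_field(maf: float | None) -> str:
    return "" if maf is None else f"{maf:.6g}"


def _dist_field(dist: int | None) -> str:
    return "" if dist is None else str(dist)


def _write_annotation(rows: list[dict], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for row in rows:
            fh.write(
                "\t".join(str(row[c]) for c in ANNOTATION_COLUMNS) + "\n"
            )


def generate_template_exome(
    n_variants: int,
    genes: list[str],
    rng_seed: int,
    out_vcf,
    out_annotation,
) -> None:
    """Write a deterministic single-sample template VCF + annotation TSV.

    Variants are placed at unique positions on the artificial contigs
    and assigned a gene, consequence class, MAF (occasionally missing,
    sometimes common enough to be filtered), zygosity and exon-edge
    distance, so downstream filters have genuine work on every template.
    Byte-identical output for identical arguments.
    """
    if n_variants < 0:
        raise ValueError("n_variants must be >= 0")
    rng = np.random.default_rng(rng_seed)
    records: list[tuple[str, int, str, str, str]] = []
    ann_rows: list[dict] = []
    if n_variants:
        if not genes:
            raise ValueError("need at least one gene symbol")
        positions = rng.choice(CONTIG_LENGTH - 1, size=n_variants, replace=False) + 1
        chroms = rng.choice(len(CONTIGS), size=n_variants)
        for pos, ci in zip(positions, chroms):
            chrom = CONTIGS[int(ci)]
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            gt = "1/1" if rng.random() < 0.2 else "0/1"
            gene = genes[int(rng.integers(len(genes)))]
            consequence = str(
                rng.choice(
                    ["missense", "synonymous", "intronic", "other"],
                    p=[0.45, 0.25, 0.15, 0.15],
                )
            )
            maf = None if rng.random() < 0.1 else float(
                np.round(10 ** rng.uniform(-5, -0.31), 6)
            )
            if consequence == "synonymous":
                dist = int(rng.integers(0, 400))
            elif consequence == "intronic":
                dist = int(rng.integers(200, 5000))
            else:
                dist = None if rng.random() < 0.3 else int(rng.integers(0, 150))
            records.append((chrom, int(pos), str(ref), str(alt), gt))
            ann_rows.append(
                {
                    "chrom": chrom,
                    "pos": int(pos),
                    "ref": str(ref),
                    "alt": str(alt),
                    "gene": gene,
                    "consequence": consequence,
                    "maf": _maf_field(maf),
                    "exon_edge_distance": _dist_field(dist),
                }
            )

    order = sorted(range(len(records)), key=lambda i: (records[i][0], records[i][1]))
    with open(out_vcf, "w") as fh:
        fh.write(VCF_HEADER)
        for i in order:
            fh.write(_format_record(*records[i]))
    _write_annotation([ann_rows[i] for i in order], Path(out_annotation))


def insert_combination(
    spec: SpikeInSpec,
    out_vcf,
    out_annotation,
    manifest_path=None,
) -> dict:
    """Spike the truth combination into a template exome.

    The output VCF contains the template records plus one record per
    inserted variant (genotype 0/1 for het, 1/1 for hom), position
    sorted; the annotation TSV gains matching rows. If an inserted
    position already carries a variant in the template, the template
    record is replaced (logged via the returned manifest's
    ``overwritten`` list). The manifest -- also written to
    ``manifest_path`` as JSON when given -- records the truth
    combination id and the patient's phenotype/panel priors.
    """
    template_lines = Path(spec.template_vcf).read_text().splitlines(keepends=True)
    header = [l for l in template_lines if l.startswith("#")]
    if not any(l.startswith("##fileformat=VCF") for l in header):
        raise ValueError(f"{spec.template_vcf} is not a VCF (no ##fileformat header)")
    body = [l for l in template_lines if not l.startswith("#")]

    inserted_keys = {(v.chrom, v.pos) for v in spec.combination.variants}
    overwritten: list[str] = []
    kept_body = []
    for line in body:
        chrom, pos = line.split("\t", 2)[:2]
        if (chrom, int(pos)) in inserted_keys:
            overwritten.append(f"{chrom}:{pos}")
        else:
            kept_body.append(line)

    for v in spec.combination.variants:
        gt = "1/1" if v.zygosity == "hom" else "0/1"
        kept_body.append(_format_record(v.chrom, v.pos, v.ref, v.alt, gt))
    kept_body.sort(key=lambda l: (l.split("\t", 2)[0], int(l.split("\t", 2)[1])))

    with open(out_vcf, "w") as fh:
        fh.writelines(header)
        fh.writelines(kept_body)

    ann_text = Path(spec.template_annotation).read_text().splitlines(keepends=True)
    with open(out_annotation, "w") as fh:
        fh.writelines(ann_text)
        for v in sorted(spec.combination.variants):
            fh.write(
                "\t".join(
                    (
                        v.chrom,
                        str(v.pos),
                        v.ref,
                        v.alt,
                        v.gene,
                        v.consequence,
                        _maf_field(v.maf),
                        _dist_field(v.exon_edge_distance),
                    )
                )
                + "\n"
            )

    manifest = {
        "truth_combination_id": spec.combination.combination_id,
        "truth_gene_pair": list(spec.combination.gene_pair),
        "patient_hpo": list(spec.patient_hpo),
        "patient_panel": list(spec.patient_panel),
        "overwritten": overwritten,
    }
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def generate_synthetic_graph(
    spec: SyntheticGraphSpec, edge_path, node_path
) -> None:
    """Write a synthetic multiplex-heterogeneous graph as TSV exports.

    Layers: ``ppi`` (gene-gene), ``gene_hpo`` (gene-HPO) and
    ``gene_disease`` (gene-disease), each with independent Erdos-Renyi
    background at ``background_edge_prob``. Planted gene-seed edges are
    added to the type-appropriate layer. Deterministic given
    ``rng_seed``; output loads cleanly through the graph store.
    """
    rng = np.random.default_rng(spec.rng_seed)
    genes = [gene_node(g) for g in spec.gene_symbols()]
    hpos = [hpo_node(h) for h in spec.hpo_terms()]
    diseases = [f"DISEASE:{d}" for d in spec.disease_ids()]

    edges: set[tuple[str, str, str]] = set()

    def er_bipartite(left: list[str], right: list[str], layer: str) -> None:
        mask = rng.random((len(left), len(right))) < spec.background_edge_prob
        for i, j in zip(*np.nonzero(mask)):
            a, b = sorted((left[int(i)], right[int(j)]))
            edges.add((a, b, layer))

    # gene-gene upper triangle
    mask = rng.random((len(genes), len(genes))) < spec.background_edge_prob
    for i, j in zip(*np.nonzero(np.triu(mask, k=1))):
        a, b = sorted((genes[int(i)], genes[int(j)]))
        edges.add((a, b, "ppi"))
    er_bipartite(genes, hpos, "gene_hpo")
    er_bipartite(genes, diseases, "gene_disease")

    for g in spec.planted_genes:
        gid = gene_node(g)
        for seed in spec.planted_seed_ids:
            if seed.startswith("HP:") or seed.startswith("HPO:"):
                sid, layer = hpo_node(seed), "gene_hpo"
            else:
                sid, layer = gene_node(seed), "ppi"
            if gid == sid:
                continue
            a, b = sorted((gid, sid))
            edges.add((a, b, layer))

    nodes = (
        [(g, "gene") for g in genes]
        + [(h, "hpo") for h in hpos]
        + [(d, "disease") for d in diseases]
    )
    with open(node_path, "w") as fh:
        fh.write("node_id\tnode_type\n")
        for nid, ntype in nodes:
            fh.write(f"{nid}\t{ntype}\n")
    with open(edge_path, "w") as fh:
        fh.write("source_id\ttarget_id\tlayer\n")
        for a, b, layer in sorted(edges):
            fh.write(f"{a}\t{b}\t{layer}\n")
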