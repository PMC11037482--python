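"""Exome ingestion, variant filtering and digenic-combination enumeration.

The pipeline consumes a single-sample VCF plus a sidecar annotation TSV
(gene symbol, consequence class, minor allele frequency, distance to the
nearest exon edge, VEP-style, keyed by chrom/pos/ref/alt). Variants are
filtered on frequency and position -- the profile of variants reported as
causal in curated oligogenic cases: common variants (MAF > 3.5%) are
removed, as are intronic variants and synonymous variants lying more than
195 nt from an exon edge. Candidate units are then all variant
combinations across two genes with at most two variants per gene.

Combination counts explode quadratically with exome size (real exomes
reach tens of millions), so enumeration is streaming and the closed-form
count is available for capacity planning: a gene with n kept variants
contributes f(n) = n + n(n-1)/2 variant subsets of size 1-2, and the
total is the sum of f(n_A) * f(n_B) over unordered gene pairs.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterator

import pandas as pd

__all__ = [
    "Variant",
    "FilterConfig",
    "FilterReport",
    "DigenicCombination",
    "read_annotated_variants",
    "apply_variant_filters",
    "generate_combinations",
    "count_combinations",
    "subset_count",
]

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "maf",
    "exon_edge_distance",
)


@dataclass(frozen=True, order=True)
class Variant:
    """One filtered exome variant assigned to a single gene.

    Coordinates are 1-based VCF coordinates; multi-allelic records are
    decomposed to one Variant per ALT, and a record annotated to several
    genes yields one Variant per gene. ``maf`` and ``exon_edge_distance``
    may be None when the annotation source has no value.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    zygosity: str  # "het" | "hom"
    maf: float | None = None
    consequence: str = "other"
    exon_edge_distance: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"1-based position must be >= 1, got {self.pos}")
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"MAF must be in [0, 1], got {self.maf}")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"zygosity must be het or hom, got {self.zygosity!r}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class FilterConfig:
    """Frequency/position filter thresholds.

    Defaults reproduce the curated-oligogenic-variant profile: keep
    MAF <= 3.5%, drop intronic variants, drop synonymous variants more
    than 195 nt from the nearest exon edge.
    """

    maf_max: float = 0.035
    synonymous_max_exon_distance: int = 195
    drop_intronic: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_max < 1.0:
            raise ValueError(f"maf_max must be in (0, 1), got {self.maf_max}")
        if self.synonymous_max_exon_distance < 0:
            raise ValueError("synonymous_max_exon_distance must be >= 0")


@dataclass
class FilterReport:
    """Removal counts per rule plus input/output totals."""

    n_input: int = 0
    n_kept: int = 0
    removed: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "removed_maf": self.removed.get("maf", 0),
            "removed_intronic": self.removed.get("intronic", 0),
            "removed_synonymous_distance": self.removed.get("synonymous_distance", 0),
        }


@dataclass(frozen=True)
class DigenicCombination:
    """Unordered gene pair carrying 1-2 variants per gene.

    The canonical ``combination_id`` sorts the genes lexicographically and
    the variant ids within each gene, so the same combination always gets
    the same id regardless of construction order.
    """

    gene_pair: tuple[str, str]
    variants_a: tuple[Variant, ...]
    variants_b: tuple[Variant, ...]

    def __post_init__(self) -> None:
        a, b = self.gene_pair
        if a == b:
            raise ValueError(f"gene pair must span two genes, got {a!r} twice")
        if a > b:
            object.__setattr__(self, "gene_pair", (b, a))
            va, vb = self.variants_b, self.variants_a
            object.__setattr__(self, "variants_a", va)
            object.__setattr__(self, "variants_b", vb)
        object.__setattr__(
            self, "variants_a", tuple(sorted(set(self.variants_a)))
        )
        object.__setattr__(
            self, "variants_b", tuple(sorted(set(self.variants_b)))
        )
        for variants, gene in ((self.variants_a, self.gene_pair[0]), (self.variants_b, self.gene_pair[1])):
            if not 1 <= len(variants) <= 2:
                raise ValueError(
                    f"each gene carries 1-2 variants, got {len(variants)} for {gene}"
                )
            if any(v.gene != gene for v in variants):
                raise ValueError(f"variant assigned to wrong gene side for {gene}")

    @property
    def combination_id(self) -> str:
        va = "+".join(v.variant_id for v in self.variants_a)
        vb = "+".join(v.variant_id for v in self.variants_b)
        a, b = self.gene_pair
        return f"{a}({va})|{b}({vb})"

    @property
    def variants(self) -> tuple[Variant, ...]:
        return self.variants_a + self.variants_b


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s in ("", ".", "NA", "nan"):
        return None
    return float(s)


def read_annotated_variants(
    vcf_path, annotation_path, sample: str | None = None
) -> list[Variant]:
    """Read a VCF and join the sidecar annotation into Variant records.

    One Variant is produced per (record, ALT allele, annotated gene).
    Zygosity comes from the selected sample's genotype (het for 0/1-style
    calls, hom for 1/1; hemizygous calls are treated as hom). Records with
    no matching annotation row are dropped and counted in a single warning.

    Raises
    ------
    ValueError
        For a multi-sample VCF without ``sample``, an unknown sample name,
        or a missing/malformed annotation file.
    """
    from cyvcf2 import VCF

    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation file {annotation_path} lacks columns {missing}")
    ann_by_key: dict[tuple, list[dict]] = defaultdict(list)
    for row in ann.to_dict("records"):
        key = (str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])
        ann_by_key[key].append(row)

    vcf = VCF(str(vcf_path))
    samples = vcf.samples
    if sample is None:
        if len(samples) != 1:
            raise ValueError(
                f"VCF has {len(samples)} samples; select one with sample="
            )
        sample_idx = 0
    else:
        if sample not in samples:
            raise ValueError(f"sample {sample!r} not in VCF samples {samples}")
        sample_idx = samples.index(sample)

    variants: list[Variant] = []
    n_unannotated = 0
    for record in vcf:
        gt = record.genotypes[sample_idx]
        alleles = [a for a in gt[:-1] if a is not None and a >= 0]
        for alt_idx, alt in enumerate(record.ALT, start=1):
            calls = [a for a in alleles if a == alt_idx]
            if not calls:
                continue  # ALT not carried by this sample
            # all called alleles are this ALT => hom; covers 1/1 and
            # hemizygous single-allele calls, which are treated as hom
            zygosity = "hom" if len(calls) == len(alleles) else "het"
            key = (str(record.CHROM), int(record.POS), record.REF, alt)
            rows = ann_by_key.get(key)
            if not rows:
                n_unannotated += 1
                continue
            for row in rows:
                dist = _parse_optional_float(row["exon_edge_distance"])
                variants.append(
                    Variant(
                        chrom=str(record.CHROM),
                        pos=int(record.POS),
                        ref=record.REF,
                        alt=alt,
                        gene=row["gene"],
                        zygosity=zygosity,
                        maf=_parse_optional_float(row["maf"]),
                        consequence=row["consequence"],
                        exon_edge_distance=None if dist is None else int(dist),
                    )
                )
    if n_unannotated:
        logger.warning("%d VCF allele(s) had no annotation row and were dropped", n_unannotated)
    return variants


def _removal_rule(v: Variant, cfg: FilterConfig) -> str | None:
    """First matching removal rule, or None if the variant is kept.

    Missing MAF is treated as rare (kept); missing exon-edge distance on a
    synonymous variant is likewise kept for lack of evidence.
    """
    if v.maf is not None and v.maf > cfg.maf_max:
        return "maf"
    if cfg.drop_intronic and v.consequence == "intronic":
        return "intronic"
    if (
        v.consequence == "synonymous"
        and v.exon_edge_distance is not None
        and v.exon_edge_distance > cfg.synonymous_max_exon_distance
    ):
        return "synonymous_distance"
    return None


def apply_variant_filters(
    variants: list[Variant], cfg: FilterConfig | None = None
) -> tuple[list[Variant], FilterReport]:
    """Apply frequency/position filters; return kept variants and counts.

    A variant is removed iff MAF > ``maf_max``, or it is intronic, or it
    is synonymous and further than ``synonymous_max_exon_distance`` nt
    from an exon edge. A variant violating several rules is counted once,
    under the first rule in the order MAF, intronic, synonymous-distance.
    """
    cfg = cfg or FilterConfig()
    report = FilterReport(n_input=len(variants))
    kept: list[Variant] = []
    for v in variants:
        rule = _removal_rule(v, cfg)
        if rule is None:
            kept.append(v)
        else:
            report.removed[rule] += 1
    report.n_kept = len(kept)
    return kept, report


def _gene_subsets(variants: list[Variant]) -> list[tuple[Variant, ...]]:
    """All subsets of size 1-2, in deterministic sorted order."""
    ordered = sorted(set(variants))
    subsets: list[tuple[Variant, ...]] = [(v,) for v in ordered]
    subsets.extend(itertools.combinations(ordered, 2))
    return subsets


def generate_combinations(kept: list[Variant]) -> Iterator[DigenicCombination]:
    """Stream every digenic combination over the kept variants.

    For each unordered gene pair (lexicographic order) every cross product
    of the two genes' variant subsets of size 1-2 is emitted, ordered
    deterministically. Memory is bounded by the largest per-gene variant
    set, not by the total combination count.
    """
    by_gene: dict[str, list[Variant]] = defaultdict(list)
    for v in kept:
        by_gene[v.gene].append(v)
    genes = sorted(by_gene)
    if len(genes) < 2:
        logger.warning("fewer than 2 genes with kept variants; no combinations")
        return
    for gene_a, gene_b in itertools.combinations(genes, 2):
        subsets_a = _gene_subsets(by_gene[gene_a])
        subsets_b = _gene_subsets(by_gene[gene_b])
        for va in subsets_a:
            for vb in subsets_b:
                yield DigenicCombination(
                    gene_pair=(gene_a, gene_b), variants_a=va, variants_b=vb
                )


def subset_count(n: int) -> int:
    """Number of variant subsets of size 1-2 from n variants: n + n(n-1)/2."""
    return n + n * (n - 1) // 2


def count_combinations(kept: list[Variant]) -> int:
    """Closed-form combination count, equal to the stream length."""
    per_gene = Counter()
    for v in set(kept):
        per_gene[v.gene] += 1
    counts = [subset_count(n) for n in per_gene.values()]
    total = 0
    for i, fa in enumerate(counts):
        for fb in counts[i + 1 :]:
            total += fa * fb
    return total
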