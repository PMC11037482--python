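"""VCF ingestion, filter rules and combination enumeration."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hop.variant_pipeline import (
    DigenicCombination,
    FilterConfig,
    apply_variant_filters,
    count_combinations,
    generate_combinations,
    read_annotated_variants,
    subset_count,
)

from conftest import make_variant

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1
1\t200\t.\tC\tG\t.\tPASS\t.\tGT\t1/1
1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t0/1
1\t400\t.\tT\tC\t.\tPASS\t.\tGT\t0/1
"""

ANN_TEXT = """\
chrom\tpos\tref\talt\tgene\tconsequence\tmaf\texon_edge_distance
1\t100\tA\tT\tG1\tmissense\t0.001\t10
1\t200\tC\tG\tG2\tmissense\t0.002\t
1\t300\tG\tA\tG3\tsynonymous\t\t50
1\t300\tG\tA\tG4\tmissense\t0.003\t5
"""


@pytest.fixture
def exome_files(tmp_path):
    vcf = tmp_path / "s.vcf"
    ann = tmp_path / "s.tsv"
    vcf.write_text(VCF_TEXT)
    ann.write_text(ANN_TEXT)
    return vcf, ann


class TestReadAnnotatedVariants:
    def test_join_zygosity_and_per_gene_expansion(self, exome_files):
        variants = read_annotated_variants(*exome_files)
        by_id = {}
        for v in variants:
            by_id.setdefault(v.variant_id, []).append(v)
        assert by_id["1:100:A:T"][0].zygosity == "het"
        assert by_id["1:200:C:G"][0].zygosity == "hom"
        # record at pos 300 annotated to two genes -> two Variants
        assert {v.gene for v in by_id["1:300:G:A"]} == {"G3", "G4"}
        # pos 400 has no annotation row -> dropped
        assert "1:400:T:C" not in by_id

    def test_missing_fields_parsed_as_none(self, exome_files):
        variants = read_annotated_variants(*exome_files)
        v200 = next(v for v in variants if v.pos == 200)
        v300 = next(v for v in variants if v.pos == 300 and v.gene == "G3")
        assert v200.exon_edge_distance is None
        assert v300.maf is None

    def test_multisample_requires_selector(self, tmp_path, exome_files):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            VCF_TEXT.replace("\tS1\n", "\tS1\tS2\n").replace(
                "\tGT\t0/1", "\tGT\t0/1\t0/0"
            ).replace("\tGT\t1/1", "\tGT\t1/1\t0/0")
        )
        with pytest.raises(ValueError, match="sample"):
            read_annotated_variants(vcf, exome_files[1])
        variants = read_annotated_variants(vcf, exome_files[1], sample="S1")
        assert variants


class TestFilters:
    @pytest.mark.parametrize(
        ("variant", "removed_by"),
        [
            (make_variant(maf=0.05), "maf"),
            (make_variant(maf=0.036), "maf"),
            (make_variant(maf=0.035), None),  # boundary: kept at exactly 3.5%
            (make_variant(maf=0.001, consequence="intronic"), "intronic"),
            (
                make_variant(consequence="synonymous", exon_edge_distance=200),
                "synonymous_distance",
            ),
            (make_variant(consequence="synonymous", exon_edge_distance=195), None),
            (make_variant(consequence="synonymous", exon_edge_distance=150), None),
            (make_variant(maf=None), None),  # missing MAF treated as rare
            (make_variant(consequence="synonymous", exon_edge_distance=None), None),
        ],
    )
    def test_single_variant_rules(self, variant, removed_by):
        kept, report = apply_variant_filters([variant], FilterConfig())
        if removed_by is None:
            assert kept == [variant]
        else:
            assert kept == []
            assert report.removed[removed_by] == 1

    def test_report_totals(self):
        variants = [
            make_variant(pos=1, maf=0.5),
            make_variant(pos=2, consequence="intronic"),
            make_variant(pos=3),
        ]
        kept, report = apply_variant_filters(variants)
        assert report.n_input == 3 and report.n_kept == 1
        assert report.as_dict()["removed_maf"] == 1

    def test_idempotent_and_order_independent(self):
        variants = [
            make_variant(pos=p, maf=m, consequence=c)
            for p, m, c in [
                (1, 0.5, "missense"), (2, 0.001, "intronic"),
                (3, 0.01, "missense"), (4, None, "synonymous"),
            ]
        ]
        kept1, _ = apply_variant_filters(variants)
        kept2, _ = apply_variant_filters(kept1)
        assert kept1 == kept2
        kept_rev, _ = apply_variant_filters(variants[::-1])
        assert set(kept_rev) == set(kept1)


def brute_force_combinations(variants):
    """Oracle: exhaustive subset enumeration per gene pair."""
    by_gene = {}
    for v in set(variants):
        by_gene.setdefault(v.gene, []).append(v)
    combos = set()
    for ga, gb in itertools.combinations(sorted(by_gene), 2):
        subsets_a = [
            s for r in (1, 2) for s in itertools.combinations(sorted(by_gene[ga]), r)
        ]
        subsets_b = [
            s for r in (1, 2) for s in itertools.combinations(sorted(by_gene[gb]), r)
        ]
        for sa in subsets_a:
            for sb in subsets_b:
                combos.add(
                    DigenicCombination(
                        gene_pair=(ga, gb), variants_a=sa, variants_b=sb
                    ).combination_id
                )
    return combos


class TestCombinations:
    def test_one_variant_each_one_combination(self):
        variants = [make_variant(gene="A", pos=1), make_variant(gene="B", pos=2)]
        combos = list(generate_combinations(variants))
        assert len(combos) == 1 == count_combinations(variants)

    def test_two_by_three_gives_eighteen(self):
        variants = [make_variant(gene="A", pos=p) for p in (1, 2)] + [
            make_variant(gene="B", pos=p) for p in (3, 4, 5)
        ]
        combos = list(generate_combinations(variants))
        assert len(combos) == 18 == count_combinations(variants)
        assert len(brute_force_combinations(variants)) == 18

    def test_three_singleton_genes_three_pairs(self):
        variants = [make_variant(gene=g, pos=p) for g, p in [("A", 1), ("B", 2), ("C", 3)]]
        combos = list(generate_combinations(variants))
        assert len(combos) == 3
        assert {c.gene_pair for c in combos} == {("A", "B"), ("A", "C"), ("B", "C")}

    def test_fewer_than_two_genes_empty(self):
        assert list(generate_combinations([make_variant(gene="A")])) == []
        assert count_combinations([]) == 0

    def test_combination_id_order_invariant(self):
        va = make_variant(gene="A", pos=1)
        vb = make_variant(gene="B", pos=2)
        c1 = DigenicCombination(("A", "B"), (va,), (vb,))
        c2 = DigenicCombination(("B", "A"), (vb,), (va,))
        assert c1.combination_id == c2.combination_id

    def test_at_most_two_variants_per_gene_enforced(self):
        vs = tuple(make_variant(gene="A", pos=p) for p in (1, 2, 3))
        with pytest.raises(ValueError, match="1-2 variants"):
            DigenicCombination(("A", "B"), vs, (make_variant(gene="B", pos=9),))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 6), min_size=0, max_size=6),
    )
    def test_stream_matches_closed_form_and_brute_force(self, counts):
        variants = [
            make_variant(gene=f"G{gi}", pos=100 * gi + k + 1)
            for gi, n in enumerate(counts)
            for k in range(n)
        ]
        stream = [c.combination_id for c in generate_combinations(variants)]
        assert len(stream) == count_combinations(variants)
        assert len(stream) == len(set(stream))  # no repeated ids
        assert set(stream) == brute_force_combinations(variants)
        # emission order is deterministic
        again = [c.combination_id for c in generate_combinations(variants)]
        assert stream == again

    @pytest.mark.parametrize(("n", "expected"), [(0, 0), (1, 1), (2, 3), (3, 6), (6, 21)])
    def test_subset_count_closed_form(self, n, expected):
        assert subset_count(n) == expected
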