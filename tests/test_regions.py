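"""Interval selection, merging, and gene-relative classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hervtriage.regions import (
    CPGRecord,
    GenomicInterval,
    SchemaError,
    classify_relation,
    filter_de_cpgs,
    merge_regions,
    select_near,
)


def iv(start, end, chrom="chr1", strand="."):
    return GenomicInterval(chrom, start, end, strand)


def make_gene(symbol, start, end, strand="+", exons=None):
    body = GenomicInterval("chr1", start, end, strand)
    exons = exons or [GenomicInterval("chr1", start, start + 10, strand)]
    return CPGRecord(symbol, body, exons, log2_fold_change=2.0, adjusted_p=0.01)


class TestGenomicInterval:
    def test_rejects_malformed(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)

    @pytest.mark.parametrize(
        "a,b,gap",
        [
            ((0, 10), (20, 30), 10),
            ((0, 10), (10, 20), 0),   # bookended: zero gap, no overlap
            ((0, 10), (5, 15), 0),
            ((20, 30), (0, 10), 10),  # symmetric
        ],
    )
    def test_gap(self, a, b, gap):
        assert iv(*a).gap(iv(*b)) == gap

    def test_gap_cross_chromosome_undefined(self):
        assert iv(0, 10).gap(iv(0, 10, chrom="chr2")) is None


class TestFilterDeCpgs:
    @pytest.mark.parametrize(
        "log2fc,p,kept",
        [
            (1.2, 0.01, True),    # both strict inequalities hold
            (-1.5, 0.04, True),   # absolute-value symmetry
            (1.0, 0.001, False),  # boundary: strict >
            (2.0, 0.05, False),   # boundary: strict <
            (0.5, 0.001, False),
        ],
    )
    def test_cutoffs(self, log2fc, p, kept):
        table = pd.DataFrame(
            {"gene": ["G1"], "log2_fold_change": [log2fc], "adjusted_p": [p]}
        )
        assert (len(filter_de_cpgs(table)) == 1) is kept

    def test_order_preserved_and_duplicates_collapsed(self):
        table = pd.DataFrame(
            {
                "gene": ["B", "A", "B"],
                "log2_fold_change": [2.0, -2.0, 3.0],
                "adjusted_p": [0.01, 0.02, 0.001],
            }
        )
        out = filter_de_cpgs(table)
        assert list(out["gene"]) == ["B", "A"]
        assert out.loc[0, "log2_fold_change"] == 2.0  # first occurrence kept

    def test_missing_column_is_schema_error(self):
        with pytest.raises(SchemaError):
            filter_de_cpgs(pd.DataFrame({"gene": ["G"], "adjusted_p": [0.1]}))


class TestSelectNear:
    def test_radius_boundary_inclusive(self):
        gene = make_gene("G1", 22_000, 30_000)
        selected = select_near([(iv(1_000, 2_000), "MSTA", "soloLTR")], [gene])
        assert len(selected) == 1 and selected[0].distance == 20_000

    def test_radius_boundary_plus_one_excluded(self):
        gene = make_gene("G1", 22_001, 30_000)
        assert select_near([(iv(1_000, 2_000), "MSTA", "soloLTR")], [gene]) == []

    def test_nearest_gene_tie_breaks_lexicographically(self):
        g1 = make_gene("ZZZ", 3_000, 4_000)
        g2 = make_gene("AAA", 0, 1_000)
        out = select_near([(iv(1_500, 2_500), "MLT1A", "soloLTR")], [g1, g2])
        assert out[0].gene == "AAA"  # equal 500 bp gaps

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            select_near([], [], radius_bp=-1)

    def test_matches_brute_force_scan(self, rng):
        genes = [
            make_gene(f"G{i}", int(s), int(s) + 5_000)
            for i, s in enumerate(rng.integers(0, 2_000_000, size=10))
        ]
        elements = [
            (iv(int(s), int(s) + 500), "MSTA", "soloLTR")
            for s in rng.integers(0, 2_000_000, size=1000)
        ]
        selected = {
            (a.element.start, a.element.end): a.gene
            for a in select_near(elements, genes, 20_000)
        }
        # brute force: all-pairs gap scan
        expected = {}
        for e, _, _ in elements:
            best = None
            for g in genes:
                gap = max(0, g.body.start - e.end, e.start - g.body.end)
                if gap <= 20_000:
                    key = (gap, g.symbol)
                    if best is None or key < best:
                        best = key
            if best is not None:
                expected[(e.start, e.end)] = best[1]
        assert selected == expected

    def test_radius_zero_selects_exactly_overlaps(self, rng):
        genes = [make_gene("G0", 1_000, 2_000)]
        elements = [
            (iv(int(s), int(s) + 100), "F", "soloLTR")
            for s in rng.integers(0, 3_000, size=200)
        ]
        selected = {a.element.start for a in select_near(elements, genes, 0)}
        expected = {
            e.start for e, _, _ in elements
            if e.start < 2_000 and e.end > 1_000
        }
        assert selected == expected


class TestMergeRegions:
    def test_overlap_chain(self):
        out = merge_regions([iv(0, 10), iv(5, 20), iv(30, 40)])
        assert [(o.start, o.end) for o in out] == [(0, 20), (30, 40)]

    def test_bookended_not_merged(self):
        out = merge_regions([iv(0, 10), iv(10, 20)])
        assert [(o.start, o.end) for o in out] == [(0, 10), (10, 20)]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 40)),
            min_size=0,
            max_size=60,
        )
    )
    def test_position_set_oracle_and_idempotence(self, spans):
        intervals = [iv(s, s + w) for s, w in spans]
        merged = merge_regions(intervals)
        # base-position set equality with a per-position union oracle
        base_in = set()
        for i in intervals:
            base_in.update(range(i.start, i.end))
        base_out = set()
        for m in merged:
            base_out.update(range(m.start, m.end))
        assert base_in == base_out
        # sorted and pairwise disjoint
        for a, b in zip(merged, merged[1:]):
            assert a.end <= b.start
        # idempotent
        again = merge_regions(merged)
        assert [(m.start, m.end) for m in again] == [
            (m.start, m.end) for m in merged
        ]
        # total length shrinks unless inputs pairwise disjoint
        assert sum(len(m) for m in merged) <= sum(len(i) for i in intervals)


class TestClassifyRelation:
    def test_exonic_precedence_one_base_overlap(self):
        gene = make_gene(
            "G", 0, 10_000,
            exons=[GenomicInterval("chr1", 5_000, 5_100, "+")],
        )
        relation, d = classify_relation(iv(4_901, 5_001), gene)
        assert (relation, d) == ("exonic", 0)

    def test_intronic_when_no_exon_touched(self):
        gene = make_gene(
            "G", 0, 10_000, exons=[GenomicInterval("chr1", 0, 100, "+")]
        )
        assert classify_relation(iv(5_000, 5_500), gene)[0] == "intronic"

    @pytest.mark.parametrize(
        "strand,expected", [("+", "downstream"), ("-", "upstream")]
    )
    def test_flank_is_strand_aware(self, strand, expected):
        gene = make_gene("G", 0, 10_000)
        gene.body = GenomicInterval("chr1", 0, 10_000, strand)
        relation, d = classify_relation(iv(15_000, 15_500), gene)
        assert relation == expected and d == 5_000
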