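"""Activity classification: expressed genes, DNA/ssRNA status, aggregation."""

import pytest

from soilvirome.activity import (
    ActivityCall,
    aggregate_by_month,
    call_expressed_genes,
    classify_dna_votu,
    classify_ssrna_votu,
)
from soilvirome.coverage import ReadPlacement, accumulate_coverage
from soilvirome.io import Gene


def _cov(placements, length=1000, contig="c", lib="metaT_s1"):
    reads = [
        ReadPlacement(f"r{i}", contig, s, e, strand, lib)
        for i, (s, e, strand) in enumerate(placements)
    ]
    return accumulate_coverage(reads, {contig: length})


def _gene(start=1, end=300, strand="+", gene_id="g1", category="unknown"):
    return Gene(gene_id=gene_id, contig_id="c", start=start, end=end, strand=strand,
                category=category)


class TestExpressedGenes:
    def test_half_breadth_boundary_expressed(self):
        # 150 of 300 coding positions at 1x: breadth exactly 50%, median via
        # deeper middle coverage stays positive only when > half covered
        cov = _cov([(1, 150, "+"), (1, 151, "+")])
        calls = call_expressed_genes([_gene()], cov, ["metaT_s1"])
        assert calls[0].coding_breadth == pytest.approx(151 / 3)
        cov = _cov([(1, 151, "+"), (1, 151, "+")])
        calls = call_expressed_genes([_gene()], cov, ["metaT_s1"])
        assert calls[0].expressed  # breadth 50.33%, median 2

    def test_breadth_just_below_half_not_expressed(self):
        # 149 of 300 coding positions covered: breadth 49.67% < 50%
        cov = _cov([(1, 149, "+")])
        call = call_expressed_genes([_gene()], cov, ["metaT_s1"])[0]
        assert call.coding_breadth == pytest.approx(149 / 3)
        assert not call.expressed

    def test_median_zero_blocks_expression(self):
        # exactly 50% breadth gives lower-median depth 0 -> not expressed
        cov = _cov([(1, 150, "+")])
        call = call_expressed_genes([_gene()], cov, ["metaT_s1"])[0]
        assert call.coding_breadth == pytest.approx(50.0)
        assert call.coding_median_depth == 0
        assert not call.expressed

    def test_noncoding_strand_coverage_ignored(self):
        cov = _cov([(1, 300, "-")])
        assert not call_expressed_genes([_gene(strand="+")], cov, ["metaT_s1"])[0].expressed

    def test_gene_outside_contig_is_error(self):
        cov = _cov([(1, 100, "+")], length=200)
        with pytest.raises(ValueError):
            call_expressed_genes([_gene(end=500)], cov, ["metaT_s1"])

    def test_missing_library_coverage_gives_null_call(self):
        calls = call_expressed_genes([_gene()], {}, ["metaT_s1"])
        assert not calls[0].expressed


def _expressed_call(gene_id, lib="metaT_s1"):
    from soilvirome.activity import ExpressedGeneCall

    return ExpressedGeneCall(gene_id, lib, coding_breadth=100.0, coding_median_depth=3)


class TestDNAClassification:
    CATS = {"terminase": "encapsidation", "integrase": "lysogeny", "polA": "replication"}

    def _metag(self, breadth_frac):
        n = int(1000 * breadth_frac)
        if n == 0:
            return []
        return list(_cov([(1, n, "+")], lib="metaG_s1").values())

    def test_encapsidation_gene_gives_lytic(self):
        call = classify_dna_votu("v", "s1", self._metag(0.5),
                                 [_expressed_call("terminase")], self.CATS)
        assert call.status == "active-lytic"
        assert call.n_lytic_genes == 1

    def test_lysogeny_gene_gives_active_other(self):
        call = classify_dna_votu("v", "s1", self._metag(0.5),
                                 [_expressed_call("integrase")], self.CATS)
        assert call.status == "active"
        assert call.n_lytic_genes == 0

    def test_no_signal_is_absent(self):
        call = classify_dna_votu("v", "s1", [], [], self.CATS)
        assert call.status == "absent"

    def test_present_without_expression_is_inactive(self):
        call = classify_dna_votu("v", "s1", self._metag(0.5), [], self.CATS)
        assert call.status == "present-inactive"

    def test_presence_needs_10pct_breadth(self):
        assert classify_dna_votu("v", "s1", self._metag(0.05), [], self.CATS).status == "absent"
        assert (
            classify_dna_votu("v", "s1", self._metag(0.15), [], self.CATS).status
            == "present-inactive"
        )

    def test_unknown_category_treated_nonlytic(self):
        call = classify_dna_votu("v", "s1", self._metag(0.5),
                                 [_expressed_call("mystery")], self.CATS)
        assert call.status == "active"


class TestRNAClassification:
    def _cov_rna(self, plus_frac, minus_frac, depth=2, length=1000):
        reads = []
        if plus_frac:
            for d in range(depth):
                reads.append((1, int(length * plus_frac), "+"))
        if minus_frac:
            reads.append((1, int(length * minus_frac), "-"))
        return list(_cov(reads, length=length).values())

    def test_both_strands_covered_is_active(self):
        call = classify_ssrna_votu("v", "s1", self._cov_rna(0.6, 0.55))
        assert call.status == "active"

    def test_coding_only_is_detected(self):
        call = classify_ssrna_votu("v", "s1", self._cov_rna(0.6, 0.10))
        assert call.status == "detected"

    def test_low_coding_breadth_is_absent(self):
        call = classify_ssrna_votu("v", "s1", self._cov_rna(0.4, 0.0))
        assert call.status == "absent"

    def test_antisense_without_coding_is_absent(self):
        call = classify_ssrna_votu("v", "s1", self._cov_rna(0.0, 0.9))
        assert call.status == "absent"

    def test_both_strand_rule_within_single_library(self):
        # coding strand in one sample, antisense in another: never "active"
        cov_a = self._cov_rna(0.9, 0.0)
        cov_b = self._cov_rna(0.0, 0.9)
        call = classify_ssrna_votu("v", "month", cov_a + cov_b)
        assert call.status == "detected"


class TestMonthAggregation:
    def _call(self, unit, status, molecule="DNA"):
        return ActivityCall("v", unit, molecule, status)

    def test_single_active_sample_makes_month_active(self):
        calls = [self._call(f"s{i}", "present-inactive") for i in range(14)]
        calls.append(self._call("s14", "active"))
        months = {f"s{i}": "May" for i in range(15)}
        out = aggregate_by_month(calls, months)
        assert out[0].status == "active"

    def test_absent_everywhere_stays_absent(self):
        calls = [self._call(f"s{i}", "absent") for i in range(3)]
        out = aggregate_by_month(calls, {f"s{i}": "Mar" for i in range(3)})
        assert out[0].status == "absent"

    def test_ordering_present_inactive_beats_absent(self):
        calls = [
            self._call("s0", "present-inactive"),
            self._call("s1", "present-inactive"),
            self._call("s2", "absent"),
        ]
        out = aggregate_by_month(calls, {f"s{i}": "Jun" for i in range(3)})
        assert out[0].status == "present-inactive"

    def test_lytic_dominates(self):
        calls = [self._call("s0", "active"), self._call("s1", "active-lytic")]
        out = aggregate_by_month(calls, {"s0": "Jun", "s1": "Jun"})
        assert out[0].status == "active-lytic"

    def test_sample_without_month_is_error(self):
        with pytest.raises(KeyError):
            aggregate_by_month([self._call("ghost", "active")], {})


def test_adding_placements_never_demotes_status(rng):
    """Monotonicity: extra metatranscriptome reads can only promote a vOTU."""
    from soilvirome.activity import DNA_STATUS_ORDER

    cats = {"g1": "replication", "g2": "lysis"}
    genes = [_gene(1, 300, "+", "g1", "replication"), _gene(401, 700, "+", "g2", "lysis")]
    rank = {s: i for i, s in enumerate(DNA_STATUS_ORDER)}
    reads = []
    last = 0
    for _ in range(30):
        s = int(rng.integers(1, 900))
        reads.append((s, min(s + 149, 1000), "+"))
        cov = _cov(reads)
        metag = list(_cov([(1, 500, "+")], lib="metaG_s1").values())
        calls = call_expressed_genes(genes, cov, ["metaT_s1"])
        status = classify_dna_votu("v", "s1", metag, calls, cats).status
        assert rank[status] >= last
        last = rank[status]
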