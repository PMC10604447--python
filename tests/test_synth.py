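"""Synthetic community generator: determinism, planted structure, contracts."""

import numpy as np
import pytest
from scipy.stats import binom

from soilvirome import synth
from soilvirome.io import write_fasta, write_gff3


class TestGenerateGenomes:
    def test_forced_single_genome(self):
        contigs, genes = synth.generate_genomes(
            1, length_range=(5000, 5000), gene_density=1.0, molecule_mix=0.0, seed=1
        )
        assert len(contigs) == 1
        assert contigs[0].length == 5000
        assert len(genes) == 5

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        for run in ("a", "b"):
            contigs, genes = synth.generate_genomes(10, seed=42)
            write_fasta(contigs, tmp_path / f"{run}.fasta")
            write_gff3(genes, tmp_path / f"{run}.gff3")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_molecule_mix_within_binomial_interval(self):
        contigs, _ = synth.generate_genomes(200, molecule_mix=0.5, seed=7)
        n_rna = sum(c.molecule == "RNA" for c in contigs)
        lo, hi = binom.ppf([0.005, 0.995], 200, 0.5)
        assert lo <= n_rna <= hi

    def test_every_genome_has_a_gene_and_no_overlap(self):
        contigs, genes = synth.generate_genomes(30, length_range=(1000, 8000), seed=3)
        by_contig = {}
        for g in genes:
            by_contig.setdefault(g.contig_id, []).append(g)
        lengths = {c.id: c.length for c in contigs}
        for c in contigs:
            glist = sorted(by_contig[c.id], key=lambda g: g.start)
            assert glist
            for g in glist:
                assert 1 <= g.start <= g.end <= lengths[c.id]
            for g1, g2 in zip(glist, glist[1:]):
                assert g1.end < g2.start  # non-overlapping

    def test_rna_genes_on_coding_strand(self):
        contigs, genes = synth.generate_genomes(40, molecule_mix=1.0, seed=5)
        assert all(g.strand == "+" for g in genes)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n=0),
            dict(n=1, length_range=(500, 5000)),
            dict(n=1, length_range=(5000, 300_000)),
            dict(n=1, molecule_mix=1.5),
            dict(n=1, gene_density=0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            synth.generate_genomes(**kwargs)


class TestPlantTruth:
    def test_seasonal_fraction_and_strategies(self, small_design):
        contigs, genes = synth.generate_genomes(100, molecule_mix=0.0, seed=21)
        truth = synth.plant_truth(contigs, genes, small_design, seasonal_fraction=0.1, seed=22)
        # seasonal vOTUs are active in exactly one month; constitutive ones in
        # all months or none, so the planted count is recoverable exactly
        seasonal = [
            v
            for v, sched in truth.schedule.items()
            if sum(s != "inactive" for s in sched.values()) == 1
        ]
        assert len(seasonal) == 10
        strategies = {truth.host_strategy[v] for v in seasonal}
        assert strategies <= {"winter-adapted", "snowmelt-specialist", "spring-adapted", "none"}
        assert len([v for v in truth.host_strategy.values() if v != "none"]) > 0

    def test_lytic_schedules_have_lytic_expressed_gene(self, small_design):
        contigs, genes = synth.generate_genomes(60, molecule_mix=0.0, seed=23)
        truth = synth.plant_truth(contigs, genes, small_design, seed=24)
        categories = {g.gene_id: g.category for g in genes}
        lytic_set = {"virion-structure", "encapsidation", "lysis"}
        for votu, sched in truth.schedule.items():
            for month, status in sched.items():
                if status == "active-lytic":
                    cats = {categories[g] for g in truth.expressed_genes[(votu, month)]}
                    assert cats & lytic_set
                elif status == "active":
                    cats = {categories[g] for g in truth.expressed_genes[(votu, month)]}
                    assert not (cats & lytic_set)


class TestSimulatePlacements:
    def test_library_sizes_equal_row_counts(self, small_community):
        placements = small_community["placements"]
        libraries = small_community["libraries"]
        per_lib = placements.groupby("library_id").size()
        for row in libraries.itertuples(index=False):
            assert row.total_reads == per_lib.get(row.library_id, 0)

    def test_inactive_votu_has_no_metat_reads(self, small_community):
        truth = small_community["truth"]
        placements = small_community["placements"]
        metat = placements[placements["library_id"].str.startswith("metaT")]
        always_inactive = [
            v
            for v, sched in truth.schedule.items()
            if truth.molecule[v] == "DNA" and all(s == "inactive" for s in sched.values())
        ]
        if always_inactive:
            assert metat[metat["contig_id"].isin(always_inactive)].empty

    def test_detected_ssrna_has_no_minus_reads(self, small_community):
        truth = small_community["truth"]
        placements = small_community["placements"]
        detected_only = [
            v
            for v, sched in truth.schedule.items()
            if truth.molecule[v] == "RNA"
            and "detected" in sched.values()
            and "active" not in sched.values()
        ]
        sub = placements[placements["contig_id"].isin(detected_only)]
        assert (sub["strand"] == "+").all()

    def test_active_ssrna_emits_minus_strand(self, small_community):
        truth = small_community["truth"]
        placements = small_community["placements"]
        active_rna = [
            v
            for v, sched in truth.schedule.items()
            if truth.molecule[v] == "RNA" and "active" in sched.values()
        ]
        if active_rna:
            sub = placements[placements["contig_id"].isin(active_rna)]
            assert (sub["strand"] == "-").any()

    def test_metat_dna_reads_confined_to_expressed_genes(self, small_community):
        truth = small_community["truth"]
        genes = {g.gene_id: g for g in small_community["genes"]}
        placements = small_community["placements"]
        metat = placements[placements["library_id"].str.startswith("metaT")]
        for votu, sched in truth.schedule.items():
            if truth.molecule[votu] != "DNA":
                continue
            for month, status in sched.items():
                if status == "inactive":
                    continue
                lib_mask = metat["library_id"].str.contains(f"metaT_{month}_")
                sub = metat[(metat["contig_id"] == votu) & lib_mask]
                intervals = [
                    (genes[g].start, genes[g].end, genes[g].strand)
                    for g in truth.expressed_genes[(votu, month)]
                ]
                for row in sub.itertuples(index=False):
                    assert any(
                        s <= row.start and row.end <= e and row.strand == st
                        for s, e, st in intervals
                    )

    def test_determinism(self, small_design, small_community):
        contigs, genes, truth = (
            small_community["contigs"],
            small_community["genes"],
            small_community["truth"],
        )
        p1, l1 = synth.simulate_placements(truth, small_design, contigs, genes, seed=99)
        p2, l2 = synth.simulate_placements(truth, small_design, contigs, genes, seed=99)
        assert p1.equals(p2)
        assert l1.equals(l2)

    def test_month_mismatch_is_schema_error(self, small_design, small_community):
        truth = small_community["truth"]
        bad = synth.CommunityDesign(months=("Jan", "Feb"), depths=("d",), locations=("l",),
                                    replicates_per_cell=1)
        with pytest.raises(ValueError, match="months"):
            synth.simulate_placements(truth, bad, small_community["contigs"],
                                      small_community["genes"])


class TestExpressionMatrix:
    def test_shapes_and_seasonal_count(self):
        matrix, meta, seasonal = synth.simulate_expression_matrix(seed=1)
        assert matrix.shape == (200, 48)
        assert len(seasonal) == 10
        assert set(meta["month"]) == {"Mar", "May", "Jun", "Sep"}

    def test_null_mode_has_no_planted_peaks(self):
        matrix, meta, seasonal = synth.simulate_expression_matrix(peak_fold=1.0, seed=2)
        months = meta["month"]
        # planted "seasonal" set is still returned but means are flat
        votu = sorted(seasonal)[0]
        by_month = matrix.loc[votu].groupby(months).mean()
        assert by_month.max() < 4 * by_month.min()
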