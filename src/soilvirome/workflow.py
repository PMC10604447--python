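"""End-to-end drivers connecting coverage, classification and statistics.

These functions operate on in-memory tables (placement DataFrame, library
table, contigs, genes) and are the single code path used by the CLI, the
analysis scripts and the validation experiments.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from soilvirome.activity import (
    ActivityCall,
    aggregate_by_month,
    call_expressed_genes,
    classify_dna_votu,
    classify_ssrna_votu,
)
from soilvirome.catalog import ViralContig
from soilvirome.coverage import StrandCoverage, accumulate_coverage, rpkm_matrix
from soilvirome.io import Gene
from soilvirome.synth import placements_from_frame

__all__ = [
    "coverage_from_frame",
    "mapped_read_counts",
    "abundance_matrices",
    "classify_samples",
    "classify_months",
    "activity_table",
]


def coverage_from_frame(
    placements: pd.DataFrame, contig_lengths: Mapping[str, int]
) -> dict[tuple[str, str], StrandCoverage]:
    return accumulate_coverage(placements_from_frame(placements), contig_lengths)


def mapped_read_counts(placements: pd.DataFrame) -> dict[tuple[str, str], int]:
    counts = placements.groupby(["contig_id", "library_id"]).size()
    return {(c, l): int(n) for (c, l), n in counts.items()}


def abundance_matrices(
    placements: pd.DataFrame,
    library_table: pd.DataFrame,
    contig_lengths: Mapping[str, int],
    breadth_mask: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(metagenome, metatranscriptome) breadth-masked RPKM matrices."""
    coverages = coverage_from_frame(placements, contig_lengths)
    counts = mapped_read_counts(placements)
    matrices = []
    for lib_type in ("metaG", "metaT"):
        libs = library_table.loc[library_table["type"] == lib_type]
        totals = {
            row.library_id: int(row.total_reads)
            for row in libs.itertuples(index=False)
            if row.total_reads > 0
        }
        matrices.append(
            rpkm_matrix(coverages, counts, contig_lengths, totals, breadth_mask=breadth_mask)
        )
    return matrices[0], matrices[1]


def classify_samples(
    placements: pd.DataFrame,
    library_table: pd.DataFrame,
    contigs: Sequence[ViralContig],
    genes: Sequence[Gene],
    presence_breadth: float = 10.0,
) -> list[ActivityCall]:
    """Per-sample activity calls for every vOTU.

    Samples are the pairing of one metagenome and one metatranscriptome
    library with identical (month, depth, location) metadata and matching
    library-id suffix; unpaired libraries form single-library samples.
    """
    lengths = {c.id: c.length for c in contigs}
    coverages = coverage_from_frame(placements, lengths)
    genes_by_contig: dict[str, list[Gene]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig_id, []).append(g)
    categories = {g.gene_id: g.category for g in genes}

    # pair libraries into samples on the shared suffix after the type prefix
    def sample_of(library_id: str) -> str:
        for prefix in ("metaG_", "metaT_"):
            if library_id.startswith(prefix):
                return library_id[len(prefix) :]
        return library_id

    lib_info = library_table.set_index("library_id")
    samples: dict[str, dict[str, list[str]]] = {}
    for lib_id, row in lib_info.iterrows():
        samples.setdefault(sample_of(lib_id), {"metaG": [], "metaT": []})[row["type"]].append(
            lib_id
        )

    calls: list[ActivityCall] = []
    for sample_id, libs in sorted(samples.items()):
        metag_libs = libs["metaG"]
        metat_libs = libs["metaT"]
        for contig in contigs:
            if contig.molecule == "DNA":
                metag_covs = [
                    coverages[(contig.id, lib)]
                    for lib in metag_libs
                    if (contig.id, lib) in coverages
                ]
                gene_calls = call_expressed_genes(
                    genes_by_contig.get(contig.id, []), coverages, metat_libs
                )
                calls.append(
                    classify_dna_votu(
                        contig.id,
                        sample_id,
                        metag_covs,
                        gene_calls,
                        categories,
                        presence_breadth=presence_breadth,
                    )
                )
            else:
                metat_covs = [
                    coverages[(contig.id, lib)]
                    for lib in metat_libs
                    if (contig.id, lib) in coverages
                ]
                calls.append(classify_ssrna_votu(contig.id, sample_id, metat_covs))
    return calls


def classify_months(
    placements: pd.DataFrame,
    library_table: pd.DataFrame,
    contigs: Sequence[ViralContig],
    genes: Sequence[Gene],
    presence_breadth: float = 10.0,
) -> list[ActivityCall]:
    """Sample-level classification aggregated to months (any-active)."""
    calls = classify_samples(placements, library_table, contigs, genes, presence_breadth)
    lib_info = library_table.drop_duplicates("library_id").set_index("library_id")
    sample_to_month = {}
    for lib_id, row in lib_info.iterrows():
        sample = lib_id.split("_", 1)[1] if "_" in lib_id else lib_id
        sample_to_month[sample] = row["month"]
    return aggregate_by_month(calls, sample_to_month)


def activity_table(calls: Sequence[ActivityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "votu_id": c.votu_id,
                "unit": c.unit,
                "molecule": c.molecule,
                "status": c.status,
                "n_expressed_genes": c.n_expressed_genes,
                "n_lytic_genes": c.n_lytic_genes,
            }
            for c in calls
        ]
    )
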