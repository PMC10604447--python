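"""Activity and infection-cycle classification from strand-specific coverage.

DNA vOTUs: a gene counts as *expressed* in a metatranscriptome library when
its coding strand is covered over ≥50% of its positions with a lower-median
depth >0. A vOTU with ≥1 expressed gene is *active*; if any expressed gene
belongs to a lytic functional category (virion structure, encapsidation, or
lysis) the vOTU is *active-lytic*; a vOTU present in metagenomes (breadth
≥10% in ≥1 library of the grouping unit) without expressed genes is
*present-inactive*; otherwise *absent*.

ssRNA vOTUs (genomes are themselves the mRNA-sense strand, so expressed-gene
logic does not apply): *detected* when the coding strand is covered ≥50% at
≥1× with lower-median depth >0; *active* when additionally the antisense
strand — the replication intermediate — is covered ≥50% at ≥1×; otherwise
*absent*.

Sample-level calls aggregate to months under an any-active policy: the month
status is the maximum per-sample status under
absent < present-inactive/detected < active < active-lytic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from soilvirome.coverage import StrandCoverage, breadth, median_depth
from soilvirome.io import Gene

__all__ = [
    "ExpressedGeneCall",
    "ActivityCall",
    "DEFAULT_LYTIC_CATEGORIES",
    "DNA_STATUS_ORDER",
    "RNA_STATUS_ORDER",
    "call_expressed_genes",
    "classify_dna_votu",
    "classify_ssrna_votu",
    "aggregate_by_month",
]

logger = logging.getLogger(__name__)

DEFAULT_LYTIC_CATEGORIES = frozenset({"virion-structure", "encapsidation", "lysis"})

DNA_STATUS_ORDER = ("absent", "present-inactive", "active", "active-lytic")
RNA_STATUS_ORDER = ("absent", "detected", "active")


@dataclass(frozen=True)
class ExpressedGeneCall:
    gene_id: str
    library_id: str
    coding_breadth: float
    coding_median_depth: int

    @property
    def expressed(self) -> bool:
        return self.coding_breadth >= 50.0 and self.coding_median_depth > 0


@dataclass(frozen=True)
class ActivityCall:
    votu_id: str
    unit: str  # sample or month id
    molecule: str  # DNA | RNA
    status: str
    n_expressed_genes: int = 0
    n_lytic_genes: int = 0


def _strand_mode(strand: str) -> str:
    return "plus" if strand == "+" else "minus"


def call_expressed_genes(
    genes: Sequence[Gene],
    coverages: Mapping[tuple[str, str], StrandCoverage],
    metat_libraries: Sequence[str],
) -> list[ExpressedGeneCall]:
    """Evaluate the expressed-gene rule per gene per metatranscriptome library.

    Breadth and lower-median depth are computed on the gene's coding strand
    only, over the gene interval. Genes with no coverage record in a library
    get a (non-expressed) call with breadth 0.
    """
    calls = []
    for gene in genes:
        mode = _strand_mode(gene.strand)
        for lib in metat_libraries:
            cov = coverages.get((gene.contig_id, lib))
            if cov is None:
                calls.append(ExpressedGeneCall(gene.gene_id, lib, 0.0, 0))
                continue
            if gene.end > cov.length:
                raise ValueError(
                    f"gene {gene.gene_id} [{gene.start},{gene.end}] outside contig "
                    f"{gene.contig_id} of length {cov.length}"
                )
            calls.append(
                ExpressedGeneCall(
                    gene_id=gene.gene_id,
                    library_id=lib,
                    coding_breadth=breadth(cov, (gene.start, gene.end), mode),
                    coding_median_depth=median_depth(cov, (gene.start, gene.end), mode),
                )
            )
    return calls


def classify_dna_votu(
    votu_id: str,
    unit: str,
    metag_coverages: Iterable[StrandCoverage],
    expressed_calls: Iterable[ExpressedGeneCall],
    categories: Mapping[str, str],
    lytic_categories: frozenset[str] = DEFAULT_LYTIC_CATEGORIES,
    presence_breadth: float = 10.0,
) -> ActivityCall:
    """Classify one DNA vOTU within one grouping unit (sample or month).

    ``metag_coverages`` are the representative's metagenome coverages over the
    unit's libraries; ``expressed_calls`` the metatranscriptome expressed-gene
    calls for the representative's genes over the unit's libraries (a gene
    expressed in any library of the unit counts).
    """
    expressed = {c.gene_id for c in expressed_calls if c.expressed}
    lytic = set()
    for gene_id in expressed:
        cat = categories.get(gene_id)
        if cat is None:
            logger.warning("gene %s has no category label; treated as non-lytic", gene_id)
        elif cat in lytic_categories:
            lytic.add(gene_id)
    present = any(breadth(cov) >= presence_breadth for cov in metag_coverages)
    if expressed:
        status = "active-lytic" if lytic else "active"
    elif present:
        status = "present-inactive"
    else:
        status = "absent"
    return ActivityCall(votu_id, unit, "DNA", status,
                        n_expressed_genes=len(expressed), n_lytic_genes=len(lytic))


def classify_ssrna_votu(
    votu_id: str,
    unit: str,
    metat_coverages: Iterable[StrandCoverage],
    coding_strand: str = "+",
    breadth_min: float = 50.0,
) -> ActivityCall:
    """Classify one ssRNA vOTU from metatranscriptome strand-split coverage.

    Both-strand detection must hold within a single library (one sequencing
    of one sample); the unit status is the maximum over its libraries.
    The antisense condition is breadth-at-≥1× only — the median-depth clause
    applies to the coding strand.
    """
    anti = "minus" if coding_strand == "+" else "plus"
    coding = "plus" if coding_strand == "+" else "minus"
    best = 0
    for cov in metat_coverages:
        coding_ok = (
            breadth(cov, strand_mode=coding) >= breadth_min
            and median_depth(cov, strand_mode=coding) > 0
        )
        if not coding_ok:
            continue
        if breadth(cov, strand_mode=anti) >= breadth_min:
            best = max(best, 2)
        else:
            best = max(best, 1)
    return ActivityCall(votu_id, unit, "RNA", RNA_STATUS_ORDER[best])


def aggregate_by_month(
    calls: Iterable[ActivityCall],
    sample_to_month: Mapping[str, str],
) -> list[ActivityCall]:
    """Any-active aggregation: month status = max per-sample status.

    A vOTU is called active for a month as soon as one of the month's samples
    supports it. Expressed/lytic gene counts are summed as the maximum
    per-sample count (a per-month recount would require re-pooling calls).
    """
    ranks = {s: i for i, s in enumerate(DNA_STATUS_ORDER)}
    ranks.update({s: i for i, s in enumerate(RNA_STATUS_ORDER)})
    grouped: dict[tuple[str, str, str], list[ActivityCall]] = {}
    for call in calls:
        month = sample_to_month.get(call.unit)
        if month is None:
            raise KeyError(f"sample {call.unit!r} has no month in the metadata")
        grouped.setdefault((call.votu_id, month, call.molecule), []).append(call)
    out = []
    for (votu_id, month, molecule), group in sorted(grouped.items()):
        best = max(group, key=lambda c: ranks[c.status])
        out.append(
            ActivityCall(
                votu_id,
                month,
                molecule,
                best.status,
                n_expressed_genes=max(c.n_expressed_genes for c in group),
                n_lytic_genes=max(c.n_lytic_genes for c in group),
            )
        )
    return out
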