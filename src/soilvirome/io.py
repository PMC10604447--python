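"""Readers and writers for the pipeline's on-disk formats.

Formats handled here:

* genomes — FASTA (Biopython)
* gene features — GFF3 (1-based inclusive; strand in column 7; gene id in the
  ``ID`` attribute), plus a gene→functional-category TSV
* read placements — either a placement TSV dialect
  (``read_id  contig_id  start  end  strand  library_id``, header required)
  or BAM/SAM via pysam with a stranded-protocol flag
* library table — TSV: ``library_id  type  month  depth  location  total_reads``
* trees — Newick via dendropy (supports stored as internal-node labels)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from soilvirome.catalog import ViralContig
from soilvirome.coverage import ReadPlacement

__all__ = [
    "Gene",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_category_table",
    "write_category_table",
    "read_placements_tsv",
    "write_placements_tsv",
    "read_placements_bam",
    "read_library_table",
    "write_library_table",
    "read_votu_table",
    "write_votu_table",
]

PLACEMENT_COLUMNS = ["read_id", "contig_id", "start", "end", "strand", "library_id"]
LIBRARY_COLUMNS = ["library_id", "type", "month", "depth", "location", "total_reads"]


@dataclass(frozen=True)
class Gene:
    """A gene feature on a contig (1-based inclusive coordinates)."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+' | '-'
    category: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError(f"bad gene interval [{self.start}, {self.end}] for {self.gene_id}")
        if self.strand not in "+-":
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str | Path, completeness: Mapping[str, float] | None = None,
               molecule: str | Mapping[str, str] = "DNA") -> list[ViralContig]:
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        mol = molecule if isinstance(molecule, str) else molecule.get(rec.id, "DNA")
        comp = None if completeness is None else completeness.get(rec.id)
        contigs.append(ViralContig(id=rec.id, sequence=str(rec.seq).upper(),
                                   molecule=mol, completeness=comp))
    return contigs


def write_fasta(contigs: Iterable[ViralContig], path: str | Path) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs]
    SeqIO.write(records, str(path), "fasta")


def _parse_gff_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[Gene]:
    """Parse gene features from GFF3; the ``ID`` attribute names the gene."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in ("gene", "CDS"):
                continue
            attributes = _parse_gff_attributes(attrs)
            gene_id = attributes.get("ID")
            if gene_id is None:
                raise ValueError(f"GFF3 feature without ID attribute: {line!r}")
            genes.append(Gene(gene_id=gene_id, contig_id=seqid, start=int(start),
                              end=int(end), strand=strand,
                              category=attributes.get("category", "unknown")))
    return genes


def write_gff3(genes: Iterable[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};category={g.category}"
            fh.write(
                f"{g.contig_id}\tsoilvirome\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_category_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["gene_id"], df["category"]))


def write_category_table(genes: Iterable[Gene], path: str | Path) -> None:
    pd.DataFrame(
        [{"gene_id": g.gene_id, "category": g.category} for g in genes]
    ).to_csv(path, sep="\t", index=False)


def read_placements_tsv(path: str | Path) -> Iterator[ReadPlacement]:
    """Stream placements from the TSV dialect (header line required)."""
    for chunk in pd.read_csv(path, sep="\t", chunksize=100_000,
                             dtype={"start": int, "end": int}):
        missing = set(PLACEMENT_COLUMNS) - set(chunk.columns)
        if missing:
            raise ValueError(f"placement table missing columns: {sorted(missing)}")
        for row in chunk.itertuples(index=False):
            yield ReadPlacement(read_id=row.read_id, contig_id=row.contig_id,
                                start=row.start, end=row.end, strand=row.strand,
                                library_id=row.library_id)


def write_placements_tsv(placements: Iterable[ReadPlacement], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PLACEMENT_COLUMNS) + "\n")
        for p in placements:
            fh.write(f"{p.read_id}\t{p.contig_id}\t{p.start}\t{p.end}\t{p.strand}\t{p.library_id}\n")


def read_placements_bam(
    path: str | Path,
    library_id: str,
    stranded_protocol: str = "rf",
) -> Iterator[ReadPlacement]:
    """Read placements from a BAM/SAM file via pysam.

    ``stranded_protocol`` maps mate orientation to transcript sense for
    stranded metatranscriptome libraries: with the dUTP (``rf``) protocol,
    read 1 aligns antisense to the transcript, so its alignment strand is
    flipped (and read 2 kept); ``fr`` is the opposite convention. Use ``fr``
    for unstranded DNA libraries where alignment strand is reported as-is
    (read 2 flipped so a proper pair contributes one orientation).
    """
    import pysam

    if stranded_protocol not in ("rf", "fr"):
        raise ValueError("stranded_protocol must be 'rf' or 'fr'")
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        for aln in bam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            reverse = aln.is_reverse
            # flip to coding-strand sense depending on protocol and mate
            flip_read1 = stranded_protocol == "rf"
            if (aln.is_read1 or not aln.is_paired) and flip_read1:
                reverse = not reverse
            elif aln.is_read2 and not flip_read1:
                reverse = not reverse
            yield ReadPlacement(
                read_id=aln.query_name,
                contig_id=aln.reference_name,
                start=aln.reference_start + 1,
                end=aln.reference_end,
                strand="-" if reverse else "+",
                library_id=library_id,
            )


def read_library_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"total_reads": int})
    missing = set(LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"library table missing columns: {sorted(missing)}")
    return df


def write_library_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_votu_table(path: str | Path) -> dict[str, list[str]]:
    """vOTU membership TSV → representative → member list."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    clusters: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        clusters.setdefault(row.representative_id, []).append(row.member_id)
    return clusters


def write_votu_table(votus: Sequence, path: str | Path) -> None:
    rows = []
    for i, votu in enumerate(votus):
        for member in votu.members:
            rows.append({"votu_id": f"vOTU_{i + 1:05d}",
                         "representative_id": votu.representative,
                         "member_id": member})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
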