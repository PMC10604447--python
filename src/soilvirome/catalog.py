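"""vOTU catalog construction.

Viral contigs are retained if they are long enough (default ≥5 kbp) or
estimated sufficiently complete (default ≥50%), then dereplicated into
species-rank viral OTUs (vOTUs) by greedy clustering at ≥95% average
nucleotide identity (ANI) over ≥85% aligned fraction (AF), with the longest
member of each cluster as its representative.

The pairwise aligner used here is an exact-seed (k=11) chained-fragment
aligner with ungapped extension, adequate for desk-scale synthetic contigs;
precomputed alignment records from an external aligner (e.g. MUMmer) can be
supplied to :func:`greedy_cluster` instead.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ViralContig",
    "PairwiseAlignmentRecord",
    "VOTU",
    "retention_filter",
    "compute_pairwise_ani",
    "all_pairwise_ani",
    "greedy_cluster",
    "cluster_contigs",
    "insertion_sequence_filter",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ViralContig:
    """A viral contig with optional completeness metadata.

    ``completeness`` is a percentage in [0, 100] as produced by an external
    completeness estimator, or ``None`` when unknown.
    """

    id: str
    sequence: str
    molecule: str = "DNA"  # DNA | RNA
    completeness: float | None = None

    def __post_init__(self) -> None:
        if self.completeness is not None and not (0 <= self.completeness <= 100):
            raise ValueError(
                f"completeness of {self.id} must be in [0, 100], got {self.completeness}"
            )
        if self.molecule not in ("DNA", "RNA"):
            raise ValueError(f"molecule must be DNA or RNA, got {self.molecule!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairwiseAlignmentRecord:
    """ANI/AF summary of the local alignments between two sequences.

    ``ani`` is the alignment-length-weighted mean percent identity over all
    merged fragments; ``af_query``/``af_target`` are the percent of each
    sequence covered by the union of aligned fragments.
    """

    query: str
    target: str
    ani: float
    af_query: float
    af_target: float

    def af_for(self, contig_id: str) -> float:
        if contig_id == self.query:
            return self.af_query
        if contig_id == self.target:
            return self.af_target
        raise KeyError(f"{contig_id} is not part of this record")


@dataclass
class VOTU:
    """A vOTU: representative contig id plus all member ids (incl. itself)."""

    representative: str
    members: list[str] = field(default_factory=list)


def retention_filter(
    contigs: Iterable[ViralContig],
    min_len: int = 5000,
    min_completeness: float = 50.0,
) -> list[ViralContig]:
    """Keep contigs that are ≥ ``min_len`` bp OR ≥ ``min_completeness`` % complete.

    Contigs with unknown completeness fail the completeness clause and are
    retained only on length.
    """
    retained = []
    for c in contigs:
        if c.length >= min_len:
            retained.append(c)
        elif c.completeness is not None and c.completeness >= min_completeness:
            retained.append(c)
    return retained


def _seed_fragments(a: str, b: str, k: int) -> list[tuple[int, int, int]]:
    """Chained ungapped fragments between a and b from shared k-mers.

    Returns (start_a, start_b, length) triples, one per diagonal run of seeds,
    after ungapped extension.  Coordinates are 0-based.
    """
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(a) - k + 1):
        index[a[i : i + k]].append(i)
    # seeds grouped by diagonal (i - j)
    diagonals: dict[int, list[int]] = defaultdict(list)
    for j in range(len(b) - k + 1):
        for i in index.get(b[j : j + k], ()):
            diagonals[i - j].append(j)

    fragments: list[tuple[int, int, int]] = []
    max_seed_gap = 100  # bp between consecutive seeds on a diagonal to chain them
    for diag, js in diagonals.items():
        js.sort()
        run_start = js[0]
        prev = js[0]
        runs: list[tuple[int, int]] = []
        for j in js[1:]:
            if j - prev > max_seed_gap:
                runs.append((run_start, prev + k))
                run_start = j
            prev = j
        runs.append((run_start, prev + k))
        for b0, b1 in runs:
            a0 = b0 + diag
            a1 = b1 + diag
            # ungapped extension while bases match exactly
            while a0 > 0 and b0 > 0 and a[a0 - 1] == b[b0 - 1]:
                a0 -= 1
                b0 -= 1
            while a1 < len(a) and b1 < len(b) and a[a1] == b[b1]:
                a1 += 1
                b1 += 1
            fragments.append((a0, b0, a1 - a0))
    return fragments


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    total += cur_hi - cur_lo
    return total


def compute_pairwise_ani(
    a: ViralContig,
    b: ViralContig,
    k: int = 11,
    min_identity: float = 70.0,
) -> PairwiseAlignmentRecord | None:
    """ANI/AF between two contigs from exact-seed chained local fragments.

    Both orientations of ``b`` are tried; the orientation with more aligned
    bases wins.  Fragments below ``min_identity`` percent identity are
    discarded.  Returns ``None`` when no fragment is found (no shared k-mer),
    which callers treat as ANI 0.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("sequences must be non-empty")
    best: tuple[int, list[tuple[int, int, int, float]]] | None = None
    for oriented in (b.sequence, reverse_complement(b.sequence)):
        frags = []
        for a0, b0, length in _seed_fragments(a.sequence, oriented, k):
            sub_a = a.sequence[a0 : a0 + length]
            sub_b = oriented[b0 : b0 + length]
            matches = sum(x == y for x, y in zip(sub_a, sub_b))
            pid = 100.0 * matches / length
            if pid >= min_identity:
                frags.append((a0, b0, length, pid))
        aligned = sum(f[2] for f in frags)
        if best is None or aligned > best[0]:
            best = (aligned, frags)
    assert best is not None
    _, frags = best
    if not frags:
        return None
    total_len = sum(f[2] for f in frags)
    ani = sum(f[2] * f[3] for f in frags) / total_len
    cov_a = _merged_length([(f[0], f[0] + f[2]) for f in frags])
    cov_b = _merged_length([(f[1], f[1] + f[2]) for f in frags])
    return PairwiseAlignmentRecord(
        query=a.id,
        target=b.id,
        ani=ani,
        af_query=100.0 * cov_a / a.length,
        af_target=100.0 * cov_b / b.length,
    )


def all_pairwise_ani(contigs: Sequence[ViralContig], k: int = 11) -> list[PairwiseAlignmentRecord]:
    """All-vs-all ANI records (each unordered pair once, self-pairs skipped)."""
    records = []
    for i, a in enumerate(contigs):
        for b in contigs[i + 1 :]:
            rec = compute_pairwise_ani(a, b, k=k)
            if rec is not None:
                records.append(rec)
    return records


def greedy_cluster(
    records: Iterable[PairwiseAlignmentRecord],
    contigs: Sequence[ViralContig],
    min_ani: float = 95.0,
    min_af: float = 85.0,
) -> list[VOTU]:
    """Greedy length-ordered clustering into vOTUs.

    Contigs are sorted by descending length (ties broken by id); each contig
    joins the earliest-seeded cluster whose seed it matches at
    ``ani ≥ min_ani`` and aligned fraction of the *shorter* sequence
    ``≥ min_af``, else it seeds a new vOTU.  Seeds are therefore always a
    longest member of their cluster.
    """
    lengths = {c.id: c.length for c in contigs}
    pair: dict[frozenset[str], PairwiseAlignmentRecord] = {}
    for rec in records:
        if rec.query not in lengths or rec.target not in lengths:
            missing = rec.query if rec.query not in lengths else rec.target
            raise KeyError(f"alignment record references unknown contig {missing!r}")
        pair[frozenset((rec.query, rec.target))] = rec

    order = sorted(contigs, key=lambda c: (-c.length, c.id))
    votus: list[VOTU] = []
    for c in order:
        placed = False
        for votu in votus:
            rec = pair.get(frozenset((c.id, votu.representative)))
            if rec is None:
                continue
            shorter = (
                c.id
                if lengths[c.id] < lengths[votu.representative]
                else votu.representative
                if lengths[votu.representative] < lengths[c.id]
                else min(c.id, votu.representative)
            )
            if rec.ani >= min_ani and rec.af_for(shorter) >= min_af:
                votu.members.append(c.id)
                placed = True
                break
        if not placed:
            votus.append(VOTU(representative=c.id, members=[c.id]))
    return votus


def cluster_contigs(
    contigs: Sequence[ViralContig],
    min_ani: float = 95.0,
    min_af: float = 85.0,
    k: int = 11,
) -> list[VOTU]:
    """Convenience: compute all pairwise ANI records, then greedy-cluster."""
    return greedy_cluster(all_pairwise_ani(contigs, k=k), contigs, min_ani, min_af)


_IS_KEYWORDS = ("transposase", "insertion sequence", "insertion element")


def insertion_sequence_filter(
    contigs: Iterable[ViralContig],
    gene_products: Mapping[str, Sequence[str]],
    keywords: Sequence[str] = _IS_KEYWORDS,
) -> list[ViralContig]:
    """Optional annotation-based refinement of vOTU representatives.

    Drops contigs whose annotated genes are all insertion-sequence related
    (keyword match, case-insensitive) and contigs with no annotated gene at
    all.  ``gene_products`` maps contig id → product strings of its annotated
    genes.  Off by default in the pipeline.
    """
    kept = []
    lowered = tuple(k.lower() for k in keywords)
    for c in contigs:
        products = [p for p in gene_products.get(c.id, ()) if p]
        if not products:
            continue
        if all(any(k in p.lower() for k in lowered) for p in products):
            continue
        kept.append(c)
    return kept
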