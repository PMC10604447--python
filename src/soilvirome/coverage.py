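"""Strand-specific coverage and breadth-masked RPKM.

Read placements on vOTU representatives are accumulated into per-position
forward/reverse depth vectors. From these we derive breadth (percent of
positions covered at ≥1×), the lower-median depth, and RPKM (reads per
kilobase of contig per million library reads) masked to 0 when reads cover
less than ``breadth_mask`` percent (default 10%) of the contig.

All interval coordinates are 1-based inclusive, as in GFF3 and the placement
table dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ReadPlacement",
    "StrandCoverage",
    "accumulate_coverage",
    "breadth",
    "median_depth",
    "rpkm",
    "rpkm_matrix",
    "coverage_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadPlacement:
    """One placed read: contig interval (1-based inclusive) on a strand."""

    read_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+' | '-'
    library_id: str


@dataclass
class StrandCoverage:
    """Per-position strand-split depth for one contig in one library."""

    contig_id: str
    library_id: str
    depth_plus: np.ndarray
    depth_minus: np.ndarray

    @property
    def length(self) -> int:
        return self.depth_plus.shape[0]

    def strand_depth(self, strand_mode: str) -> np.ndarray:
        if strand_mode == "plus":
            return self.depth_plus
        if strand_mode == "minus":
            return self.depth_minus
        if strand_mode == "both-combined":
            return self.depth_plus + self.depth_minus
        raise ValueError(f"unknown strand_mode {strand_mode!r}")


def accumulate_coverage(
    placements: Iterable[ReadPlacement],
    contig_lengths: Mapping[str, int],
) -> dict[tuple[str, str], StrandCoverage]:
    """Accumulate placements into strand-split depth vectors.

    Depth at a position is the number of placements whose [start, end]
    interval covers it, split by strand. Placements on unknown contigs or
    outside contig bounds are skipped and counted in the log (record-level
    errors do not abort the run).

    Uses difference arrays: O(reads + total contig length).
    """
    diffs: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    n_bad = 0
    for p in placements:
        length = contig_lengths.get(p.contig_id)
        if length is None or not (1 <= p.start <= p.end <= length) or p.strand not in "+-":
            n_bad += 1
            continue
        key = (p.contig_id, p.library_id)
        d = diffs.get(key)
        if d is None:
            d = {
                "+": np.zeros(length + 1, dtype=np.int64),
                "-": np.zeros(length + 1, dtype=np.int64),
            }
            diffs[key] = d
        vec = d[p.strand]
        vec[p.start - 1] += 1
        vec[p.end] -= 1
    if n_bad:
        logger.warning("skipped %d invalid placements (out of bounds / unknown contig)", n_bad)
    out: dict[tuple[str, str], StrandCoverage] = {}
    for (contig_id, library_id), d in diffs.items():
        out[(contig_id, library_id)] = StrandCoverage(
            contig_id=contig_id,
            library_id=library_id,
            depth_plus=np.cumsum(d["+"][:-1]),
            depth_minus=np.cumsum(d["-"][:-1]),
        )
    return out


def _interval_slice(cov: StrandCoverage, interval: tuple[int, int] | None) -> tuple[int, int]:
    if interval is None:
        return 1, cov.length
    start, end = interval
    if start > end:
        raise ValueError(f"empty interval ({start}, {end})")
    if not (1 <= start and end <= cov.length):
        raise ValueError(f"interval ({start}, {end}) outside contig of length {cov.length}")
    return start, end


def breadth(
    cov: StrandCoverage,
    interval: tuple[int, int] | None = None,
    strand_mode: str = "both-combined",
) -> float:
    """Percent of interval positions with depth ≥ 1 under the strand mode."""
    start, end = _interval_slice(cov, interval)
    depth = cov.strand_depth(strand_mode)[start - 1 : end]
    return 100.0 * float(np.count_nonzero(depth)) / depth.shape[0]


def median_depth(
    cov: StrandCoverage,
    interval: tuple[int, int] | None = None,
    strand_mode: str = "both-combined",
) -> int:
    """Lower median of per-position depth over the interval.

    The lower median (element at index (n-1)//2 of the sorted depths) is
    integer-valued and conservative at the exact-50%-breadth boundary.
    """
    start, end = _interval_slice(cov, interval)
    depth = cov.strand_depth(strand_mode)[start - 1 : end]
    return int(np.sort(depth)[(depth.shape[0] - 1) // 2])


def rpkm(
    mapped_reads: int,
    contig_len: int,
    library_total: int,
    breadth_pct: float,
    breadth_mask: float = 10.0,
) -> float:
    """Reads per kilobase of contig per million library reads.

    Returns 0 when reads cover less than ``breadth_mask`` percent of the
    contig, so that spurious low-breadth recruitment does not register as
    abundance.
    """
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if breadth_pct < breadth_mask:
        return 0.0
    return mapped_reads / (contig_len / 1000.0) / (library_total / 1e6)


def rpkm_matrix(
    coverages: Mapping[tuple[str, str], StrandCoverage],
    mapped_reads: Mapping[tuple[str, str], int],
    contig_lengths: Mapping[str, int],
    library_totals: Mapping[str, int],
    breadth_mask: float = 10.0,
    strand_mode: str = "both-combined",
) -> pd.DataFrame:
    """vOTU × library RPKM matrix with the breadth mask applied.

    ``mapped_reads`` gives read counts per (contig, library); libraries with
    no placements on a contig get RPKM 0. Breadth for the mask is computed
    under ``strand_mode`` (combined strands by default).
    """
    contigs = sorted(contig_lengths)
    libraries = sorted(library_totals)
    mat = np.zeros((len(contigs), len(libraries)))
    for i, c in enumerate(contigs):
        for j, lib in enumerate(libraries):
            n = mapped_reads.get((c, lib), 0)
            if n == 0:
                continue
            cov = coverages.get((c, lib))
            b = breadth(cov, strand_mode=strand_mode) if cov is not None else 0.0
            mat[i, j] = rpkm(n, contig_lengths[c], library_totals[lib], b, breadth_mask)
    return pd.DataFrame(mat, index=contigs, columns=libraries)


def coverage_summary(
    coverages: Mapping[tuple[str, str], StrandCoverage],
    mapped_reads: Mapping[tuple[str, str], int] | None = None,
) -> pd.DataFrame:
    """Long-form per-contig per-library per-strand summary table."""
    rows = []
    for (contig_id, library_id), cov in sorted(coverages.items()):
        for strand_mode, strand in (("plus", "+"), ("minus", "-"), ("both-combined", "both")):
            rows.append(
                {
                    "contig_id": contig_id,
                    "library_id": library_id,
                    "strand": strand,
                    "breadth": breadth(cov, strand_mode=strand_mode),
                    "median_depth": median_depth(cov, strand_mode=strand_mode),
                    "mapped_reads": (mapped_reads or {}).get((contig_id, library_id), 0),
                }
            )
    return pd.DataFrame(rows)
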