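"""Synthetic seed-bank virome with planted ground truth.

Generates viral genomes (DNA and ssRNA), gene annotations with functional
categories, a months × depths × locations sampling design with paired
metagenome/metatranscriptome libraries, and strand-aware read placements
that reproduce the statistical structure the analysis assumes:

* a seed-bank DNA community — every DNA vOTU persists in metagenomes in all
  months, while only a subset is transcriptionally active, including a small
  seasonal subset (default 5%) with clear month-specific schedules;
* strand-specific transcription — metatranscriptome reads from active DNA
  vOTUs fall only on the coding strands of their scheduled expressed genes;
* dual-strand replication signal for ssRNA genomes — "detected" vOTUs emit
  coding-strand reads only, "active" vOTUs additionally emit minus-strand
  reads (replication intermediates) at a minority fraction (default 0.2);
* negative-binomial read-count noise, collapsing to deterministic tiling in
  noiseless mode.

The defaults mirror the field design of a subalpine watershed study: four
sampling dates spanning snow cover, snowmelt, plant growth and autumn, three
soil depth increments, and two hillslope locations (48 samples per library
type). Truth tables are written alongside the data for evaluation only and
are never read by the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from soilvirome.catalog import ViralContig
from soilvirome.coverage import ReadPlacement
from soilvirome.io import Gene

__all__ = [
    "CommunityDesign",
    "PlantedTruth",
    "GENE_CATEGORIES",
    "DEFAULT_SEASONS",
    "generate_genomes",
    "plant_truth",
    "simulate_placements",
    "simulate_expression_matrix",
    "truth_status_table",
    "placements_from_frame",
    "placements_to_frame",
    "write_truth_tables",
]

GENE_CATEGORIES = (
    "virion-structure",
    "encapsidation",
    "lysis",
    "replication",
    "lysogeny",
    "unknown",
)
_CATEGORY_WEIGHTS = (0.15, 0.10, 0.10, 0.20, 0.10, 0.35)
_LYTIC = {"virion-structure", "encapsidation", "lysis"}

DEFAULT_SEASONS = {"Mar": "winter", "May": "snowmelt", "Jun": "spring", "Sep": "autumn"}
_STRATEGY_BY_PEAK = {
    "Mar": "winter-adapted",
    "May": "snowmelt-specialist",
    "Jun": "spring-adapted",
}

READ_LENGTH = 150  # bp; 2x151 sequencing, fragments clipped at contig ends


@dataclass
class CommunityDesign:
    """Sampling design: every (month, depth, location, replicate) cell yields
    one paired metagenome + metatranscriptome sample."""

    months: Sequence[str] = ("Mar", "May", "Jun", "Sep")
    depths: Sequence[str] = ("00-05cm", "05-15cm", "15cm-plus")
    locations: Sequence[str] = ("upslope", "downslope")
    replicates_per_cell: int = 2
    library_size_mean: int = 100_000
    library_size_dispersion: float = 10.0
    seasons: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_SEASONS))

    def __post_init__(self) -> None:
        if not self.months or not self.depths or not self.locations:
            raise ValueError("months, depths and locations must be non-empty")
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")

    def samples(self) -> pd.DataFrame:
        """One row per sample with its paired library ids and metadata."""
        rows = []
        for month in self.months:
            for depth in self.depths:
                for loc in self.locations:
                    for rep in range(1, self.replicates_per_cell + 1):
                        sample_id = f"{month}_{depth}_{loc}_r{rep}"
                        rows.append(
                            {
                                "sample_id": sample_id,
                                "month": month,
                                "season": self.seasons.get(month, month),
                                "depth": depth,
                                "location": loc,
                                "replicate": rep,
                                "metaG": f"metaG_{sample_id}",
                                "metaT": f"metaT_{sample_id}",
                            }
                        )
        return pd.DataFrame(rows)


@dataclass
class PlantedTruth:
    """Ground truth for a synthetic community.

    ``schedule[votu][month]`` holds the planted state: for DNA vOTUs one of
    ``inactive | active | active-lytic`` (DNA vOTUs always persist in
    metagenomes — the seed bank); for ssRNA vOTUs one of
    ``absent | detected | active``. ``expressed_genes[(votu, month)]`` lists
    the genes transcribed in the months a DNA vOTU is active.
    """

    molecule: dict[str, str] = field(default_factory=dict)
    baseline_abundance: dict[str, float] = field(default_factory=dict)
    schedule: dict[str, dict[str, str]] = field(default_factory=dict)
    expressed_genes: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    host_label: dict[str, str] = field(default_factory=dict)
    host_strategy: dict[str, str] = field(default_factory=dict)
    months: tuple[str, ...] = ()

    def validate(self) -> None:
        for votu, sched in self.schedule.items():
            mol = self.molecule[votu]
            for month, status in sched.items():
                if mol == "DNA" and status not in ("inactive", "active", "active-lytic"):
                    raise ValueError(f"bad DNA status {status!r} for {votu}/{month}")
                if mol == "RNA" and status not in ("absent", "detected", "active"):
                    raise ValueError(f"bad RNA status {status!r} for {votu}/{month}")
                if mol == "DNA" and status in ("active", "active-lytic"):
                    if not self.expressed_genes.get((votu, month)):
                        raise ValueError(f"{votu} active in {month} without expressed genes")


def generate_genomes(
    n: int,
    length_range: tuple[int, int] = (5000, 15000),
    gene_density: float = 1.0,
    molecule_mix: float = 0.2,
    seed: int = 0,
) -> tuple[list[ViralContig], list[Gene]]:
    """Random viral genomes with non-overlapping gene annotations.

    ``gene_density`` is in genes per kbp; ``molecule_mix`` is the fraction of
    genomes drawn as ssRNA (all genes on the coding '+' strand, genomes at
    the short end of the length range). Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if not (1000 <= lo <= hi <= 200_000):
        raise ValueError("length_range must satisfy 1000 <= lo <= hi <= 200000")
    if not (0 <= molecule_mix <= 1):
        raise ValueError("molecule_mix must be in [0, 1]")
    if gene_density <= 0:
        raise ValueError("gene_density must be positive")
    rng = np.random.default_rng(seed)
    contigs: list[ViralContig] = []
    genes: list[Gene] = []
    bases = np.array(list("ACGT"))
    for i in range(n):
        votu_id = f"sv_{i + 1:05d}"
        is_rna = rng.random() < molecule_mix
        if is_rna:
            # ssRNA genomes are short (Leviviricetes-like); cap near the low end
            length = int(rng.integers(lo, min(hi, max(lo + 1, 6000)) + 1))
        else:
            length = int(rng.integers(lo, hi + 1))
        seq = "".join(bases[rng.integers(0, 4, size=length)])
        completeness = float(np.clip(rng.normal(75, 20), 5, 100))
        contigs.append(
            ViralContig(
                id=votu_id,
                sequence=seq,
                molecule="RNA" if is_rna else "DNA",
                completeness=round(completeness, 1),
            )
        )
        n_genes = max(1, round(gene_density * length / 1000))
        slot = length // n_genes
        for g in range(n_genes):
            slot_start = g * slot + 1
            gene_len = int(min(rng.integers(300, 901), slot - 10)) if slot > 310 else max(
                100, slot - 10
            )
            start = slot_start + int(rng.integers(0, max(1, slot - gene_len - 9)))
            end = min(start + gene_len - 1, length)
            strand = "+" if is_rna else ("+" if rng.random() < 0.5 else "-")
            category = str(rng.choice(GENE_CATEGORIES, p=_CATEGORY_WEIGHTS))
            genes.append(
                Gene(
                    gene_id=f"{votu_id}_g{g + 1:03d}",
                    contig_id=votu_id,
                    start=start,
                    end=end,
                    strand=strand,
                    category=category,
                )
            )
    return contigs, genes


def plant_truth(
    contigs: Sequence[ViralContig],
    genes: Sequence[Gene],
    design: CommunityDesign,
    seasonal_fraction: float = 0.05,
    active_fraction: float = 0.5,
    seed: int = 0,
) -> PlantedTruth:
    """Plant activity schedules, abundances and host strategies.

    DNA vOTUs all persist in metagenomes (seed bank). A ``seasonal_fraction``
    subset (default 5%, mirroring the small fraction of phages with clear
    differential activity in real soil viromes) is active in exactly one peak
    month and inactive otherwise; of the remainder, ``active_fraction`` are
    constitutively active (half of eligible ones lytic) and the rest
    constitutively inactive. Seasonal vOTUs with a winter/snowmelt/spring
    peak get a host with the matching ecological strategy. ssRNA vOTUs draw
    absent/detected/active states per month (high-turnover community).
    """
    rng = np.random.default_rng(seed)
    genes_by_contig: dict[str, list[Gene]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig_id, []).append(g)

    truth = PlantedTruth(months=tuple(design.months))
    dna = [c for c in contigs if c.molecule == "DNA"]
    rna = [c for c in contigs if c.molecule == "RNA"]
    for c in contigs:
        truth.molecule[c.id] = c.molecule
        truth.baseline_abundance[c.id] = float(rng.lognormal(0.0, 1.0))

    n_seasonal = int(round(seasonal_fraction * len(dna)))
    # prefer genomes carrying a lytic-category gene for lytic schedules
    has_lytic = {c.id for c in dna if any(g.category in _LYTIC for g in genes_by_contig[c.id])}
    order = list(rng.permutation([c.id for c in dna]))
    seasonal = sorted(order[:n_seasonal])
    rest = order[n_seasonal:]

    has_nonlytic = {
        c.id for c in dna if any(g.category not in _LYTIC for g in genes_by_contig[c.id])
    }

    def choose_lytic(votu: str) -> bool:
        # lytic schedules need a lytic-category gene; non-lytic schedules need
        # a non-lytic gene to express (expressing a lytic gene IS a lytic call)
        if votu not in has_nonlytic:
            return True
        if votu not in has_lytic:
            return False
        return bool(rng.random() < 0.5)

    def pick_expressed(votu: str, lytic: bool) -> list[str]:
        glist = genes_by_contig[votu]
        pool = glist if lytic else [g for g in glist if g.category not in _LYTIC]
        chosen = [g for g in pool if rng.random() < 0.5]
        if not chosen:
            chosen = [pool[int(rng.integers(0, len(pool)))]]
        if lytic:
            lytic_genes = [g for g in glist if g.category in _LYTIC]
            if not any(g.category in _LYTIC for g in chosen):
                chosen.append(lytic_genes[int(rng.integers(0, len(lytic_genes)))])
        return sorted({g.gene_id for g in chosen})

    for votu in seasonal:
        peak = design.months[int(rng.integers(0, len(design.months)))]
        lytic = choose_lytic(votu)
        status = "active-lytic" if lytic else "active"
        truth.schedule[votu] = {
            m: (status if m == peak else "inactive") for m in design.months
        }
        truth.expressed_genes[(votu, peak)] = pick_expressed(votu, lytic)
        strategy = _STRATEGY_BY_PEAK.get(peak)
        if strategy is not None:
            truth.host_label[votu] = f"host_{peak}"
            truth.host_strategy[votu] = strategy
        else:
            truth.host_strategy[votu] = "none"

    for votu in rest:
        if rng.random() < active_fraction:
            lytic = choose_lytic(votu)
            status = "active-lytic" if lytic else "active"
            expressed = pick_expressed(votu, lytic)
            truth.schedule[votu] = {m: status for m in design.months}
            for m in design.months:
                truth.expressed_genes[(votu, m)] = expressed
        else:
            truth.schedule[votu] = {m: "inactive" for m in design.months}
        truth.host_strategy[votu] = "none"

    for c in rna:
        truth.schedule[c.id] = {
            m: str(rng.choice(["absent", "detected", "active"], p=[0.5, 0.25, 0.25]))
            for m in design.months
        }
        truth.host_strategy[c.id] = "none"

    truth.validate()
    return truth


def _nb_count(rng: np.random.Generator, mean: float, dispersion: float | None) -> int:
    """Negative-binomial count with NB 'size' parameterisation (Poisson as
    dispersion → ∞ / None)."""
    if mean <= 0:
        return 0
    if dispersion is None or np.isinf(dispersion):
        return int(rng.poisson(mean))
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _tile_reads(lo: int, hi: int, read_length: int = READ_LENGTH) -> list[tuple[int, int]]:
    """Deterministic tiling of [lo, hi] at 1x: stride = read length."""
    out = []
    pos = lo
    while pos <= hi:
        out.append((pos, min(pos + read_length - 1, hi)))
        pos += read_length
    return out


def _random_reads(
    rng: np.random.Generator, count: int, lo: int, hi: int, read_length: int = READ_LENGTH
) -> list[tuple[int, int]]:
    if count <= 0:
        return []
    max_start = max(lo, hi - read_length + 1)
    starts = rng.integers(lo, max_start + 1, size=count)
    return [(int(s), min(int(s) + read_length - 1, hi)) for s in starts]


def simulate_placements(
    truth: PlantedTruth,
    design: CommunityDesign,
    contigs: Sequence[ViralContig],
    genes: Sequence[Gene],
    depth_per_active_gene: float = 20.0,
    noise_dispersion: float | None = 5.0,
    neg_strand_fraction: float = 0.2,
    seed: int = 0,
    noiseless: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate strand-aware read placements for every library of the design.

    Returns ``(placements, library_table)`` where placements has the columns
    of the placement TSV dialect and the library table's ``total_reads``
    equals the number of placement rows emitted for each library.

    Metagenome libraries sample both strands of every DNA vOTU (uniform
    positions, counts negative-binomial around abundance × library size);
    metatranscriptome libraries follow the planted schedules: coding-strand
    reads confined to expressed genes for active DNA vOTUs, genome-wide
    coding-strand reads for detected ssRNA vOTUs, plus minus-strand reads at
    ``neg_strand_fraction`` for actively replicating ssRNA vOTUs. In
    noiseless mode every signal is a deterministic 1× tiling of its target
    interval, so the downstream classifier must recover the schedule exactly.
    """
    if tuple(truth.months) != tuple(design.months):
        raise ValueError(
            f"truth months {truth.months} do not match design months {tuple(design.months)}"
        )
    if not (0 < neg_strand_fraction < 1):
        raise ValueError("neg_strand_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    lengths = {c.id: c.length for c in contigs}
    genes_by_id = {g.gene_id: g for g in genes}
    dna = sorted(v for v, m in truth.molecule.items() if m == "DNA")
    rna = sorted(v for v, m in truth.molecule.items() if m == "RNA")
    weights = truth.baseline_abundance
    total_w = sum(weights[v] for v in dna) or 1.0

    rows: list[tuple[str, str, int, int, str, str]] = []
    lib_rows = []
    samples = design.samples()
    for sample in samples.itertuples(index=False):
        month = sample.month
        # --- metagenome: seed-bank DNA community, both strands, any activity
        lib = sample.metaG
        n_before = len(rows)
        for votu in dna:
            length = lengths[votu]
            if noiseless:
                for strand in "+-":
                    for s, e in _tile_reads(1, length):
                        rows.append((f"{lib}_{votu}_{strand}_{s}", votu, s, e, strand, lib))
            else:
                mean = weights[votu] / total_w * design.library_size_mean
                count = _nb_count(rng, mean, noise_dispersion)
                for ri, (s, e) in enumerate(_random_reads(rng, count, 1, length)):
                    strand = "+" if rng.random() < 0.5 else "-"
                    rows.append((f"{lib}_{votu}_{ri}", votu, s, e, strand, lib))
        lib_rows.append((lib, "metaG", month, sample.depth, sample.location, len(rows) - n_before))

        # --- metatranscriptome: schedule-driven, strand-specific
        lib = sample.metaT
        n_before = len(rows)
        for votu in dna:
            status = truth.schedule[votu][month]
            if status == "inactive":
                continue
            for gene_id in truth.expressed_genes[(votu, month)]:
                g = genes_by_id[gene_id]
                if noiseless:
                    reads = _tile_reads(g.start, g.end)
                else:
                    mean = depth_per_active_gene * g.length / READ_LENGTH
                    count = _nb_count(rng, mean, noise_dispersion)
                    reads = _random_reads(rng, count, g.start, g.end)
                for ri, (s, e) in enumerate(reads):
                    rows.append((f"{lib}_{gene_id}_{ri}", votu, s, e, g.strand, lib))
        for votu in rna:
            status = truth.schedule[votu][month]
            if status == "absent":
                continue
            length = lengths[votu]
            if noiseless:
                plus = _tile_reads(1, length)
                minus = _tile_reads(1, length) if status == "active" else []
            else:
                mean = depth_per_active_gene * length / READ_LENGTH
                plus = _random_reads(rng, _nb_count(rng, mean, noise_dispersion), 1, length)
                minus = []
                if status == "active":
                    minus_mean = mean * neg_strand_fraction / (1 - neg_strand_fraction)
                    minus = _random_reads(
                        rng, _nb_count(rng, minus_mean, noise_dispersion), 1, length
                    )
            for ri, (s, e) in enumerate(plus):
                rows.append((f"{lib}_{votu}_p{ri}", votu, s, e, "+", lib))
            for ri, (s, e) in enumerate(minus):
                rows.append((f"{lib}_{votu}_m{ri}", votu, s, e, "-", lib))
        lib_rows.append((lib, "metaT", month, sample.depth, sample.location, len(rows) - n_before))

    placements = pd.DataFrame(
        rows, columns=["read_id", "contig_id", "start", "end", "strand", "library_id"]
    )
    library_table = pd.DataFrame(
        lib_rows, columns=["library_id", "type", "month", "depth", "location", "total_reads"]
    )
    return placements, library_table


def simulate_expression_matrix(
    n_votus: int = 200,
    seasonal_fraction: float = 0.05,
    months: Sequence[str] = ("Mar", "May", "Jun", "Sep"),
    samples_per_month: int = 12,
    baseline_mean: float = 50.0,
    peak_fold: float = 10.0,
    dispersion: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """Abundance-level generator for the differential-activity task.

    Emulates the metatranscriptome RPKM matrix of active DNA vOTUs directly:
    null vOTUs have a month-constant negative-binomial mean (lognormal across
    vOTUs), seasonal vOTUs (``seasonal_fraction``, default 5%) have their
    peak-month mean multiplied by ``peak_fold``. Set ``peak_fold=1`` for an
    all-null matrix. Returns (matrix, sample metadata, seasonal vOTU ids).
    """
    rng = np.random.default_rng(seed)
    sample_ids = [f"{m}_s{i + 1}" for m in months for i in range(samples_per_month)]
    meta = pd.DataFrame(
        {
            "month": [s.split("_")[0] for s in sample_ids],
            "season": [DEFAULT_SEASONS.get(s.split("_")[0], s.split("_")[0]) for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    n_seasonal = int(round(seasonal_fraction * n_votus))
    votus = [f"av_{i + 1:05d}" for i in range(n_votus)]
    seasonal = set(votus[:n_seasonal])
    mat = np.zeros((n_votus, len(sample_ids)))
    month_of = meta["month"].to_numpy()
    for i, votu in enumerate(votus):
        mu = baseline_mean * float(rng.lognormal(0.0, 0.5))
        peak = months[int(rng.integers(0, len(months)))]
        for j, m in enumerate(month_of):
            mean = mu * (peak_fold if (votu in seasonal and m == peak) else 1.0)
            mat[i, j] = _nb_count(rng, mean, dispersion)
    matrix = pd.DataFrame(mat, index=votus, columns=sample_ids)
    return matrix, meta, seasonal


def truth_status_table(truth: PlantedTruth) -> pd.DataFrame:
    """Expected classifier output per vOTU-month (evaluation only).

    DNA 'inactive' maps to the classifier's 'present-inactive' since DNA
    vOTUs always persist in metagenomes.
    """
    rows = []
    for votu, sched in sorted(truth.schedule.items()):
        for month, status in sched.items():
            expected = status
            if truth.molecule[votu] == "DNA" and status == "inactive":
                expected = "present-inactive"
            rows.append(
                {
                    "votu_id": votu,
                    "month": month,
                    "molecule": truth.molecule[votu],
                    "true_status": expected,
                }
            )
    return pd.DataFrame(rows)


def placements_from_frame(frame: pd.DataFrame):
    """Iterate a placement DataFrame as ReadPlacement records."""
    for row in frame.itertuples(index=False):
        yield ReadPlacement(
            read_id=row.read_id,
            contig_id=row.contig_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            library_id=row.library_id,
        )


def placements_to_frame(placements) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": p.read_id,
                "contig_id": p.contig_id,
                "start": p.start,
                "end": p.end,
                "strand": p.strand,
                "library_id": p.library_id,
            }
            for p in placements
        ]
    )


def write_truth_tables(truth: PlantedTruth, out_dir: str | Path) -> None:
    """Write ground-truth TSVs (status schedule + host strategies).

    These files exist for evaluation and are never read by analysis modules.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_status_table(truth).to_csv(out / "truth_status.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "votu_id": votu,
                "molecule": truth.molecule[votu],
                "baseline_abundance": truth.baseline_abundance.get(votu, np.nan),
                "host_label": truth.host_label.get(votu, ""),
                "host_strategy": truth.host_strategy.get(votu, "none"),
            }
            for votu in sorted(truth.schedule)
        ]
    ).to_csv(out / "truth_votus.tsv", sep="\t", index=False)
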