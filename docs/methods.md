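# Methods

This note documents the models and procedures behind `soilvirome`, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the package's known limitations. It states nothing that
the test suite or `scripts/acceptance.py` does not itself compute.

## vOTU catalog

Contigs are retained when they are ≥ `min_len` (default 5000 bp) **or**
their externally estimated completeness is ≥ `min_completeness` (default
50%); unknown completeness fails the completeness clause, so short contigs
without an estimate are dropped. Retained contigs are dereplicated into
species-rank vOTUs by greedy clustering: contigs are sorted by descending
length (ties broken by lexicographic id, so output is deterministic), and
each contig joins the earliest-seeded cluster whose seed it matches at
ANI ≥ 95% and aligned fraction ≥ 85%, else it seeds a new cluster. Two
conventions had to be fixed where common practice varies:

- **AF is evaluated on the shorter sequence of the pair** (the standard
  dereplication convention: a genome fragment should join its source
  genome even though it covers little of it).
- **Seeds are visited in creation (length) order**, which makes the seed a
  longest member of its cluster by construction and hence the natural
  representative.

The built-in aligner is an exact-seed chained-fragment aligner: shared
11-mers are grouped by alignment diagonal, chained into ungapped fragments
(seed gaps ≤ 100 bp), extended outward while bases match, and filtered at
≥ 70% fragment identity; both orientations of the second sequence are
tried. ANI is the alignment-length-weighted mean fragment identity and AF
the merged fragment coverage of each sequence. This is adequate for
desk-scale synthetic genomes with point mutations and exact fragments; for
real contigs with indels, records from an external whole-genome aligner
can be supplied to `greedy_cluster` directly. An optional annotation-based
refinement (`insertion_sequence_filter`) drops contigs whose only
annotated genes are insertion-sequence related, or that have no annotated
gene at all; it is off by default because it requires external annotations.

## Strand-specific coverage and RPKM

Read placements (1-based inclusive intervals with strand) are accumulated
into per-position forward/reverse depth vectors with difference arrays.
Out-of-bounds placements are counted and logged rather than aborting the
run. From these vectors:

- **breadth** — percent of interval positions with depth ≥ 1 on the
  requested strand (or on the summed strands);
- **median depth** — the *lower* median (sorted depth at index
  `(n−1)//2`). The lower median is integer-valued and conservative at the
  exact-50%-breadth boundary: an interval covered on exactly half its
  positions at 1× has lower-median 0 and therefore does not pass a
  "median > 0" rule. (The interpolated median would give 0.5 there and
  flip several boundary calls.)
- **RPKM** — `reads / (contig_len/1000) / (library_total/1e6)`, set to 0
  when breadth < 10% of the contig, so sparse spurious recruitment does
  not register as abundance. The mask uses combined-strand breadth by
  default (configurable). The library total is taken from the library
  table (all filtered reads of the library), not from reads recruited to
  the catalog.

Reads count toward the contig they are placed on, with no multi-mapping
reweighting: mapping is assumed to be against vOTU representatives only.
The BAM/SAM reader maps mate orientation to transcript sense with a
`stranded_protocol` flag: `rf` (dUTP kits; read 1 antisense) flips read 1,
`fr` flips read 2.

## Activity classification

For DNA vOTUs, per metatranscriptome library, a gene is **expressed** iff
its coding strand has breadth ≥ 50% *and* lower-median depth > 0 over the
gene interval. Within a grouping unit (a sample, or a month when pooling),
a vOTU is:

- **active-lytic** — ≥ 1 expressed gene with a lytic-category label
  (default lytic set: virion-structure, encapsidation, lysis);
- **active** — ≥ 1 expressed gene, none lytic;
- **present-inactive** — no expressed gene but metagenome breadth ≥ 10%
  (the same threshold as the RPKM mask, so "present" means "would have a
  non-zero abundance") in ≥ 1 metagenome library of the unit;
- **absent** — otherwise.

Genes with unknown category labels are treated as non-lytic with a logged
warning. For ssRNA vOTUs the genome itself is the message-sense strand, so
gene expression is uninformative; instead a vOTU is **detected** when the
coding strand passes the breadth-50%/median rule and **active** when the
antisense strand — the replication intermediate — is additionally covered
≥ 50% at ≥ 1× *in the same library*. The antisense condition is breadth
only; the median clause applies to the coding strand, following the
asymmetric phrasing of the decision rule. Month-level calls take the
maximum per-sample status under
absent < present-inactive/detected < active < active-lytic (any-active
policy). When classification is run directly at month units, expressed
genes pool across the month's samples, so a structural gene expressed in
one sample and a lysis gene in another combine into a lytic call; the
sample-then-aggregate path keeps them separate. Both paths are exposed;
the sample-level path is the default in the workflow drivers.

## Clade annotation and UniFrac

Trees are rooted Newick files with supports as internal node labels.
`collapse_low_support` contracts every internal edge whose child support is
below the threshold (default 50), reattaching children to the grandparent;
nodes without a parseable support are kept. The operation is idempotent.

`propagate_annotations` implements the *most recent unanimous clade* rule:
walking root-ward from a query tip, the first ancestor whose clade contains
at least one annotated reference assigns its label if all its annotated
references agree, and blocks the assignment otherwise. Two open points were
resolved as follows: references lacking an annotation for the queried field
are ignored (they neither assign nor break unanimity — partial reference
metadata is the norm), and the *nearest* informative clade decides rather
than any deeper unanimous one (the nearest clade is the most specific
phylogenetic claim; a deeper clade that is unanimous necessarily contains
the nearer conflicting references, so the two rules differ exactly when the
nearest evidence is ambiguous). Representative assignments are copied
verbatim to cluster members; a member listed under two representatives is a
partition violation and an error.

Dataset distances on the same tree use presence/absence of tips by default
(matching marker-cluster sharing analyses) or abundance maps. The
generalized form is

    d = Σᵢ bᵢ (pᵢ+qᵢ)^α |pᵢ−qᵢ|/(pᵢ+qᵢ) ÷ Σᵢ bᵢ (pᵢ+qᵢ)^α

over branches with pᵢ+qᵢ > 0, with α = 0.5 by default (α weights abundant
lineages; at α = 0 every represented branch counts equally). The
unweighted mode is unique-branch-length over union-branch-length. Both are
exposed because "generalized unweighted" is ambiguous in common usage; α
is honored in generalized mode only.

## Seasonal statistics

Presence is RPKM > 0. A vOTU is *core* when present in ≥ 1 sample of every
season and *season-specific* when present in exactly one season.
Bray–Curtis is Σ|x−y|/Σ(x+y) (undefined, and an error, for two all-zero
samples). PERMANOVA uses Anderson's pseudo-F from among/within sums of
squared distances with unrestricted label permutations (no strata), a
+1-corrected p-value, and a seeded generator; permutations are evaluated
vectorized so the 999-permutation default is cheap.

Differential activity runs a one-way ANOVA of metatranscriptome RPKM
across months per vOTU (raw RPKM by default; a log10(x+1) transform is a
flag, since practice varies and the choice is not critical for strong
effects). Effect size is **η² = SS_between/SS_total**, the standard
multiple-group effect size reported alongside ANOVA in profile-analysis
tools; a vOTU is *seasonal* when Storey q ≤ 0.05 and η² > 0.3. Zero
variance vOTUs are excluded (logged). Tukey–Kramer pairwise month
comparisons (studentized-range quantiles with the unequal-n correction, via
statsmodels) are attached for vOTUs passing the q cutoff, and the peak
month is the argmax of the z-scored month means. Storey q-values use the
plateau π0 estimate at λ = 0.5 (`#{p>λ}/(m(1−λ))`, capped to [1/m, 1]) by
default, with an optional cubic-spline smoother over a λ grid; forcing
π0 = 1 reduces the procedure exactly to Benjamini–Hochberg, which the tests
assert. z-profiles are (month mean − grand mean of month means)/sd of month
means, with all-zero profiles mapped to z = 0, grouped by the host
ecological strategy (winter-adapted / snowmelt-specialist / spring-adapted)
with unassigned hosts in their own group.

## Synthetic community and what it does (not) show

The generator emulates the statistical structure the analysis assumes, at
desk scale:

- **Design** — defaults mirror a subalpine watershed field campaign: four
  sampling dates spanning snow cover (Mar), snowmelt (May), plant growth
  (Jun) and autumn (Sep), three soil depth increments, two hillslope
  locations, two replicates — 48 paired metagenome/metatranscriptome
  samples.
- **Genomes** — random sequence, 5–15 kbp (ssRNA capped near 6 kbp),
  1 gene/kbp in non-overlapping slots, functional categories drawn with
  unknown as the commonest label; ssRNA genes all on the coding strand.
- **Seed bank** — every DNA vOTU persists in metagenomes in all months
  (lognormal abundance weights, σ = 1); 5% are seasonal (active in exactly
  one month — mirroring the small fraction of phages with clear
  differential activity in real soil viromes), half of the rest
  constitutively active, the rest silent. Lytic schedules are only planted
  on genomes carrying a lytic-category gene, and non-lytic active
  schedules never express one (expressing a lytic gene *is* a lytic call).
- **Reads** — 150 bp, clipped at contig/gene ends. Counts are negative
  binomial (size parameter default 5; Poisson as size → ∞) around
  abundance × library size (metagenome) or around
  `depth_per_active_gene × len/150` (metatranscriptome; default 20×).
  Active ssRNA vOTUs emit minus-strand reads at a default 0.2 fraction —
  replication intermediates are minority species. In noiseless mode every
  signal is a deterministic 1× tiling, which makes the classifier
  round-trip an exact contract.
- **Leakage guard** — truth tables are written next to the data for
  scoring only; no analysis module reads them.

Deliberate departures from real data: no sequencing errors, quality
scores, mapping ambiguity, or assembly artifacts; abundances are
independent across vOTUs; schedules are deterministic per month. Passing
round-trips therefore demonstrate that the decision rules and bookkeeping
are correct, not that the thresholds are optimal for noisy real mappings.

One emulation limit deserves emphasis: because the synthetic libraries
contain *only* viral reads, library totals (which equal the emitted row
counts) swing with community activity, making RPKM strongly compositional
— a surge of the ssRNA community in one month deflates every DNA vOTU's
metatranscriptome RPKM that month. Real libraries are dominated by
cellular reads, which buffers totals. The placement-level analysis scripts
show this coupling (and say so); the differential-activity operating
characteristics are therefore measured on the abundance-level generator
(`simulate_expression_matrix`), which plants month-constant negative
binomial means for null vOTUs and a fold-10 peak month for seasonal ones
at 12 samples/month — isolating the statistical procedure from the
normalization artifact.

## Numerical choices and degenerate inputs

- Lower medians and integer depths throughout; no interpolation.
- Greedy clustering ties (equal lengths) break lexicographically; equal
  length AF pairs use the lexicographically smaller id's AF.
- PERMANOVA with a zero within-group SS yields F = ∞; permutations
  re-creating the partition tie at ∞, so the minimal attainable p is only
  reached when no permutation does.
- Bray–Curtis on two all-zero vectors, empty coverage intervals, empty
  p-value lists, empty UniFrac datasets, unrooted trees, month-mismatched
  designs and sub-2-sample groups are all explicit errors, not NaNs.
- All stochastic code paths take a seed or Generator; identical seeds give
  bit-identical outputs (placement tables, FASTA/GFF bytes, permutation
  p-values).

## Problem sizes

The validation experiments use 100 random coverage sets (≤ 5 kbp, ≤ 1000
reads), 100 random clustering instances (≤ 30 sequences), 50 random trees
(≤ 32 tips), a 40-genome noiseless round-trip, a 200-genome noisy
round-trip at 5× gene depth, 500 PERMANOVA null simulations at 999
permutations, 100 FDR replicates of 1000 tests, and a 200-vOTU × 48-sample
differential-activity recovery. The analysis scripts run a 60-genome
community over the full 96-library design at 20k reads/library. These
sizes were chosen so the whole suite runs on a laptop-class machine in
minutes while keeping every statistical check adequately powered.

## Known limitations

- The internal ANI aligner is ungapped; indel-rich divergence
  underestimates AF. Use external alignment records for real data.
- Provirus flanks are not treated specially; classification assumes inputs
  are already boundary-refined viral regions.
- PERMANOVA has no strata/blocking; repeated-measures designs inflate its
  type-I error.
- Host "ecological strategy" grouping is a straight join on a provided
  host→strategy table; no inference is attempted.
- Tree building, virus detection, completeness estimation and host
  prediction are out of scope: trees, completeness and labels are inputs.
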