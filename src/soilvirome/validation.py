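"""Validation experiments: brute-force oracles and simulation calibrations.

Each oracle here is an intentionally naive, independent re-derivation of a
pipeline quantity (per-base counting, exhaustive clade enumeration, direct
branch enumeration, literal greedy re-tracing). The experiment functions
run the pipeline implementation against its oracle, or measure operating
characteristics (null calibration, recovery, realized FDR) on planted
synthetic data, and return plain numbers. They are shared by the test suite
and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from soilvirome import activity, clades, stats, synth, workflow
from soilvirome.catalog import PairwiseAlignmentRecord, VOTU, greedy_cluster
from soilvirome.coverage import ReadPlacement, accumulate_coverage, rpkm

__all__ = [
    "brute_force_coverage",
    "coverage_oracle_experiment",
    "greedy_cluster_oracle",
    "random_cluster_instance",
    "clustering_oracle_experiment",
    "propagate_oracle",
    "random_annotated_tree",
    "propagation_oracle_experiment",
    "unifrac_bruteforce",
    "classifier_roundtrip_noiseless",
    "classifier_noisy_balanced_accuracy",
    "permanova_null_calibration",
    "storey_fdr_experiment",
    "seasonal_recovery_experiment",
    "seasonal_null_experiment",
    "rpkm_contract_check",
]


# --------------------------------------------------------------------------
# coverage


def brute_force_coverage(
    placements: Sequence[ReadPlacement], length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-base counting oracle: walk every read over every position."""
    plus = np.zeros(length, dtype=np.int64)
    minus = np.zeros(length, dtype=np.int64)
    for p in placements:
        target = plus if p.strand == "+" else minus
        for pos in range(p.start, p.end + 1):
            target[pos - 1] += 1
    return plus, minus


def coverage_oracle_experiment(n_sets: int = 100, seed: int = 0) -> dict[str, float]:
    """Compare the coverage engine with the per-base counter on random sets."""
    rng = np.random.default_rng(seed)
    agree = 0
    for i in range(n_sets):
        length = int(rng.integers(200, 5001))
        n_reads = int(rng.integers(1, 1001))
        placements = []
        for r in range(n_reads):
            start = int(rng.integers(1, length + 1))
            end = min(start + int(rng.integers(1, 151)) - 1, length)
            strand = "+" if rng.random() < 0.5 else "-"
            placements.append(ReadPlacement(f"r{r}", "c", start, end, strand, "lib"))
        cov = accumulate_coverage(placements, {"c": length})[("c", "lib")]
        plus, minus = brute_force_coverage(placements, length)
        if np.array_equal(cov.depth_plus, plus) and np.array_equal(cov.depth_minus, minus):
            agree += 1
    return {"n_sets": n_sets, "n_agree": agree, "agreement": agree / n_sets}


# --------------------------------------------------------------------------
# clustering


def greedy_cluster_oracle(
    records: Sequence[PairwiseAlignmentRecord],
    lengths: Mapping[str, int],
    min_ani: float = 95.0,
    min_af: float = 85.0,
) -> list[tuple[str, tuple[str, ...]]]:
    """Literal greedy re-trace: repeatedly pick the longest unplaced contig,
    attach it to the earliest qualifying seed, else open a new cluster."""
    by_pair: dict[tuple[str, str], PairwiseAlignmentRecord] = {}
    for rec in records:
        by_pair[(rec.query, rec.target)] = rec
        by_pair[(rec.target, rec.query)] = rec
    remaining = sorted(lengths, key=lambda c: (-lengths[c], c))
    clusters: list[list[str]] = []
    for contig in remaining:
        home = None
        for cluster in clusters:
            seed = cluster[0]
            rec = by_pair.get((contig, seed))
            if rec is None:
                continue
            if lengths[contig] < lengths[seed]:
                shorter = contig
            elif lengths[seed] < lengths[contig]:
                shorter = seed
            else:
                shorter = min(contig, seed)
            af = rec.af_query if rec.query == shorter else rec.af_target
            if rec.ani >= min_ani and af >= min_af:
                home = cluster
                break
        if home is None:
            clusters.append([contig])
        else:
            home.append(contig)
    return [(c[0], tuple(sorted(c))) for c in clusters]


@dataclass
class _FakeContig:
    id: str
    length: int


def random_cluster_instance(
    rng: np.random.Generator, max_n: int = 30
) -> tuple[list[PairwiseAlignmentRecord], dict[str, int]]:
    """Random ANI/AF records over contigs with random (possibly tied) lengths."""
    n = int(rng.integers(2, max_n + 1))
    lengths = {f"c{i:02d}": int(rng.integers(3, 20)) * 1000 for i in range(n)}
    ids = list(lengths)
    records = []
    for a, b in combinations(ids, 2):
        if rng.random() < 0.5:
            continue  # unreported pair: below the reporting floor
        records.append(
            PairwiseAlignmentRecord(
                query=a,
                target=b,
                ani=float(rng.uniform(80, 100)),
                af_query=float(rng.uniform(50, 100)),
                af_target=float(rng.uniform(50, 100)),
            )
        )
    return records, lengths


def clustering_oracle_experiment(n_instances: int = 100, seed: int = 0) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    agree = 0
    reps_longest = True
    for _ in range(n_instances):
        records, lengths = random_cluster_instance(rng)
        contigs = [_FakeContig(i, l) for i, l in lengths.items()]
        votus = greedy_cluster(records, contigs)
        got = sorted((v.representative, tuple(sorted(v.members))) for v in votus)
        expected = sorted(greedy_cluster_oracle(records, lengths))
        if got == expected:
            agree += 1
        for v in votus:
            if any(lengths[m] > lengths[v.representative] for m in v.members):
                reps_longest = False
    return {
        "n_instances": n_instances,
        "n_agree": agree,
        "agreement": agree / n_instances,
        "representatives_always_longest": float(reps_longest),
    }


# --------------------------------------------------------------------------
# clade propagation


def propagate_oracle(
    tree: dendropy.Tree, reference_values: Mapping[str, str]
) -> dict[str, str | None]:
    """Exhaustive oracle: enumerate every clade as a leaf-label set, then for
    each query tip take the smallest clade containing it and any annotated
    reference, and apply the unanimity rule."""
    clades_list: list[set[str]] = []
    for node in tree.preorder_internal_node_iter():
        leaves = {
            (lf.taxon.label if lf.taxon else lf.label) for lf in node.leaf_iter()
        }
        clades_list.append(leaves)
    all_tips = {lf.taxon.label if lf.taxon else lf.label for lf in tree.leaf_node_iter()}
    out: dict[str, str | None] = {}
    for tip in sorted(all_tips - set(reference_values)):
        candidates = [
            c
            for c in clades_list
            if tip in c and len(c) < len(all_tips) + 1 and any(r in c for r in reference_values)
        ]
        # smallest clade containing the tip and >=1 annotated reference
        candidates = [c for c in candidates if c != {tip}]
        if not candidates:
            out[tip] = None
            continue
        nearest = min(candidates, key=len)
        vals = {reference_values[r] for r in reference_values if r in nearest}
        out[tip] = vals.pop() if len(vals) == 1 else None
    return out


def random_annotated_tree(
    rng: np.random.Generator, max_tips: int = 32, n_taxa: int = 3
) -> tuple[dendropy.Tree, dict[str, str]]:
    """Random rooted tree with a random reference subset annotated from a
    small taxon alphabet (some references left unannotated)."""
    n = int(rng.integers(4, max_tips + 1))
    groups = [f"t{i:02d}" for i in range(n)]
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        merged = f"({groups[i]}:{rng.uniform(0.1, 1):.3f},{groups[j]}:{rng.uniform(0.1, 1):.3f})"
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] + [merged]
    tree = clades.load_tree(data=groups[0] + ";")
    tips = [f"t{i:02d}" for i in range(n)]
    n_refs = int(rng.integers(1, max(2, n // 2)))
    refs = rng.choice(tips, size=n_refs, replace=False)
    values = {}
    for r in refs:
        if rng.random() < 0.8:  # some references lack the annotation field
            values[str(r)] = f"Taxon{int(rng.integers(0, n_taxa))}"
    return tree, values


def propagation_oracle_experiment(n_trees: int = 50, seed: int = 0) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    agree = 0
    total = 0
    for _ in range(n_trees):
        tree, values = random_annotated_tree(rng)
        if not values:
            values = {"t00": "Taxon0"}
        result = clades.propagate_annotations(tree, values)
        expected = propagate_oracle(tree, values)
        total += 1
        if result.assignments == expected:
            agree += 1
    return {"n_trees": total, "n_agree": agree, "agreement": agree / total}


# --------------------------------------------------------------------------
# UniFrac


def unifrac_bruteforce(
    tree: dendropy.Tree, dataset_a, dataset_b, alpha: float = 0.5, mode: str = "generalized"
) -> float:
    """Direct branch enumeration: for every branch, recompute the descending
    tip set from scratch and apply the distance formula term by term."""
    wa = {str(k): float(v) for k, v in (
        dataset_a.items() if isinstance(dataset_a, Mapping) else [(t, 1.0) for t in dataset_a]
    )}
    wb = {str(k): float(v) for k, v in (
        dataset_b.items() if isinstance(dataset_b, Mapping) else [(t, 1.0) for t in dataset_b]
    )}
    ta, tb = sum(wa.values()), sum(wb.values())
    num = den = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None or not node.edge.length:
            continue
        below = {lf.taxon.label if lf.taxon else lf.label for lf in node.leaf_iter()}
        p = sum(w for t, w in wa.items() if t in below) / ta
        q = sum(w for t, w in wb.items() if t in below) / tb
        b = node.edge.length
        if mode == "unweighted":
            if p > 0 or q > 0:
                den += b
                if (p > 0) != (q > 0):
                    num += b
        else:
            if p + q > 0:
                w = b * (p + q) ** alpha
                den += w
                num += w * abs(p - q) / (p + q)
    return num / den if den else 0.0


# --------------------------------------------------------------------------
# classifier round-trips


def _roundtrip_community(
    n: int, seed: int, molecule_mix: float, design: synth.CommunityDesign
):
    contigs, genes = synth.generate_genomes(
        n, length_range=(5000, 12000), molecule_mix=molecule_mix, seed=seed
    )
    truth = synth.plant_truth(contigs, genes, design, seed=seed + 1)
    return contigs, genes, truth


def classifier_roundtrip_noiseless(n: int = 40, seed: int = 0) -> dict[str, float]:
    """Noiseless simulation → classification must equal the planted truth
    for 100% of vOTU-month pairs (DNA and ssRNA)."""
    design = synth.CommunityDesign(depths=("0-5cm",), locations=("up",), replicates_per_cell=1)
    contigs, genes, truth = _roundtrip_community(n, seed, molecule_mix=0.3, design=design)
    placements, libraries = synth.simulate_placements(
        truth, design, contigs, genes, seed=seed + 2, noiseless=True
    )
    calls = workflow.classify_months(placements, libraries, contigs, genes)
    expected = synth.truth_status_table(truth).set_index(["votu_id", "month"])["true_status"]
    n_match = 0
    total = 0
    for call in calls:
        total += 1
        if expected.loc[(call.votu_id, call.unit)] == call.status:
            n_match += 1
    return {"n_pairs": total, "n_match": n_match, "accuracy": n_match / total}


def classifier_noisy_balanced_accuracy(
    n: int = 200, depth_per_active_gene: float = 5.0, seed: int = 0
) -> dict[str, float]:
    """Balanced accuracy of the DNA active-vs-inactive call under
    negative-binomial noise at the given mean expressed-gene depth."""
    design = synth.CommunityDesign(
        depths=("0-5cm",),
        locations=("up",),
        replicates_per_cell=2,
        library_size_mean=30_000,
    )
    contigs, genes, truth = _roundtrip_community(n, seed, molecule_mix=0.0, design=design)
    placements, libraries = synth.simulate_placements(
        truth,
        design,
        contigs,
        genes,
        depth_per_active_gene=depth_per_active_gene,
        seed=seed + 2,
        noiseless=False,
    )
    calls = workflow.classify_months(placements, libraries, contigs, genes)
    expected = synth.truth_status_table(truth).set_index(["votu_id", "month"])["true_status"]
    tp = tn = fp = fn = 0
    for call in calls:
        truth_active = expected.loc[(call.votu_id, call.unit)] in ("active", "active-lytic")
        pred_active = call.status in ("active", "active-lytic")
        if truth_active and pred_active:
            tp += 1
        elif truth_active:
            fn += 1
        elif pred_active:
            fp += 1
        else:
            tn += 1
    sens = tp / (tp + fn) if tp + fn else 1.0
    spec = tn / (tn + fp) if tn + fp else 1.0
    return {
        "n_votu_months": tp + tn + fp + fn,
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": (sens + spec) / 2,
    }


# --------------------------------------------------------------------------
# statistics calibrations


def permanova_null_calibration(
    n_sims: int = 500,
    n_per_group: int = 10,
    n_features: int = 30,
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Type-I error of PERMANOVA under exchangeable labels.

    Two equal groups of lognormal abundance profiles with no group effect;
    Bray–Curtis distances; rejection rate at ``alpha`` should sit near
    ``alpha``.
    """
    rng = np.random.default_rng(seed)
    labels = ["a"] * n_per_group + ["b"] * n_per_group
    rejections = 0
    for _ in range(n_sims):
        profiles = rng.lognormal(0.0, 1.0, size=(2 * n_per_group, n_features))
        mat = pd.DataFrame(profiles.T)
        dist = stats.bray_curtis_matrix(mat)
        res = stats.permanova(dist, labels, n_permutations=n_permutations, seed=rng)
        if res.p_value <= alpha:
            rejections += 1
    return {"n_sims": n_sims, "rejection_rate": rejections / n_sims, "alpha": alpha}


def storey_fdr_experiment(
    n_reps: int = 100,
    m: int = 1000,
    null_fraction: float = 0.8,
    effect: float = 3.0,
    q_cut: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Realized FDR of Storey q-values on mixtures of null and shifted tests."""
    rng = np.random.default_rng(seed)
    n_null = int(m * null_fraction)
    n_alt = m - n_null
    fdrs = []
    from scipy.stats import norm

    for _ in range(n_reps):
        p_null = rng.uniform(0, 1, size=n_null)
        z_alt = rng.normal(effect, 1.0, size=n_alt)
        p_alt = norm.sf(z_alt)
        p = np.concatenate([p_null, p_alt])
        q = stats.storey_qvalues(p)
        discoveries = q < q_cut
        n_disc = discoveries.sum()
        false_disc = discoveries[:n_null].sum()
        fdrs.append(false_disc / n_disc if n_disc else 0.0)
    return {"n_reps": n_reps, "realized_fdr": float(np.mean(fdrs)), "q_cut": q_cut}


def seasonal_recovery_experiment(seed: int = 0) -> dict[str, float]:
    """Sensitivity and realized FDR of the differential-activity procedure on
    a community where 5% of active vOTUs have strong month-specific
    schedules (the planted seasonal subset)."""
    matrix, meta, seasonal = synth.simulate_expression_matrix(seed=seed)
    results = stats.differential_activity(matrix, meta)
    flagged = {r.votu_id for r in results if r.seasonal}
    tp = len(flagged & seasonal)
    fp = len(flagged - seasonal)
    sens = tp / len(seasonal) if seasonal else 1.0
    fdr = fp / len(flagged) if flagged else 0.0
    return {
        "n_votus": matrix.shape[0],
        "n_seasonal_planted": len(seasonal),
        "n_flagged": len(flagged),
        "sensitivity": sens,
        "realized_fdr": fdr,
    }


def seasonal_null_experiment(seed: int = 0) -> dict[str, float]:
    """Seasonal-flag rate when no month effect is planted (should be ≤ α)."""
    matrix, meta, _ = synth.simulate_expression_matrix(peak_fold=1.0, seed=seed)
    results = stats.differential_activity(matrix, meta)
    n_flagged = sum(r.seasonal for r in results)
    return {"n_votus": matrix.shape[0], "flag_rate": n_flagged / max(1, len(results))}


def rpkm_contract_check() -> dict[str, float]:
    """Closed-form RPKM arithmetic and the 10% breadth mask."""
    exact = rpkm(100, 10_000, 1_000_000, breadth_pct=50.0)
    masked = rpkm(100, 10_000, 1_000_000, breadth_pct=9.9)
    zero = rpkm(0, 10_000, 1_000_000, breadth_pct=100.0)
    return {"rpkm_example": exact, "rpkm_below_mask": masked, "rpkm_zero_reads": zero}
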