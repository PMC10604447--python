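"""Phylogeny-based annotation propagation and UniFrac-family distances.

Rooted marker-gene trees (e.g. RdRP phylogenies rooted on reverse
transcriptases) carry a mix of *reference* tips with known taxon/host labels
and *query* tips from the study. After contracting branches with support
below a threshold (default 50), each query tip inherits a label from the
most recent ancestral clade whose annotated references are unanimous for
that label; if the nearest clade containing any annotated reference is not
unanimous, the query stays unassigned. Assignments on cluster
representatives are then copied verbatim to all cluster members.

The same trees support community distances between datasets of tips:
unweighted UniFrac (unique / union branch length over the tips present in
either dataset) and the generalized form

    d = Σ_i b_i (p_i + q_i)^α |p_i − q_i| / (p_i + q_i)  ÷  Σ_i b_i (p_i + q_i)^α

over branches with p_i + q_i > 0, where p_i, q_i are the proportions of each
dataset descending from branch i and α (default 0.5) controls the weight on
abundant lineages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "PropagationResult",
    "load_tree",
    "node_support",
    "collapse_low_support",
    "propagate_annotations",
    "propagate_to_cluster_members",
    "unifrac_distance",
    "pairwise_unifrac",
]

logger = logging.getLogger(__name__)


@dataclass
class PropagationResult:
    """Per-query-tip assignment and the size of the supporting clade."""

    assignments: dict[str, str | None] = field(default_factory=dict)
    clade_size: dict[str, int] = field(default_factory=dict)


def load_tree(path: str | Path | None = None, data: str | None = None) -> dendropy.Tree:
    """Load a rooted Newick tree (supports as internal-node labels)."""
    kwargs = dict(
        schema="newick",
        rooting="force-rooted",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if data is not None:
        return dendropy.Tree.get(data=data, **kwargs)
    return dendropy.Tree.get(path=str(path), **kwargs)


def node_support(node: dendropy.Node) -> float | None:
    """Branch support of an internal node, parsed from its label."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def collapse_low_support(tree: dendropy.Tree, threshold: float = 50.0) -> dendropy.Tree:
    """Contract internal edges whose child-node support is below ``threshold``.

    Children of a contracted node are reattached to its parent, keeping their
    own edge lengths; tips are never removed. Nodes without a parseable
    support value are kept. Returns a new tree.
    """
    out = tree.clone(depth=1)
    changed = True
    while changed:
        changed = False
        for node in list(out.postorder_internal_node_iter(exclude_seed_node=True)):
            if node.is_leaf():
                continue
            support = node_support(node)
            if support is not None and support < threshold:
                parent = node.parent_node
                for child in list(node.child_nodes()):
                    node.remove_child(child)
                    parent.add_child(child)
                parent.remove_child(node)
                changed = True
    return out


def _require_rooted(tree: dendropy.Tree) -> None:
    if tree.is_rooted is False:
        raise ValueError("tree must be rooted (re-read with rooting='force-rooted' if intended)")


def propagate_annotations(
    tree: dendropy.Tree,
    reference_values: Mapping[str, str],
    query_tips: Iterable[str] | None = None,
) -> PropagationResult:
    """Assign labels to query tips by the most-recent-unanimous-clade rule.

    ``reference_values`` maps reference tip labels to their annotation for
    one field (taxon or host); reference tips lacking an annotation for the
    field are simply omitted and neither assign nor break unanimity. Query
    tips default to all tips not present in ``reference_values``.

    For each query tip, ancestors are walked root-ward; the first ancestor
    whose clade contains ≥1 annotated reference assigns its value if those
    references are unanimous, and blocks the assignment otherwise.
    """
    _require_rooted(tree)
    if not reference_values:
        raise ValueError("at least one annotated reference tip is required")
    # per-node: set of distinct reference values and clade tip count, postorder
    values: dict[dendropy.Node, set[str]] = {}
    tip_counts: dict[dendropy.Node, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            v = reference_values.get(label)
            values[node] = {v} if v is not None else set()
            tip_counts[node] = 1
        else:
            values[node] = set().union(*(values[c] for c in node.child_nodes()))
            tip_counts[node] = sum(tip_counts[c] for c in node.child_nodes())

    tip_nodes = {
        (node.taxon.label if node.taxon else node.label): node
        for node in tree.leaf_node_iter()
    }
    if query_tips is None:
        query_tips = [t for t in tip_nodes if t not in reference_values]

    result = PropagationResult()
    for tip in query_tips:
        node = tip_nodes.get(tip)
        if node is None:
            raise KeyError(f"query tip {tip!r} not found in tree")
        assigned: str | None = None
        size = 0
        ancestor = node.parent_node
        while ancestor is not None:
            vals = values[ancestor]
            if vals:
                if len(vals) == 1:
                    assigned = next(iter(vals))
                    size = tip_counts[ancestor]
                break
            ancestor = ancestor.parent_node
        result.assignments[tip] = assigned
        result.clade_size[tip] = size
    return result


def propagate_to_cluster_members(
    result: Mapping[str, str | None],
    clusters: Mapping[str, Sequence[str]],
) -> dict[str, str | None]:
    """Copy each representative's assignment verbatim to its cluster members."""
    out: dict[str, str | None] = {}
    for rep, members in clusters.items():
        if rep not in result:
            logger.warning("representative %s has no propagation result; members unassigned", rep)
        value = result.get(rep)
        for member in members:
            if member in out:
                raise ValueError(f"member {member!r} listed under two representatives")
            out[member] = value
    return out


def _as_weights(dataset) -> dict[str, float]:
    if isinstance(dataset, Mapping):
        return {str(k): float(v) for k, v in dataset.items() if v > 0}
    return {str(t): 1.0 for t in dataset}


def unifrac_distance(
    tree: dendropy.Tree,
    dataset_a,
    dataset_b,
    alpha: float = 0.5,
    mode: str = "generalized",
) -> float:
    """UniFrac distance between two tip sets / abundance maps on one tree.

    ``mode='unweighted'`` uses presence/absence of tips; ``'generalized'``
    weights branches by dataset proportions raised to ``alpha``.
    """
    wa = _as_weights(dataset_a)
    wb = _as_weights(dataset_b)
    if not wa or not wb:
        raise ValueError("datasets must be non-empty")
    total_a = sum(wa.values())
    total_b = sum(wb.values())

    # per-node descending mass for each dataset
    mass_a: dict[dendropy.Node, float] = {}
    mass_b: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            mass_a[node] = wa.get(label, 0.0)
            mass_b[node] = wb.get(label, 0.0)
        else:
            mass_a[node] = sum(mass_a[c] for c in node.child_nodes())
            mass_b[node] = sum(mass_b[c] for c in node.child_nodes())

    num = 0.0
    den = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        b_len = node.edge.length or 0.0
        if b_len == 0.0:
            continue
        p = mass_a[node] / total_a
        q = mass_b[node] / total_b
        if mode == "unweighted":
            in_a = p > 0
            in_b = q > 0
            if in_a or in_b:
                den += b_len
                if in_a != in_b:
                    num += b_len
        elif mode == "generalized":
            if p + q > 0:
                w = b_len * (p + q) ** alpha
                den += w
                num += w * abs(p - q) / (p + q)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    if den == 0.0:
        return 0.0
    return num / den


def pairwise_unifrac(
    tree: dendropy.Tree,
    datasets: Mapping[str, object],
    alpha: float = 0.5,
    mode: str = "generalized",
) -> pd.DataFrame:
    """Symmetric dataset × dataset UniFrac distance matrix."""
    names = sorted(datasets)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = unifrac_distance(tree, datasets[a], datasets[b], alpha=alpha, mode=mode)
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat
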