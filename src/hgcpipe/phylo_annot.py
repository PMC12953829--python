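"""Gene-tree plumbing: outgroup rerooting, monophyly, clade summaries.

Trees are dendropy objects read from newick.  Rerooting places the root at
the midpoint of the edge separating the outgroup from the ingroup, which
preserves the leaf set and all unrooted pairwise path lengths.  Clade
summaries join per-sample relative abundance onto leaf sets and report mean
root-to-tip branch lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CladeDefinition:
    clade_name: str
    members: list[str]


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def _taxa_for(tree: dendropy.Tree, labels: Iterable[str]) -> list[dendropy.Taxon]:
    labels = list(labels)
    known = {t.label: t for t in tree.taxon_namespace}
    missing = [l for l in labels if l not in known]
    if missing:
        raise ValueError(f"labels absent from tree: {sorted(missing)}")
    return [known[l] for l in labels]


def _bipartition_separates(tree: dendropy.Tree, labels: set[str]):
    """Find an edge whose bipartition splits exactly ``labels`` from the rest.

    Returns the edge, or None.  Works in the unrooted sense: an edge matches
    if the leaves on its child side equal the set or its complement.
    """
    all_leaves = leaf_labels(tree)
    target = frozenset(labels)
    complement = frozenset(all_leaves - labels)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if below == target or below == complement:
            return node.edge
    return None


def is_monophyletic(tree: dendropy.Tree, leaf_set: Iterable[str]) -> bool:
    """True iff some edge bipartitions exactly ``leaf_set`` from the rest."""
    labels = set(leaf_set)
    if not labels:
        raise ValueError("empty leaf set")
    all_leaves = leaf_labels(tree)
    unknown = labels - all_leaves
    if unknown:
        raise ValueError(f"labels absent from tree: {sorted(unknown)}")
    if labels == all_leaves:
        return True
    return _bipartition_separates(tree, labels) is not None


def reroot_on_outgroup(
    tree: dendropy.Tree,
    outgroup_leaves: Sequence[str],
    inplace: bool = False,
) -> tuple[dendropy.Tree, bool]:
    """Root the tree on the branch separating the outgroup from the rest.

    The root is placed at the midpoint of that branch, so the leaf set and
    all unrooted pairwise path lengths are unchanged.  Returns the rooted
    tree and a flag telling whether the outgroup was monophyletic in the
    unrooted topology; when it is not, a warning is logged and the tree is
    rooted on the outgroup MRCA edge anyway.
    """
    if not outgroup_leaves:
        raise ValueError("outgroup is empty")
    labels = set(outgroup_leaves)
    all_leaves = leaf_labels(tree)
    unknown = labels - all_leaves
    if unknown:
        raise ValueError(f"outgroup leaves absent from tree: {sorted(unknown)}")
    if labels == all_leaves:
        raise ValueError("outgroup cannot contain every leaf")
    if not inplace:
        tree = tree.clone(depth=1)

    # already rooted on the outgroup edge -> idempotent no-op
    root_children = tree.seed_node.child_nodes()
    if len(root_children) == 2:
        for child in root_children:
            below = {lf.taxon.label for lf in child.leaf_iter()}
            if below == labels:
                tree.is_rooted = True
                return tree, True

    edge = _bipartition_separates(tree, labels)
    monophyletic = edge is not None
    if edge is None:
        logger.warning(
            "outgroup %s is not monophyletic; rooting on its MRCA edge",
            sorted(labels),
        )
        tree.is_rooted = True  # mrca is evaluated relative to the current root
        mrca = tree.mrca(taxa=_taxa_for(tree, labels))
        if mrca is tree.seed_node:
            # MRCA is the current root; fall back to one outgroup pendant edge
            mrca = next(
                lf for lf in tree.leaf_node_iter() if lf.taxon.label in labels
            )
        edge = mrca.edge

    length = edge.length if edge.length is not None else 0.0
    tree.reroot_at_edge(
        edge,
        length1=length / 2.0,
        length2=length / 2.0,
        update_bipartitions=False,
    )
    tree.is_rooted = True
    return tree, monophyletic


def path_length_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf-by-leaf patristic distance matrix (sorted label order)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(leaf_labels(tree))
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    data = [
        [pdm.patristic_distance(taxa[a], taxa[b]) for b in labels] for a in labels
    ]
    return pd.DataFrame(data, index=labels, columns=labels)


def root_to_tip_lengths(tree: dendropy.Tree) -> dict[str, float]:
    out = {}
    for lf in tree.leaf_node_iter():
        out[lf.taxon.label] = lf.distance_from_root()
    return out


def clade_summary(
    tree: dendropy.Tree,
    clades: Sequence[CladeDefinition] | Mapping[str, Sequence[str]],
    abundance: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-clade abundance sums and branch-length statistics.

    Returns ``(stats, clade_abundance)``: stats has one row per clade with
    member count, mean root-to-tip length and its descending rank (1 =
    longest); clade_abundance is long-format (clade_name, sample_id,
    rel_abundance_pct) summing member genes per sample.  Members missing
    from the abundance table contribute 0 with a warning.
    """
    if isinstance(clades, Mapping):
        clades = [CladeDefinition(k, list(v)) for k, v in clades.items()]
    all_leaves = leaf_labels(tree)
    tips = root_to_tip_lengths(tree)
    stat_rows = []
    ab_rows = []
    for clade in clades:
        missing = set(clade.members) - all_leaves
        if missing:
            raise ValueError(
                f"clade {clade.clade_name}: members absent from tree: {sorted(missing)}"
            )
        mean_tip = sum(tips[m] for m in clade.members) / len(clade.members)
        stat_rows.append((clade.clade_name, len(clade.members), mean_tip))
        if abundance is not None:
            present = set(abundance["gene_id"])
            for m in set(clade.members) - present:
                logger.warning(
                    "clade %s member %s missing from abundance table; treated as 0",
                    clade.clade_name, m,
                )
            sub = abundance[abundance["gene_id"].isin(clade.members)]
            for sample_id in sorted(abundance["sample_id"].unique()):
                total = float(
                    sub.loc[sub["sample_id"] == sample_id, "rel_abundance_pct"].sum()
                )
                ab_rows.append((clade.clade_name, sample_id, total))
    stats = pd.DataFrame(
        stat_rows, columns=["clade_name", "n_members", "mean_root_to_tip"]
    )
    stats["length_rank"] = (
        stats["mean_root_to_tip"].rank(ascending=False, method="min").astype(int)
    )
    clade_ab = pd.DataFrame(
        ab_rows, columns=["clade_name", "sample_id", "rel_abundance_pct"]
    )
    return stats, clade_ab


def total_tree_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.edges())


def annotate_leaves(
    tree: dendropy.Tree,
    taxonomy: Mapping[str, str],
    abundance: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Leaf annotation table: taxonomy plus per-sample abundance columns."""
    rows = []
    for label in sorted(leaf_labels(tree)):
        rows.append((label, taxonomy.get(label, "unassigned")))
    out = pd.DataFrame(rows, columns=["leaf_id", "taxonomy_label"])
    if abundance is not None:
        wide = abundance.pivot_table(
            index="gene_id", columns="sample_id",
            values="rel_abundance_pct", aggfunc="sum", fill_value=0.0,
        )
        out = out.merge(wide, left_on="leaf_id", right_index=True, how="left")
        out = out.fillna(0.0)
    return out
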