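"""Newick I/O, 50% majority-rule consensus, and the species correlation
structure implied by a rooted, branch-lengthed tree.

Consensus semantics: a non-trivial clade is retained iff its frequency over
the tree sample *strictly* exceeds the cutoff (ties collapse to
polytomies).  Consensus branch lengths are the mean (or median) of the
corresponding branch over the trees that contain the clade.

The correlation matrix entry for two species is the depth of their most
recent common ancestor divided by the maximum root-to-tip depth, i.e. the
shared fraction of their root-to-tip paths; this is positive semidefinite
by construction and well defined for polytomies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "PhyloCorrelation",
    "parse_newick",
    "parse_newick_list",
    "majority_rule_consensus",
    "correlation_matrix",
]

log = logging.getLogger(__name__)


@dataclass
class Phylogeny:
    """A rooted tree with unique tip labels and non-negative branch lengths."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def clades(self) -> dict[frozenset, float]:
        """Map each clade (frozenset of tip labels) to its subtending branch
        length; root clade length is 0 if absent."""
        out: dict[frozenset, float] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                tips = frozenset([node.taxon.label])
            else:
                tips = frozenset().union(
                    *(c._clade_tips for c in node.child_nodes())
                )
            node._clade_tips = tips
            out[tips] = node.edge.length if node.edge.length is not None else 0.0
        return out

    def depths(self) -> dict[frozenset, float]:
        """Root-to-node path length for every clade."""
        out: dict[frozenset, float] = {}
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                tips = frozenset([node.taxon.label])
            else:
                tips = frozenset().union(*(c._clade_tips for c in node.child_nodes()))
            node._clade_tips = tips
            out[tips] = node.root_distance
        return out


@dataclass
class PhyloCorrelation:
    """Species-by-species shared-path correlation matrix (unit diagonal)."""

    species: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        C = self.matrix
        if C.shape != (len(self.species), len(self.species)):
            raise ValueError("matrix shape does not match species list")
        if not np.allclose(C, C.T):
            raise ValueError("matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.species, columns=self.species)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="species_id", lineterminator="\n")


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick tree, preserving topology and branch lengths."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc
    tree.is_rooted = True
    return Phylogeny(tree)


def parse_newick_list(text: str) -> list[Phylogeny]:
    """Parse a multi-tree Newick document (one tree per semicolon)."""
    try:
        trees = dendropy.TreeList.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc
    if not trees:
        raise ValueError("no trees found")
    out = []
    for t in trees:
        t.is_rooted = True
        out.append(Phylogeny(t))
    return out


def majority_rule_consensus(
    trees: Sequence[Phylogeny],
    cutoff: float = 0.5,
    branch_lengths: str = "mean",
) -> Phylogeny:
    """Strict-majority-rule consensus of a sample of rooted trees.

    Retains exactly the non-trivial clades whose frequency strictly exceeds
    ``cutoff``; retained clades are pairwise compatible for any cutoff
    >= 0.5 so the consensus tree is well defined.  Branch lengths are the
    ``mean`` or ``median`` of the clade's subtending branch over the trees
    that contain it; tip branches average over all trees.
    """
    if not trees:
        raise ValueError("need at least one tree")
    if not 0.5 <= cutoff < 1.0:
        raise ValueError("cutoff must be in [0.5, 1)")
    if branch_lengths not in ("mean", "median"):
        raise ValueError("branch_lengths must be 'mean' or 'median'")
    tip_sets = [frozenset(t.tip_labels) for t in trees]
    if any(s != tip_sets[0] for s in tip_sets[1:]):
        raise ValueError("trees have mismatched tip sets")
    all_tips = tip_sets[0]
    n = len(trees)

    counts: dict[frozenset, int] = {}
    lengths: dict[frozenset, list[float]] = {}
    for t in trees:
        for clade, length in t.clades().items():
            counts[clade] = counts.get(clade, 0) + 1
            lengths.setdefault(clade, []).append(length)

    agg = np.mean if branch_lengths == "mean" else np.median

    retained = [
        clade
        for clade, c in counts.items()
        if 1 < len(clade) < len(all_tips) and c / n > cutoff
    ]
    # build nested structure: parent of each clade = smallest retained superset
    nodes: dict[frozenset, dendropy.Node] = {}
    taxon_ns = dendropy.TaxonNamespace(sorted(all_tips))
    root = dendropy.Node()
    nodes[all_tips] = root
    for clade in sorted(retained, key=len, reverse=True):
        node = dendropy.Node()
        node.edge.length = float(agg(lengths[clade]))
        nodes[clade] = node
    # attach internal nodes under their minimal superset (process large->small)
    for clade in sorted(retained, key=len, reverse=True):
        parent = min(
            (c for c in nodes if c != clade and clade <= c), key=len
        )
        nodes[parent].add_child(nodes[clade])
    for tip in sorted(all_tips):
        leaf = dendropy.Node()
        leaf.taxon = taxon_ns.get_taxon(tip)
        leaf.edge.length = float(agg(lengths[frozenset([tip])]))
        parent = min((c for c in nodes if tip in c), key=len)
        nodes[parent].add_child(leaf)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tree.is_rooted = True
    return Phylogeny(tree)


def correlation_matrix(
    phylogeny: Phylogeny, species: Sequence[str]
) -> PhyloCorrelation:
    """Shared root-to-tip path length of each species pair, scaled by the
    maximum root-to-tip depth of the tree after pruning to ``species``."""
    species = list(species)
    tips = set(phylogeny.tip_labels)
    missing = sorted(set(species) - tips)
    if missing:
        raise ValueError(f"species absent from tree: {missing}")
    tree = phylogeny.tree.clone(depth=1)
    if set(species) != tips:
        tree.retain_taxa_with_labels(species)
    pruned = Phylogeny(tree)

    depths = pruned.depths()
    height = max(d for clade, d in depths.items() if len(clade) == 1)
    if not height > 0:
        raise ValueError("tree height must be positive")

    idx = {sp: i for i, sp in enumerate(species)}
    k = len(species)
    C = np.zeros((k, k))
    # MRCA depth of a cross-child pair at a node is that node's depth
    for node in pruned.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        children_tipsets = []
        for child in node.child_nodes():
            children_tipsets.append([l.taxon.label for l in child.leaf_iter()])
        d = depths[node._clade_tips] / height
        for a in range(len(children_tipsets)):
            for b in range(a + 1, len(children_tipsets)):
                for si in children_tipsets[a]:
                    for sj in children_tipsets[b]:
                        if si in idx and sj in idx:
                            C[idx[si], idx[sj]] = d
                            C[idx[sj], idx[si]] = d
    np.fill_diagonal(C, 1.0)
    zero_pairs = int(np.sum(np.isclose(C, 1.0)) - k) // 2
    if zero_pairs:
        log.warning("%d species pairs at zero phylogenetic distance", zero_pairs)
    return PhyloCorrelation(species, C)
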