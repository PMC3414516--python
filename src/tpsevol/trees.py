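"""Phylogenetic tree wrapper used by every tree-aware stage.

A thin layer over dendropy: Newick IO, leaf bookkeeping, clade tags
(A / B1 / B2 style branch classes supplied as a sidecar mapping), and the
rooted/unrooted handling the likelihood engine needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .errors import TreeDataMismatchError


@dataclass
class PhyloTree:
    """Topology + branch lengths + optional support and clade tags."""

    tree: dendropy.Tree
    clade_tags: dict[str, frozenset[str]] = field(default_factory=dict)

    # ------------------------------------------------------------ basics
    @classmethod
    def from_newick(
        cls, newick: str, clade_tags: dict | None = None
    ) -> "PhyloTree":
        t = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(
            tree=t,
            clade_tags={
                k: frozenset(v) for k, v in (clade_tags or {}).items()
            },
        )

    @classmethod
    def from_newick_file(cls, path, clade_tags: dict | None = None):
        with open(path) as fh:
            return cls.from_newick(fh.read(), clade_tags)

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True
        ).strip()

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            tree=self.tree.clone(depth=1), clade_tags=dict(self.clade_tags)
        )

    @property
    def leaf_ids(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.tree.leaf_nodes())

    # -------------------------------------------------------- unrooting
    def derooted(self) -> "PhyloTree":
        """Copy with any basal bifurcation collapsed (2n-3 free edges).

        An unrooted representation avoids the non-identifiable split of
        one edge into two at a rooted tree's basal node.
        """
        out = self.copy()
        seed = out.tree.seed_node
        children = seed.child_nodes()
        if len(children) == 2:
            keep, merge = children
            if merge.is_leaf() and not keep.is_leaf():
                keep, merge = merge, keep
            extra = (keep.edge.length or 0.0) + (merge.edge.length or 0.0)
            if merge.is_leaf():
                # 2-leaf tree: nothing to collapse
                return out
            for gc in list(merge.child_nodes()):
                merge.remove_child(gc)
                seed.add_child(gc)
            seed.remove_child(merge)
            keep.edge.length = extra
        out.tree.update_bipartitions(
            suppress_unifurcations=True, collapse_unrooted_basal_bifurcation=False
        )
        return out

    # ----------------------------------------------------------- clades
    def clade_leaf_set(self, tag: str) -> frozenset[str]:
        if tag not in self.clade_tags:
            raise TreeDataMismatchError(f"unknown clade tag {tag!r}")
        missing = self.clade_tags[tag] - set(self.leaf_ids)
        if missing:
            raise TreeDataMismatchError(
                f"clade {tag} lists leaves absent from the tree: "
                f"{sorted(missing)}"
            )
        return self.clade_tags[tag]

    def subtree_for_leaves(self, keep: list[str]) -> "PhyloTree":
        """Pruned copy retaining only the named leaves."""
        out = self.copy()
        taxa = [
            t for t in out.tree.taxon_namespace if t.label in set(keep)
        ]
        out.tree.retain_taxa(taxa)
        out.clade_tags = {
            k: frozenset(v & set(keep)) for k, v in out.clade_tags.items()
        }
        return out

    def bipartition_sets(self) -> set[frozenset[str]]:
        """Leaf-set encodings of all internal edges (unrooted splits)."""
        all_leaves = frozenset(self.leaf_ids)
        out = set()
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node or node.is_leaf():
                continue
            below = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            if 1 < len(below) < len(all_leaves) - 1:
                out.add(min(below, all_leaves - below, key=sorted))
        return out
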