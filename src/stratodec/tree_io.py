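"""Time-calibrated trees: Newick input, node ages, annotated NEXUS output.

Trees are rooted, binary and ultrametric, with branch lengths in Myr and
node ages measured in Myr before present (tips at age 0).  Parsing is
delegated to dendropy; internally the tree is flattened to arrays indexed
by a postorder node numbering, which is what the pruning engine consumes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy

__all__ = ["TimeTree", "TreeError", "read_newick", "write_annotated_tree"]


class TreeError(ValueError):
    """Invalid tree input (missing lengths, polytomy, non-ultrametric)."""


@dataclass
class TimeTree:
    """Rooted binary ultrametric tree in flat postorder arrays.

    Node ids are postorder positions: every child precedes its parent and
    the root is the last id.  ``children[i]`` is ``None`` for tips, else a
    ``(left, right)`` pair preserving the input child order.  ``labels[i]``
    is the taxon name for tips, ``None`` for internal nodes.
    """

    children: list[tuple[int, int] | None]
    parent: list[int]
    ages: list[float]
    labels: list[str | None]

    @property
    def n_nodes(self) -> int:
        return len(self.ages)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def root_age(self) -> float:
        return self.ages[self.root]

    @property
    def tip_ids(self) -> list[int]:
        return [i for i, c in enumerate(self.children) if c is None]

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_ids]

    @property
    def internal_ids(self) -> list[int]:
        """Internal node ids in postorder (children before parents)."""
        return [i for i, c in enumerate(self.children) if c is not None]

    def branch_length(self, node: int) -> float:
        """Length (Myr) of the branch subtending ``node``."""
        p = self.parent[node]
        if p < 0:
            return 0.0
        return self.ages[p] - self.ages[node]

    def newick(self, annotations: dict[int, str] | None = None) -> str:
        """Newick string; optional ``[&...]`` comment payload per node id."""
        ann = annotations or {}

        def fmt(node: int) -> str:
            kids = self.children[node]
            if kids is None:
                s = self.labels[node] or f"n{node}"
            else:
                s = "(" + ",".join(fmt(k) for k in kids) + ")"
            if node in ann:
                s += f"[&{ann[node]}]"
            p = self.parent[node]
            if p >= 0:
                s += f":{self.ages[p] - self.ages[node]:.12g}"
            return s

        return fmt(self.root) + ";"


def read_newick(
    text: str,
    ultrametric_rtol: float = 1e-6,
    resolve_polytomies: bool = False,
    seed: int | None = None,
) -> TimeTree:
    """Parse a Newick tree with branch lengths into a :class:`TimeTree`.

    Node ages are computed from branch lengths with tips fixed at age 0;
    ultrametricity is verified to relative tolerance ``ultrametric_rtol``
    of the root age.  Polytomies raise :class:`TreeError` unless
    ``resolve_polytomies`` is set, in which case they are resolved randomly
    with zero-length branches under ``seed``.
    """
    dtree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )
    if resolve_polytomies:
        dtree.resolve_polytomies(rng=random.Random(seed))
    # root-to-tip distances to check ultrametricity
    dtree.calc_node_root_distances(return_leaf_distances_only=False)
    leaf_depths = [lf.root_distance for lf in dtree.leaf_node_iter()]
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is None:
            raise TreeError("branch without a length")
    depth = max(leaf_depths)
    if depth <= 0:
        raise TreeError("tree has zero depth")
    if max(leaf_depths) - min(leaf_depths) > ultrametric_rtol * depth:
        raise TreeError(
            f"tree is not ultrametric: tip depths span "
            f"[{min(leaf_depths):.6g}, {max(leaf_depths):.6g}]"
        )

    children: list[tuple[int, int] | None] = []
    parent: list[int] = []
    ages: list[float] = []
    labels: list[str | None] = []
    ids: dict[dendropy.Node, int] = {}
    for nd in dtree.postorder_node_iter():
        kids = nd.child_nodes()
        if len(kids) not in (0, 2):
            raise TreeError(
                f"node with {len(kids)} children: only binary trees are "
                "supported (pass resolve_polytomies=True to resolve randomly)"
            )
        i = len(ages)
        ids[nd] = i
        if kids:
            l, r = ids[kids[0]], ids[kids[1]]
            children.append((l, r))
            # age from descendants keeps parent-child length consistency
            ages.append(max(ages[l] + kids[0].edge.length, ages[r] + kids[1].edge.length))
        else:
            children.append(None)
            ages.append(0.0)
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError("tip without a label")
        labels.append(nd.taxon.label if nd.taxon is not None else None)
    parent = [-1] * len(ages)
    for nd, i in ids.items():
        for k in nd.child_nodes():
            parent[ids[k]] = i
    return TimeTree(children=children, parent=parent, ages=ages, labels=labels)


def write_annotated_tree(tree: TimeTree, annotations: dict[int, str] | None = None) -> str:
    """Serialize to NEXUS with bracketed node comments (e.g. most-probable
    range and its probability).  Stripping the comments and re-reading the
    TREES block recovers the same topology and branch lengths."""
    taxa = tree.tip_labels
    lines = [
        "#NEXUS",
        "BEGIN TAXA;",
        f"    DIMENSIONS NTAX={len(taxa)};",
        "    TAXLABELS " + " ".join(taxa) + ";",
        "END;",
        "BEGIN TREES;",
        "    TREE annotated = " + tree.newick(annotations),
        "END;",
    ]
    return "\n".join(lines) + "\n"
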