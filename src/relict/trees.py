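"""Rooted phylogeny container used throughout the package.

A :class:`Phylogeny` stores a rooted tree in flat arrays (parent pointers,
postorder, per-edge lengths and branch-class tags) which is what the pruning
likelihood and the simulators need. Newick parsing/serialisation is delegated
to dendropy; the flat representation is purely internal.

Branch classes label the *edge above* each node (the root's tag is unused).
The default class for every edge is ``"bg"`` (background).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

DEFAULT_CLASS = "bg"


class Phylogeny:
    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        labels: Sequence[str | None],
        classes: Sequence[str] | None = None,
    ):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        n = len(self.parent)
        if len(self.lengths) != n or len(labels) != n:
            raise ValueError("parent, lengths and labels must have equal length")
        self.labels: list[str | None] = list(labels)
        self.classes: list[str] = list(classes) if classes is not None else [DEFAULT_CLASS] * n
        if len(self.classes) != n:
            raise ValueError("classes must have one entry per node")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for v in range(n):
            p = int(self.parent[v])
            if p >= 0:
                self.children[p].append(v)
        self.postorder = self._postorder()

    # -- basic structure -------------------------------------------------

    def _postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()  # reverse preorder of mirrored children = postorder
        return np.asarray(order, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_indices(self) -> list[int]:
        return [v for v in range(self.n_nodes) if not self.children[v]]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[v] or f"node{v}" for v in self.tip_indices]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        for v in reversed(self.postorder):  # preorder
            p = int(self.parent[v])
            if p >= 0:
                d[v] = d[p] + self.lengths[v]
        return d

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        tip_depths = self.depths()[self.tip_indices]
        span = tip_depths.max() - tip_depths.min()
        return bool(span <= rel_tol * max(tip_depths.max(), 1.0))

    def total_length(self) -> float:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return float(self.lengths[mask].sum())

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), self.lengths.copy(), list(self.labels), list(self.classes))

    def scale(self, factor: float) -> "Phylogeny":
        """Return a copy with all branch lengths multiplied by ``factor``."""
        out = self.copy()
        out.lengths = out.lengths * float(factor)
        out.lengths[out.root] = 0.0
        return out

    def with_height(self, height: float) -> "Phylogeny":
        """Rescale so the maximum root-to-tip depth equals ``height``."""
        cur = self.depths()[self.tip_indices].max()
        if cur <= 0:
            raise ValueError("tree has zero height")
        return self.scale(height / cur)

    # -- branch classes --------------------------------------------------

    def mrca(self, tips: Iterable[str]) -> int:
        want = set(tips)
        have = {lbl: v for v, lbl in zip(self.tip_indices, self.tip_labels)}
        missing = want - set(have)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        nodes = [have[t] for t in want]
        paths = []
        for v in nodes:
            path = []
            while v >= 0:
                path.append(v)
                v = int(self.parent[v])
            paths.append(set(path))
        shared = set.intersection(*paths)
        # deepest shared node
        d = self.depths()
        return max(shared, key=lambda v: d[v])

    def tag_clade(self, tips: Iterable[str], label: str, include_stem: bool = True) -> "Phylogeny":
        """Return a copy with every edge inside the clade spanned by ``tips``
        tagged with branch class ``label`` (optionally including the stem edge
        above the clade's MRCA)."""
        out = self.copy()
        m = out.mrca(tips)
        stack = list(out.children[m])
        inside = []
        while stack:
            v = stack.pop()
            inside.append(v)
            stack.extend(out.children[v])
        for v in inside:
            out.classes[v] = label
        if include_stem and m != out.root:
            out.classes[m] = label
        return out

    def descendant_tips(self, node: int) -> list[int]:
        stack = [node]
        tips = []
        while stack:
            v = stack.pop()
            if not self.children[v]:
                tips.append(v)
            else:
                stack.extend(self.children[v])
        return tips

    # -- dendropy / Newick interop --------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = []
        lengths = []
        labels: list[str | None] = []
        classes = []
        for nd in nodes:
            parent.append(index[id(nd.parent_node)] if nd.parent_node else -1)
            lengths.append(float(nd.edge.length) if nd.edge.length is not None else 0.0)
            if nd.taxon is not None:
                labels.append(nd.taxon.label)
            else:
                labels.append(nd.label)
            cls_tag = None
            if nd.annotations.get_value("class") is not None:
                cls_tag = str(nd.annotations.get_value("class"))
            classes.append(cls_tag or DEFAULT_CLASS)
        return cls(parent, lengths, labels, classes)

    def to_dendropy(self, annotate_classes: bool = False) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = {}
        for v in reversed(self.postorder):  # preorder
            nd = tree.seed_node if int(self.parent[v]) < 0 else dendropy.Node()
            p = int(self.parent[v])
            if p >= 0:
                dnodes[p].add_child(nd)
                nd.edge.length = float(self.lengths[v])
            if not self.children[v]:
                nd.taxon = taxa.new_taxon(self.labels[v] or f"node{v}")
            elif self.labels[v]:
                nd.label = self.labels[v]
            if annotate_classes and p >= 0:
                nd.annotations.add_new("class", self.classes[v])
            dnodes[v] = nd
        return tree

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(schema="newick", suppress_rooting=True).strip()

    # -- rerooting (used for likelihood invariance checks) ---------------

    def reroot_at_edge(self, node: int, fraction: float = 0.5) -> "Phylogeny":
        """Reroot on the edge above ``node``, splitting its length."""
        if node == self.root:
            raise ValueError("cannot reroot on the root's (non-)edge")
        tree = self.to_dendropy()
        dnodes = list(tree.preorder_node_iter())
        target = dnodes[list(reversed(self.postorder)).index(node)]
        length = target.edge.length or 0.0
        tree.reroot_at_edge(
            target.edge, length1=length * (1 - fraction), length2=length * fraction,
            update_bipartitions=False,
        )
        out = Phylogeny.from_dendropy(tree)
        return out


def read_branch_classes(tree: Phylogeny, table: dict[str, str]) -> Phylogeny:
    """Apply a branch-class map to a tree.

    Keys are either a tip label (tags that terminal edge) or a
    ``"a|b|c"``-joined set of tip labels (tags the edge above their MRCA).
    """
    out = tree.copy()
    for key, label in table.items():
        tips = key.split("|")
        if len(tips) == 1:
            idx = {lbl: v for v, lbl in zip(out.tip_indices, out.tip_labels)}
            out.classes[idx[tips[0]]] = label
        else:
            out.classes[out.mrca(tips)] = label
    return out
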