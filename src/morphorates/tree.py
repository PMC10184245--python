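"""Dated phylogeny container.

Wraps a :mod:`dendropy` tree in a flat array representation (parent
pointers, branch lengths, node depths, postorder) that the numerical
modules consume directly.  Branch lengths are in millions of years; node
*depths* are measured from the root (root depth 0), node *ages* from the
present (tips of an ultrametric tree have age ~0).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["PhyloTree", "read_tree"]


@dataclass
class PhyloTree:
    """A rooted dated phylogeny in array form.

    Nodes are indexed ``0 .. n_nodes-1``; the first ``n_tips`` indices are
    tips in the order of ``tip_labels``.  ``parent[root] == -1`` and the
    root's branch length is 0.
    """

    parent: np.ndarray          # (n_nodes,) int
    branch_lengths: np.ndarray  # (n_nodes,) float, edge above each node
    tip_labels: list[str]
    postorder: np.ndarray       # internal+tip node indices, children first
    newick: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.branch_lengths = np.asarray(self.branch_lengths, dtype=np.float64)
        n = len(self.parent)
        if np.any(self.branch_lengths[self.root != np.arange(n)] < 0):
            raise ValueError("negative branch length")
        self._depths: np.ndarray | None = None

    # ---------------------------------------------------------- construction
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        dtree = dtree.clone(depth=1)
        nodes = list(dtree.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        labels = [t.taxon.label if t.taxon else "" for t in tips]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        internals = [nd for nd in nodes if not nd.is_leaf()]
        index = {}
        for i, nd in enumerate(tips):
            index[id(nd)] = i
        for j, nd in enumerate(internals):
            index[id(nd)] = len(tips) + j
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        blen = np.zeros(n, dtype=np.float64)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise ValueError(f"missing branch length above node {i}")
                if nd.edge.length < 0:
                    raise ValueError(f"negative branch length above node {i}")
                blen[i] = float(nd.edge.length)
        post = np.array([index[id(nd)] for nd in dtree.postorder_node_iter()],
                        dtype=np.int64)
        newick = dtree.as_string(schema="newick").strip()
        return cls(parent=parent, branch_lengths=blen, tip_labels=labels,
                   postorder=post, newick=newick)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(dtree)

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick")

    def to_newick(self) -> str:
        if self.newick:
            return self.newick
        # rebuild from arrays
        children: dict[int, list[int]] = {}
        for i, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(i)

        def render(i: int) -> str:
            if i < self.n_tips:
                core = self.tip_labels[i].replace(" ", "_")
            else:
                core = "(" + ",".join(render(c) for c in children[i]) + ")"
            if self.parent[i] >= 0:
                core += f":{self.branch_lengths[i]:.10g}"
            return core

        return render(int(self.root)) + ";"

    # ------------------------------------------------------------ properties
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root(self) -> int:
        return int(np.where(self.parent == -1)[0][0])

    @property
    def depths(self) -> np.ndarray:
        """Distance of every node from the root."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            for i in self.postorder[::-1]:  # preorder
                p = self.parent[i]
                if p >= 0:
                    d[i] = d[p] + self.branch_lengths[i]
            self._depths = d
        return self._depths

    @property
    def root_age(self) -> float:
        """Maximum root-to-tip path length (the tree's time span, Ma)."""
        return float(self.depths[: self.n_tips].max())

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths.sum())

    def node_ages(self) -> np.ndarray:
        """Time before present of every node (root = root_age)."""
        return self.root_age - self.depths

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.depths[: self.n_tips]
        return bool((d.max() - d.min()) <= rel_tol * max(d.max(), 1e-300))

    def tip_index(self, labels) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.tip_labels)}
        try:
            return np.array([pos[l] for l in labels], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"species {e.args[0]!r} not among tree tips") from None

    # --------------------------------------------------------------- algebra
    def mrca_depths(self) -> np.ndarray:
        """N x N matrix of shared root-to-MRCA path lengths (the BM vcv)."""
        n, ntip = self.n_nodes, self.n_tips
        # tips below each node, as boolean masks built in postorder
        below = np.zeros((n, ntip), dtype=bool)
        C = np.zeros((ntip, ntip))
        depths = self.depths
        for i in self.postorder:
            if i < ntip:
                below[i, i] = True
            else:
                kids = np.where(self.parent == i)[0]
                for a in range(len(kids)):
                    below[i] |= below[kids[a]]
                    for b in range(a + 1, len(kids)):
                        m1, m2 = below[kids[a]], below[kids[b]]
                        C[np.ix_(m1, m2)] = depths[i]
                        C[np.ix_(m2, m1)] = depths[i]
        C[np.arange(ntip), np.arange(ntip)] = depths[:ntip]
        return C

    def vcv(self, order: list[str] | None = None) -> np.ndarray:
        """Brownian-motion covariance among tips, optionally reordered."""
        C = self.mrca_depths()
        if order is not None:
            idx = self.tip_index(order)
            C = C[np.ix_(idx, idx)]
        return C

    def clade_tips(self, node: int) -> list[str]:
        ntip = self.n_tips
        out, stack = [], [node]
        while stack:
            i = stack.pop()
            if i < ntip:
                out.append(self.tip_labels[i])
            else:
                stack.extend(np.where(self.parent == i)[0])
        return out

    def mrca(self, labels) -> int:
        """Most recent common ancestor node index of a set of tip labels."""
        idx = set(self.tip_index(labels).tolist())
        # walk up from one tip, take the first ancestor covering all
        anc = []
        i = next(iter(idx))
        while i != -1:
            anc.append(i)
            i = self.parent[i]
        covered = {next(iter(idx))}
        for node in anc:
            covered_tips = set(self.tip_index(self.clade_tips(node)).tolist())
            if idx <= covered_tips:
                return node
        raise RuntimeError("unreachable: root covers all tips")

    def restrict_to(self, labels) -> "PhyloTree":
        """Prune the tree to the given tip labels (order preserved by label)."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"species not in tree: {sorted(missing)[:5]}")
        dtree = self.to_dendropy()
        taxa = [t for t in dtree.taxon_namespace if t.label in keep]
        dtree.retain_taxa(taxa)
        return PhyloTree.from_dendropy(dtree)

    def branch_time_spans(self) -> np.ndarray:
        """(n_nodes, 2) start/end ages (Ma before present) of each branch."""
        ages = self.node_ages()
        spans = np.zeros((self.n_nodes, 2))
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                spans[i] = (ages[p], ages[i])  # older, younger
        return spans


def read_tree(path) -> PhyloTree:
    """Read a Newick tree with branch lengths in Myr.

    Ultrametricity is reported (as an attribute check), not required.
    Raises on negative or missing branch lengths and duplicate tips.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    tree = PhyloTree.from_newick(text)
    return tree
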