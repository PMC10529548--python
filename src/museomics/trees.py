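"""Dated rooted binary trees (chronograms) in flat-array form.

Nodes are indexed 0..2n-2: tips 0..n-1 (carrying labels), internal nodes
n..2n-2 with the root last in postorder. Ages are in Myr with tips at 0;
every parent is strictly older than its children. The flat representation
keeps the MCMC and pruning-likelihood inner loops free of object traversal.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


@dataclass
class Chronogram:
    tip_labels: list[str]
    children: dict[int, tuple[int, int]]  # internal node -> (left, right)
    parent: np.ndarray  # parent[i]; -1 for root
    ages: np.ndarray  # Myr, tips 0
    postorder: list[int]  # internal nodes, children-first; root last

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return self.postorder[-1]

    def validate(self) -> None:
        if (self.ages < 0).any():
            raise ValueError("node ages must be >= 0")
        for node, (l, r) in self.children.items():
            if self.ages[node] <= max(self.ages[l], self.ages[r]):
                raise ValueError(
                    f"node {node} (age {self.ages[node]}) not older than its children"
                )

    def durations(self) -> np.ndarray:
        """Edge durations in Myr indexed by child node (root entry is 0)."""
        d = self.ages[self.parent] - self.ages
        d[self.parent < 0] = 0.0
        return d

    def mrca(self, tip_label_set) -> int:
        """Most recent common ancestor of a set of tip labels."""
        want = set(tip_label_set)
        idx = {lab: i for i, lab in enumerate(self.tip_labels)}
        missing = want - set(idx)
        if missing:
            raise ValueError(f"unknown tips: {sorted(missing)}")
        nodes = {idx[lab] for lab in want}
        if len(nodes) < 2:
            raise ValueError("MRCA needs at least 2 tips")
        below = self.tips_below()
        for node in self.postorder:
            if nodes <= below[node]:
                return node
        raise AssertionError("unreachable: root covers all tips")

    def tips_below(self) -> dict[int, set[int]]:
        below: dict[int, set[int]] = {i: {i} for i in range(self.n_tips)}
        for node in self.postorder:
            l, r = self.children[node]
            below[node] = below[l] | below[r]
        return below

    def is_monophyletic(self, tip_label_set) -> bool:
        idx = {lab: i for i, lab in enumerate(self.tip_labels)}
        want = {idx[lab] for lab in tip_label_set}
        node = self.mrca(tip_label_set)
        return self.tips_below()[node] == want

    def copy(self) -> "Chronogram":
        return Chronogram(
            list(self.tip_labels),
            dict(self.children),
            self.parent.copy(),
            self.ages.copy(),
            list(self.postorder),
        )

    # -- conversion ---------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, ultrametric_tol: float = 1e-6) -> "Chronogram":
        """Build from a rooted, binary, ultrametric dendropy tree whose edge
        lengths are ages (time units)."""
        leaves = list(tree.leaf_node_iter())
        labels = [lf.taxon.label for lf in leaves]
        index = {id(lf): i for i, lf in enumerate(leaves)}
        n = len(leaves)
        internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
        for nd in internals:
            if len(nd.child_nodes()) != 2:
                raise ValueError("tree must be strictly binary")
        for j, nd in enumerate(internals):
            index[id(nd)] = n + j
        parent = np.full(2 * n - 1, -1, dtype=int)
        ages = np.zeros(2 * n - 1)
        children: dict[int, tuple[int, int]] = {}
        # node depth from root, then age = max_depth - depth
        depth = {id(tree.seed_node): 0.0}
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None:
                depth[id(nd)] = depth[id(nd.parent_node)] + (nd.edge.length or 0.0)
        max_depth = max(depth[id(lf)] for lf in leaves)
        for lf in leaves:
            if abs(depth[id(lf)] - max_depth) > ultrametric_tol * max(1.0, max_depth):
                raise ValueError("tree is not ultrametric; cannot interpret as chronogram")
        for nd in tree.preorder_node_iter():
            i = index[id(nd)]
            ages[i] = max(max_depth - depth[id(nd)], 0.0)
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
            if not nd.is_leaf():
                c = nd.child_nodes()
                children[i] = (index[id(c[0])], index[id(c[1])])
        for lf in leaves:
            ages[index[id(lf)]] = 0.0
        postorder = [index[id(nd)] for nd in internals]
        return cls(labels, children, parent, ages, postorder)

    @classmethod
    def from_topology(cls, tree: dendropy.Tree, root_age: float = 1.0) -> "Chronogram":
        """Build from a rooted binary topology, assigning provisional ages
        proportional to node height rank (root at root_age)."""
        chrono = None
        leaves = list(tree.leaf_node_iter())
        n = len(leaves)
        index = {id(lf): i for i, lf in enumerate(leaves)}
        internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
        for nd in internals:
            if len(nd.child_nodes()) != 2:
                raise ValueError("topology must be strictly binary")
        for j, nd in enumerate(internals):
            index[id(nd)] = n + j
        parent = np.full(2 * n - 1, -1, dtype=int)
        ages = np.zeros(2 * n - 1)
        children: dict[int, tuple[int, int]] = {}
        level = np.zeros(2 * n - 1, dtype=int)
        for nd in internals:
            i = index[id(nd)]
            c = nd.child_nodes()
            children[i] = (index[id(c[0])], index[id(c[1])])
            for ch in c:
                parent[index[id(ch)]] = i
            level[i] = 1 + max(level[index[id(ch)]] for ch in c)
        max_level = level.max()
        ages = level / max_level * root_age
        postorder = [index[id(nd)] for nd in internals]
        return cls(labels := [lf.taxon.label for lf in leaves], children, parent, ages, postorder)

    def to_newick(self, edge_lengths: np.ndarray | None = None, annotations: dict[int, str] | None = None) -> str:
        """Newick string; edge lengths default to durations (Myr)."""
        lens = edge_lengths if edge_lengths is not None else self.durations()

        def fmt(node: int) -> str:
            note = annotations.get(node, "") if annotations else ""
            if node < self.n_tips:
                core = self.tip_labels[node] + note
            else:
                l, r = self.children[node]
                core = f"({fmt(l)},{fmt(r)})" + note
            if self.parent[node] >= 0:
                return f"{core}:{lens[node]:.12g}"
            return core

        return fmt(self.root) + ";"


def random_chronogram(
    n_tips: int, birth_rate: float, rng: np.random.Generator, prefix: str = "t"
) -> Chronogram:
    """Draw node ages and a random join topology from a Yule (pure-birth)
    process: going rootward, the waiting time while k lineages remain is
    Exponential(birth_rate * k)."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    labels = [f"{prefix}{i}" for i in range(n_tips)]
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=int)
    ages = np.zeros(n_nodes)
    children: dict[int, tuple[int, int]] = {}
    postorder: list[int] = []
    active = list(range(n_tips))
    t = 0.0
    nxt = n_tips
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        children[nxt] = (a, b)
        parent[a] = parent[b] = nxt
        ages[nxt] = t
        postorder.append(nxt)
        active[i] = nxt
        active.pop(j)
        nxt += 1
    return Chronogram(labels, children, parent, ages, postorder)
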