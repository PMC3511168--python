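"""Rooted species phylogeny with supergroup labels.

The tree container is deliberately minimal: Dollo parsimony and the
locus-ancestry queries only need rooted topology — parent pointers,
subtree leaf sets, MRCA — not branch lengths or likelihoods.  Newick
text is parsed and emitted through dendropy at the IO boundary; all
queries run on flat integer-indexed arrays.

The root node is interpreted as LECA (the Last Eukaryotic Common
Ancestor) throughout the package.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny", "random_rooted_tree"]


class Phylogeny:
    """Rooted (binary or multifurcating) tree over species leaves.

    Nodes are integers ``0..n_nodes-1`` in preorder with the root at 0.
    Every leaf carries a species id and, optionally, a supergroup label
    (e.g. ``Unikonta`` / ``Bikonta``).
    """

    def __init__(
        self,
        parent: Sequence[int],
        labels: Sequence[str | None],
        supergroups: Mapping[str, str] | None = None,
    ):
        self.parent = list(parent)
        self.labels = list(labels)
        n = len(self.parent)
        if n == 0 or self.parent[0] != -1 or any(self.parent[i] >= i or self.parent[i] < 0 for i in range(1, n)):
            raise ValueError("parent array must be preorder with root first")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        if len(self.children[0]) < 2:
            raise ValueError("root must have at least 2 children")
        self.leaves = [i for i in range(n) if not self.children[i]]
        self.leaf_index: dict[str, int] = {}
        for i in self.leaves:
            if self.labels[i] is None:
                raise ValueError(f"leaf node {i} lacks a species label")
            if self.labels[i] in self.leaf_index:
                raise ValueError(f"duplicate leaf label {self.labels[i]!r}")
            self.leaf_index[self.labels[i]] = i
        # depth and postorder
        self.depth = [0] * n
        for i in range(1, n):
            self.depth[i] = self.depth[self.parent[i]] + 1
        self.postorder = sorted(range(n), key=lambda i: -self.depth[i])
        # subtree leaf-name sets
        self._leafset: list[frozenset[str]] = [frozenset()] * n
        acc: list[set[str]] = [set() for _ in range(n)]
        for i in self.postorder:
            if not self.children[i]:
                acc[i].add(self.labels[i])
            if i != 0:
                acc[self.parent[i]] |= acc[i]
        self._leafset = [frozenset(s) for s in acc]
        self.supergroups = dict(supergroups or {})
        for sp in self.supergroups:
            if sp not in self.leaf_index:
                raise ValueError(f"supergroup map names unknown leaf {sp!r}")

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, supergroups: Mapping[str, str] | None = None) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=False)
        parent: list[int] = []
        labels: list[str | None] = []
        index: dict[int, int] = {}
        for node in tree.preorder_node_iter():
            idx = len(parent)
            index[id(node)] = idx
            parent.append(-1 if node.parent_node is None else index[id(node.parent_node)])
            name = None
            if node.taxon is not None:
                name = node.taxon.label
            elif node.label:
                name = node.label
            labels.append(name)
        return cls(parent, labels, supergroups)

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if not self.children[i]:
                return self.labels[i]
            inner = ",".join(render(c) for c in self.children[i])
            lbl = self.labels[i] or ""
            return f"({inner}){lbl}"

        return render(0) + ";"

    # -- queries ------------------------------------------------------

    @property
    def root(self) -> int:
        return 0

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def node_name(self, node: int) -> str:
        """Stable human-readable node label (leaf name, or the sorted
        leaf set rendered compactly for unnamed internal nodes)."""
        if self.labels[node]:
            return self.labels[node]
        return "mrca(" + "+".join(sorted(self._leafset[node])) + ")"

    def leaf(self, species_id: str) -> int:
        try:
            return self.leaf_index[species_id]
        except KeyError:
            raise KeyError(f"species {species_id!r} is not a leaf of the tree") from None

    def leaf_names(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    def leaves_under(self, node: int) -> frozenset[str]:
        return self._leafset[node]

    def is_ancestor(self, anc: int, node: int) -> bool:
        """True if ``anc`` is ``node`` or an ancestor of it."""
        while node != -1:
            if node == anc:
                return True
            if self.depth[node] <= self.depth[anc]:
                return False
            node = self.parent[node]
        return False

    def mrca(self, species_ids: Iterable[str]) -> int:
        nodes = [self.leaf(s) for s in species_ids]
        if not nodes:
            raise ValueError("mrca of an empty species set is undefined")
        cur = nodes[0]
        for other in nodes[1:]:
            a, b = cur, other
            while a != b:
                if self.depth[a] < self.depth[b]:
                    b = self.parent[b]
                else:
                    a = self.parent[a]
            cur = a
        return cur

    def supergroup_of(self, species_id: str) -> str | None:
        return self.supergroups.get(species_id)


def random_rooted_tree(n_leaves: int, rng: np.random.Generator, prefix: str = "t") -> Phylogeny:
    """Uniform-ish random rooted binary tree built by random pairwise
    joins (coalescent-style), used for enumeration tests."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    # build child lists bottom-up, then renumber in preorder
    subtrees: list[object] = [f"{prefix}{i + 1}" for i in range(n_leaves)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        subtrees.append((a, b))

    parent: list[int] = []
    labels: list[str | None] = []

    def emit(node: object, par: int) -> None:
        idx = len(parent)
        parent.append(par)
        if isinstance(node, tuple):
            labels.append(None)
            for ch in node:
                emit(ch, idx)
        else:
            labels.append(node)

    emit(subtrees[0], -1)
    return Phylogeny(parent, labels)
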