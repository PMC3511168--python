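"""Dollo-parsimony ancestral-state reconstruction of binary characters.

Under Dollo parsimony a character (a snoRNA family, clan, intron locus
or modification-site locus) is gained exactly once and may be lost any
number of times; absence is the default state.  For a rooted tree the
minimal single-gain scenario is fully determined: the gain sits at the
MRCA of all presence leaves and losses sit on the highest branches
whose subtrees contain only absence leaves.  A character is traceable
to the root (LECA) iff presence leaves occur in at least two child
subtrees of the root.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datamodel import FamilyCatalog
from .phylo import Phylogeny

__all__ = [
    "PresenceMatrix",
    "CharacterReconstruction",
    "AncestralReconstruction",
    "infer_gain_node",
    "reconstruct",
    "is_in_ancestor",
    "count_traceable",
    "brute_force_min_losses",
]


@dataclass
class PresenceMatrix:
    """Binary characters × taxa matrix.

    ``df`` has character ids as the index and species ids as columns,
    values strictly 0/1.  Taxa for which a character was not assessed
    are scored 0 (absence is the conservative Dollo default); an
    explicit ``unscored`` mask may mark them but does not change the
    reconstruction.
    """

    df: pd.DataFrame
    character_kind: str  # family | clan | intron_locus | site_locus
    unscored: pd.DataFrame | None = None

    def __post_init__(self):
        vals = set(pd.unique(self.df.values.ravel())) if self.df.size else set()
        if not vals <= {0, 1}:
            raise ValueError(f"presence matrix must be strictly 0/1, found {sorted(vals - {0, 1})}")

    @classmethod
    def from_observations(
        cls, observations: dict[str, set[str]], taxa: list[str], character_kind: str
    ) -> "PresenceMatrix":
        """Build from character → set-of-present-species observations."""
        df = pd.DataFrame(0, index=sorted(observations), columns=list(taxa), dtype=int)
        for char, species in observations.items():
            for sp in species:
                if sp not in df.columns:
                    raise KeyError(f"taxon {sp!r} not among matrix taxa")
                df.loc[char, sp] = 1
        return cls(df, character_kind)

    def to_tsv(self) -> str:
        return self.df.to_csv(sep="\t", index_label="character")

    @classmethod
    def from_tsv(cls, text: str, character_kind: str) -> "PresenceMatrix":
        import io as _io

        df = pd.read_csv(_io.StringIO(text), sep="\t", index_col="character")
        return cls(df.astype(int), character_kind)

    def union(self, groups: dict[str, list[str]], character_kind: str) -> "PresenceMatrix":
        """Derived matrix whose characters are unions of member
        characters (a taxon has the group iff it has ≥ 1 member) — used
        to score clans from member families."""
        rows = {}
        for gid, members in groups.items():
            present = [m for m in members if m in self.df.index]
            if present:
                rows[gid] = (self.df.loc[present].sum(axis=0) > 0).astype(int)
        df = pd.DataFrame(rows).T if rows else pd.DataFrame(columns=self.df.columns, dtype=int)
        df = df.reindex(columns=self.df.columns, fill_value=0).sort_index()
        return PresenceMatrix(df, character_kind)


@dataclass
class CharacterReconstruction:
    character_id: str
    gain_node: int
    loss_branches: frozenset[int]  # branch identified by its child node
    node_states: list[int]

    @property
    def min_losses(self) -> int:
        return len(self.loss_branches)


@dataclass
class AncestralReconstruction:
    tree: Phylogeny
    character_kind: str
    characters: dict[str, CharacterReconstruction] = field(default_factory=dict)

    def __getitem__(self, character_id: str) -> CharacterReconstruction:
        try:
            return self.characters[character_id]
        except KeyError:
            raise KeyError(f"unknown character {character_id!r}") from None

    def leca_characters(self) -> set[str]:
        root = self.tree.root
        return {c for c, r in self.characters.items() if r.node_states[root] == 1}

    def report(self) -> dict:
        """JSON-serializable per-character summary."""
        out = {}
        for cid in sorted(self.characters):
            rec = self.characters[cid]
            out[cid] = {
                "gain_node": self.tree.node_name(rec.gain_node),
                "loss_branches": sorted(self.tree.node_name(b) for b in rec.loss_branches),
                "min_losses": rec.min_losses,
                "in_leca": bool(rec.node_states[self.tree.root]),
            }
        return out


class NoPresenceError(ValueError):
    """Character with an all-zero leaf pattern has no Dollo placement."""


def infer_gain_node(tree: Phylogeny, leaf_states: dict[str, int]) -> int:
    """MRCA of all presence leaves: the unique minimal gain placement."""
    present = [sp for sp, st in leaf_states.items() if st]
    if not present:
        raise NoPresenceError("all-zero leaf pattern")
    for sp in present:
        tree.leaf(sp)  # raises KeyError for unknown taxa
    return tree.mrca(present)


def _reconstruct_one(tree: Phylogeny, leaf_states: dict[str, int]) -> tuple[int, frozenset[int], list[int]]:
    gain = infer_gain_node(tree, leaf_states)
    present = {sp for sp, st in leaf_states.items() if st}
    # has_presence[node]: any presence leaf in the subtree
    has = [False] * tree.n_nodes
    for i in tree.postorder:
        if not tree.children[i]:
            has[i] = tree.labels[i] in present
        else:
            has[i] = any(has[c] for c in tree.children[i])
    # losses: highest branches below the gain whose subtree lacks presence
    losses: set[int] = set()
    states = [0] * tree.n_nodes
    stack = [gain]
    while stack:
        node = stack.pop()
        states[node] = 1
        for c in tree.children[node]:
            if has[c]:
                stack.append(c)
            else:
                losses.add(c)
    return gain, frozenset(losses), states


def reconstruct(tree: Phylogeny, matrix: PresenceMatrix) -> AncestralReconstruction:
    """Dollo reconstruction of every character in the matrix.

    Characters with all-zero patterns are skipped (they carry no
    placement information).  Raises ``KeyError`` for taxa that are not
    leaves of the tree.
    """
    for sp in matrix.df.columns:
        tree.leaf(sp)
    recon = AncestralReconstruction(tree=tree, character_kind=matrix.character_kind)
    for cid, row in matrix.df.iterrows():
        leaf_states = {sp: int(v) for sp, v in row.items()}
        if not any(leaf_states.values()):
            continue
        gain, losses, states = _reconstruct_one(tree, leaf_states)
        recon.characters[cid] = CharacterReconstruction(
            character_id=str(cid), gain_node=gain, loss_branches=losses, node_states=states
        )
    return recon


def is_in_ancestor(recon: AncestralReconstruction, character_id: str, node: int) -> bool:
    """Whether the character is reconstructed as present at ``node``."""
    rec = recon[character_id]
    if not 0 <= node < recon.tree.n_nodes:
        raise IndexError(f"node {node} not in tree")
    return rec.node_states[node] == 1


def count_traceable(
    recon: AncestralReconstruction, node: int, catalog: FamilyCatalog
) -> dict[str, int]:
    """Counts of characters present at ``node``, by kind and snoRNA
    class (family/clan kinds only; clans are classed by their members,
    mixed-class clans counted under ``mixed``)."""
    counts = {"total": 0, "CD": 0, "HACA": 0, "mixed": 0}
    kind = recon.character_kind
    clans = catalog.clans() if kind == "clan" else {}
    for cid, rec in recon.characters.items():
        if rec.node_states[node] != 1:
            continue
        counts["total"] += 1
        if kind == "family":
            counts[catalog.class_of(cid).value] += 1
        elif kind == "clan":
            classes = {catalog.class_of(m).value for m in clans.get(cid, [])}
            counts[classes.pop() if len(classes) == 1 else "mixed"] += 1
    return counts


def brute_force_min_losses(tree: Phylogeny, leaf_states: dict[str, int]) -> tuple[int, int]:
    """Test oracle: exhaustive search over all single-gain placements.

    For every candidate gain node covering all presence leaves, count
    the losses needed (one per maximal presence-free subtree below the
    gain) and return the minimum together with the root state implied
    by the optimal placement.  Only for small trees (≤ 12 leaves).
    """
    if len(tree.leaves) > 12:
        raise ValueError("brute-force oracle limited to 12 leaves")
    present = {sp for sp, st in leaf_states.items() if st}
    if not present:
        raise NoPresenceError("all-zero leaf pattern")
    has = [False] * tree.n_nodes
    for i in tree.postorder:
        if not tree.children[i]:
            has[i] = tree.labels[i] in present
        else:
            has[i] = any(has[c] for c in tree.children[i])

    best: tuple[int, int] | None = None
    for gain in range(tree.n_nodes):
        if not present <= tree.leaves_under(gain):
            continue
        losses = 0
        stack = [gain]
        covered_root = 1 if gain == tree.root else 0
        while stack:
            node = stack.pop()
            for c in tree.children[node]:
                if has[c]:
                    stack.append(c)
                else:
                    losses += 1
        cand = (losses, covered_root)
        if best is None or losses < best[0]:
            best = cand
    assert best is not None
    return best
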