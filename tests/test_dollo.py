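"""Dollo parsimony: gain placement, minimal losses, LECA queries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from snoleca.datamodel import FamilyCatalog, FamilyInfo, SnoClass
from snoleca.dollo import (
    NoPresenceError,
    PresenceMatrix,
    brute_force_min_losses,
    count_traceable,
    infer_gain_node,
    is_in_ancestor,
    reconstruct,
)
from snoleca.phylo import random_rooted_tree


def matrix_for(tree, pattern):
    leaves = tree.leaf_names()
    return PresenceMatrix(
        pd.DataFrame([list(pattern)], index=["c"], columns=leaves), "family"
    )


class TestGainNode:
    def test_full_presence_gains_at_root(self, tree4):
        assert infer_gain_node(tree4, {"A": 1, "B": 1, "C": 1, "D": 1}) == tree4.root

    def test_singleton_gains_at_leaf(self, tree4):
        assert infer_gain_node(tree4, {"A": 1, "B": 0, "C": 0, "D": 0}) == tree4.leaf("A")

    def test_cross_root_pattern_gains_at_root(self, tree4):
        assert infer_gain_node(tree4, {"A": 1, "B": 0, "C": 1, "D": 0}) == tree4.root

    def test_all_zero_rejected(self, tree4):
        with pytest.raises(NoPresenceError):
            infer_gain_node(tree4, {"A": 0, "B": 0, "C": 0, "D": 0})

    def test_unknown_taxon_rejected(self, tree4):
        with pytest.raises(KeyError):
            infer_gain_node(tree4, {"Z": 1})


class TestReconstruct:
    def test_cross_root_two_losses(self, tree4):
        rec = reconstruct(tree4, matrix_for(tree4, (1, 0, 1, 0)))["c"]
        assert rec.gain_node == tree4.root
        assert rec.min_losses == 2
        assert rec.node_states[tree4.root] == 1
        assert {tree4.labels[b] for b in rec.loss_branches} == {"B", "D"}

    def test_clade_confined_no_losses(self, tree4):
        rec = reconstruct(tree4, matrix_for(tree4, (1, 1, 0, 0)))["c"]
        assert rec.gain_node == tree4.mrca(["A", "B"])
        assert rec.min_losses == 0
        assert rec.node_states[tree4.root] == 0

    def test_unknown_taxon_rejected(self, tree4):
        df = pd.DataFrame([[1]], index=["c"], columns=["nope"])
        with pytest.raises(KeyError):
            reconstruct(tree4, PresenceMatrix(df, "family"))

    def test_monotonic_gain_moves_rootward(self, rng):
        """Adding a presence leaf keeps the gain node or moves it
        toward the root, never deeper."""
        tree = random_rooted_tree(8, rng)
        leaves = tree.leaf_names()
        for _ in range(30):
            k = int(rng.integers(1, 8))
            chosen = list(rng.choice(leaves, size=k, replace=False))
            extra = [l for l in leaves if l not in chosen]
            g1 = infer_gain_node(tree, {l: 1 for l in chosen})
            if extra:
                g2 = infer_gain_node(tree, {l: 1 for l in chosen + [extra[0]]})
                assert tree.is_ancestor(g2, g1)


class TestOracleEquivalence:
    def test_matches_brute_force_on_exhaustive_patterns(self, rng):
        """reconstruct == exhaustive single-gain enumeration (losses and
        root state) over all 2^6 patterns on random 6-leaf trees."""
        for _ in range(5):
            tree = random_rooted_tree(6, rng)
            leaves = tree.leaf_names()
            pats = [p for p in itertools.product([0, 1], repeat=6) if any(p)]
            df = pd.DataFrame(pats, index=[f"c{i}" for i in range(len(pats))], columns=leaves)
            recs = reconstruct(tree, PresenceMatrix(df, "family"))
            for i, pat in enumerate(pats):
                mb, rb = brute_force_min_losses(tree, dict(zip(leaves, pat)))
                rec = recs[f"c{i}"]
                assert rec.min_losses == mb
                assert rec.node_states[tree.root] == rb

    def test_is_in_ancestor_equals_path_walk(self, rng):
        """Presence at a node ⟺ the gain is ancestral to it and no loss
        branch lies on the path between them."""
        tree = random_rooted_tree(7, rng)
        leaves = tree.leaf_names()
        for _ in range(20):
            pat = rng.integers(0, 2, size=7)
            if not pat.any():
                continue
            recon = reconstruct(tree, matrix_for(tree, tuple(pat)))
            rec = recon["c"]
            for node in range(tree.n_nodes):
                onpath = False
                cur = node
                below_gain = tree.is_ancestor(rec.gain_node, node)
                while cur != -1 and cur != rec.gain_node:
                    if cur in rec.loss_branches:
                        onpath = True
                    cur = tree.parent[cur]
                want = below_gain and not onpath
                assert is_in_ancestor(recon, "c", node) == want


class TestCountsAndClans:
    def catalog(self):
        return FamilyCatalog(
            [
                FamilyInfo("f1", "cl1", SnoClass.CD),
                FamilyInfo("f2", "cl1", SnoClass.CD),
                FamilyInfo("f3", None, SnoClass.HACA),
            ]
        )

    def test_count_traceable_by_class(self, tree4):
        df = pd.DataFrame(
            [[1, 1, 1, 1], [1, 1, 0, 0], [1, 0, 1, 0]],
            index=["f1", "f2", "f3"],
            columns=tree4.leaf_names(),
        )
        rec = reconstruct(tree4, PresenceMatrix(df, "family"))
        counts = count_traceable(rec, tree4.root, self.catalog())
        assert counts == {"total": 2, "CD": 1, "HACA": 1, "mixed": 0}

    def test_clan_union_scores_any_member(self, tree4):
        df = pd.DataFrame(
            [[1, 0, 0, 0], [0, 0, 1, 0]], index=["f1", "f2"], columns=tree4.leaf_names()
        )
        fam = PresenceMatrix(df, "family")
        clan = fam.union(self.catalog().clans(), "clan")
        # neither family alone spans the root, but the clan does
        rec_f = reconstruct(tree4, fam)
        rec_c = reconstruct(tree4, clan)
        assert rec_f["f1"].node_states[tree4.root] == 0
        assert rec_c["cl1"].node_states[tree4.root] == 1

    def test_empty_matrix_counts_zero(self, tree4):
        df = pd.DataFrame(columns=tree4.leaf_names(), dtype=int)
        rec = reconstruct(tree4, PresenceMatrix(df, "family"))
        assert count_traceable(rec, tree4.root, self.catalog())["total"] == 0

    def test_matrix_tsv_roundtrip(self, tree4):
        df = pd.DataFrame(
            [[1, 0, 1, 0]], index=["f1"], columns=tree4.leaf_names()
        )
        m = PresenceMatrix(df, "family")
        m2 = PresenceMatrix.from_tsv(m.to_tsv(), "family")
        assert m2.df.equals(m.df)

    def test_non_binary_rejected(self, tree4):
        df = pd.DataFrame([[2, 0, 0, 0]], index=["f1"], columns=tree4.leaf_names())
        with pytest.raises(ValueError, match="0/1"):
            PresenceMatrix(df, "family")
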