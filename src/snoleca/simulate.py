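"""Phylogeny-structured synthetic input bundles with full ground truth.

The generator emulates the statistical structure of the real inputs —
per-species annotations, rRNA and host-protein alignments, a rooted
supergroup tree, a family catalog, known modification sites and a
tissue expression matrix — while planting every event it simulates
into truth tables:

* family evolution: single-origin gains (ancestral families at the
  root, later families on branches) with independent per-branch loss;
* intragenomic mobility: a family relocates to a different host intron
  on a chosen branch and the new association is inherited;
* convergent insertion: two independently gained families of different
  classes occupy the same orthologous intron locus on the two sides of
  the root — the signature that positional conservation alone does not
  establish snoRNA homology;
* guide targets: per-species rRNA windows whose reverse complements
  are embedded into the C/D snoRNAs of the assigned families, at
  alignment columns shared across species;
* host genes: orthologous exon/intron structures with ancestral and
  derived introns, UTRs, both strands, and snoRNAs inside introns;
* expression: Dirichlet tissue profiles with broader breadth (higher
  Shannon entropy) for snoRNA host genes.

snoRNA and rRNA sequences are certified: after planting, a
deterministic repair loop mutates bases until the guide search finds
exactly the planted windows and nothing else, so the truth tables are
exact rather than probabilistic.  All randomness flows from one seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import digamma

from .datamodel import (
    FamilyCatalog,
    FamilyInfo,
    Gene,
    GenomeAnnotation,
    Interval,
    MultipleAlignment,
    SnoClass,
    SnoRNARecord,
    Transcript,
    revcomp,
)
from .guides import GuideSearchParams, search_guides
from .introns import OrthologGroup
from .phylo import Phylogeny
from .pipeline import InputSet

__all__ = [
    "SimulationParams",
    "SyntheticBundle",
    "make_supergroup_tree",
    "simulate_family_evolution",
    "simulate_expression",
    "simulate_bundle",
    "write_bundle",
    "verify_bundle",
]

NT = np.array(list("ACGT"))
AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulationParams:
    """Study conditions for the synthetic bundle.  Defaults give a
    12-taxon, two-supergroup fixture with 50 ancestral families and
    moderate loss, sized so every stage is exercised in seconds."""

    seed: int
    supergroups: tuple[str, ...] = ("Unikonta", "Bikonta")
    taxa_per_supergroup: int = 6
    n_ancestral_families: int = 50
    loss_prob: float = 0.15
    gain_rate: float = 0.1
    n_mobility_events: int = 5
    source_retention_prob: float = 0.0
    n_convergent_pairs: int = 3
    n_host_genes: int = 30
    introns_per_gene: int = 6
    intron_gain_prob: float = 0.05
    intron_loss_prob: float = 0.05
    protein_length: int = 400
    protein_subst_rate: float = 0.02
    protein_del_rate: float = 1.0
    rrna_lengths: tuple[tuple[str, int], ...] = (("SSU", 1800), ("LSU", 3000))
    rrna_subst_rate: float = 0.01
    rrna_del_rate: float = 2.0
    n_planted_sites: int = 30
    n_confined_sites: int = 4
    n_known_extra: int = 2
    guide_length_range: tuple[int, int] = (10, 14)
    snorna_length: int = 80
    n_decoys: int = 30
    intergenic_prob: float = 0.15
    frac_cd: float = 0.8
    n_cleavage_only: int = 2
    n_generic_clans: int = 6
    n_nonhost_genes: int = 200
    n_tissues: int = 12
    entropy_gap: float = 0.5
    host_alpha: float = 5.0
    expression_level_mu: float = 5.0
    expression_level_sigma: float = 0.5

    def __post_init__(self):
        for p in (self.loss_prob, self.intron_gain_prob, self.intron_loss_prob, self.frac_cd):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.taxa_per_supergroup < 1:
            raise ValueError("need at least one taxon per supergroup")
        if self.n_tissues < 2:
            raise ValueError("need at least 2 tissues")


@dataclass
class _Family:
    family_id: str
    sno_class: SnoClass = SnoClass.CD
    clan_id: str | None = None
    cleavage_only: bool = False
    born_node: int = 0
    immune: bool = False
    home: tuple | None = None  # ("intron", gid, column) | ("intergenic",)
    sites: list[str] = field(default_factory=list)


@dataclass
class _Site:
    site_id: str
    subunit: str
    column: int
    guide_len: int
    families: list[str] = field(default_factory=list)
    confined: bool = False


@dataclass
class SyntheticBundle:
    params: SimulationParams
    inputs: InputSet
    truth: dict


# ---------------------------------------------------------------------------
# tree & family evolution
# ---------------------------------------------------------------------------


def _balanced(leaves: list[str]):
    if len(leaves) == 1:
        return leaves[0]
    mid = len(leaves) // 2
    return (_balanced(leaves[:mid]), _balanced(leaves[mid:]))


def make_supergroup_tree(params: SimulationParams) -> Phylogeny:
    """Rooted tree with one balanced clade per supergroup; the root is
    LECA (the unikont/bikont split for the default two supergroups)."""
    tops = []
    supergroups = {}
    for sg in params.supergroups:
        leaves = [f"{sg[:3]}{i + 1:02d}" for i in range(params.taxa_per_supergroup)]
        for leaf in leaves:
            supergroups[leaf] = sg
        tops.append(_balanced(leaves))
    shape = tuple(tops) if len(tops) > 1 else tops[0]
    parent: list[int] = []
    labels: list[str | None] = []

    def emit(node, par):
        idx = len(parent)
        parent.append(par)
        if isinstance(node, tuple):
            labels.append(None)
            for ch in node:
                emit(ch, idx)
        else:
            labels.append(node)

    emit(shape, -1)
    return Phylogeny(parent, labels, supergroups)


def simulate_family_evolution(
    tree: Phylogeny, params: SimulationParams, rng: np.random.Generator
) -> tuple[dict[str, _Family], dict[str, set[str]], dict[str, list[int]]]:
    """Single-origin gain / per-branch loss evolution of families.

    Ancestral families are born at the root; additional families on
    Poisson-drawn branches; convergent-insertion plants are born at the
    two root-child subtrees; confined-site families inside one subtree.
    Returns (families, leaf presence sets, loss branches).
    """
    if not tree.leaves:
        raise ValueError("tree has no leaves")
    families: dict[str, _Family] = {}
    for i in range(params.n_ancestral_families):
        families[f"F{i + 1:03d}"] = _Family(family_id=f"F{i + 1:03d}", born_node=tree.root)
    gained = 0
    for node in range(1, tree.n_nodes):
        for _ in range(rng.poisson(params.gain_rate)):
            gained += 1
            families[f"G{gained:03d}"] = _Family(family_id=f"G{gained:03d}", born_node=node)
    root_kids = tree.children[tree.root]
    classes_cycle = [
        (SnoClass.CD, SnoClass.HACA),
        (SnoClass.HACA, SnoClass.CD),
        (SnoClass.CD, SnoClass.CD),
    ]
    for p in range(params.n_convergent_pairs):
        ca, cb = classes_cycle[p % len(classes_cycle)]
        families[f"V{p + 1:02d}A"] = _Family(
            family_id=f"V{p + 1:02d}A", sno_class=ca, born_node=root_kids[0], immune=True
        )
        families[f"V{p + 1:02d}B"] = _Family(
            family_id=f"V{p + 1:02d}B", sno_class=cb, born_node=root_kids[1], immune=True
        )
    confined_home = root_kids[0]
    if tree.children[confined_home]:
        confined_home = tree.children[confined_home][0]
    if not tree.children[confined_home]:  # need ≥ 2 species for a locus
        confined_home = root_kids[0]
    for s in range(params.n_confined_sites):
        families[f"S{s + 1:02d}"] = _Family(
            family_id=f"S{s + 1:02d}", born_node=confined_home, immune=True
        )

    # assign classes to ancestral / gained families
    for fid in sorted(families):
        fam = families[fid]
        if fid.startswith(("F", "G")):
            fam.sno_class = SnoClass.CD if rng.random() < params.frac_cd else SnoClass.HACA

    # presence propagation (preorder; carried set per node)
    carried: dict[int, set[str]] = {tree.root: set()}
    losses: dict[str, list[int]] = {fid: [] for fid in families}
    order = sorted(range(tree.n_nodes), key=lambda n: tree.depth[n])
    for node in order:
        if node == tree.root:
            carried[node] = {f for f, m in families.items() if m.born_node == tree.root}
            continue
        inherited = set()
        for fid in sorted(carried[tree.parent[node]]):
            if not families[fid].immune and rng.random() < params.loss_prob:
                losses[fid].append(node)
            else:
                inherited.add(fid)
        inherited |= {f for f, m in families.items() if m.born_node == node}
        carried[node] = inherited
    presence = {
        fid: {tree.labels[leaf] for leaf in tree.leaves if fid in carried[leaf]}
        for fid in families
    }
    return families, presence, losses


def _expected_leca(tree: Phylogeny, species: set[str]) -> bool:
    kids = tree.children[tree.root]
    return sum(1 for k in kids if species & tree.leaves_under(k)) >= 2


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def _dirichlet_entropy(alpha: float, k: int) -> float:
    """E[Shannon entropy] of proportions under symmetric Dirichlet."""
    return float(digamma(k * alpha + 1) - digamma(alpha + 1))


def simulate_expression(
    host_genes: list[str],
    nonhost_genes: list[str],
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Gene × tissue matrix: hosts draw near-uniform Dirichlet tissue
    proportions, non-hosts concentrated ones, with the non-host
    concentration solved so the mean entropy gap equals the requested
    δ (nats); overall signal levels are log-normal."""
    k = params.n_tissues
    target = _dirichlet_entropy(params.host_alpha, k) - params.entropy_gap
    if target <= _dirichlet_entropy(1e-4, k):
        raise ValueError("entropy gap too large for the tissue count")
    alpha_nonhost = (
        params.host_alpha
        if params.entropy_gap == 0
        else float(
            brentq(lambda a: _dirichlet_entropy(a, k) - target, 1e-4, params.host_alpha)
        )
    )
    tissues = [f"T{i + 1:02d}" for i in range(k)]
    rows = {}
    for gene in list(host_genes) + list(nonhost_genes):
        alpha = params.host_alpha if gene in set(host_genes) else alpha_nonhost
        level = rng.lognormal(params.expression_level_mu, params.expression_level_sigma)
        rows[gene] = rng.dirichlet(np.full(k, alpha)) * level
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=tissues)
    truth = {
        "host_genes": sorted(host_genes),
        "nonhost_genes": sorted(nonhost_genes),
        "alpha_host": params.host_alpha,
        "alpha_nonhost": alpha_nonhost,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# rRNA simulation with planted guide windows
# ---------------------------------------------------------------------------


class _RnaSet:
    """Per-subunit alignment-column-space sequences for every species,
    with deletion masks and protected (planted-window) columns."""

    def __init__(self, tree: Phylogeny, params: SimulationParams, rng: np.random.Generator):
        self.tree = tree
        self.lengths = dict(params.rrna_lengths)
        self.chars: dict[str, dict[str, np.ndarray]] = {}
        self.deleted: dict[str, dict[str, np.ndarray]] = {}
        self.protected: dict[str, set[int]] = {su: set() for su in self.lengths}
        self.root_chars: dict[str, np.ndarray] = {
            su: rng.choice(NT, size=n) for su, n in self.lengths.items()
        }

    def reserve_columns(self, su: str, count: int, spacing: int, rng) -> list[int]:
        lo, hi = 30, self.lengths[su] - 30
        slots = np.arange(lo, hi, spacing)
        if count > len(slots):
            raise ValueError(
                f"rRNA capacity exceeded: {count} sites do not fit in {su} "
                f"at spacing {spacing}"
            )
        return sorted(int(c) for c in rng.permutation(slots)[:count])

    def protect(self, su: str, cols) -> None:
        self.protected[su].update(int(c) for c in cols)

    def evolve(self, params: SimulationParams, rng: np.random.Generator) -> None:
        """Point substitutions and clade-level column deletions along
        the tree; protected columns are never deleted."""
        tree = self.tree
        for su, L in self.lengths.items():
            node_chars = {tree.root: self.root_chars[su].copy()}
            node_del = {tree.root: np.zeros(L, dtype=bool)}
            for node in sorted(range(1, tree.n_nodes), key=lambda n: tree.depth[n]):
                chars = node_chars[tree.parent[node]].copy()
                dele = node_del[tree.parent[node]].copy()
                n_sub = rng.binomial(L, params.rrna_subst_rate)
                for col in rng.integers(0, L, size=n_sub):
                    cur = chars[col]
                    chars[col] = rng.choice(NT[NT != cur])
                candidates = np.nonzero(~dele)[0]
                candidates = np.array(
                    [c for c in candidates if c not in self.protected[su]], dtype=int
                )
                n_del = min(rng.poisson(params.rrna_del_rate), len(candidates))
                if n_del:
                    dele[rng.choice(candidates, size=n_del, replace=False)] = True
                node_chars[node] = chars
                node_del[node] = dele
            self.chars[su] = {
                tree.labels[leaf]: node_chars[leaf] for leaf in tree.leaves
            }
            self.deleted[su] = {tree.labels[leaf]: node_del[leaf] for leaf in tree.leaves}

    def colmap(self, su: str, species: str) -> np.ndarray:
        return np.nonzero(~self.deleted[su][species])[0]

    def ungapped(self, su: str, species: str) -> str:
        mask = ~self.deleted[su][species]
        return "".join(self.chars[su][species][mask])

    def ungapped_pos(self, su: str, species: str, column: int) -> int:
        return int((~self.deleted[su][species][:column]).sum())

    def alignment(self, su: str) -> MultipleAlignment:
        rows = {}
        for sp in self.chars[su]:
            chars = self.chars[su][sp].copy().astype(object)
            chars[self.deleted[su][sp]] = "-"
            rows[sp] = "".join(chars)
        return MultipleAlignment(f"rRNA_{su}", rows)


# ---------------------------------------------------------------------------
# snoRNA sequence planting + certification repair
# ---------------------------------------------------------------------------


class _SnoSeq:
    def __init__(self, sno_id: str, family_id: str | None, length: int, rng):
        self.sno_id = sno_id
        self.family_id = family_id
        self.seq = list(rng.choice(NT, size=length))
        self.embeds: list[tuple[int, int, str, str]] = []  # (start, end, subunit, site_id)
        self.shields: list[tuple[int, int]] = []  # guard bases flanking embeds
        self.expected: dict[tuple[str, int, int], str] = {}  # (su, start, end) -> site

    def embed_guide(
        self,
        offset: int,
        window: str,
        su: str,
        site_id: str,
        wstart: int,
        rrna: str,
        rng,
        n_guard: int = 2,
    ):
        """Write the antisense guide and set ``n_guard`` flanking bases
        on each side to deliberate mismatches against the rRNA
        continuation of the duplex, so the planted window can never be
        displaced by a higher-scoring extension.  Guard bases are
        shielded from later repair mutations."""
        g = len(window)
        self.seq[offset : offset + g] = list(revcomp(window))
        self.embeds.append((offset, offset + g, su, site_id))
        self.expected[(su, wstart, wstart + g)] = site_id
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        lo, hi = offset, offset + g
        for p in list(range(offset - n_guard, offset)) + list(range(offset + g, offset + g + n_guard)):
            if not 0 <= p < len(self.seq):
                continue
            # duplex pairing is antiparallel: sno position p pairs with
            # rRNA position wstart + (offset + g - 1 - p)
            u = wstart + (offset + g - 1 - p)
            if 0 <= u < len(rrna):
                bad = comp[rrna[u]]
                self.seq[p] = str(rng.choice(NT[NT != bad]))
            lo, hi = min(lo, p), max(hi, p + 1)
        self.shields.append((lo, hi))

    def masked(self, p: int) -> bool:
        """True if position p is planted material (guide or guard)."""
        return any(lo <= p < hi for lo, hi in self.shields) or any(
            es <= p < ee for es, ee, _, _ in self.embeds
        )

    def text(self) -> str:
        return "".join(self.seq)


def _certify_species(
    species: str,
    rnas: _RnaSet,
    snos: list[_SnoSeq],
    site_windows: dict[str, dict[str, tuple[int, int]]],
    rng: np.random.Generator,
    search: GuideSearchParams,
    max_rounds: int = 300,
) -> None:
    """Repair loop: mutate snoRNA flanks (or, when a spurious match
    falls inside planted material, unprotected rRNA bases) until every
    C/D snoRNA's hit set equals exactly its planted windows.

    ``site_windows[su][site_id]`` gives the planted ungapped window per
    subunit for this species.  Mutating a protected window (last
    resort, cross-site similarity) re-embeds the affected guides.
    """
    protected_u: dict[str, set[int]] = {}
    for su in rnas.lengths:
        pos = {rnas.ungapped_pos(su, species, c) for c in rnas.protected[su]}
        protected_u[su] = pos
    rrna_cache = {su: rnas.ungapped(su, species) for su in rnas.lengths}

    def mutate_rrna(su: str, upos: int) -> None:
        col = int(rnas.colmap(su, species)[upos])
        cur = rnas.chars[su][species][col]
        rnas.chars[su][species][col] = rng.choice(NT[NT != cur])
        rrna_cache[su] = rnas.ungapped(su, species)

    def reembed(su: str, site_id: str) -> None:
        wstart, wend = site_windows[su][site_id]
        window = rrna_cache[su][wstart:wend]
        for s in snos:
            for estart, eend, esu, sid in s.embeds:
                if esu == su and sid == site_id:
                    s.seq[estart:eend] = list(revcomp(window))

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def break_runs(positions: list[int], setter) -> None:
        """Mutate every listed (currently matching) position: the whole
        stretch becomes non-complementary on this diagonal, so no run
        survives and any extension crossing it strictly loses score.
        Mutating all positions (not a subset) matters when several
        overlapping spurious windows constrain the same few bases."""
        for p in positions:
            setter(p)

    def sno_matches(s: _SnoSeq, h, su: str) -> list[int]:
        """snoRNA positions inside the hit whose base is complementary
        to the aligned rRNA base (the duplex pairs in reverse)."""
        out = []
        for p in range(h.snorna_start, h.snorna_end):
            u = h.start + (h.snorna_end - 1 - p)
            if comp.get(s.seq[p]) == rrna_cache[su][u]:
                out.append(p)
        return out

    dirty_snos = {s.sno_id for s in snos}
    for _ in range(max_rounds):
        if not dirty_snos:
            break
        current, dirty_snos = dirty_snos, set()
        for s in snos:
            if s.sno_id not in current:
                continue
            for su in rnas.lengths:
                # snapshot per subunit: a repair in the previous subunit
                # may already have mutated this snoRNA
                record = _as_record(s, species)
                hits = search_guides(record, rrna_cache[su], search, subunit=su)
                for h in hits:
                    if (su, h.start, h.end) in s.expected:
                        continue
                    # repair one hit, then re-search: later hits in this
                    # list may be stale once bases have been mutated
                    dirty_snos.add(s.sno_id)
                    # prefer mutating matching snoRNA flank bases
                    # (planted guides and their guard bases are off-limits) —
                    # unless the planted material alone could sustain a
                    # passing window, in which case only an rRNA mutation at
                    # the spurious target can kill the match for good
                    matched = sno_matches(s, h, su)
                    flank = [p for p in matched if not s.masked(p)]
                    sustain = math.ceil(
                        search.min_identity * search.min_length - 1e-9
                    )
                    if flank and len(matched) - len(flank) < sustain:

                        def set_sno(p):
                            cur = s.seq[p]
                            s.seq[p] = str(rng.choice(NT[NT != cur]))
                            # sticky: never re-randomise this base again —
                            # overlapping spurious windows could otherwise
                            # fight over it with incompatible demands
                            s.shields.append((p, p + 1))

                        break_runs(flank, set_sno)
                        break
                    # match sustained by planted guide material: fix the
                    # rRNA (every C/D snoRNA is then re-checked)
                    matched_p = set(matched)
                    free = [
                        h.start + (h.snorna_end - 1 - p)
                        for p in sorted(matched_p)
                        if h.start + (h.snorna_end - 1 - p) not in protected_u[su]
                    ]
                    if free:
                        break_runs(sorted(free), lambda u: mutate_rrna(su, u))
                        dirty_snos.update(x.sno_id for x in snos)
                        break
                    # protected but outside any guide-bearing site window
                    # (e.g. a known-site column with no planted guide):
                    # safe to mutate directly
                    in_site = lambda u: any(
                        ws <= u < we for ws, we in site_windows[su].values()
                    )
                    loose = [
                        h.start + (h.snorna_end - 1 - p)
                        for p in sorted(matched_p)
                        if not in_site(h.start + (h.snorna_end - 1 - p))
                    ]
                    if loose:
                        break_runs(sorted(loose), lambda u: mutate_rrna(su, u))
                        dirty_snos.update(x.sno_id for x in snos)
                        break
                    # inside a guide-bearing site window (planted-vs-planted
                    # similarity): mutate a random base of that window and
                    # re-embed the guides that target it
                    target = None
                    for sid, (ws, we) in sorted(site_windows[su].items()):
                        if ws < h.end and h.start < we:
                            target = (sid, ws, we)
                            break
                    if target is None:
                        raise RuntimeError(
                            f"unrepairable spurious hit for {s.sno_id} in {species}"
                        )
                    sid, ws, we = target
                    mutate_rrna(su, int(rng.integers(ws, we)))
                    reembed(su, sid)
                    dirty_snos.update(x.sno_id for x in snos)
                    break
    else:
        raise RuntimeError(f"certification did not converge for species {species}")
    # final verification: exactly the planted hits, all perfect
    for s in snos:
        record = _as_record(s, species)
        for su in rnas.lengths:
            hits = search_guides(record, rrna_cache[su], search, subunit=su)
            found = {(su, h.start, h.end) for h in hits}
            want = {k for k in s.expected if k[0] == su}
            if found != want:
                raise RuntimeError(
                    f"certification failed for {s.sno_id} in {species}: "
                    f"{sorted(found)} != {sorted(want)}"
                )


def _as_record(s: _SnoSeq, species: str) -> SnoRNARecord:
    return SnoRNARecord(
        snorna_id=s.sno_id,
        species_id=species,
        family_id=s.family_id,
        sno_class=SnoClass.CD,
        interval=Interval(0, max(len(s.seq), 20)),
        strand="+",
        sequence=s.text(),
    )


# ---------------------------------------------------------------------------
# host genes / introns / genome assembly
# ---------------------------------------------------------------------------


class _GroupModel:
    """One ortholog group: protein alignment evolution and per-species
    intron complements (ancestral + derived, minus losses)."""

    def __init__(self, gid: str, index: int, params: SimulationParams, rng):
        self.gid = gid
        self.index = index
        self.P = params.protein_length
        self.root_aa = rng.choice(AA, size=self.P)
        slots = np.arange(15, self.P - 15, 13)
        order = rng.permutation(slots)
        self.ancestral_cols = sorted(int(c) for c in order[: params.introns_per_gene])
        self._spare = [int(c) for c in order[params.introns_per_gene :]]
        self.essential: set[int] = set()
        self.derived_born: dict[int, int] = {}  # column -> node
        self.strand = "+" if index % 2 == 0 else "-"
        self.has_utr5_intron = index % 3 == 0

    def evolve(self, tree: Phylogeny, params: SimulationParams, rng) -> None:
        protected = set(self.ancestral_cols) | set(self._spare)
        node_aa = {tree.root: self.root_aa.copy()}
        node_del = {tree.root: np.zeros(self.P, dtype=bool)}
        node_introns = {tree.root: set(self.ancestral_cols)}
        for node in sorted(range(1, tree.n_nodes), key=lambda n: tree.depth[n]):
            aa = node_aa[tree.parent[node]].copy()
            dele = node_del[tree.parent[node]].copy()
            introns = set(node_introns[tree.parent[node]])
            n_sub = rng.binomial(self.P, params.protein_subst_rate)
            for col in rng.integers(0, self.P, size=n_sub):
                cur = aa[col]
                aa[col] = rng.choice(AA[AA != cur])
            candidates = [
                c for c in np.nonzero(~dele)[0] if c not in protected
            ]
            n_del = min(rng.poisson(params.protein_del_rate), len(candidates))
            if n_del:
                for c in rng.choice(np.array(candidates), size=n_del, replace=False):
                    dele[c] = True
            # intron loss (essential introns are retained) and gain
            for col in sorted(introns):
                if col not in self.essential and rng.random() < params.intron_loss_prob:
                    introns.discard(col)
            if self._spare and rng.random() < params.intron_gain_prob:
                new = self._spare.pop(0)
                introns.add(new)
                self.derived_born[new] = node
            node_aa[node] = aa
            node_del[node] = dele
            node_introns[node] = introns
        self.leaf_aa = {tree.labels[l]: node_aa[l] for l in tree.leaves}
        self.leaf_del = {tree.labels[l]: node_del[l] for l in tree.leaves}
        self.leaf_introns = {tree.labels[l]: sorted(node_introns[l]) for l in tree.leaves}

    def aa_position(self, species: str, column: int) -> int:
        return int((~self.leaf_del[species][:column]).sum())

    def alignment(self) -> MultipleAlignment:
        rows = {}
        for sp, aa in self.leaf_aa.items():
            chars = aa.copy().astype(object)
            chars[self.leaf_del[sp]] = "-"
            rows[sp] = "".join(chars)
        return MultipleAlignment("protein", rows)


def _build_gene(
    gm: _GroupModel,
    species: str,
    occupants: dict[int, list[_SnoSeq]],
    cursor: int,
    rng: np.random.Generator,
) -> tuple[dict, int]:
    """Assemble one gene in transcript order, then lay it on the genome
    (reverse-complemented for minus-strand genes).  Returns a dict with
    the gene model, snoRNA genomic intervals and the gene sequence."""
    P_s = int((~gm.leaf_del[species]).sum())
    intron_cols = gm.leaf_introns[species]
    aa_pos = [gm.aa_position(species, c) for c in intron_cols]
    bounds = [0] + [3 * a for a in aa_pos] + [3 * P_s]
    assert all(b2 > b1 for b1, b2 in zip(bounds, bounds[1:])), "intron positions collide"
    coding = "".join(rng.choice(NT, size=3 * P_s))
    pieces: list[tuple[str, str, int]] = []  # (kind, seq, payload)
    utr3 = "".join(rng.choice(NT, size=45))
    if gm.has_utr5_intron:
        pieces.append(("exon_utr", "".join(rng.choice(NT, size=60)), -1))
        pieces.append(("intron_utr", "".join(rng.choice(NT, size=120)), -1))
        lead = ""
    else:
        lead = "".join(rng.choice(NT, size=20))
    sno_payloads: list[tuple[str, int, int]] = []  # (sno_id, tx_start, tx_end)

    for i, (b1, b2) in enumerate(zip(bounds, bounds[1:])):
        seq = coding[b1:b2]
        if i == 0:
            seq = lead + seq
        if i == len(bounds) - 2:
            seq = seq + utr3
        pieces.append(("exon_coding", seq, i))
        if i < len(intron_cols):
            col = intron_cols[i]
            intron_seq = list(rng.choice(NT, size=250))
            offset = 40
            spans = []
            for sno in occupants.get(col, []):
                text = sno.text()
                if offset + len(text) + 20 > len(intron_seq):
                    intron_seq.extend(
                        rng.choice(NT, size=offset + len(text) + 40 - len(intron_seq))
                    )
                intron_seq[offset : offset + len(text)] = list(text)
                spans.append((sno.sno_id, offset, offset + len(text)))
                offset += len(text) + 40
            start_of_intron = sum(len(p[1]) for p in pieces)
            pieces.append(("intron_coding", "".join(intron_seq), col))
            for sno_id, s0, s1 in spans:
                sno_payloads.append((sno_id, start_of_intron + s0, start_of_intron + s1))

    tx_seq = "".join(p[1] for p in pieces)
    T = len(tx_seq)
    strand = gm.strand

    def to_genomic(a: int, b: int) -> Interval:
        if strand == "+":
            return Interval(cursor + a, cursor + b)
        return Interval(cursor + T - b, cursor + T - a)

    exons, cds = [], []
    pos = 0
    cds_seen = 0
    for kind, seq, payload in pieces:
        a, b = pos, pos + len(seq)
        if kind.startswith("exon"):
            exons.append(to_genomic(a, b))
            if kind == "exon_coding":
                # coding sub-span within this exon (strip UTR lead/tail)
                ca, cb = a, b
                if payload == 0:
                    ca = a + len(lead)
                if payload == len(bounds) - 2:
                    cb = b - len(utr3)
                if cb > ca:
                    cds.append(to_genomic(ca, cb))
        pos = b
    gene_seq = tx_seq if strand == "+" else revcomp(tx_seq)
    sno_intervals = {
        sno_id: to_genomic(a, b) for sno_id, a, b in sno_payloads
    }
    return (
        {
            "exons": exons,
            "cds": cds,
            "strand": strand,
            "snorna_intervals": sno_intervals,
            "gene_seq": gene_seq,
        },
        cursor + T,
    )


# ---------------------------------------------------------------------------
# the full bundle
# ---------------------------------------------------------------------------


def simulate_bundle(params: SimulationParams) -> SyntheticBundle:
    """Generate the complete input bundle plus truth tables."""
    ss = np.random.SeedSequence(params.seed)
    streams = ss.spawn(8)
    rng_fam = np.random.default_rng(streams[0])
    rng_rna = np.random.default_rng(streams[1])
    rng_guide = np.random.default_rng(streams[2])
    rng_gene = np.random.default_rng(streams[3])
    rng_expr = np.random.default_rng(streams[4])
    rng_repair = np.random.default_rng(streams[5])
    rng_misc = np.random.default_rng(streams[6])

    tree = make_supergroup_tree(params)
    species_list = tree.leaf_names()
    families, presence, losses = simulate_family_evolution(tree, params, rng_fam)

    # ---- clans, cleavage-only flags --------------------------------------
    anc_cd = [
        f for f in sorted(families)
        if families[f].born_node == tree.root and families[f].sno_class is SnoClass.CD
    ]
    leca_cd = [f for f in anc_cd if _expected_leca(tree, presence[f])]
    for fid in anc_cd[: params.n_cleavage_only]:
        families[fid].cleavage_only = True
    guide_eligible = [f for f in leca_cd if not families[f].cleavage_only]
    glo, ghi = params.guide_length_range
    max_per_family = max((params.snorna_length - 10) // (ghi + 6), 1)
    needed = 4 + max(-(-(max(params.n_planted_sites - 3, 0)) // max_per_family), 1)
    if len(guide_eligible) < needed:
        raise ValueError(
            f"family capacity exceeded: {len(guide_eligible)} surviving LECA "
            f"C/D guide families cannot carry {params.n_planted_sites} planted "
            f"sites (need ≥ {needed}); lower loss_prob or the site count"
        )
    clan_dup = guide_eligible[:2]
    clan_split = guide_eligible[2:4]
    for fid in clan_dup:
        families[fid].clan_id = "CL_DUP"
    for fid in clan_split:
        families[fid].clan_id = "CL_SPL"
    pool = [f for f in anc_cd if families[f].clan_id is None and not families[f].cleavage_only]
    for i in range(params.n_generic_clans):
        pair = pool[4 + 2 * i : 6 + 2 * i]
        if len(pair) < 2:
            break
        for fid in pair:
            families[fid].clan_id = f"CL{i + 1:03d}"

    # ---- mobility events --------------------------------------------------
    internal = [
        n
        for n in range(1, tree.n_nodes)
        if tree.children[n] and len(tree.leaves_under(n)) >= 2
    ]
    mobile_pool = [
        f
        for f in sorted(families)
        if families[f].born_node == tree.root and not families[f].immune
    ]
    mobility: list[dict] = []
    attempts = 0
    while len(mobility) < params.n_mobility_events and attempts < 200:
        attempts += 1
        node = int(rng_fam.choice(internal))
        fid = str(rng_fam.choice(mobile_pool))
        clade = tree.leaves_under(node)
        if any(m["family"] == fid for m in mobility):
            continue
        # the family must have survived to this branch
        if not presence[fid] & clade:
            continue
        presence[fid] = set(presence[fid]) | set(clade)  # persistent after the move
        mobility.append({"family": fid, "node": node, "retain_source": bool(rng_fam.random() < params.source_retention_prob)})
    if len(mobility) < params.n_mobility_events:
        raise RuntimeError("could not place all mobility events")

    # ---- rRNA with planted sites ------------------------------------------
    rnas = _RnaSet(tree, params, rng_rna)
    subunits = list(rnas.lengths)
    n_special = 1 + 2  # split-clan site + two dup-clan sites
    n_regular = max(params.n_planted_sites - n_special, 0)
    site_list: list[_Site] = []

    def new_site(idx: int, su: str, col: int, confined: bool) -> _Site:
        return _Site(
            site_id=f"site{idx:03d}",
            subunit=su,
            column=col,
            guide_len=int(rng_guide.integers(glo, ghi + 1)),
            confined=confined,
        )

    per_su_counts = {su: 0 for su in subunits}
    total_sites = params.n_planted_sites + params.n_confined_sites + params.n_known_extra
    for i in range(total_sites):
        per_su_counts[subunits[i % len(subunits)]] += 1
    cols_by_su = {
        su: rnas.reserve_columns(su, per_su_counts[su], 24, rng_guide) for su in subunits
    }
    cursor_su = {su: 0 for su in subunits}

    def take_col(su: str) -> int:
        col = cols_by_su[su][cursor_su[su]]
        cursor_su[su] += 1
        return col

    for i in range(params.n_planted_sites):
        su = subunits[i % len(subunits)]
        site_list.append(new_site(i, su, take_col(su), confined=False))
    confined_sites = []
    for j in range(params.n_confined_sites):
        su = subunits[(params.n_planted_sites + j) % len(subunits)]
        s = new_site(params.n_planted_sites + j, su, take_col(su), confined=True)
        site_list.append(s)
        confined_sites.append(s)
    extra_cols = []
    for j in range(params.n_known_extra):
        su = subunits[(params.n_planted_sites + params.n_confined_sites + j) % len(subunits)]
        extra_cols.append((su, take_col(su)))

    # protect all planted windows (center ± 8 covers the longest guide)
    for s in site_list:
        rnas.protect(s.subunit, range(s.column - 8, s.column + 9))
    for su, col in extra_cols:
        rnas.protect(su, range(col - 8, col + 9))
    rnas.evolve(params, rng_rna)

    # assign sites to families
    cross = [s for s in site_list if not s.confined]
    cross[0].families = list(clan_split)
    cross[1].families = [clan_dup[0]]
    cross[2].families = [clan_dup[1]]
    rot = [f for f in guide_eligible if f not in set(clan_split) | set(clan_dup)]
    counts = {f: 0 for f in rot}
    ri = 0
    for s in cross[3:]:
        for _ in range(len(rot) * 2):
            fid = rot[ri % len(rot)]
            ri += 1
            if counts[fid] < max_per_family:
                s.families = [fid]
                counts[fid] += 1
                break
        else:
            raise ValueError("not enough C/D family capacity for the planted sites")
    conf_fams = [f for f in sorted(families) if f.startswith("S")]
    for s, fid in zip(confined_sites, conf_fams):
        s.families = [fid]
    for s in site_list:
        for fid in s.families:
            families[fid].sites.append(s.site_id)
    sites_by_id = {s.site_id: s for s in site_list}

    # ---- home loci --------------------------------------------------------
    group_ids = [f"G{i + 1:02d}" for i in range(params.n_host_genes)]
    gms = {
        gid: _GroupModel(gid, i, params, rng_gene) for i, gid in enumerate(group_ids)
    }
    slot_pool = [
        (gid, col) for gid in group_ids for col in gms[gid].ancestral_cols
    ]
    slot_order = [slot_pool[i] for i in rng_gene.permutation(len(slot_pool))]
    slot_cursor = 0

    def take_slot() -> tuple[str, int]:
        nonlocal slot_cursor
        if slot_cursor >= len(slot_order):
            raise ValueError("not enough intron slots for family homes")
        s = slot_order[slot_cursor]
        slot_cursor += 1
        return s

    for fid in sorted(families):
        fam = families[fid]
        if fid.startswith("V"):
            continue  # convergent pairs share a slot, handled below
        if rng_gene.random() < params.intergenic_prob:
            fam.home = ("intergenic",)
        else:
            gid, col = take_slot()
            fam.home = ("intron", gid, col)
            gms[gid].essential.add(col)
    convergent_truth = []
    for p in range(params.n_convergent_pairs):
        gid, col = take_slot()
        a, b = f"V{p + 1:02d}A", f"V{p + 1:02d}B"
        families[a].home = ("intron", gid, col)
        families[b].home = ("intron", gid, col)
        gms[gid].essential.add(col)
        convergent_truth.append({"group": gid, "column": col, "families": [a, b]})
    mob_truth = []
    for m in mobility:
        gid, col = take_slot()
        m["dest"] = (gid, col)
        gms[gid].essential.add(col)
        mob_truth.append(m)

    for gid in group_ids:
        gms[gid].evolve(tree, params, rng_gene)

    # ---- occupancy map: (species, gid, col) -> families -------------------
    def home_of(fid: str, sp: str) -> tuple | None:
        fam = families[fid]
        for m in mobility:
            if m["family"] == fid and sp in tree.leaves_under(m["node"]):
                if m["retain_source"]:
                    return ("both", fam.home, ("intron", *m["dest"]))
                return ("intron", *m["dest"])
        return fam.home

    occupancy: dict[tuple[str, str, int], list[str]] = {}
    intergenic_by_sp: dict[str, list[str]] = {sp: [] for sp in species_list}
    for fid in sorted(families):
        for sp in sorted(presence[fid]):
            home = home_of(fid, sp)
            homes = []
            if home is None:
                continue
            if home[0] == "both":
                homes = [home[1], home[2]]
            else:
                homes = [home]
            for h in homes:
                if h[0] == "intergenic":
                    intergenic_by_sp[sp].append(fid)
                else:
                    _, gid, col = h
                    occupancy.setdefault((sp, gid, col), []).append(fid)

    # ---- snoRNA sequences with guides, certified --------------------------
    search = GuideSearchParams()
    sno_seqs: dict[str, dict[str, _SnoSeq]] = {sp: {} for sp in species_list}
    site_windows: dict[str, dict[str, dict[str, tuple[int, int]]]] = {
        sp: {su: {} for su in subunits} for sp in species_list
    }
    for sp in species_list:
        for s in site_list:
            upos = rnas.ungapped_pos(s.subunit, sp, s.column)
            g = s.guide_len
            wstart = upos - (g - 1) // 2
            site_windows[sp][s.subunit][s.site_id] = (wstart, wstart + g)

    decoy_sp = [species_list[i % len(species_list)] for i in range(params.n_decoys)]
    for sp in species_list:
        rrna_str = {su: rnas.ungapped(su, sp) for su in subunits}
        for fid in sorted(families):
            if sp not in presence[fid]:
                continue
            fam = families[fid]
            sno = _SnoSeq(f"{fid}.{sp}", fid, params.snorna_length, rng_guide)
            if fam.sno_class is SnoClass.CD:
                offset = 5
                for site_id in fam.sites:
                    s = sites_by_id[site_id]
                    wstart, wend = site_windows[sp][s.subunit][site_id]
                    window = rrna_str[s.subunit][wstart:wend]
                    sno.embed_guide(
                        offset, window, s.subunit, site_id, wstart,
                        rrna_str[s.subunit], rng_guide,
                    )
                    offset += (wend - wstart) + 6
            sno_seqs[sp][sno.sno_id] = sno
        for d, dsp in enumerate(decoy_sp):
            if dsp != sp:
                continue
            sno = _SnoSeq(f"DEC{d + 1:03d}.{sp}", None, params.snorna_length, rng_guide)
            sno_seqs[sp][sno.sno_id] = sno

    for sp in species_list:
        cd_like = [
            s
            for s in sno_seqs[sp].values()
            if s.family_id is None or families[s.family_id].sno_class is SnoClass.CD
        ]
        _certify_species(
            sp, rnas, sorted(cd_like, key=lambda s: s.sno_id), site_windows[sp], rng_repair, search
        )

    # ---- genomes ----------------------------------------------------------
    annotations: dict[str, GenomeAnnotation] = {}
    genome_seqs: dict[str, str] = {}
    for sp in species_list:
        ann = GenomeAnnotation(species_id=sp)
        chunks: list[str] = []
        cursor = 0
        for gid in group_ids:
            gm = gms[gid]
            spacer = "".join(rng_misc.choice(NT, size=300))
            chunks.append(spacer)
            cursor += 300
            occ = {
                col: [
                    sno_seqs[sp][f"{fid}.{sp}"]
                    for fid in occupancy.get((sp, gid, col), [])
                ]
                for col in gm.leaf_introns[sp]
            }
            built, cursor = _build_gene(gm, sp, occ, cursor, rng_misc)
            chunks.append(built["gene_seq"])
            gene_id = f"{gid}.{sp}"
            tx = Transcript(
                transcript_id=f"{gene_id}.t1",
                gene_id=gene_id,
                strand=built["strand"],
                exons=built["exons"],
                cds=built["cds"],
            )
            gene = Gene(gene_id=gene_id, strand=built["strand"], transcripts=[tx])
            ann.genes[gene_id] = gene
            for sno_id, iv in sorted(built["snorna_intervals"].items()):
                s = sno_seqs[sp][sno_id]
                ann.snornas.append(
                    SnoRNARecord(
                        snorna_id=sno_id,
                        species_id=sp,
                        family_id=s.family_id,
                        sno_class=families[s.family_id].sno_class
                        if s.family_id
                        else SnoClass.CD,
                        interval=iv,
                        strand=built["strand"],
                        sequence=s.text(),
                    )
                )
        # intergenic snoRNAs and decoys at the end of the chromosome
        tail_ids = [f"{fid}.{sp}" for fid in sorted(set(intergenic_by_sp[sp]))]
        tail_ids += sorted(
            sid for sid in sno_seqs[sp] if sid.startswith("DEC")
        )
        for sid in tail_ids:
            s = sno_seqs[sp][sid]
            spacer = "".join(rng_misc.choice(NT, size=120))
            chunks.append(spacer)
            cursor += 120
            text = s.text()
            chunks.append(text)
            iv = Interval(cursor, cursor + len(text))
            cursor += len(text)
            fam = s.family_id
            ann.snornas.append(
                SnoRNARecord(
                    snorna_id=sid,
                    species_id=sp,
                    family_id=fam,
                    sno_class=families[fam].sno_class if fam else SnoClass.CD,
                    interval=iv,
                    strand="+",
                    sequence=text,
                )
            )
        chunks.append("".join(rng_misc.choice(NT, size=200)))
        genome_seqs[sp] = "".join(chunks)
        annotations[sp] = ann

    # ---- catalog ----------------------------------------------------------
    catalog = FamilyCatalog(
        [
            FamilyInfo(
                family_id=fid,
                clan_id=families[fid].clan_id,
                sno_class=families[fid].sno_class,
                cleavage_only=families[fid].cleavage_only,
            )
            for fid in sorted(families)
        ]
    )

    # ---- known sites -------------------------------------------------------
    known_rows = []
    for s in site_list:
        if s.confined:
            continue
        for fid in s.families:
            for sp in sorted(presence[fid]):
                upos = rnas.ungapped_pos(s.subunit, sp, s.column)
                base = str(rnas.chars[s.subunit][sp][s.column])
                known_rows.append(
                    {
                        "species": sp,
                        "subunit": s.subunit,
                        "site_position": upos,
                        "modification_type": f"{base}m",
                        "snorna_id": f"{fid}.{sp}",
                        "family_id": fid,
                    }
                )
    ref_sp = species_list[0]
    for su, col in extra_cols:
        upos = rnas.ungapped_pos(su, ref_sp, col)
        base = str(rnas.chars[su][ref_sp][col])
        known_rows.append(
            {
                "species": ref_sp,
                "subunit": su,
                "site_position": upos,
                "modification_type": f"{base}m",
                "snorna_id": "",
                "family_id": "",
            }
        )
    known = pd.DataFrame(known_rows)

    # ---- ortholog groups ---------------------------------------------------
    groups = {
        gid: OrthologGroup(
            group_id=gid,
            members={sp: (f"{gid}.{sp}", f"{gid}.{sp}.t1") for sp in species_list},
            alignment=gms[gid].alignment(),
        )
        for gid in group_ids
    }

    # ---- expression --------------------------------------------------------
    host_groups = sorted(
        {gid for (sp, gid, col) in occupancy if sp == ref_sp}
    )
    host_genes = [f"{gid}.{ref_sp}" for gid in host_groups]
    nonhost_genes = [
        f"{gid}.{ref_sp}" for gid in group_ids if gid not in set(host_groups)
    ] + [f"NH{i + 1:04d}" for i in range(params.n_nonhost_genes)]
    expression, expr_truth = simulate_expression(host_genes, nonhost_genes, params, rng_expr)

    # ---- truth tables ------------------------------------------------------
    intron_truth = {}
    for gid in group_ids:
        gm = gms[gid]
        all_cols = sorted(set(gm.ancestral_cols) | set(gm.derived_born))
        for col in all_cols:
            sp_with = sorted(
                sp for sp in species_list if col in gm.leaf_introns[sp]
            )
            if not sp_with:
                continue
            intron_truth[f"{gid}:c{col}"] = {
                "group": gid,
                "column": col,
                "species": sp_with,
                "ancestral": col in gm.ancestral_cols,
                "expected_leca": _expected_leca(tree, set(sp_with)),
                "occupants": {
                    sp: sorted(occupancy.get((sp, gid, col), []))
                    for sp in sp_with
                    if occupancy.get((sp, gid, col))
                },
            }
    site_truth = {}
    for s in site_list:
        carriers = sorted(set().union(*(presence[f] for f in s.families)) if s.families else set())
        site_truth[s.site_id] = {
            "subunit": s.subunit,
            "column": s.column,
            "guide_len": s.guide_len,
            "families": sorted(s.families),
            "species": carriers,
            "confined": s.confined,
            "expected_leca": _expected_leca(tree, set(carriers)),
            "ungapped_positions": {
                sp: rnas.ungapped_pos(s.subunit, sp, s.column) for sp in carriers
            },
        }
    family_truth = {
        fid: {
            "sno_class": families[fid].sno_class.value,
            "clan": families[fid].clan_id,
            "cleavage_only": families[fid].cleavage_only,
            "born_node": tree.node_name(families[fid].born_node),
            "presence": sorted(presence[fid]),
            "expected_leca": _expected_leca(tree, presence[fid]),
            "home": list(families[fid].home) if families[fid].home else None,
            "sites": sorted(families[fid].sites),
        }
        for fid in sorted(families)
    }
    mobility_truth = [
        {
            "family": m["family"],
            "node": tree.node_name(m["node"]),
            "node_index": m["node"],
            "dest_group": m["dest"][0],
            "dest_column": m["dest"][1],
            "dest_locus": f"{m['dest'][0]}:c{m['dest'][1]}",
            "carriers": sorted(tree.leaves_under(m["node"])),
            "retain_source": m["retain_source"],
        }
        for m in mob_truth
    ]
    truth = {
        "families": family_truth,
        "sites": site_truth,
        "intron_loci": intron_truth,
        "mobility": mobility_truth,
        "convergent": convergent_truth,
        "expression": expr_truth,
        "n_recoverable_known": int((known["family_id"] != "").sum()),
        "reference_species": ref_sp,
    }

    inputs = InputSet(
        tree=tree,
        catalog=catalog,
        annotations=annotations,
        rrna_alignments={su: rnas.alignment(su) for su in subunits},
        groups=groups,
        known_sites=known,
        expression=expression,
        expression_species=ref_sp,
    )
    bundle = SyntheticBundle(params=params, inputs=inputs, truth=truth)
    bundle.genomes = genome_seqs  # type: ignore[attr-defined]
    return bundle


# ---------------------------------------------------------------------------
# writing & verification
# ---------------------------------------------------------------------------


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> None:
    """Write the bundle as the standard on-disk input layout consumed
    by the pipeline loader, plus ``truth/*.json``."""
    from . import io as sio

    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "alignments" / "groups").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    inputs = bundle.inputs
    (out / "tree.nwk").write_text(inputs.tree.to_newick() + "\n")
    sg_lines = ["species\tsupergroup"] + [
        f"{sp}\t{inputs.tree.supergroups[sp]}" for sp in inputs.tree.leaf_names()
    ]
    (out / "supergroups.tsv").write_text("\n".join(sg_lines) + "\n")
    with open(out / "families.tsv", "w") as fh:
        sio.write_family_catalog(inputs.catalog, fh)
    all_snos = {}
    for sp in sorted(inputs.annotations):
        ann = inputs.annotations[sp]
        (out / "genomes" / f"{sp}.gff3").write_text(sio.write_genome_annotation(ann))
        with open(out / "genomes" / f"{sp}.fa", "w") as fh:
            sio.write_fasta({"chr1": bundle.genomes[sp]}, fh)  # type: ignore[attr-defined]
        for sno in ann.snornas:
            all_snos[sno.snorna_id] = sno.sequence
    with open(out / "snornas.fa", "w") as fh:
        sio.write_fasta(dict(sorted(all_snos.items())), fh)
    for su, aln in inputs.rrna_alignments.items():
        with open(out / "alignments" / f"rRNA_{su}.afa", "w") as fh:
            sio.write_alignment(aln, fh)
    rows = []
    for gid in sorted(inputs.groups):
        group = inputs.groups[gid]
        with open(out / "alignments" / "groups" / f"{gid}.afa", "w") as fh:
            sio.write_alignment(group.alignment, fh)
        for sp in sorted(group.members):
            gene_id, tx_id = group.members[sp]
            rows.append(
                {"group_id": gid, "species": sp, "gene_id": gene_id, "transcript_id": tx_id}
            )
    pd.DataFrame(rows).to_csv(out / "ortholog_groups.tsv", sep="\t", index=False)
    inputs.known_sites.to_csv(out / "known_sites.tsv", sep="\t", index=False)
    if inputs.expression is not None:
        inputs.expression.round(6).to_csv(out / "expression.tsv", sep="\t", index_label="gene")
    for name, table in bundle.truth.items():
        if isinstance(table, (dict, list)):
            (out / "truth" / f"{name}.json").write_text(
                json.dumps(table, indent=2, sort_keys=True) + "\n"
            )
    (out / "truth" / "meta.json").write_text(
        json.dumps(
            {
                "seed": bundle.params.seed,
                "n_species": len(inputs.tree.leaf_names()),
                "reference_species": bundle.truth["reference_species"],
                "n_recoverable_known": bundle.truth["n_recoverable_known"],
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )


def verify_bundle(bundle: SyntheticBundle) -> None:
    """Independent replay checker: the emitted files must reproduce the
    recorded truth (single origin, presence, occupancy containment and
    guide complementarity)."""
    inputs = bundle.inputs
    tree = inputs.tree
    fam_truth = bundle.truth["families"]
    # presence replay from annotations
    obs: dict[str, set[str]] = {}
    for sp, ann in inputs.annotations.items():
        for sno in ann.snornas:
            if sno.family_id:
                obs.setdefault(sno.family_id, set()).add(sp)
    for fid, rec in fam_truth.items():
        got = sorted(obs.get(fid, set()))
        if got != rec["presence"]:
            raise AssertionError(f"presence mismatch for {fid}: {got} != {rec['presence']}")
        # single origin: presence confined to the gain clade
        born = rec["born_node"]
        clade = {
            tree.node_name(n): tree.leaves_under(n) for n in range(tree.n_nodes)
        }[born]
        if not set(rec["presence"]) <= clade:
            raise AssertionError(f"{fid}: presence escapes its gain clade")
    # guide complementarity: every planted window's revcomp occurs in the snoRNA
    for sid, rec in bundle.truth["sites"].items():
        for fid in rec["families"]:
            for sp in rec["species"]:
                if sp not in fam_truth[fid]["presence"]:
                    continue
                aln = inputs.rrna_alignments[rec["subunit"]]
                rrna = aln.ungapped(sp)
                upos = rec["ungapped_positions"][sp]
                g = rec["guide_len"]
                wstart = upos - (g - 1) // 2
                window = rrna[wstart : wstart + g]
                sno = next(
                    s for s in inputs.annotations[sp].snornas if s.snorna_id == f"{fid}.{sp}"
                )
                if revcomp(window) not in sno.sequence:
                    raise AssertionError(f"guide for {sid}/{fid}/{sp} not embedded")
    # occupancy containment
    for lid, rec in bundle.truth["intron_loci"].items():
        for sp, fams in rec.get("occupants", {}).items():
            ann = inputs.annotations[sp]
            for fid in fams:
                sno = next(s for s in ann.snornas if s.snorna_id == f"{fid}.{sp}")
                gene = ann.genes[f"{rec['group']}.{sp}"]
                tx = gene.transcripts[0]
                if not any(iv.contains(sno.interval) for iv in tx.introns()):
                    raise AssertionError(f"occupant {fid}.{sp} not inside an intron of {lid}")
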