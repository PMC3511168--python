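"""Antisense mapping of C/D snoRNA guides onto rRNA.

Box C/D snoRNAs direct 2'-O-methylation through a contiguous guide
element base-paired antisense to the target rRNA.  The search here is
a deterministic word-seeded, ungapped reimplementation of a
short-sequence blastn run (word size 5, gap penalties high enough that
gapped alignments never occur at guide scale):

1. the reverse complement of the snoRNA is compared against the rRNA;
2. every diagonal sharing an exact ``word_size``-mer is scanned and
   every ungapped window of length ≥ ``min_length`` and identity ≥
   ``min_identity`` that begins and ends in a matched base becomes a
   candidate (trimming to the maximal-scoring extent always strips
   edge mismatches, so hits are match-bounded);
3. overlapping candidates are deduplicated to the best-scoring one
   (score = matches·match + mismatches·mismatch, ties to the leftmost,
   then longest, window).

With the default thresholds every reportable window necessarily
contains an exact run of ≥ 5 matches (pigeonhole: a window of length L
with ≤ ⌊L/10⌋ mismatches has a match run ≥ 5), so restricting to
seeded diagonals loses nothing and the output equals an exhaustive
scan of all ungapped antisense windows.  H/ACA snoRNAs have bipartite
guides and are rejected (no equivalent analysis is attempted).

Hit centers are projected into curated-alignment columns so that
per-species coordinates become comparable, then binned into
cross-species site loci by single-linkage clustering at ± 2 columns;
loci seen in a single species are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .datamodel import (
    MultipleAlignment,
    SnoClass,
    SnoRNARecord,
    revcomp,
    ungapped_to_column,
)
from .dollo import PresenceMatrix, reconstruct
from .phylo import Phylogeny

__all__ = [
    "GuideSearchParams",
    "LocusBinningParams",
    "GuideHit",
    "SiteLocus",
    "SnoClassError",
    "search_guides",
    "project_hit",
    "bin_sites",
    "infer_leca_sites",
    "compare_to_known",
    "single_linkage_bins",
]


class SnoClassError(ValueError):
    """Guide search applied to a snoRNA class it does not support."""


@dataclass(frozen=True)
class GuideSearchParams:
    word_size: int = 5
    match_score: int = 1
    mismatch_score: int = -2
    min_length: int = 10
    min_identity: float = 0.9

    def __post_init__(self):
        if self.word_size < 4:
            raise ValueError("word_size must be ≥ 4")
        if self.min_length < self.word_size:
            raise ValueError("min_length must be ≥ word_size")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class LocusBinningParams:
    site_tolerance: int = 2  # alignment columns, rRNA site loci
    intron_tolerance: int = 5  # alignment columns (amino acids), intron loci

    def __post_init__(self):
        if self.site_tolerance < 0 or self.intron_tolerance < 0:
            raise ValueError("tolerances must be ≥ 0")


@dataclass
class GuideHit:
    snorna_id: str
    family_id: str | None
    species_id: str
    subunit: str  # SSU | LSU
    start: int  # rRNA, ungapped 0-based half-open
    end: int
    snorna_start: int  # matched segment on the snoRNA (0-based half-open)
    snorna_end: int
    score: int
    identity: float
    center_column: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Single-nucleotide hit center on the rRNA (floor midpoint)."""
        return (self.start + self.end - 1) // 2


@dataclass
class SiteLocus:
    locus_id: str
    subunit: str
    column: int  # representative alignment column
    hits: list[GuideHit] = field(default_factory=list)

    @property
    def species(self) -> set[str]:
        return {h.species_id for h in self.hits}

    @property
    def families(self) -> set[str]:
        return {h.family_id for h in self.hits if h.family_id is not None}

    def local_coordinates(self) -> dict[str, list[tuple[str, int]]]:
        """Per-species (snoRNA id, ungapped rRNA center) pairs."""
        out: dict[str, list[tuple[str, int]]] = {}
        for h in sorted(self.hits, key=lambda h: (h.species_id, h.snorna_id, h.start)):
            out.setdefault(h.species_id, []).append((h.snorna_id, h.center))
        return out


@lru_cache(maxsize=16)
def _word_index(rrna: str, word_size: int) -> dict[str, tuple[int, ...]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(rrna) - word_size + 1):
        idx.setdefault(rrna[i : i + word_size], []).append(i)
    return {w: tuple(ps) for w, ps in idx.items()}


def _passing_windows(
    query: str, rrna: str, params: GuideSearchParams
) -> list[tuple[int, int, int, int, int]]:
    """All (rstart, rend, qstart, score, matches) windows on seeded
    diagonals passing the length/identity thresholds."""
    w = params.word_size
    n, m = len(query), len(rrna)
    if n < w or m < w:
        return []
    index = _word_index(rrna, w)
    diags: set[int] = set()
    for qpos in range(n - w + 1):
        for gpos in index.get(query[qpos : qpos + w], ()):
            diags.add(gpos - qpos)
    qa = np.frombuffer(query.encode(), dtype=np.uint8)
    ra = np.frombuffer(rrna.encode(), dtype=np.uint8)
    min_len, min_id = params.min_length, params.min_identity
    thr = [
        max(ell - int((1.0 - min_id) * ell + 1e-9), 0) for ell in range(n + 1)
    ]  # min matches so that matches/ell ≥ min_identity
    out: list[tuple[int, int, int, int, int]] = []

    def emit(qstart: int, ell: int, mt: int, d: int) -> None:
        score = mt * params.match_score + (ell - mt) * params.mismatch_score
        out.append((qstart + d, qstart + d + ell, qstart, score, mt))

    for d in sorted(diags):
        qlo, qhi = max(0, -d), min(n, m - d)
        L = qhi - qlo
        if L < min_len:
            continue
        match = qa[qlo:qhi] == ra[qlo + d : qhi + d]
        idx = np.flatnonzero(match)
        if idx.size < thr[min_len]:
            continue
        # maximal runs of consecutive matches, half-open [starts, ends)
        brk = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([idx[0]], idx[brk + 1]))
        ends = np.concatenate((idx[brk] + 1, [idx[-1] + 1]))
        R = len(starts)
        mm_budget = int((1.0 - min_id) * L + 1e-9)
        for i in range(R):
            si, ei = int(starts[i]), int(ends[i])
            mi = ei - si
            # windows wholly inside run i (all-match)
            for s in range(si, ei - min_len + 1):
                for e in range(s + min_len, ei + 1):
                    emit(qlo + s, e - s, e - s, d)
            # windows spanning runs i..j with the intervening mismatches
            mm = 0
            mid = 0
            for j in range(i + 1, R):
                sj, ej = int(starts[j]), int(ends[j])
                mm += sj - int(ends[j - 1])
                if j > i + 1:
                    mid += int(ends[j - 1]) - int(starts[j - 1])
                if mm > mm_budget:
                    break
                mj = ej - sj
                best = mi + mid + mj
                if best < thr[best + mm]:
                    continue  # even the maximal window fails identity
                for a in range(1, mi + 1):  # suffix of run i
                    for b in range(1, mj + 1):  # prefix of run j
                        mt = a + mid + b
                        ell = mt + mm
                        if ell >= min_len and mt >= thr[ell]:
                            emit(qlo + ei - a, ell, mt, d)
    return out


def _dedup_best(windows: list[tuple[int, int, int, int, int]]):
    """Greedy best-score selection of non-overlapping (on the rRNA)
    windows; ties resolved to the leftmost, then the longest, window."""
    kept: list[tuple[int, int, int, int, int]] = []
    for win in sorted(windows, key=lambda t: (-t[3], t[0], -(t[1] - t[0]), t[2])):
        if all(win[1] <= k[0] or k[1] <= win[0] for k in kept):
            kept.append(win)
    kept.sort(key=lambda t: t[0])
    return kept


def search_guides(
    snorna: SnoRNARecord,
    rrna: str,
    params: GuideSearchParams = GuideSearchParams(),
    subunit: str = "SSU",
) -> list[GuideHit]:
    """Find all antisense guide matches of a C/D snoRNA on an ungapped
    rRNA sequence (see module docstring for the exact semantics)."""
    if snorna.sno_class is not SnoClass.CD:
        raise SnoClassError(
            f"{snorna.snorna_id} is {snorna.sno_class.value}; guide search is C/D-only"
        )
    query = revcomp(snorna.sequence)
    n = len(query)
    hits = []
    for rstart, rend, qstart, score, mt in _dedup_best(_passing_windows(query, rrna, params)):
        ell = rend - rstart
        hits.append(
            GuideHit(
                snorna_id=snorna.snorna_id,
                family_id=snorna.family_id,
                species_id=snorna.species_id,
                subunit=subunit,
                start=rstart,
                end=rend,
                snorna_start=n - (qstart + ell),
                snorna_end=n - qstart,
                score=score,
                identity=mt / ell,
            )
        )
    return hits


def project_hit(hit: GuideHit, alignment: MultipleAlignment) -> GuideHit:
    """Fill ``center_column``: the alignment column of the hit center,
    making per-species rRNA coordinates comparable across species."""
    hit.center_column = ungapped_to_column(alignment, hit.species_id, hit.center)
    return hit


def single_linkage_bins(values: list[int], tolerance: int) -> list[list[int]]:
    """Single-linkage clusters of integer positions: the transitive
    closure of |Δ| ≤ tolerance, computed over sorted values."""
    order = sorted(range(len(values)), key=lambda i: (values[i], i))
    bins: list[list[int]] = []
    prev = None
    for i in order:
        if prev is None or values[i] - prev > tolerance:
            bins.append([])
        bins[-1].append(i)
        prev = values[i]
    return bins


def bin_sites(
    hits: list[GuideHit],
    params: LocusBinningParams = LocusBinningParams(),
    min_species: int = 2,
) -> list[SiteLocus]:
    """Cluster projected hits of one rRNA subunit into site loci
    (single-linkage, link distance ≤ site tolerance); loci seen in
    fewer than ``min_species`` distinct species are discarded."""
    if not hits:
        return []
    subunits = {h.subunit for h in hits}
    if len(subunits) > 1:
        raise ValueError(f"bin_sites expects a single subunit, got {sorted(subunits)}")
    if any(h.center_column is None for h in hits):
        raise ValueError("all hits must be projected to alignment columns before binning")
    subunit = subunits.pop()
    loci = []
    cols = [h.center_column for h in hits]
    for members in single_linkage_bins(cols, params.site_tolerance):
        mhits = sorted(
            (hits[i] for i in members),
            key=lambda h: (h.center_column, h.species_id, h.snorna_id, h.start),
        )
        if len({h.species_id for h in mhits}) < min_species:
            continue
        centers = sorted(h.center_column for h in mhits)
        rep = centers[(len(centers) - 1) // 2]  # lower median: deterministic
        loci.append(SiteLocus(locus_id=f"{subunit}:c{rep}", subunit=subunit, column=rep, hits=mhits))
    loci.sort(key=lambda l: l.column)
    return loci


def infer_leca_sites(loci: list[SiteLocus], tree: Phylogeny) -> set[str]:
    """Site loci whose phylogenetic distribution is compatible with
    presence in LECA under Dollo parsimony (root state 1)."""
    if not loci:
        return set()
    obs = {l.locus_id: l.species for l in loci}
    matrix = PresenceMatrix.from_observations(obs, tree.leaf_names(), "site_locus")
    recon = reconstruct(tree, matrix)
    return recon.leca_characters()


def compare_to_known(
    loci: list[SiteLocus],
    known: pd.DataFrame,
    alignments: dict[str, MultipleAlignment],
    tolerance: int = 2,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Recovery of a known-modification-site table by the mapped loci.

    A known site (one row: species, subunit, ungapped position) is
    recovered iff some locus contains a hit from that species whose
    center column lies within ``tolerance`` of the projected known
    position.  Returns the per-row report plus totals.
    """
    rows = []
    for row in known.itertuples(index=False):
        aln = alignments[row.subunit]
        col = ungapped_to_column(aln, row.species, int(row.site_position))
        recovered = any(
            h.species_id == row.species and abs(h.center_column - col) <= tolerance
            for locus in loci
            if locus.subunit == row.subunit
            for h in locus.hits
        )
        rows.append(
            {
                "species": row.species,
                "subunit": row.subunit,
                "site_position": int(row.site_position),
                "site_column": col,
                "modification_type": row.modification_type,
                "family_id": row.family_id,
                "recovered": recovered,
            }
        )
    report = pd.DataFrame(rows)
    totals = {
        "n_known": len(report),
        "n_recovered": int(report["recovered"].sum()) if len(report) else 0,
    }
    return report, totals
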