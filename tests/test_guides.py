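"""Guide search, projection, site binning and LECA-site inference."""

import numpy as np
import pytest

from oracles import brute_force_guide_windows, transitive_closure_components
from snoleca.datamodel import Interval, MultipleAlignment, SnoClass, SnoRNARecord, revcomp
from snoleca.guides import (
    GuideHit,
    GuideSearchParams,
    LocusBinningParams,
    SnoClassError,
    bin_sites,
    compare_to_known,
    infer_leca_sites,
    project_hit,
    search_guides,
    single_linkage_bins,
)

NT = list("ACGT")


def sno(seq, species="sp1", fam="RF1", cls=SnoClass.CD, sid="sno1"):
    return SnoRNARecord(
        snorna_id=sid,
        species_id=species,
        family_id=fam,
        sno_class=cls,
        interval=Interval(0, max(len(seq), 20)),
        strand="+",
        sequence=seq,
    )


def hit(species, column, subunit="SSU", fam="RF1", sid=None, start=100):
    return GuideHit(
        snorna_id=sid or f"s_{species}_{column}",
        family_id=fam,
        species_id=species,
        subunit=subunit,
        start=start,
        end=start + 12,
        snorna_start=0,
        snorna_end=12,
        score=12,
        identity=1.0,
        center_column=column,
    )


class TestSearchGuides:
    def test_planted_perfect_complement(self, rng):
        rrna = "".join(rng.choice(NT, size=400))
        window = rrna[200:212]
        seq = "TTTTTGGGTT" + revcomp(window) + "TTGGTTTTGG"
        hits = search_guides(sno(seq + "TGGTGGTGGTGGTTGGTTGGTGGTGGTT"), rrna)
        planted = [h for h in hits if (h.start, h.end) == (200, 212)]
        assert len(planted) == 1
        assert planted[0].identity == 1.0
        assert planted[0].center == (200 + 211) // 2

    def test_central_mismatch_keeps_full_hit(self):
        rrna = "A" * 50 + "ACGTACGTACGT" + "A" * 50
        window = "ACGTACGTACGT"
        mutated = window[:6] + "A" + window[7:]  # G -> A at position 6
        assert mutated != window
        seq = "C" * 20 + revcomp(mutated) + "C" * 20
        hits = search_guides(sno(seq), rrna, GuideSearchParams(min_identity=0.9))
        best = max(hits, key=lambda h: h.score)
        assert (best.start, best.end) == (50, 62)
        assert best.identity == pytest.approx(11 / 12)

    def test_haca_rejected(self):
        with pytest.raises(SnoClassError):
            search_guides(sno("A" * 30, cls=SnoClass.HACA), "ACGT" * 100)

    def test_matches_brute_force_window_oracle(self, rng):
        """Exhaustive all-window enumeration (independent oracle) gives
        the identical deduplicated hit set, planted or random."""
        p = GuideSearchParams()
        for rep in range(8):
            rrna = "".join(rng.choice(NT, size=400))
            seq = "".join(rng.choice(NT, size=60))
            if rep % 2 == 0:
                seq = seq[:20] + revcomp(rrna[100:112]) + seq[32:]
            got = [
                (h.start, h.end, h.score, h.identity)
                for h in search_guides(sno(seq), rrna, p)
            ]
            want = [
                (rs, re, sc, mt / (re - rs))
                for rs, re, _, sc, mt in brute_force_guide_windows(revcomp(seq), rrna, p)
            ]
            assert got == want


class TestProjection:
    def test_gapless_identity(self):
        aln = MultipleAlignment("rRNA_SSU", {"sp1": "ACGT" * 30})
        h = hit("sp1", None)
        h.center_column = None
        assert project_hit(h, aln).center_column == h.center

    def test_leading_gaps_shift(self):
        aln = MultipleAlignment("rRNA_SSU", {"sp1": "-" * 10 + "A" * 200})
        h = hit("sp1", None)
        h.center_column = None
        assert project_hit(h, aln).center_column == h.center + 10


class TestBinSites:
    def test_within_tolerance_single_locus(self):
        loci = bin_sites([hit("a", 507), hit("b", 508)])
        assert len(loci) == 1 and loci[0].species == {"a", "b"}

    def test_single_species_loci_discarded(self):
        loci = bin_sites([hit("a", 507), hit("b", 512)])
        assert loci == []

    def test_mixed_subunits_rejected(self):
        with pytest.raises(ValueError, match="single subunit"):
            bin_sites([hit("a", 1, subunit="SSU"), hit("b", 2, subunit="LSU")])

    def test_unprojected_hits_rejected(self):
        h = hit("a", 1)
        h.center_column = None
        with pytest.raises(ValueError, match="projected"):
            bin_sites([h])

    def test_partition_equals_transitive_closure_and_order_invariance(self, rng):
        for _ in range(50):
            vals = [int(v) for v in rng.integers(0, 60, size=rng.integers(1, 25))]
            tol = int(rng.integers(0, 4))
            got = {frozenset(b) for b in single_linkage_bins(vals, tol)}
            want = set(transitive_closure_components(vals, tol))
            assert got == want
            # order invariance at the locus level
            hits = [hit(f"s{i}", v, sid=f"x{i}") for i, v in enumerate(vals)]
            perm = [hits[i] for i in rng.permutation(len(hits))]
            a = [(l.column, frozenset(h.snorna_id for h in l.hits)) for l in bin_sites(hits, min_species=1)]
            b = [(l.column, frozenset(h.snorna_id for h in l.hits)) for l in bin_sites(perm, min_species=1)]
            assert a == b


class TestLecaSites:
    def test_root_rule(self, tree4):
        loci = bin_sites(
            [hit("A", 100), hit("C", 101), hit("A", 300), hit("B", 301)]
        )
        leca = infer_leca_sites(loci, tree4)
        ids = {l.locus_id: l for l in loci}
        crossing = [l.locus_id for l in loci if {"A", "C"} <= l.species]
        confined = [l.locus_id for l in loci if l.species == {"A", "B"}]
        assert set(crossing) <= leca
        assert not (set(confined) & leca)


class TestCompareToKnown:
    def make(self, tree4):
        import pandas as pd

        aln = MultipleAlignment("rRNA_SSU", {"A": "A" * 500, "C": "A" * 500})
        loci = bin_sites([hit("A", 100), hit("C", 101)])
        known = pd.DataFrame(
            [
                {"species": "A", "subunit": "SSU", "site_position": 101,
                 "modification_type": "Am", "snorna_id": "s", "family_id": "RF1"},
                {"species": "A", "subunit": "SSU", "site_position": 400,
                 "modification_type": "Am", "snorna_id": "", "family_id": ""},
            ]
        )
        return loci, known, {"SSU": aln}

    def test_recovered_and_missed(self, tree4):
        loci, known, alns = self.make(tree4)
        report, totals = compare_to_known(loci, known, alns)
        assert totals == {"n_known": 2, "n_recovered": 1}
        assert report.loc[0, "recovered"] and not report.loc[1, "recovered"]
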