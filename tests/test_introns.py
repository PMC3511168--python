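"""Intron projection, locus binning, occupancy and homology verdicts."""

import numpy as np
import pytest

from oracles import transitive_closure_components
from snoleca.datamodel import (
    FamilyCatalog,
    FamilyInfo,
    GenomeAnnotation,
    Interval,
    MultipleAlignment,
    SnoClass,
    SnoRNARecord,
    Transcript,
)
from snoleca.introns import (
    IntronLocus,
    IntronMember,
    Occupant,
    OrthologGroup,
    Verdict,
    assign_snorna_occupancy,
    bin_intron_loci,
    cross_supergroup_homology,
    date_associations,
    intron_protein_position,
)


def coding_tx(strand, exon_cds_lengths, utr5=0, utr3=0, origin=0, utr5_intron=None):
    """Build a transcript from coding-exon lengths (nt) separated by
    150-nt introns, plus optional UTR decoration."""
    exons, cds = [], []
    pos = origin
    if utr5_intron is not None:
        exons.append(Interval(pos, pos + utr5_intron))
        pos += utr5_intron + 150
    first = True
    for i, ln in enumerate(exon_cds_lengths):
        lead = utr5 if first and utr5_intron is None else 0
        tail = utr3 if i == len(exon_cds_lengths) - 1 else 0
        exons.append(Interval(pos, pos + lead + ln + tail))
        cds.append(Interval(pos + lead, pos + lead + ln))
        pos += lead + ln + tail + 150
        first = False
    tx = Transcript("t1", "g1", strand, exons, cds)
    return tx


class TestIntronProteinPosition:
    def test_first_exon_300nt(self):
        tx = coding_tx("+", [300, 150])
        assert intron_protein_position(tx, 0) == 100

    def test_utr_intron_excluded(self):
        tx = coding_tx("+", [300, 150], utr5_intron=60)
        assert intron_protein_position(tx, 0) is None  # between UTR exons
        assert intron_protein_position(tx, 1) == 100

    def test_minus_strand_symmetric(self):
        tx = coding_tx("-", [150, 300])  # transcript order: genomic-right first
        assert intron_protein_position(tx, 0) == 100

    def test_index_out_of_range(self):
        tx = coding_tx("+", [300, 150])
        with pytest.raises(IndexError):
            intron_protein_position(tx, 5)

    @pytest.mark.parametrize("strand", "+-")
    def test_matches_codon_enumeration(self, strand, rng):
        """Splice-and-count oracle: the amino-acid index equals the
        number of coding bases upstream of the intron // 3, computed by
        explicit enumeration of the spliced CDS."""
        from snoleca.datamodel import genomic_to_cdna

        for _ in range(20):
            lens = [int(3 * rng.integers(5, 60)) for _ in range(int(rng.integers(2, 5)))]
            tx = coding_tx(strand, lens, utr5=int(rng.integers(0, 30)))
            cds_positions = [g for iv in tx.cds for g in range(iv.start, iv.end)]
            if strand == "-":
                cds_positions = cds_positions[::-1]
            introns = tx.introns()
            for idx, intron in enumerate(introns):
                want = None
                upstream = [
                    i
                    for i, g in enumerate(cds_positions)
                    if (g < intron.start if strand == "+" else g >= intron.end)
                ]
                if upstream and len(upstream) < len(cds_positions):
                    want = len(upstream) // 3
                assert intron_protein_position(tx, idx) == want


def member(sp, col, iv=(0, 100), strand="+", idx=0):
    return IntronMember(
        species_id=sp,
        transcript_id=f"{sp}.t1",
        intron_index=idx,
        aa_position=col,
        column=col,
        interval=Interval(*iv),
        strand=strand,
    )


def group(species, ncols=400):
    aln = MultipleAlignment("protein", {sp: "A" * ncols for sp in species})
    return OrthologGroup("G1", {sp: (f"G1.{sp}", f"G1.{sp}.t1") for sp in species}, aln)


class TestBinIntronLoci:
    def test_within_five_one_locus(self):
        g = group(["a", "b"])
        loci = bin_intron_loci(g, [member("a", 100), member("b", 104)])
        assert len(loci) == 1 and loci[0].species == {"a", "b"}

    def test_beyond_five_two_loci(self):
        g = group(["a", "b"])
        loci = bin_intron_loci(g, [member("a", 100), member("b", 106)])
        assert len(loci) == 2

    def test_equals_transitive_closure_and_order_invariant(self, rng):
        g = group([f"s{i}" for i in range(30)])
        for _ in range(30):
            vals = [int(v) for v in rng.integers(0, 120, size=rng.integers(1, 20))]
            members = [member(f"s{i}", v, idx=i) for i, v in enumerate(vals)]
            loci = bin_intron_loci(g, members)
            got = {
                frozenset(m.species_id for ms in l.members.values() for m in ms)
                for l in loci
            }
            want = {
                frozenset(f"s{i}" for i in comp)
                for comp in transitive_closure_components(vals, 5)
            }
            assert got == want
            perm = [members[i] for i in rng.permutation(len(members))]
            assert [l.column for l in bin_intron_loci(g, perm)] == [l.column for l in loci]


def locus_with(occ, species=("A", "C"), members=None):
    locus = IntronLocus(group_id="G1", locus_id="G1:c100", column=100)
    for sp in species:
        locus.members[sp] = [member(sp, 100)]
    for sp, occs in occ.items():
        locus.occupancy[sp] = occs
    return locus


class TestOccupancy:
    def make_ann(self, sno_iv, sno_strand="+"):
        tx = coding_tx("+", [300, 150])
        ann = GenomeAnnotation("A")
        from snoleca.datamodel import Gene

        ann.genes["G1.A"] = Gene("G1.A", "+", [tx])
        ann.snornas.append(
            SnoRNARecord(
                snorna_id="x.A",
                species_id="A",
                family_id="f1",
                sno_class=SnoClass.CD,
                interval=Interval(*sno_iv),
                strand=sno_strand,
                sequence="A" * 30,
            )
        )
        return ann, tx

    def test_contained_same_strand_assigned(self):
        ann, tx = self.make_ann((320, 380))  # inside intron [300, 450)
        locus = IntronLocus("G1", "G1:c100", 100)
        locus.members["A"] = [member("A", 100, iv=(300, 450))]
        assign_snorna_occupancy(ann, [locus])
        assert [o.snorna_id for o in locus.occupancy["A"]] == ["x.A"]

    def test_boundary_spanning_flagged(self):
        ann, tx = self.make_ann((280, 330))
        locus = IntronLocus("G1", "G1:c100", 100)
        locus.members["A"] = [member("A", 100, iv=(300, 450))]
        assign_snorna_occupancy(ann, [locus])
        assert locus.occupancy == {} and locus.flagged == ["x.A"]

    def test_antisense_skipped_by_default(self):
        ann, tx = self.make_ann((320, 380), sno_strand="-")
        locus = IntronLocus("G1", "G1:c100", 100)
        locus.members["A"] = [member("A", 100, iv=(300, 450))]
        assign_snorna_occupancy(ann, [locus])
        assert locus.occupancy == {}
        assign_snorna_occupancy(ann, [locus], same_strand=False)
        assert "A" in locus.occupancy


class TestHomologyVerdicts:
    def catalog(self):
        return FamilyCatalog(
            [
                FamilyInfo("cd1", "cl1", SnoClass.CD),
                FamilyInfo("cd2", "cl1", SnoClass.CD),
                FamilyInfo("cd3", None, SnoClass.CD),
                FamilyInfo("haca1", None, SnoClass.HACA),
            ]
        )

    def occ(self, fam, cls=SnoClass.CD):
        return Occupant(snorna_id=f"{fam}.x", family_id=fam, sno_class=cls)

    @pytest.mark.parametrize(
        "occ_a, occ_c, verdict",
        [
            ("cd1", "cd1", Verdict.SAME_FAMILY),
            ("cd1", "cd2", Verdict.SAME_CLAN),
            ("cd1", "cd3", Verdict.SAME_CLASS_NO_EVIDENCE),
            ("cd3", "haca1", Verdict.UNRELATED_CLASSES),
        ],
    )
    def test_verdict_table(self, tree4, occ_a, occ_c, verdict):
        cat = self.catalog()
        cls = {f: cat.class_of(f) for f in cat.families}
        locus = locus_with(
            {"A": [self.occ(occ_a, cls[occ_a])], "C": [self.occ(occ_c, cls[occ_c])]}
        )
        tree4.supergroups.update({"A": "Uni", "B": "Uni", "C": "Bik", "D": "Bik"})
        assert cross_supergroup_homology(locus, cat, tree4).verdict is verdict

    def test_single_supergroup(self, tree4):
        tree4.supergroups.update({"A": "Uni", "B": "Uni", "C": "Bik", "D": "Bik"})
        locus = locus_with({"A": [self.occ("cd1")]}, species=("A", "B"))
        v = cross_supergroup_homology(locus, self.catalog(), tree4)
        assert v.verdict is Verdict.SINGLE_SUPERGROUP

    def test_no_occupancy_rejected(self, tree4):
        with pytest.raises(ValueError, match="no occupancy"):
            cross_supergroup_homology(locus_with({}), self.catalog(), tree4)


class TestDating:
    def test_universal_association_not_recent(self, tree4):
        locus = locus_with(
            {sp: [Occupant(f"f.{sp}", "f1", SnoClass.CD)] for sp in "ABCD"},
            species=tuple("ABCD"),
        )
        d = date_associations([locus], tree4, {"G1": set("ABCD")})[0]
        assert d.association_node == tree4.root and not d.recent_gain

    def test_clade_association_in_leca_gene_is_recent(self, tree4):
        locus = locus_with(
            {sp: [Occupant(f"f.{sp}", "f1", SnoClass.CD)] for sp in "AB"},
            species=tuple("ABCD"),
        )
        d = date_associations([locus], tree4, {"G1": set("ABCD")})[0]
        assert d.association_node == tree4.mrca(["A", "B"])
        assert d.host_node == tree4.root
        assert d.recent_gain
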