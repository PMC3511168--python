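"""Coordinate arithmetic, interval types and format round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snoleca.datamodel import (
    Interval,
    MultipleAlignment,
    OutOfTranscriptError,
    Transcript,
    cdna_to_genomic,
    column_to_ungapped,
    genomic_to_cdna,
    locate_full_length,
    revcomp,
    ungapped_to_column,
)
from snoleca import io as sio


def make_tx(strand, exons, cds=()):
    return Transcript(
        transcript_id="t1",
        gene_id="g1",
        strand=strand,
        exons=[Interval(*e) for e in exons],
        cds=[Interval(*c) for c in cds],
    )


class TestGenomicToCdna:
    def test_plus_strand_second_exon_start(self):
        tx = make_tx("+", [(0, 100), (200, 300)])
        assert genomic_to_cdna(tx, 200) == 100

    def test_minus_strand_counts_from_five_prime(self):
        tx = make_tx("-", [(0, 100), (200, 300)])
        assert genomic_to_cdna(tx, 299) == 0
        assert genomic_to_cdna(tx, 0) == 199

    def test_intronic_position_rejected(self):
        tx = make_tx("+", [(0, 100), (200, 300)])
        with pytest.raises(OutOfTranscriptError):
            genomic_to_cdna(tx, 150)

    @pytest.mark.parametrize("strand", "+-")
    def test_matches_explicit_splice_enumeration(self, strand, rng):
        """Brute-force oracle: the cDNA index equals the position of the
        genomic coordinate in the explicitly spliced coordinate list."""
        for _ in range(25):
            n_ex = rng.integers(1, 5)
            pos, exons = 0, []
            for _ in range(n_ex):
                pos += int(rng.integers(1, 50))
                ln = int(rng.integers(1, 60))
                exons.append((pos, pos + ln))
                pos += ln
            tx = make_tx(strand, exons)
            spliced = [g for s, e in exons for g in range(s, e)]
            if strand == "-":
                spliced = spliced[::-1]
            for c, g in enumerate(spliced):
                assert genomic_to_cdna(tx, g) == c
                assert cdna_to_genomic(tx, c) == g


class TestAlignmentColumns:
    def test_single_gap(self):
        aln = MultipleAlignment("protein", {"sp": "A-CG"})
        assert ungapped_to_column(aln, "sp", 1) == 2

    def test_gapless_identity_and_dot_gaps(self):
        aln = MultipleAlignment("rRNA_SSU", {"a": "ACGT", "b": "..GT"})
        assert ungapped_to_column(aln, "a", 3) == 3
        assert ungapped_to_column(aln, "b", 0) == 2

    def test_roundtrip_against_linear_scan(self, rng):
        for _ in range(20):
            row = "".join(rng.choice(list("ACGT-."), size=40))
            if not any(c not in "-." for c in row):
                continue
            aln = MultipleAlignment("protein", {"x": row})
            scan = [i for i, ch in enumerate(row) if ch not in "-."]
            for pos, col in enumerate(scan):
                assert ungapped_to_column(aln, "x", pos) == col
                assert column_to_ungapped(aln, "x", col) == pos

    def test_missing_row(self):
        aln = MultipleAlignment("protein", {"a": "AC"})
        from snoleca.datamodel import MissingRowError

        with pytest.raises(MissingRowError):
            ungapped_to_column(aln, "zz", 0)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGU-.", min_size=1, max_size=60))
    def test_roundtrip_identity_property(self, row):
        """ungapped→column→ungapped is the identity on the whole
        domain, for arbitrary gap placements (- and . both gaps)."""
        aln = MultipleAlignment("rRNA_SSU", {"x": row})
        n = len(aln.ungapped("x"))
        for pos in range(n):
            col = ungapped_to_column(aln, "x", pos)
            assert row[col] not in "-."
            assert column_to_ungapped(aln, "x", col) == pos


class TestLocateFullLength:
    def test_exact_embed(self):
        assert locate_full_length("ACGT", "TTACGTTT", 1) == [(2, "+", 0), (2, "-", 0)]

    def test_one_mismatch(self):
        hits = locate_full_length("ACGA", "TTACGTTT", 1)
        assert (2, "+", 1) in hits

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            locate_full_length("", "ACGT")

    def test_matches_exhaustive_hamming_scan(self, rng):
        nt = list("ACGT")
        for _ in range(10):
            genome = "".join(rng.choice(nt, size=300))
            query = "".join(rng.choice(nt, size=12))
            want = []
            for strand, q in (("+", query), ("-", revcomp(query))):
                for p in range(len(genome) - len(q) + 1):
                    d = sum(a != b for a, b in zip(q, genome[p : p + len(q)]))
                    if d <= 1:
                        want.append((p, strand, d))
            want.sort()
            assert locate_full_length(query, genome, 1) == want


class TestGFF3:
    GFF = (
        "##gff-version 3\n##species spX\n"
        "chr1\t.\tgene\t101\t400\t.\t+\t.\tID=g1\n"
        "chr1\t.\tmRNA\t101\t400\t.\t+\t.\tID=t1;Parent=g1\n"
        "chr1\t.\texon\t101\t200\t.\t+\t.\tParent=t1\n"
        "chr1\t.\texon\t301\t400\t.\t+\t.\tParent=t1\n"
        "chr1\t.\tCDS\t151\t200\t.\t+\t.\tParent=t1\n"
        "chr1\t.\tsnoRNA\t210\t260\t.\t+\t.\tID=sno1;sno_class=CD;family_id=RF1\n"
    )

    def test_coordinate_convention(self):
        ann = sio.read_genome_annotation(self.GFF)
        tx = ann.genes["g1"].transcripts[0]
        assert tx.exons[0] == Interval(100, 200)  # 101..200 closed -> [100, 200)
        assert ann.snornas[0].interval == Interval(209, 260)

    def test_roundtrip_preserves_features(self):
        ann = sio.read_genome_annotation(self.GFF)
        text = sio.write_genome_annotation(ann)
        ann2 = sio.read_genome_annotation(text)
        assert sio.write_genome_annotation(ann2) == text
        tx, tx2 = ann.genes["g1"].transcripts[0], ann2.genes["g1"].transcripts[0]
        assert tx.exons == tx2.exons and tx.cds == tx2.cds

    def test_malformed_line_reports_line_number(self):
        bad = self.GFF + "chr1\tonly\tthree\n"
        with pytest.raises(sio.GFF3ParseError, match="line 9"):
            sio.read_genome_annotation(bad)

    def test_transcript_without_exons_rejected(self):
        bad = (
            "##species spX\n"
            "chr1\t.\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "chr1\t.\tmRNA\t1\t100\t.\t+\t.\tID=t1;Parent=g1\n"
        )
        with pytest.raises(sio.ValidationError, match="no exons"):
            sio.read_genome_annotation(bad)

    def test_cds_outside_exon_space_rejected(self):
        bad = self.GFF + "chr1\t.\tCDS\t250\t280\t.\t+\t.\tParent=t1\n"
        with pytest.raises(ValueError, match="outside exon"):
            sio.read_genome_annotation(bad)
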