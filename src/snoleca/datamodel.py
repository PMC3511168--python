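"""Core domain types and coordinate arithmetic.

All intervals are 0-based half-open ``[start, end)`` internally; GFF3's
1-based closed coordinates are converted at the IO boundary.  Gap
characters in alignments are ``-`` and ``.`` (SILVA-style alignments
use dots).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

GAP_CHARS = frozenset("-.")

_COMPLEMENT = str.maketrans("ACGTUacgtuNn", "TGCAAtgcaaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result in DNA letters)."""
    return seq.translate(_COMPLEMENT)[::-1]


class SnoClass(str, enum.Enum):
    """The two broad snoRNA classes: box C/D (2'-O-methylation guides)
    and box H/ACA (pseudouridylation guides)."""

    CD = "CD"
    HACA = "HACA"


class OutOfTranscriptError(ValueError):
    """Genomic position does not fall in any exon of the transcript."""


class MissingRowError(KeyError):
    """Species row absent from a multiple alignment."""


@dataclass(frozen=True)
class Interval:
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Transcript:
    """A transcript: sorted, non-overlapping exons plus an optional CDS
    (a subset of exon space), all in genomic coordinates."""

    transcript_id: str
    gene_id: str
    strand: str  # '+' or '-'
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"transcript {self.transcript_id}: overlapping exons")
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for c in self.cds:
            if not any(e.contains(c) for e in self.exons):
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS segment outside exon space"
                )

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def introns(self) -> list[Interval]:
        """Introns in transcript (5'→3') order."""
        ivs = [Interval(a.end, b.start) for a, b in zip(self.exons, self.exons[1:])]
        return ivs if self.strand == "+" else ivs[::-1]


@dataclass
class Gene:
    gene_id: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    def longest_cds_transcript(self) -> Transcript:
        """The transcript with the longest total CDS (ties: first id);
        isoform choice when a gene model carries several."""
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        return max(
            sorted(self.transcripts, key=lambda t: t.transcript_id),
            key=lambda t: sum(len(c) for c in t.cds),
        )


@dataclass
class SnoRNARecord:
    snorna_id: str
    species_id: str
    family_id: str | None  # None = unassigned
    sno_class: SnoClass
    interval: Interval
    strand: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 20:
            raise ValueError(f"snoRNA {self.snorna_id}: sequence shorter than 20 nt")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class GenomeAnnotation:
    """Per-species annotation: genes with transcript models, plus the
    species' snoRNA complement."""

    species_id: str
    genes: dict[str, Gene] = field(default_factory=dict)
    snornas: list[SnoRNARecord] = field(default_factory=list)


@dataclass(frozen=True)
class FamilyInfo:
    family_id: str
    clan_id: str | None
    sno_class: SnoClass
    cleavage_only: bool = False


class FamilyCatalog:
    """Rfam-style catalog: family → (clan, class, function flag).

    ``cleavage_only`` marks families (U3/snoU13-like) that act in rRNA
    cleavage rather than as modification guides and are excluded from
    the modification-site evidence intersection.
    """

    def __init__(self, families: Sequence[FamilyInfo]):
        self.families: dict[str, FamilyInfo] = {}
        for f in families:
            if f.family_id in self.families:
                raise ValueError(f"duplicate family {f.family_id}")
            self.families[f.family_id] = f

    def __contains__(self, family_id: str) -> bool:
        return family_id in self.families

    def __getitem__(self, family_id: str) -> FamilyInfo:
        try:
            return self.families[family_id]
        except KeyError:
            raise KeyError(f"unknown family {family_id!r}") from None

    def clan_of(self, family_id: str) -> str | None:
        return self[family_id].clan_id

    def class_of(self, family_id: str) -> SnoClass:
        return self[family_id].sno_class

    def clans(self) -> dict[str, list[str]]:
        """clan_id → sorted member family ids (clans with ≥ 1 member)."""
        out: dict[str, list[str]] = {}
        for f in self.families.values():
            if f.clan_id is not None:
                out.setdefault(f.clan_id, []).append(f.family_id)
        return {c: sorted(ms) for c, ms in sorted(out.items())}


class MultipleAlignment:
    """A curated multiple alignment (rRNA subunit or host protein)."""

    def __init__(self, kind: str, rows: Mapping[str, str]):
        self.kind = kind
        self.rows = dict(rows)
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        self.n_columns = lengths.pop() if lengths else 0
        self._maps: dict[str, np.ndarray] = {}

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.rows

    def ungapped(self, species_id: str) -> str:
        row = self._row(species_id)
        return "".join(ch for ch in row if ch not in GAP_CHARS)

    def _row(self, species_id: str) -> str:
        try:
            return self.rows[species_id]
        except KeyError:
            raise MissingRowError(f"species {species_id!r} not in {self.kind} alignment") from None

    def _colmap(self, species_id: str) -> np.ndarray:
        if species_id not in self._maps:
            row = self._row(species_id)
            self._maps[species_id] = np.array(
                [i for i, ch in enumerate(row) if ch not in GAP_CHARS], dtype=np.int64
            )
        return self._maps[species_id]


def genomic_to_cdna(transcript: Transcript, genomic_pos: int) -> int:
    """Map a genomic position inside an exon to its 0-based offset in
    the spliced transcript, counting from the transcript 5' end."""
    offset = 0
    for exon in transcript.exons:
        if exon.start <= genomic_pos < exon.end:
            plus = offset + (genomic_pos - exon.start)
            if transcript.strand == "+":
                return plus
            return transcript.spliced_length - 1 - plus
        offset += len(exon)
    raise OutOfTranscriptError(
        f"position {genomic_pos} not exonic in transcript {transcript.transcript_id}"
    )


def cdna_to_genomic(transcript: Transcript, cdna_pos: int) -> int:
    """Inverse of :func:`genomic_to_cdna`."""
    total = transcript.spliced_length
    if not 0 <= cdna_pos < total:
        raise OutOfTranscriptError(f"cDNA position {cdna_pos} outside transcript")
    plus = cdna_pos if transcript.strand == "+" else total - 1 - cdna_pos
    for exon in transcript.exons:
        if plus < len(exon):
            return exon.start + plus
        plus -= len(exon)
    raise AssertionError("unreachable")


def ungapped_to_column(alignment: MultipleAlignment, species_id: str, seq_pos: int) -> int:
    """Alignment column holding the ``seq_pos``-th non-gap character of
    the species' row."""
    cmap = alignment._colmap(species_id)
    if not 0 <= seq_pos < len(cmap):
        raise IndexError(
            f"ungapped position {seq_pos} outside row of length {len(cmap)} "
            f"({species_id}, {alignment.kind})"
        )
    return int(cmap[seq_pos])


def column_to_ungapped(alignment: MultipleAlignment, species_id: str, column: int) -> int:
    """Ungapped position of a non-gap alignment column (inverse of
    :func:`ungapped_to_column`)."""
    row = alignment._row(species_id)
    if not 0 <= column < alignment.n_columns:
        raise IndexError(f"column {column} outside alignment of width {alignment.n_columns}")
    if row[column] in GAP_CHARS:
        raise ValueError(f"column {column} is a gap in row {species_id}")
    cmap = alignment._colmap(species_id)
    return int(np.searchsorted(cmap, column))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def locate_full_length(
    query: str, genome: str, max_subst: int = 1
) -> list[tuple[int, str, int]]:
    """All full-length placements of ``query`` on either strand of
    ``genome`` with Hamming distance ≤ ``max_subst`` (no indels).

    The default of one substitution implements a "fewer than 2
    substitutions" full-length match rule.  Returns ``(position,
    strand, substitutions)`` triples sorted by position; a minus-strand
    hit at ``p`` means the reverse complement of the query matches
    ``genome[p:p+len(query)]``.
    """
    if not query:
        raise ValueError("empty query")
    if len(query) > len(genome):
        return []
    g = _encode(genome)
    hits: list[tuple[int, str, int]] = []
    win = np.lib.stride_tricks.sliding_window_view(g, len(query))
    for strand, q in (("+", query), ("-", revcomp(query))):
        mism = (win != _encode(q)).sum(axis=1)
        for pos in np.nonzero(mism <= max_subst)[0]:
            hits.append((int(pos), strand, int(mism[pos])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits
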