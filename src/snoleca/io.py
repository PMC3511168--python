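"""Readers and writers for the standard input formats.

GFF3 (1-based closed) is converted to internal 0-based half-open
coordinates on read and back on write.  FASTA goes through Biopython,
tables through pandas, Newick through the phylogeny module.

The GFF3 dialect used here is the plain Ensembl-style feature set:
``gene`` → ``mRNA`` → ``exon``/``CDS``, plus ``snoRNA`` features that
carry ``family_id`` and ``sno_class`` attributes and an optional
``Parent`` gene.  snoRNA sequences live in a companion FASTA keyed by
snoRNA id.
"""

from __future__ import annotations

import io as _io
from typing import Mapping, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

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
)
from .phylo import Phylogeny

__all__ = [
    "GFF3ParseError",
    "ValidationError",
    "read_genome_annotation",
    "write_genome_annotation",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_alignment",
    "read_phylogeny",
    "read_family_catalog",
    "write_family_catalog",
    "read_known_sites",
    "read_expression_matrix",
]


class GFF3ParseError(ValueError):
    def __init__(self, lineno: int, message: str):
        super().__init__(f"GFF3 line {lineno}: {message}")
        self.lineno = lineno


class ValidationError(ValueError):
    pass


def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise GFF3ParseError(lineno, f"malformed attribute {part!r}")
        key, value = part.split("=", 1)
        attrs[key] = value
    return attrs


def read_genome_annotation(
    stream: TextIO | str,
    species_id: str | None = None,
    snorna_sequences: Mapping[str, str] | None = None,
) -> GenomeAnnotation:
    """Parse a GFF3 stream into a :class:`GenomeAnnotation`.

    The species id comes from the ``##species`` directive unless given
    explicitly.  ``snorna_sequences`` supplies sequences for snoRNA
    features (keyed by feature ID); features without a sequence get a
    placeholder of Ns matching their genomic length.
    """
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    genes: dict[str, Gene] = {}
    tx_meta: dict[str, tuple[str, str]] = {}  # id -> (gene_id, strand)
    tx_exons: dict[str, list[Interval]] = {}
    tx_cds: dict[str, list[Interval]] = {}
    tx_order: list[str] = []
    sno_rows: list[tuple[str, Interval, str, dict[str, str]]] = []

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if line.startswith("##species"):
            parts = line.split()
            if len(parts) == 2 and species_id is None:
                species_id = parts[1]
            continue
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GFF3ParseError(lineno, f"expected 9 tab-separated fields, got {len(fields)}")
        _seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise GFF3ParseError(lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
        if start1 < 1 or end1 < start1:
            raise GFF3ParseError(lineno, f"invalid 1-based closed interval {start1}-{end1}")
        iv = Interval(start1 - 1, end1)  # to 0-based half-open
        attrs = _parse_attributes(attr_s, lineno)
        if ftype == "gene":
            gid = attrs.get("ID")
            if gid is None:
                raise GFF3ParseError(lineno, "gene without ID")
            genes[gid] = Gene(gene_id=gid, strand=strand)
        elif ftype in ("mRNA", "transcript"):
            tid, gid = attrs.get("ID"), attrs.get("Parent")
            if tid is None or gid is None:
                raise GFF3ParseError(lineno, "transcript needs ID and Parent")
            tx_meta[tid] = (gid, strand)
            tx_order.append(tid)
        elif ftype == "exon":
            tid = attrs.get("Parent")
            if tid is None:
                raise GFF3ParseError(lineno, "exon without Parent")
            tx_exons.setdefault(tid, []).append(iv)
        elif ftype == "CDS":
            tid = attrs.get("Parent")
            if tid is None:
                raise GFF3ParseError(lineno, "CDS without Parent")
            tx_cds.setdefault(tid, []).append(iv)
        elif ftype == "snoRNA":
            sid = attrs.get("ID")
            if sid is None:
                raise GFF3ParseError(lineno, "snoRNA without ID")
            sno_rows.append((sid, iv, strand, attrs))
        # other feature types are ignored

    if species_id is None:
        raise ValidationError("no species id: pass species_id or add a ##species directive")

    ann = GenomeAnnotation(species_id=species_id)
    ann.genes = genes
    for tid in tx_order:
        gid, strand = tx_meta[tid]
        if tid not in tx_exons:
            raise ValidationError(f"transcript {tid} has no exons")
        if gid not in genes:
            raise ValidationError(f"transcript {tid} references unknown gene {gid}")
        tx = Transcript(
            transcript_id=tid,
            gene_id=gid,
            strand=strand,
            exons=tx_exons[tid],
            cds=tx_cds.get(tid, []),
        )
        genes[gid].transcripts.append(tx)
    for tid in tx_exons:
        if tid not in tx_meta:
            raise ValidationError(f"exon references unknown transcript {tid}")

    seqs = dict(snorna_sequences or {})
    for sid, iv, strand, attrs in sno_rows:
        family = attrs.get("family_id") or None
        cls = SnoClass(attrs.get("sno_class", "CD"))
        seq = seqs.get(sid, "N" * max(len(iv), 20))
        ann.snornas.append(
            SnoRNARecord(
                snorna_id=sid,
                species_id=species_id,
                family_id=family,
                sno_class=cls,
                interval=iv,
                strand=strand,
                sequence=seq,
            )
        )
    return ann


def write_genome_annotation(ann: GenomeAnnotation, seqid: str = "chr1") -> str:
    """Serialize an annotation back to GFF3 text (deterministic order)."""
    out = ["##gff-version 3", f"##species {ann.species_id}"]

    def line(ftype: str, iv: Interval, strand: str, attrs: str) -> str:
        return "\t".join(
            [seqid, "snoleca", ftype, str(iv.start + 1), str(iv.end), ".", strand, ".", attrs]
        )

    for gid in sorted(ann.genes):
        gene = ann.genes[gid]
        spans = [tx.span for tx in gene.transcripts]
        gspan = Interval(min(s.start for s in spans), max(s.end for s in spans))
        out.append(line("gene", gspan, gene.strand, f"ID={gid}"))
        for tx in sorted(gene.transcripts, key=lambda t: t.transcript_id):
            out.append(line("mRNA", tx.span, tx.strand, f"ID={tx.transcript_id};Parent={gid}"))
            for e in tx.exons:
                out.append(line("exon", e, tx.strand, f"Parent={tx.transcript_id}"))
            for c in tx.cds:
                out.append(line("CDS", c, tx.strand, f"Parent={tx.transcript_id}"))
    for sno in sorted(ann.snornas, key=lambda s: s.snorna_id):
        attrs = f"ID={sno.snorna_id};sno_class={sno.sno_class.value}"
        if sno.family_id:
            attrs += f";family_id={sno.family_id}"
        out.append(line("snoRNA", sno.interval, sno.strand, attrs))
    return "\n".join(out) + "\n"


def read_fasta(stream: TextIO | str) -> dict[str, str]:
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(stream, "fasta")}


def write_fasta(seqs: Mapping[str, str], handle: TextIO) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, handle, "fasta")


def read_alignment(stream: TextIO | str, kind: str) -> MultipleAlignment:
    return MultipleAlignment(kind, read_fasta(stream))


def write_alignment(aln: MultipleAlignment, handle: TextIO) -> None:
    write_fasta(aln.rows, handle)


def read_phylogeny(newick: str, supergroup_tsv: str | None = None) -> Phylogeny:
    """Build a phylogeny from Newick text plus an optional two-column
    leaf→supergroup TSV (header ``species\tsupergroup``)."""
    supergroups = None
    if supergroup_tsv is not None:
        df = pd.read_csv(_io.StringIO(supergroup_tsv), sep="\t", dtype=str)
        supergroups = dict(zip(df["species"], df["supergroup"]))
    return Phylogeny.from_newick(newick, supergroups)


def read_family_catalog(stream: TextIO | str) -> FamilyCatalog:
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t", dtype=str).fillna("")
    infos = []
    for row in df.itertuples(index=False):
        infos.append(
            FamilyInfo(
                family_id=row.family_id,
                clan_id=row.clan_id or None,
                sno_class=SnoClass(row.sno_class),
                cleavage_only=(row.function == "cleavage_only"),
            )
        )
    return FamilyCatalog(infos)


def write_family_catalog(catalog: FamilyCatalog, handle: TextIO) -> None:
    handle.write("family_id\tclan_id\tsno_class\tfunction\n")
    for fid in sorted(catalog.families):
        f = catalog.families[fid]
        func = "cleavage_only" if f.cleavage_only else "modification_guide"
        handle.write(f"{fid}\t{f.clan_id or ''}\t{f.sno_class.value}\t{func}\n")


def read_known_sites(stream: TextIO | str) -> pd.DataFrame:
    """Known modification sites: columns ``species, subunit,
    site_position, modification_type, snorna_id, family_id`` with
    0-based ungapped per-species rRNA positions."""
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t", dtype={"site_position": int}).fillna("")
    required = {"species", "subunit", "site_position", "modification_type", "snorna_id", "family_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"known-site table lacks columns: {sorted(missing)}")
    return df


def read_expression_matrix(stream: TextIO | str) -> pd.DataFrame:
    """Gene × tissue signal matrix (TSV, first column gene id)."""
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    return pd.read_csv(stream, sep="\t", index_col=0)
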