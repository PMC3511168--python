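"""Intron positional conservation and intronic snoRNA occupancy.

Introns of orthologous host genes are projected onto the group's
protein alignment: the intron position is the amino-acid index of the
last coding base of the exon immediately upstream of the intron
(coding offset // 3), mapped through the species' alignment row.
Introns lying in untranslated regions are excluded.  Projected
positions are binned into discrete loci by single-linkage clustering
at ± 5 alignment columns; locus ancestry is assessed with Dollo
parsimony, snoRNA occupancy is attached by interval containment, and
cross-supergroup homology of the occupying snoRNAs is classified
(same family / same clan / same class without further evidence /
unrelated classes / single supergroup).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .datamodel import (
    FamilyCatalog,
    GenomeAnnotation,
    Interval,
    MultipleAlignment,
    SnoClass,
    Transcript,
    genomic_to_cdna,
    ungapped_to_column,
)
from .dollo import PresenceMatrix, reconstruct
from .guides import single_linkage_bins
from .phylo import Phylogeny

__all__ = [
    "OrthologGroup",
    "IntronMember",
    "Occupant",
    "IntronLocus",
    "Verdict",
    "HomologyVerdict",
    "AssociationDating",
    "intron_protein_position",
    "project_group_introns",
    "bin_intron_loci",
    "reconstruct_intron_ancestry",
    "assign_snorna_occupancy",
    "cross_supergroup_homology",
    "date_associations",
]


@dataclass
class OrthologGroup:
    """A seed-gene-anchored ortholog group with one member gene per
    species and a shared protein alignment (rows keyed by species)."""

    group_id: str
    members: dict[str, tuple[str, str]]  # species -> (gene_id, transcript_id)
    alignment: MultipleAlignment

    def __post_init__(self):
        for sp in self.members:
            if sp not in self.alignment:
                raise KeyError(f"group {self.group_id}: species {sp} missing from alignment")


@dataclass
class IntronMember:
    species_id: str
    transcript_id: str
    intron_index: int  # transcript (5'→3') order
    aa_position: int
    column: int
    interval: Interval  # genomic intron interval
    strand: str


@dataclass
class Occupant:
    snorna_id: str
    family_id: str | None
    sno_class: SnoClass


@dataclass
class IntronLocus:
    group_id: str
    locus_id: str
    column: int  # representative alignment column (amino-acid space)
    members: dict[str, list[IntronMember]] = field(default_factory=dict)
    occupancy: dict[str, list[Occupant]] = field(default_factory=dict)
    flagged: list[str] = field(default_factory=list)  # boundary-spanning snoRNAs

    @property
    def species(self) -> set[str]:
        return set(self.members)

    def occupied_species(self) -> set[str]:
        return {sp for sp, occ in self.occupancy.items() if occ}

    def families(self) -> set[str]:
        return {o.family_id for occ in self.occupancy.values() for o in occ if o.family_id}


class Verdict(str, enum.Enum):
    SAME_FAMILY = "same_family"
    SAME_CLAN = "same_clan"
    SAME_CLASS_NO_EVIDENCE = "same_class_no_evidence"
    UNRELATED_CLASSES = "unrelated_classes"
    SINGLE_SUPERGROUP = "single_supergroup"


@dataclass
class HomologyVerdict:
    locus_id: str
    verdict: Verdict
    families_by_supergroup: dict[str, set[str]]
    classes_by_supergroup: dict[str, set[str]]


@dataclass
class AssociationDating:
    family_id: str
    locus_id: str
    association_node: int  # MRCA of species sharing the association
    host_node: int  # Dollo placement of host-gene presence
    recent_gain: bool  # association strictly shallower than the host gene


def intron_protein_position(transcript: Transcript, intron_index: int) -> int | None:
    """Amino-acid index of an intron on the protein, or ``None`` for
    UTR introns.

    The position is the number of coding bases upstream of the intron
    (through the last CDS base of the exon immediately 5' of it),
    integer-divided by 3 — e.g. an intron after a 300-nt first coding
    exon sits at amino acid 100.  Introns outside the CDS genomic span
    (5' or 3' UTR introns) are excluded.
    """
    introns = transcript.introns()
    if not 0 <= intron_index < len(introns):
        raise IndexError(
            f"intron index {intron_index} out of range for {transcript.transcript_id}"
        )
    if not transcript.cds:
        raise ValueError(f"transcript {transcript.transcript_id} has no CDS")
    intron = introns[intron_index]
    cds_span = Interval(transcript.cds[0].start, transcript.cds[-1].end)
    if not (cds_span.start <= intron.start and intron.end <= cds_span.end):
        return None  # UTR intron
    # genomic position of the CDS base adjacent to the intron on its 5' side
    if transcript.strand == "+":
        boundary = intron.start - 1
    else:
        boundary = intron.end
    cds_start_genomic = (
        transcript.cds[0].start if transcript.strand == "+" else transcript.cds[-1].end - 1
    )
    n_coding_upstream = (
        genomic_to_cdna(transcript, boundary)
        - genomic_to_cdna(transcript, cds_start_genomic)
        + 1
    )
    if n_coding_upstream <= 0:
        return None
    return n_coding_upstream // 3


def project_group_introns(
    group: OrthologGroup, annotations: dict[str, GenomeAnnotation]
) -> list[IntronMember]:
    """All non-UTR introns of the group's member transcripts, projected
    to protein-alignment columns."""
    members: list[IntronMember] = []
    for species in sorted(group.members):
        gene_id, tx_id = group.members[species]
        ann = annotations[species]
        gene = ann.genes[gene_id]
        tx = next(t for t in gene.transcripts if t.transcript_id == tx_id)
        for idx, intron in enumerate(tx.introns()):
            aa = intron_protein_position(tx, idx)
            if aa is None:
                continue
            col = ungapped_to_column(group.alignment, species, aa)
            members.append(
                IntronMember(
                    species_id=species,
                    transcript_id=tx_id,
                    intron_index=idx,
                    aa_position=aa,
                    column=col,
                    interval=intron,
                    strand=tx.strand,
                )
            )
    return members


def bin_intron_loci(
    group: OrthologGroup,
    members: list[IntronMember],
    tolerance: int = 5,
) -> list[IntronLocus]:
    """Single-linkage binning of projected intron positions (link
    distance ≤ ``tolerance`` columns), deterministic and independent of
    input order."""
    if not members:
        return []
    cols = [m.column for m in members]
    loci = []
    for idxs in single_linkage_bins(cols, tolerance):
        mem = sorted(
            (members[i] for i in idxs),
            key=lambda m: (m.column, m.species_id, m.transcript_id, m.intron_index),
        )
        centers = sorted(m.column for m in mem)
        rep = centers[(len(centers) - 1) // 2]
        locus = IntronLocus(
            group_id=group.group_id, locus_id=f"{group.group_id}:c{rep}", column=rep
        )
        for m in mem:
            locus.members.setdefault(m.species_id, []).append(m)
        loci.append(locus)
    loci.sort(key=lambda l: l.column)
    return loci


def reconstruct_intron_ancestry(loci: list[IntronLocus], tree: Phylogeny) -> set[str]:
    """Locus ids whose presence pattern traces to LECA under Dollo."""
    if not loci:
        return set()
    obs = {l.locus_id: l.species for l in loci}
    matrix = PresenceMatrix.from_observations(obs, tree.leaf_names(), "intron_locus")
    return reconstruct(tree, matrix).leca_characters()


def assign_snorna_occupancy(
    annotation: GenomeAnnotation,
    loci: list[IntronLocus],
    same_strand: bool = True,
) -> None:
    """Attach the species' snoRNAs to the intron loci they occupy.

    A snoRNA occupies a locus iff its genomic interval is fully
    contained in that species' intron at the locus and (by default)
    lies on the host strand.  snoRNAs overlapping an intron without
    full containment (exon-boundary spanning) are flagged, not
    assigned.  Modifies the loci in place.
    """
    species = annotation.species_id
    for locus in loci:
        for member in locus.members.get(species, []):
            for sno in annotation.snornas:
                if not member.interval.overlaps(sno.interval):
                    continue
                if not member.interval.contains(sno.interval):
                    locus.flagged.append(sno.snorna_id)
                    continue
                if same_strand and sno.strand != member.strand:
                    continue
                locus.occupancy.setdefault(species, []).append(
                    Occupant(
                        snorna_id=sno.snorna_id,
                        family_id=sno.family_id,
                        sno_class=sno.sno_class,
                    )
                )


def cross_supergroup_homology(
    locus: IntronLocus, catalog: FamilyCatalog, tree: Phylogeny
) -> HomologyVerdict:
    """Classify homology evidence for the snoRNAs occupying a locus
    across supergroups.

    ``same_family`` if one family spans ≥ 2 supergroups; ``same_clan``
    if only clan-level identity spans; ``unrelated_classes`` if the
    cross-supergroup occupants include both C/D and H/ACA snoRNAs;
    ``same_class_no_evidence`` for same-class occupants with no family
    or clan link; ``single_supergroup`` otherwise.
    """
    occupied = locus.occupied_species()
    if not occupied:
        raise ValueError(f"locus {locus.locus_id} has no occupancy")
    fams_by_sg: dict[str, set[str]] = {}
    clans_by_sg: dict[str, set[str]] = {}
    classes_by_sg: dict[str, set[str]] = {}
    for sp in sorted(occupied):
        sg = tree.supergroup_of(sp) or "unassigned"
        for occ in locus.occupancy[sp]:
            classes_by_sg.setdefault(sg, set()).add(occ.sno_class.value)
            if occ.family_id is not None:
                if occ.family_id not in catalog:
                    raise KeyError(f"unknown family {occ.family_id!r}")
                fams_by_sg.setdefault(sg, set()).add(occ.family_id)
                clan = catalog.clan_of(occ.family_id)
                if clan is not None:
                    clans_by_sg.setdefault(sg, set()).add(clan)

    def spans(by_sg: dict[str, set[str]]) -> bool:
        seen: dict[str, set[str]] = {}
        for sg, items in by_sg.items():
            for it in items:
                seen.setdefault(it, set()).add(sg)
        return any(len(sgs) >= 2 for sgs in seen.values())

    if len(classes_by_sg) < 2:
        verdict = Verdict.SINGLE_SUPERGROUP
    elif spans(fams_by_sg):
        verdict = Verdict.SAME_FAMILY
    elif spans(clans_by_sg):
        verdict = Verdict.SAME_CLAN
    elif len(set().union(*classes_by_sg.values())) > 1:
        verdict = Verdict.UNRELATED_CLASSES
    else:
        verdict = Verdict.SAME_CLASS_NO_EVIDENCE
    return HomologyVerdict(
        locus_id=locus.locus_id,
        verdict=verdict,
        families_by_supergroup=fams_by_sg,
        classes_by_supergroup=classes_by_sg,
    )


def date_associations(
    loci: list[IntronLocus],
    tree: Phylogeny,
    host_presence: dict[str, set[str]],
) -> list[AssociationDating]:
    """Date every (family, locus) association.

    The association node is the MRCA of all species in which the family
    occupies the locus; the host node is the Dollo placement (MRCA of
    carriers) of the host gene itself, from ``host_presence`` (group id
    → species with a member gene).  A recent gain is flagged when the
    association node is strictly shallower than the host placement —
    the snoRNA moved into a pre-existing (possibly LECA) gene.
    """
    out = []
    for locus in loci:
        by_family: dict[str, set[str]] = {}
        for sp, occ in locus.occupancy.items():
            for o in occ:
                if o.family_id is not None:
                    by_family.setdefault(o.family_id, set()).add(sp)
        host_species = host_presence.get(locus.group_id, set())
        if not host_species:
            continue
        host_node = tree.mrca(host_species)
        for fam in sorted(by_family):
            assoc = tree.mrca(by_family[fam])
            recent = tree.is_ancestor(host_node, assoc) and assoc != host_node
            out.append(
                AssociationDating(
                    family_id=fam,
                    locus_id=locus.locus_id,
                    association_node=assoc,
                    host_node=host_node,
                    recent_gain=recent,
                )
            )
    return out
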