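"""End-to-end orchestration and total-evidence accounting.

The pipeline runs the stages in order — family presence matrix →
Dollo reconstruction → guide→rRNA site mapping → site loci → LECA
sites → intron atlas → occupancy and homology verdicts → host-gene
expression comparison → total-evidence intersection — writing every
intermediate table, deterministically for a given input set and seed.

Evidence sets follow the three independent lines of the analysis:

* A — families/clans traceable to LECA on their annotated
  presence/absence distribution alone;
* B — families supporting at least one LECA-conserved guide-mapped
  modification-site locus;
* C — families supported by independently reported (known-site table)
  modification sites whose distribution is LECA-compatible.

Families that are not box C/D, or are known to function exclusively in
rRNA cleavage, are excluded from the site-based intersection and
listed separately.  Families grouped into a clan are intersected at
clan level (the clan is the likely orthologous unit).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .datamodel import FamilyCatalog, GenomeAnnotation, MultipleAlignment, SnoClass
from .dollo import PresenceMatrix, count_traceable, reconstruct
from .expression import compare_host_vs_nonhost
from .guides import (
    GuideHit,
    GuideSearchParams,
    LocusBinningParams,
    SiteLocus,
    bin_sites,
    compare_to_known,
    infer_leca_sites,
    project_hit,
    search_guides,
    single_linkage_bins,
)
from .introns import (
    IntronLocus,
    OrthologGroup,
    assign_snorna_occupancy,
    bin_intron_loci,
    cross_supergroup_homology,
    date_associations,
    project_group_introns,
    reconstruct_intron_ancestry,
)
from .phylo import Phylogeny

__all__ = [
    "InputSet",
    "PipelineConfig",
    "ConfigError",
    "EvidenceSets",
    "total_evidence",
    "clan_expansion_check",
    "run_stages",
    "run_pipeline",
]

SUBUNITS = ("SSU", "LSU")


def _subunits(rrna_alignments: dict) -> list[str]:
    """Subunits actually present, canonical (SSU, LSU) order first."""
    known = [su for su in SUBUNITS if su in rrna_alignments]
    return known + sorted(set(rrna_alignments) - set(known))


class ConfigError(ValueError):
    pass


@dataclass
class InputSet:
    """Everything the pipeline consumes, already parsed."""

    tree: Phylogeny
    catalog: FamilyCatalog
    annotations: dict[str, GenomeAnnotation]
    rrna_alignments: dict[str, MultipleAlignment]
    groups: dict[str, OrthologGroup]
    known_sites: pd.DataFrame
    expression: pd.DataFrame | None = None
    expression_species: str | None = None


@dataclass
class PipelineConfig:
    input_dir: str
    out_dir: str
    seed: int = 0
    search: GuideSearchParams = field(default_factory=GuideSearchParams)
    binning: LocusBinningParams = field(default_factory=LocusBinningParams)
    same_strand: bool = True
    site_c_rule: str = "leca"  # how known sites qualify for evidence set C
    expression_species: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        search = GuideSearchParams(**raw.pop("search", {}))
        binning = LocusBinningParams(**raw.pop("binning", {}))
        try:
            return cls(search=search, binning=binning, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None

    def validate(self) -> None:
        base = Path(self.input_dir)
        if not base.is_dir():
            raise ConfigError(f"input directory not found: {base}")
        for rel in ("tree.nwk", "supergroups.tsv", "families.tsv"):
            if not (base / rel).exists():
                raise ConfigError(f"missing input file: {base / rel}")


def load_inputs(config: PipelineConfig) -> InputSet:
    """Load the standard input bundle layout from ``input_dir``:

    tree.nwk, supergroups.tsv, families.tsv, genomes/<sp>.gff3,
    genomes/<sp>.fa, snornas.fa, alignments/rRNA_<SU>.afa,
    alignments/groups/<gid>.afa, ortholog_groups.tsv, known_sites.tsv,
    expression.tsv.
    """
    config.validate()
    base = Path(config.input_dir)
    tree = sio.read_phylogeny(
        (base / "tree.nwk").read_text(), (base / "supergroups.tsv").read_text()
    )
    catalog = sio.read_family_catalog((base / "families.tsv").read_text())
    sno_seqs = sio.read_fasta((base / "snornas.fa").read_text())
    annotations = {}
    for sp in tree.leaf_names():
        gff = base / "genomes" / f"{sp}.gff3"
        annotations[sp] = sio.read_genome_annotation(
            gff.read_text(), species_id=sp, snorna_sequences=sno_seqs
        )
    rrna = {}
    for path in sorted((base / "alignments").glob("rRNA_*.afa")):
        su = path.stem.removeprefix("rRNA_")
        rrna[su] = sio.read_alignment(path.read_text(), f"rRNA_{su}")
    groups_df = pd.read_csv(base / "ortholog_groups.tsv", sep="\t", dtype=str)
    groups: dict[str, OrthologGroup] = {}
    for gid, sub in groups_df.groupby("group_id"):
        aln = sio.read_alignment(
            (base / "alignments" / "groups" / f"{gid}.afa").read_text(), "protein"
        )
        members = {
            r.species: (r.gene_id, r.transcript_id) for r in sub.itertuples(index=False)
        }
        groups[gid] = OrthologGroup(group_id=gid, members=members, alignment=aln)
    known = sio.read_known_sites((base / "known_sites.tsv").read_text())
    expr_path = base / "expression.tsv"
    expression = sio.read_expression_matrix(expr_path.read_text()) if expr_path.exists() else None
    return InputSet(
        tree=tree,
        catalog=catalog,
        annotations=annotations,
        rrna_alignments=rrna,
        groups=groups,
        known_sites=known,
        expression=expression,
        expression_species=config.expression_species or tree.leaf_names()[0],
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_families(inputs: InputSet):
    """Presence matrices for families and clans; Dollo reconstruction;
    LECA sets and traceable counts."""
    obs: dict[str, set[str]] = {}
    for sp, ann in inputs.annotations.items():
        for sno in ann.snornas:
            if sno.family_id is not None:
                obs.setdefault(sno.family_id, set()).add(sp)
    taxa = inputs.tree.leaf_names()
    fam_matrix = PresenceMatrix.from_observations(obs, taxa, "family")
    clan_matrix = fam_matrix.union(inputs.catalog.clans(), "clan")
    fam_recon = reconstruct(inputs.tree, fam_matrix)
    clan_recon = reconstruct(inputs.tree, clan_matrix)
    return {
        "family_matrix": fam_matrix,
        "clan_matrix": clan_matrix,
        "family_recon": fam_recon,
        "clan_recon": clan_recon,
        "leca_families": fam_recon.leca_characters(),
        "leca_clans": clan_recon.leca_characters(),
        "family_counts": count_traceable(fam_recon, inputs.tree.root, inputs.catalog),
        "clan_counts": count_traceable(clan_recon, inputs.tree.root, inputs.catalog),
    }


def stage_sites(inputs: InputSet, search: GuideSearchParams, binning: LocusBinningParams):
    """Guide search for every C/D snoRNA against its own species' rRNA
    (both subunits), projection into alignment columns, locus binning
    and LECA-site inference, plus known-site recovery."""
    subunits = _subunits(inputs.rrna_alignments)
    hits_by_subunit: dict[str, list[GuideHit]] = {su: [] for su in subunits}
    for sp in sorted(inputs.annotations):
        ann = inputs.annotations[sp]
        for su in subunits:
            aln = inputs.rrna_alignments[su]
            if sp not in aln:
                continue
            rrna = aln.ungapped(sp)
            for sno in sorted(ann.snornas, key=lambda s: s.snorna_id):
                if sno.sno_class is not SnoClass.CD:
                    continue
                for hit in search_guides(sno, rrna, search, subunit=su):
                    hits_by_subunit[su].append(project_hit(hit, aln))
    loci: list[SiteLocus] = []
    for su in subunits:
        loci.extend(bin_sites(hits_by_subunit[su], binning))
    leca_ids = infer_leca_sites(loci, inputs.tree)
    recovery, totals = compare_to_known(
        loci, inputs.known_sites, inputs.rrna_alignments, binning.site_tolerance
    )
    fam_to_leca_loci: dict[str, set[str]] = {}
    for locus in loci:
        if locus.locus_id in leca_ids:
            for fam in locus.families:
                fam_to_leca_loci.setdefault(fam, set()).add(locus.locus_id)
    return {
        "hits": hits_by_subunit,
        "loci": loci,
        "leca_site_ids": leca_ids,
        "recovery": recovery,
        "recovery_totals": totals,
        "family_leca_sites": fam_to_leca_loci,
    }


def stage_introns(inputs: InputSet, same_strand: bool = True):
    """Intron projection and binning per ortholog group, LECA-locus
    inference, snoRNA occupancy, homology verdicts and association
    dating."""
    all_loci: list[IntronLocus] = []
    host_presence: dict[str, set[str]] = {}
    for gid in sorted(inputs.groups):
        group = inputs.groups[gid]
        host_presence[gid] = set(group.members)
        members = project_group_introns(group, inputs.annotations)
        loci = bin_intron_loci(group, members, tolerance=5)
        for sp in sorted(group.members):
            assign_snorna_occupancy(inputs.annotations[sp], loci, same_strand=same_strand)
        all_loci.extend(loci)
    leca_ids = reconstruct_intron_ancestry(all_loci, inputs.tree)
    verdicts = {}
    for locus in all_loci:
        if locus.occupied_species():
            verdicts[locus.locus_id] = cross_supergroup_homology(
                locus, inputs.catalog, inputs.tree
            )
    datings = date_associations(all_loci, inputs.tree, host_presence)
    leca_snorna_loci = {
        l.locus_id for l in all_loci if l.locus_id in leca_ids and l.occupied_species()
    }
    return {
        "loci": all_loci,
        "leca_intron_ids": leca_ids,
        "verdicts": verdicts,
        "datings": datings,
        "host_presence": host_presence,
        "leca_snorna_intron_ids": leca_snorna_loci,
    }


def host_gene_set(annotation: GenomeAnnotation, same_strand: bool = True) -> set[str]:
    """Genes of one species whose introns carry ≥ 1 snoRNA."""
    hosts = set()
    for gid, gene in annotation.genes.items():
        for tx in gene.transcripts:
            for intron in tx.introns():
                for sno in annotation.snornas:
                    if intron.contains(sno.interval) and (
                        not same_strand or sno.strand == tx.strand
                    ):
                        hosts.add(gid)
    return hosts


def stage_expression(inputs: InputSet, same_strand: bool = True):
    """Host vs non-host expression-breadth comparison for the
    designated expression species."""
    if inputs.expression is None:
        return None
    sp = inputs.expression_species or inputs.tree.leaf_names()[0]
    hosts = host_gene_set(inputs.annotations[sp], same_strand)
    hosts &= set(inputs.expression.index)
    if not hosts:
        return None
    return compare_host_vs_nonhost(inputs.expression, hosts)


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------


@dataclass
class EvidenceSets:
    """Intersectable evidence units (clan id where defined, else family
    id) for the three lines of evidence, plus excluded units."""

    a: set[str]
    b: set[str]
    c: set[str]
    exclusions: dict[str, str]  # unit -> reason


def _unit_of(family_id: str, catalog: FamilyCatalog) -> str:
    clan = catalog.clan_of(family_id)
    return clan if clan is not None else family_id


def build_evidence_sets(
    inputs: InputSet,
    leca_families: set[str],
    leca_clans: set[str],
    family_leca_sites: dict[str, set[str]],
    site_c_rule: str = "leca",
    binning: LocusBinningParams = LocusBinningParams(),
) -> EvidenceSets:
    catalog = inputs.catalog
    clans = catalog.clans()
    # A: LECA units from annotation distributions
    a = set(leca_clans)
    for fam in leca_families:
        if catalog.clan_of(fam) is None:
            a.add(fam)
    # exclusions: non-C/D or cleavage-only units
    exclusions: dict[str, str] = {}
    for unit in sorted(a):
        members = clans.get(unit, [unit])
        classes = {catalog.class_of(m) for m in members if m in catalog}
        if classes != {SnoClass.CD}:
            exclusions[unit] = "not_cd"
        elif any(catalog[m].cleavage_only for m in members if m in catalog):
            exclusions[unit] = "cleavage_only"
    a -= set(exclusions)
    # B: units supporting ≥ 1 LECA guide-mapped site locus
    b = {
        _unit_of(fam, catalog)
        for fam, loci in family_leca_sites.items()
        if loci and fam in catalog
    }
    # C: units supported by independently mapped LECA-compatible sites
    c = _independent_site_units(inputs, site_c_rule, binning)
    b -= set(exclusions)
    c -= set(exclusions)
    return EvidenceSets(a=a, b=b, c=c, exclusions=exclusions)


def _independent_site_units(
    inputs: InputSet, rule: str, binning: LocusBinningParams
) -> set[str]:
    """Bin the known-site table into cross-species loci and keep the
    families of loci whose species distribution satisfies the rule
    (default: Dollo-LECA-compatible)."""
    from .datamodel import ungapped_to_column

    known = inputs.known_sites
    units: set[str] = set()
    for su in _subunits(inputs.rrna_alignments):
        sub = known[known["subunit"] == su]
        if not len(sub):
            continue
        rows = list(sub.itertuples(index=False))
        cols = [
            ungapped_to_column(inputs.rrna_alignments[su], r.species, int(r.site_position))
            for r in rows
        ]
        for idxs in single_linkage_bins(cols, binning.site_tolerance):
            species = {rows[i].species for i in idxs}
            fams = {rows[i].family_id for i in idxs if rows[i].family_id}
            if rule == "leca":
                root = inputs.tree.root
                kids = inputs.tree.children[root]
                covered = sum(
                    1 for k in kids if species & inputs.tree.leaves_under(k)
                )
                ok = covered >= 2
            else:
                raise ConfigError(f"unknown site_c_rule {rule!r}")
            if ok:
                for fam in fams:
                    if fam in inputs.catalog:
                        units.add(_unit_of(fam, inputs.catalog))
    return units


def total_evidence(sets: EvidenceSets) -> dict:
    """Cardinalities, pairwise intersections and the total-evidence
    triple intersection A∩B∩C."""
    inter = sets.a & sets.b & sets.c
    report = {
        "n_a": len(sets.a),
        "n_b": len(sets.b),
        "n_c": len(sets.c),
        "n_ab": len(sets.a & sets.b),
        "n_ac": len(sets.a & sets.c),
        "n_bc": len(sets.b & sets.c),
        "n_abc": len(inter),
        "a": sorted(sets.a),
        "b": sorted(sets.b),
        "c": sorted(sets.c),
        "intersection": sorted(inter),
        "exclusions": dict(sorted(sets.exclusions.items())),
    }
    assert report["n_abc"] <= min(report["n_a"], report["n_b"], report["n_c"])
    return report


def clan_expansion_check(
    clan_id: str,
    leca_families: set[str],
    family_leca_sites: dict[str, set[str]],
    catalog: FamilyCatalog,
) -> str:
    """Did a multi-family LECA clan arise by ancestral duplication?

    ``duplication`` iff ≥ 2 member families map to distinct LECA site
    loci; if the members target one orthologous site the clan is more
    parsimoniously an artefact of model building (or orthologous
    descent): ``artefactual_split_or_orthologous``.
    """
    members = [m for m in catalog.clans().get(clan_id, []) if m in leca_families]
    if len(members) < 2:
        return "not_applicable"
    loci_per_family = [family_leca_sites.get(m, set()) for m in members]
    distinct = set().union(*loci_per_family)
    mapped = [l for l in loci_per_family if l]
    if len(mapped) >= 2 and len(distinct) >= 2:
        # at least two families with sites, not all at the same locus
        if any(l1 and l2 and not (l1 & l2) for l1 in loci_per_family for l2 in loci_per_family):
            return "duplication"
    return "artefactual_split_or_orthologous"


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_stages(inputs: InputSet, config: PipelineConfig) -> dict:
    """Run all stages on an in-memory input set; returns the full
    result dictionary (no files written)."""
    fam = stage_families(inputs)
    sites = stage_sites(inputs, config.search, config.binning)
    intr = stage_introns(inputs, config.same_strand)
    expr = stage_expression(inputs, config.same_strand)
    # families whose LECA status is considered for clan expansion
    ev_sets = build_evidence_sets(
        inputs,
        fam["leca_families"],
        fam["leca_clans"],
        sites["family_leca_sites"],
        config.site_c_rule,
        config.binning,
    )
    evidence = total_evidence(ev_sets)
    clan_checks = {
        clan: clan_expansion_check(
            clan, fam["leca_families"], sites["family_leca_sites"], inputs.catalog
        )
        for clan in sorted(inputs.catalog.clans())
    }
    return {
        "families": fam,
        "sites": sites,
        "introns": intr,
        "expression": expr,
        "evidence_sets": ev_sets,
        "evidence": evidence,
        "clan_expansion": clan_checks,
    }


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_reports(results: dict, inputs: InputSet, config: PipelineConfig, out_dir: str | Path) -> None:
    """Write every stage's tables/reports deterministically."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = inputs.tree
    fam = results["families"]
    (out / "family_matrix.tsv").write_text(fam["family_matrix"].to_tsv())
    (out / "clan_matrix.tsv").write_text(fam["clan_matrix"].to_tsv())
    _json_dump(
        {
            "families": fam["family_recon"].report(),
            "clans": fam["clan_recon"].report(),
            "leca_families": sorted(fam["leca_families"]),
            "leca_clans": sorted(fam["leca_clans"]),
            "family_counts": fam["family_counts"],
            "clan_counts": fam["clan_counts"],
        },
        out / "families_report.json",
    )
    sites = results["sites"]
    hit_rows = [
        {
            "snorna_id": h.snorna_id,
            "family_id": h.family_id or "",
            "species": h.species_id,
            "subunit": h.subunit,
            "start": h.start,
            "end": h.end,
            "center": h.center,
            "center_column": h.center_column,
            "score": h.score,
            "identity": round(h.identity, 6),
        }
        for su in _subunits(inputs.rrna_alignments)
        for h in sites["hits"][su]
    ]
    pd.DataFrame(hit_rows).to_csv(out / "guide_hits.tsv", sep="\t", index=False)
    locus_rows = [
        {
            "locus_id": l.locus_id,
            "subunit": l.subunit,
            "column": l.column,
            "n_species": len(l.species),
            "species": ",".join(sorted(l.species)),
            "families": ",".join(sorted(l.families)),
            "in_leca": l.locus_id in sites["leca_site_ids"],
        }
        for l in sites["loci"]
    ]
    pd.DataFrame(locus_rows).to_csv(out / "site_loci.tsv", sep="\t", index=False)
    sites["recovery"].to_csv(out / "known_site_recovery.tsv", sep="\t", index=False)
    intr = results["introns"]
    occ_rows = []
    for l in intr["loci"]:
        for sp in sorted(l.members):
            occs = l.occupancy.get(sp, [])
            occ_rows.append(
                {
                    "group_id": l.group_id,
                    "locus_id": l.locus_id,
                    "column": l.column,
                    "species": sp,
                    "snornas": ",".join(sorted(o.snorna_id for o in occs)),
                    "families": ",".join(sorted({o.family_id or "" for o in occs})),
                    "in_leca": l.locus_id in intr["leca_intron_ids"],
                }
            )
    pd.DataFrame(occ_rows).to_csv(out / "intron_loci.tsv", sep="\t", index=False)
    _json_dump(
        {
            lid: {
                "verdict": v.verdict.value,
                "families_by_supergroup": {
                    sg: sorted(fs) for sg, fs in sorted(v.families_by_supergroup.items())
                },
                "classes_by_supergroup": {
                    sg: sorted(cs) for sg, cs in sorted(v.classes_by_supergroup.items())
                },
            }
            for lid, v in sorted(intr["verdicts"].items())
        },
        out / "homology_verdicts.json",
    )
    dating_rows = [
        {
            "family_id": d.family_id,
            "locus_id": d.locus_id,
            "association_node": tree.node_name(d.association_node),
            "host_node": tree.node_name(d.host_node),
            "recent_gain": d.recent_gain,
        }
        for d in intr["datings"]
    ]
    pd.DataFrame(dating_rows).to_csv(out / "association_dating.tsv", sep="\t", index=False)
    expr = results["expression"]
    if expr is not None:
        r = expr["rank_sum"]
        _json_dump(
            {
                "u_statistic": r.u_statistic,
                "p_value": r.p_value,
                "sided": r.sided.value,
                "exact": r.exact,
                "n_host": expr["n_host"],
                "n_nonhost": expr["n_nonhost"],
                "host_median_entropy": round(expr["host_median_entropy"], 6),
                "nonhost_median_entropy": round(expr["nonhost_median_entropy"], 6),
            },
            out / "expression_report.json",
        )
    _json_dump(
        {"total_evidence": results["evidence"], "clan_expansion": results["clan_expansion"]},
        out / "evidence.json",
    )
    cfg_text = json.dumps(
        {
            "seed": config.seed,
            "search": vars(config.search),
            "binning": vars(config.binning),
            "same_strand": config.same_strand,
            "site_c_rule": config.site_c_rule,
        },
        sort_keys=True,
    )
    _json_dump(
        {"seed": config.seed, "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest(), "config": json.loads(cfg_text)},
        out / "run_manifest.json",
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Load inputs per the config, run every stage, write all reports
    into ``config.out_dir``; idempotent for identical inputs + seed."""
    inputs = load_inputs(config)
    results = run_stages(inputs, config)
    write_reports(results, inputs, config, config.out_dir)
    return results
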