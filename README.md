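# snoleca

Comparative genomics of small nucleolar RNA (snoRNA) families across
eukaryotes: how far back can individual snoRNA families, their rRNA
modification sites, and their host-gene associations be traced — and
in particular, which of them were already present in the Last
Eukaryotic Common Ancestor (LECA)?

`snoleca` is a reusable, fully tested implementation of that analysis
for researchers studying non-coding RNA evolution. It takes per-species
genome annotations (GFF3), snoRNA and rRNA sequences (FASTA), curated
SSU/LSU rRNA and host-protein alignments, a rooted species tree with
supergroup labels, an Rfam-style family catalog, a known
modification-site table and a gene × tissue expression matrix — and it
ships a phylogeny-aware synthetic-data generator that fabricates all of
these inputs with complete ground truth, so every stage of the pipeline
is testable without any external downloads.

## The analysis

**Dollo parsimony placement.** A binary character (presence of a snoRNA
family, clan, intron locus or modification-site locus across species)
evolves under Dollo parsimony: one gain, arbitrarily many losses,
absence as the default state. On a rooted tree the minimal scenario is
determined: the gain sits at the MRCA of the presence leaves, and
losses sit on the highest branches whose subtrees lack the character.
A character is traceable to LECA (the root, placed between unikonts
and bikonts) iff presence leaves occur in at least two child subtrees
of the root.

**Guide → rRNA site mapping.** Box C/D snoRNAs carry contiguous
antisense guides that direct 2′-O-methylation of rRNA. The mapper is a
deterministic word-seeded ungapped search (word size W = 5, match +1 /
mismatch −2, minimum hit length 10, minimum identity 0.9, no gaps) of
each snoRNA's reverse complement against its own species' rRNA. Hit
centers are projected through the curated rRNA alignment into column
space, binned into cross-species site loci by single-linkage clustering
at ± 2 columns, and filtered: loci restricted to a single species are
discarded, and Dollo parsimony keeps only loci whose species
distribution is compatible with presence in LECA.

**Intron atlas.** Introns of orthologous host genes are mapped onto the
group's protein alignment (position = coding bases upstream of the
intron ÷ 3, projected to alignment columns; UTR introns excluded) and
binned at ± 5 columns. LECA intron loci are identified with the same
Dollo rule; intronic snoRNA occupancy is attached by interval
containment, and the occupants of each locus are classified across
supergroups: same family / same clan / same class without further
evidence / unrelated classes / single supergroup. Each (family, locus)
association is dated at the MRCA of its carriers; an association
strictly younger than its (often LECA) host gene is a recent gain —
evidence of intragenomic snoRNA mobility.

**Expression breadth.** For each gene, breadth of expression over k
tissues is the Shannon entropy S = −Σ pᵢ ln pᵢ of the tissue
proportions pᵢ = Eᵢ/T (0 = single tissue, ln k = uniform). snoRNA host
genes are compared with non-host genes by a one-sided Mann–Whitney
rank-sum test (exact null for small samples, tie-corrected normal
approximation otherwise).

**Total evidence.** Three independent lines — (A) LECA placement from
annotated presence/absence, (B) LECA-conserved guide-mapped sites, and
(C) independently reported modification sites with LECA-compatible
distributions — are intersected at the clan level, after excluding
non-C/D families and families acting only in rRNA cleavage.

## Worked example

Generate a 6-species synthetic data set with 20 ancestral families and
12 planted modification sites, run every stage, and read off the
headline quantities:

```python
from snoleca import SimulationParams, simulate_bundle, run_stages, PipelineConfig

params = SimulationParams(
    seed=7, taxa_per_supergroup=3, n_ancestral_families=20,
    n_planted_sites=12, n_confined_sites=2, n_known_extra=1, n_decoys=10,
    n_host_genes=10, n_generic_clans=2, n_mobility_events=2,
    n_convergent_pairs=2, n_nonhost_genes=60,
)
bundle = simulate_bundle(params)
results = run_stages(bundle.inputs, PipelineConfig(input_dir=".", out_dir="out", seed=7))
```

which prints, via the summary fields of each stage:

```
LECA families: 12 (C/D 9, H/ACA 3)
LECA clans: 4
site loci: 14, LECA-conserved: 12
known-site recovery: 63/64
LECA intron loci: 53, snoRNA-bearing: 22
evidence |A|=6 |B|=6 |C|=6 |A∩B∩C|=6
host vs non-host entropy: 2.387 vs 1.921 nats, one-sided p = 2.45e-06
```

Reading: 12 of the surviving families still span both sides of the root
and are placed in LECA; all 12 planted cross-root modification-site
loci are recovered as LECA-conserved (14 loci pass the ≥ 2-species
filter, of which the two planted single-supergroup loci are correctly
excluded from the LECA set); 22 LECA intron loci carry a snoRNA; the
three evidence lines agree on 6 clan-level units; and host genes are
significantly more broadly expressed than non-hosts.

The same run is available from the shell:

```bash
snoleca simulate --seed 7 --out data/
snoleca all --input-dir data/ --out out/ --seed 7
```

which writes the presence matrices, guide-hit and locus tables,
homology verdicts, association dating, expression report and the
total-evidence intersection into `out/`.

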