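# Methods

This note documents the models and procedures implemented in
`snoleca`, their assumptions, the tunable parameters, and the design
choices made where the design was genuinely open. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Dollo parsimony on a rooted supergroup tree

Characters are binary presence/absence vectors over species — a snoRNA
family, a clan, an intron locus or a modification-site locus. Dollo
parsimony assumes each character is gained exactly once and that
absence is the default state; this is the conservative choice for
features (like snoRNA families defined by sequence homology) whose
independent re-invention is considered implausible, and it requires no
rate model.

On a *rooted* tree the minimal single-gain scenario is unique and
closed-form:

* gain node = MRCA of all presence leaves;
* losses = the maximal subtrees below the gain that contain no
  presence leaf (one loss each);
* placing the gain above the MRCA always costs strictly more losses
  (every step up passes at least one presence-free sibling subtree),
  so no search is needed.

A corollary used throughout: the root (LECA) state is 1 iff presence
leaves occur in ≥ 2 child subtrees of the root. `brute_force_min_losses`
implements the exhaustive alternative (all gain placements) and is the
oracle the implementation is tested against on complete pattern
enumerations.

Decisions:

* **Missing data.** Taxa in which a character was not assessed are
  scored 0; an `unscored` mask can record them but does not alter the
  reconstruction (absence is the default state either way).
* **Clans.** A clan is scored as the union of its member families (a
  taxon has the clan iff it has ≥ 1 member). Whether the original
  analyses scored clans this way or through merged covariance-model
  hits is not determinable; union is the natural reading of
  presence/absence.
* **Multifurcations** are allowed; nothing in the algorithm assumes a
  binary tree.

## Guide → rRNA antisense search

The biological object is the contiguous C/D guide element, a 10–21 nt
antisense duplex with the target rRNA. The search emulates a blastn
run at word size 5 with gap penalties high enough that gapped
alignments cannot occur at guide scale, but is fully deterministic and
self-contained:

* query = reverse complement of the snoRNA; ungapped comparison
  against the species' own rRNA (both subunits);
* scoring +1/−2; candidate windows must have length ≥ 10, identity
  ≥ 0.9, and begin and end on a matched base (trimming to the
  maximal-scoring extent always strips edge mismatches, so this is a
  property of the hit definition, not a heuristic);
* overlapping candidates are deduplicated best-score-first with ties
  to the leftmost, then longest, window.

Rather than an X-dropoff extension heuristic, the implementation
enumerates *all* passing match-bounded windows on seeded diagonals
(organised by maximal match runs) and applies the deduplication rule
exactly. Two consequences matter: the output is a well-defined
function of the inputs, checkable against a naive all-window oracle;
and seeding loses nothing, because at identity ≥ 0.9 and length ≥ 10
every passing window provably contains an exact run of ≥ 5 matches
(pigeonhole: m mismatches split L − m matches into ≤ m + 1 runs).
With user-set thresholds far below the defaults that guarantee can
fail, in which case the seeded search is a (documented) approximation.

E-value statistics are deliberately not implemented: the
length/identity thresholds play that role, and the conservation filter
downstream (≥ 2 species per locus, LECA-compatibility) is the real
specificity mechanism — as it must be, since at rRNA scale chance
10-nt/90%-identity antisense windows are common.

Hit centers use the floor midpoint `(start + end − 1) // 2`: binning
at ± 2 needs a single integer per hit. Whether the "center" of an
interaction should be measured on the rRNA or snoRNA side is
ambiguous; the rRNA side is used. The modified base reported for a
site is the rRNA base at the representative column per species; no
box-offset (D + 5) rule is applied, because binning operates on hit
centers.

## Locus binning

Cross-species comparability comes from projecting per-species
coordinates into curated-alignment column space (`ungapped_to_column`;
gap characters `-` and `.`). Binning is single-linkage clustering of
projected positions with link distance ≤ tolerance (2 columns for
rRNA sites, 5 for intron positions) — equivalently, connected
components of the |Δcolumn| ≤ tolerance relation, computed over sorted
positions, hence deterministic and order-independent. Single linkage
was chosen over fixed-width bins to avoid bin-boundary artifacts; the
representative column is the lower median, and chained clusters can in
principle span more than ± tolerance around it (rare at realistic
densities, and irrelevant to the set partition).

Site loci observed in a single species are discarded. Intron loci keep
single-species members (the LECA filter handles conservation), and a
locus is only reported "snoRNA-bearing in LECA" when it is both
LECA-traceable and occupied.

## Intron positions

The intron position on the protein is the number of coding bases
upstream of the intron (through the last CDS base of the exon
immediately 5′ of it) divided by 3 — an intron after a 300-nt first
coding exon sits at amino acid 100, and adjacent introns flanking one
exon get distinct positions. Introns outside the CDS genomic span
(5′/3′ UTR introns) are excluded. When a gene model has several
transcripts the one with the longest CDS is used. Occupancy requires
the snoRNA interval to be fully contained in the intron and, by
default, on the host strand (intronic snoRNAs are processed from the
host pre-mRNA); snoRNAs straddling an exon boundary are flagged, not
assigned. The strand requirement is a configuration switch because the
biological literature contains rare antisense arrangements.

## Homology verdicts and association dating

For a LECA intron locus, snoRNA homology across supergroups is
assessed from catalog identity: one family spanning ≥ 2 supergroups →
`same_family`; clan-level identity only → `same_clan`; same class but
no family/clan link → `same_class_no_evidence`; both C/D and H/ACA
among the cross-supergroup occupants → `unrelated_classes`; occupancy
confined to one supergroup → `single_supergroup`. Manual sequence
inspection (the original second criterion) is outside scope and is
reduced to this catalog identity.

Association dating places each (family, locus) pair at the MRCA of
the species sharing it and compares that with the Dollo placement of
the host gene itself; a strictly shallower association in an older
gene is reported as a recent gain — the signature of intragenomic
mobility (retrotransposition) into a pre-existing intron.

## Expression breadth

S = −Σ pᵢ ln pᵢ in nats, with 0·ln 0 = 0 (tissues with zero signal
contribute nothing); all-zero profiles are an error, not S = 0.
Duplicate tissues (e.g. brain subsamples) are collapsed by averaging
within groups of a user-supplied duplicate map before the median
signal is taken; the map defaults to the identity because no canonical
grouping ships with expression matrices.

The host/non-host comparison is a one-sided Mann–Whitney test (hosts
more broadly expressed) as the primary report, since the scientific
claim is directional; two-sided is available. The U statistic uses
midranks. For n₁·n₂ ≤ 400 the p-value is exact: a subset-sum dynamic
program over the multiset of (doubled, hence integer) midranks yields
the full permutation distribution of U, which is correct under ties —
unlike the classical no-ties recursion. Larger samples use the normal
approximation with tie-corrected variance and a 0.5 continuity
correction; the suite checks the two agree to < 0.01 at n₁ = n₂ = 15.

## Total evidence

Families grouped into a clan are intersected at clan level (the clan
is the likely orthologous unit); clanless families stand for
themselves. Units that are not box C/D, or contain a family known to
act only in rRNA cleavage, are excluded from the site-based
intersection and listed with reasons. Evidence set C (independently
reported sites) is built by binning the known-site table exactly like
predicted hits and keeping loci whose species distribution satisfies
the Dollo root rule; a reference-species rule ("conserved in a chosen
species plus one other") would be an alternative reading, and the rule
is a configuration point (`site_c_rule`).

## The synthetic-data generator

The generator's defaults are the study conditions the test suite and
acceptance script run under: 2 supergroups × 6 taxa on a balanced
rooted tree, 50 ancestral families born at the root, per-branch loss
probability 0.15, new-family gain rate 0.1/branch, 5 mobility events,
3 convergent-insertion pairs, 30 host genes × 6 ancestral introns
(gain 0.05/loss 0.05 per branch), SSU 1800 nt + LSU 3000 nt with 1%
substitutions and ~2 column deletions per branch, 30 planted
modification sites with 10–14-nt guides, 80-nt snoRNAs, 30 decoys, 12
tissues and a 0.5-nat host/non-host entropy gap (host Dirichlet
concentration 5; the non-host concentration is solved from
E[S] = ψ(kα + 1) − ψ(α + 1)). Loss and mobility magnitudes are not
estimable from published summaries; they were fixed once at values
that leave all event classes well represented on a 12-leaf tree.

What it emulates, and how truth stays exact:

* **Family evolution** is simulated gain-first/loss-per-branch, so
  single origin holds by construction and the expected LECA label
  (ancestral ∧ survivors on both sides of the root) provably equals
  the Dollo reconstruction of the emitted matrix.
* **Mobility events** relocate a family to a fresh intron on a chosen
  branch and are made persistent (the family is completed in the
  clade), so the association MRCA equals the planted branch's child
  exactly and every event is datable. Convergent-insertion pairs and
  confined-site families are likewise exempt from loss so the planted
  verdict/exclusion cases cannot silently vanish.
* **Alignments** are generated in column space (substitutions plus
  clade-level column deletions, planted windows protected), so the
  ungapped↔column maps are known exactly and planted site columns
  co-bin across species by construction.
* **Gene models** carry both strands, UTR exons, UTR introns and 3′
  UTRs; intron positions are planted at codon boundaries so the
  projection oracle is exact.
* **Sequence certification.** Under the default search thresholds,
  chance antisense windows are expected in random sequence at rRNA
  scale, which would blur the truth tables. After planting, a
  deterministic repair loop searches every C/D snoRNA (and decoy)
  against its species' rRNA and mutates bases until the hit set equals
  exactly the planted windows: matching flank bases are mutated (and
  then frozen, so overlapping spurious windows cannot fight over a
  shared base), guide embeds get 2-base mismatch guards against
  score-improving extensions, and matches sustained by planted
  material are killed by mutating the unprotected rRNA at the spurious
  target. The loop is seeded, converges in a bounded number of rounds,
  and ends with a verification pass; the emitted bundle is therefore
  certified, not merely probable.

What it does **not** emulate — and hence what passing tests do not
show about real data: no box motifs (C/D/C′/D′) or secondary
structure, no codon model or rate heterogeneity in the alignments, no
annotation noise (missing genomes, fragmented assemblies), no
paralogy within ortholog groups, and real decoy snoRNAs *do* produce
chance guide-like matches that only the cross-species conservation
filter removes. Tests on this generator validate the algorithms and
their filters, not the sensitivity/specificity trade-offs of a real
genome screen.

Determinism: all randomness flows from one `SeedSequence`; regenerating
with the same seed reproduces every output byte-for-byte, which the
acceptance script re-checks end-to-end through the on-disk pipeline.

## Problem sizes

The shipped study conditions (12 taxa, 50 families, 30 sites, 30
genes, ~3 kb + 1.8 kb rRNA) keep a full generate-and-analyse cycle
around a minute on one CPU while leaving every event class populated;
the guide-mapping fixture uses 6 taxa and a single 1.8-kb subunit, and
the determinism check a 4-taxon bundle. Exhaustive oracle checks run
all 255 patterns on 8-leaf trees (25 random topologies) and all group
sizes ≤ 6 for the rank-sum null.

## Known limitations

* The Dollo engine reports one minimal scenario; it does not enumerate
  co-optimal loss placements (they do not exist under the maximal-
  absent-subtree convention, but alternative conventions would place
  losses lower).
* The guide search's seeded completeness guarantee is tied to the
  default identity/length thresholds (see above).
* `compare_to_known` matches per species row; it does not attempt to
  reconcile conflicting per-species coordinates for the same named
  site beyond the alignment projection.
* The exact rank-sum DP is O(n₁ · N · ΣR) and is capped by
  `exact_limit` (default n₁·n₂ ≤ 400); far larger exact computations
  are possible but pointless given the normal approximation's
  accuracy there.
* Single chromosome per species; coordinates are genome-wide offsets.
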