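# Methods

This note documents the models, rules, tunables and numerical choices behind
`bgcmine`, and what the synthetic benchmark does and does not demonstrate.

## Alignment and search statistics

All protein comparison is optimal Smith–Waterman local alignment on BLOSUM62
with affine gaps. The gap convention follows the BLAST-style "11 1" reading:
a gap of length L costs 11 + L, i.e. the first gapped position pays
open+extend (the `PairwiseAligner` is configured open = −12, extend = −1 to
realise this). `X` scores 0 against every residue. Identity and similarity
percentages are computed over the columns of one optimal traceback
(including internal gap columns; local alignments have no end gaps).
Because the optimal traceback is not unique, any statistic that must be
symmetric (the DSI pair identity) canonicalises its argument order before
aligning.

E-values use the Karlin–Altschul form E = K·m·n·exp(−λS) with the published
gapped-BLOSUM62 constants λ = 0.267, K = 0.041, stored in an overridable
calibration table. No composition-based statistics and no low-complexity
masking are applied; this is the simplest documented behaviour and a known
source of possible neighbour-call differences against BLAST
implementations that SEG-filter by default.

Thresholds (all configurable in `PipelineConfig`):

| parameter | default | role |
|---|---|---|
| `core_max_evalue` | 1e-1 | template search for core genes (deliberately lenient) |
| `neighbour_max_evalue` | 1e-5 | function-database search for neighbour roles; stricter because one spurious call extends borders |
| `min_score_frac` | 0.3 | domain hit floor as a fraction of the panel reference self-score |
| `strong_evalue` | 1e-5 | confidence gate for similarity-only classification evidence |

## Core detection and domain strings

Each gene keeps at most one core hit (best score; ties by lower E then
lexicographic accession), but all domain hits. Domain assignment is greedy
with re-fit: repeatedly accept the highest-scoring panel hit on the gene
with already-accepted intervals masked to `X`, until nothing reaches the
score floor. Masking guarantees non-overlap and lets repeated domains
(NRPS modules, bifunctional cyclases) surface. A supplied domain-annotation
table (the pluggable stand-in for an HMM-based annotator) takes precedence
for the genes it covers.

Two minimal definitions drive everything downstream and are the most
consequential formalisation in the package: a gene is a **PKS** iff its
domain string contains KS and (AT or ACP), and an **NRPS module** is a
consecutive (C, A, T) triple.

## Border rule and assembly

From each core gene the locus grows outward independently in both
directions; a walk stops at the first run of three consecutive genes whose
best function-database hit is absent or housekeeping ("unrelated"), and the
locus is trimmed back to the outermost related gene. "Consecutive" counts
genes only — strand and intergenic distance play no part. A contig end
terminates a walk early, and the locus is likewise trimmed to the outermost
related gene (how the original counting treated contig-gap-interrupted runs
is not specifiable; trimming is our choice). Loci sharing a gene merge;
merged loci with ≥ 2 PKS cores are flagged collaborative candidates rather
than resolved, since intertwined loci may genuinely be two pathways.
Distally located tailoring genes are out of scope by construction.

## Classification

One class per locus, first matching rule wins. Precedence: primary-
metabolism exclusions (A-T-R-R; single-copy unclustered lanosterol
synthase) → RiPP → alkyl citrate (citrate synthase + dedicated FAS pair or
hrPKS) → meroterpenoid (PKS + prenyltransferase and/or terpene cyclase) →
single-protein hybrids (PKS_NRPS if the PKS domains are N-terminal) →
collaborative PKS → disintegrated PKS → PKS subtype → type III PKS → NRPS
(≥ 1 complete module; module count reported, one module suffices) →
NRPS-like A-T-TE / A-T-R → labdane (a gene with two cyclase domains) →
GGPPS-coupled diterpene → triterpene (squalene-hopene cyclase, or
lanosterol synthase beyond the genome's primary copy) → DMAT alkaloid →
mono/sesquiterpene cyclase. The rationale for the order: exclusions first;
the most gene-content-specific composites before generic PKS; hybrids
before collaborative so a bifunctional protein is not double-counted.

PKS subtype boundaries are our formalisation (the subtype names are
standard, threshold rules are not): truncated if KS, AT or ACP is missing;
highly reducing if {KR, DH, ER} are all present; partially reducing if KR
without ER; non-reducing if no reductive domain (SAT/PT supportive, not
required). Off-pattern strings (e.g. ER without the full reductive loop)
fall to the most reduced compatible subtype so classification is total.
Disintegrated PKS requires two genes within 10 kb carrying disjoint,
individually incomplete, jointly complete hr- or nr-PKS domain sets — the
motivating observation is a split hrPKS whose second subunit (KR + ACP) sat
8 kb downstream.

Rules that rest **only** on template similarity (RiPP precursors, type III
PKS) demand a confident hit (E ≤ 1e-5). The detection threshold of 0.1 is
lenient by design and admits marginal chance hits; in the original
workflow a human curator triaged these, and the confidence gate is this
package's mechanical replacement (a 320-residue FAS subunit with a chance
E ≈ 0.09 precursor hit must not become a RiPP).

Counting: primary-metabolism loci never count; *unclustered* (single-gene)
A-T-R NRPS-like loci are excluded from class-count totals, clustered ones
count. Type III PKS loci are counted but left out of the similarity
network — they carry no modular domain string to compare, mirroring the
upstream workflow's exclusion.

## Family networking

JI is the Jaccard index of domain-type sets (0 when both empty). DSI pairs
the copies of each shared domain type greedily by descending pairwise
identity (optimal assignment would change little on the small inventories
involved and greedy is deterministic); each paired copy contributes its
pair identity, unpaired copies contribute 0, and the weighted mean runs
jointly over every copy in both loci — so DSI(A, A) = 1. The alternative
per-type-first normalisation was considered and not used. Anchor types
{CS, TC, PTase, DMAT} (our vocabulary mapping of the Citrate_synt,
Terpene_syn_C_2, UbiA and Trp_DMAT families) get multiplicative weight 2.0
— the boost magnitude is not published; 2.0 is the package default and
configurable. AI is the Jaccard of the sets of adjacent ordered domain-type
pairs of each locus's linear sequence (genes left-to-right by coordinate,
minus-strand genes reversed gene-wise).

Distance = 1 − (0.2·JI + 0.75·DSI + 0.05·AI), clamped to [0, 1]. Edges are
strict: d < cutoff. A locus with a single domain has no adjacency pairs, so
AI = 0 by convention and its self-distance is 0.05, not 0; the
self-distance-zero axiom therefore holds for loci with ≥ 2 domains. The
same convention makes empty inventories maximally distant (d = 1),
preventing degenerate domainless loci from gluing families together.
GCFs are connected components (union–find via networkx), singletons kept,
all classes mixed in one network, reference-only components pruned,
partitions provably nested across rising cutoffs.

## Synteny

Best links rank by percent similarity (positive-scoring columns), ties by
score then gene order. A link must reach 30 % identity **and** 50 % mutual
coverage: short optimal local alignments between unrelated proteins
routinely exceed 30 % column identity, so an identity floor alone produces
spurious links (near-global alignment tools avoid this implicitly; the
coverage floor is the local-alignment equivalent). Homology groups are
single-linkage over best links and invariant to input order. Co-localised
search marks genes hitting any query at E ≤ 1e-5 and reports maximal
windows with ≥ `min_queries` distinct queries and at most `max_gap_genes`
intervening non-hit genes.

## Synthetic cohorts: what they emulate, and what they do not

The generator plants ground-truth loci in filler-gene background:

- **Core genes** concatenate domain-panel reference segments (10-residue
  G/S linkers), so the domain annotator can recover the plan; accessory
  genes derive from labelled function-database entries.
- **Families** are stars: the first member species carries the archetype
  verbatim, every other member is mutated from it at the family identity
  target (exact per-segment identity, indel-free). Within-family network
  connectivity therefore runs through the archetype and is analytic:
  hub–leaf distance ≈ 0.75·(1 − identity) < 0.4 for every admissible
  target (≥ 0.5). Archetypes are drawn independently per family at 0.7
  identity to the panel, keeping cross-family domain identity near 0.5 and
  cross-family distances above every cutoff as long as no two families
  share a full domain-type inventory (the default design guarantees this).
- **Variants**: rearrangement moves the last domain-bearing gene first
  (AI < 1 versus siblings); truncation drops named domains; disintegration
  splits an archetype's segment list over two adjacent genes.
- **Fillers** (random or housekeeping-derived) are rejection-sampled so
  they never pass the template search and never get a BGC-related role.
  The rejection E-value uses a deliberately tiny search space (n = 1000):
  in E = K·m·n·e^(−λS) a smaller n makes a score *more* significant, so
  the small-n bound stays conservative for any realistic proteome. At
  least four fillers separate planted loci — one more than the 3-gene
  border run — so loci can never fuse and border recovery is exact by
  construction, not by luck.
- **Per-species decoys** exercise the exclusions: an A-T-R-R gene, a
  primary lanosterol synthase, and an unclustered type III PKS gene.
- Everything is deterministic under (design, seed); cohorts are emitted
  both as GenBank and GFF3+FASTA with truth tables alongside.

The default benchmark (8 species; families at identity 0.70–0.90 with one
rearranged, one truncated, one disintegrated variant; 10 private
singletons; ~60–80 genes per species) is sized for a single CPU: the full
pipeline completes in a few minutes. Mutation is substitution-only, genes
are intron-free with fixed codons, and filler backgrounds are short —
passing these tests shows the *rules* are implemented faithfully and
recoverable under realistic divergence, not that real-genome complications
(gene-model errors, repeats, composition bias, distal tailoring genes,
HMM-quality domain calls) are handled. Real-cohort headline counts are
correspondingly out of scope.

The bundled template library, domain panel and function database are
deterministic synthetic stand-ins (`*.synthetic.fasta`, regenerated by
`scripts/build_refdata.py`): real reference sequences are not
redistributable here. The template manifest keeps the real accessions and
metadata, and the stand-ins preserve the structural relationships the
search logic relies on (the type I PKS template is a full domain-string
composite; the bifunctional copalyl synthase carries two cyclase domains;
the squalene-hopene panel entry is related to the lanosterol synthase
template; terpene templates share a cyclase domain at varying identity).

## Known limitations

- Domain recognition is alignment-based against single references, not
  profile HMMs; remote homologs that an HMM would catch can be missed.
- The lenient core threshold can seed loci from marginal hits in small
  proteomes; the confidence gate protects classification but not the
  core-gene list itself.
- DSI uses one greedy pairing; an optimal-assignment flag would change
  results only for loci with many same-type copies at similar identities.
- Border calls depend on the function database's coverage; an unlabelled
  genuine tailoring family reads as "unrelated" and can shorten loci.
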