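"""Biosynthetic core-gene detection and domain-string annotation.

Core genes are found by local-alignment search of a bundled template library
of characterised core enzymes against each proteome (max E-value 0.1 by
default).  Biosynthetic domains are then assigned from a per-domain reference
panel by greedy non-overlapping selection of local hits scoring at least
``min_score_frac`` of the reference self-score; a pre-computed
:class:`~bgcmine.genome_io.DomainAnnotationTable` takes precedence when it
covers a gene.

A gene counts as a PKS when its domain string contains KS and (AT or ACP);
an NRPS module is a consecutive (C, A, T) triple.  These minimal definitions
drive classification downstream and are deliberately permissive: template
search (not domain completeness) decides what is a core.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .alignment import DEFAULT_SCHEME, ScoringScheme, align_score, evalue, local_align
from .genome_io import DomainAnnotationTable, Gene, Genome

__all__ = [
    "DOMAIN_VOCAB",
    "TemplateEnzyme",
    "CoreHit",
    "DomainHit",
    "scan_cores",
    "assign_domains",
    "domain_inventory",
    "BGCInventory",
    "is_pks",
    "nrps_module_count",
]

#: controlled vocabulary of biosynthetic domain labels
DOMAIN_VOCAB = (
    "SAT KS AT PT ACP CMeT DH ER KR TE R C A T E "
    "GGPPS TC CS FAS_alpha FAS_beta PTase LSS SHC DMAT GT CDPS"
).split()

TARGET_CLASSES = {
    "typeI_PKS",
    "typeIII_PKS",
    "NRPS_family",
    "terpene",
    "alkyl_citrate",
    "alkaloid_DMAT",
    "RiPP_precursor",
}


@dataclass(frozen=True)
class TemplateEnzyme:
    """One entry of the bundled core-enzyme template library."""

    accession: str
    name: str
    organism: str
    target_class: str
    protein: str

    def __post_init__(self):
        if self.target_class not in TARGET_CLASSES:
            raise ValueError(f"unknown target class {self.target_class}")


@dataclass(frozen=True)
class CoreHit:
    gene_id: str
    template_accession: str
    evalue: float
    score: float
    target_class: str


@dataclass(frozen=True)
class DomainHit:
    gene_id: str
    domain: str
    start_aa: int  # 1-based inclusive
    end_aa: int
    score: float

    def __post_init__(self):
        if self.domain not in DOMAIN_VOCAB:
            raise ValueError(f"unknown domain {self.domain}")
        if not (1 <= self.start_aa <= self.end_aa):
            raise ValueError("bad domain coordinates")


def is_pks(domains: Sequence[str]) -> bool:
    """Minimal PKS definition: KS plus (AT or ACP)."""
    s = set(domains)
    return "KS" in s and ("AT" in s or "ACP" in s)


def nrps_module_count(domains: Sequence[str]) -> int:
    """Number of complete, consecutive C-A-T modules in a domain string."""
    n = 0
    for i in range(len(domains) - 2):
        if tuple(domains[i : i + 3]) == ("C", "A", "T"):
            n += 1
    return n


def scan_cores(
    genome: Genome,
    templates: Sequence[TemplateEnzyme],
    max_evalue: float = 1e-1,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> List[CoreHit]:
    """Find core genes: best template hit per gene at E <= max_evalue.

    Deterministic and invariant to template order (ties broken by lower
    E-value then lexicographic accession); output sorted by contig, start.
    """
    if not templates:
        raise ValueError("template library is empty")
    proteome_len = sum(len(g.protein) for g in genome.genes)
    hits: List[Tuple[str, int, CoreHit]] = []
    for contig_id in sorted(genome.contigs):
        for gene in genome.contigs[contig_id]:
            best: Optional[CoreHit] = None
            for t in sorted(templates, key=lambda t: t.accession):
                sc = align_score(t.protein, gene.protein, scheme)
                ev = evalue(sc, len(t.protein), proteome_len, scheme)
                if ev > max_evalue:
                    continue
                if (
                    best is None
                    or sc > best.score
                    or (sc == best.score and ev < best.evalue)
                ):
                    best = CoreHit(
                        gene_id=gene.gene_id,
                        template_accession=t.accession,
                        evalue=ev,
                        score=sc,
                        target_class=t.target_class,
                    )
            if best is not None:
                hits.append((contig_id, gene.start, best))
    hits.sort(key=lambda h: (h[0], h[1]))
    return [h[2] for h in hits]


def _best_local_hit(masked: str, ref: str, scheme: ScoringScheme):
    """Best local hit of ref against (possibly masked) protein; returns
    (score, start, end) with 1-based inclusive protein coordinates."""
    aligner = scheme.aligner()
    score = float(aligner.score(masked, ref))
    if score <= 0:
        return 0.0, 0, 0
    aln = next(iter(aligner.align(masked, ref)))
    tblocks = aln.aligned[0]
    return score, int(tblocks[0][0]) + 1, int(tblocks[-1][1])


def assign_domains(
    gene: Gene,
    refs: Dict[str, str],
    min_score_frac: float = 0.3,
    table: Optional[DomainAnnotationTable] = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> List[DomainHit]:
    """Annotate one gene with an ordered (N->C) list of domain hits.

    Greedy with re-fit: repeatedly take the highest-scoring panel hit on the
    gene with already-accepted intervals masked out, until nothing reaches
    ``min_score_frac`` x reference self-score.  Masking guarantees accepted
    hits never overlap and lets repeated domains (e.g. NRPS modules) surface.
    """
    if table is not None and table.covers(gene.gene_id):
        rows = table.for_gene(gene.gene_id)
        hits = [
            DomainHit(
                gene_id=gene.gene_id,
                domain=r.domain,
                start_aa=int(r.start),
                end_aa=int(r.end),
                score=float(r.score),
            )
            for r in rows.itertuples()
        ]
        return sorted(hits, key=lambda h: h.start_aa)

    missing = set(DOMAIN_VOCAB) - set(refs)
    if missing:
        raise ValueError(f"domain panel missing references for {sorted(missing)}")

    self_scores = {
        d: sum(scheme.score_pair(c, c) for c in seq) for d, seq in refs.items()
    }
    prot = gene.protein
    # one screening pass: domains that fail on the unmasked protein can never
    # pass later (masking only lowers scores)
    live = []
    for d in DOMAIN_VOCAB:
        sc, s, e = _best_local_hit(prot, refs[d], scheme)
        if sc >= min_score_frac * self_scores[d]:
            live.append((d, sc, s, e))

    accepted: List[DomainHit] = []

    def masked_protein() -> str:
        chars = list(prot)
        for h in accepted:
            for i in range(h.start_aa - 1, h.end_aa):
                chars[i] = "X"
        return "".join(chars)

    candidates = {d: (sc, s, e) for d, sc, s, e in live}
    while candidates:
        d = max(candidates, key=lambda k: (candidates[k][0], k))
        sc, s, e = candidates.pop(d)
        accepted.append(
            DomainHit(gene_id=gene.gene_id, domain=d, start_aa=s, end_aa=e, score=sc)
        )
        # re-fit every remaining (and the just-used) domain to the remaining
        # unmasked intervals
        m = masked_protein()
        for dd in list(candidates) + [d]:
            sc2, s2, e2 = _best_local_hit(m, refs[dd], scheme)
            if sc2 >= min_score_frac * self_scores[dd]:
                candidates[dd] = (sc2, s2, e2)
            else:
                candidates.pop(dd, None)
    return sorted(accepted, key=lambda h: h.start_aa)


@dataclass
class BGCInventory:
    """Domain content of one locus: type multiset, per-copy subsequences and
    the coordinate-ordered linear domain sequence."""

    bgc_id: str
    types: Counter = field(default_factory=Counter)
    copies: List[Tuple[str, str]] = field(default_factory=list)  # (domain, seq)
    linear: List[str] = field(default_factory=list)

    @property
    def adjacency_pairs(self) -> set:
        return {
            (self.linear[i], self.linear[i + 1]) for i in range(len(self.linear) - 1)
        }


def domain_inventory(locus, hits_by_gene: Dict[str, List[DomainHit]]) -> BGCInventory:
    """Build the locus domain inventory.

    Genes are taken left-to-right by coordinate; each gene contributes its
    domains N->C, with minus-strand genes reversed gene-wise so the linear
    sequence follows the contig.
    """
    inv = BGCInventory(bgc_id=locus.bgc_id)
    for gene in sorted(locus.genes, key=lambda g: (g.start, g.end, g.gene_id)):
        hits = sorted(hits_by_gene.get(gene.gene_id, []), key=lambda h: h.start_aa)
        if gene.strand == "-":
            hits = hits[::-1]
        for h in hits:
            inv.types[h.domain] += 1
            inv.copies.append((h.domain, gene.protein[h.start_aa - 1 : h.end_aa]))
            inv.linear.append(h.domain)
    return inv
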