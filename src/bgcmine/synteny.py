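"""Pairwise/multi-locus gene-level comparison and co-localized homolog search.

``compare_bgcs`` reports, for each gene of a locus, the single best protein
match in the partner locus ("best link"), ranked by percent similarity
(positive-scoring columns) with score then gene order as tie-breaks.
``homology_groups`` single-links best links across many loci into gene
homology groups.  ``find_colocalized`` scans whole genomes for windows of
genes matching several query proteins with a bounded number of intervening
non-matching genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .alignment import DEFAULT_SCHEME, ScoringScheme, align_score, evalue, local_align
from .bgc_assembly import BGCLocus
from .genome_io import Genome

__all__ = [
    "SyntenyLink",
    "ColocalizedHit",
    "compare_bgcs",
    "homology_groups",
    "find_colocalized",
]


@dataclass(frozen=True)
class SyntenyLink:
    gene1: str
    gene2: str
    identity_pct: float
    similarity_pct: float
    score: float


@dataclass
class ColocalizedHit:
    species_id: str
    contig_id: str
    gene_ids: List[str]
    matched_queries: Dict[str, str]  # query id -> gene id of best match
    identities: Dict[str, float]  # query id -> identity %


def compare_bgcs(
    b1: BGCLocus,
    b2: BGCLocus,
    min_identity: float = 30.0,
    min_coverage: float = 50.0,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> List[SyntenyLink]:
    """All-vs-all protein comparison; one best link per gene of ``b1``.

    A candidate link must reach ``min_identity`` percent identity over the
    aligned columns AND cover at least ``min_coverage`` percent of both
    proteins — short local alignments between unrelated proteins routinely
    exceed 30% identity, so identity alone cannot separate homologs.
    Reciprocal consistency is not required: a gene of ``b2`` may be the best
    link of several ``b1`` genes.
    """
    if not b1.genes or not b2.genes:
        raise ValueError("both loci must contain genes")
    links = []
    order2 = {g.gene_id: i for i, g in enumerate(b2.genes)}
    for g1 in b1.genes:
        best = None
        best_key = None
        for g2 in b2.genes:
            res = local_align(g1.protein, g2.protein, scheme)
            if res.identity_pct < min_identity:
                continue
            if min(res.query_cov, res.subject_cov) < min_coverage:
                continue
            key = (-res.similarity_pct, -res.score, order2[g2.gene_id])
            if best_key is None or key < best_key:
                best_key = key
                best = SyntenyLink(
                    gene1=g1.gene_id,
                    gene2=g2.gene_id,
                    identity_pct=res.identity_pct,
                    similarity_pct=res.similarity_pct,
                    score=res.score,
                )
        if best is not None:
            links.append(best)
    return links


def homology_groups(
    loci: Sequence[BGCLocus],
    min_identity: float = 30.0,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> Dict[str, int]:
    """Single-linkage gene homology groups over pairwise best links.

    Returns gene_id -> group index; ids are assigned by first occurrence in
    locus order sorted by bgc_id, so the grouping is invariant to input
    order.
    """
    ordered = sorted(loci, key=lambda l: l.bgc_id)
    gene_ids = [g.gene_id for l in ordered for g in l.genes]
    parent = {gid: gid for gid in gene_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            # deterministic representative: lexicographically smaller root
            if rb < ra:
                ra, rb = rb, ra
            parent[rb] = ra

    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            for link in compare_bgcs(ordered[i], ordered[j], min_identity, scheme=scheme):
                union(link.gene1, link.gene2)
            for link in compare_bgcs(ordered[j], ordered[i], min_identity, scheme=scheme):
                union(link.gene1, link.gene2)

    groups: Dict[str, int] = {}
    next_id = 0
    roots_seen: Dict[str, int] = {}
    for gid in gene_ids:
        r = find(gid)
        if r not in roots_seen:
            roots_seen[r] = next_id
            next_id += 1
        groups[gid] = roots_seen[r]
    return groups


def find_colocalized(
    queries: Sequence[Tuple[str, str]],
    genomes: Sequence[Genome],
    min_queries: int = 2,
    max_gap_genes: int = 5,
    max_evalue: float = 1e-5,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> List[ColocalizedHit]:
    """Windows of genes hitting >= min_queries distinct query proteins with at
    most ``max_gap_genes`` intervening non-hit genes; maximal windows only.
    """
    if len(queries) < 2:
        raise ValueError("need at least two query proteins")
    if min_queries > len(queries):
        raise ValueError("min_queries exceeds the number of queries")

    hits: List[ColocalizedHit] = []
    for genome in genomes:
        proteome_len = sum(len(g.protein) for g in genome.genes)
        for contig_id in sorted(genome.contigs):
            genes = genome.contigs[contig_id]
            # per gene: best-matching query (if any)
            gene_query: List[Optional[Tuple[str, float, float]]] = []
            for g in genes:
                best = None
                for qid, qseq in sorted(queries, key=lambda t: t[0]):
                    sc = align_score(qseq, g.protein, scheme)
                    ev = evalue(sc, len(qseq), proteome_len, scheme)
                    if ev > max_evalue:
                        continue
                    if best is None or sc > best[1]:
                        ident = local_align(qseq, g.protein, scheme).identity_pct
                        best = (qid, sc, ident)
                gene_query.append(best)

            # maximal windows: split hit genes wherever the gap exceeds the bound
            idxs = [i for i, b in enumerate(gene_query) if b is not None]
            window: List[int] = []
            for i in idxs:
                if window and (i - window[-1] - 1) > max_gap_genes:
                    _emit(window, genes, gene_query, genome, contig_id, min_queries, hits)
                    window = []
                window.append(i)
            if window:
                _emit(window, genes, gene_query, genome, contig_id, min_queries, hits)
    return hits


def _emit(window, genes, gene_query, genome, contig_id, min_queries, out) -> None:
    matched: Dict[str, str] = {}
    ident: Dict[str, float] = {}
    for i in window:
        qid, sc, idp = gene_query[i]
        if qid not in matched or idp > ident[qid]:
            matched[qid] = genes[i].gene_id
            ident[qid] = idp
    if len(matched) >= min_queries:
        out.append(
            ColocalizedHit(
                species_id=genome.species_id,
                contig_id=contig_id,
                gene_ids=[genes[i].gene_id for i in window],
                matched_queries=matched,
                identities=ident,
            )
        )
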