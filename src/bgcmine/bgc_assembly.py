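"""Locus assembly around core genes.

Starting from each core gene, the locus is grown outward gene by gene in
each direction independently.  A walk stops as soon as three consecutive
genes get the role "unrelated" (no function-database hit at the neighbour
E-value threshold, or a best hit labelled housekeeping); the locus is then
trimmed back to the outermost related gene.  "Consecutive" counts genes
only — strand and intergenic distance play no part.  Overlapping loci from
nearby cores are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .alignment import DEFAULT_SCHEME, ScoringScheme, align_score, evalue
from .core_detection import CoreHit, DomainHit, is_pks
from .genome_io import Gene, Genome

__all__ = [
    "FUNCTION_LABELS",
    "FunctionDB",
    "BGCLocus",
    "call_gene_role",
    "extend_locus",
    "merge_overlapping",
    "assemble_loci",
]

FUNCTION_LABELS = (
    "core",
    "tailoring",
    "regulatory",
    "transport",
    "resistance",
    "housekeeping",
)

#: labels that make a gene BGC-related for the border rule
RELATED_LABELS = frozenset(FUNCTION_LABELS) - {"housekeeping"}

#: default neighbour-call threshold — stricter than the core search, since a
#: single spurious call extends borders
NEIGHBOUR_MAX_EVALUE = 1e-5


@dataclass
class FunctionDB:
    """Labelled reference proteins standing in for a curated function database."""

    entries: List[Tuple[str, str, str]]  # (entry_id, label, protein)

    def __post_init__(self):
        for eid, label, _ in self.entries:
            if label not in FUNCTION_LABELS:
                raise ValueError(f"{eid}: unknown function label {label}")
        self._total = sum(len(p) for _, _, p in self.entries)

    @property
    def total_residues(self) -> int:
        return self._total

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class BGCLocus:
    """A contiguous run of genes around >= 1 core gene."""

    bgc_id: str
    species_id: str
    contig_id: str
    genes: List[Gene]
    core_gene_ids: Set[str]
    gene_roles: Dict[str, str]
    bgc_class: Optional[str] = None
    domain_hits: Dict[str, List[DomainHit]] = field(default_factory=dict)
    core_hits: Dict[str, CoreHit] = field(default_factory=dict)
    is_reference: bool = False
    collaborative_candidate: bool = False

    def __post_init__(self):
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.gene_id))
        missing = self.core_gene_ids - {g.gene_id for g in self.genes}
        if missing:
            raise ValueError(f"{self.bgc_id}: core genes {sorted(missing)} not in locus")

    @property
    def gene_ids(self) -> List[str]:
        return [g.gene_id for g in self.genes]

    @property
    def start(self) -> int:
        return min(g.start for g in self.genes)

    @property
    def end(self) -> int:
        return max(g.end for g in self.genes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def pks_gene_ids(self) -> List[str]:
        return [
            gid
            for gid, hits in self.domain_hits.items()
            if is_pks([h.domain for h in hits])
        ]


def call_gene_role(
    gene: Gene,
    db: FunctionDB,
    max_evalue: float = NEIGHBOUR_MAX_EVALUE,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> str:
    """Function label of the best database hit at E <= max_evalue.

    "unrelated" when nothing passes or when the best hit is housekeeping
    (the best hit decides even if a related entry scores second).
    """
    if not db.entries:
        raise ValueError("function database is empty")
    best_label, best_key = None, None
    for eid, label, prot in sorted(db.entries, key=lambda t: t[0]):
        sc = align_score(gene.protein, prot, scheme)
        ev = evalue(sc, len(gene.protein), db.total_residues, scheme)
        if ev > max_evalue:
            continue
        key = (-sc, ev, eid)
        if best_key is None or key < best_key:
            best_key, best_label = key, label
    if best_label is None or best_label == "housekeeping":
        return "unrelated"
    return best_label


def _walk(roles: Sequence[str], start: int, step: int, run_len: int = 3) -> int:
    """Index of the outermost related gene reached from ``start`` walking in
    direction ``step`` before hitting ``run_len`` consecutive unrelated genes."""
    outermost = start
    consecutive = 0
    i = start + step
    while 0 <= i < len(roles):
        if roles[i] in RELATED_LABELS:
            outermost = i
            consecutive = 0
        else:
            consecutive += 1
            if consecutive >= run_len:
                break
        i += step
    return outermost


def extend_locus(
    genome: Genome,
    core: CoreHit,
    db: Optional[FunctionDB] = None,
    max_evalue: float = NEIGHBOUR_MAX_EVALUE,
    roles: Optional[Dict[str, str]] = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    bgc_id: Optional[str] = None,
) -> BGCLocus:
    """Grow a locus around one core gene with the three-consecutive-unrelated
    border rule.

    ``roles`` may supply precomputed gene roles (gene_id -> label); otherwise
    they are called against ``db``.  A contig end terminates a walk early and
    the locus is trimmed back to the outermost related gene on each side.
    """
    contig_id = None
    idx = None
    for cid, genes in genome.contigs.items():
        for i, g in enumerate(genes):
            if g.gene_id == core.gene_id:
                contig_id, idx = cid, i
                break
        if idx is not None:
            break
    if idx is None:
        raise ValueError(f"core gene {core.gene_id} not found in genome")
    genes = genome.contigs[contig_id]

    def role_of(g: Gene) -> str:
        if g.gene_id == core.gene_id:
            return "core"
        if roles is not None:
            return roles.get(g.gene_id, "unrelated")
        if db is None:
            raise ValueError("need a FunctionDB or precomputed roles")
        return call_gene_role(g, db, max_evalue, scheme)

    # roles are only needed until each walk stops; evaluate lazily
    role_cache: Dict[int, str] = {}

    class _LazyRoles:
        def __len__(self):
            return len(genes)

        def __getitem__(self, i):
            if i not in role_cache:
                role_cache[i] = role_of(genes[i])
            return role_cache[i]

    lazy = _LazyRoles()
    left = _walk(lazy, idx, -1)
    right = _walk(lazy, idx, +1)
    members = genes[left : right + 1]
    gene_roles = {
        g.gene_id: (role_cache.get(left + i) or role_of(g))
        for i, g in enumerate(members)
    }
    gene_roles[core.gene_id] = "core"
    return BGCLocus(
        bgc_id=bgc_id or f"{genome.species_id}|{core.gene_id}",
        species_id=genome.species_id,
        contig_id=contig_id,
        genes=list(members),
        core_gene_ids={core.gene_id},
        gene_roles=gene_roles,
        core_hits={core.gene_id: core},
    )


def merge_overlapping(loci: Sequence[BGCLocus]) -> List[BGCLocus]:
    """Merge loci sharing >= 1 gene (union of genes, cores and roles).

    Idempotent and invariant to input order.  Merged loci containing two or
    more PKS core genes are flagged collaborative candidates — the original
    observation that intertwined loci may really be two pathways is surfaced
    as a flag, not resolved.
    """
    ordered = sorted(loci, key=lambda l: (l.contig_id, l.start, l.bgc_id))
    parent = list(range(len(ordered)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    gene_sets = [set(l.gene_ids) for l in ordered]
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            if ordered[i].contig_id == ordered[j].contig_id and (
                gene_sets[i] & gene_sets[j]
            ):
                parent[find(j)] = find(i)
    by_root: Dict[int, List[BGCLocus]] = {}
    for i, locus in enumerate(ordered):
        by_root.setdefault(find(i), []).append(locus)
    groups: List[List[BGCLocus]] = [by_root[r] for r in sorted(by_root)]

    merged: List[BGCLocus] = []
    for grp in groups:
        if len(grp) == 1:
            locus = grp[0]
        else:
            genes = {g.gene_id: g for l in grp for g in l.genes}
            roles: Dict[str, str] = {}
            cores: Set[str] = set()
            core_hits: Dict[str, CoreHit] = {}
            dhits: Dict[str, List[DomainHit]] = {}
            for l in grp:
                cores |= l.core_gene_ids
                core_hits.update(l.core_hits)
                dhits.update(l.domain_hits)
                for gid, r in l.gene_roles.items():
                    if roles.get(gid) != "core":
                        roles[gid] = r
            first = min(grp, key=lambda l: (l.start, l.bgc_id))
            locus = BGCLocus(
                bgc_id=first.bgc_id,
                species_id=first.species_id,
                contig_id=first.contig_id,
                genes=list(genes.values()),
                core_gene_ids=cores,
                gene_roles=roles,
                domain_hits=dhits,
                core_hits=core_hits,
                is_reference=any(l.is_reference for l in grp),
            )
        merged.append(locus)

    for locus in merged:
        n_pks_cores = sum(
            1
            for gid in locus.core_gene_ids
            if is_pks([h.domain for h in locus.domain_hits.get(gid, [])])
        )
        locus.collaborative_candidate = n_pks_cores >= 2
    merged.sort(key=lambda l: (l.species_id, l.contig_id, l.start, l.bgc_id))
    return merged


def assemble_loci(
    genome: Genome,
    cores: Sequence[CoreHit],
    db: Optional[FunctionDB] = None,
    max_evalue: float = NEIGHBOUR_MAX_EVALUE,
    roles: Optional[Dict[str, str]] = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> List[BGCLocus]:
    """Extend a locus from every core hit, then merge overlaps and assign
    stable per-genome bgc ids in genome order."""
    loci = [
        extend_locus(genome, core, db, max_evalue, roles, scheme) for core in cores
    ]
    merged = merge_overlapping(loci)
    for i, locus in enumerate(merged, start=1):
        locus.bgc_id = f"{genome.species_id}_bgc{i:03d}"
    return merged
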