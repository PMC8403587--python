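"""Gene-cluster-family networking from domain inventories.

Pairwise BGC similarity combines three indices on the domain content —
Jaccard index (JI) on domain-type sets, domain sequence identity (DSI) over
greedily paired domain copies, and adjacency index (AI) on consecutive
domain-type pairs — into a weighted distance

    d = 1 - (0.2*JI + 0.75*DSI + 0.05*AI)

clamped to [0, 1].  Anchor domain types (citrate synthase, terpene cyclase,
UbiA-type prenyltransferase, tryptophan DMAT) carry extra multiplicative
weight inside DSI.  Edges connect pairs with d strictly below the cutoff;
connected components of that network are the gene cluster families (GCFs),
singletons included.  All classes are mixed in one network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .alignment import DEFAULT_SCHEME, ScoringScheme, local_align
from .core_detection import BGCInventory

__all__ = [
    "DEFAULT_ANCHORS",
    "DEFAULT_WEIGHTS",
    "DEFAULT_CUTOFFS",
    "PairDistance",
    "GCF",
    "jaccard_index",
    "dsi",
    "adjacency_index",
    "pair_distance",
    "build_network",
    "prune_reference_only",
    "conserved_gcfs",
]

#: the four anchor Pfam families mapped onto the domain vocabulary:
#: Citrate_synt -> CS, Terpene_syn_C_2 -> TC, UbiA -> PTase, Trp_DMAT -> DMAT
DEFAULT_ANCHORS: FrozenSet[str] = frozenset({"CS", "TC", "PTase", "DMAT"})

DEFAULT_WEIGHTS: Tuple[float, float, float] = (0.2, 0.75, 0.05)
DEFAULT_CUTOFFS: Tuple[float, ...] = (0.3, 0.4, 0.5, 0.6)
DEFAULT_ANCHOR_WEIGHT = 2.0


@dataclass(frozen=True)
class PairDistance:
    bgc1: str
    bgc2: str
    ji: float
    dsi: float
    ai: float
    distance: float


@dataclass
class GCF:
    gcf_id: str
    members: List[str]
    cutoff: float
    species: Set[str] = field(default_factory=set)

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


def jaccard_index(a: BGCInventory, b: BGCInventory) -> float:
    """Jaccard of the domain-type sets; 0 when both are empty."""
    ta, tb = set(a.types), set(b.types)
    union = ta | tb
    if not union:
        return 0.0
    return len(ta & tb) / len(union)


def _pair_identity(s1: str, s2: str, scheme: ScoringScheme) -> float:
    # canonical argument order: the optimal traceback is not unique, so align
    # (min, max) to make the identity — and hence DSI — exactly symmetric
    a, b = sorted((s1, s2))
    return local_align(a, b, scheme).identity_pct / 100.0


def dsi(
    a: BGCInventory,
    b: BGCInventory,
    anchors: FrozenSet[str] = DEFAULT_ANCHORS,
    anchor_weight: float = DEFAULT_ANCHOR_WEIGHT,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> float:
    """Domain sequence identity over all weighted copies of both loci.

    For each shared domain type, copies are paired greedily by descending
    pairwise identity; each paired copy contributes its pair identity and
    unpaired copies contribute 0.  The normalisation runs jointly over every
    copy in both BGCs, so identical loci score exactly 1.
    """
    for dom, seq in list(a.copies) + list(b.copies):
        if not seq:
            raise ValueError(f"domain copy {dom} lacks its subsequence")
    if not a.copies and not b.copies:
        return 0.0

    def w(domain: str) -> float:
        return anchor_weight if domain in anchors else 1.0

    num = 0.0
    den = sum(w(d) for d, _ in a.copies) + sum(w(d) for d, _ in b.copies)
    shared = set(a.types) & set(b.types)
    for dom in sorted(shared):
        ca = [s for d, s in a.copies if d == dom]
        cb = [s for d, s in b.copies if d == dom]
        pairs = sorted(
            (
                (-_pair_identity(sa, sb, scheme), i, j)
                for i, sa in enumerate(ca)
                for j, sb in enumerate(cb)
            ),
        )
        used_a: Set[int] = set()
        used_b: Set[int] = set()
        for negident, i, j in pairs:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            num += 2.0 * w(dom) * (-negident)  # a pair accounts for two copies
    return num / den if den else 0.0


def adjacency_index(a: BGCInventory, b: BGCInventory) -> float:
    """Jaccard of the sets of adjacent ordered domain-type pairs.

    Loci with fewer than two domains have no pairs and score 0 by convention
    (this keeps degenerate loci from gluing families together, at the price
    of a 0.05 self-distance for single-domain loci)."""
    pa, pb = a.adjacency_pairs, b.adjacency_pairs
    union = pa | pb
    if not union:
        return 0.0
    return len(pa & pb) / len(union)


def pair_distance(
    a: BGCInventory,
    b: BGCInventory,
    weights: Tuple[float, float, float] = DEFAULT_WEIGHTS,
    anchors: FrozenSet[str] = DEFAULT_ANCHORS,
    anchor_weight: float = DEFAULT_ANCHOR_WEIGHT,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> PairDistance:
    wj, wd, wa = weights
    ji = jaccard_index(a, b)
    d = dsi(a, b, anchors, anchor_weight, scheme) if set(a.types) & set(b.types) else 0.0
    ai = adjacency_index(a, b)
    dist = 1.0 - (wj * ji + wd * d + wa * ai)
    dist = min(1.0, max(0.0, dist))
    return PairDistance(bgc1=a.bgc_id, bgc2=b.bgc_id, ji=ji, dsi=d, ai=ai, distance=dist)


def all_pair_distances(
    inventories: Sequence[BGCInventory],
    weights: Tuple[float, float, float] = DEFAULT_WEIGHTS,
    anchors: FrozenSet[str] = DEFAULT_ANCHORS,
    anchor_weight: float = DEFAULT_ANCHOR_WEIGHT,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> List[PairDistance]:
    out = []
    invs = sorted(inventories, key=lambda i: i.bgc_id)
    for i in range(len(invs)):
        for j in range(i + 1, len(invs)):
            out.append(
                pair_distance(invs[i], invs[j], weights, anchors, anchor_weight, scheme)
            )
    return out


def build_network(
    inventories: Sequence[BGCInventory],
    cutoff: float,
    distances: Optional[Sequence[PairDistance]] = None,
    species_of: Optional[Dict[str, str]] = None,
    **kwargs,
) -> Tuple[List[PairDistance], List[GCF]]:
    """Edges (d < cutoff, strict) and GCFs as connected components.

    Every BGC belongs to exactly one GCF; isolated BGCs form singleton GCFs.
    GCF ids are stable: components ordered by size (desc) then smallest
    member id.
    """
    if not inventories:
        raise ValueError("need at least one BGC")
    if distances is None:
        distances = all_pair_distances(inventories, **kwargs)
    g = nx.Graph()
    for inv in inventories:
        g.add_node(inv.bgc_id)
    edges = [d for d in distances if d.distance < cutoff]
    for d in edges:
        g.add_edge(d.bgc1, d.bgc2)
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    gcfs = []
    for i, members in enumerate(comps, start=1):
        sp = set()
        if species_of:
            sp = {species_of[m] for m in members if m in species_of}
        gcfs.append(GCF(gcf_id=f"GCF{i:04d}", members=members, cutoff=cutoff, species=sp))
    return edges, gcfs


def prune_reference_only(
    gcfs: Sequence[GCF], reference_flags: Dict[str, bool]
) -> List[GCF]:
    """Drop GCFs whose members are all reference BGCs; mixed GCFs stay whole."""
    return [
        g
        for g in gcfs
        if not all(reference_flags.get(m, False) for m in g.members)
    ]


def conserved_gcfs(gcfs: Sequence[GCF], species_universe: Set[str]) -> int:
    """Number of GCFs whose species set covers the whole cohort."""
    if not species_universe:
        return 0
    return sum(1 for g in gcfs if species_universe <= g.species)


def export_graphml(
    inventories: Sequence[BGCInventory],
    edges: Sequence[PairDistance],
    path: str,
    node_attrs: Optional[Dict[str, Dict[str, object]]] = None,
) -> None:
    """Cytoscape-compatible GraphML export of one cutoff network."""
    g = nx.Graph()
    for inv in sorted(inventories, key=lambda i: i.bgc_id):
        g.add_node(inv.bgc_id, n_domains=len(inv.linear), **(node_attrs or {}).get(inv.bgc_id, {}))
    for e in edges:
        g.add_edge(e.bgc1, e.bgc2, ji=e.ji, dsi=e.dsi, ai=e.ai, distance=e.distance)
    nx.write_graphml(g, path)
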