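"""Synthetic multi-species cohorts with planted, ground-truth clusters.

The generator emulates a small comparative-genomics cohort: each species is
one contig of protein-coding genes in which biosynthetic loci are planted
between runs of filler genes.  Planted core genes are concatenations of
domain-panel reference segments (so the domain annotator recovers the
planned domain string), neighbouring pathway genes derive from labelled
function-database entries, and fillers are rejection-sampled to stay below
every search threshold.  Each gene family ("family" = one pathway shared by
several species) is built as a star: the first member species carries the
family archetype and every other member is mutated from it at the family's
identity target, so within-family network connectivity runs through the
archetype and recovery at the default cutoff is analytic, not accidental.

Mutation is indel-free by design: exact-position identity is then exact and
domain-identity expectations are analytic.  Everything is deterministic
under (design, seed).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from .alignment import DEFAULT_SCHEME, align_score, evalue
from .genome_io import Gene, Genome

__all__ = [
    "make_protein",
    "mutate_to_identity",
    "GenePlan",
    "FamilySpec",
    "CohortTruth",
    "TruthLocus",
    "plant_family",
    "make_cohort",
    "default_cohort_design",
    "write_cohort",
]

AAS = list("ACDEFGHIKLMNPQRSTVWY")

#: Robinson-Robinson style background amino-acid frequencies
_BG = np.array(
    [
        0.078, 0.019, 0.054, 0.063, 0.039, 0.074, 0.022, 0.051, 0.057, 0.091,
        0.022, 0.045, 0.052, 0.043, 0.051, 0.071, 0.058, 0.065, 0.013, 0.032,
    ]
)
_BG = _BG / _BG.sum()

#: identity of each family archetype to its domain-panel reference
FAMILY_DIVERGENCE = 0.7

_LINKER = "GGSGGSGGSG"

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT", "X": "NNN",
}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_protein(length: int, seed) -> str:
    """Reproducible i.i.d. protein over background amino-acid frequencies."""
    if length < 1:
        raise ValueError("protein length must be >= 1")
    rng = _rng(seed)
    return "".join(rng.choice(AAS, size=length, p=_BG))


@dataclass
class _SubTable:
    """Substitution-biased replacement distributions from the scoring matrix."""

    dists: Dict[str, Tuple[List[str], np.ndarray]]

    @classmethod
    def build(cls) -> "_SubTable":
        m = DEFAULT_SCHEME.matrix
        dists = {}
        for a in AAS:
            others = [b for b in AAS if b != a]
            w = np.array([math.exp(0.3 * float(m[a, b])) for b in others])
            dists[a] = (others, w / w.sum())
        return cls(dists=dists)


_SUBS: Optional[_SubTable] = None


def mutate_to_identity(p: str, target_identity: float, seed) -> str:
    """Point-substitute ``p`` so exact-position identity to the original is
    exactly ceil(target*len)/len; substitutions are biased toward positive
    scoring-matrix exchanges.  No indels.  Identity floor 0.2."""
    global _SUBS
    if not 0.2 <= target_identity <= 1.0:
        raise ValueError("target identity must be in [0.2, 1.0]")
    if _SUBS is None:
        _SUBS = _SubTable.build()
    rng = _rng(seed)
    L = len(p)
    n_keep = math.ceil(target_identity * L)
    n_mut = L - n_keep
    if n_mut == 0:
        return p
    positions = rng.choice(L, size=n_mut, replace=False)
    chars = list(p)
    for pos in sorted(positions):
        a = chars[pos]
        if a not in _SUBS.dists:  # X or unknown: uniform replacement
            chars[pos] = str(rng.choice([b for b in AAS]))
            continue
        others, w = _SUBS.dists[a]
        chars[pos] = str(rng.choice(others, p=w))
    return "".join(chars)


# ---------------------------------------------------------------------------
# family plans


@dataclass(frozen=True)
class GenePlan:
    """One gene of a family plan: a core-like gene built from domain-panel
    segments (``domains``) or an accessory gene derived from a function-
    database entry (``ref``)."""

    name: str
    role: str
    domains: Tuple[str, ...] = ()
    ref: Optional[str] = None

    def __post_init__(self):
        if bool(self.domains) == bool(self.ref):
            raise ValueError(f"gene {self.name}: need either domains or ref")


@dataclass
class FamilySpec:
    family_id: str
    bgc_class: str
    genes: List[GenePlan]
    species: List[str]
    identity: float = 0.8
    rearrange_in: Optional[str] = None
    truncate_in: Optional[Tuple[str, Tuple[str, ...]]] = None
    disintegrate_in: Optional[Tuple[str, str, int]] = None  # (species, gene, n_first)
    in_network: bool = True
    counted: bool = True

    def __post_init__(self):
        if not 0.5 <= self.identity <= 1.0:
            raise ValueError("within-family identity target must be in [0.5, 1.0]")
        if not any(g.domains for g in self.genes) and not any(
            g.role == "core" for g in self.genes
        ):
            raise ValueError(f"{self.family_id}: family plan has no core gene")


@dataclass
class PlantedGene:
    name: str
    role: str
    protein: str
    domains: Tuple[str, ...] = ()


@dataclass
class FamilyInstance:
    family_id: str
    species_id: str
    genes: List[PlantedGene]
    expected_class: str


def _archetype(
    spec: FamilySpec, rng: np.random.Generator, panel: Dict[str, str], fdb_seqs: Dict[str, str]
) -> Dict[str, List[Tuple[str, str]]]:
    """Family archetype: per gene, a list of (domain-or-'', segment)."""
    arch: Dict[str, List[Tuple[str, str]]] = {}
    for plan in spec.genes:
        if plan.domains:
            segs = [
                (d, mutate_to_identity(panel[d], FAMILY_DIVERGENCE, rng))
                for d in plan.domains
            ]
        else:
            segs = [("", mutate_to_identity(fdb_seqs[plan.ref], 0.8, rng))]
        arch[plan.name] = segs
    return arch


def _member_gene(
    plan: GenePlan,
    segs: List[Tuple[str, str]],
    identity: float,
    rng: np.random.Generator,
) -> PlantedGene:
    """One member's copy: each segment mutated at the exact identity target
    (per-segment, so every domain stays recognisable)."""
    parts = [
        seg if identity >= 1.0 else mutate_to_identity(seg, identity, rng)
        for _, seg in segs
    ]
    protein = _LINKER.join(parts) if plan.domains else parts[0]
    return PlantedGene(
        name=plan.name, role=plan.role, protein=protein, domains=plan.domains
    )


def plant_family(spec: FamilySpec, seed) -> Dict[str, FamilyInstance]:
    """Instantiate one family across its member species (plus variants)."""
    from .refdata import load_domain_panel, load_function_db

    rng = _rng(seed)
    panel = load_domain_panel()
    fdb_seqs = {eid: prot for eid, _, prot in load_function_db().entries}
    arch = _archetype(spec, rng, panel, fdb_seqs)

    out: Dict[str, FamilyInstance] = {}
    for k, sp in enumerate(spec.species):
        identity = 1.0 if k == 0 else spec.identity
        plans = list(spec.genes)
        expected = spec.bgc_class

        if spec.truncate_in and spec.truncate_in[0] == sp:
            drop = set(spec.truncate_in[1])
            genes = []
            for plan in plans:
                segs = arch[plan.name]
                if plan.domains and set(plan.domains) & drop:
                    kept = [(d, s) for d, s in segs if d not in drop]
                    plan = GenePlan(
                        name=plan.name,
                        role=plan.role,
                        domains=tuple(d for d, _ in kept),
                    )
                    segs = kept
                genes.append(_member_gene(plan, segs, identity, rng))
            expected = "truncated_PKS"
        elif spec.disintegrate_in and spec.disintegrate_in[0] == sp:
            _, target, n_first = spec.disintegrate_in
            genes = []
            for plan in plans:
                segs = arch[plan.name]
                if plan.name == target:
                    first, second = segs[:n_first], segs[n_first:]
                    for suffix, part in (("_a", first), ("_b", second)):
                        sub = GenePlan(
                            name=plan.name + suffix,
                            role=plan.role,
                            domains=tuple(d for d, _ in part),
                        )
                        genes.append(_member_gene(sub, part, identity, rng))
                else:
                    genes.append(_member_gene(plan, segs, identity, rng))
            expected = "disintegrated_PKS"
        else:
            genes = [
                _member_gene(plan, arch[plan.name], identity, rng) for plan in plans
            ]
            if spec.rearrange_in == sp:
                # move the last domain-bearing gene to the front so the
                # adjacency index drops below 1 versus unshuffled siblings
                dom_idx = [i for i, g in enumerate(genes) if g.domains]
                if dom_idx:
                    g = genes.pop(dom_idx[-1])
                    genes.insert(0, g)

        out[sp] = FamilyInstance(
            family_id=spec.family_id,
            species_id=sp,
            genes=genes,
            expected_class=expected,
        )
    return out


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class TruthLocus:
    species_id: str
    contig_id: str
    gene_ids: List[str]
    family_id: str
    bgc_class: str
    counted: bool = True
    in_network: bool = True

    @property
    def key(self) -> Tuple[str, frozenset]:
        return (self.species_id, frozenset(self.gene_ids))


@dataclass
class CohortTruth:
    species: List[str]
    gene_roles: Dict[str, str] = field(default_factory=dict)
    loci: List[TruthLocus] = field(default_factory=list)

    def class_matrix(self) -> pd.DataFrame:
        from .bgc_classification import BGC_CLASSES

        cols = [c for c in BGC_CLASSES if c != "excluded_primary_metabolism"]
        rows = {
            sp: {c: 0 for c in cols} for sp in sorted(self.species)
        }
        for t in self.loci:
            if t.counted:
                rows[t.species_id][t.bgc_class] += 1
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols).astype(int)

    def gcf_partition(self) -> Dict[Tuple[str, frozenset], str]:
        """Expected family label for every in-network locus (singleton loci
        keep their unique family id)."""
        return {t.key: t.family_id for t in self.loci if t.in_network}

    def conserved_families(self) -> int:
        fam_species: Dict[str, Set[str]] = {}
        for t in self.loci:
            if t.in_network:
                fam_species.setdefault(t.family_id, set()).add(t.species_id)
        return sum(1 for sps in fam_species.values() if set(self.species) <= sps)


def _filler_protein(
    rng: np.random.Generator,
    templates,
    fdb,
    core_max_evalue: float = 1e-1,
    neighbour_max_evalue: float = 1e-5,
) -> Tuple[str, str]:
    """A filler gene: random or housekeeping-derived, rejection-sampled so it
    never passes the core-template search and never gets a BGC-related role."""
    hk = [(eid, p) for eid, label, p in fdb.entries if label == "housekeeping"]
    # conservative (small) search-space lower bound: in E = K*m*n*exp(-lS) a
    # smaller n makes any score MORE significant, so rejecting against a tiny
    # n keeps fillers clean even in toy proteomes
    proteome_guess = 1_000
    for _ in range(40):
        if rng.random() < 0.5:
            prot = make_protein(int(rng.integers(230, 340)), rng)
            kind = "random"
        else:
            eid, ref = hk[int(rng.integers(len(hk)))]
            prot = mutate_to_identity(ref, 0.75, rng)
            kind = "housekeeping"
        ok = True
        for t in templates:
            sc = align_score(t.protein, prot)
            if evalue(sc, len(t.protein), proteome_guess) <= core_max_evalue:
                ok = False
                break
        if ok:
            best_label, best_sc = None, -1.0
            for eid, label, ref in fdb.entries:
                sc = align_score(prot, ref)
                if sc > best_sc and evalue(sc, len(prot), fdb.total_residues) <= neighbour_max_evalue:
                    best_sc, best_label = sc, label
            if best_label not in (None, "housekeeping"):
                ok = False
        if ok:
            return prot, kind
    raise RuntimeError("could not sample a clean filler gene")


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    # fixed codon per amino acid keeps this simple and deterministic;
    # nucleotide realism is a non-goal
    return "".join(_CODON[a] for a in protein) + "TAA"


def _revcomp(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


@dataclass
class _ContigBuilder:
    species_id: str
    contig_id: str
    rng: np.random.Generator
    seq_parts: List[str] = field(default_factory=list)
    genes: List[Gene] = field(default_factory=list)
    pos: int = 1
    counter: int = 0

    def _spacer(self) -> None:
        n = int(self.rng.integers(120, 260))
        self.seq_parts.append(
            "".join(self.rng.choice(list("ACGT"), size=n))
        )
        self.pos += n

    def add_gene(self, protein: str, product: str = "") -> str:
        self._spacer()
        self.counter += 1
        gene_id = f"{self.species_id}_g{self.counter:03d}"
        nt = _back_translate(protein, self.rng)
        strand = "+" if self.rng.random() < 0.85 else "-"
        self.seq_parts.append(nt if strand == "+" else _revcomp(nt))
        start = self.pos
        end = self.pos + len(nt) - 1
        self.pos = end + 1
        self.genes.append(
            Gene(
                gene_id=gene_id,
                contig_id=self.contig_id,
                start=start,
                end=end,
                strand=strand,
                protein=protein,
                product=product,
            )
        )
        return gene_id

    def finish(self) -> Tuple[str, List[Gene]]:
        self._spacer()
        return "".join(self.seq_parts), self.genes


def default_cohort_design(species: Sequence[str]) -> List[FamilySpec]:
    """The cohort family design: six multi-species families (one carrying a
    disintegrated variant, one a rearranged variant, one a truncated variant)
    plus ten species-private singleton loci covering the other classes."""
    sp = list(species)
    n = len(sp)

    def pick(i: int) -> str:
        return sp[i % n]

    fams = [
        FamilySpec(
            family_id="F1_hrpks",
            bgc_class="hrPKS",
            identity=0.85,
            species=sp,
            disintegrate_in=(pick(3), "pks1", 5),
            genes=[
                GenePlan("pks1", "core", domains=("KS", "AT", "DH", "CMeT", "ER", "KR", "ACP")),
                GenePlan("p450", "tailoring", ref="tail_p450"),
                GenePlan("omt", "tailoring", ref="tail_omt"),
                GenePlan("mfs", "transport", ref="trans_mfs"),
            ],
        ),
        FamilySpec(
            family_id="F2_meroterpenoid",
            bgc_class="meroterpenoid",
            identity=0.80,
            species=sp[: min(6, n)],
            rearrange_in=pick(2),
            genes=[
                GenePlan("npks", "core", domains=("SAT", "KS", "AT", "PT", "ACP", "TE")),
                GenePlan("ptase", "core", domains=("PTase",)),
                GenePlan("fmo", "tailoring", ref="tail_fmo"),
                GenePlan("reg", "regulatory", ref="reg_zn2c6"),
            ],
        ),
        FamilySpec(
            family_id="F3_nrps",
            bgc_class="NRPS",
            identity=0.75,
            species=sp[1 : min(7, n)] or sp[:1],
            genes=[
                GenePlan("nrps", "core", domains=("C", "A", "T", "C", "A", "T", "TE")),
                GenePlan("abc", "transport", ref="trans_abc"),
                GenePlan("p450b", "tailoring", ref="tail_p450"),
            ],
        ),
        FamilySpec(
            family_id="F4_alkylcitrate",
            bgc_class="alkyl_citrate",
            identity=0.90,
            species=sp,
            genes=[
                GenePlan("cs", "core", domains=("CS",)),
                GenePlan("fasA", "core", domains=("FAS_alpha",)),
                GenePlan("fasB", "core", domains=("FAS_beta",)),
                GenePlan("hydro", "tailoring", ref="tail_hydrolase"),
            ],
        ),
        FamilySpec(
            family_id="F5_diterpene",
            bgc_class="diterpene_GGPPS",
            identity=0.70,
            species=sp[2 : min(8, n)] or sp[:1],
            genes=[
                GenePlan("tc", "core", domains=("TC",)),
                GenePlan("ggpps", "core", domains=("GGPPS",)),
            ],
        ),
        FamilySpec(
            family_id="F6_prpks",
            bgc_class="prPKS",
            identity=0.80,
            species=sp[: min(5, n)],
            truncate_in=(pick(4), ("AT",)),
            genes=[
                GenePlan("prpks", "core", domains=("KS", "AT", "DH", "KR", "ACP", "TE")),
                GenePlan("ktr", "tailoring", ref="tail_ktr"),
                GenePlan("res", "resistance", ref="res_efflux"),
            ],
        ),
    ]

    singles = [
        ("S01_atte", "NRPS_like_ATTE",
         [GenePlan("atte", "core", domains=("A", "T", "TE")),
          GenePlan("oxr", "tailoring", ref="tail_oxred")]),
        ("S02_atr", "NRPS_like_ATR",
         [GenePlan("atr", "core", domains=("A", "T", "R")),
          GenePlan("fmo2", "tailoring", ref="tail_fmo")]),
        ("S03_dmat", "DMAT_alkaloid",
         [GenePlan("dmat", "core", domains=("DMAT",)),
          GenePlan("p450c", "tailoring", ref="tail_p450"),
          GenePlan("reg2", "regulatory", ref="reg_bzip")]),
        ("S04_terpene", "terpene_mono_sesqui",
         [GenePlan("stc", "core", domains=("TC",)),
          GenePlan("omt2", "tailoring", ref="tail_omt")]),
        ("S05_triterpene", "triterpene",
         [GenePlan("shc", "core", domains=("SHC",)),
          GenePlan("gt", "tailoring", ref="tail_hydrolase")]),
        ("S06_ripp", "RiPP",
         [GenePlan("prec", "core", ref="core_ripp_precursor"),
          GenePlan("halo", "tailoring", ref="tail_halo"),
          GenePlan("mate", "transport", ref="trans_mate")]),
        ("S07_labdane", "labdane_diterpene",
         [GenePlan("cps", "core", domains=("TC", "TC")),
          GenePlan("p450d", "tailoring", ref="tail_p450")]),
        ("S08_collab", "collaborative_PKS",
         [GenePlan("npks2", "core", domains=("SAT", "KS", "AT", "PT", "ACP", "TE")),
          GenePlan("hrpks2", "core", domains=("KS", "AT", "DH", "ER", "KR", "ACP")),
          GenePlan("acyl", "tailoring", ref="tail_acyl")]),
        ("S09_pksnrps", "PKS_NRPS",
         [GenePlan("hyb1", "core", domains=("KS", "AT", "DH", "KR", "ACP", "C", "A", "T", "R")),
          GenePlan("oxr2", "tailoring", ref="tail_oxred")]),
        ("S10_nrpspks", "NRPS_PKS",
         [GenePlan("hyb2", "core", domains=("C", "A", "T", "KS", "AT", "ACP", "TE")),
          GenePlan("omt3", "tailoring", ref="tail_omt")]),
    ]
    for i, (fid, cls, genes) in enumerate(singles):
        fams.append(
            FamilySpec(
                family_id=fid,
                bgc_class=cls,
                identity=0.8,
                species=[pick(i)],
                genes=genes,
            )
        )
    return fams


def make_cohort(
    n_species: int = 8,
    families: Optional[List[FamilySpec]] = None,
    filler_between: int = 4,
    seed: int = 0,
    extras: bool = True,
) -> Tuple[Dict[str, Genome], CohortTruth]:
    """Build the cohort: genomes plus the complete ground truth.

    ``filler_between`` (>= 4 recommended: one more than the 3-gene border
    run, so planted loci can never fuse) is the number of filler genes
    between consecutive planted loci and at contig ends.  ``extras`` plants
    the per-species primary-metabolism decoys (an A-T-R-R gene, a primary
    lanosterol synthase) and an unclustered type III PKS gene.
    """
    from .refdata import load_domain_panel, load_function_db, load_templates

    if filler_between < 4:
        raise ValueError("filler_between must be >= 4 to keep borders unambiguous")
    species = [f"sp{i:02d}" for i in range(n_species)]
    if families is None:
        families = default_cohort_design(species)

    templates = load_templates()
    fdb = load_function_db()
    t3_template = next(t for t in templates if t.target_class == "typeIII_PKS")
    panel = load_domain_panel()

    master = np.random.default_rng(seed)
    fam_seeds = {f.family_id: master.integers(2**31) for f in sorted(families, key=lambda f: f.family_id)}
    instances: Dict[str, List[FamilyInstance]] = {sp: [] for sp in species}
    for fam in sorted(families, key=lambda f: f.family_id):
        for sp, inst in plant_family(fam, int(fam_seeds[fam.family_id])).items():
            instances[sp].append(inst)

    genomes: Dict[str, Genome] = {}
    truth = CohortTruth(species=species)

    for sp in species:
        rng = np.random.default_rng([seed, species.index(sp) + 1])
        contig_id = f"{sp}_c01"
        builder = _ContigBuilder(species_id=sp, contig_id=contig_id, rng=rng)

        def add_fillers(k: int) -> None:
            for _ in range(k):
                prot, kind = _filler_protein(rng, templates, fdb)
                gid = builder.add_gene(prot, product=f"filler ({kind})")
                truth.gene_roles[gid] = "unrelated"

        planted: List[Tuple[str, str, List[PlantedGene], bool, bool]] = []
        for inst in sorted(instances[sp], key=lambda i: i.family_id):
            fam = next(f for f in families if f.family_id == inst.family_id)
            counted = fam.counted and not (
                inst.expected_class == "NRPS_like_ATR" and len(inst.genes) == 1
            )
            in_network = fam.in_network and inst.expected_class != "typeIII_PKS"
            planted.append(
                (inst.family_id, inst.expected_class, inst.genes, counted, in_network)
            )
        if extras:
            planted.append(
                (
                    f"X_{sp}_atrr",
                    "excluded_primary_metabolism",
                    [
                        PlantedGene(
                            name="atrr",
                            role="core",
                            protein=_LINKER.join(
                                mutate_to_identity(panel[d], 0.8, rng)
                                for d in ("A", "T", "R", "R")
                            ),
                            domains=("A", "T", "R", "R"),
                        )
                    ],
                    False,
                    False,
                )
            )
            planted.append(
                (
                    f"X_{sp}_lss",
                    "excluded_primary_metabolism",
                    [
                        PlantedGene(
                            name="lss",
                            role="core",
                            protein=mutate_to_identity(panel["LSS"], 0.8, rng),
                            domains=("LSS",),
                        )
                    ],
                    False,
                    False,
                )
            )
            planted.append(
                (
                    f"X_{sp}_t3pks",
                    "typeIII_PKS",
                    [
                        PlantedGene(
                            name="t3pks",
                            role="core",
                            protein=mutate_to_identity(t3_template.protein, 0.75, rng),
                        )
                    ],
                    True,
                    False,
                )
            )

        add_fillers(filler_between)
        for family_id, cls, genes, counted, in_network in planted:
            gene_ids = []
            for pg in genes:
                gid = builder.add_gene(pg.protein, product=f"{family_id}:{pg.name}")
                truth.gene_roles[gid] = pg.role
                gene_ids.append(gid)
            truth.loci.append(
                TruthLocus(
                    species_id=sp,
                    contig_id=contig_id,
                    gene_ids=gene_ids,
                    family_id=family_id,
                    bgc_class=cls,
                    counted=counted,
                    in_network=in_network,
                )
            )
            add_fillers(filler_between)

        seq, genes = builder.finish()
        genome = Genome(species_id=sp)
        genome.contig_seqs[contig_id] = seq
        for g in genes:
            genome.add_gene(g)
        genomes[sp] = genome.finalize()

    return genomes, truth


# ---------------------------------------------------------------------------
# on-disk cohort layout


def write_cohort(
    genomes: Dict[str, Genome], truth: CohortTruth, outdir: str, seed: Optional[int] = None
) -> None:
    """Write the cohort: per-species GenBank, GFF3 + FASTA, truth TSVs and a
    cohort YAML manifest."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    os.makedirs(outdir, exist_ok=True)
    truth_dir = os.path.join(outdir, "truth")
    os.makedirs(truth_dir, exist_ok=True)

    for sp in sorted(genomes):
        genome = genomes[sp]
        records = []
        for contig_id in sorted(genome.contigs):
            seq = genome.contig_seqs[contig_id]
            rec = SeqRecord(
                Seq(seq),
                id=contig_id,
                name=contig_id[:16],
                description=f"synthetic contig of {sp}",
                annotations={"molecule_type": "DNA", "date": "01-JAN-2000"},
            )
            for g in genome.contigs[contig_id]:
                rec.features.append(
                    SeqFeature(
                        FeatureLocation(g.start - 1, g.end, strand=1 if g.strand == "+" else -1),
                        type="CDS",
                        qualifiers={
                            "locus_tag": [g.gene_id],
                            "translation": [g.protein],
                            "product": [g.product or "hypothetical protein"],
                        },
                    )
                )
            records.append(rec)
        SeqIO.write(records, os.path.join(outdir, f"{sp}.gbk"), "genbank")
        with open(os.path.join(outdir, f"{sp}.fna"), "w") as fh:
            for rec in records:
                fh.write(f">{rec.id}\n")
                s = str(rec.seq)
                for i in range(0, len(s), 80):
                    fh.write(s[i : i + 80] + "\n")
        with open(os.path.join(outdir, f"{sp}.gff3"), "w") as fh:
            fh.write("##gff-version 3\n")
            for rec in records:
                for g in genome.contigs[rec.id]:
                    attrs = f"ID={g.gene_id};product={g.product or 'hypothetical protein'}"
                    fh.write(
                        f"{rec.id}\tbgcmine_sim\tCDS\t{g.start}\t{g.end}\t.\t"
                        f"{g.strand}\t0\t{attrs}\n"
                    )

    pd.DataFrame(
        sorted(truth.gene_roles.items()), columns=["gene_id", "role"]
    ).to_csv(os.path.join(truth_dir, "gene_roles.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "species_id": t.species_id,
                "contig_id": t.contig_id,
                "gene_ids": ",".join(t.gene_ids),
                "family_id": t.family_id,
                "bgc_class": t.bgc_class,
                "counted": t.counted,
                "in_network": t.in_network,
            }
            for t in truth.loci
        ]
    ).to_csv(os.path.join(truth_dir, "loci.tsv"), sep="\t", index=False)
    truth.class_matrix().to_csv(os.path.join(truth_dir, "class_matrix.tsv"), sep="\t")
    pd.DataFrame(
        [
            {"species_id": sp, "gene_ids": ",".join(sorted(gs)), "family_id": fid}
            for (sp, gs), fid in sorted(
                truth.gcf_partition().items(), key=lambda kv: (kv[0][0], kv[1])
            )
        ]
    ).to_csv(os.path.join(truth_dir, "gcf_truth.tsv"), sep="\t", index=False)

    manifest = {
        "species": truth.species,
        "n_loci": len(truth.loci),
        "conserved_families": truth.conserved_families(),
    }
    if seed is not None:
        manifest["seed"] = int(seed)
    with open(os.path.join(outdir, "cohort.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
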