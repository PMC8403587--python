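"""Biosynthetic class assignment for assembled loci.

Each locus receives exactly one class from a fixed precedence list: the
exclusions (primary metabolism) fire first, then the most gene-content-
specific composite classes (alkyl citrate, meroterpenoid), then hybrids
before collaborative PKS so that one bifunctional protein is not counted
twice, then the PKS subtypes, NRPS(-like) classes and the terpene/alkaloid
classes.

The hr/pr/nr subtype boundaries are formalised as: highly reducing when the
full reductive loop (KR, DH, ER) is present; partially reducing when KR is
present without ER; non-reducing when no reductive domain occurs at all
(SAT/PT are supportive but not required); truncated when KS, AT or ACP is
missing.  Domain strings outside these canonical patterns fall to the most
reduced compatible subtype so classification stays total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .bgc_assembly import BGCLocus
from .core_detection import DomainHit, is_pks, nrps_module_count

__all__ = [
    "BGC_CLASSES",
    "GenomeContext",
    "ClassifiedLocus",
    "classify_pks_subtype",
    "detect_disintegrated",
    "classify_locus",
    "class_count_table",
]

BGC_CLASSES = [
    "nrPKS",
    "hrPKS",
    "prPKS",
    "typeIII_PKS",
    "collaborative_PKS",
    "truncated_PKS",
    "disintegrated_PKS",
    "meroterpenoid",
    "alkyl_citrate",
    "PKS_NRPS",
    "NRPS_PKS",
    "NRPS",
    "NRPS_like_ATTE",
    "NRPS_like_ATR",
    "terpene_mono_sesqui",
    "diterpene_GGPPS",
    "labdane_diterpene",
    "triterpene",
    "DMAT_alkaloid",
    "RiPP",
    "excluded_primary_metabolism",
]

_HR_COMPLETE = {"KS", "AT", "DH", "ER", "KR", "ACP"}
_NR_COMPLETE = {"KS", "AT", "ACP"}


class ClassificationError(ValueError):
    pass


@dataclass
class GenomeContext:
    """Genome-level facts classification needs beyond the locus itself:
    lanosterol-synthase copy ids in genome order (the first is treated as the
    primary-metabolism ergosterol copy)."""

    lss_gene_ids: List[str] = field(default_factory=list)

    def is_primary_lss(self, gene_id: str) -> bool:
        return bool(self.lss_gene_ids) and self.lss_gene_ids[0] == gene_id


def classify_pks_subtype(ds: Sequence[str]) -> str:
    """Subtype of a single PKS domain string: nrPKS/hrPKS/prPKS/truncated_PKS."""
    s = set(ds)
    if not is_pks(ds):
        raise ClassificationError(f"not a PKS domain string: {list(ds)}")
    if not {"KS", "AT", "ACP"} <= s:
        return "truncated_PKS"
    if {"KR", "DH", "ER"} <= s:
        return "hrPKS"
    if "KR" in s and "ER" not in s:
        return "prPKS"
    if not s & {"KR", "DH", "ER"}:
        return "nrPKS"
    # off-pattern strings (e.g. ER without KR, DH alone): most reduced match
    return "hrPKS" if "ER" in s else "prPKS"


def _gene_domain_strings(locus: BGCLocus) -> Dict[str, List[str]]:
    return {
        gid: [h.domain for h in sorted(hits, key=lambda h: h.start_aa)]
        for gid, hits in locus.domain_hits.items()
    }


def detect_disintegrated(locus: BGCLocus, max_gap_kb: float = 10.0) -> bool:
    """True iff two nearby genes carry complementary partial PKS domain sets
    that together complete an hrPKS or nrPKS.

    "Complementary" requires each gene alone to be incomplete, disjoint
    essential domains, and the union to cover the complete set; the genes'
    spans must lie within ``max_gap_kb`` of each other.
    """
    ds = _gene_domain_strings(locus)
    pksish = [
        (gid, set(d) & (_HR_COMPLETE | {"SAT", "PT", "CMeT", "TE"}))
        for gid, d in ds.items()
        if set(d) & _HR_COMPLETE
    ]
    genes = {g.gene_id: g for g in locus.genes}
    for i in range(len(pksish)):
        for j in range(i + 1, len(pksish)):
            (g1, s1), (g2, s2) = pksish[i], pksish[j]
            e1, e2 = s1 & _HR_COMPLETE, s2 & _HR_COMPLETE
            for target in (_HR_COMPLETE, _NR_COMPLETE):
                if (
                    e1 & target
                    and e2 & target
                    and not (e1 & e2)
                    and target <= (e1 | e2)
                    and e1 != target
                    and e2 != target
                ):
                    a, b = genes[g1], genes[g2]
                    gap_nt = max(0, max(a.start, b.start) - min(a.end, b.end))
                    if gap_nt / 1000.0 <= max_gap_kb:
                        return True
    return False


def _hybrid_orientation(ds: Sequence[str]) -> Optional[str]:
    """PKS_NRPS / NRPS_PKS for a single protein carrying both machineries."""
    s = set(ds)
    if not (is_pks(ds) and {"C", "A", "T"} <= s):
        return None
    first_pks = min(i for i, d in enumerate(ds) if d in ("KS", "AT", "ACP"))
    first_nrps = min(i for i, d in enumerate(ds) if d in ("C", "A", "T"))
    return "PKS_NRPS" if first_pks < first_nrps else "NRPS_PKS"


def classify_locus(
    locus: BGCLocus,
    context: Optional[GenomeContext] = None,
    max_gap_kb: float = 10.0,
    strong_evalue: float = 1e-5,
) -> Tuple[str, str]:
    """Assign the single class of a locus; returns (class, fired_rule).

    Pure function of the locus domain content plus genome context; the fired
    rule names which precedence step matched, for auditing.

    Rules that rest purely on template similarity (RiPP precursor, type III
    PKS) require a confident hit (E <= ``strong_evalue``): the lenient
    detection threshold admits marginal chance hits that must not override
    domain-content evidence.
    """
    if not locus.core_gene_ids:
        raise ClassificationError(f"{locus.bgc_id}: locus has no core gene")
    ds = _gene_domain_strings(locus)
    all_types = {d for s in ds.values() for d in s}
    target_classes = {
        h.target_class
        for h in locus.core_hits.values()
        if h.evalue <= strong_evalue
    }

    # 1. primary-metabolism exclusions
    for gid, s in ds.items():
        for i in range(len(s) - 3):
            if tuple(s[i : i + 4]) == ("A", "T", "R", "R"):
                return "excluded_primary_metabolism", "A-T-R-R glycine betaine reductase"
    lss_genes = [gid for gid, s in ds.items() if "LSS" in s]
    if lss_genes and "SHC" not in all_types:
        primary = (
            context.is_primary_lss(lss_genes[0])
            if context is not None
            else len(lss_genes) == 1
        )
        if primary and locus.n_genes == 1:
            return "excluded_primary_metabolism", "single-copy unclustered LSS (ergosterol)"

    # 2. RiPP by precursor similarity
    if "RiPP_precursor" in target_classes:
        return "RiPP", "RiPP precursor hit"

    pks_genes = {gid: s for gid, s in ds.items() if is_pks(s)}
    hybrid_genes = {
        gid: o for gid, s in ds.items() if (o := _hybrid_orientation(s)) is not None
    }
    true_pks = {gid: s for gid, s in pks_genes.items() if gid not in hybrid_genes}

    # 3. alkyl citrate: citrate synthase + dedicated FAS pair or an hrPKS
    if "CS" in all_types:
        has_fas = "FAS_alpha" in all_types and "FAS_beta" in all_types
        has_hr = any(classify_pks_subtype(s) == "hrPKS" for s in true_pks.values())
        if has_fas or has_hr:
            return "alkyl_citrate", "citrate synthase with FAS pair or hrPKS"

    # 4. meroterpenoid: PKS plus prenyltransferase and/or terpene cyclase
    if true_pks and ("PTase" in all_types or "TC" in all_types):
        return "meroterpenoid", "PKS with prenyltransferase/terpene cyclase"

    # 5. hybrids on a single protein
    if hybrid_genes:
        orientations = sorted(set(hybrid_genes.values()))
        return orientations[0], "single-protein PKS/NRPS hybrid"

    # 6. collaborative: two or more PKS core genes
    if len(true_pks) >= 2:
        return "collaborative_PKS", ">=2 PKS genes in one locus"

    # 7. disintegrated PKS
    if not true_pks and detect_disintegrated(locus, max_gap_kb):
        return "disintegrated_PKS", "complementary split PKS domain sets"
    if (
        len(true_pks) == 1
        and classify_pks_subtype(next(iter(true_pks.values()))) == "truncated_PKS"
        and detect_disintegrated(locus, max_gap_kb)
    ):
        return "disintegrated_PKS", "complementary split PKS domain sets"

    # 8. PKS subtype
    if len(true_pks) == 1:
        sub = classify_pks_subtype(next(iter(true_pks.values())))
        return sub, f"PKS subtype rule ({sub})"
    if any(s & {"KS", "AT", "ACP", "SAT", "PT"} for s in map(set, ds.values())):
        return "truncated_PKS", "partial PKS domains only"

    # 9. type III PKS (template similarity, not domain string)
    if "typeIII_PKS" in target_classes:
        return "typeIII_PKS", "type III template similarity"

    # 10. NRPS: >= 1 complete C-A-T module
    if any(nrps_module_count(s) >= 1 for s in ds.values()):
        return "NRPS", "complete C-A-T module(s)"

    # 11. NRPS-like single-module release variants
    for gid, s in ds.items():
        st = set(s)
        if {"A", "T"} <= st and "C" not in st:
            if "TE" in st:
                return "NRPS_like_ATTE", "A-T-TE architecture"
            if "R" in st:
                return "NRPS_like_ATR", "A-T-R architecture"

    # 12-16. terpene and alkaloid classes
    if any(s.count("TC") >= 2 for s in ds.values()):
        return "labdane_diterpene", "bifunctional (copalyl-route) cyclase"
    if "TC" in all_types and "GGPPS" in all_types:
        return "diterpene_GGPPS", "cyclase coupled to GGPPS"
    if "SHC" in all_types or ("LSS" in all_types):
        return "triterpene", "additional triterpene cyclase"
    if "DMAT" in all_types:
        return "DMAT_alkaloid", "tryptophan DMAT"
    if "TC" in all_types:
        return "terpene_mono_sesqui", "mono/sesquiterpene cyclase"

    raise ClassificationError(
        f"{locus.bgc_id}: no classification rule matched "
        f"(domains {sorted(all_types)}, targets {sorted(target_classes)})"
    )


@dataclass
class ClassifiedLocus:
    locus: BGCLocus
    bgc_class: str
    rule: str

    @property
    def counted(self) -> bool:
        """Whether this locus enters class-count totals: primary-metabolism
        loci and *unclustered* A-T-R NRPS-like genes are excluded."""
        if self.bgc_class == "excluded_primary_metabolism":
            return False
        if self.bgc_class == "NRPS_like_ATR" and self.locus.n_genes == 1:
            return False
        return True


def classify_all(
    loci: Sequence[BGCLocus], context: Optional[GenomeContext] = None
) -> List[ClassifiedLocus]:
    out = []
    for locus in loci:
        cls, rule = classify_locus(locus, context)
        locus.bgc_class = cls
        out.append(ClassifiedLocus(locus=locus, bgc_class=cls, rule=rule))
    return out


def class_count_table(
    classified_by_species: Dict[str, Sequence[ClassifiedLocus]]
) -> pd.DataFrame:
    """Species x class integer count matrix (excluded loci not counted)."""
    counted_classes = [c for c in BGC_CLASSES if c != "excluded_primary_metabolism"]
    rows = {}
    for sp in sorted(classified_by_species):
        counts = {c: 0 for c in counted_classes}
        for cl in classified_by_species[sp]:
            if cl.counted:
                counts[cl.bgc_class] += 1
        rows[sp] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=counted_classes).astype(
        int
    )
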