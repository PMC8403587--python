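"""Class taxonomy: subtype rules, disintegration, precedence, count table."""

import numpy as np
import pytest

from bgcmine.bgc_classification import (
    BGC_CLASSES,
    ClassificationError,
    GenomeContext,
    class_count_table,
    classify_all,
    classify_locus,
    classify_pks_subtype,
    detect_disintegrated,
)
from conftest import make_locus


@pytest.mark.parametrize(
    "ds,expected",
    [
        (["KS", "AT", "DH", "CMeT", "ER", "KR", "ACP"], "hrPKS"),
        (["KS", "AT", "DH", "ER", "KR", "ACP"], "hrPKS"),
        (["SAT", "KS", "AT", "PT", "ACP", "TE"], "nrPKS"),
        (["KS", "AT", "ACP"], "nrPKS"),
        (["KS", "AT", "DH", "KR", "ACP"], "prPKS"),
        (["KS", "AT", "KR", "ACP", "TE"], "prPKS"),
        (["KS", "AT"], "truncated_PKS"),  # ACP missing
        (["KS", "ACP", "KR"], "truncated_PKS"),  # AT missing
        (["KS", "AT", "ER", "ACP"], "hrPKS"),  # off-pattern: most reduced match
        (["KS", "AT", "DH", "ACP"], "prPKS"),  # off-pattern, no ER
    ],
)
def test_pks_subtype_rule_table(ds, expected):
    assert classify_pks_subtype(ds) == expected


def test_non_pks_input_is_an_error():
    with pytest.raises(ClassificationError):
        classify_pks_subtype(["C", "A", "T"])


class TestDisintegrated:
    def test_split_hrpks_eight_kb_apart(self):
        # first subunit with KS-AT-DH-CMeT-ER, second with the missing KR+ACP
        locus = make_locus(
            [
                {"name": "g1", "domains": ["KS", "AT", "DH", "CMeT", "ER"], "core": True},
                {"name": "g2", "domains": ["KR", "ACP"], "gap_nt": 8000},
            ]
        )
        assert detect_disintegrated(locus) is True

    def test_two_complete_pks_are_not_disintegrated(self):
        locus = make_locus(
            [
                {"name": "g1", "domains": ["KS", "AT", "DH", "ER", "KR", "ACP"], "core": True},
                {"name": "g2", "domains": ["KS", "AT", "DH", "ER", "KR", "ACP"], "core": True},
            ]
        )
        assert detect_disintegrated(locus) is False

    def test_complementary_but_fifty_kb_apart(self):
        locus = make_locus(
            [
                {"name": "g1", "domains": ["KS", "AT", "DH", "CMeT", "ER"], "core": True},
                {"name": "g2", "domains": ["KR", "ACP"], "gap_nt": 50000},
            ]
        )
        assert detect_disintegrated(locus) is False


def L(*gene_specs, **kw):
    return make_locus(list(gene_specs), **kw)


CLASS_FIXTURES = [
    # (description, locus, context, expected class)
    ("hrPKS", L({"name": "g1", "domains": ["KS", "AT", "DH", "CMeT", "ER", "KR", "ACP"], "core": True}), None, "hrPKS"),
    ("nrPKS", L({"name": "g1", "domains": ["SAT", "KS", "AT", "PT", "ACP", "TE"], "core": True}), None, "nrPKS"),
    ("prPKS", L({"name": "g1", "domains": ["KS", "AT", "DH", "KR", "ACP"], "core": True}), None, "prPKS"),
    ("truncated", L({"name": "g1", "domains": ["KS", "ACP"], "core": True}), None, "truncated_PKS"),
    ("collaborative", L(
        {"name": "g1", "domains": ["SAT", "KS", "AT", "PT", "ACP"], "core": True},
        {"name": "g2", "domains": ["KS", "AT", "DH", "ER", "KR", "ACP"], "core": True},
    ), None, "collaborative_PKS"),
    ("disintegrated", L(
        {"name": "g1", "domains": ["KS", "AT", "DH", "CMeT", "ER"], "core": True},
        {"name": "g2", "domains": ["KR", "ACP"], "gap_nt": 8000},
    ), None, "disintegrated_PKS"),
    ("typeIII", L({"name": "g1", "domains": [], "core": True, "target": "typeIII_PKS"}), None, "typeIII_PKS"),
    ("meroterpenoid PKS+PTase", L(
        {"name": "g1", "domains": ["SAT", "KS", "AT", "PT", "ACP", "TE"], "core": True},
        {"name": "g2", "domains": ["PTase"]},
    ), None, "meroterpenoid"),
    ("meroterpenoid PKS+TC", L(
        {"name": "g1", "domains": ["KS", "AT", "DH", "ER", "KR", "ACP"], "core": True},
        {"name": "g2", "domains": ["TC"]},
    ), None, "meroterpenoid"),
    ("alkyl citrate CS+FAS", L(
        {"name": "g1", "domains": ["CS"], "core": True, "target": "alkyl_citrate"},
        {"name": "g2", "domains": ["FAS_alpha"]},
        {"name": "g3", "domains": ["FAS_beta"]},
    ), None, "alkyl_citrate"),
    ("alkyl citrate CS+hrPKS", L(
        {"name": "g1", "domains": ["CS"], "core": True, "target": "alkyl_citrate"},
        {"name": "g2", "domains": ["KS", "AT", "DH", "ER", "KR", "ACP"], "core": True},
    ), None, "alkyl_citrate"),
    ("PKS-NRPS hybrid", L(
        {"name": "g1", "domains": ["KS", "AT", "DH", "KR", "ACP", "C", "A", "T", "R"], "core": True},
    ), None, "PKS_NRPS"),
    ("NRPS-PKS hybrid", L(
        {"name": "g1", "domains": ["C", "A", "T", "KS", "AT", "ACP", "TE"], "core": True},
    ), None, "NRPS_PKS"),
    ("NRPS two modules", L(
        {"name": "g1", "domains": ["C", "A", "T", "C", "A", "T", "TE"], "core": True,
         "target": "NRPS_family"},
    ), None, "NRPS"),
    ("NRPS-like A-T-TE", L(
        {"name": "g1", "domains": ["A", "T", "TE"], "core": True, "target": "NRPS_family"},
    ), None, "NRPS_like_ATTE"),
    ("NRPS-like A-T-R", L(
        {"name": "g1", "domains": ["A", "T", "R"], "core": True, "target": "NRPS_family"},
        {"name": "g2", "domains": []},
    ), None, "NRPS_like_ATR"),
    ("A-T-R-R excluded (glycine betaine reductase)", L(
        {"name": "g1", "domains": ["A", "T", "R", "R"], "core": True, "target": "NRPS_family"},
    ), None, "excluded_primary_metabolism"),
    ("single-copy unclustered LSS excluded", L(
        {"name": "g1", "domains": ["LSS"], "core": True, "target": "terpene"},
    ), GenomeContext(lss_gene_ids=["g1"]), "excluded_primary_metabolism"),
    ("second LSS copy is a triterpene", L(
        {"name": "g1", "domains": ["LSS"], "core": True, "target": "terpene"},
    ), GenomeContext(lss_gene_ids=["other", "g1"]), "triterpene"),
    ("SHC triterpene", L(
        {"name": "g1", "domains": ["SHC"], "core": True, "target": "terpene"},
        {"name": "g2", "domains": []},
    ), None, "triterpene"),
    ("labdane bifunctional cyclase", L(
        {"name": "g1", "domains": ["TC", "TC"], "core": True, "target": "terpene"},
    ), None, "labdane_diterpene"),
    ("GGPPS-coupled diterpene", L(
        {"name": "g1", "domains": ["TC"], "core": True, "target": "terpene"},
        {"name": "g2", "domains": ["GGPPS"]},
    ), None, "diterpene_GGPPS"),
    ("mono/sesquiterpene cyclase", L(
        {"name": "g1", "domains": ["TC"], "core": True, "target": "terpene"},
    ), None, "terpene_mono_sesqui"),
    ("DMAT alkaloid", L(
        {"name": "g1", "domains": ["DMAT"], "core": True, "target": "alkaloid_DMAT"},
        {"name": "g2", "domains": []},
    ), None, "DMAT_alkaloid"),
    ("RiPP precursor", L(
        {"name": "g1", "domains": [], "core": True, "target": "RiPP_precursor"},
        {"name": "g2", "domains": []},
    ), None, "RiPP"),
]


@pytest.mark.parametrize(
    "desc,locus,context,expected", CLASS_FIXTURES, ids=[f[0] for f in CLASS_FIXTURES]
)
def test_class_fixture(desc, locus, context, expected):
    cls, rule = classify_locus(locus, context)
    assert cls == expected, f"{desc}: {rule}"


def test_locus_without_core_is_an_error():
    locus = make_locus([{"name": "g1", "domains": ["TC"]}])
    with pytest.raises(ClassificationError):
        classify_locus(locus)


def test_classification_is_order_invariant_and_total():
    """Randomised rule-satisfying loci always get exactly one class, and the
    class never depends on gene order within the locus."""
    rng = np.random.default_rng(99)
    archetypes = [f[1] for f in CLASS_FIXTURES]
    supportive = [[], ["GT"], ["E"], ["CDPS"]]
    for _ in range(60):
        base = archetypes[int(rng.integers(len(archetypes)))]
        specs = []
        for g in base.genes:
            doms = [h.domain for h in sorted(base.domain_hits[g.gene_id], key=lambda h: h.start_aa)]
            specs.append(
                {
                    "name": g.gene_id,
                    "domains": doms,
                    "core": g.gene_id in base.core_gene_ids,
                    "target": base.core_hits[g.gene_id].target_class
                    if g.gene_id in base.core_hits
                    else None,
                    "gap_nt": g.start - 1 if not specs else 200,
                }
            )
        # add a noise gene with supportive-only domains
        extra = supportive[int(rng.integers(len(supportive)))]
        if extra:
            specs.append({"name": "gnoise", "domains": extra})
        cls1, _ = classify_locus(make_locus(specs))
        assert cls1 in BGC_CLASSES
        # permute non-positional structure: reverse the gene list (gaps kept
        # small so disintegration distance constraints still hold)
        cls2, _ = classify_locus(make_locus(specs[::-1]))
        assert cls1 == cls2


class TestClassCountTable:
    def test_empty_cohort_is_all_zero(self):
        df = class_count_table({"spA": []})
        assert df.values.sum() == 0
        assert "excluded_primary_metabolism" not in df.columns

    def test_single_genome_single_hrpks(self):
        locus = make_locus(
            [{"name": "g1", "domains": ["KS", "AT", "DH", "ER", "KR", "ACP"], "core": True}]
        )
        (cl,) = classify_all([locus])
        df = class_count_table({"spA": [cl]})
        assert df.loc["spA", "hrPKS"] == 1
        assert df.loc["spA"].sum() == 1

    def test_exclusions_not_counted(self):
        excl = make_locus(
            [{"name": "g1", "domains": ["A", "T", "R", "R"], "core": True,
              "target": "NRPS_family"}],
            bgc_id="b_excl",
        )
        atr = make_locus(
            [{"name": "g2", "domains": ["A", "T", "R"], "core": True,
              "target": "NRPS_family"}],
            bgc_id="b_atr",
        )
        cls = classify_all([excl, atr])
        df = class_count_table({"spA": cls})
        # A-T-R-R is primary metabolism; a *single-gene* A-T-R locus is
        # unclustered and also left out of the totals
        assert df.loc["spA"].sum() == 0

    def test_matches_generator_truth(self, small_cohort, small_cohort_result):
        _, truth = small_cohort
        assert small_cohort_result.class_table.equals(truth.class_matrix())
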