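"""The cohort generator: primitives, planted families and whole cohorts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bgcmine.synthetic_data import (
    FamilySpec,
    GenePlan,
    default_cohort_design,
    make_cohort,
    make_protein,
    mutate_to_identity,
    plant_family,
)


class TestMakeProtein:
    def test_deterministic_under_seed(self):
        assert make_protein(120, 42) == make_protein(120, 42)

    def test_different_seeds_differ(self):
        assert make_protein(120, 1) != make_protein(120, 2)

    def test_zero_length_is_an_error(self):
        with pytest.raises(ValueError):
            make_protein(0, 1)


class TestMutateToIdentity:
    def test_target_one_is_identity(self):
        p = make_protein(100, 3)
        assert mutate_to_identity(p, 1.0, 4) == p

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.floats(min_value=0.25, max_value=0.99), st.integers(0, 10**6))
    def test_exact_position_identity(self, target, seed):
        p = make_protein(100, 5)
        q = mutate_to_identity(p, target, seed)
        conserved = sum(a == b for a, b in zip(p, q))
        assert conserved == math.ceil(target * 100)
        assert len(q) == len(p)  # indel-free

    def test_floor_enforced(self):
        with pytest.raises(ValueError):
            mutate_to_identity("MKTAYIAK" * 10, 0.1, 1)


def _family(identity=1.0, **kw):
    return FamilySpec(
        family_id="Ftest",
        bgc_class="hrPKS",
        identity=identity,
        species=["spA", "spB"],
        genes=[
            GenePlan("pks", "core", domains=("KS", "AT", "DH", "ER", "KR", "ACP")),
            GenePlan("p450", "tailoring", ref="tail_p450"),
        ],
        **kw,
    )


def _as_locus(instance, bgc_id):
    """Assemble a planted family instance into a locus for inspection."""
    from bgcmine.core_detection import assign_domains
    from bgcmine.genome_io import Gene
    from bgcmine.bgc_assembly import BGCLocus
    from bgcmine.refdata import load_domain_panel

    panel = load_domain_panel()
    genes, pos = [], 1
    for pg in instance.genes:
        nt = 3 * (len(pg.protein) + 1)
        genes.append(
            Gene(f"{bgc_id}_{pg.name}", "c1", pos, pos + nt - 1, "+", pg.protein)
        )
        pos += nt + 200
    locus = BGCLocus(
        bgc_id=bgc_id,
        species_id=instance.species_id,
        contig_id="c1",
        genes=genes,
        core_gene_ids={g.gene_id for g, pg in zip(genes, instance.genes) if pg.role == "core"},
        gene_roles={g.gene_id: pg.role for g, pg in zip(genes, instance.genes)},
    )
    for g in genes:
        locus.domain_hits[g.gene_id] = assign_domains(g, panel)
    return locus


class TestPlantFamily:
    def test_identity_one_gives_full_identity_links(self):
        from bgcmine.synteny import compare_bgcs

        instances = plant_family(_family(identity=1.0), seed=5)
        a = _as_locus(instances["spA"], "bA")
        b = _as_locus(instances["spB"], "bB")
        links = compare_bgcs(a, b)
        assert len(links) == len(a.genes)
        assert all(l.identity_pct == 100.0 for l in links)

    def test_disintegration_variant_detected(self):
        from bgcmine.bgc_classification import detect_disintegrated

        spec = _family(identity=0.85, disintegrate_in=("spB", "pks", 4))
        instances = plant_family(spec, seed=6)
        assert len(instances["spB"].genes) == len(instances["spA"].genes) + 1
        assert instances["spB"].expected_class == "disintegrated_PKS"
        locus = _as_locus(instances["spB"], "bB")
        assert detect_disintegrated(locus)

    def test_rearranged_variant_lowers_adjacency_index(self):
        from bgcmine.core_detection import domain_inventory
        from bgcmine.gcf_network import adjacency_index

        spec = FamilySpec(
            family_id="Fr",
            bgc_class="meroterpenoid",
            identity=1.0,
            species=["spA", "spB"],
            rearrange_in="spB",
            genes=[
                GenePlan("npks", "core", domains=("SAT", "KS", "AT", "PT", "ACP", "TE")),
                GenePlan("ptase", "core", domains=("PTase",)),
            ],
        )
        instances = plant_family(spec, seed=7)
        a = _as_locus(instances["spA"], "bA")
        b = _as_locus(instances["spB"], "bB")
        ia = domain_inventory(a, a.domain_hits)
        ib = domain_inventory(b, b.domain_hits)
        assert adjacency_index(ia, ib) < 1.0

    def test_truncation_variant_drops_domains(self):
        spec = _family(identity=0.85, truncate_in=("spB", ("AT",)))
        instances = plant_family(spec, seed=8)
        locus = _as_locus(instances["spB"], "bB")
        doms = {h.domain for hits in locus.domain_hits.values() for h in hits}
        assert "AT" not in doms
        assert instances["spB"].expected_class == "truncated_PKS"


class TestMakeCohort:
    def test_same_seed_byte_identical(self, tmp_path):
        from bgcmine.synthetic_data import write_cohort

        for name in ("one", "two"):
            genomes, truth = make_cohort(n_species=2, families=[], seed=3, extras=True)
            write_cohort(genomes, truth, str(tmp_path / name))
        for f in sorted((tmp_path / "one").rglob("*")):
            if f.is_file():
                g = tmp_path / "two" / f.relative_to(tmp_path / "one")
                assert f.read_bytes() == g.read_bytes(), f.name

    def test_zero_families_yields_zero_bgcs(self, templates):
        from bgcmine.core_detection import scan_cores

        genomes, truth = make_cohort(n_species=1, families=[], seed=4, extras=False)
        assert truth.loci == []
        (genome,) = genomes.values()
        assert scan_cores(genome, templates) == []

    def test_fillers_are_clean(self, small_cohort, function_db):
        from bgcmine.bgc_assembly import call_gene_role

        genomes, truth = small_cohort
        sp = sorted(genomes)[0]
        fillers = [
            g for g in genomes[sp].genes if truth.gene_roles[g.gene_id] == "unrelated"
        ][:8]
        assert fillers
        for g in fillers:
            assert call_gene_role(g, function_db) == "unrelated"

    def test_filler_separation_bound_enforced(self):
        with pytest.raises(ValueError):
            make_cohort(n_species=1, filler_between=2, seed=1)

    def test_truth_bookkeeping(self, small_cohort):
        genomes, truth = small_cohort
        # every planted gene id exists in its genome
        all_ids = {g.gene_id for gm in genomes.values() for g in gm.genes}
        for t in truth.loci:
            assert set(t.gene_ids) <= all_ids
        # default design: the two cohort-wide families are conserved
        assert truth.conserved_families() == 4  # with 3 species, 4 families span all

    def test_default_design_shape(self):
        fams = default_cohort_design([f"sp{i:02d}" for i in range(8)])
        multi = [f for f in fams if len(f.species) > 1]
        singles = [f for f in fams if len(f.species) == 1]
        assert len(multi) == 6 and len(singles) == 10
        assert sum(1 for f in multi if len(f.species) == 8) == 2
        assert any(f.rearrange_in for f in multi)
        assert any(f.truncate_in for f in multi)
        assert any(f.disintegrate_in for f in multi)
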