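"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pytest

from bgcmine.alignment import DEFAULT_SCHEME
from bgcmine.bgc_assembly import BGCLocus
from bgcmine.core_detection import CoreHit, DomainHit
from bgcmine.genome_io import Gene, Genome

# ---------------------------------------------------------------------------
# independent brute-force Smith-Waterman oracle (affine gaps, "11 1": a gap
# of length L costs open + L*extend). Quadratic space, no optimisations —
# deliberately a different implementation path from the package.

NEG = float("-inf")


def sw_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    m = DEFAULT_SCHEME.matrix
    n1, n2 = len(a), len(b)
    M = [[0.0] * (n2 + 1) for _ in range(n1 + 1)]
    Ix = [[NEG] * (n2 + 1) for _ in range(n1 + 1)]
    Iy = [[NEG] * (n2 + 1) for _ in range(n1 + 1)]
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            s = float(m[a[i - 1], b[j - 1]])
            M[i][j] = s + max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


def random_peptide(rng: np.random.Generator, max_len: int = 30) -> str:
    from bgcmine.synthetic_data import AAS

    length = int(rng.integers(1, max_len + 1))
    return "".join(rng.choice(AAS, size=length))


# ---------------------------------------------------------------------------
# toy-genome and toy-locus builders


def make_toy_genome(
    n_genes: int, species: str = "toy", contig: str = "c1", protein: str = "MAAAAQ"
) -> Genome:
    g = Genome(species_id=species)
    pos = 1
    for i in range(n_genes):
        nt_len = 3 * (len(protein) + 1)
        g.add_gene(
            Gene(
                gene_id=f"g{i}",
                contig_id=contig,
                start=pos,
                end=pos + nt_len - 1,
                strand="+",
                protein=protein,
            )
        )
        pos += nt_len + 200
    return g.finalize()


def make_locus(
    gene_specs: Sequence[dict],
    species: str = "spX",
    contig: str = "c1",
    bgc_id: str = "toy_bgc",
) -> BGCLocus:
    """Build a locus straight from per-gene domain strings.

    Each spec: name, domains (list), core (bool), target (template class for
    core hits), gap_nt (distance to previous gene, default 200), strand.
    """
    genes: List[Gene] = []
    domain_hits: Dict[str, List[DomainHit]] = {}
    core_hits: Dict[str, CoreHit] = {}
    cores = set()
    roles = {}
    pos = 1
    for spec in gene_specs:
        name = spec["name"]
        domains = list(spec.get("domains", []))
        pos += spec.get("gap_nt", 200)
        prot_len = max(30, 30 * max(1, len(domains)))
        nt_len = 3 * (prot_len + 1)
        gene = Gene(
            gene_id=name,
            contig_id=contig,
            start=pos,
            end=pos + nt_len - 1,
            strand=spec.get("strand", "+"),
            protein="M" + "A" * (prot_len - 1),
        )
        pos = gene.end + 1
        genes.append(gene)
        domain_hits[name] = [
            DomainHit(
                gene_id=name,
                domain=d,
                start_aa=i * 25 + 1,
                end_aa=i * 25 + 20,
                score=100.0,
            )
            for i, d in enumerate(domains)
        ]
        roles[name] = "core" if spec.get("core") else spec.get("role", "tailoring")
        if spec.get("core"):
            cores.add(name)
            core_hits[name] = CoreHit(
                gene_id=name,
                template_accession=spec.get("accession", "TPL0001"),
                evalue=1e-30,
                score=500.0,
                target_class=spec.get("target", "typeI_PKS"),
            )
    return BGCLocus(
        bgc_id=bgc_id,
        species_id=species,
        contig_id=contig,
        genes=genes,
        core_gene_ids=cores,
        gene_roles=roles,
        domain_hits=domain_hits,
        core_hits=core_hits,
    )


# ---------------------------------------------------------------------------
# shared expensive fixtures


@pytest.fixture(scope="session")
def domain_panel():
    from bgcmine.refdata import load_domain_panel

    return load_domain_panel()


@pytest.fixture(scope="session")
def templates():
    from bgcmine.refdata import load_templates

    return load_templates()


@pytest.fixture(scope="session")
def function_db():
    from bgcmine.refdata import load_function_db

    return load_function_db()


@pytest.fixture(scope="session")
def small_cohort():
    """Three-species default-design cohort used across modules."""
    from bgcmine.synthetic_data import make_cohort

    return make_cohort(n_species=3, seed=7)


@pytest.fixture(scope="session")
def small_cohort_result(small_cohort):
    """Full pipeline run on the three-species cohort (computed once)."""
    from bgcmine.pipeline import PipelineConfig, run_pipeline

    genomes, _ = small_cohort
    return run_pipeline(PipelineConfig(), genomes=genomes, write=False)


@pytest.fixture(scope="session")
def planted_recovery_cohort():
    """The eight-species planted-recovery cohort plus a full pipeline run."""
    from bgcmine.pipeline import PipelineConfig, run_pipeline
    from bgcmine.synthetic_data import make_cohort

    genomes, truth = make_cohort(n_species=8, seed=11)
    config = PipelineConfig(outdir="unused", default_cutoff=0.4)
    result = run_pipeline(config, genomes=genomes, write=False)
    return genomes, truth, result
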