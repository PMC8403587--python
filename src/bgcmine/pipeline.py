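"""End-to-end orchestration: detect -> assemble -> classify -> network -> report.

The pipeline is deterministic given its configuration: every threshold is
recorded in the output directory, all tables are sorted, and reruns produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .alignment import DEFAULT_SCHEME, ScoringScheme
from .bgc_assembly import BGCLocus, FunctionDB, assemble_loci
from .bgc_classification import (
    ClassifiedLocus,
    GenomeContext,
    class_count_table,
    classify_all,
)
from .core_detection import BGCInventory, assign_domains, domain_inventory, scan_cores
from .gcf_network import (
    DEFAULT_ANCHORS,
    DEFAULT_CUTOFFS,
    DEFAULT_WEIGHTS,
    GCF,
    PairDistance,
    all_pair_distances,
    build_network,
    conserved_gcfs,
    export_graphml,
    prune_reference_only,
)
from .genome_io import (
    DomainAnnotationTable,
    Genome,
    GenomeIOError,
    read_domain_table,
    read_genbank,
    read_gff_fasta,
    write_bgc_gff,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "presence_matrix", "summary_stats"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the published defaults."""

    inputs: List[str] = field(default_factory=list)
    references: List[str] = field(default_factory=list)
    domain_tables: Dict[str, str] = field(default_factory=dict)
    outdir: str = "bgcmine_out"
    core_max_evalue: float = 1e-1
    neighbour_max_evalue: float = 1e-5
    min_score_frac: float = 0.3
    cutoffs: Tuple[float, ...] = DEFAULT_CUTOFFS
    default_cutoff: float = 0.4
    weights: Tuple[float, float, float] = DEFAULT_WEIGHTS
    anchor_weight: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if sum(self.weights) > 1.0 + 1e-9:
            raise ValueError("index weights must sum to <= 1")
        for c in tuple(self.cutoffs) + (self.default_cutoff,):
            if not 0.0 < c < 1.0:
                raise ValueError(f"cutoff {c} outside (0, 1)")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cutoffs", "weights"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cutoffs"] = list(self.cutoffs)
        d["weights"] = list(self.weights)
        return d


@dataclass
class PipelineResult:
    genomes: Dict[str, Genome]
    classified: Dict[str, List[ClassifiedLocus]]
    inventories: List[BGCInventory]
    distances: List[PairDistance]
    networks: Dict[float, Tuple[List[PairDistance], List[GCF]]]
    class_table: pd.DataFrame
    presence: pd.DataFrame
    summary: dict

    def all_loci(self) -> List[BGCLocus]:
        return [cl.locus for sp in sorted(self.classified) for cl in self.classified[sp]]

    def gcfs(self, cutoff: Optional[float] = None) -> List[GCF]:
        if cutoff is None:
            cutoff = min(self.networks) if self.networks else None
        return self.networks[cutoff][1]


def load_genomes(paths: Sequence[str]) -> Dict[str, Genome]:
    """Load genomes from GenBank files or GFF3+FASTA pairs.

    A path may be a directory (scanned for ``*.gbk``/``*.gb``/``*.gff3``) or
    a file; ``x.gff3`` expects ``x.fna`` or ``x.fasta`` alongside.
    """
    files: List[str] = []
    for p in paths:
        if os.path.isdir(p):
            files.extend(sorted(glob.glob(os.path.join(p, "*.gbk"))))
            files.extend(sorted(glob.glob(os.path.join(p, "*.gb"))))
            if not files:
                files.extend(sorted(glob.glob(os.path.join(p, "*.gff3"))))
        else:
            files.append(p)
    if not files:
        raise GenomeIOError(f"no genome inputs found under {list(paths)}")
    genomes: Dict[str, Genome] = {}
    for f in sorted(files):
        if f.endswith((".gbk", ".gb", ".genbank")):
            g = read_genbank(f)
        elif f.endswith(".gff3"):
            base = f[: -len(".gff3")]
            fasta = base + ".fna" if os.path.exists(base + ".fna") else base + ".fasta"
            g = read_gff_fasta(f, fasta)
        else:
            raise GenomeIOError(f"unrecognised genome input {f}")
        genomes[g.species_id] = g
    return genomes


def load_reference_locus(
    gbk: str,
    domain_table: Optional[str] = None,
    min_score_frac: float = 0.3,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> BGCLocus:
    """Read one characterised reference cluster (all CDS of the file form the
    locus) and annotate its domains."""
    from .refdata import load_domain_panel

    genome = read_genbank(gbk)
    genes = genome.genes
    table = read_domain_table(domain_table) if domain_table else None
    panel = load_domain_panel()
    locus = BGCLocus(
        bgc_id=f"ref|{genome.species_id}",
        species_id=genome.species_id,
        contig_id=genes[0].contig_id,
        genes=genes,
        core_gene_ids=set(),
        gene_roles={g.gene_id: "core" for g in genes},
        is_reference=True,
    )
    for g in genes:
        locus.domain_hits[g.gene_id] = assign_domains(
            g, panel, min_score_frac, table, scheme
        )
    return locus


def _annotate_and_classify(
    genome: Genome,
    config: PipelineConfig,
    templates,
    fdb: FunctionDB,
    panel: Dict[str, str],
    scheme: ScoringScheme,
) -> List[ClassifiedLocus]:
    cores = scan_cores(genome, templates, config.core_max_evalue, scheme)
    loci = assemble_loci(genome, cores, fdb, config.neighbour_max_evalue, scheme=scheme)
    table = None
    if genome.species_id in config.domain_tables:
        table = read_domain_table(config.domain_tables[genome.species_id])
    for locus in loci:
        for g in locus.genes:
            locus.domain_hits[g.gene_id] = assign_domains(
                g, panel, config.min_score_frac, table, scheme
            )
    lss_ids = [
        g.gene_id
        for locus in loci
        for g in locus.genes
        if any(h.domain == "LSS" for h in locus.domain_hits.get(g.gene_id, []))
    ]
    context = GenomeContext(lss_gene_ids=lss_ids)
    return classify_all(loci, context)


def presence_matrix(gcfs: Sequence[GCF], species: Sequence[str]) -> pd.DataFrame:
    """GCF x species boolean presence/absence matrix."""
    species = sorted(species)
    rows = {}
    for g in sorted(gcfs, key=lambda g: g.gcf_id):
        rows[g.gcf_id] = {sp: sp in g.species for sp in species}
    df = pd.DataFrame.from_dict(rows, orient="index")
    if df.empty:
        df = pd.DataFrame(columns=species)
    return df[species].astype(bool) if len(df) else df


def summary_stats(
    classified: Dict[str, List[ClassifiedLocus]],
    gcfs: Sequence[GCF],
    species: Sequence[str],
) -> dict:
    """Headline totals: BGC counts, mean per species, GCF/singleton counts,
    conserved and >= 4-member family counts."""
    counted = [cl for sp in classified for cl in classified[sp] if cl.counted]
    n_species = len(species)
    non_ref_gcfs = list(gcfs)
    return {
        "n_species": n_species,
        "total_bgcs": len(counted),
        "mean_bgcs_per_species": (len(counted) / n_species) if n_species else 0.0,
        "n_gcfs": len(non_ref_gcfs),
        "n_singletons": sum(1 for g in non_ref_gcfs if g.is_singleton),
        "n_gcfs_min4": sum(1 for g in non_ref_gcfs if len(g.members) >= 4),
        "n_conserved_gcfs": conserved_gcfs(non_ref_gcfs, set(species)),
    }


def run_pipeline(
    config: PipelineConfig,
    genomes: Optional[Dict[str, Genome]] = None,
    write: bool = True,
) -> PipelineResult:
    """Run the whole pipeline; optionally write the results bundle.

    Loci classified as primary metabolism and type III PKS loci stay in the
    class table but are left out of the similarity network (type III synthases
    carry no modular domain string to compare).
    """
    from .refdata import load_domain_panel, load_function_db, load_templates

    scheme = DEFAULT_SCHEME
    templates = load_templates()
    fdb = load_function_db()
    panel = load_domain_panel()

    if genomes is None:
        genomes = load_genomes(config.inputs)
    species = sorted(genomes)

    classified: Dict[str, List[ClassifiedLocus]] = {}
    for sp in species:
        classified[sp] = _annotate_and_classify(
            genomes[sp], config, templates, fdb, panel, scheme
        )

    ref_loci = [
        load_reference_locus(p, min_score_frac=config.min_score_frac, scheme=scheme)
        for p in sorted(config.references)
    ]

    network_loci: List[BGCLocus] = [
        cl.locus
        for sp in species
        for cl in classified[sp]
        if cl.counted and cl.bgc_class != "typeIII_PKS"
    ] + ref_loci

    inventories = [
        domain_inventory(locus, locus.domain_hits) for locus in network_loci
    ]
    species_of = {l.bgc_id: l.species_id for l in network_loci if not l.is_reference}
    ref_flags = {l.bgc_id: l.is_reference for l in network_loci}

    distances = all_pair_distances(
        inventories,
        weights=config.weights,
        anchor_weight=config.anchor_weight,
        scheme=scheme,
    )
    networks: Dict[float, Tuple[List[PairDistance], List[GCF]]] = {}
    for cutoff in sorted(config.cutoffs):
        edges, gcfs = build_network(
            inventories, cutoff, distances=distances, species_of=species_of
        )
        gcfs = prune_reference_only(gcfs, ref_flags)
        networks[cutoff] = (edges, gcfs)

    class_table = class_count_table(classified)
    default_gcfs = networks[config.default_cutoff][1]
    presence = presence_matrix(default_gcfs, species)
    summary = summary_stats(classified, default_gcfs, species)
    summary["default_cutoff"] = config.default_cutoff

    result = PipelineResult(
        genomes=genomes,
        classified=classified,
        inventories=inventories,
        distances=distances,
        networks=networks,
        class_table=class_table,
        presence=presence,
        summary=summary,
    )
    if write:
        _write_bundle(result, config)
    return result


def _write_bundle(result: PipelineResult, config: PipelineConfig) -> None:
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(out, "params.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    result.class_table.to_csv(os.path.join(out, "class_table.tsv"), sep="\t")

    loci_rows = []
    trace_rows = {}
    for sp in sorted(result.classified):
        for cl in result.classified[sp]:
            l = cl.locus
            loci_rows.append(
                {
                    "bgc_id": l.bgc_id,
                    "species_id": l.species_id,
                    "contig_id": l.contig_id,
                    "start": l.start,
                    "end": l.end,
                    "n_genes": l.n_genes,
                    "bgc_class": cl.bgc_class,
                    "counted": cl.counted,
                    "core_genes": ",".join(sorted(l.core_gene_ids)),
                    "gene_ids": ",".join(l.gene_ids),
                }
            )
            trace_rows[l.bgc_id] = {"class": cl.bgc_class, "rule": cl.rule}
    pd.DataFrame(loci_rows).to_csv(os.path.join(out, "loci.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "rule_trace.json"), "w") as fh:
        json.dump(trace_rows, fh, indent=2, sort_keys=True)

    loci_dir = os.path.join(out, "loci_gff")
    os.makedirs(loci_dir, exist_ok=True)
    for sp in sorted(result.classified):
        write_bgc_gff(
            [cl.locus for cl in result.classified[sp]],
            os.path.join(loci_dir, f"{sp}.bgc.gff3"),
        )

    for cutoff, (edges, gcfs) in sorted(result.networks.items()):
        tag = f"{cutoff:.2f}"
        pd.DataFrame(
            [
                {
                    "bgc1": e.bgc1,
                    "bgc2": e.bgc2,
                    "JI": round(e.ji, 6),
                    "DSI": round(e.dsi, 6),
                    "AI": round(e.ai, 6),
                    "distance": round(e.distance, 6),
                }
                for e in sorted(edges, key=lambda e: (e.bgc1, e.bgc2))
            ]
        ).to_csv(os.path.join(out, f"edges_c{tag}.tsv"), sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "gcf_id": g.gcf_id,
                    "cutoff": g.cutoff,
                    "n_members": len(g.members),
                    "species": ",".join(sorted(g.species)),
                    "members": ",".join(g.members),
                }
                for g in gcfs
            ]
        ).to_csv(os.path.join(out, f"gcf_c{tag}.tsv"), sep="\t", index=False)
        export_graphml(
            result.inventories,
            edges,
            os.path.join(out, f"network_c{tag}.graphml"),
        )

    result.presence.to_csv(os.path.join(out, "presence_matrix.tsv"), sep="\t")
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
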