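"""Annotated-genome I/O and the coordinate/identifier model.

Coordinates are 1-based inclusive throughout (GenBank convention); GFF3 is
already 1-based so its reader converts nothing.  Within a contig, genes are
kept ordered by start, tie-broken by end then ``gene_id``; genes wholly
contained in other genes are retained as distinct entries.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Gene",
    "Genome",
    "DomainAnnotationTable",
    "GenomeIOError",
    "read_genbank",
    "read_gff_fasta",
    "read_domain_table",
    "write_bgc_gff",
    "read_bgc_gff",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class GenomeIOError(ValueError):
    """Raised for malformed or inconsistent genome input."""


@dataclass(frozen=True)
class Gene:
    """One protein-coding gene (CDS) on a contig.

    ``start``/``end`` are 1-based inclusive nucleotide positions of the full
    CDS span on the contig; ``protein`` is the translated product with the
    terminal stop trimmed and internal stops rendered as ``X``.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeIOError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in "+-":
            raise GenomeIOError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if len(self.protein) < 1:
            raise GenomeIOError(f"gene {self.gene_id}: empty protein")
        bad = set(self.protein) - AA_ALPHABET
        if bad:
            raise GenomeIOError(
                f"gene {self.gene_id}: non-amino-acid letters {sorted(bad)}"
            )

    @property
    def span_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class Genome:
    """An annotated genome: per-contig gene lists ordered by start."""

    species_id: str
    contigs: Dict[str, List[Gene]] = field(default_factory=dict)
    contig_seqs: Dict[str, str] = field(default_factory=dict)
    metadata: Dict[str, object] = field(default_factory=dict)

    def add_gene(self, gene: Gene) -> None:
        self.contigs.setdefault(gene.contig_id, []).append(gene)

    def finalize(self) -> "Genome":
        seen: set[str] = set()
        for cid, genes in self.contigs.items():
            genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
            for g in genes:
                if g.gene_id in seen:
                    raise GenomeIOError(f"duplicate gene_id {g.gene_id}")
                seen.add(g.gene_id)
        return self

    @property
    def genes(self) -> List[Gene]:
        out: List[Gene] = []
        for cid in sorted(self.contigs):
            out.extend(self.contigs[cid])
        return out

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.contigs.values())


#: column order of the domain side-car TSV
DOMAIN_TABLE_COLUMNS = ["gene_id", "domain", "start", "end", "score"]


@dataclass
class DomainAnnotationTable:
    """Pre-computed per-gene domain annotations (stand-in for an HMM scan)."""

    rows: pd.DataFrame

    def for_gene(self, gene_id: str) -> pd.DataFrame:
        return self.rows[self.rows.gene_id == gene_id]

    def covers(self, gene_id: str) -> bool:
        return bool((self.rows.gene_id == gene_id).any())

    def __len__(self) -> int:
        return len(self.rows)


def _translate_cds(nt: str, gene_id: str) -> str:
    """Standard-code translation; trims one terminal stop, X at internal stops."""
    prot = str(Seq(nt).translate(table=1))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        import warnings

        warnings.warn(f"gene {gene_id}: internal stop codon(s), kept as X")
        prot = prot.replace("*", "X")
    return prot


def read_genbank(path: str, species_id: Optional[str] = None) -> Genome:
    """Read a GenBank flat file into a :class:`Genome` (one Gene per CDS)."""
    records = list(SeqIO.parse(path, "genbank"))
    if not records:
        raise GenomeIOError(f"{path}: no records")
    sp = species_id or os.path.splitext(os.path.basename(path))[0]
    genome = Genome(species_id=sp)
    counter = 0
    for rec in records:
        genome.contig_seqs[rec.id] = str(rec.seq)
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            counter += 1
            quals = feat.qualifiers
            gene_id = (
                quals.get("locus_tag", quals.get("gene", [f"cds{counter:05d}"]))[0]
            )
            strand = "-" if feat.location.strand == -1 else "+"
            start = int(feat.location.start) + 1  # to 1-based inclusive
            end = int(feat.location.end)
            if "translation" in quals:
                prot = quals["translation"][0]
            else:
                nt = str(feat.extract(rec.seq))
                prot = _translate_cds(nt, gene_id)
            genome.add_gene(
                Gene(
                    gene_id=gene_id,
                    contig_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    protein=prot,
                    product=quals.get("product", [""])[0],
                )
            )
    return genome.finalize()


def read_gff_fasta(gff: str, fasta: str, species_id: Optional[str] = None) -> Genome:
    """Read GFF3 CDS features plus a genomic FASTA into a :class:`Genome`.

    Multi-exon CDS (same ID) are joined in feature order with phase respected;
    minus-strand proteins are translations of the reverse complement.
    """
    import gffutils

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta, "fasta")}
    sp = species_id or os.path.splitext(os.path.basename(gff))[0]
    genome = Genome(species_id=sp)
    genome.contig_seqs.update(seqs)

    try:
        db = gffutils.create_db(
            gff, ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except gffutils.exceptions.EmptyInputError:
        return genome.finalize()  # header-only GFF: zero genes
    by_id: Dict[str, List] = {}
    order: List[str] = []
    counter = 0
    for feat in db.all_features(featuretype="CDS", order_by=("seqid", "start")):
        counter += 1
        fid = feat.attributes.get("ID", [f"cds{counter:05d}"])[0]
        # gffutils may uniquify joined-CDS IDs; strip its _N suffix
        base = fid.rsplit("_", 1)
        if len(base) == 2 and base[1].isdigit() and base[0] in by_id:
            fid = base[0]
        if fid not in by_id:
            by_id[fid] = []
            order.append(fid)
        by_id[fid].append(feat)

    for fid in order:
        parts = sorted(by_id[fid], key=lambda f: f.start)
        contig = parts[0].seqid
        if contig not in seqs:
            raise GenomeIOError(f"CDS {fid} references absent contig {contig}")
        contig_seq = seqs[contig]
        for p in parts:
            if p.start < 1 or p.end > len(contig_seq):
                raise GenomeIOError(f"CDS {fid}: coordinates out of contig bounds")
        strand = parts[0].strand or "+"
        if strand == "-":
            ordered = parts[::-1]
            nt = "".join(
                str(Seq(contig_seq[p.start - 1 : p.end]).reverse_complement())
                for p in ordered
            )
        else:
            ordered = parts
            nt = "".join(contig_seq[p.start - 1 : p.end] for p in ordered)
        phase = ordered[0].frame
        if phase in ("0", "1", "2"):
            nt = nt[int(phase) :]
        prot = _translate_cds(nt, fid)
        product = parts[0].attributes.get("product", [""])[0]
        genome.add_gene(
            Gene(
                gene_id=fid,
                contig_id=contig,
                start=min(p.start for p in parts),
                end=max(p.end for p in parts),
                strand=strand,
                protein=prot,
                product=product,
            )
        )
    return genome.finalize()


def read_domain_table(path: str, vocab: Optional[Iterable[str]] = None) -> DomainAnnotationTable:
    """Read and validate the TSV domain side-car (gene_id, domain, start, end, score)."""
    if vocab is None:
        from .core_detection import DOMAIN_VOCAB as vocab  # noqa: PLC0415

    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"gene_id": str, "domain": str},
    )
    missing = set(DOMAIN_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise GenomeIOError(f"{path}: missing columns {sorted(missing)}")
    if len(df):
        unknown = set(df.domain) - set(vocab)
        if unknown:
            raise GenomeIOError(
                f"{path}: unknown domain name(s) {sorted(unknown)}; "
                f"vocabulary: {sorted(vocab)}"
            )
        if (df.end < df.start).any() or (df.start < 1).any():
            raise GenomeIOError(f"{path}: rows with end < start or start < 1")
    df = df.sort_values(["gene_id", "start"], kind="stable").reset_index(drop=True)
    return DomainAnnotationTable(rows=df[DOMAIN_TABLE_COLUMNS])


def write_domain_table(table: DomainAnnotationTable, path: str) -> None:
    table.rows.to_csv(path, sep="\t", index=False)


def write_bgc_gff(loci, path: str) -> None:
    """Write loci as GFF3: one ``biosynthetic_gene_cluster`` feature per locus
    plus child ``gene`` features carrying the translation."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            start = min(g.start for g in locus.genes)
            end = max(g.end for g in locus.genes)
            attrs = (
                f"ID={locus.bgc_id};species={locus.species_id};"
                f"bgc_class={locus.bgc_class or '.'};"
                f"core_genes={','.join(sorted(locus.core_gene_ids))}"
            )
            fh.write(
                f"{locus.contig_id}\tbgcmine\tbiosynthetic_gene_cluster\t"
                f"{start}\t{end}\t.\t+\t.\t{attrs}\n"
            )
            for g in locus.genes:
                role = locus.gene_roles.get(g.gene_id, "unrelated")
                gattrs = (
                    f"ID={g.gene_id};Parent={locus.bgc_id};role={role};"
                    f"translation={g.protein}"
                )
                fh.write(
                    f"{g.contig_id}\tbgcmine\tgene\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{gattrs}\n"
                )


def read_bgc_gff(path: str):
    """Round-trip reader for :func:`write_bgc_gff` output."""
    from .bgc_assembly import BGCLocus

    loci: List = []
    genes_by_parent: Dict[str, List[Gene]] = {}
    roles_by_parent: Dict[str, Dict[str, str]] = {}
    meta: Dict[str, dict] = {}
    order: List[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            if cols[2] == "biosynthetic_gene_cluster":
                bid = attrs["ID"]
                order.append(bid)
                meta[bid] = {
                    "contig": cols[0],
                    "species": attrs.get("species", ""),
                    "class": attrs.get("bgc_class", "."),
                    "cores": set(attrs.get("core_genes", "").split(","))
                    - {""},
                }
            elif cols[2] == "gene":
                parent = attrs["Parent"]
                g = Gene(
                    gene_id=attrs["ID"],
                    contig_id=cols[0],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    protein=attrs["translation"],
                )
                genes_by_parent.setdefault(parent, []).append(g)
                roles_by_parent.setdefault(parent, {})[g.gene_id] = attrs.get(
                    "role", "unrelated"
                )
    for bid in order:
        genes = sorted(genes_by_parent.get(bid, []), key=lambda g: g.start)
        m = meta[bid]
        loci.append(
            BGCLocus(
                bgc_id=bid,
                species_id=m["species"],
                contig_id=m["contig"],
                genes=genes,
                core_gene_ids=m["cores"],
                gene_roles=roles_by_parent.get(bid, {}),
                bgc_class=None if m["class"] == "." else m["class"],
            )
        )
    return loci
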