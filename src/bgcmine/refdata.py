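"""Bundled reference libraries.

Three libraries ship with the package, regenerated deterministically by
``scripts/build_refdata.py``:

* core-enzyme template library (``templates.synthetic.fasta`` + manifest TSV
  with accession/name/organism/target class metadata);
* per-domain reference panel (``domain_panel.synthetic.fasta``), one
  representative sequence per domain label;
* labelled function database (``function_db.synthetic.fasta`` + label TSV)
  standing in for a curated protein-function database.

All sequences are synthetic stand-ins (real template/database sequences are
not redistributable here); the template manifest carries the real accessions
and metadata, and the synthetic sequences are constructed so that the
pipeline's search logic behaves like the real one (e.g. the type I PKS
template is a full domain-string composite, the bifunctional copalyl
synthase template carries two cyclase domains).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Dict, List

from Bio import SeqIO

from .bgc_assembly import FunctionDB
from .core_detection import TemplateEnzyme

__all__ = [
    "load_domain_panel",
    "load_templates",
    "load_function_db",
]


def _data_path(name: str):
    return resources.files("bgcmine").joinpath("data", name)


def _read_fasta(name: str) -> Dict[str, str]:
    with resources.as_file(_data_path(name)) as path:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _read_tsv(name: str) -> List[Dict[str, str]]:
    with resources.as_file(_data_path(name)) as path:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            return [
                dict(zip(header, line.rstrip("\n").split("\t")))
                for line in fh
                if line.strip()
            ]


@lru_cache(maxsize=1)
def load_domain_panel() -> Dict[str, str]:
    """Domain label -> representative reference sequence."""
    return _read_fasta("domain_panel.synthetic.fasta")


@lru_cache(maxsize=1)
def load_templates() -> tuple:
    """The bundled core-enzyme template library."""
    seqs = _read_fasta("templates.synthetic.fasta")
    rows = _read_tsv("templates.tsv")
    return tuple(
        TemplateEnzyme(
            accession=r["accession"],
            name=r["name"],
            organism=r["organism"],
            target_class=r["target_class"],
            protein=seqs[r["accession"]],
        )
        for r in rows
    )


@lru_cache(maxsize=1)
def load_function_db() -> FunctionDB:
    """The bundled labelled function database."""
    seqs = _read_fasta("function_db.synthetic.fasta")
    rows = _read_tsv("function_db.tsv")
    return FunctionDB(
        entries=[(r["entry_id"], r["label"], seqs[r["entry_id"]]) for r in rows]
    )
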