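"""Regenerate the bundled synthetic reference libraries.

Writes the domain panel, core-enzyme template library and function database
under ``src/bgcmine/data/``.  All sequences are deterministic synthetic
stand-ins; the template manifest carries the real accession/name/organism
metadata.  Run from the repository root:

    python scripts/build_refdata.py
"""

from __future__ import annotations

import os

import numpy as np

from bgcmine.synthetic_data import make_protein, mutate_to_identity

ROOT_SEED = 20210826

PANEL_LENGTHS = {
    "SAT": 180, "KS": 300, "AT": 240, "PT": 200, "ACP": 70, "CMeT": 130,
    "DH": 150, "ER": 220, "KR": 200, "TE": 180, "R": 250, "C": 300, "A": 320,
    "T": 70, "E": 260, "GGPPS": 240, "TC": 260, "CS": 320, "FAS_alpha": 320,
    "FAS_beta": 320, "PTase": 240, "LSS": 340, "SHC": 340, "DMAT": 300,
    "GT": 280, "CDPS": 200,
}

# (entry_id, label, length) -- sequences for 'core_<domain>' entries are the
# panel sequences themselves; others are independent random proteins
FUNCTION_DB_EXTRA = [
    ("tail_p450", "tailoring", 400),
    ("tail_fmo", "tailoring", 380),
    ("tail_omt", "tailoring", 300),
    ("tail_ktr", "tailoring", 280),
    ("tail_acyl", "tailoring", 340),
    ("tail_oxred", "tailoring", 360),
    ("tail_halo", "tailoring", 320),
    ("tail_hydrolase", "tailoring", 300),
    ("reg_zn2c6", "regulatory", 320),
    ("reg_bzip", "regulatory", 280),
    ("reg_c2h2", "regulatory", 300),
    ("trans_mfs", "transport", 420),
    ("trans_abc", "transport", 520),
    ("trans_mate", "transport", 380),
    ("res_efflux", "resistance", 360),
    ("res_target", "resistance", 300),
    ("hk_actin", "housekeeping", 375),
    ("hk_tubulin", "housekeeping", 445),
    ("hk_ef1a", "housekeeping", 460),
    ("hk_gapdh", "housekeeping", 335),
    ("hk_rps", "housekeeping", 180),
    ("hk_histone", "housekeeping", 135),
]

# Table rows of the real template manifest: accession, name, organism,
# target class, and the recipe for the synthetic stand-in sequence.
TEMPLATES = [
    ("APH07629", "orsellinic acid synthase PKS1", "Agaricomycetes sp.", "typeI_PKS"),
    ("XP_960427", "chalcone synthase", "Neurospora crassa", "typeIII_PKS"),
    ("S3DQP3", "A1 domain of nonribosomal peptide synthetase GloA", "Glarea lozoyensis", "NRPS_family"),
    ("AHY23922", "1,8-cineole synthase", "Hypoxylon sp.", "terpene"),
    ("AWM95795", "humulene synthase Asr6", "Sarocladium sp.", "terpene"),
    ("Q6WP50", "presilphiperfolan-8-beta-ol synthase Bot2", "Botrytis cinerea", "terpene"),
    ("QOE88883", "brasilane synthase BraA", "Annulohypoxylon truncatum", "terpene"),
    ("C9K2Q3", "fusicoccadiene synthase", "Alternaria brassicicola", "terpene"),
    ("A0A1B4XBG5", "cycloaraneosene synthase SdnA", "Sordaria araneosa", "terpene"),
    ("B2DBF1", "copalyl diphosphate synthase", "Diaporthe amygdali", "terpene"),
    ("P38604", "lanosterol synthase Erg7", "Saccharomyces cerevisiae", "terpene"),
    ("QOV03404", "citrate synthase SpoE", "Hypomontagnella monticulosa", "alkyl_citrate"),
    ("D4D449", "tryptophan dimethylallyltransferase", "Trichophyton verrucosum", "alkaloid_DMAT"),
    ("AMR44282", "phomopsin precursor PhomA", "Diaporthe leptostromiformis", "RiPP_precursor"),
    ("OphMA", "omphalotin precursor OphMA", "Omphalotus olearius", "RiPP_precursor"),
    ("ACB30126", "epichloecyclin precursor GigA", "Epichloe festucae", "RiPP_precursor"),
]


def write_fasta(path: str, entries) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def main() -> None:
    out = os.path.join(os.path.dirname(__file__), "..", "src", "bgcmine", "data")
    out = os.path.abspath(out)
    os.makedirs(out, exist_ok=True)
    rng = np.random.default_rng(ROOT_SEED)

    panel = {}
    for dom in sorted(PANEL_LENGTHS):
        panel[dom] = make_protein(PANEL_LENGTHS[dom], rng)
    # SHC is a squalene-hopene-type cyclase: related to (detectable via) the
    # lanosterol synthase template, so derive it rather than draw it fresh
    panel["SHC"] = mutate_to_identity(panel["LSS"], 0.55, rng)

    write_fasta(
        os.path.join(out, "domain_panel.synthetic.fasta"),
        [(d, panel[d]) for d in sorted(panel)],
    )
    with open(os.path.join(out, "domain_panel.tsv"), "w") as fh:
        fh.write("domain\tlength\n")
        for d in sorted(panel):
            fh.write(f"{d}\t{len(panel[d])}\n")

    def flank(n: int) -> str:
        return make_protein(n, rng)

    tmpl_seqs = {
        "APH07629": "".join(panel[d] for d in ("SAT", "KS", "AT", "PT", "ACP", "CMeT", "TE")),
        "XP_960427": make_protein(360, rng),
        "S3DQP3": panel["A"] + flank(60),
        "AHY23922": panel["TC"] + flank(50),
        "AWM95795": mutate_to_identity(panel["TC"], 0.8, rng) + flank(50),
        "Q6WP50": mutate_to_identity(panel["TC"], 0.75, rng) + flank(50),
        "QOE88883": mutate_to_identity(panel["TC"], 0.7, rng) + flank(50),
        "C9K2Q3": mutate_to_identity(panel["TC"], 0.8, rng) + flank(50),
        "A0A1B4XBG5": mutate_to_identity(panel["TC"], 0.75, rng) + flank(50),
        "B2DBF1": mutate_to_identity(panel["TC"], 0.85, rng)
        + flank(30)
        + mutate_to_identity(panel["TC"], 0.7, rng),
        "P38604": panel["LSS"] + flank(40),
        "QOV03404": panel["CS"] + flank(50),
        "D4D449": panel["DMAT"] + flank(40),
        "AMR44282": make_protein(60, rng),
        "OphMA": make_protein(70, rng),
        "ACB30126": make_protein(64, rng),
    }
    write_fasta(
        os.path.join(out, "templates.synthetic.fasta"),
        [(acc, tmpl_seqs[acc]) for acc, *_ in TEMPLATES],
    )
    with open(os.path.join(out, "templates.tsv"), "w") as fh:
        fh.write("accession\tname\torganism\ttarget_class\n")
        for acc, name, org, cls in TEMPLATES:
            fh.write(f"{acc}\t{name}\t{org}\t{cls}\n")

    fdb_entries = [(f"core_{d}", "core", panel[d]) for d in sorted(panel)]
    fdb_entries.append(("core_typeIII", "core", tmpl_seqs["XP_960427"]))
    fdb_entries.append(("core_ripp_precursor", "core", tmpl_seqs["AMR44282"]))
    for eid, label, length in FUNCTION_DB_EXTRA:
        fdb_entries.append((eid, label, make_protein(length, rng)))
    write_fasta(
        os.path.join(out, "function_db.synthetic.fasta"),
        [(eid, seq) for eid, _, seq in fdb_entries],
    )
    with open(os.path.join(out, "function_db.tsv"), "w") as fh:
        fh.write("entry_id\tlabel\n")
        for eid, label, _ in fdb_entries:
            fh.write(f"{eid}\t{label}\n")
    print(f"wrote reference data to {out}")


if __name__ == "__main__":
    main()
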