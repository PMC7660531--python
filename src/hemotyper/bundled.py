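"""Bundled toy allele database.

A small, openly transcribed database covering the nine blood-group systems
KEL, FY (ACKR1), JK (SLC14A1), YT (ACHE), DO (ART4), CO (AQP1), IN (CD44),
DI (SLC4A1) and LW (ICAM4): the 14 SNaPshot-assayed bi-allelic positions
plus SLC14A1 c.130G>A (the defining SNV of the weak Kidd allele JK*01W.01),
and the ISBT alleles needed to type every genotype at those positions,
including the FY promoter (GATA-box) null allele and the cis/trans-ambiguous
FY*02N.01 / FY*01N.01+FY*02 configuration that read-backed phasing resolves.

Gene references are synthetic: deterministically generated sequences with a
realistic layout (5' flank containing the promoter, a two-exon CDS, one
intron, an in-exon 3' UTR and a 3' flank), carrying the documented reference
base at every variable position.  Real ISBT tables cover hundreds to
thousands of positions per system; a full-scale table in the same TSV format
loads through :func:`hemotyper.db.load_database`.
"""

from __future__ import annotations

import random
from pathlib import Path

from .db import (
    AlleleDatabase,
    AlleleDefinition,
    GeneReference,
    VariablePosition,
    cdna_to_gene_pos,
    gene_pos_to_cdna,
    write_database,
)

# layout constants (bases)
UPSTREAM = 450   # 5' flank; keeps promoter SNPs far enough from the gene
INTRON = 180     # edge for full read-pair coverage in simulations
DOWNSTREAM = 350

#: gene -> (ISBT system, CDS length, 3' UTR bases kept inside the last exon)
_GENE_PLAN: dict[str, tuple[str, int, int]] = {
    "KEL": ("KEL", 1830, 60),
    "ACKR1": ("FY", 300, 60),
    "SLC14A1": ("JK", 870, 60),
    "ACHE": ("YT", 1080, 60),
    "ART4": ("DO", 810, 60),
    "CD44": ("IN", 150, 90),   # longer 3' UTR: post-stop exonic variants occur here
    "AQP1": ("CO", 150, 60),
    "SLC4A1": ("DI", 2568, 60),
    "ICAM4": ("LW", 312, 60),
}

#: gene -> list of (cDNA label, region)
_POSITIONS: dict[str, list[tuple[str, str]]] = {
    "KEL": [("c.578C>T", "exon"), ("c.1790T>C", "exon")],
    "ACKR1": [("c.-67T>C", "promoter"), ("c.125G>A", "exon"), ("c.265C>T", "exon")],
    "SLC14A1": [("c.130G>A", "exon"), ("c.838G>A", "exon")],
    "ACHE": [("c.1057C>A", "exon")],
    "ART4": [("c.323G>T", "exon"), ("c.350C>T", "exon"), ("c.793A>G", "exon")],
    "CD44": [("c.137G>C", "exon")],
    "AQP1": [("c.134C>T", "exon")],
    "SLC4A1": [("c.2561C>T", "exon")],
    "ICAM4": [("c.299A>G", "exon")],
}

#: gene -> allele name -> {cDNA label: alt base}; {} marks the reference allele
_ALLELES: dict[str, dict[str, dict[str, str]]] = {
    "KEL": {
        "KEL*02": {},
        "KEL*01": {"c.578C>T": "T"},
        "KEL*02.06": {"c.1790T>C": "C"},
    },
    "ACKR1": {
        "FY*01": {},
        "FY*02": {"c.125G>A": "A"},
        "FY*01N.01": {"c.-67T>C": "C"},
        "FY*02N.01": {"c.-67T>C": "C", "c.125G>A": "A"},
        "FY*01W.01": {"c.265C>T": "T"},
    },
    "SLC14A1": {
        "JK*01": {},
        "JK*02": {"c.838G>A": "A"},
        "JK*01W.01": {"c.130G>A": "A"},
    },
    "ACHE": {"YT*01": {}, "YT*02": {"c.1057C>A": "A"}},
    "ART4": {
        "DO*01": {},
        "DO*02": {"c.793A>G": "G"},
        "DO*02.-04": {"c.793A>G": "G", "c.323G>T": "T"},
        "DO*01.-05": {"c.350C>T": "T"},
    },
    "CD44": {"IN*02": {}, "IN*01": {"c.137G>C": "C"}},
    "AQP1": {"CO*01": {}, "CO*02": {"c.134C>T": "T"}},
    "SLC4A1": {"DI*02": {}, "DI*01": {"c.2561C>T": "T"}},
    "ICAM4": {"LW*05": {}, "LW*07": {"c.299A>G": "G"}},
}

#: the 14 SNaPshot polymorphisms, keyed by their printed label
TABLE1_POLYMORPHISMS: dict[str, tuple[str, str]] = {
    "KEL (578C>T)": ("KEL", "c.578C>T"),
    "KEL (1790T>C)": ("KEL", "c.1790T>C"),
    "ACKR1 (-67T>C)": ("ACKR1", "c.-67T>C"),
    "ACKR1 (125G>A)": ("ACKR1", "c.125G>A"),
    "ACKR1 (265C>T)": ("ACKR1", "c.265C>T"),
    "SLC14A1 (838G>A)": ("SLC14A1", "c.838G>A"),
    "ACHE (1057C>A)": ("ACHE", "c.1057C>A"),
    "ART4 (793A>G)": ("ART4", "c.793A>G"),
    "ART4 (323G>T)": ("ART4", "c.323G>T"),
    "ART4 (350C>T)": ("ART4", "c.350C>T"),
    "CD44 (137G>C)": ("CD44", "c.137G>C"),
    "AQP1 (134C>T)": ("AQP1", "c.134C>T"),
    "SLC4A1 (2561C>T)": ("SLC4A1", "c.2561C>T"),
    "ICAM4 (299A>G)": ("ICAM4", "c.299A>G"),
}


def _parse_label(label: str) -> tuple[int, str, str]:
    body = label[2:]
    i = 1 if body[0] == "-" else 0
    while body[i].isdigit():
        i += 1
    return int(body[:i]), body[i], body[i + 2]


def _build_gene(gene_id: str) -> GeneReference:
    isbt, cds_len, utr3 = _GENE_PLAN[gene_id]
    exon1_len = (cds_len // 2 // 3) * 3
    exon1 = (UPSTREAM, UPSTREAM + exon1_len)
    exon2_start = exon1[1] + INTRON
    exon2 = (exon2_start, exon2_start + (cds_len - exon1_len) + utr3)
    length = exon2[1] + DOWNSTREAM

    rng = random.Random(f"hemotyper-reference:{gene_id}")
    seq = [rng.choice("ACGT") for _ in range(length)]

    # terminal stop codon at the end of the CDS
    stop_at = exon2[0] + (cds_len - exon1_len) - 3
    seq[stop_at : stop_at + 3] = "TAA"

    for label, _region in _POSITIONS[gene_id]:
        n, ref, _alt = _parse_label(label)
        if n < 0:
            pos = UPSTREAM + n
        else:
            remaining = n - 1
            pos = (
                exon1[0] + remaining
                if remaining < exon1_len
                else exon2[0] + (remaining - exon1_len)
            )
        seq[pos] = ref
    return GeneReference(gene_id, isbt, "".join(seq), (exon1, exon2), 0, cds_len)


def bundled_database() -> AlleleDatabase:
    """Construct the toy database in memory (deterministic)."""
    genes = {gid: _build_gene(gid) for gid in _GENE_PLAN}
    positions: list[VariablePosition] = []
    for gid, rows in _POSITIONS.items():
        for label, region in rows:
            _n, ref, alt = _parse_label(label)
            pos = cdna_to_gene_pos(genes[gid], label)
            positions.append(
                VariablePosition(gid, pos, label, ref, frozenset({alt}), region)
            )
    alleles = {
        gid: [
            AlleleDefinition(
                name,
                gid,
                {cdna_to_gene_pos(genes[gid], lbl): base for lbl, base in states.items()},
            )
            for name, states in defs.items()
        ]
        for gid, defs in _ALLELES.items()
    }
    return AlleleDatabase(genes, positions, alleles)


def write_bundled_database(out_dir: str | Path) -> dict[str, Path]:
    """Write the toy database to TSV + FASTA + sidecar under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "db": out_dir / "blood_groups.tsv",
        "fasta": out_dir / "references.fasta",
        "annot": out_dir / "references.bed",
    }
    write_database(bundled_database(), paths["db"], paths["fasta"], paths["annot"])
    return paths


__all__ = [
    "TABLE1_POLYMORPHISMS",
    "bundled_database",
    "write_bundled_database",
    "gene_pos_to_cdna",
]
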