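"""Cohort screen for polymorphisms absent from the allele database.

A non-catalogued SNV is reported when, among samples whose pileup depth at
the site is at least ``min_depth`` (default 10 reads) and whose genotype
call there carries the variant allele (het or hom-alt, using the same
caller as typing so a lone erroneous read never creates a carrier), the
number of carrier samples reaches ``min_samples`` (default 5).  Carriers
are counted as distinct samples, not supporting reads.

Exonic variants are annotated by translating the affected codon with and
without the variant (standard nuclear code); exonic positions downstream
of the stop codon are classed ``post_stop``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio.Seq import Seq

from .align import call_genotype
from .db import AlleleDatabase, GeneReference

_ROWS = "ACGT"


@dataclass(frozen=True)
class CohortVariant:
    """A recurrent non-database SNV found in the cohort."""

    gene_id: str
    gene_pos: int
    ref_base: str
    alt_base: str
    n_carriers: int
    carrier_depths: Mapping[str, int]
    region: str  # exon | intron
    effect: str  # synonymous | non_synonymous | non_coding | post_stop

    def __post_init__(self) -> None:
        object.__setattr__(self, "carrier_depths", dict(self.carrier_depths))

    @property
    def carriers(self) -> frozenset[str]:
        return frozenset(self.carrier_depths)


def annotate_effect(gene: GeneReference, gene_pos: int, ref_base: str, alt_base: str) -> str:
    """Coding-effect class of a substitution on one gene."""
    if not 0 <= gene_pos < gene.length:
        raise ValueError(f"position {gene_pos} outside {gene.gene_id}")
    idx = gene.cds_index(gene_pos)
    if idx is None:
        return "non_coding"
    cds_idx = idx - gene.cds_start_phase
    if cds_idx < 0:
        return "non_coding"
    if cds_idx >= gene.cds_len - gene.cds_start_phase:
        return "post_stop"
    cds = gene.coding_sequence()
    codon_i = cds_idx // 3
    codon = list(cds[codon_i * 3 : codon_i * 3 + 3])
    if len(codon) < 3:
        return "non_coding"  # trailing partial codon in a malformed CDS
    within = cds_idx % 3
    if codon[within] != ref_base:
        raise ValueError(
            f"{gene.gene_id}:{gene_pos}: ref base {ref_base} does not match CDS"
        )
    aa_ref = str(Seq("".join(codon)).translate())
    codon[within] = alt_base
    aa_alt = str(Seq("".join(codon)).translate())
    return "synonymous" if aa_ref == aa_alt else "non_synonymous"


def _region(gene: GeneReference, gene_pos: int) -> str:
    for start, end in gene.exons:
        if start <= gene_pos < end:
            return "exon"
    return "intron"


def screen_cohort(
    sample_pileups: Mapping[str, Mapping[str, np.ndarray]],
    db: AlleleDatabase,
    min_depth: int = 10,
    min_samples: int = 5,
    het_min: float = 0.2,
    hom_max: float = 0.1,
    carrier_mode: str = "caller",
) -> list[CohortVariant]:
    """Screen full-gene cohort pileups for recurrent non-database SNVs.

    ``sample_pileups`` maps sample id -> gene id -> 4 x L base-count matrix
    (rows A/C/G/T) as produced by :func:`hemotyper.align.full_pileup`.
    One record is emitted per (position, alt base) pair.

    ``carrier_mode`` "caller" (default) requires the variant to pass the
    het/hom genotype caller; "presence" counts any sample with at least
    one variant-supporting read at sufficient depth.
    """
    if carrier_mode not in {"caller", "presence"}:
        raise ValueError(f"unknown carrier_mode {carrier_mode!r}")
    carriers: dict[tuple[str, int, str], dict[str, int]] = {}
    for gene_id in db.gene_ids():
        gene = db.genes[gene_id]
        ref_arr = np.frombuffer(gene.sequence.encode(), dtype=np.uint8)
        ref_codes = np.searchsorted(np.frombuffer(b"ACGT", dtype=np.uint8), ref_arr)
        db_positions = set(db.positions_for_gene(gene_id))
        for sample_id, mats in sample_pileups.items():
            mat = mats.get(gene_id)
            if mat is None:
                continue
            total = mat.sum(axis=0)
            ref_counts = mat[ref_codes, np.arange(mat.shape[1])]
            candidate = np.nonzero((total - ref_counts) > 0)[0]
            for pos in candidate:
                if int(total[pos]) < min_depth or int(pos) in db_positions:
                    continue
                counts = {b: int(mat[i, pos]) for i, b in enumerate(_ROWS) if mat[i, pos]}
                ref_base = gene.sequence[pos]
                if carrier_mode == "presence":
                    variant_bases = [b for b in counts if b != ref_base]
                else:
                    call = call_genotype(gene_id, int(pos), counts, ref_base,
                                         min_depth=min_depth, het_min=het_min,
                                         hom_max=hom_max)
                    variant_bases = [b for b in call.alleles if b != ref_base]
                for base in variant_bases:
                    key = (gene_id, int(pos), base)
                    carriers.setdefault(key, {})[sample_id] = int(total[pos])

    out = []
    for (gene_id, pos, alt), depth_by_sample in sorted(carriers.items()):
        if len(depth_by_sample) < min_samples:
            continue
        gene = db.genes[gene_id]
        ref_base = gene.sequence[pos]
        region = _region(gene, pos)
        effect = annotate_effect(gene, pos, ref_base, alt) if region == "exon" else "non_coding"
        out.append(
            CohortVariant(gene_id, pos, ref_base, alt, len(depth_by_sample),
                          depth_by_sample, region, effect)
        )
    return out


def write_novel_tsv(variants, path: str | Path) -> None:
    """S5/S6-shaped report: gene, 1-based position, ref, alt, carriers,
    region, effect."""
    with open(path, "w") as fh:
        fh.write("gene\tposition\tref\talt\tn_carriers\tregion\teffect\n")
        for v in variants:
            fh.write(f"{v.gene_id}\t{v.gene_pos + 1}\t{v.ref_base}\t{v.alt_base}\t"
                     f"{v.n_carriers}\t{v.region}\t{v.effect}\n")
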