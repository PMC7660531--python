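"""Blood-group allele-definition database.

The database catalogues, per gene, the variable positions that distinguish
blood-group alleles (ISBT nomenclature, e.g. ``JK*01W.01``) and the alleles
themselves, each defined as the set of base states it carries at those
positions.  Genotype calling, phasing and diplotype assignment all operate
against this catalogue.

Coordinates are 0-based half-open internally.  cDNA labels (``c.838G>A``,
``c.-67T>C``) follow HGVS display conventions: position 1 is the first base
of the CDS, negative positions count upstream of the CDS start.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")

_CDNA_RE = re.compile(r"^c\.(-?\d+)([ACGT])>([ACGT])$")


class DatabaseError(ValueError):
    """Raised when an allele database violates its invariants."""


@dataclass(frozen=True)
class GeneReference:
    """A single-gene reference sequence with exon/CDS annotation.

    ``exons`` are disjoint, ordered half-open intervals in gene coordinates.
    The CDS starts at the first base of the first exon; ``cds_len`` is the
    number of coding bases in the exon concatenation (the remainder of the
    last exon, if any, is 3' UTR — exonic but downstream of the stop codon).
    """

    gene_id: str
    isbt_system: str
    sequence: str
    exons: tuple[tuple[int, int], ...]
    cds_start_phase: int = 0
    cds_len: int | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if set(seq) - VALID_BASES:
            raise DatabaseError(f"{self.gene_id}: non-ACGT base in reference")
        prev_end = 0
        for start, end in self.exons:
            if not (0 <= start < end <= len(seq)):
                raise DatabaseError(f"{self.gene_id}: exon [{start},{end}) out of bounds")
            if start < prev_end:
                raise DatabaseError(f"{self.gene_id}: exons overlap or are unordered")
            prev_end = end
        exonic = sum(e - s for s, e in self.exons)
        if self.cds_len is None:
            object.__setattr__(self, "cds_len", exonic)
        if not 0 <= self.cds_start_phase <= 2:
            raise DatabaseError(f"{self.gene_id}: cds_start_phase must be 0-2")
        if self.cds_len > exonic:
            raise DatabaseError(f"{self.gene_id}: cds_len exceeds exonic length")
        if self.cds_start_phase == 0 and self.cds_len % 3 != 0:
            raise DatabaseError(f"{self.gene_id}: CDS length {self.cds_len} not a multiple of 3")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds_start(self) -> int:
        return self.exons[0][0]

    def cds_index(self, gene_pos: int) -> int | None:
        """0-based index within the exon concatenation, or None if intronic/
        intergenic."""
        offset = 0
        for start, end in self.exons:
            if start <= gene_pos < end:
                return offset + (gene_pos - start)
            offset += end - start
        return None

    def coding_sequence(self) -> str:
        """Concatenated exonic sequence truncated to the CDS."""
        cat = "".join(self.sequence[s:e] for s, e in self.exons)
        return cat[self.cds_start_phase : self.cds_len]


@dataclass(frozen=True)
class VariablePosition:
    """A catalogued polymorphic site on a gene reference."""

    gene_id: str
    gene_pos: int
    cdna_label: str
    ref_base: str
    alt_bases: frozenset[str]
    region: str  # exon | intron | utr | promoter

    def __post_init__(self) -> None:
        object.__setattr__(self, "alt_bases", frozenset(self.alt_bases))
        if self.ref_base not in VALID_BASES:
            raise DatabaseError(f"{self.gene_id}:{self.cdna_label}: bad ref base")
        if not self.alt_bases or not self.alt_bases <= VALID_BASES:
            raise DatabaseError(f"{self.gene_id}:{self.cdna_label}: bad alt bases")
        if self.ref_base in self.alt_bases:
            raise DatabaseError(f"{self.gene_id}:{self.cdna_label}: ref listed among alts")
        if self.region not in {"exon", "intron", "utr", "promoter"}:
            raise DatabaseError(f"{self.gene_id}:{self.cdna_label}: bad region {self.region!r}")

    @property
    def bases(self) -> frozenset[str]:
        return self.alt_bases | {self.ref_base}


@dataclass(frozen=True)
class AlleleDefinition:
    """An ISBT-named allele: the bases by which it deviates from (or is
    anchored to) the gene's reference allele, keyed by gene position."""

    allele_name: str
    gene_id: str
    variant_states: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant_states", dict(self.variant_states))


def cdna_to_gene_pos(gene: GeneReference, cdna_label: str) -> int:
    """Map an HGVS-style cDNA label to a 0-based gene offset.

    ``c.N`` (N >= 1) walks the exons from the CDS start; ``c.-N`` counts
    linearly upstream of the CDS start (promoter / 5' flank).
    """
    m = _CDNA_RE.match(cdna_label)
    if m is None:
        raise DatabaseError(f"malformed cDNA label {cdna_label!r}")
    n = int(m.group(1))
    ref = m.group(2)
    if n == 0:
        raise DatabaseError(f"{cdna_label!r}: cDNA position 0 does not exist")
    if n < 0:
        pos = gene.cds_start + n  # n is negative
        if pos < 0:
            raise DatabaseError(f"{cdna_label!r}: upstream of gene start")
    else:
        remaining = n - 1 + gene.cds_start_phase
        pos = None
        for start, end in gene.exons:
            if remaining < end - start:
                pos = start + remaining
                break
            remaining -= end - start
        if pos is None:
            raise DatabaseError(f"{cdna_label!r}: beyond exonic sequence of {gene.gene_id}")
    if gene.sequence[pos] != ref:
        raise DatabaseError(
            f"{cdna_label!r}: reference disagreement at {gene.gene_id} pos {pos} "
            f"(label says {ref}, sequence has {gene.sequence[pos]})"
        )
    return pos


def gene_pos_to_cdna(gene: GeneReference, gene_pos: int, alt: str) -> str:
    """Inverse of :func:`cdna_to_gene_pos` for upstream and exonic positions."""
    if not 0 <= gene_pos < gene.length:
        raise DatabaseError(f"gene_pos {gene_pos} outside {gene.gene_id}")
    ref = gene.sequence[gene_pos]
    if gene_pos < gene.cds_start:
        n = gene_pos - gene.cds_start  # negative
    else:
        idx = gene.cds_index(gene_pos)
        if idx is None:
            raise DatabaseError(f"no cDNA label for intronic position {gene_pos} of {gene.gene_id}")
        n = idx - gene.cds_start_phase + 1
    return f"c.{n}{ref}>{alt}"


class AlleleDatabase:
    """Immutable catalogue of gene references, variable positions and alleles."""

    def __init__(
        self,
        genes: Mapping[str, GeneReference],
        positions: Iterable[VariablePosition],
        alleles: Mapping[str, Iterable[AlleleDefinition]],
    ) -> None:
        self.genes: dict[str, GeneReference] = dict(genes)
        self.positions: dict[tuple[str, int], VariablePosition] = {}
        for vp in positions:
            key = (vp.gene_id, vp.gene_pos)
            if key in self.positions:
                raise DatabaseError(f"duplicate position {vp.gene_id}:{vp.gene_pos}")
            self.positions[key] = vp
        self.alleles: dict[str, tuple[AlleleDefinition, ...]] = {
            g: tuple(a) for g, a in alleles.items()
        }
        self._validate()
        self._sorted_pos: dict[str, list[int]] = {}
        for gene_id in self.genes:
            self._sorted_pos[gene_id] = sorted(
                p for (g, p) in self.positions if g == gene_id
            )

    def _validate(self) -> None:
        if not self.genes:
            raise DatabaseError("no genes defined")
        for (gene_id, pos), vp in self.positions.items():
            gene = self.genes.get(gene_id)
            if gene is None:
                raise DatabaseError(f"position references unknown gene {gene_id}")
            if not 0 <= pos < gene.length:
                raise DatabaseError(f"{gene_id}:{pos} outside gene bounds")
            if gene.sequence[pos] != vp.ref_base:
                raise DatabaseError(
                    f"{gene_id}:{pos}: ref base {vp.ref_base} does not match "
                    f"sequence base {gene.sequence[pos]}"
                )
        for gene_id, defs in self.alleles.items():
            if gene_id not in self.genes:
                raise DatabaseError(f"alleles reference unknown gene {gene_id}")
            seen: set[str] = set()
            for ad in defs:
                if ad.allele_name in seen:
                    raise DatabaseError(f"duplicate allele name {ad.allele_name}")
                seen.add(ad.allele_name)
                for pos, base in ad.variant_states.items():
                    vp = self.positions.get((gene_id, pos))
                    if vp is None:
                        raise DatabaseError(
                            f"{ad.allele_name}: state at unregistered position {pos}"
                        )
                    if base not in vp.bases:
                        raise DatabaseError(
                            f"{ad.allele_name}: base {base} not a known state at "
                            f"{gene_id}:{pos}"
                        )

    # -- queries ---------------------------------------------------------

    def gene_ids(self) -> list[str]:
        return sorted(self.genes)

    def positions_for_gene(self, gene_id: str) -> list[int]:
        return list(self._sorted_pos[gene_id])

    def position_count(self, gene_id: str) -> int:
        return len(self._sorted_pos[gene_id])

    @property
    def total_positions(self) -> int:
        return len(self.positions)

    def position_counts(self) -> dict[str, int]:
        return {g: self.position_count(g) for g in self.gene_ids()}

    def allele(self, gene_id: str, allele_name: str) -> AlleleDefinition:
        for ad in self.alleles.get(gene_id, ()):
            if ad.allele_name == allele_name:
                return ad
        raise KeyError(f"unknown allele {allele_name} for gene {gene_id}")

    def allele_names(self, gene_id: str) -> list[str]:
        return sorted(ad.allele_name for ad in self.alleles.get(gene_id, ()))

    def allele_base(self, gene_id: str, allele: AlleleDefinition | str, gene_pos: int) -> str:
        """Base carried by an allele at a registered position (reference base
        unless the allele explicitly deviates there)."""
        if isinstance(allele, str):
            allele = self.allele(gene_id, allele)
        if gene_pos in allele.variant_states:
            return allele.variant_states[gene_pos]
        return self.positions[(gene_id, gene_pos)].ref_base

    def reference_allele(self, gene_id: str) -> AlleleDefinition:
        """The allele carrying the reference base at every variable position;
        synthesized (named ``<gene>*REF``) if no listed allele qualifies."""
        if gene_id not in self.genes:
            raise KeyError(f"unknown gene {gene_id}")
        ref_states = {
            p: self.positions[(gene_id, p)].ref_base for p in self._sorted_pos[gene_id]
        }
        for ad in self.alleles.get(gene_id, ()):
            if all(base == ref_states[p] for p, base in ad.variant_states.items()):
                return ad
        return AlleleDefinition(f"{gene_id}*REF", gene_id, {})

    def haplotype_sequence(self, gene_id: str, allele: AlleleDefinition | str) -> str:
        """Full gene sequence carried by one allele (reference with the
        allele's variant states applied)."""
        if isinstance(allele, str):
            allele = self.allele(gene_id, allele)
        seq = list(self.genes[gene_id].sequence)
        for pos, base in allele.variant_states.items():
            seq[pos] = base
        return "".join(seq)

    def covering_positions(self, gene_id: str, start: int, end: int) -> list[int]:
        """Registered positions of a gene falling in [start, end)."""
        sp = self._sorted_pos[gene_id]
        lo = bisect_right(sp, start - 1)
        hi = bisect_right(sp, end - 1)
        return sp[lo:hi]


# -- file formats --------------------------------------------------------
#
# Database TSV: UTF-8, header, tab-separated columns
#   gene  label  gene_pos  ref  alt  alleles  region
# with alt a comma-separated set and alleles a semicolon-separated list of
# allele names carrying the alt at this row's position (multi-allelic rows
# use "name:base" entries to pick the alt).  Reference-anchored alleles
# (no deviations) are declared on a row with label "." and gene_pos -1.
#
# Gene references: multi-FASTA, ids matching the gene column.  Annotation
# sidecar: BED-like TSV (gene_id, start, end, cds_phase, feature) with
# feature CDS or UTR3; 0-based half-open.

_DB_COLUMNS = ["gene", "label", "gene_pos", "ref", "alt", "alleles", "region"]


def _read_annotation(annot_path: Path) -> dict[str, dict]:
    out: dict[str, dict] = {}
    with open(annot_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise DatabaseError(f"annotation sidecar: expected 5 columns, got {fields!r}")
            gene_id, start, end, phase, feature = fields
            rec = out.setdefault(gene_id, {"segments": [], "phase": int(phase)})
            rec["segments"].append((int(start), int(end), feature))
    return out


def _gene_from_annotation(gene_id: str, seq: str, annot: dict) -> GeneReference:
    segments = sorted(annot["segments"])
    exons: list[tuple[int, int]] = []
    cds_len = 0
    for start, end, feature in segments:
        if exons and start == exons[-1][1]:
            exons[-1] = (exons[-1][0], end)
        else:
            exons.append((start, end))
        if feature == "CDS":
            cds_len += end - start
    return GeneReference(
        gene_id=gene_id,
        isbt_system=annot.get("isbt", gene_id),
        sequence=seq,
        exons=tuple(exons),
        cds_start_phase=annot["phase"],
        cds_len=cds_len,
    )


def load_database(
    db_path: str | Path,
    ref_path: str | Path,
    annot_path: str | Path | None = None,
    isbt_names: Mapping[str, str] | None = None,
) -> AlleleDatabase:
    """Load and validate an allele database from its TSV + FASTA + sidecar
    files.  Fails atomically (raises :class:`DatabaseError`) on any
    invariant violation."""
    db_path = Path(db_path)
    ref_path = Path(ref_path)
    if annot_path is None:
        annot_path = ref_path.with_suffix(".bed")
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(ref_path), "fasta")}
    annots = _read_annotation(Path(annot_path))
    genes: dict[str, GeneReference] = {}
    for gene_id, seq in seqs.items():
        if gene_id not in annots:
            raise DatabaseError(f"no annotation for gene {gene_id}")
        ann = dict(annots[gene_id])
        if isbt_names and gene_id in isbt_names:
            ann["isbt"] = isbt_names[gene_id]
        genes[gene_id] = _gene_from_annotation(gene_id, seq, ann)
    if not genes:
        raise DatabaseError("no genes defined")

    positions: list[VariablePosition] = []
    allele_states: dict[str, dict[str, dict[int, str]]] = {}
    with open(db_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _DB_COLUMNS:
            raise DatabaseError(f"database TSV header must be {_DB_COLUMNS}, got {header}")
        seen: set[tuple[str, int]] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_DB_COLUMNS):
                raise DatabaseError(f"line {lineno}: expected {len(_DB_COLUMNS)} columns")
            gene_id, label, gene_pos_s, ref, alt, alleles_s, region = fields
            gene = genes.get(gene_id)
            if gene is None:
                raise DatabaseError(f"line {lineno}: missing gene sequence for {gene_id}")
            gene_states = allele_states.setdefault(gene_id, {})
            if label == ".":  # reference-anchored allele declaration
                for name in filter(None, alleles_s.split(";")):
                    gene_states.setdefault(name, {})
                continue
            gene_pos = int(gene_pos_s)
            if label != ".":
                mapped = cdna_to_gene_pos(gene, label) if label.startswith("c.") else gene_pos
                if mapped != gene_pos:
                    raise DatabaseError(
                        f"line {lineno}: label {label} maps to {mapped}, row says {gene_pos}"
                    )
            if (gene_id, gene_pos) in seen:
                raise DatabaseError(f"line {lineno}: duplicate row for {gene_id}:{gene_pos}")
            seen.add((gene_id, gene_pos))
            alts = [a for a in alt.split(",") if a]
            vp = VariablePosition(gene_id, gene_pos, label, ref, frozenset(alts), region)
            positions.append(vp)
            for entry in filter(None, alleles_s.split(";")):
                if ":" in entry:
                    name, base = entry.split(":", 1)
                else:
                    name, base = entry, alts[0]
                gene_states.setdefault(name, {})[gene_pos] = base

    alleles = {
        gene_id: [
            AlleleDefinition(name, gene_id, states)
            for name, states in sorted(allele_states.get(gene_id, {}).items())
        ]
        for gene_id in genes
    }
    return AlleleDatabase(genes, positions, alleles)


def write_database(
    db: AlleleDatabase,
    db_path: str | Path,
    ref_path: str | Path,
    annot_path: str | Path | None = None,
) -> None:
    """Serialize a database back to its TSV + FASTA + sidecar files; output
    round-trips through :func:`load_database`."""
    ref_path = Path(ref_path)
    if annot_path is None:
        annot_path = ref_path.with_suffix(".bed")
    records = [
        SeqRecord(Seq(g.sequence), id=g.gene_id, description=g.isbt_system)
        for g in (db.genes[gid] for gid in db.gene_ids())
    ]
    SeqIO.write(records, str(ref_path), "fasta")
    with open(annot_path, "w") as fh:
        for gid in db.gene_ids():
            g = db.genes[gid]
            remaining_cds = g.cds_len
            for start, end in g.exons:
                seg = end - start
                cds_part = min(seg, remaining_cds)
                if cds_part > 0:
                    fh.write(f"{gid}\t{start}\t{start + cds_part}\t{g.cds_start_phase}\tCDS\n")
                if cds_part < seg:
                    fh.write(f"{gid}\t{start + cds_part}\t{end}\t{g.cds_start_phase}\tUTR3\n")
                remaining_cds -= cds_part
    with open(db_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_DB_COLUMNS) + "\n")
        for gid in db.gene_ids():
            anchored = [
                ad.allele_name
                for ad in db.alleles.get(gid, ())
                if not any(
                    base != db.positions[(gid, p)].ref_base
                    for p, base in ad.variant_states.items()
                )
            ]
            if anchored:
                fh.write(f"{gid}\t.\t-1\t.\t.\t{';'.join(sorted(anchored))}\t.\n")
            for pos in db.positions_for_gene(gid):
                vp = db.positions[(gid, pos)]
                alts = sorted(vp.alt_bases)
                carriers = []
                for ad in db.alleles.get(gid, ()):
                    base = ad.variant_states.get(pos)
                    if base is not None and base != vp.ref_base:
                        if len(alts) == 1:
                            carriers.append(ad.allele_name)
                        else:
                            carriers.append(f"{ad.allele_name}:{base}")
                fh.write(
                    f"{gid}\t{vp.cdna_label}\t{pos}\t{vp.ref_base}\t"
                    f"{','.join(alts)}\t{';'.join(sorted(carriers))}\t{vp.region}\n"
                )
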