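"""Per-gene read mapping, pileup construction and genotype calling.

Reads are mapped directly against each gene reference (no whole-genome
reference).  Production inputs may be SAM/BAM from any short-read aligner
(ingested with pysam); for self-contained runs and tests the module ships a
small seed-and-extend matcher: a 31-mer seed index per gene, ungapped
extension, up to 5 mismatches, best placement by mismatch count with ties
reported as multi-mapping and excluded from pileups.

Genotype calling at a catalogued position applies the minimum-depth rule
(default 5 reads) and a configurable minor-allele-fraction band over the
two most frequent bases: f >= 0.2 -> heterozygous, f <= 0.1 -> homozygous,
in between -> no-call (ambiguous fractions).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .db import AlleleDatabase, VariablePosition
from .preprocess import ReadRecord
from .simulate import revcomp

GENOME_SIZE = 2_867_437_753  # reference human genome size used for depth QC

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


@dataclass(frozen=True)
class AlignmentRecord:
    """An ungapped placement of one read on one gene reference, stored in
    gene-forward orientation."""

    read_name: str
    mate: int
    gene_id: str | None
    gene_start: int
    bases: str
    qualities: tuple[int, ...]
    mismatches: int
    status: str  # unique | multi | unmapped
    is_reverse: bool = False

    @property
    def gene_end(self) -> int:
        return self.gene_start + len(self.bases)


@dataclass(frozen=True)
class PositionCall:
    """Per-sample pileup summary and genotype call at one catalogued
    position.  ``depth`` is exactly the sum of counted bases."""

    gene_id: str
    gene_pos: int
    depth: int
    base_counts: Mapping[str, int]
    genotype: str  # hom_ref | hom_alt | het | no_call
    alleles: tuple[str, ...]  # () for no_call, (b,) for hom, (b1, b2) for het
    no_call_reason: str | None = None  # depth_below_min | ambiguous_fractions

    @property
    def is_het(self) -> bool:
        return self.genotype == "het"

    @property
    def is_no_call(self) -> bool:
        return self.genotype == "no_call"

    def base_multiset(self) -> tuple[str, str] | None:
        """The unordered pair of called bases, or None for a no-call."""
        if self.genotype == "no_call":
            return None
        if self.genotype == "het":
            return tuple(sorted(self.alleles))  # type: ignore[return-value]
        return (self.alleles[0], self.alleles[0])


@dataclass
class DepthReport:
    """The study's depth QC: per-gene and genome-wide fold-coverage from
    read counts."""

    gene_reads: dict[str, int] = field(default_factory=dict)
    gene_sizes: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0
    read_length: int = 150
    genome_size: int = GENOME_SIZE

    def gene_depth(self, gene_id: str) -> float:
        return gene_depth(self.gene_reads.get(gene_id, 0), self.read_length,
                          self.gene_sizes[gene_id])

    def genome_depth(self) -> float:
        return genome_depth(self.total_reads, self.read_length, self.genome_size)


def gene_depth(mapped_reads: int, read_len: int = 150, gene_size: int = 0) -> float:
    """Estimated fold-coverage of a gene: mapped reads x read length / gene
    size."""
    if gene_size <= 0:
        raise ValueError("gene_size must be positive")
    return mapped_reads * read_len / gene_size


def genome_depth(total_reads: int, read_len: int = 150,
                 genome_size: int = GENOME_SIZE) -> float:
    """Estimated genome fold-coverage: total reads x read length / genome
    size."""
    return total_reads * read_len / genome_size


# -- internal seed-and-extend matcher ------------------------------------


class GeneIndex:
    """Seed index over the gene references for the built-in matcher."""

    def __init__(self, db: AlleleDatabase, k: int = 31) -> None:
        self.k = k
        self.arrays: dict[str, np.ndarray] = {}
        self.lengths: dict[str, int] = {}
        seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for gene_id in db.gene_ids():
            seq = db.genes[gene_id].sequence
            self.arrays[gene_id] = np.frombuffer(seq.encode(), dtype=np.uint8)
            self.lengths[gene_id] = len(seq)
            for i in range(len(seq) - k + 1):
                seeds[seq[i : i + k]].append((gene_id, i))
        self.seeds: dict[str, list[tuple[str, int]]] = dict(seeds)

    def candidates(self, bases: str) -> set[tuple[str, int]]:
        """Candidate (gene, start) placements from seed hits at staggered
        offsets (plus a final seed flush against the read's 3' end)."""
        n = len(bases)
        hits: set[tuple[str, int]] = set()
        offsets = list(range(0, max(n - self.k, 0) + 1, self.k))
        if offsets and offsets[-1] != n - self.k:
            offsets.append(n - self.k)
        for off in offsets:
            for gene_id, pos in self.seeds.get(bases[off : off + self.k], ()):
                start = pos - off
                if 0 <= start <= self.lengths[gene_id] - n:
                    hits.add((gene_id, start))
        return hits


def _mismatches(index: GeneIndex, gene_id: str, start: int, read_arr: np.ndarray) -> int:
    ref = index.arrays[gene_id][start : start + read_arr.size]
    return int(np.count_nonzero(ref != read_arr))


def map_read(read: ReadRecord, index: GeneIndex, max_mismatches: int = 5) -> AlignmentRecord:
    """Map a single read with the built-in matcher, trying both strands."""
    best: list[tuple[str, int, bool]] = []
    best_mm = max_mismatches + 1
    for is_rev, bases in ((False, read.bases), (True, revcomp(read.bases))):
        if len(bases) < index.k:
            continue
        arr = np.frombuffer(bases.encode(), dtype=np.uint8)
        for gene_id, start in index.candidates(bases):
            mm = _mismatches(index, gene_id, start, arr)
            if mm < best_mm:
                best_mm = mm
                best = [(gene_id, start, is_rev)]
            elif mm == best_mm:
                if (gene_id, start, is_rev) not in best:
                    best.append((gene_id, start, is_rev))
    if not best or best_mm > max_mismatches:
        return AlignmentRecord(read.name, read.mate, None, -1, read.bases,
                               read.qualities, -1, "unmapped")
    status = "unique" if len(best) == 1 else "multi"
    gene_id, start, is_rev = best[0]
    bases = revcomp(read.bases) if is_rev else read.bases
    quals = read.qualities[::-1] if is_rev else read.qualities
    return AlignmentRecord(read.name, read.mate, gene_id, start, bases, quals,
                           best_mm, status, is_rev)


def map_reads(
    pairs: Sequence[tuple[ReadRecord, ReadRecord]],
    db: AlleleDatabase,
    max_mismatches: int = 5,
    k: int = 31,
    index: GeneIndex | None = None,
) -> list[AlignmentRecord]:
    """Map preprocessed read pairs against all gene references with the
    built-in matcher."""
    if index is None:
        index = GeneIndex(db, k=k)
    out: list[AlignmentRecord] = []
    for r1, r2 in pairs:
        out.append(map_read(r1, index, max_mismatches))
        out.append(map_read(r2, index, max_mismatches))
    return out


def read_sam(path: str | Path, db: AlleleDatabase) -> list[AlignmentRecord]:
    """Ingest alignments from SAM/BAM produced by an external aligner."""
    import pysam

    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped:
                out.append(AlignmentRecord(rec.query_name, 2 if rec.is_read2 else 1,
                                           None, -1, rec.query_sequence or "",
                                           tuple(rec.query_qualities or ()), -1,
                                           "unmapped"))
                continue
            gene_id = rec.reference_name
            if gene_id not in db.genes:
                raise ValueError(f"SAM reference {gene_id!r} not in database")
            try:
                mm = int(rec.get_tag("NM"))
            except KeyError:
                mm = 0
            status = "multi" if rec.mapping_quality == 0 else "unique"
            out.append(AlignmentRecord(
                rec.query_name, 2 if rec.is_read2 else 1, gene_id,
                rec.reference_start, rec.query_sequence,
                tuple(rec.query_qualities or (30,) * len(rec.query_sequence)),
                mm, status, rec.is_reverse))
    return out


# -- pileups -------------------------------------------------------------


def _fragment_groups(alignments: Iterable[AlignmentRecord]):
    """Group uniquely mapped records by read name (a template = one
    fragment); both mates of a fragment count once at shared positions."""
    groups: dict[tuple[str, str], list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        if a.status == "unique":
            groups[(a.read_name, a.gene_id)].append(a)
    return groups


def pileup(
    alignments: Iterable[AlignmentRecord],
    db: AlleleDatabase,
    base_q_floor: int = 13,
) -> dict[tuple[str, int], Counter]:
    """Base counts at every catalogued position from uniquely mapped reads.

    Overlapping mates of one fragment contribute a single observation per
    position; mates disagreeing at a shared position contribute none.
    """
    counts: dict[tuple[str, int], Counter] = {
        key: Counter() for key in db.positions
    }
    for (name, gene_id), recs in _fragment_groups(alignments).items():
        obs: dict[int, str] = {}
        bad: set[int] = set()
        for a in recs:
            for pos in db.covering_positions(gene_id, a.gene_start, a.gene_end):
                i = pos - a.gene_start
                if a.qualities[i] < base_q_floor:
                    continue
                base = a.bases[i]
                if base not in "ACGT":
                    continue
                if pos in obs and obs[pos] != base:
                    bad.add(pos)
                obs[pos] = base
        for pos, base in obs.items():
            if pos not in bad:
                counts[(gene_id, pos)][base] += 1
    return counts


def full_pileup(
    alignments: Iterable[AlignmentRecord],
    db: AlleleDatabase,
    base_q_floor: int = 13,
) -> dict[str, np.ndarray]:
    """Base-count matrices (4 x gene length, rows A/C/G/T) over *all* gene
    positions, for the novel-variant screen.  Overlap between mates of one
    fragment is counted once (the later-starting mate is clipped)."""
    mats = {
        gene_id: np.zeros((4, db.genes[gene_id].length), dtype=np.int32)
        for gene_id in db.gene_ids()
    }
    for (name, gene_id), recs in _fragment_groups(alignments).items():
        mat = mats[gene_id]
        recs = sorted(recs, key=lambda a: a.gene_start)
        covered_to = -1
        for a in recs:
            start = max(a.gene_start, covered_to)
            if start >= a.gene_end:
                continue
            off = start - a.gene_start
            arr = np.frombuffer(a.bases.encode(), dtype=np.uint8)[off:]
            quals = np.asarray(a.qualities, dtype=np.int16)[off:]
            codes = _BASE_CODE[arr]
            keep = (codes < 4) & (quals >= base_q_floor)
            idx = np.arange(start, a.gene_end)[keep]
            np.add.at(mat, (codes[keep], idx), 1)
            covered_to = max(covered_to, a.gene_end)
    return mats


# -- genotype calling ----------------------------------------------------


def call_genotype(
    gene_id: str,
    gene_pos: int,
    counts: Mapping[str, int],
    ref_base: str,
    min_depth: int = 5,
    het_min: float = 0.2,
    hom_max: float = 0.1,
) -> PositionCall:
    """Call a genotype from pileup base counts at one position.

    Depth below ``min_depth`` is a no-call.  Otherwise the minor-allele
    fraction f over the two most frequent bases decides: f >= ``het_min``
    heterozygous, f <= ``hom_max`` homozygous (majority base), in between a
    no-call for ambiguous fractions.
    """
    counts = {b: c for b, c in counts.items() if c > 0}
    depth = sum(counts.values())
    if depth < min_depth:
        return PositionCall(gene_id, gene_pos, depth, counts, "no_call", (),
                            "depth_below_min")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    (b1, c1), *rest = ranked
    c2 = rest[0][1] if rest else 0
    b2 = rest[0][0] if rest else None
    f = c2 / (c1 + c2)
    if f >= het_min:
        alleles = tuple(sorted((b1, b2)))
        return PositionCall(gene_id, gene_pos, depth, counts, "het", alleles)
    if f <= hom_max:
        genotype = "hom_ref" if b1 == ref_base else "hom_alt"
        return PositionCall(gene_id, gene_pos, depth, counts, genotype, (b1,))
    return PositionCall(gene_id, gene_pos, depth, counts, "no_call", (),
                        "ambiguous_fractions")


def call_positions(
    counts: Mapping[tuple[str, int], Mapping[str, int]],
    db: AlleleDatabase,
    min_depth: int = 5,
    het_min: float = 0.2,
    hom_max: float = 0.1,
) -> dict[tuple[str, int], PositionCall]:
    """Call genotypes at every catalogued position."""
    return {
        (gene_id, pos): call_genotype(
            gene_id, pos, counts.get((gene_id, pos), {}),
            db.positions[(gene_id, pos)].ref_base,
            min_depth=min_depth, het_min=het_min, hom_max=hom_max,
        )
        for (gene_id, pos) in db.positions
    }


def depth_report(
    alignments: Iterable[AlignmentRecord],
    db: AlleleDatabase,
    total_reads: int | None = None,
    read_length: int = 150,
    genome_size: int = GENOME_SIZE,
) -> DepthReport:
    """Per-gene mapped-read counts and depth estimates for QC."""
    report = DepthReport(read_length=read_length, genome_size=genome_size)
    n = 0
    for a in alignments:
        n += 1
        if a.status == "unique":
            report.gene_reads[a.gene_id] = report.gene_reads.get(a.gene_id, 0) + 1
    report.total_reads = total_reads if total_reads is not None else n
    report.gene_sizes = {g: db.genes[g].length for g in db.gene_ids()}
    return report


def write_calls_tsv(
    calls: Mapping[tuple[str, int], PositionCall],
    db: AlleleDatabase,
    path: str | Path,
    phase_lookup: Mapping[tuple[str, int], tuple[int, str]] | None = None,
) -> None:
    """Export calls as a minimal VCF-like TSV (CHROM, 1-based POS, REF, ALT,
    DP, AD, GT); het genotypes get phased ``0|1`` notation and a phase-set
    id when phasing information is supplied."""
    with open(path, "w") as fh:
        fh.write("CHROM\tPOS\tREF\tALT\tDP\tAD\tGT\tPS\n")
        for (gene_id, pos) in sorted(calls):
            call = calls[(gene_id, pos)]
            vp: VariablePosition = db.positions[(gene_id, pos)]
            alts = sorted(vp.alt_bases)
            order = [vp.ref_base] + alts
            ad = ",".join(str(call.base_counts.get(b, 0)) for b in order)
            ps = "."
            if call.genotype == "no_call":
                gt = "./."
            elif call.genotype == "hom_ref":
                gt = "0/0"
            elif call.genotype == "hom_alt":
                try:
                    gt_i = order.index(call.alleles[0])
                except ValueError:
                    gt_i = -1
                gt = f"{gt_i}/{gt_i}" if gt_i >= 0 else "./."
            else:
                idx = sorted(order.index(b) if b in order else -1 for b in call.alleles)
                if -1 in idx:
                    gt = "./."
                elif phase_lookup and (gene_id, pos) in phase_lookup:
                    ps_id, first = phase_lookup[(gene_id, pos)]
                    a, b = idx
                    if order[a] != first:
                        a, b = b, a
                    gt = f"{a}|{b}"
                    ps = str(ps_id)
                else:
                    gt = f"{idx[0]}/{idx[1]}"
            fh.write(f"{gene_id}\t{pos + 1}\t{vp.ref_base}\t{','.join(alts)}\t"
                     f"{call.depth}\t{ad}\t{gt}\t{ps}\n")
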