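"""Paired-end read simulation from chosen diplotypes.

Emulates 2x150 bp Illumina-style sequencing of a single gene: fragments are
drawn uniformly along the gene from one of the two haplotype sequences (fair
coin per fragment), sequenced from both ends, and corrupted with i.i.d.
substitution errors.  A truth manifest records the haplotype of origin of
every fragment, so downstream alignment, genotype calling, phasing and
typing can all be checked against simulated truth.

The number of read pairs for a target mean depth d over a gene of length L
with read length r is round(d * L / (2 * r)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .db import AlleleDatabase, DatabaseError
from .preprocess import ReadRecord

_COMP = str.maketrans("ACGT", "TGCA")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one simulated sample at one gene."""

    gene_id: str
    allele_pair: tuple[str, str]
    mean_depth: float = 30.0
    read_length: int = 150
    fragment_length_mean: float = 300.0
    fragment_length_sd: float = 50.0
    base_error_rate: float = 0.001
    quality_profile: str = "constant"  # "constant" (Q30) or "decay" (3' to Q10)
    seed: int = 0
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not 0 <= self.base_error_rate < 1:
            raise ValueError("base_error_rate must be in [0, 1)")
        if self.read_length > self.fragment_length_mean:
            raise ValueError("read_length must not exceed fragment_length_mean")


@dataclass
class TruthManifest:
    """Ground truth for one simulated sample at one gene."""

    sample_id: str
    gene_id: str
    allele_pair: tuple[str, str]
    haplotypes: tuple[str, str]
    #: fragment name -> (haplotype index, start, fragment length)
    fragments: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.fragments)


def _qualities(spec: SimulationSpec) -> tuple[int, ...]:
    n = spec.read_length
    if spec.quality_profile == "constant":
        return (30,) * n
    if spec.quality_profile == "decay":
        # linear decay from Q30 to Q10 over the final 40 bases
        tail = min(40, n)
        quals = [30] * (n - tail)
        quals += [max(10, round(30 - 20 * (i + 1) / tail)) for i in range(tail)]
        return tuple(quals)
    raise ValueError(f"unknown quality profile {spec.quality_profile!r}")


def _apply_errors(bases: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return bases
    hit = rng.random(bases.size) < rate
    n = int(hit.sum())
    if n == 0:
        return bases
    out = bases.copy()
    # substitute with a uniformly chosen *different* base
    shift = rng.integers(1, 4, size=n)
    idx = np.nonzero(hit)[0]
    code = np.searchsorted(_BASES, out[idx])  # bases are ACGT-sorted byte values
    lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    out[idx] = lookup[(code + shift) % 4]
    return out


def simulate_reads(
    spec: SimulationSpec,
    db: AlleleDatabase,
    rng: np.random.Generator | None = None,
    haplotype_override: Sequence[str] | None = None,
) -> tuple[list[tuple[ReadRecord, ReadRecord]], TruthManifest]:
    """Simulate read pairs for one sample.

    Returns the read pairs and the truth manifest.  ``haplotype_override``
    substitutes explicit haplotype sequences (used for injected variants).
    """
    if spec.gene_id not in db.genes:
        raise KeyError(f"unknown gene {spec.gene_id}")
    if haplotype_override is not None:
        haps = tuple(haplotype_override)
    else:
        haps = tuple(db.haplotype_sequence(spec.gene_id, a) for a in spec.allele_pair)
    gene_len = len(haps[0])
    if spec.read_length > gene_len:
        raise ValueError("read_length exceeds gene length")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    n_pairs = round(spec.mean_depth * gene_len / (2 * spec.read_length))
    quals = _qualities(spec)
    hap_arrays = [np.frombuffer(h.encode(), dtype=np.uint8) for h in haps]

    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    manifest = TruthManifest(spec.sample_id, spec.gene_id, tuple(spec.allele_pair), haps)
    rl = spec.read_length
    for i in range(n_pairs):
        # truncated-normal fragment length, re-drawn until it fits the gene
        while True:
            frag_len = int(round(rng.normal(spec.fragment_length_mean, spec.fragment_length_sd)))
            if rl <= frag_len <= gene_len:
                break
        start = int(rng.integers(0, gene_len - frag_len + 1))
        hap = int(rng.integers(0, 2))
        name = f"{spec.sample_id}:{spec.gene_id}:frag{i:06d}"
        manifest.fragments[name] = (hap, start, frag_len)
        arr = hap_arrays[hap]
        fwd = _apply_errors(arr[start : start + rl], spec.base_error_rate, rng)
        rev = _apply_errors(arr[start + frag_len - rl : start + frag_len],
                            spec.base_error_rate, rng)
        r1 = ReadRecord(name, fwd.tobytes().decode(), quals, 1)
        r2 = ReadRecord(name, revcomp(rev.tobytes().decode()), quals, 2)
        pairs.append((r1, r2))
    return pairs, manifest


@dataclass(frozen=True)
class InjectedVariant:
    """A non-database SNV injected into chosen cohort samples (het)."""

    gene_id: str
    gene_pos: int
    alt_base: str
    carriers: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "carriers", frozenset(self.carriers))


@dataclass
class CohortTruth:
    """Cohort-level manifest: per-sample diplotypes and injected variants."""

    diplotypes: dict[str, dict[str, tuple[str, str]]]  # sample -> gene -> pair
    manifests: dict[str, dict[str, TruthManifest]]
    injected: tuple[InjectedVariant, ...] = ()


def simulate_cohort(
    specs: Iterable[SimulationSpec],
    db: AlleleDatabase,
    master_seed: int = 0,
    extra_variants: Iterable[InjectedVariant] = (),
) -> tuple[dict[str, list[tuple[ReadRecord, ReadRecord]]], CohortTruth]:
    """Simulate a cohort; each spec is one (sample, gene) condition.

    Per-sample random streams are derived deterministically from
    ``master_seed``, so the same seed and specs give byte-identical output.
    Injected variants are applied (heterozygously, on haplotype 0) to
    carriers' haplotypes before fragments are drawn; a variant colliding
    with a database position is an error.
    """
    specs = list(specs)
    extra_variants = tuple(extra_variants)
    if len(set((s.sample_id, s.gene_id) for s in specs)) != len(specs):
        raise ValueError("duplicate (sample_id, gene_id) in cohort specs")
    for v in extra_variants:
        if (v.gene_id, v.gene_pos) in db.positions:
            raise DatabaseError(
                f"injected variant collides with database position "
                f"{v.gene_id}:{v.gene_pos}"
            )

    reads: dict[str, list[tuple[ReadRecord, ReadRecord]]] = {}
    truth = CohortTruth({}, {}, extra_variants)
    for i, spec in enumerate(sorted(specs, key=lambda s: (s.sample_id, s.gene_id))):
        rng = np.random.default_rng([master_seed, i])
        haps = [
            list(db.haplotype_sequence(spec.gene_id, a)) for a in spec.allele_pair
        ]
        for v in extra_variants:
            if v.gene_id == spec.gene_id and spec.sample_id in v.carriers:
                haps[0][v.gene_pos] = v.alt_base
        pairs, manifest = simulate_reads(
            spec, db, rng=rng, haplotype_override=["".join(h) for h in haps]
        )
        reads.setdefault(spec.sample_id, []).extend(pairs)
        truth.diplotypes.setdefault(spec.sample_id, {})[spec.gene_id] = tuple(spec.allele_pair)
        truth.manifests.setdefault(spec.sample_id, {})[spec.gene_id] = manifest
    return reads, truth


# -- FASTQ / manifest output --------------------------------------------


def write_fastq(
    pairs: Sequence[tuple[ReadRecord, ReadRecord]],
    path1: str | Path,
    path2: str | Path,
) -> None:
    """Write mates to a standard pair of 4-line FASTQ files."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r1, r2 in pairs:
            for fh, r in ((f1, r1), (f2, r2)):
                qual = "".join(chr(q + 33) for q in r.qualities)
                fh.write(f"@{r.name}/{r.mate}\n{r.bases}\n+\n{qual}\n")


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[tuple[ReadRecord, ReadRecord]]:
    """Read mate-paired FASTQ files written by :func:`write_fastq` (or any
    name-synchronised pair of FASTQ files)."""
    from Bio import SeqIO

    pairs = []
    for rec1, rec2 in zip(
        SeqIO.parse(str(path1), "fastq"), SeqIO.parse(str(path2), "fastq")
    ):
        name1 = rec1.id.rsplit("/", 1)[0]
        name2 = rec2.id.rsplit("/", 1)[0]
        if name1 != name2:
            raise ValueError(f"FASTQ files out of sync: {rec1.id} vs {rec2.id}")
        pairs.append(
            (
                ReadRecord(name1, str(rec1.seq), tuple(rec1.letter_annotations["phred_quality"]), 1),
                ReadRecord(name2, str(rec2.seq), tuple(rec2.letter_annotations["phred_quality"]), 2),
            )
        )
    return pairs


def write_manifest_tsv(truth: CohortTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgene\tallele_a\tallele_b\tn_pairs\n")
        for sample in sorted(truth.diplotypes):
            for gene, pair in sorted(truth.diplotypes[sample].items()):
                n = truth.manifests[sample][gene].n_pairs
                fh.write(f"{sample}\t{gene}\t{pair[0]}\t{pair[1]}\t{n}\n")
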