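"""Read trimming and pair filtering prior to alignment.

Rules applied, in order, to each mate:

1. 3' quality trimming at Q20 using the BWA-style partial-sum algorithm
   (the semantics of the trimmer behind Trim Galore): cut at the position
   that maximises the running sum of (threshold - q) from the 3' end.  The
   5' end is never touched.
2. 3' adapter removal by suffix-overlap against the adapter's prefix, with
   a minimum overlap of 3 bases and floor(0.1 * overlap) allowed mismatches.

Pairs with either mate shorter than 40 bases after trimming are dropped
entirely, so the output is always properly paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: shared 13-mer prefix of the Illumina TruSeq R1/R2 adapters
TRUSEQ_ADAPTER = "AGATCGGAAGAGC"


@dataclass(frozen=True)
class ReadRecord:
    name: str
    bases: str
    qualities: tuple[int, ...]
    mate: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "qualities", tuple(self.qualities))
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"{self.name}: bases/qualities length mismatch")

    def __len__(self) -> int:
        return len(self.bases)

    def prefix(self, n: int) -> "ReadRecord":
        return ReadRecord(self.name, self.bases[:n], self.qualities[:n], self.mate)


@dataclass
class PreprocessStats:
    n_pairs_in: int = 0
    n_pairs_out: int = 0
    n_pairs_dropped_short: int = 0
    n_orphans: int = 0
    bases_quality_trimmed: int = 0
    bases_adapter_trimmed: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def quality_trim(read: ReadRecord, q_floor: int = 20) -> ReadRecord:
    """Trim low-quality bases from the 3' end (BWA partial-sum rule)."""
    cut = len(read)
    score = 0
    best = 0
    for i in range(len(read) - 1, -1, -1):
        score += q_floor - read.qualities[i]
        if score < 0:
            break
        if score > best:
            best = score
            cut = i
    return read.prefix(cut)


def adapter_trim(
    read: ReadRecord,
    adapter: str = TRUSEQ_ADAPTER,
    min_overlap: int = 3,
    error_rate: float = 0.1,
) -> ReadRecord:
    """Remove a 3' adapter contamination: the longest read suffix matching a
    prefix of the adapter with at most floor(error_rate * overlap)
    mismatches."""
    max_k = min(len(read), len(adapter))
    for k in range(max_k, min_overlap - 1, -1):
        suffix = read.bases[len(read) - k :]
        allowed = int(error_rate * k)
        mism = 0
        for a, b in zip(suffix, adapter):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        if mism <= allowed:
            return read.prefix(len(read) - k)
    return read


def pair_up(reads: Iterable[ReadRecord]) -> tuple[list[tuple[ReadRecord, ReadRecord]], int]:
    """Match mates by name; returns (pairs, orphan count)."""
    by_name: dict[str, dict[int, ReadRecord]] = {}
    order: list[str] = []
    for r in reads:
        if r.name not in by_name:
            order.append(r.name)
        by_name.setdefault(r.name, {})[r.mate] = r
    pairs = []
    orphans = 0
    for name in order:
        mates = by_name[name]
        if 1 in mates and 2 in mates:
            pairs.append((mates[1], mates[2]))
        else:
            orphans += len(mates)
    return pairs, orphans


def filter_pairs(
    pairs: Sequence[tuple[ReadRecord, ReadRecord]],
    min_len: int = 40,
    adapter: str = TRUSEQ_ADAPTER,
    q_floor: int = 20,
    stats: PreprocessStats | None = None,
) -> list[tuple[ReadRecord, ReadRecord]]:
    """Quality- and adapter-trim both mates, then drop any pair with a mate
    shorter than ``min_len`` (pairs-only output)."""
    if stats is None:
        stats = PreprocessStats()
    stats.n_pairs_in += len(pairs)
    out = []
    for r1, r2 in pairs:
        trimmed = []
        for r in (r1, r2):
            # iterate to a fixed point: removing an adapter can expose a
            # low-quality tail (and vice versa), so one sweep may not be
            # final and preprocessing must be idempotent
            while True:
                qt = quality_trim(r, q_floor)
                stats.bases_quality_trimmed += len(r) - len(qt)
                at = adapter_trim(qt, adapter)
                stats.bases_adapter_trimmed += len(qt) - len(at)
                if len(at) == len(r):
                    break
                r = at
            trimmed.append(at)
        if all(len(t) >= min_len for t in trimmed):
            out.append((trimmed[0], trimmed[1]))
        else:
            stats.n_pairs_dropped_short += 1
    stats.n_pairs_out += len(out)
    return out


def preprocess_reads(
    reads: Iterable[ReadRecord],
    min_len: int = 40,
    adapter: str = TRUSEQ_ADAPTER,
    q_floor: int = 20,
) -> tuple[list[tuple[ReadRecord, ReadRecord]], PreprocessStats]:
    """Full preprocessing of a flat read stream: mate pairing, trimming and
    pair-integrity filtering, with per-rule removal counts."""
    stats = PreprocessStats()
    pairs, orphans = pair_up(reads)
    stats.n_orphans = orphans
    kept = filter_pairs(pairs, min_len=min_len, adapter=adapter, q_floor=q_floor, stats=stats)
    return kept, stats
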