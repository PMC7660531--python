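"""Diplotype assignment: matching genotype calls and phase sets against the
allele database.

For each gene, every unordered pair of database alleles (including the
reference allele) is tested against the evidence: at every called position
the pair's base multiset must equal the called genotype's, and within every
phase set the pair's haplotype strings must match the inferred pair up to
swap.  Enumeration is exhaustive — per-gene allele counts are small — so
the production path and a brute-force oracle coincide by construction.

Statuses: ``resolved`` (exactly one surviving pair), ``ambiguous`` (several
pairs, listed lexicographically), ``not_defined`` (no pair fits, or a
no-call sits at a position that discriminates the surviving pairs).  The
depth-reliability rule is advisory metadata: gene depth must be strictly
above 15x for a call to be flagged reliable; results below that are still
reported, flagged ``low_depth``.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .align import DepthReport, PositionCall
from .db import AlleleDatabase
from .phasing import PhaseSet

RELIABILITY_DEPTH = 15.0


@dataclass(frozen=True)
class TypingResult:
    """Per-gene typing outcome for one sample."""

    gene_id: str
    sample_id: str
    status: str  # resolved | ambiguous | not_defined
    diplotypes: tuple[tuple[str, str], ...]
    uncovered_positions: tuple[int, ...] = ()
    reliability: str | None = None  # reliable | low_depth
    evidence: Mapping[int, int] = field(default_factory=dict)  # pos -> depth
    annotations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "evidence", dict(self.evidence))

    @property
    def diplotype_str(self) -> str:
        return ";".join("/".join(pair) for pair in self.diplotypes)


def reliability_flag(depth_report: DepthReport, gene_id: str,
                     threshold: float = RELIABILITY_DEPTH) -> str:
    """``low_depth`` unless the gene's estimated depth is strictly above the
    threshold (default 15x)."""
    return "reliable" if depth_report.gene_depth(gene_id) > threshold else "low_depth"


def _pair_matches_calls(
    db: AlleleDatabase,
    gene_id: str,
    pair: tuple,
    called: Mapping[int, tuple[str, str]],
) -> bool:
    a, b = pair
    for pos, multiset in called.items():
        pair_bases = tuple(sorted((db.allele_base(gene_id, a, pos),
                                   db.allele_base(gene_id, b, pos))))
        if pair_bases != multiset:
            return False
    return True


def _pair_matches_phase(
    db: AlleleDatabase,
    gene_id: str,
    pair: tuple,
    phase_sets: Sequence[PhaseSet],
) -> bool:
    a, b = pair
    for ps in phase_sets:
        hap_a = "".join(db.allele_base(gene_id, a, p) for p in ps.positions)
        hap_b = "".join(db.allele_base(gene_id, b, p) for p in ps.positions)
        if {hap_a, hap_b} != set(ps.haplotype_pair()):
            return False
    return True


def assign_diplotype(
    gene_id: str,
    calls: Iterable[PositionCall],
    phase_sets: Iterable[PhaseSet],
    db: AlleleDatabase,
    sample_id: str = "sample",
    gene_depth: float | None = None,
    reliability_threshold: float = RELIABILITY_DEPTH,
) -> TypingResult:
    """Assign the diplotype of one gene from its position calls and phase
    sets."""
    if gene_id not in db.genes:
        raise KeyError(f"gene {gene_id} absent from database")
    calls = [c for c in calls if c.gene_id == gene_id]
    phase_sets = [ps for ps in phase_sets if ps.gene_id == gene_id]

    called: dict[int, tuple[str, str]] = {}
    no_calls: list[int] = []
    evidence: dict[int, int] = {}
    for c in calls:
        evidence[c.gene_pos] = c.depth
        ms = c.base_multiset()
        if ms is None:
            no_calls.append(c.gene_pos)
        else:
            called[c.gene_pos] = ms
    # catalogued positions with no pileup record at all are uncovered
    for p in db.positions_for_gene(gene_id):
        if p not in called and p not in no_calls:
            no_calls.append(p)
            evidence.setdefault(p, 0)

    names = db.allele_names(gene_id)
    ref = db.reference_allele(gene_id)
    if ref.allele_name not in names:
        names.append(ref.allele_name)
        names.sort()
    allele_by_name = {n: (ref if n == ref.allele_name else db.allele(gene_id, n))
                      for n in names}

    candidates = [
        (a, b)
        for a, b in combinations_with_replacement(names, 2)
        if _pair_matches_calls(db, gene_id, (allele_by_name[a], allele_by_name[b]), called)
        and _pair_matches_phase(db, gene_id, (allele_by_name[a], allele_by_name[b]), phase_sets)
    ]

    annotations: list[str] = []
    reliability = None
    if gene_depth is not None:
        reliability = "reliable" if gene_depth > reliability_threshold else "low_depth"

    if not candidates:
        if called:
            annotations.append("unreported polymorphism combination")
        status = "not_defined"
    else:
        # a no-call blocks resolution only where it discriminates survivors
        discriminating = [
            p for p in no_calls
            if len({
                tuple(sorted((db.allele_base(gene_id, allele_by_name[a], p),
                              db.allele_base(gene_id, allele_by_name[b], p))))
                for a, b in candidates
            }) > 1
        ]
        if discriminating:
            status = "not_defined"
            annotations.append("defining position(s) below depth threshold")
        elif len(candidates) == 1:
            status = "resolved"
        else:
            status = "ambiguous"
    return TypingResult(
        gene_id=gene_id,
        sample_id=sample_id,
        status=status,
        diplotypes=tuple(sorted(tuple(sorted(p)) for p in candidates)),
        uncovered_positions=tuple(sorted(no_calls)),
        reliability=reliability,
        evidence=evidence,
        annotations=tuple(annotations),
    )


@dataclass
class CohortTyping:
    """Per-sample, per-gene typing results with cohort-level tallies."""

    results: list[TypingResult]

    def tally(self, gene_id: str) -> Counter:
        """Counts per resolved diplotype (plus per non-resolved status)."""
        out: Counter = Counter()
        for r in self.results:
            if r.gene_id != gene_id:
                continue
            if r.status == "resolved":
                out["/".join(r.diplotypes[0])] += 1
            else:
                out[r.status] += 1
        return out

    def allele_tally(self, gene_id: str) -> Counter:
        """Allele counts over resolved samples (2 per sample)."""
        out: Counter = Counter()
        for r in self.results:
            if r.gene_id == gene_id and r.status == "resolved":
                out.update(r.diplotypes[0])
        return out

    def to_rows(self) -> list[dict]:
        return [
            {
                "sample": r.sample_id,
                "gene": r.gene_id,
                "status": r.status,
                "diplotypes": r.diplotype_str,
                "reliability": r.reliability or "",
                "min_defining_depth": min(r.evidence.values()) if r.evidence else 0,
            }
            for r in self.results
        ]


def cohort_type(
    samples: Mapping[str, tuple[Iterable[PositionCall], Iterable[PhaseSet]]],
    db: AlleleDatabase,
    gene_depths: Mapping[str, Mapping[str, float]] | None = None,
) -> CohortTyping:
    """Type every sample at every database gene.

    ``samples`` maps sample id -> (position calls, phase sets);
    ``gene_depths`` optionally maps sample id -> gene id -> estimated depth
    for the reliability flag.
    """
    if not samples:
        raise ValueError("cohort must contain at least one sample")
    results = []
    for sample_id in sorted(samples):
        calls, phase_sets = samples[sample_id]
        calls = list(calls)
        phase_sets = list(phase_sets)
        for gene_id in db.gene_ids():
            depth = None
            if gene_depths is not None:
                depth = gene_depths.get(sample_id, {}).get(gene_id)
            results.append(
                assign_diplotype(gene_id, calls, phase_sets, db,
                                 sample_id=sample_id, gene_depth=depth)
            )
    return CohortTyping(results)


def write_typing_tsv(typing: CohortTyping, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgene\tstatus\tdiplotypes\treliability\tmin_defining_depth\n")
        for row in typing.to_rows():
            fh.write("\t".join(str(row[k]) for k in
                               ("sample", "gene", "status", "diplotypes",
                                "reliability", "min_defining_depth")) + "\n")


def write_typing_json(typing: CohortTyping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(typing.to_rows(), fh, indent=2)
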