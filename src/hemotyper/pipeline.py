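"""End-to-end convenience wrappers tying the stages together.

These are the code paths the CLI drives; tests and scripted analyses use
them directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import align, diplotype, phasing, preprocess
from .db import AlleleDatabase
from .preprocess import ReadRecord


@dataclass
class SampleResult:
    """Everything the pipeline derives for one sample."""

    sample_id: str
    calls: dict[tuple[str, int], align.PositionCall]
    phase_sets: list[phasing.PhaseSet]
    depth: align.DepthReport
    typing: dict[str, diplotype.TypingResult] = field(default_factory=dict)
    preprocess_stats: preprocess.PreprocessStats | None = None


def type_sample(
    pairs: Sequence[tuple[ReadRecord, ReadRecord]],
    db: AlleleDatabase,
    sample_id: str = "sample",
    index: align.GeneIndex | None = None,
    run_preprocess: bool = True,
    min_depth: int = 5,
    het_min: float = 0.2,
    hom_max: float = 0.1,
    base_q_floor: int = 13,
    phase_min_support: int = 2,
) -> SampleResult:
    """Preprocess, map, call, phase and type one sample's read pairs."""
    stats = None
    if run_preprocess:
        pairs, stats = preprocess.preprocess_reads(
            r for pair in pairs for r in pair
        )
    if index is None:
        index = align.GeneIndex(db)
    alignments = align.map_reads(pairs, db, index=index)
    counts = align.pileup(alignments, db, base_q_floor=base_q_floor)
    calls = align.call_positions(counts, db, min_depth=min_depth,
                                 het_min=het_min, hom_max=hom_max)
    het_calls = [c for c in calls.values() if c.is_het]
    fragments = phasing.build_fragments(alignments, het_calls,
                                        base_q_floor=base_q_floor)
    phase_sets = phasing.phase(fragments, het_calls,
                               min_support=phase_min_support)
    depth = align.depth_report(alignments, db)
    result = SampleResult(sample_id, calls, phase_sets, depth,
                          preprocess_stats=stats)
    for gene_id in db.gene_ids():
        result.typing[gene_id] = diplotype.assign_diplotype(
            gene_id, calls.values(), phase_sets, db,
            sample_id=sample_id, gene_depth=depth.gene_depth(gene_id),
        )
    return result


def type_cohort(
    cohort_pairs: Mapping[str, Sequence[tuple[ReadRecord, ReadRecord]]],
    db: AlleleDatabase,
    **kwargs,
) -> dict[str, SampleResult]:
    """Run :func:`type_sample` for every sample, sharing the seed index."""
    index = align.GeneIndex(db)
    return {
        sample_id: type_sample(pairs, db, sample_id=sample_id, index=index, **kwargs)
        for sample_id, pairs in sorted(cohort_pairs.items())
    }
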