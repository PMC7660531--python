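"""Concordance of WGS-derived typing against a truth genotyping table.

The truth table is SNaPshot-style: per sample and bi-allelic polymorphism,
one of homozygous wild-type (``hom_wt``), homozygous mutated (``hom_mt``),
heterozygous (``het``) or not defined (``nd``).  Truth ``nd`` records are
excluded from evaluation.  Each evaluable observation is scored correct,
incorrect, or nd (the WGS side gave no call — an ambiguous WGS typing also
scores nd), and binned by the truth zygosity.

Summary percentages:

* typed concordance   = 100 * correct / (correct + incorrect)
* overall concordance = 100 * correct / (correct + incorrect + nd)
* unresolved          = 100 * nd / total

reported half-up at one decimal and at integer rounding (per-polymorphism
figures are conventionally quoted at one decimal, headline figures at
integer precision).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .align import PositionCall
from .db import AlleleDatabase

TRUTH_CLASSES = ("hom_wt", "hom_mt", "het", "nd")


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    polymorphism: str  # e.g. "SLC14A1 (838G>A)"
    gene_id: str
    cdna_label: str
    genotype: str

    def __post_init__(self) -> None:
        if self.genotype not in TRUTH_CLASSES:
            raise ValueError(f"bad truth genotype {self.genotype!r}")


@dataclass
class Counts:
    correct: int = 0
    incorrect: int = 0
    nd: int = 0

    @property
    def total(self) -> int:
        return self.correct + self.incorrect + self.nd

    def __add__(self, other: "Counts") -> "Counts":
        return Counts(self.correct + other.correct,
                      self.incorrect + other.incorrect,
                      self.nd + other.nd)


@dataclass
class ConcordanceTable:
    """Zygosity x {correct, incorrect, nd} counts, per polymorphism and
    aggregated."""

    rows: dict[str, dict[str, Counts]] = field(default_factory=dict)
    excluded_truth_nd: int = 0

    def row(self, polymorphism: str) -> dict[str, Counts]:
        return self.rows.setdefault(polymorphism,
                                    {"hom": Counts(), "het": Counts()})

    def totals(self) -> dict[str, Counts]:
        hom = Counts()
        het = Counts()
        for cells in self.rows.values():
            hom = hom + cells["hom"]
            het = het + cells["het"]
        return {"hom": hom, "het": het, "all": hom + het}

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for name, cells in self.rows.items():
            recs.append({
                "polymorphism": name,
                "hom_correct": cells["hom"].correct,
                "hom_incorrect": cells["hom"].incorrect,
                "hom_nd": cells["hom"].nd,
                "het_correct": cells["het"].correct,
                "het_incorrect": cells["het"].incorrect,
                "het_nd": cells["het"].nd,
            })
        return pd.DataFrame.from_records(recs)

    @classmethod
    def from_counts(
        cls,
        rows: Mapping[str, tuple[int, int, int, int, int, int]],
    ) -> "ConcordanceTable":
        """Build from printed per-polymorphism counts, each row a 6-tuple
        (hom correct, hom incorrect, hom nd, het correct, het incorrect,
        het nd)."""
        table = cls()
        for name, (hc, hi, hn, ec, ei, en) in rows.items():
            table.rows[name] = {"hom": Counts(hc, hi, hn), "het": Counts(ec, ei, en)}
        return table


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def build_concordance(
    wgs: Mapping[tuple[str, str], str],
    truth: Iterable[TruthRecord],
) -> ConcordanceTable:
    """Score WGS genotype classes against truth records.

    ``wgs`` maps (sample, polymorphism) -> class in {hom_wt, hom_mt, het,
    nd}; a missing entry scores nd.  Truth nd records are excluded.
    """
    table = ConcordanceTable()
    for rec in truth:
        if rec.genotype == "nd":
            table.excluded_truth_nd += 1
            continue
        zyg = "het" if rec.genotype == "het" else "hom"
        cell = table.row(rec.polymorphism)[zyg]
        called = wgs.get((rec.sample_id, rec.polymorphism), "nd")
        if called == "nd":
            cell.nd += 1
        elif called == rec.genotype:
            cell.correct += 1
        else:
            cell.incorrect += 1
    return table


def wgs_classes_from_calls(
    calls_by_sample: Mapping[str, Mapping[tuple[str, int], PositionCall]],
    db: AlleleDatabase,
    polymorphisms: Mapping[str, tuple[str, str]],
    ambiguous: Iterable[tuple[str, str]] = (),
) -> dict[tuple[str, str], str]:
    """Translate per-position calls into truth-table classes.

    ``polymorphisms`` maps polymorphism label -> (gene, cDNA label); the
    label must resolve to a database position.  (sample, polymorphism)
    pairs listed in ``ambiguous`` (e.g. ambiguous diplotype typings) are
    downgraded to nd.
    """
    from .db import cdna_to_gene_pos

    pos_of: dict[str, tuple[str, int]] = {}
    for name, (gene_id, label) in polymorphisms.items():
        if gene_id not in db.genes:
            raise KeyError(f"truth polymorphism {name!r}: unknown gene {gene_id}")
        pos = cdna_to_gene_pos(db.genes[gene_id], label)
        if (gene_id, pos) not in db.positions:
            raise KeyError(f"truth polymorphism {name!r} absent from database")
        pos_of[name] = (gene_id, pos)

    ambiguous = set(ambiguous)
    out: dict[tuple[str, str], str] = {}
    for sample_id, calls in calls_by_sample.items():
        for name, key in pos_of.items():
            call = calls.get(key)
            if call is None or call.is_no_call or (sample_id, name) in ambiguous:
                out[(sample_id, name)] = "nd"
            elif call.genotype == "het":
                out[(sample_id, name)] = "het"
            elif call.genotype == "hom_ref":
                out[(sample_id, name)] = "hom_wt"
            else:
                out[(sample_id, name)] = "hom_mt"
    return out


@dataclass
class ConcordanceStats:
    """Summary percentages (raw, unrounded)."""

    typed: float
    overall: float
    unresolved: float
    hom_typed: float | None
    het_typed: float | None
    per_polymorphism: dict[str, float]

    def rounded(self, ndigits: int = 1) -> dict:
        rnd = lambda v: None if v is None else round_half_up(v, ndigits)
        return {
            "typed": rnd(self.typed),
            "overall": rnd(self.overall),
            "unresolved": rnd(self.unresolved),
            "hom_typed": rnd(self.hom_typed),
            "het_typed": rnd(self.het_typed),
            "per_polymorphism": {k: rnd(v) for k, v in self.per_polymorphism.items()},
        }


def _typed_pct(c: Counts) -> float | None:
    typed = c.correct + c.incorrect
    return 100.0 * c.correct / typed if typed else None


def concordance_stats(table: ConcordanceTable) -> ConcordanceStats:
    """Typed/overall/unresolved percentages, per zygosity and polymorphism."""
    totals = table.totals()
    all_cells = totals["all"]
    if all_cells.total == 0:
        raise ValueError("empty concordance table")
    typed = _typed_pct(all_cells)
    return ConcordanceStats(
        typed=typed if typed is not None else 100.0,
        overall=100.0 * all_cells.correct / all_cells.total,
        unresolved=100.0 * all_cells.nd / all_cells.total,
        hom_typed=_typed_pct(totals["hom"]),
        het_typed=_typed_pct(totals["het"]),
        per_polymorphism={
            name: pct
            for name, cells in table.rows.items()
            if (pct := _typed_pct(cells["hom"] + cells["het"])) is not None
        },
    )


def depth_by_status(
    observations: Iterable[tuple[str, float]],
) -> pd.DataFrame:
    """Grouped read-count summary per typing status.

    ``observations`` yields (status, read count) with status in {correct,
    incorrect, nd} (any status labels are accepted).  Groups with no
    observations are omitted, not reported as zero; downstream hypothesis
    testing is left to external statistics software.
    """
    df = pd.DataFrame(observations, columns=["status", "reads"])
    if df.empty:
        return pd.DataFrame(columns=["status", "n", "mean", "min", "max"])
    out = (
        df.groupby("status")["reads"]
        .agg(n="count", mean="mean", min="min", max="max")
        .reset_index()
    )
    return out


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    """Truth TSV columns: sample, gene, label, genotype (polymorphism id is
    ``gene (label-without-c.)``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "gene", "label", "genotype"}
    if not required <= set(df.columns):
        raise ValueError(f"truth TSV must have columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        label = row.label
        name = f"{row.gene} ({label[2:] if label.startswith('c.') else label})"
        records.append(TruthRecord(row.sample, name, row.gene, label, row.genotype))
    return records


def write_concordance_tsv(table: ConcordanceTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)
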