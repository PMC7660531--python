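"""Read-backed phasing of heterozygous catalogued positions.

Heterozygous positions of one gene are nodes of a graph; every fragment
(read pair treated as one template, or single reads in strict mode)
co-observing two positions votes for a relative orientation (cis: both
first-allele or both second-allele bases; trans: mixed).  An edge survives
if its majority orientation has at least ``min_support`` concordant
fragments and at least a 2/3 majority; ties and weakly supported edges are
removed, splitting the component.  Each connected component becomes a
:class:`PhaseSet` with two complementary haplotype strings; isolated
heterozygous positions yield singleton phase sets.

Phasing is evidence-based only — no population/statistical phasing.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx

from .align import AlignmentRecord, PositionCall


@dataclass(frozen=True)
class Fragment:
    """Observations of one sequencing template at heterozygous positions."""

    fragment_id: str
    gene_id: str
    observations: Mapping[int, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", dict(self.observations))


@dataclass(frozen=True)
class PhaseSet:
    """A connected group of phased heterozygous positions.

    ``haplotype_a`` and ``haplotype_b`` differ at every member position;
    which is labelled a/b is arbitrary (downstream typing is invariant
    under the swap).  ``support`` counts concordant fragments per adjacent
    member pair."""

    gene_id: str
    positions: tuple[int, ...]
    haplotype_a: str
    haplotype_b: str
    support: tuple[int, ...]
    conflicts: int = 0

    def haplotype_pair(self) -> frozenset[str]:
        return frozenset((self.haplotype_a, self.haplotype_b))


def build_fragments(
    alignments: Iterable[AlignmentRecord],
    het_calls: Iterable[PositionCall],
    base_q_floor: int = 13,
    joint_mates: bool = True,
) -> list[Fragment]:
    """Collect per-template base observations at heterozygous positions.

    Observations are kept only where the fragment's base is one of the two
    called alleles (other bases are sequencing errors for phasing purposes)
    and passes the base-quality floor.  With ``joint_mates`` (default) both
    mates of a pair form one fragment; strict single-read mode treats each
    mate separately, phasing only physically overlapping positions.
    """
    het_at: dict[tuple[str, int], tuple[str, ...]] = {
        (c.gene_id, c.gene_pos): c.alleles for c in het_calls if c.is_het
    }
    by_gene: dict[str, list[int]] = defaultdict(list)
    for gene_id, pos in het_at:
        by_gene[gene_id].append(pos)
    for positions in by_gene.values():
        positions.sort()

    groups: dict[tuple[str, str], dict[int, str]] = defaultdict(dict)
    dropped: dict[tuple[str, str], set[int]] = defaultdict(set)
    for a in alignments:
        if a.status != "unique" or a.gene_id not in by_gene:
            continue
        key_id = a.read_name if joint_mates else f"{a.read_name}/{a.mate}"
        key = (key_id, a.gene_id)
        obs = groups[key]
        for pos in by_gene[a.gene_id]:
            if not a.gene_start <= pos < a.gene_end:
                continue
            i = pos - a.gene_start
            if a.qualities[i] < base_q_floor:
                continue
            base = a.bases[i]
            if base not in het_at[(a.gene_id, pos)]:
                continue  # third-allele observation: discard as error
            if pos in obs and obs[pos] != base:
                dropped[key].add(pos)  # mates disagree
            obs[pos] = base
    fragments = []
    for (frag_id, gene_id), obs in groups.items():
        obs = {p: b for p, b in obs.items() if p not in dropped[(frag_id, gene_id)]}
        if obs:
            fragments.append(Fragment(frag_id, gene_id, obs))
    return fragments


def phase(
    fragments: Iterable[Fragment],
    het_calls: Iterable[PositionCall],
    min_support: int = 2,
    min_majority: float = 2 / 3,
) -> list[PhaseSet]:
    """Assemble phase sets from fragment co-observations."""
    het_calls = [c for c in het_calls if c.is_het]
    alleles = {(c.gene_id, c.gene_pos): c.alleles for c in het_calls}
    genes = sorted({c.gene_id for c in het_calls})

    # orientation votes per position pair: True = cis (same allele index)
    votes: dict[str, dict[tuple[int, int], list[int]]] = {
        g: defaultdict(lambda: [0, 0]) for g in genes
    }
    co_support: dict[tuple[str, int, int], int] = defaultdict(int)
    for frag in fragments:
        if frag.gene_id not in votes:
            continue
        positions = sorted(frag.observations)
        for p, q in combinations(positions, 2):
            ap = alleles[(frag.gene_id, p)]
            aq = alleles[(frag.gene_id, q)]
            cis = (frag.observations[p] == ap[0]) == (frag.observations[q] == aq[0])
            votes[frag.gene_id][(p, q)][0 if cis else 1] += 1

    phase_sets: list[PhaseSet] = []
    for gene_id in genes:
        graph = nx.Graph()
        positions = sorted(p for (g, p) in alleles if g == gene_id)
        graph.add_nodes_from(positions)
        for (p, q), (n_cis, n_trans) in votes[gene_id].items():
            top, orient = max((n_cis, "cis"), (n_trans, "trans"))
            total = n_cis + n_trans
            if n_cis == n_trans or top < min_support or top / total < min_majority:
                continue  # tie or weak support: edge removed, component splits
            graph.add_edge(p, q, orientation=orient, support=top,
                           conflict=total - top)
            co_support[(gene_id, p, q)] = top
        for comp in nx.connected_components(graph):
            members = tuple(sorted(comp))
            parity: dict[int, int] = {members[0]: 0}
            conflicts = 0
            for u, v in nx.bfs_edges(graph, members[0]):
                flip = 0 if graph.edges[u, v]["orientation"] == "cis" else 1
                parity[v] = parity[u] ^ flip
            for u, v, data in graph.subgraph(comp).edges(data=True):
                expected = "cis" if parity[u] == parity[v] else "trans"
                if data["orientation"] != expected:
                    conflicts += data["support"]
                conflicts += data["conflict"]
            hap_a = "".join(alleles[(gene_id, p)][parity[p]] for p in members)
            hap_b = "".join(alleles[(gene_id, p)][1 - parity[p]] for p in members)
            support = tuple(
                co_support.get((gene_id, p, q), 0)
                for p, q in zip(members, members[1:])
            )
            phase_sets.append(
                PhaseSet(gene_id, members, hap_a, hap_b, support, conflicts)
            )
    return sorted(phase_sets, key=lambda ps: (ps.gene_id, ps.positions))


def phase_lookup(phase_sets: Iterable[PhaseSet]) -> dict[tuple[str, int], tuple[int, str]]:
    """Map (gene, position) -> (phase-set id, haplotype-a base), for phased
    VCF-style output."""
    out: dict[tuple[str, int], tuple[int, str]] = {}
    for i, ps in enumerate(phase_sets):
        for pos, base in zip(ps.positions, ps.haplotype_a):
            out[(ps.gene_id, pos)] = (i + 1, base)
    return out


def write_phase_tsv(phase_sets: Iterable[PhaseSet], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tpositions\thap_a\thap_b\tsupport\tconflicts\n")
        for ps in phase_sets:
            fh.write(
                f"{ps.gene_id}\t{','.join(str(p + 1) for p in ps.positions)}\t"
                f"{ps.haplotype_a}\t{ps.haplotype_b}\t"
                f"{','.join(map(str, ps.support))}\t{ps.conflicts}\n"
            )
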