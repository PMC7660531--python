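"""Mapping, pileups, genotype calling and depth QC."""

import numpy as np
import pytest

from hemotyper.align import (
    GENOME_SIZE,
    GeneIndex,
    call_genotype,
    depth_report,
    full_pileup,
    gene_depth,
    genome_depth,
    map_reads,
    pileup,
    read_sam,
)
from hemotyper.db import AlleleDatabase, GeneReference, VariablePosition
from hemotyper.preprocess import ReadRecord
from hemotyper.simulate import SimulationSpec, revcomp, simulate_reads


class TestMapping:
    def test_error_free_reads_map_uniquely_at_true_offsets(self, db, gene_index):
        spec = SimulationSpec("SLC14A1", ("JK*01", "JK*01"), mean_depth=10,
                              base_error_rate=0.0, seed=2)
        pairs, manifest = simulate_reads(spec, db)
        alignments = map_reads(pairs, db, index=gene_index)
        assert alignments and all(a.status == "unique" for a in alignments)
        for a in alignments:
            hap, start, frag_len = manifest.fragments[a.read_name]
            expected = start if a.mate == 1 else start + frag_len - 150
            assert (a.gene_id, a.gene_start) == ("SLC14A1", expected)

    def test_empty_read_set(self, db, gene_index):
        assert map_reads([], db, index=gene_index) == []

    def test_reverse_strand_read_stored_gene_forward(self, db, gene_index):
        seq = db.genes["KEL"].sequence[500:650]
        r = ReadRecord("rev", revcomp(seq), (30,) * 150, 1)
        (a,) = map_reads([(r, r)], db, index=gene_index)[:1]
        assert a.is_reverse and a.bases == seq and a.gene_start == 500

    def test_paralogous_tie_reported_multi_and_excluded(self):
        # two genes sharing a 300-base block: reads from it are ambiguous
        import random
        rng = random.Random(0)
        shared = "".join(rng.choice("ACGT") for _ in range(300))
        tail_a = "".join(rng.choice("ACGT") for _ in range(300))
        tail_b = "".join(rng.choice("ACGT") for _ in range(300))
        ga = GeneReference("GA", "GA", shared + tail_a, ((0, 600),), 0, 600)
        gb = GeneReference("GB", "GB", shared + tail_b, ((0, 600),), 0, 600)
        pa = VariablePosition("GA", 10, f"c.11{shared[10]}>{'A' if shared[10] != 'A' else 'C'}",
                              shared[10], {"A" if shared[10] != "A" else "C"}, "exon")
        db2 = AlleleDatabase({"GA": ga, "GB": gb}, [pa], {"GA": [], "GB": []})
        r = ReadRecord("amb", shared[:150], (30,) * 150, 1)
        (a,) = map_reads([(r, r)], db2)[:1]
        assert a.status == "multi"
        counts = pileup(map_reads([(r, r)], db2), db2)
        assert sum(counts[("GA", 10)].values()) == 0


class TestPileup:
    def test_hom_ref_position_counts(self, db, gene_index):
        spec = SimulationSpec("CD44", ("IN*02", "IN*02"), mean_depth=20,
                              base_error_rate=0.0, seed=3)
        pairs, _ = simulate_reads(spec, db)
        counts = pileup(map_reads(pairs, db, index=gene_index), db)
        (pos,) = db.positions_for_gene("CD44")
        vp = db.positions[("CD44", pos)]
        assert set(counts[("CD44", pos)]) == {vp.ref_base}
        assert counts[("CD44", pos)][vp.ref_base] > 10

    def test_overlapping_mates_counted_once(self, db, gene_index):
        # fragment shorter than two read lengths: mates overlap mid-fragment
        spec = SimulationSpec("CD44", ("IN*02", "IN*02"), mean_depth=20,
                              base_error_rate=0.0, seed=4,
                              fragment_length_mean=170.0, fragment_length_sd=5.0)
        pairs, manifest = simulate_reads(spec, db)
        counts = pileup(map_reads(pairs, db, index=gene_index), db)
        (pos,) = db.positions_for_gene("CD44")
        n_fragments = sum(
            1 for _, start, frag_len in manifest.fragments.values()
            if start <= pos < start + frag_len
        )
        assert sum(counts[("CD44", pos)].values()) == n_fragments

    def test_depth_bounded_by_fragment_overlap_oracle(self, db, gene_index):
        spec = SimulationSpec("ICAM4", ("LW*05", "LW*07"), mean_depth=15,
                              base_error_rate=0.001, seed=5)
        pairs, manifest = simulate_reads(spec, db)
        counts = pileup(map_reads(pairs, db, index=gene_index), db)
        for pos in db.positions_for_gene("ICAM4"):
            overlap = sum(
                1 for _, start, frag_len in manifest.fragments.values()
                if start <= pos < start + frag_len
            )
            assert sum(counts[("ICAM4", pos)].values()) <= overlap

    def test_low_quality_bases_excluded(self, db, gene_index):
        seq = db.genes["AQP1"].sequence
        (pos,) = db.positions_for_gene("AQP1")
        start = pos - 10
        quals = [30] * 150
        quals[10] = 5  # the catalogued position, below the Q13 floor
        r1 = ReadRecord("lowq", seq[start : start + 150], tuple(quals), 1)
        r2 = ReadRecord("lowq", revcomp(seq[start + 150 : start + 300]), (30,) * 150, 2)
        counts = pileup(map_reads([(r1, r2)], db, index=gene_index), db)
        assert sum(counts[("AQP1", pos)].values()) == 0

    def test_full_pileup_matches_positional_pileup(self, db, gene_index):
        spec = SimulationSpec("ACHE", ("YT*01", "YT*02"), mean_depth=12,
                              base_error_rate=0.0, seed=6)
        pairs, _ = simulate_reads(spec, db)
        alignments = map_reads(pairs, db, index=gene_index)
        counts = pileup(alignments, db)
        mats = full_pileup(alignments, db)
        (pos,) = db.positions_for_gene("ACHE")
        dense = {b: int(mats["ACHE"][i, pos]) for i, b in enumerate("ACGT")
                 if mats["ACHE"][i, pos]}
        assert dense == dict(counts[("ACHE", pos)])


class TestGenotypeCalling:
    @pytest.mark.parametrize(
        "counts,genotype,reason",
        [
            ({"G": 4}, "no_call", "depth_below_min"),
            ({"G": 10}, "hom_ref", None),
            ({"A": 10}, "hom_alt", None),
            ({"G": 5, "A": 5}, "het", None),
            ({"G": 9, "A": 1}, "hom_ref", None),          # f = 0.1 <= hom band
            ({"G": 17, "A": 3}, "no_call", "ambiguous_fractions"),  # f = 0.15
            ({"G": 8, "A": 2}, "het", None),              # f = 0.2 reaches het band
            ({}, "no_call", "depth_below_min"),
        ],
    )
    def test_minor_fraction_bands(self, counts, genotype, reason):
        call = call_genotype("G1", 0, counts, ref_base="G")
        assert call.genotype == genotype
        assert call.no_call_reason == reason
        assert call.depth == sum(counts.values())

    def test_het_alleles_sorted(self):
        call = call_genotype("G1", 0, {"T": 6, "A": 6}, ref_base="T")
        assert call.alleles == ("A", "T")
        assert call.base_multiset() == ("A", "T")


class TestDepthFormulas:
    def test_gene_depth_arithmetic(self):
        assert gene_depth(1000, 150, 15000) == 10.0
        assert gene_depth(0, 150, 15000) == 0.0
        with pytest.raises(ValueError):
            gene_depth(10, 150, 0)

    def test_genome_depth_formula_and_constant(self):
        # 45 Gb of sequence on a 3 Gb genome = 15x
        assert genome_depth(300_000_000, 150, 3_000_000_000) == 15.0
        assert genome_depth(0) == 0.0
        assert genome_depth(100_000_000) == pytest.approx(
            15_000_000_000 / 2_867_437_753)
        assert GENOME_SIZE == 2_867_437_753

    def test_gene_depth_matches_per_base_coverage(self, db, gene_index):
        spec = SimulationSpec("ART4", ("DO*01", "DO*01"), mean_depth=25,
                              base_error_rate=0.0, seed=8)
        pairs, manifest = simulate_reads(spec, db)
        alignments = map_reads(pairs, db, index=gene_index)
        report = depth_report(alignments, db)
        # brute-force per-base coverage oracle
        L = db.genes["ART4"].length
        cov = np.zeros(L)
        for _, start, frag_len in manifest.fragments.values():
            cov[start : start + 150] += 1
            cov[start + frag_len - 150 : start + frag_len] += 1
        assert report.gene_depth("ART4") == pytest.approx(cov.mean(), rel=0.05)


class TestSamIngestion:
    def test_sam_roundtrip_agrees_with_internal_matcher(self, db, gene_index, tmp_path):
        import pysam

        spec = SimulationSpec("ICAM4", ("LW*05", "LW*07"), mean_depth=8,
                              base_error_rate=0.0, seed=9)
        pairs, _ = simulate_reads(spec, db)
        internal = map_reads(pairs, db, index=gene_index)

        header = {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": g, "LN": db.genes[g].length} for g in db.gene_ids()],
        }
        path = tmp_path / "sample.sam"
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for a in internal:
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = a.read_name
                rec.query_sequence = a.bases
                rec.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in a.qualities))
                rec.reference_name = a.gene_id
                rec.reference_start = a.gene_start
                rec.cigarstring = f"{len(a.bases)}M"
                rec.mapping_quality = 60
                rec.flag = (1 | (64 if a.mate == 1 else 128)
                            | (16 if a.is_reverse else 0))
                rec.set_tag("NM", a.mismatches)
                out.write(rec)
        external = read_sam(path, db)
        assert len(external) == len(internal)
        assert {(a.read_name, a.mate, a.gene_id, a.gene_start) for a in external} == \
               {(a.read_name, a.mate, a.gene_id, a.gene_start) for a in internal}
        assert pileup(external, db) == pileup(internal, db)

    def test_unknown_reference_rejected(self, db, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text("@SQ\tSN:HBB\tLN:1000\nr1\t0\tHBB\t1\t60\t10M\t*\t0\t0\t"
                        "ACGTACGTAC\tIIIIIIIIII\n")
        with pytest.raises(ValueError, match="not in database"):
            read_sam(path, db)
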