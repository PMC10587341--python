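"""Generator determinism, planted-truth consistency, and the statistical
structure of simulated reads and transcripts."""

import math
import random

import pytest

from immloci.annotate import Cassette, translate
from immloci.io import ParameterError, SeqRecord, revcomp
from immloci.simulate import (
    DefectRates,
    JunctionModel,
    LocusSpec,
    degrade_assembly,
    make_diploid_region,
    make_segment_library,
    plant_chromosome_ends,
    plant_locus,
    random_dna,
    simulate_long_reads,
    simulate_transcripts,
)


class TestSegmentLibrary:
    def test_same_seed_identical(self, trb_spec):
        a = make_segment_library(trb_spec, seed=1)
        b = make_segment_library(trb_spec, seed=1)
        assert a == b

    def test_different_seeds_differ(self, trb_spec):
        a = make_segment_library(trb_spec, seed=1)
        b = make_segment_library(trb_spec, seed=2)
        assert any(x.seq != y.seq for x, y in zip(a, b))

    def test_v_entries_are_clean_orfs(self, trb_locus):
        library, _, _ = trb_locus
        for entry in library:
            if entry.seg_type != "V":
                continue
            assert entry.seq.startswith("ATG")
            assert 258 <= len(entry.seq) <= 318
            aa = translate(entry.seq)
            assert "*" not in aa
            assert aa[entry.cys_codon] == "C"

    def test_j_entries_carry_motif(self, trb_locus):
        library, _, _ = trb_locus
        import re

        for entry in library:
            if entry.seg_type != "J":
                continue
            aa = translate(entry.seq)
            assert re.search(r"[FW]G.G", aa)


class TestPlantLocus:
    def test_truth_segments_extract_to_library_sequence(self, trb_locus):
        library, chromosome, truth = trb_locus
        by_name = {e.name: e for e in library}
        for seg in truth.segments:
            sub = chromosome.seq[seg.interval.start : seg.interval.end]
            if seg.interval.strand == "-":
                sub = revcomp(sub)
            assert sub == by_name[seg.name].seq

    def test_defect_free_truth_all_functional(self, trb_locus):
        _, _, truth = trb_locus
        assert len(truth.segments) == 17
        assert all(s.functionality == "F" for s in truth.segments)

    def test_cassette_order(self, trb_cassette_locus):
        _, _, _, truth = trb_cassette_locus
        tail = [s.seg_type for s in truth.segments][4:]  # after the V block
        expected = (
            ["D"] + ["J"] * 6 + ["C"] + ["D"] + ["J"] * 7 + ["C"] + ["D"] + ["J"] * 6 + ["C"]
        )
        assert tail == expected

    def test_forced_stop_defect(self):
        spec = LocusSpec(
            locus="IGH", n_v=5, n_j=2, n_c=1, defect_rates=DefectRates(stop_codon=1.0)
        )
        library = make_segment_library(spec, seed=7)
        _, truth = plant_locus(library, spec, seed=8)
        v_truth = [s for s in truth.segments if s.seg_type == "V"]
        assert all(s.functionality == "P" for s in v_truth)
        assert all("internal_stop" in s.defect_flags for s in v_truth)

    def test_byte_determinism(self, trb_spec):
        library = make_segment_library(trb_spec, seed=1)
        c1, t1 = plant_locus(library, trb_spec, seed=2)
        c2, t2 = plant_locus(library, trb_spec, seed=2)
        assert c1.seq == c2.seq
        assert [s.interval for s in t1.segments] == [s.interval for s in t2.segments]


class TestChromosomeEnds:
    def test_telomere_appended(self):
        base = SeqRecord(id="c", seq=random_dna(random.Random(1), 5_000))
        out, truth = plant_chromosome_ends(base, telomere_units=3_000, seed=0)
        assert out.seq.endswith("TTAGGG" * 3)
        assert out.seq[-18_000:] == "TTAGGG" * 3_000
        assert len(truth.telomeres[0]) == 18_000

    def test_zero_units_identity(self):
        base = SeqRecord(id="c", seq=random_dna(random.Random(1), 5_000))
        out, truth = plant_chromosome_ends(base, telomere_units=0, seed=0)
        assert out.seq == base.seq and not truth.telomeres

    def test_satdna_truth_length(self):
        base = SeqRecord(id="c", seq=random_dna(random.Random(1), 5_000))
        pattern = random_dna(random.Random(2), 23)
        out, truth = plant_chromosome_ends(
            base, telomere_units=0, satdna_pattern=pattern, satdna_copies=200, seed=0
        )
        iv = truth.satdna[0]
        assert len(iv) == 4_600
        assert out.seq[iv.start : iv.end] == pattern * 200


class TestDegradeAssembly:
    def test_gap_census_and_truth(self):
        genome = [SeqRecord(id="chr1", seq=random_dna(random.Random(1), 60_000))]
        old, scaffolds, truth = degrade_assembly(
            genome, n_gaps=5, gap_len_range=(200, 800), n_excised_scaffolds=0, seed=6
        )
        import re

        runs = [m.span() for m in re.finditer("N+", old[0].seq)]
        assert len(runs) == 5
        for gap in truth.gaps:
            assert old[0].seq[gap.old_interval.start : gap.old_interval.end].strip("N") == ""
            assert len(gap.old_interval) == len(gap.new_interval)

    def test_excised_scaffold_matches_origin(self):
        genome = [SeqRecord(id="chr1", seq=random_dna(random.Random(2), 60_000))]
        _, scaffolds, truth = degrade_assembly(
            genome, n_gaps=0, gap_len_range=(200, 800), n_excised_scaffolds=2, seed=3
        )
        by_id = {s.id: s for s in scaffolds}
        for placement in truth.placements:
            iv = placement.new_interval
            assert by_id[placement.scaffold_id].seq == genome[0].seq[iv.start : iv.end]


class TestDiploidRegion:
    def test_zero_density_identical(self):
        h1, h2, variants = make_diploid_region(10_000, 0.0, seed=1)
        assert h1.seq == h2.seq and not variants

    def test_site_count_within_binomial_bounds(self):
        n, p = 100_000, 1e-3
        _h1, _h2, variants = make_diploid_region(n, p, seed=5)
        mean = n * p
        sd = math.sqrt(n * p * (1 - p))
        assert abs(len(variants) - mean) <= 3 * sd

    def test_all_truth_sites_differ(self):
        h1, h2, variants = make_diploid_region(50_000, 1e-3, seed=2)
        for v in variants:
            assert h1.seq[v.pos] == v.ref != v.alt == h2.seq[v.pos]
            assert v.gt == (0, 1) and v.phased


class TestLongReads:
    def test_error_free_reads_match_origin(self):
        h1, h2, _ = make_diploid_region(50_000, 1e-3, seed=1)
        reads, paf = simulate_long_reads((h1, h2), depth=5, mean_len=8_000, error_rate=0.0, seed=2)
        haps = {h1.id: h1, h2.id: h2}
        for read, row in zip(reads, paf):
            origin = haps[row.target_name].seq[row.target_start : row.target_end]
            assert read.seq == origin

    def test_interior_depth_within_20pct(self):
        h1, h2, _ = make_diploid_region(100_000, 0.0, seed=1)
        depth, mean_len = 30, 15_000
        reads, paf = simulate_long_reads((h1, h2), depth=depth, mean_len=mean_len, error_rate=0.0, seed=4)
        cover = [0] * 100_000
        for row in paf:
            for pos in range(row.target_start, row.target_end):
                cover[pos] += 1
        interior = cover[mean_len : 100_000 - mean_len]
        mean_cover = sum(interior) / len(interior)
        assert abs(mean_cover - depth) <= 0.2 * depth

    def test_haplotype_alternation(self):
        h1, h2, _ = make_diploid_region(20_000, 0.0, seed=1)
        _, paf = simulate_long_reads((h1, h2), depth=10, mean_len=4_000, error_rate=0.0, seed=3)
        n0 = sum(1 for r in paf if r.target_name == h1.id)
        n1 = len(paf) - n0
        assert abs(n0 - n1) <= 1


class TestTranscripts:
    def test_point_mass_weights(self, igh_repertoire):
        library, _, _, _ = igh_repertoire
        weights = {"V": {"IGHV1": 1.0}, "J": {"IGHJ1": 1.0}}
        _, truth = simulate_transcripts(library, weights, JunctionModel(), n=50, seed=2)
        assert all(t.v_name == "IGHV1" and t.j_name == "IGHJ1" for t in truth)

    def test_zero_trim_verbatim_v(self, igh_repertoire):
        library, weights, _, _ = igh_repertoire
        jm = JunctionModel(trim_max=0, n_max=0, productive_fraction=1.0)
        transcripts, truth = simulate_transcripts(library, weights, jm, n=20, seed=3)
        by_name = {e.name: e for e in library}
        for tx, tr in zip(transcripts, truth):
            assert by_name[tr.v_name].seq in tx.seq

    def test_v_frequency_within_3se(self, igh_repertoire):
        library, weights, _, _ = igh_repertoire
        n = 2_000
        _, truth = simulate_transcripts(library, weights, JunctionModel(), n=n, seed=9)
        se = math.sqrt(0.1 * 0.9 / n)
        for name in weights["V"]:
            freq = sum(t.v_name == name for t in truth) / n
            assert abs(freq - 0.1) <= 3 * se

    def test_bad_weights_rejected(self, igh_repertoire):
        library, _, _, _ = igh_repertoire
        with pytest.raises(ParameterError):
            simulate_transcripts(
                library,
                {"V": {"IGHV1": 0.7}, "J": {"IGHJ1": 1.0}},
                JunctionModel(),
                n=5,
                seed=1,
            )
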