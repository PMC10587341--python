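"""Segment recovery, RSS detection, functionality classification and
locus-formula synthesis against planted ground truth."""

import random

import pytest

from immloci.annotate import (
    Cassette,
    GeneSegment,
    RSS_HEPTAMER,
    RSS_NONAMER,
    _scan_flank,
    build_locus_structure,
    classify_functionality,
    detect_rss,
    expand_formula,
    find_segments,
    summarize_loci,
    tabulate_counts,
)
from immloci.io import GenomicInterval, SegmentLibraryEntry, ValidationError
from immloci.simulate import (
    DefectRates,
    LocusSpec,
    make_segment_library,
    plant_locus,
    random_dna,
)


def classify_all(chromosome, library, segments, **kwargs):
    by_name = {e.name: e for e in library}
    seqs = {chromosome.id: chromosome.seq}
    return [classify_functionality(seqs, s, by_name, **kwargs) for s in segments]


class TestFindSegments:
    def test_planted_recovery_exact(self, trb_locus):
        library, chromosome, truth = trb_locus
        segments = find_segments([chromosome], library)
        assert len(segments) == 17
        truth_iv = {s.name: s.interval for s in truth.segments}
        for seg in segments:
            assert seg.interval == truth_iv[seg.name]
            assert seg.identity_to_reference == 100.0

    def test_near_identical_library_entries_merge(self):
        rng = random.Random(19)
        spec = LocusSpec(locus="IGK", n_v=1, n_j=1, n_c=1)
        library = make_segment_library(spec, seed=19)
        chromosome, _ = plant_locus(library, spec, seed=20)
        v = next(e for e in library if e.seg_type == "V")
        twin_seq = list(v.seq)
        for p in rng.sample(range(len(twin_seq)), 3):  # ~99% identical twin
            twin_seq[p] = rng.choice([b for b in "ACGT" if b != twin_seq[p]])
        twin = SegmentLibraryEntry(
            name="IGKV99", locus="IGK", seg_type="V", seq="".join(twin_seq)
        )
        segments = find_segments([chromosome], library + [twin])
        v_hits = [s for s in segments if s.seg_type == "V"]
        assert len(v_hits) == 1
        assert v_hits[0].name == v.name  # the exact entry wins the merge

    def test_minus_strand_locus_order_and_coords(self):
        spec = LocusSpec(locus="TRA", n_v=5, n_j=3, n_c=1, strand="-")
        library = make_segment_library(spec, seed=1)
        chromosome, truth = plant_locus(library, spec, seed=2)
        segments = find_segments([chromosome], library)
        assert [s.name for s in segments] == [s.name for s in truth.segments]
        assert all(s.interval.strand == "-" for s in segments)
        truth_iv = {s.name: s.interval for s in truth.segments}
        assert all(s.interval == truth_iv[s.name] for s in segments)


class TestDetectRSS:
    def _planted_segment(self, spec_kwargs, seed=30):
        spec = LocusSpec(**spec_kwargs)
        library = make_segment_library(spec, seed=seed)
        chromosome, truth = plant_locus(library, spec, seed=seed + 1)
        return chromosome, truth

    def test_perfect_consensus_scores_one(self):
        chromosome, truth = self._planted_segment(dict(locus="TRB", n_v=2, n_j=1, n_c=1))
        v = next(s for s in truth.segments if s.seg_type == "V")
        rss = detect_rss(chromosome.seq, v)
        assert rss is not None
        assert rss.score == 1.0
        assert rss.heptamer == RSS_HEPTAMER and rss.nonamer == RSS_NONAMER
        assert rss.spacer_len == 23  # heavy-type locus

    def test_single_heptamer_change_still_detected(self):
        flank = "CTCAGTG" + "A" * 23 + RSS_NONAMER + "ACGT" * 6
        rss = _scan_flank(flank)
        assert rss is not None
        assert rss.score == pytest.approx((6 / 7 + 1.0) / 2, abs=1e-9)

    def test_random_flanks_rarely_score(self):
        rng = random.Random(11)
        false_positives = 0
        for _ in range(100):
            best = _scan_flank(random_dna(rng, 60))
            if best is not None and best.score >= 0.7:
                false_positives += 1
        assert false_positives <= 5

    def test_j_segment_5prime_flank(self):
        chromosome, truth = self._planted_segment(dict(locus="IGK", n_v=1, n_j=2, n_c=1))
        j = next(s for s in truth.segments if s.seg_type == "J")
        rss = detect_rss(chromosome.seq, j)
        assert rss is not None and rss.score == 1.0


class TestClassifyFunctionality:
    def test_defect_free_all_functional(self, trb_locus):
        library, chromosome, truth = trb_locus
        segments = find_segments([chromosome], library)
        classified = classify_all(chromosome, library, segments)
        assert all(s.functionality == "F" and not s.defect_flags for s in classified)

    @pytest.mark.parametrize(
        "rates,expected_v,expected_flag",
        [
            (DefectRates(stop_codon=1.0), "P", "internal_stop"),
            (DefectRates(frameshift=1.0), "P", "frameshift"),
            (DefectRates(rss_mutation=1.0), "ORF", "bad_rss"),
        ],
    )
    def test_forced_defects_recovered(self, rates, expected_v, expected_flag):
        spec = LocusSpec(locus="TRB", n_v=4, n_j=2, n_c=1, defect_rates=rates)
        library = make_segment_library(spec, seed=12)
        chromosome, truth = plant_locus(library, spec, seed=13)
        segments = find_segments([chromosome], library)
        classified = classify_all(chromosome, library, segments)
        for seg in classified:
            if seg.seg_type == "V":
                assert seg.functionality == expected_v
                assert expected_flag in seg.defect_flags

    def test_functionality_matches_truth_with_mixed_defects(self):
        spec = LocusSpec(
            locus="IGH",
            n_v=12,
            n_j=3,
            n_c=1,
            defect_rates=DefectRates(stop_codon=0.3, frameshift=0.2, rss_mutation=0.3),
        )
        library = make_segment_library(spec, seed=40)
        chromosome, truth = plant_locus(library, spec, seed=41)
        segments = find_segments([chromosome], library)
        classified = classify_all(chromosome, library, segments)
        truth_fn = {s.name: s.functionality for s in truth.segments}
        observed = {s.name: s.functionality for s in classified}
        assert observed == truth_fn


class TestLocusStructure:
    def _segments_from_types(self, locus, types, last_name=None):
        out = []
        pos = 0
        counters = {t: 0 for t in "VDJC"}
        for t in types:
            counters[t] += 1
            out.append(
                GeneSegment(
                    name=f"{locus}{t}{counters[t]}",
                    locus=locus,
                    seg_type=t,
                    interval=GenomicInterval("c", pos, pos + 10),
                )
            )
            pos += 20
        if last_name:
            from dataclasses import replace

            out[-1] = replace(out[-1], name=last_name)
        return out

    def test_trb_printed_pattern(self):
        types = (
            ["V"] * 152
            + ["D"] + ["J"] * 6 + ["C"]
            + ["D"] + ["J"] * 7 + ["C"]
            + ["D"] + ["J"] * 6 + ["C"]
            + ["V"]
        )
        segments = self._segments_from_types("TRB", types, last_name="TRBV30")
        structure = build_locus_structure(segments)
        assert structure.formula == "(TRBV)152-[TRBD-(TRBJ)6/7-TRBC]3-TRBV30"
        assert structure.expand() == types

    def test_igl_printed_pattern(self):
        types = ["J", "C"] * 6
        structure = build_locus_structure(self._segments_from_types("IGL", types))
        assert structure.formula == "(IGLJ-IGLC)6"
        assert structure.expand() == types
        assert expand_formula(structure.formula) == types

    def test_single_segment_renders_name(self):
        structure = build_locus_structure(self._segments_from_types("TRG", ["V"]))
        assert structure.formula == "TRGV1"
        assert structure.expand() == ["V"]

    def test_round_trip_on_random_structures(self):
        rng = random.Random(8)
        for _ in range(50):
            types = []
            for _block in range(rng.randint(1, 4)):
                unit = [rng.choice("VDJC") for _ in range(rng.randint(1, 3))]
                copies = rng.randint(1, 4)
                for _c in range(copies):
                    for t in unit:
                        types.extend([t] * rng.randint(1, 3))
            # collapse impossible adjacencies is unnecessary: any list is valid
            structure = build_locus_structure(self._segments_from_types("TRA", types))
            assert structure.expand() == types

    def test_empty_structure(self):
        structure = build_locus_structure([])
        assert structure.formula == "" and structure.expand() == []


class TestSummary:
    def test_printed_v_row_aggregation(self):
        from immloci.reported import NCBA_BOST1_GENE_COUNTS

        table = tabulate_counts(NCBA_BOST1_GENE_COUNTS)
        assert table.loc[("V", "total"), "Sum"] == 741
        assert table.loc[("V", "F"), "Sum"] == 355
        assert table.loc[("Sum", "total"), "Sum"] == 915

    def test_summary_from_structures_partition(self, trb_locus):
        library, chromosome, truth = trb_locus
        segments = find_segments([chromosome], library)
        classified = classify_all(chromosome, library, segments)
        table = summarize_loci([build_locus_structure(classified)])
        for seg_type in "VDJC":
            total = table.loc[(seg_type, "total"), "TRB"]
            parts = sum(table.loc[(seg_type, cls), "TRB"] for cls in ("F", "P", "ORF"))
            assert total == parts

    def test_empty_and_duplicate_loci(self):
        table = tabulate_counts({})
        assert table["Sum"].sum() == 0
        with pytest.raises(ValidationError):
            summarize_loci(
                [
                    build_locus_structure([]),
                    build_locus_structure([]),
                ]
            )
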