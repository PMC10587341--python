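"""Alignment engine: exactness against a brute-force affine DP, banding,
seeding and mapping of planted sequences."""

import random
import re

import pytest

from immloci.align import (
    AlignmentScoring,
    build_seed_index,
    local_align,
    map_query,
)
from immloci.io import ParameterError, SeqRecord, revcomp

SCORING = AlignmentScoring()


def brute_force_score(q: str, t: str, sc: AlignmentScoring) -> int:
    """Plain-python affine local DP; the oracle for the vectorised aligner."""
    n, m = len(q), len(t)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(m + 1):
            E[i][j] = max(H[i - 1][j] + sc.gap_open, E[i - 1][j] + sc.gap_extend)
            if j > 0:
                F[i][j] = max(H[i][j - 1] + sc.gap_open, F[i][j - 1] + sc.gap_extend)
                s = sc.match if q[i - 1] == t[j - 1] else sc.mismatch
                H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            else:
                H[i][j] = max(0, E[i][j])
            best = max(best, H[i][j])
    return best


def random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def test_self_alignment_example():
    a = local_align(
        SeqRecord(id="q", seq="ACGTTGCA"),
        SeqRecord(id="t", seq="ACGTTGCA"),
        AlignmentScoring(1, -2, -3, -1),
    )
    assert a.score == 8 and a.identity == 100.0 and a.cigar == "8M"


def test_single_base_match():
    a = local_align(
        SeqRecord(id="q", seq="ACGT"),
        SeqRecord(id="t", seq="TTTT"),
        AlignmentScoring(1, -2, -3, -1),
    )
    assert a.score == 1  # brute force over 4x4: best is one T matched


def test_score_matches_brute_force_on_random_pairs():
    rng = random.Random(7)
    for _ in range(150):
        q = random_seq(rng, rng.randint(1, 30))
        t = random_seq(rng, rng.randint(1, 30))
        a = local_align(SeqRecord(id="q", seq=q), SeqRecord(id="t", seq=t), SCORING)
        assert a.score == brute_force_score(q, t, SCORING)


def test_alignment_internals_consistent():
    """CIGAR lengths, intervals and match counts agree along the traced path."""
    rng = random.Random(13)
    for _ in range(100):
        q = random_seq(rng, rng.randint(5, 40))
        t = random_seq(rng, rng.randint(5, 40))
        a = local_align(SeqRecord(id="q", seq=q), SeqRecord(id="t", seq=t), SCORING)
        if a.is_empty:
            continue
        ops = [(int(c), op) for c, op in re.findall(r"(\d+)([MID])", a.cigar)]
        assert sum(c for c, _ in ops) == a.block_length
        assert sum(c for c, op in ops if op in "MI") == len(a.query_interval)
        assert sum(c for c, op in ops if op in "MD") == len(a.target_interval)
        pi, pj, matches = a.query_interval.start, a.target_interval.start, 0
        for c, op in ops:
            if op == "M":
                matches += sum(q[pi + x] == t[pj + x] for x in range(c))
                pi += c
                pj += c
            elif op == "I":
                pi += c
            else:
                pj += c
        assert matches == a.matches
        assert a.matches <= a.block_length
        assert 0 <= a.identity <= 100


def test_banded_equals_unbanded_when_band_covers_all():
    rng = random.Random(7)
    for _ in range(150):
        q = random_seq(rng, rng.randint(1, 30))
        t = random_seq(rng, rng.randint(1, 30))
        full = local_align(SeqRecord(id="q", seq=q), SeqRecord(id="t", seq=t), SCORING)
        banded = local_align(
            SeqRecord(id="q", seq=q), SeqRecord(id="t", seq=t), SCORING, band=60
        )
        assert banded.score == full.score


def test_score_symmetry():
    rng = random.Random(21)
    for _ in range(50):
        q = random_seq(rng, rng.randint(1, 25))
        t = random_seq(rng, rng.randint(1, 25))
        ab = local_align(SeqRecord(id="a", seq=q), SeqRecord(id="b", seq=t), SCORING)
        ba = local_align(SeqRecord(id="b", seq=t), SeqRecord(id="a", seq=q), SCORING)
        assert ab.score == ba.score


def test_identity_invariant_under_target_shift():
    rng = random.Random(5)
    core = random_seq(rng, 200)
    query = SeqRecord(id="q", seq=core[50:150])
    t1 = SeqRecord(id="t1", seq=core)
    t2 = SeqRecord(id="t2", seq=random_seq(rng, 300) + core)
    a1 = local_align(query, t1, SCORING)
    a2 = local_align(query, t2, SCORING)
    assert a1.identity == a2.identity == 100.0
    assert a2.target_interval.start == a1.target_interval.start + 300


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def test_seed_index_positions_and_n_exclusion():
    index = build_seed_index([SeqRecord(id="t", seq="ACGTACGTACGT")], k=8)
    canonical = min("ACGTACGT", revcomp("ACGTACGT"))
    positions = {pos for _tidx, pos, _fwd in index.table[canonical]}
    assert positions == {0, 4}
    index2 = build_seed_index([SeqRecord(id="t", seq="ACGTNACGTACG")], k=8)
    assert not any("N" in k for k in index2.table)
    assert build_seed_index([], k=13).table == {}


@pytest.mark.parametrize("k", [7, 22])
def test_seed_index_k_range(k):
    with pytest.raises(ParameterError):
        build_seed_index([SeqRecord(id="t", seq="ACGTACGTACGTACGTACGTACGT")], k=k)


def test_map_query_planted_exact_copy():
    rng = random.Random(11)
    target = SeqRecord(id="t", seq=random_seq(rng, 50_000))
    start = 17_000
    query = SeqRecord(id="q", seq=target.seq[start : start + 500])
    index = build_seed_index([target], k=13)
    hits = map_query(query, index, [target], SCORING)
    assert hits and hits[0].identity == 100.0
    assert hits[0].target_interval.start == start
    assert hits[0].target_interval.end == start + 500
    assert hits[0].strand == "+"
    assert hits[0].unique

    rc_query = SeqRecord(id="q", seq=revcomp(query.seq))
    rc_hits = map_query(rc_query, index, [target], SCORING)
    assert rc_hits[0].strand == "-"
    assert rc_hits[0].target_interval.start == start
    assert rc_hits[0].target_interval.end == start + 500


def test_map_query_mutated_copy():
    rng = random.Random(3)
    target = SeqRecord(id="t", seq=random_seq(rng, 50_000))
    start = 30_000
    sub = list(target.seq[start : start + 500])
    for p in rng.sample(range(500), 25):  # 5% substitutions
        sub[p] = rng.choice([b for b in "ACGT" if b != sub[p]])
    query = SeqRecord(id="q", seq="".join(sub))
    index = build_seed_index([target], k=13)
    hits = map_query(query, index, [target], SCORING)
    assert hits
    assert 93.0 <= hits[0].identity <= 97.0
    assert abs(hits[0].target_interval.start - start) <= 5
    assert abs(hits[0].target_interval.end - (start + 500)) <= 5


def test_map_query_repeated_plantings_always_exact():
    rng = random.Random(17)
    target = SeqRecord(id="t", seq=random_seq(rng, 30_000))
    index = build_seed_index([target], k=13)
    for _ in range(30):
        start = rng.randint(0, len(target.seq) - 300)
        query = SeqRecord(id="q", seq=target.seq[start : start + 300])
        hits = map_query(query, index, [target], SCORING)
        assert hits[0].identity == 100.0
        assert hits[0].target_interval.start == start
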