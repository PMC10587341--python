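"""Het-SNP calling, wMEC phasing (exact and greedy), read partitioning,
consensus haplotigs and MHC transcript validation."""

import random

import pytest

from immloci.io import SeqRecord
from immloci.phase import (
    HetSite,
    ReadAlleleMatrix,
    _block_cost,
    build_allele_matrix,
    haplotype_consensus,
    partition_reads,
    phase_wmec,
    pileup_het_snps,
    validate_mhc_genes,
)
from immloci.io import ValidationError
from immloci.simulate import make_diploid_region, random_dna, simulate_long_reads


@pytest.fixture(scope="module")
def diploid_30x():
    hap1, hap2, truth_vcf = make_diploid_region(100_000, 1e-3, seed=5)
    reads, paf = simulate_long_reads(
        (hap1, hap2), depth=30, mean_len=20_000, error_rate=0.0, seed=8
    )
    region = SeqRecord(id="ref", seq=hap1.seq)
    alignments = list(zip(reads, paf))
    truth_hap = {row.query_name: int(row.tags[0][-1]) for row in paf}
    return region, hap1, hap2, truth_vcf, alignments, truth_hap


def brute_force_mec(matrix: ReadAlleleMatrix, columns) -> float:
    reads = [r for r in matrix.entries if any(c in matrix.entries[r] for c in columns)]
    best = None
    for bits in range(2 ** len(reads)):
        assignment = {r: (bits >> i) & 1 for i, r in enumerate(reads)}
        cost, _h0, _h1 = _block_cost(matrix, list(columns), assignment)
        best = cost if best is None else min(best, cost)
    return best


def make_matrix(rows: dict[str, dict[int, int]], n_cols: int) -> ReadAlleleMatrix:
    sites = [HetSite(10 * i, "A", "G", 20, 0.5) for i in range(n_cols)]
    matrix = ReadAlleleMatrix(sites=sites)
    for read_id, cols in rows.items():
        matrix.entries[read_id] = {c: (a, 1.0) for c, a in cols.items()}
    return matrix


class TestPileup:
    def test_error_free_calls_match_truth_interior(self, diploid_30x):
        region, _, _, truth_vcf, alignments, _ = diploid_30x
        called = pileup_het_snps(alignments, region)
        truth_pos = {v.pos for v in truth_vcf}
        called_pos = {s.position for s in called}
        assert called_pos <= truth_pos  # no false positives anywhere
        interior = {p for p in truth_pos if 20_000 <= p <= 80_000}
        assert interior <= called_pos  # full recall away from coverage edges
        for site in called:
            assert 0.25 <= site.alt_fraction <= 0.75

    def test_homozygous_positions_not_called(self, diploid_30x):
        region, _, _, truth_vcf, alignments, _ = diploid_30x
        called_pos = {s.position for s in pileup_het_snps(alignments, region)}
        truth_pos = {v.pos for v in truth_vcf}
        assert not (called_pos - truth_pos)

    def test_noisy_reads_recall_and_precision(self):
        hap1, hap2, truth_vcf = make_diploid_region(60_000, 1e-3, seed=5)
        reads, paf = simulate_long_reads(
            (hap1, hap2), depth=30, mean_len=15_000, error_rate=0.02, seed=8
        )
        region = SeqRecord(id="ref", seq=hap1.seq)
        called = pileup_het_snps(list(zip(reads, paf)), region)
        truth_pos = {v.pos for v in truth_vcf if 15_000 <= v.pos <= 45_000}
        called_pos = {s.position for s in called if 15_000 <= s.position <= 45_000}
        recall = len(called_pos & truth_pos) / len(truth_pos)
        precision = len(called_pos & truth_pos) / len(called_pos)
        assert recall >= 0.95 and precision >= 0.95


class TestWMEC:
    def test_consistent_reads_single_block(self):
        matrix = make_matrix({"r1": {0: 0, 1: 0}, "r2": {1: 0, 2: 1}}, 3)
        blocks = phase_wmec(matrix)
        assert len(blocks) == 1
        block = blocks[0]
        assert block.mec_cost == 0
        assert block.hap0 == "001"
        assert block.hap1 == "110"

    def test_one_discordant_read_costs_one(self):
        matrix = make_matrix(
            {"r1": {0: 0, 1: 0}, "r2": {1: 0, 2: 1}, "r3": {0: 0, 1: 1}}, 3
        )
        blocks = phase_wmec(matrix)
        assert blocks[0].mec_cost == brute_force_mec(matrix, blocks[0].columns) == 1
        assert blocks[0].hap0 == "001"  # majority phase unchanged

    def test_disjoint_reads_make_two_blocks(self):
        matrix = make_matrix({"r1": {0: 0, 1: 1}, "r2": {3: 1, 4: 0}}, 5)
        blocks = phase_wmec(matrix)
        assert len(blocks) == 2
        assert blocks[0].columns == [0, 1]
        assert blocks[1].columns == [3, 4]

    def test_exact_dp_equals_brute_force(self):
        rng = random.Random(3)
        for _ in range(120):
            n_cols = rng.randint(2, 5)
            n_reads = rng.randint(2, 8)
            rows = {}
            for i in range(n_reads):
                a = rng.randint(0, n_cols - 1)
                b = rng.randint(a, n_cols - 1)
                rows[f"r{i}"] = {c: rng.randint(0, 1) for c in range(a, b + 1)}
            matrix = make_matrix(rows, n_cols)
            blocks = phase_wmec(matrix)
            assert all(b.exact for b in blocks)
            total = sum(b.mec_cost for b in blocks)
            brute = sum(brute_force_mec(matrix, b.columns) for b in blocks)
            assert total == brute

    def test_read_order_invariance_up_to_flip(self):
        rng = random.Random(14)
        rows = {}
        for i in range(8):
            a = rng.randint(0, 3)
            b = rng.randint(a, 3)
            rows[f"r{i}"] = {c: rng.randint(0, 1) for c in range(a, b + 1)}
        matrix = make_matrix(rows, 4)
        blocks = phase_wmec(matrix)
        shuffled = make_matrix(rows, 4)
        order = list(rows)
        rng.shuffle(order)
        shuffled.entries = {r: shuffled.entries[r] for r in order}
        blocks2 = phase_wmec(shuffled)
        assert blocks[0].mec_cost == blocks2[0].mec_cost
        assert blocks2[0].hap0 in (blocks[0].hap0, blocks[0].hap1)

    def test_hap1_complement_invariant(self):
        rng = random.Random(15)
        rows = {
            f"r{i}": {c: rng.randint(0, 1) for c in range(rng.randint(0, 2), 4)}
            for i in range(6)
        }
        for block in phase_wmec(make_matrix(rows, 4)):
            assert all(a != b for a, b in zip(block.hap0, block.hap1))
            assert block.hap0[0] == "0"


class TestEndToEndPhasing:
    def test_single_block_matches_truth_phasing(self, diploid_30x):
        region, _, _, _, alignments, truth_hap = diploid_30x
        sites = pileup_het_snps(alignments, region)
        matrix = build_allele_matrix(alignments, sites)
        blocks = phase_wmec(matrix)
        assert len(blocks) == 1
        block = blocks[0]
        assert block.mec_cost == 0
        # reference is haplotype 1, so truth hap0 is all reference alleles
        assert set(block.hap0) == {"0"}

    def test_partition_matches_truth_origin(self, diploid_30x):
        region, _, _, _, alignments, truth_hap = diploid_30x
        sites = pileup_het_snps(alignments, region)
        matrix = build_allele_matrix(alignments, sites)
        blocks = phase_wmec(matrix)
        (set0, set1), = partition_reads(matrix, blocks)
        correct = sum(truth_hap[r] == 0 for r in set0) + sum(truth_hap[r] == 1 for r in set1)
        flipped = sum(truth_hap[r] == 1 for r in set0) + sum(truth_hap[r] == 0 for r in set1)
        assert max(correct, flipped) == len(set0) + len(set1)

    def test_tied_read_unassigned(self):
        matrix = make_matrix({"r1": {0: 0, 1: 0}, "r2": {0: 1, 1: 1}, "tie": {0: 0, 1: 1}}, 2)
        blocks = phase_wmec(matrix)
        (set0, set1), = partition_reads(matrix, blocks)
        assert "tie" not in set0 | set1

    def test_consensus_recovers_haplotypes(self, diploid_30x):
        region, hap1, hap2, _, alignments, truth_hap = diploid_30x
        sites = pileup_het_snps(alignments, region)
        matrix = build_allele_matrix(alignments, sites)
        blocks = phase_wmec(matrix)
        (set0, set1), = partition_reads(matrix, blocks)
        h0 = haplotype_consensus(set0, alignments, region, "h0")
        h1 = haplotype_consensus(set1, alignments, region, "h1")
        # identity holds over the well-covered span; edge het sites below the
        # pileup depth cutoff are uncalled and fall back to the reference base
        span = slice(20_000, 80_000)
        built = {h0.seq[span], h1.seq[span]}
        assert {hap1.seq[span], hap2.seq[span]} == built

    def test_consensus_without_reads_is_reference(self):
        region = SeqRecord(id="ref", seq=random_dna(random.Random(1), 1_000))
        out = haplotype_consensus(set(), [], region)
        assert out.seq == region.seq

    def test_noisy_consensus_identity(self):
        hap1, hap2, _ = make_diploid_region(60_000, 1e-3, seed=5)
        reads, paf = simulate_long_reads(
            (hap1, hap2), depth=30, mean_len=15_000, error_rate=0.02, seed=8
        )
        region = SeqRecord(id="ref", seq=hap1.seq)
        alignments = list(zip(reads, paf))
        truth_hap = {row.query_name: int(row.tags[0][-1]) for row in paf}
        sites = pileup_het_snps(alignments, region)
        matrix = build_allele_matrix(alignments, sites)
        blocks = phase_wmec(matrix)
        partitions = partition_reads(matrix, blocks)
        set0 = set().union(*(p[0] for p in partitions))
        set1 = set().union(*(p[1] for p in partitions))
        assigned = len(set0) + len(set1)
        correct = sum(truth_hap[r] == 0 for r in set0) + sum(truth_hap[r] == 1 for r in set1)
        correct = max(correct, assigned - correct)
        assert correct / assigned >= 0.95
        hap = haplotype_consensus(set0, alignments, region)
        span = slice(15_000, 45_000)
        target = hap1.seq if sum(truth_hap[r] == 0 for r in set0) * 2 >= len(set0) else hap2.seq
        matches = sum(a == b for a, b in zip(hap.seq[span], target[span]))
        assert matches / 30_000 >= 0.999


class TestValidateMHC:
    def test_two_pairs_vs_one_pair(self):
        rng = random.Random(42)
        dqa, dqb = random_dna(rng, 800), random_dna(rng, 900)
        genes = [SeqRecord(id="DQA", seq=dqa), SeqRecord(id="DQB", seq=dqb)]
        hap1 = (
            random_dna(rng, 3_000) + dqb + random_dna(rng, 2_000) + dqa
            + random_dna(rng, 4_000) + dqb + random_dna(rng, 2_000) + dqa
            + random_dna(rng, 3_000)
        )
        hap2 = random_dna(rng, 4_000) + dqb + random_dna(rng, 2_500) + dqa + random_dna(rng, 4_000)
        haplotigs = [SeqRecord(id="hap1", seq=hap1), SeqRecord(id="hap2", seq=hap2)]
        transcripts = []
        for i in range(2):
            transcripts.append(SeqRecord(id=f"txa{i}", seq=dqa))
            transcripts.append(SeqRecord(id=f"txb{i}", seq=dqb))
        table = validate_mhc_genes(genes, haplotigs, transcripts)
        validated = table[table.validated]
        assert len(validated[validated.haplotig == "hap1"]) == 4  # two DQB/DQA pairs
        assert len(validated[validated.haplotig == "hap2"]) == 2  # one pair

    def test_divergent_transcript_excluded(self):
        rng = random.Random(43)
        gene = random_dna(rng, 800)
        hap = random_dna(rng, 2_000) + gene + random_dna(rng, 2_000)
        divergent = list(gene)
        for p in rng.sample(range(800), 80):  # 90% identity
            divergent[p] = rng.choice([b for b in "ACGT" if b != divergent[p]])
        table = validate_mhc_genes(
            [SeqRecord(id="G", seq=gene)],
            [SeqRecord(id="h", seq=hap)],
            [SeqRecord(id="tx", seq="".join(divergent))],
        )
        assert table.n_transcripts.iloc[0] == 0
        assert not table.validated.any()

    def test_single_transcript_insufficient(self):
        rng = random.Random(44)
        gene = random_dna(rng, 800)
        hap = random_dna(rng, 2_000) + gene + random_dna(rng, 2_000)
        table = validate_mhc_genes(
            [SeqRecord(id="G", seq=gene)],
            [SeqRecord(id="h", seq=hap)],
            [SeqRecord(id="tx", seq=gene)],
        )
        assert table.n_transcripts.iloc[0] == 1
        assert not table.validated.any()

    def test_no_haplotigs_rejected(self):
        with pytest.raises(ValidationError):
            validate_mhc_genes([SeqRecord(id="G", seq="ACGT" * 100)], [], [])
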