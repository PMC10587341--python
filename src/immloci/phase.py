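"""Read-backed phasing of a diploid region and MHC gene validation.

Heterozygous SNPs are called from a pileup of aligned long reads; reads
covering shared sites form connected blocks that are phased under the
weighted minimum-error-correction (wMEC) objective: find the bipartition of
reads into two haplotypes minimising the weighted number of read-allele
flips needed for consistency.  Blocks with few overlapping reads are solved
exactly by dynamic programming over columns (state = bipartition of active
reads); larger blocks fall back to a greedy score-based partitioning whose
reported cost is the exact MEC cost of the returned bipartition.

Haplotigs are built by reference-guided weighted-majority consensus over the
reads assigned to each haplotype, and MHC-like gene loci are validated by
requiring multiple full-length transcripts at >= 95% overall identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentScoring, build_seed_index, local_align, map_query
from .io import PafRow, SeqRecord, ValidationError

log = logging.getLogger("immloci")


@dataclass(frozen=True)
class HetSite:
    position: int
    ref_allele: str
    alt_allele: str
    depth: int
    alt_fraction: float


@dataclass
class ReadAlleleMatrix:
    """Reads x het-sites allele matrix.

    ``entries[read_id]`` maps column index -> (allele in {0, 1}, weight).
    Columns are ordered by genomic position; each read covers a contiguous
    column range (long reads over SNPs).
    """

    sites: list[HetSite]
    entries: dict[str, dict[int, tuple[int, float]]] = field(default_factory=dict)

    @property
    def n_columns(self) -> int:
        return len(self.sites)

    def read_span(self, read_id: str) -> tuple[int, int]:
        cols = self.entries[read_id]
        return min(cols), max(cols)


@dataclass
class PhaseBlock:
    columns: list[int]
    hap0: str  # allele string over the block's columns
    hap1: str
    read_assignment: dict[str, int]  # read_id -> 0/1
    mec_cost: float
    exact: bool


ReadAlignments = Sequence[tuple[SeqRecord, PafRow]]


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _pileup_counts(read_alignments: ReadAlignments, region_len: int) -> "np.ndarray":
    """4 x region_len base counts from substitution-only alignments."""
    counts = np.zeros((4, region_len), dtype=np.int32)
    code = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        code[ord(b)] = i
    for read, aln in read_alignments:
        start = aln.target_start
        end = min(aln.target_end, region_len, start + len(read.seq))
        if end <= start:
            continue
        codes = code[np.frombuffer(read.seq[: end - start].encode(), dtype=np.uint8)]
        positions = np.arange(start, end)
        valid = codes >= 0
        np.add.at(counts, (codes[valid], positions[valid]), 1)
    return counts


def _read_base_at(read: SeqRecord, aln: PafRow, position: int) -> str | None:
    """Base a read places at a reference position (substitution-only alignments)."""
    if not (aln.target_start <= position < aln.target_end):
        return None
    offset = position - aln.target_start
    if 0 <= offset < len(read.seq):
        return read.seq[offset]
    return None


def pileup_het_snps(
    read_alignments: ReadAlignments,
    region: SeqRecord,
    min_depth: int = 10,
    min_alt_frac: float = 0.25,
) -> list[HetSite]:
    """Call heterozygous SNPs from a read pileup.

    A site is reported when depth >= ``min_depth`` and both of the two most
    frequent alleles carry a fraction >= ``min_alt_frac``; sites with three
    such alleles are skipped with a warning, as are sites where neither
    frequent allele matches the reference.
    """
    counts = _pileup_counts(read_alignments, len(region.seq))
    depths = counts.sum(axis=0)
    candidates = np.flatnonzero(depths >= min_depth)

    sites: list[HetSite] = []
    for pos in candidates:
        pos = int(pos)
        col = {b: int(counts[i, pos]) for i, b in enumerate("ACGT") if counts[i, pos]}
        depth = int(depths[pos])
        if depth < min_depth:
            continue
        frequent = [b for b, c in col.items() if c / depth >= min_alt_frac]
        if len(frequent) < 2:
            continue
        if len(frequent) > 2:
            log.warning("tri-allelic site at %d skipped", pos)
            continue
        ref = region.seq[pos]
        if ref not in frequent:
            log.warning("site at %d: neither frequent allele matches reference; skipped", pos)
            continue
        alt = frequent[0] if frequent[1] == ref else frequent[1]
        sites.append(
            HetSite(
                position=pos,
                ref_allele=ref,
                alt_allele=alt,
                depth=depth,
                alt_fraction=col[alt] / depth,
            )
        )
    return sites


def build_allele_matrix(
    read_alignments: ReadAlignments,
    sites: Sequence[HetSite],
    weight: float = 1.0,
) -> ReadAlleleMatrix:
    """Project reads onto het-site columns (allele 0 = ref, 1 = alt)."""
    matrix = ReadAlleleMatrix(sites=list(sites))
    for read, aln in read_alignments:
        row: dict[int, tuple[int, float]] = {}
        for col, site in enumerate(sites):
            base = _read_base_at(read, aln, site.position)
            if base == site.ref_allele:
                row[col] = (0, weight)
            elif base == site.alt_allele:
                row[col] = (1, weight)
            # other bases (errors) stay missing: weight 0
        if row:
            matrix.entries[read.id] = row
    return matrix


# ---------------------------------------------------------------------------
# wMEC phasing
# ---------------------------------------------------------------------------

def _connected_blocks(matrix: ReadAlleleMatrix) -> list[list[int]]:
    """Columns linked by a shared read form one block (union-find)."""
    parent = list(range(matrix.n_columns))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for cols in matrix.entries.values():
        cs = sorted(cols)
        for a, b in zip(cs, cs[1:]):
            union(a, b)
    blocks: dict[int, list[int]] = {}
    covered = set()
    for cols in matrix.entries.values():
        covered.update(cols)
    for c in sorted(covered):
        blocks.setdefault(find(c), []).append(c)
    return [blocks[k] for k in sorted(blocks, key=lambda r: min(blocks[r]))]


def _block_cost(
    matrix: ReadAlleleMatrix,
    columns: Sequence[int],
    assignment: Mapping[str, int],
) -> tuple[float, str, str]:
    """Exact MEC cost of a given read bipartition, with the optimal
    complementary haplotype strings (hap1 = complement of hap0)."""
    cost = 0.0
    hap0_chars: list[str] = []
    for col in columns:
        w = [0.0, 0.0, 0.0, 0.0]  # (hap, allele) -> weight
        for read_id, side in assignment.items():
            entry = matrix.entries[read_id].get(col)
            if entry is None:
                continue
            allele, weight = entry
            w[side * 2 + allele] += weight
        # choose c = allele of hap0 at this column (hap1 takes 1-c)
        cost_c0 = w[0 * 2 + 1] + w[1 * 2 + 0]  # hap0 reads with allele1, hap1 with 0
        cost_c1 = w[0 * 2 + 0] + w[1 * 2 + 1]
        if cost_c0 <= cost_c1:
            cost += cost_c0
            hap0_chars.append("0")
        else:
            cost += cost_c1
            hap0_chars.append("1")
    hap0 = "".join(hap0_chars)
    hap1 = "".join("1" if c == "0" else "0" for c in hap0)
    return cost, hap0, hap1


def _phase_block_exact(matrix: ReadAlleleMatrix, columns: list[int]) -> PhaseBlock | None:
    """Column dynamic program over bipartitions of active reads.

    Returns None when the active-read bound is exceeded at some column.
    """
    reads = [r for r in matrix.entries if any(c in matrix.entries[r] for c in columns)]
    col_set = set(columns)
    spans = {
        r: (
            min(c for c in matrix.entries[r] if c in col_set),
            max(c for c in matrix.entries[r] if c in col_set),
        )
        for r in reads
    }
    # DP over columns; state = frozenset of reads on haplotype 0 among active
    active_prev: list[str] = []
    states: dict[frozenset, tuple[float, tuple]] = {frozenset(): (0.0, ())}
    col_choices: list[dict[frozenset, int]] = []

    for col in columns:
        active = [r for r in reads if spans[r][0] <= col <= spans[r][1]]
        if len(active) > 15:
            return None
        carried = [r for r in active if r in active_prev]
        new_reads = [r for r in active if r not in active_prev]
        next_states: dict[frozenset, tuple[float, tuple]] = {}
        choice_rec: dict[frozenset, int] = {}
        for state, (cost, trail) in states.items():
            carry = frozenset(r for r in state if r in carried)
            for mask in range(1 << len(new_reads)):
                side0 = carry | frozenset(
                    r for b, r in enumerate(new_reads) if mask >> b & 1
                )
                # column cost for this bipartition of active reads
                w00 = w01 = w10 = w11 = 0.0
                for r in active:
                    entry = matrix.entries[r].get(col)
                    if entry is None:
                        continue
                    allele, weight = entry
                    if r in side0:
                        if allele == 0:
                            w00 += weight
                        else:
                            w01 += weight
                    else:
                        if allele == 0:
                            w10 += weight
                        else:
                            w11 += weight
                cost_c0 = w01 + w10
                cost_c1 = w00 + w11
                col_cost = min(cost_c0, cost_c1)
                key = frozenset(side0)
                total = cost + col_cost
                prev = next_states.get(key)
                if prev is None or total < prev[0]:
                    next_states[key] = (total, trail + (state,))
        # prune: only the carried-read projection matters forward, but we
        # keep full states keyed by active side0 (size-bounded)
        states = next_states
        active_prev = active
        col_choices.append({})

    # recover best final state and reconstruct assignment by replaying
    best_state = min(states, key=lambda s: states[s][0])
    best_cost, trail = states[best_state]
    # replay: reads keep the side they had when active; reconstruct from trail
    assignment: dict[str, int] = {}
    chain = list(trail) + [best_state]
    for col_idx, col in enumerate(columns):
        state = chain[col_idx + 1]
        active = [r for r in reads if spans[r][0] <= col <= spans[r][1]]
        for r in active:
            if r not in assignment:
                assignment[r] = 0 if r in state else 1
    cost, hap0, hap1 = _block_cost(matrix, columns, assignment)
    # normalise: allele 0 on hap0 at the first column
    if hap0 and hap0[0] == "1":
        hap0, hap1 = hap1, hap0
        assignment = {r: 1 - s for r, s in assignment.items()}
    return PhaseBlock(
        columns=columns,
        hap0=hap0,
        hap1=hap1,
        read_assignment=assignment,
        mec_cost=cost,
        exact=True,
    )


def _phase_block_greedy(matrix: ReadAlleleMatrix, columns: list[int]) -> PhaseBlock:
    """Greedy seeding: reads in start order join the haplotype they disagree
    with least, given the running per-column weighted allele votes."""
    col_set = set(columns)
    reads = sorted(
        (r for r in matrix.entries if any(c in col_set for c in matrix.entries[r])),
        key=lambda r: min(c for c in matrix.entries[r] if c in col_set),
    )
    votes: dict[int, list[float]] = {c: [0.0, 0.0] for c in columns}  # hap0 allele votes
    assignment: dict[str, int] = {}
    for read_id in reads:
        row = matrix.entries[read_id]
        score0 = score1 = 0.0
        for col, (allele, weight) in row.items():
            if col not in col_set:
                continue
            v = votes[col]
            margin = v[1] - v[0]  # >0: hap0 leans allele 1
            lean = 1 if margin > 0 else 0 if margin < 0 else None
            if lean is None:
                continue
            if allele == lean:
                score0 += weight
            else:
                score1 += weight
        side = 0 if score0 >= score1 else 1
        assignment[read_id] = side
        for col, (allele, weight) in row.items():
            if col not in col_set:
                continue
            # update hap0 vote: side-0 reads vote directly, side-1 complement
            voted = allele if side == 0 else 1 - allele
            votes[col][voted] += weight
    cost, hap0, hap1 = _block_cost(matrix, columns, assignment)
    if hap0 and hap0[0] == "1":
        hap0, hap1 = hap1, hap0
        assignment = {r: 1 - s for r, s in assignment.items()}
        cost, hap0b, hap1b = _block_cost(matrix, columns, assignment)
        hap0, hap1 = hap0b, hap1b
    return PhaseBlock(
        columns=columns,
        hap0=hap0,
        hap1=hap1,
        read_assignment=assignment,
        mec_cost=cost,
        exact=False,
    )


def phase_wmec(matrix: ReadAlleleMatrix, max_dp_reads: int = 15) -> list[PhaseBlock]:
    """Phase every connected block of the allele matrix.

    Blocks whose active-read count never exceeds ``max_dp_reads`` are solved
    exactly; larger blocks use the greedy partitioner.  By convention hap0
    carries allele 0 at the block's first column.
    """
    blocks: list[PhaseBlock] = []
    for columns in _connected_blocks(matrix):
        exact = _phase_block_exact(matrix, columns) if max_dp_reads > 0 else None
        blocks.append(exact if exact is not None else _phase_block_greedy(matrix, columns))
    return blocks


def partition_reads(
    matrix: ReadAlleleMatrix, blocks: Sequence[PhaseBlock]
) -> list[tuple[set[str], set[str]]]:
    """Assign each read to the haplotype minimising its weighted mismatches;
    exact ties are left unassigned."""
    out: list[tuple[set[str], set[str]]] = []
    for block in blocks:
        col_index = {c: i for i, c in enumerate(block.columns)}
        hap_sets: tuple[set[str], set[str]] = (set(), set())
        for read_id, row in matrix.entries.items():
            mism0 = mism1 = 0.0
            covered = False
            for col, (allele, weight) in row.items():
                if col not in col_index:
                    continue
                covered = True
                h0 = int(block.hap0[col_index[col]])
                if allele != h0:
                    mism0 += weight
                if allele != 1 - h0:
                    mism1 += weight
            if not covered or mism0 == mism1:
                continue
            hap_sets[0 if mism0 < mism1 else 1].add(read_id)
        out.append(hap_sets)
    return out


def haplotype_consensus(
    read_set: set[str],
    read_alignments: ReadAlignments,
    region: SeqRecord,
    hap_id: str = "haplotig",
) -> SeqRecord:
    """Reference-guided consensus: per-position weighted majority over the
    assigned reads; uncovered positions take the reference base."""
    subset = [(r, a) for r, a in read_alignments if r.id in read_set]
    counts = _pileup_counts(subset, len(region.seq))
    covered = counts.sum(axis=0) > 0
    # argmax prefers the alphabetically first base on exact ties
    winners = np.argmax(counts, axis=0)
    bases = np.frombuffer(region.seq.encode(), dtype=np.uint8).copy()
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    bases[covered] = letters[winners[covered]]
    return SeqRecord(id=hap_id, seq=bases.tobytes().decode())


# ---------------------------------------------------------------------------
# MHC gene validation
# ---------------------------------------------------------------------------

def validate_mhc_genes(
    gene_alleles: Sequence[SeqRecord],
    haplotigs: Sequence[SeqRecord],
    transcripts: Sequence[SeqRecord],
    min_locus_identity: float = 80.0,
    min_transcript_identity: float = 95.0,
    min_coverage: float = 90.0,
    min_transcripts: int = 2,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> pd.DataFrame:
    """Validate MHC-like gene loci with full-length transcripts.

    Step 1: gene alleles are mapped to the haplotigs (candidate loci at
    identity > ``min_locus_identity``).  Step 2: transcripts are mapped to
    the gene alleles (candidate transcripts per gene).  Step 3: a transcript
    is credible for a locus iff it aligns essentially full-length (coverage
    >= ``min_coverage``%) at overall identity >= ``min_transcript_identity``
    (inclusive).  Step 4: a locus is validated iff supported by at least
    ``min_transcripts`` credible transcripts.
    """
    if not haplotigs:
        raise ValidationError("no haplotigs provided")
    index = build_seed_index(list(haplotigs), k=13)

    # step 1: candidate loci
    loci: list[dict] = []
    for allele in gene_alleles:
        for aln in map_query(allele, index, list(haplotigs), scoring):
            if aln.is_empty or aln.identity <= min_locus_identity:
                continue
            assert aln.target_interval is not None
            loci.append(
                {
                    "gene": allele.id,
                    "haplotig": aln.target_id,
                    "start": aln.target_interval.start,
                    "end": aln.target_interval.end,
                    "locus_identity": aln.identity,
                    "n_transcripts": 0,
                }
            )

    # step 2: candidate transcripts per gene
    allele_index = build_seed_index(list(gene_alleles), k=13)
    tx_candidates: dict[str, list[str]] = {}
    for tx in transcripts:
        for aln in map_query(tx, allele_index, list(gene_alleles), scoring):
            if aln.is_empty:
                continue
            tx_candidates.setdefault(aln.target_id, []).append(tx.id)
            break  # best gene only

    tx_by_id = {t.id: t for t in transcripts}
    hap_by_id = {h.id: h for h in haplotigs}

    # step 3: credible transcripts per locus
    for locus in loci:
        hap = hap_by_id[locus["haplotig"]]
        margin = 200
        lo = max(0, locus["start"] - margin)
        hi = min(len(hap.seq), locus["end"] + margin)
        window = SeqRecord(id=hap.id, seq=hap.seq[lo:hi])
        supported = 0
        for tx_id in tx_candidates.get(locus["gene"], []):
            tx = tx_by_id[tx_id]
            aln = local_align(tx, window, scoring)
            if aln.is_empty or aln.query_interval is None:
                continue
            coverage = 100.0 * len(aln.query_interval) / len(tx.seq)
            if coverage >= min_coverage and aln.identity >= min_transcript_identity:
                supported += 1
        locus["n_transcripts"] = supported

    df = pd.DataFrame(
        loci,
        columns=["gene", "haplotig", "start", "end", "locus_identity", "n_transcripts"],
    )
    df["validated"] = df["n_transcripts"] >= min_transcripts
    return df.sort_values(["haplotig", "start"]).reset_index(drop=True)
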