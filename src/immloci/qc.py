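"""Assembly statistics and telomere/satDNA annotation.

N50, gap census, consensus quality (QV) from homozygous variant counts, a
purpose-built short-tandem-repeat finder, telomere calling under the
chromosome-end rule, and satDNA family assignment by consensus alignment.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .align import AlignmentScoring, local_align
from .io import GenomicInterval, ParameterError, SeqRecord

log = logging.getLogger("immloci")

TELOMERE_UNIT = "TTAGGG"


def contig_n50(lengths: Sequence[int]) -> int:
    """Smallest L such that contigs of length >= L together cover at least
    half the assembly."""
    if not lengths:
        raise ParameterError("empty length list")
    if any(x <= 0 for x in lengths):
        raise ParameterError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def find_n_runs(seq: str, min_len: int = 1, seq_id: str = "seq") -> list[GenomicInterval]:
    """Maximal runs of N of length >= min_len (gaps are N-runs)."""
    return [
        GenomicInterval(seq_id, m.start(), m.end())
        for m in re.finditer("N+", seq)
        if m.end() - m.start() >= min_len
    ]


def estimate_qv(n_homozygous_errors: int, genome_size: int, cap: float = 99.0) -> float:
    """Phred-scaled consensus accuracy: -10*log10(errors / genome size)."""
    if genome_size <= 0:
        raise ParameterError("genome_size must be positive")
    if n_homozygous_errors < 0:
        raise ParameterError("error count must be >= 0")
    if n_homozygous_errors == 0:
        return cap
    return -10.0 * math.log10(n_homozygous_errors / genome_size)


def error_rate_percent(n_errors: int, genome_size: int) -> float:
    if genome_size <= 0:
        raise ParameterError("genome_size must be positive")
    return 100.0 * n_errors / genome_size


@dataclass(frozen=True)
class AssemblyStats:
    n_sequences: int
    total_length: int
    n50: int
    gap_intervals: tuple[GenomicInterval, ...]
    qv: float | None = None
    snp_error_rate_pct: float | None = None
    indel_error_rate_pct: float | None = None


def assembly_stats(
    assembly: Sequence[SeqRecord],
    n_homo_snps: int | None = None,
    n_homo_indels: int | None = None,
) -> AssemblyStats:
    lengths = [len(r.seq) for r in assembly]
    gaps: list[GenomicInterval] = []
    for rec in assembly:
        gaps.extend(find_n_runs(rec.seq, seq_id=rec.id))
    total = sum(lengths)
    qv = snp_rate = indel_rate = None
    if n_homo_snps is not None and n_homo_indels is not None:
        qv = estimate_qv(n_homo_snps + n_homo_indels, total)
        snp_rate = error_rate_percent(n_homo_snps, total)
        indel_rate = error_rate_percent(n_homo_indels, total)
    return AssemblyStats(
        n_sequences=len(assembly),
        total_length=total,
        n50=contig_n50(lengths),
        gap_intervals=tuple(gaps),
        qv=qv,
        snp_error_rate_pct=snp_rate,
        indel_error_rate_pct=indel_rate,
    )


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TandemRepeatRecord:
    interval: GenomicInterval
    period: int
    copy_number: float
    consensus_pattern: str  # lexicographically smallest rotation
    purity: float  # percent of bases matching the tiled consensus

    def __post_init__(self) -> None:
        if self.copy_number < 2:
            raise ParameterError("copy_number must be >= 2")
        if self.period != len(self.consensus_pattern):
            raise ParameterError("period must equal consensus length")


def canonical_rotation(pattern: str) -> str:
    return min(pattern[i:] + pattern[:i] for i in range(len(pattern)))


def _candidate_periods(seq: str, max_period: int, k: int = 8, min_votes: int = 4) -> list[int]:
    """Periods proposed by k-mer distance voting: repeated k-mers whose
    consecutive occurrences are a constant short distance apart vote for that
    distance as a period."""
    positions: dict[str, int] = {}
    votes: dict[int, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        if kmer in positions:
            d = i - positions[kmer]
            if 1 <= d <= max_period:
                votes[d] = votes.get(d, 0) + 1
        positions[kmer] = i
    return sorted(p for p, v in votes.items() if v >= min_votes)


def find_tandem_repeats(
    seq: str,
    max_period: int = 500,
    min_copies: float = 3,
    min_purity: float = 85.0,
    seq_id: str = "seq",
) -> list[TandemRepeatRecord]:
    """Locate short tandem repeat arrays.

    k-mer distance voting proposes candidate periods; for each period the
    self-match profile ``seq[i] == seq[i+p]`` is smoothed over one period and
    maximal high-agreement windows become candidate arrays.  Each array is
    scored against its per-phase majority consensus (purity = percent of
    bases matching the tiled consensus).  Smaller periods take precedence
    where arrays of harmonic periods (p, 2p, ...) would overlap.
    """
    if max_period > 2000:
        raise ParameterError("max_period must be <= 2000")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    records: list[TandemRepeatRecord] = []
    claimed: list[tuple[int, int]] = []
    purity_frac = min_purity / 100.0

    for p in _candidate_periods(seq, max_period):
        if p > n // 2:
            continue
        match = (arr[:-p] == arr[p:]).astype(np.float64)
        if len(match) < p:
            continue
        # windowed agreement over one period
        kernel = np.ones(p) / p
        smooth = np.convolve(match, kernel, mode="valid")
        inside = smooth >= purity_frac
        # maximal runs of in-array positions
        edges = np.flatnonzero(np.diff(np.concatenate(([0], inside.view(np.int8), [0]))))
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            start, end = int(run_start), int(run_end) + 2 * p - 1
            end = min(end, n)
            if end - start < min_copies * p:
                continue
            if any(
                min(end, ce) - max(start, cs) > 0.5 * (end - start)
                for cs, ce in claimed
            ):
                continue
            consensus, purity, start, end = _polish_array(seq, start, end, p)
            if purity < min_purity or (end - start) < min_copies * p:
                continue
            records.append(
                TandemRepeatRecord(
                    interval=GenomicInterval(seq_id, start, end),
                    period=p,
                    copy_number=(end - start) / p,
                    consensus_pattern=canonical_rotation(consensus),
                    purity=purity,
                )
            )
            claimed.append((start, end))
    records.sort(key=lambda r: r.interval.start)
    return records


def _polish_array(seq: str, start: int, end: int, p: int) -> tuple[str, float, int, int]:
    """Per-phase majority consensus and purity; trims ragged edges that do
    not match the consensus."""
    window = seq[start:end]
    cols: list[dict[str, int]] = [dict() for _ in range(p)]
    for i, base in enumerate(window):
        col = cols[i % p]
        col[base] = col.get(base, 0) + 1
    consensus = "".join(max(c, key=c.get) if c else "A" for c in cols)
    tiled_match = [window[i] == consensus[i % p] for i in range(len(window))]
    # trim edges to the outermost matching base
    left = 0
    while left < len(tiled_match) and not tiled_match[left]:
        left += 1
    right = len(tiled_match)
    while right > left and not tiled_match[right - 1]:
        right -= 1
    if right <= left:
        return consensus, 0.0, start, start
    matches = sum(tiled_match[left:right])
    purity = 100.0 * matches / (right - left)
    # rotate consensus to the trimmed frame
    consensus = "".join(consensus[(left + i) % p] for i in range(p))
    return consensus, purity, start + left, start + right


# ---------------------------------------------------------------------------
# telomeres
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TelomereCall:
    chromosome: str
    end: str  # "p" (sequence start) or "q" (sequence end)
    interval: GenomicInterval
    length: int


def call_telomeres(
    chromosome: SeqRecord,
    min_len: int = 15_000,
    end_slack: int = 1_000,
) -> list[TelomereCall]:
    """Telomeres are (TTAGGG)n arrays touching a chromosome end.

    Arrays matching the canonical telomere unit on either strand are kept
    only when they reach within ``end_slack`` of a sequence end and span at
    least ``min_len`` (tandem arrays elsewhere are not telomeres).
    """
    unit_canon = canonical_rotation(TELOMERE_UNIT)
    comp_canon = canonical_rotation("CCCTAA")
    calls: list[TelomereCall] = []
    n = len(chromosome.seq)
    # restrict the scan to the terminal windows; telomeric arrays are terminal
    window = max(min_len * 3, 50_000)
    for side in ("p", "q"):
        if side == "p":
            lo, hi = 0, min(n, window)
        else:
            lo, hi = max(0, n - window), n
        sub = chromosome.seq[lo:hi]
        for rec in find_tandem_repeats(sub, max_period=12, min_copies=3, seq_id=chromosome.id):
            if rec.consensus_pattern not in (unit_canon, comp_canon):
                continue
            iv = GenomicInterval(chromosome.id, rec.interval.start + lo, rec.interval.end + lo)
            if len(iv) < min_len:
                continue
            if side == "p" and iv.start <= end_slack:
                calls.append(TelomereCall(chromosome.id, "p", iv, len(iv)))
            elif side == "q" and iv.end >= n - end_slack:
                calls.append(TelomereCall(chromosome.id, "q", iv, len(iv)))
    # dedupe (p and q windows can overlap on short sequences)
    seen = set()
    out = []
    for c in calls:
        key = (c.interval.start, c.interval.end, c.end)
        if key not in seen:
            seen.add(key)
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# satDNA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SatDNACall:
    interval: GenomicInterval
    family: str
    identity: float
    copy_number: float


def classify_satdna(
    repeats: Sequence[TandemRepeatRecord],
    sat_db: Sequence[SeqRecord],
    min_identity: float = 80.0,
    merge_dist: int = 1_000,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> list[SatDNACall]:
    """Assign tandem-repeat consensus patterns to satDNA families.

    Each consensus is aligned against every database entry across all
    rotations (strict identity > ``min_identity`` percent of the aligned
    block); overlapping or adjacent same-family calls are merged with copy
    numbers summed.
    """
    calls: list[SatDNACall] = []
    for rec in repeats:
        best_family, best_identity, best_cov = None, 0.0, 0.0
        for entry in sat_db:
            rotations = (
                [rec.consensus_pattern[i:] + rec.consensus_pattern[:i] for i in range(rec.period)]
                if rec.period <= 64
                else [rec.consensus_pattern]
            )
            for rot in rotations:
                aln = local_align(SeqRecord(id="c", seq=rot), SeqRecord(id="db", seq=entry.seq), scoring)
                if aln.is_empty or aln.query_interval is None:
                    continue
                cov = len(aln.query_interval) / rec.period
                if cov < 0.9:
                    continue
                # identity over the full consensus, counting unaligned ends as mismatch
                identity = 100.0 * aln.matches / max(rec.period, aln.block_length)
                if identity > best_identity:
                    best_family, best_identity, best_cov = entry.id, identity, cov
        if best_family is not None and best_identity > min_identity:
            calls.append(
                SatDNACall(
                    interval=rec.interval,
                    family=best_family,
                    identity=best_identity,
                    copy_number=rec.copy_number,
                )
            )
    # merge same-family neighbours
    calls.sort(key=lambda c: (c.family, c.interval.seq_id, c.interval.start))
    merged: list[SatDNACall] = []
    for call in calls:
        if (
            merged
            and merged[-1].family == call.family
            and merged[-1].interval.seq_id == call.interval.seq_id
            and call.interval.start - merged[-1].interval.end <= merge_dist
        ):
            prev = merged[-1]
            merged[-1] = SatDNACall(
                interval=GenomicInterval(
                    prev.interval.seq_id,
                    prev.interval.start,
                    max(prev.interval.end, call.interval.end),
                ),
                family=prev.family,
                identity=max(prev.identity, call.identity),
                copy_number=prev.copy_number + call.copy_number,
            )
        else:
            merged.append(call)
    merged.sort(key=lambda c: (c.interval.seq_id, c.interval.start))
    return merged
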