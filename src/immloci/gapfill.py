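"""Two-assembly comparison: gap closure and unplaced-scaffold placement.

For each N-gap of an old assembly, 10-kb flanks up- and downstream are mapped
onto the new assembly; the gap is *closed* when both flanks land on one
contig, same strand, in order, each above the identity threshold (strict
>90%).  Unplaced scaffolds are split at their own gaps, each piece mapped,
and a scaffold is *placed* when its aligned-and-matching bases exceed half
its non-N length on a single contig with consistent order and strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .align import Alignment, AlignmentScoring, SeedIndex, build_seed_index, map_query
from .io import GenomicInterval, SeqRecord
from .qc import find_n_runs

log = logging.getLogger("immloci")


@dataclass(frozen=True)
class GapClosure:
    gap: GenomicInterval
    left: Alignment | None
    right: Alignment | None
    status: str  # closed / unresolved / conflicting
    closing_contig: str | None = None
    estimated_span: int | None = None


@dataclass(frozen=True)
class ScaffoldPlacement:
    scaffold_id: str
    pieces: tuple[Alignment, ...]
    target_contig: str | None
    placed_fraction: float
    status: str  # placed / partial / unplaced


def extract_gap_flanks(
    old_assembly: dict[str, str],
    gap: GenomicInterval,
    flank_len: int = 10_000,
) -> tuple[SeqRecord | None, SeqRecord | None]:
    """Fetch the sequences up- and downstream of a gap, excluding N.

    Flanks are truncated (with a warning) where the gap sits within
    ``flank_len`` of a sequence end or of an adjacent gap; a flank truncated
    to nothing is returned as ``None``.
    """
    seq = old_assembly[gap.seq_id]
    left_lo = max(0, gap.start - flank_len)
    left_seq = seq[left_lo : gap.start]
    n_pos = left_seq.rfind("N")
    if n_pos != -1:
        left_seq = left_seq[n_pos + 1 :]
    if len(left_seq) < flank_len:
        log.warning("gap %s:%d-%d left flank truncated to %d bp", gap.seq_id, gap.start, gap.end, len(left_seq))

    right_seq = seq[gap.end : gap.end + flank_len]
    n_pos = right_seq.find("N")
    if n_pos != -1:
        right_seq = right_seq[:n_pos]
    if len(right_seq) < flank_len:
        log.warning("gap %s:%d-%d right flank truncated to %d bp", gap.seq_id, gap.start, gap.end, len(right_seq))

    left = (
        SeqRecord(id=f"{gap.seq_id}_{gap.start}_L", seq=left_seq) if left_seq else None
    )
    right = (
        SeqRecord(id=f"{gap.seq_id}_{gap.start}_R", seq=right_seq) if right_seq else None
    )
    return left, right


def close_gap(
    gap: GenomicInterval,
    flanks: tuple[SeqRecord | None, SeqRecord | None],
    new_assembly: Sequence[SeqRecord],
    index: SeedIndex | None = None,
    min_identity: float = 90.0,
    max_span: int = 10_000_000,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> GapClosure:
    """Decide whether a gap of the old assembly is closed by the new one.

    closed: both flanks above ``min_identity`` (strict) on one contig, same
    strand, right flank downstream of left, span within ``max_span``.
    conflicting: both flanks confidently aligned but inconsistent (different
    contigs, strands, or order).  unresolved: a flank missing or below
    threshold.
    """
    if index is None:
        index = build_seed_index(list(new_assembly), k=13)
    best: list[Alignment | None] = []
    for flank in flanks:
        if flank is None:
            best.append(None)
            continue
        hits = map_query(flank, index, list(new_assembly), scoring)
        best.append(hits[0] if hits else None)
    left, right = best

    def confident(aln: Alignment | None) -> bool:
        return aln is not None and not aln.is_empty and aln.identity > min_identity

    if not confident(left) or not confident(right):
        return GapClosure(gap=gap, left=left, right=right, status="unresolved")
    assert left is not None and right is not None
    if left.target_id != right.target_id or left.strand != right.strand:
        return GapClosure(gap=gap, left=left, right=right, status="conflicting")
    lt, rt = left.target_interval, right.target_interval
    assert lt is not None and rt is not None
    if left.strand == "+":
        span = rt.start - lt.end
    else:
        span = lt.start - rt.end
    if span < 0 or span > max_span:
        return GapClosure(gap=gap, left=left, right=right, status="conflicting")
    return GapClosure(
        gap=gap,
        left=left,
        right=right,
        status="closed",
        closing_contig=left.target_id,
        estimated_span=span,
    )


def place_scaffold(
    scaffold: SeqRecord,
    new_assembly: Sequence[SeqRecord],
    index: SeedIndex | None = None,
    min_fraction: float = 50.0,
    min_piece_identity: float = 90.0,
    min_piece_len: int = 100,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> ScaffoldPlacement:
    """Split a scaffold at its N-gaps and map each piece onto the new assembly.

    placed: matching bases of qualifying pieces exceed ``min_fraction``
    percent of the scaffold's non-N length, all on one contig in consistent
    order and strand.  partial: single contig but at or below the fraction.
    unplaced: no qualifying piece, or pieces scattered across contigs.
    """
    if index is None:
        index = build_seed_index(list(new_assembly), k=13)
    seq = scaffold.seq
    non_n_len = len(seq) - seq.count("N")
    gaps = find_n_runs(seq, seq_id=scaffold.id)
    bounds = [0] + [b for g in gaps for b in (g.start, g.end)] + [len(seq)]
    pieces: list[tuple[int, Alignment]] = []
    for lo, hi in zip(bounds[::2], bounds[1::2]):
        if hi - lo < min_piece_len:
            continue
        piece = SeqRecord(id=f"{scaffold.id}_{lo}", seq=seq[lo:hi])
        hits = map_query(piece, index, list(new_assembly), scoring)
        if not hits:
            continue
        hit = hits[0]
        if hit.is_empty or hit.identity <= min_piece_identity:
            continue
        # a qualifying piece must align over a meaningful stretch; chance
        # seed hits of a few k-mers otherwise promote junk to "partial"
        if hit.query_interval is None or len(hit.query_interval) < min_piece_len:
            continue
        pieces.append((lo, hit))

    if not pieces:
        return ScaffoldPlacement(scaffold.id, (), None, 0.0, "unplaced")

    # majority contig among qualifying pieces, weighted by matches
    weight: dict[str, int] = {}
    for _lo, hit in pieces:
        weight[hit.target_id] = weight.get(hit.target_id, 0) + hit.matches
    contig = max(weight, key=lambda c: weight[c])
    on_contig = [(lo, h) for lo, h in pieces if h.target_id == contig]

    strands = {h.strand for _lo, h in on_contig}
    consistent = len(strands) == 1
    if consistent and len(on_contig) > 1:
        strand = strands.pop()
        ordered = sorted(on_contig, key=lambda t: t[0])
        starts = [h.target_interval.start for _lo, h in ordered if h.target_interval]
        if strand == "+":
            consistent = all(a <= b for a, b in zip(starts, starts[1:]))
        else:
            consistent = all(a >= b for a, b in zip(starts, starts[1:]))

    others = any(h.target_id != contig for _lo, h in pieces)
    matching = sum(h.matches for _lo, h in on_contig)
    fraction = 100.0 * matching / non_n_len if non_n_len else 0.0

    if consistent and not others and fraction > min_fraction:
        status = "placed"
    elif not others and consistent:
        status = "partial"
    else:
        status = "unplaced"
    return ScaffoldPlacement(
        scaffold_id=scaffold.id,
        pieces=tuple(h for _lo, h in pieces),
        target_contig=contig if status != "unplaced" else None,
        placed_fraction=fraction,
        status=status,
    )


def gapfill_report(
    closures: Sequence[GapClosure],
    placements: Sequence[ScaffoldPlacement],
    scaffold_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Summary counts by status plus total placed scaffold length."""
    rows = []
    for status in ("closed", "unresolved", "conflicting"):
        rows.append(("gap", status, sum(1 for c in closures if c.status == status), 0))
    total_placed_len = 0
    for status in ("placed", "partial", "unplaced"):
        count = sum(1 for p in placements if p.status == status)
        length = 0
        if scaffold_lengths:
            length = sum(
                scaffold_lengths.get(p.scaffold_id, 0)
                for p in placements
                if p.status == status
            )
        if status == "placed":
            total_placed_len = length
        rows.append(("scaffold", status, count, length))
    df = pd.DataFrame(rows, columns=["kind", "status", "count", "total_length"])
    df.attrs["total_placed_length"] = total_placed_len
    return df
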