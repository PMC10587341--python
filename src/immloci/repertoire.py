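"""Full-length transcript V(D)J assignment and repertoire profiling.

Each transcript receives best V and J calls by local-alignment score, an
optional D call (exact-run matching between the V and J alignment ends), a C
call 3' of J, a CDR3 spanning the conserved V cysteine codon through the
codon preceding J's F/W-G-X-G motif, and a productivity flag (in frame,
stop-free from V through J).  Aggregations produce V-(D)-J usage matrices
(Sankey-ready) and CDRH3 length profiles with an ultralong class.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from .align import Alignment, AlignmentScoring, build_seed_index, local_align, map_query
from .annotate import D_BEARING_LOCI, translate
from .io import GenomicInterval, SegmentLibraryEntry, SeqRecord

log = logging.getLogger("immloci")


@dataclass(frozen=True)
class TranscriptAnnotation:
    transcript_id: str
    locus: str | None
    v_call: str | None
    d_call: str | None
    j_call: str | None
    c_call: str | None
    v_score: int = 0
    j_score: int = 0
    v_identity: float = 0.0
    j_identity: float = 0.0
    cdr3_nt: str | None = None
    cdr3_aa: str | None = None
    productive: bool = False

    @property
    def assigned(self) -> bool:
        return self.v_call is not None and self.j_call is not None


def _best_hit(
    transcript: SeqRecord,
    entries: Sequence[SegmentLibraryEntry],
    scoring: AlignmentScoring,
    region: tuple[int, int] | None = None,
) -> tuple[SegmentLibraryEntry, Alignment] | None:
    """Best-scoring library entry against (a region of) the transcript.

    Ties break to higher identity, then lexicographic name.
    """
    lo, hi = region if region else (0, len(transcript.seq))
    if hi <= lo:
        return None
    window = SeqRecord(id=transcript.id, seq=transcript.seq[lo:hi])
    best: tuple[SegmentLibraryEntry, Alignment] | None = None
    for entry in entries:
        aln = local_align(SeqRecord(id=entry.name, seq=entry.seq), window, scoring)
        if aln.is_empty:
            continue
        key = (aln.score, aln.identity)
        if best is None:
            best = (entry, aln)
            continue
        best_key = (best[1].score, best[1].identity)
        if key > best_key or (key == best_key and entry.name < best[0].name):
            best = (entry, aln)
    if best is None:
        return None
    entry, aln = best
    if region and aln.target_interval is not None:
        ti = aln.target_interval
        aln = replace(
            aln,
            target_interval=GenomicInterval(transcript.id, ti.start + lo, ti.end + lo),
        )
    return entry, aln


def _longest_common_run(window: str, segment: str) -> int:
    """Length of the longest exact common substring (small inputs)."""
    best = 0
    n, m = len(window), len(segment)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        wi = window[i - 1]
        for j in range(1, m + 1):
            if wi == segment[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def assign_vdj(
    transcript: SeqRecord,
    library: Sequence[SegmentLibraryEntry],
    scoring: AlignmentScoring = AlignmentScoring(),
    min_v_score: int = 100,
    d_min_match: int = 8,
) -> TranscriptAnnotation:
    """Assign V/(D)/J/C segments to one transcript.

    The locus is fixed by the best V; J is the best same-locus entry 3' of
    the V alignment; D (D-bearing loci only) requires >= ``d_min_match``
    consecutive matching bases between the V and J ends; C is the best
    alignment 3' of J.  Transcripts whose best V score is below
    ``min_v_score`` are left unassigned.

    Candidate segments are seeded against a per-transcript k-mer index
    (k=11, short enough that trimmed J segments still seed) and extended by
    banded local alignment; unseeded entries cannot outscore seeded ones at
    the defaults, so ranking by extended score is unaffected.
    """
    index = build_seed_index([transcript], k=11)

    def seeded_best(
        entries: Sequence[SegmentLibraryEntry], min_start: int | None = None
    ) -> tuple[SegmentLibraryEntry, Alignment] | None:
        best: tuple[SegmentLibraryEntry, Alignment] | None = None
        for entry in entries:
            for aln in map_query(
                SeqRecord(id=entry.name, seq=entry.seq),
                index,
                [transcript],
                scoring,
            ):
                if aln.is_empty or aln.strand != "+" or aln.target_interval is None:
                    continue
                if min_start is not None and aln.target_interval.start < min_start:
                    continue
                key = (aln.score, aln.identity)
                if best is None:
                    best = (entry, aln)
                    continue
                best_key = (best[1].score, best[1].identity)
                if key > best_key or (key == best_key and entry.name < best[0].name):
                    best = (entry, aln)
                break  # map_query sorts by score; first acceptable hit is best
        return best

    v_entries = [e for e in library if e.seg_type == "V"]
    v_hit = seeded_best(v_entries)
    if v_hit is None or v_hit[1].score < min_v_score:
        return TranscriptAnnotation(
            transcript_id=transcript.id,
            locus=None,
            v_call=None,
            d_call=None,
            j_call=None,
            c_call=None,
        )
    v_entry, v_aln = v_hit
    locus = v_entry.locus
    assert v_aln.target_interval is not None
    v_end = v_aln.target_interval.end

    j_entries = [e for e in library if e.seg_type == "J" and e.locus == locus]
    j_hit = seeded_best(j_entries, min_start=v_end)
    if j_hit is None:
        return TranscriptAnnotation(
            transcript_id=transcript.id,
            locus=locus,
            v_call=v_entry.name,
            d_call=None,
            j_call=None,
            c_call=None,
            v_score=v_aln.score,
            v_identity=v_aln.identity,
        )
    j_entry, j_aln = j_hit
    assert j_aln.target_interval is not None
    j_start = j_aln.target_interval.start
    j_end = j_aln.target_interval.end

    d_call = None
    if locus in D_BEARING_LOCI and j_start > v_end:
        junction_window = transcript.seq[v_end:j_start]
        best_run, best_name = 0, None
        for entry in (e for e in library if e.seg_type == "D" and e.locus == locus):
            run = _longest_common_run(junction_window, entry.seq)
            if run > best_run or (run == best_run and best_name and entry.name < best_name):
                best_run, best_name = run, entry.name
        if best_run >= d_min_match:
            d_call = best_name

    c_entries = [e for e in library if e.seg_type == "C" and e.locus == locus]
    c_call = None
    c_hit = seeded_best(c_entries, min_start=j_end)
    if c_hit is not None and c_hit[1].score >= scoring.match * 30:
        c_call = c_hit[0].name

    annotation = TranscriptAnnotation(
        transcript_id=transcript.id,
        locus=locus,
        v_call=v_entry.name,
        d_call=d_call,
        j_call=j_entry.name,
        c_call=c_call,
        v_score=v_aln.score,
        j_score=j_aln.score,
        v_identity=v_aln.identity,
        j_identity=j_aln.identity,
    )
    return extract_cdr3(annotation, transcript, library, v_aln=v_aln, j_aln=j_aln)


def extract_cdr3(
    annotation: TranscriptAnnotation,
    transcript: SeqRecord,
    library: Sequence[SegmentLibraryEntry],
    v_aln: Alignment | None = None,
    j_aln: Alignment | None = None,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> TranscriptAnnotation:
    """Fill cdr3_nt/cdr3_aa/productive on an annotated transcript.

    CDR3 runs from the codon of the library-annotated conserved V cysteine
    (2nd-CYS) through the codon preceding the J motif.  Productive requires
    the junction in frame and no stop from the V start through the J end.
    If the J entry lacks an annotated motif, or the motif cannot be located
    in the transcript frame, CDR3 is undefined and productive is False.
    """
    if not annotation.assigned:
        return annotation
    by_name = {e.name: e for e in library}
    v_entry = by_name[annotation.v_call]
    j_entry = by_name[annotation.j_call]
    if v_entry.cys_codon is None or j_entry.motif_codon is None:
        return annotation
    if v_aln is None:
        v_aln = local_align(SeqRecord(id=v_entry.name, seq=v_entry.seq), transcript, scoring)
    if j_aln is None:
        j_aln = local_align(SeqRecord(id=j_entry.name, seq=j_entry.seq), transcript, scoring)
    if v_aln.is_empty or j_aln.is_empty:
        return annotation

    cys_in_v = 3 * v_entry.cys_codon
    cys_tx = _project(v_aln, cys_in_v)
    motif_in_j = 3 * j_entry.motif_codon
    motif_tx = _project(j_aln, motif_in_j)
    if cys_tx is None or motif_tx is None or motif_tx <= cys_tx:
        return annotation

    # verify the motif is genuinely present in the J frame of the transcript
    j_frame = transcript.seq[motif_tx : motif_tx + 12]
    if not re.match(r"[FW]G.G", translate(j_frame) + "XXXX"):
        return annotation

    cdr3_nt = transcript.seq[cys_tx:motif_tx]
    assert v_aln.target_interval is not None and j_aln.target_interval is not None
    v_start_tx = v_aln.target_interval.start - (v_aln.query_interval.start if v_aln.query_interval else 0)
    v_start_tx = max(0, v_start_tx)
    j_end_tx = j_aln.target_interval.end
    orf = transcript.seq[v_start_tx:j_end_tx]
    in_frame = len(cdr3_nt) % 3 == 0 and (cys_tx - v_start_tx) % 3 == 0
    aa_orf = translate(orf[: len(orf) - len(orf) % 3])
    productive = in_frame and "*" not in aa_orf
    cdr3_aa = translate(cdr3_nt) if len(cdr3_nt) % 3 == 0 else None
    if productive and cdr3_aa is not None and "*" in cdr3_aa:
        productive = False
    return replace(annotation, cdr3_nt=cdr3_nt, cdr3_aa=cdr3_aa, productive=productive)


def _project(aln: Alignment, query_pos: int) -> int | None:
    """Map a query coordinate through an alignment to target coordinates."""
    if aln.query_interval is None or aln.target_interval is None:
        return None
    q = aln.query_interval.start
    t = aln.target_interval.start
    if query_pos < q:
        # upstream of the aligned region: extrapolate only short distances
        if q - query_pos > 30:
            return None
        return t - (q - query_pos)
    for count, op in re.findall(r"(\d+)([MID])", aln.cigar):
        count = int(count)
        if op == "M":
            if query_pos < q + count:
                return t + (query_pos - q)
            q += count
            t += count
        elif op == "I":
            if query_pos < q + count:
                return t
            q += count
        else:
            t += count
    if query_pos - q <= 30:
        return t + (query_pos - q)
    return None


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class UsageProfile:
    locus: str
    counts: dict[tuple, int]
    total: int


def usage_profile(
    annotations: Sequence[TranscriptAnnotation], locus: str
) -> tuple[UsageProfile, pd.DataFrame]:
    """V-(D)-J combination counts plus a Sankey-ready link table
    (columns: source, target, value)."""
    with_d = locus in D_BEARING_LOCI
    counts: dict[tuple, int] = {}
    for ann in annotations:
        if not ann.assigned or ann.locus != locus:
            continue
        key = (
            (ann.v_call, ann.d_call, ann.j_call) if with_d else (ann.v_call, ann.j_call)
        )
        counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())

    links: dict[tuple[str, str], int] = {}
    for key, value in counts.items():
        chain = [str(part) for part in key]
        for src, dst in zip(chain, chain[1:]):
            links[(src, dst)] = links.get((src, dst), 0) + value
    df = pd.DataFrame(
        [(s, d, v) for (s, d), v in sorted(links.items())],
        columns=["source", "target", "value"],
    )
    return UsageProfile(locus=locus, counts=counts, total=total), df


def cdrh3_profile(
    annotations: Sequence[TranscriptAnnotation],
    ultralong_aa_threshold: int = 40,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CDR3 amino-acid length histogram plus the ultralong transcript table.

    The histogram counts every productive transcript with a defined CDR3;
    transcripts at or above the ultralong threshold are tabulated with their
    V and D calls (the cattle ultralong-CDRH3 class shows exclusive V/D
    usage, which this table exposes).
    """
    lengths: dict[int, int] = {}
    ultra_rows = []
    for ann in annotations:
        if not ann.productive or ann.cdr3_aa is None:
            continue
        n_aa = len(ann.cdr3_aa)
        lengths[n_aa] = lengths.get(n_aa, 0) + 1
        if n_aa >= ultralong_aa_threshold:
            ultra_rows.append(
                (ann.transcript_id, n_aa, ann.v_call, ann.d_call, ann.j_call)
            )
    hist = pd.DataFrame(
        sorted(lengths.items()), columns=["cdr3_aa_length", "count"]
    )
    ultra = pd.DataFrame(
        ultra_rows, columns=["transcript_id", "cdr3_aa_length", "v_call", "d_call", "j_call"]
    )
    return hist, ultra
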