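"""Synthetic genomes, reads and transcripts with planted ground truth.

Every generator takes an explicit integer seed and is byte-deterministic for
a given (seed, spec) pair.  The emitted structures carry the statistical
assumptions the downstream stages test against: ordered V/(D)/J/C segments
flanked by canonical RSS motifs, tandem D-J-C cassettes, telomere/satDNA
arrays, N-gap-degraded "old" assemblies with excised scaffolds, a diploid
MHC-like region with heterozygous SNPs plus long reads, and recombined V(D)J
transcripts with junctional diversity.

Intergenic/spacer DNA is i.i.d. over ACGT at GC 0.42 (cattle-like), a neutral
background in which accidental RSS motifs are vanishingly rare.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace

from .annotate import (
    Cassette,
    GeneSegment,
    HEAVY_TYPE_LOCI,
    D_BEARING_LOCI,
    RSS_HEPTAMER,
    RSS_NONAMER,
    translate,
)
from .io import (
    GenomicInterval,
    PafRow,
    ParameterError,
    SegmentLibraryEntry,
    SeqRecord,
    VcfVariant,
    revcomp,
)

GC_CONTENT = 0.42
STOP_CODONS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


def random_dna(rng: random.Random, length: int, gc: float = GC_CONTENT) -> str:
    half_gc, half_at = gc / 2, (1 - gc) / 2
    return "".join(
        rng.choices("ACGT", weights=(half_at, half_gc, half_gc, half_at), k=length)
    )


def _random_codons(rng: random.Random, n: int) -> list[str]:
    return rng.choices(_NONSTOP_CODONS, k=n)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DefectRates:
    stop_codon: float = 0.0
    frameshift: float = 0.0
    rss_mutation: float = 0.0

    def __post_init__(self) -> None:
        for name, value in (
            ("stop_codon", self.stop_codon),
            ("frameshift", self.frameshift),
            ("rss_mutation", self.rss_mutation),
        ):
            if not (0.0 <= value <= 1.0):
                raise ParameterError(f"defect rate {name}={value} outside [0, 1]")


@dataclass(frozen=True)
class LocusSpec:
    """Composition of one synthetic immune locus."""

    locus: str
    n_v: int = 0
    n_d: int = 0
    n_j: int = 0
    n_c: int = 0
    cassette: Cassette | None = None
    defect_rates: DefectRates = field(default_factory=DefectRates)
    spacing: int = 300
    strand: str = "+"
    v_spacer: int | None = None  # RSS spacer lengths; None = locus default
    j_spacer: int = 23
    d_spacer: int = 12

    def __post_init__(self) -> None:
        if self.cassette is not None:
            if self.cassette.copies < 1:
                raise ParameterError("cassette copies must be >= 1")
            totals = {
                t: sum(counts)
                for t, counts in (
                    (elem[0], elem[1]) for elem in self.cassette.elements
                )
            }
            for seg_type, total in totals.items():
                declared = getattr(self, f"n_{seg_type.lower()}")
                if declared and declared != total:
                    raise ParameterError(
                        f"n_{seg_type.lower()}={declared} inconsistent with cassette total {total}"
                    )

    @property
    def v_spacer_len(self) -> int:
        if self.v_spacer is not None:
            return self.v_spacer
        return 23 if self.locus in HEAVY_TYPE_LOCI else 12

    def segment_totals(self) -> dict[str, int]:
        totals = {"V": self.n_v, "D": self.n_d, "J": self.n_j, "C": self.n_c}
        if self.cassette is not None:
            for seg_type, counts in self.cassette.elements:
                totals[seg_type] = sum(counts)
        return totals


@dataclass
class GapTruth:
    old_interval: GenomicInterval  # N-run span in the degraded assembly
    new_interval: GenomicInterval  # true content span in the source genome


@dataclass
class PlacementTruth:
    scaffold_id: str
    new_interval: GenomicInterval


@dataclass
class TranscriptTruth:
    transcript_id: str
    locus: str
    v_name: str
    d_name: str | None
    j_name: str
    c_name: str | None
    junction_nt: str
    productive: bool


@dataclass
class TruthSet:
    """Planted ground truth accompanying a synthetic dataset."""

    segments: list[GeneSegment] = field(default_factory=list)
    gaps: list[GapTruth] = field(default_factory=list)
    placements: list[PlacementTruth] = field(default_factory=list)
    haplotype_variants: list[VcfVariant] = field(default_factory=list)
    transcripts: list[TranscriptTruth] = field(default_factory=list)
    telomeres: list[GenomicInterval] = field(default_factory=list)
    satdna: list[GenomicInterval] = field(default_factory=list)


# ---------------------------------------------------------------------------
# segment libraries
# ---------------------------------------------------------------------------

def make_segment_library(spec: LocusSpec, seed: int) -> list[SegmentLibraryEntry]:
    """Generate an IMGT-like reference library for one locus.

    V entries are ATG-initiated open reading frames of 288 +/- 30 bp with
    conserved cysteine codons at IMGT-like positions (1st-CYS early, 2nd-CYS
    near the 3' end) and no internal stop.  J entries carry an in-frame
    F/W-G-X-G motif.  Names follow ``<locus><type><index>``.
    """
    totals = spec.segment_totals()
    if totals["V"] < 1 and spec.n_v < 0:
        raise ParameterError("n_v must be >= 1 for V-bearing loci")
    rng = random.Random(seed)
    entries: list[SegmentLibraryEntry] = []

    for i in range(totals["V"]):
        n_codons = rng.randint(86, 106)  # 258..318 bp
        codons = _random_codons(rng, n_codons)
        codons[0] = "ATG"
        codons[22] = rng.choice(("TGT", "TGC"))  # 1st-CYS
        cys2 = n_codons - 3
        codons[cys2] = rng.choice(("TGT", "TGC"))  # 2nd-CYS
        entries.append(
            SegmentLibraryEntry(
                name=f"{spec.locus}V{i + 1}",
                locus=spec.locus,
                seg_type="V",
                subgroup=f"{spec.locus}V{(i % 3) + 1}S",
                seq="".join(codons),
                cys_codon=cys2,
            )
        )
    for i in range(totals["D"]):
        length = rng.randint(16, 28)  # long enough to seed with default k=13
        entries.append(
            SegmentLibraryEntry(
                name=f"{spec.locus}D{i + 1}",
                locus=spec.locus,
                seg_type="D",
                seq=random_dna(rng, length, gc=0.5),
            )
        )
    for i in range(totals["J"]):
        n_codons = rng.randint(15, 19)
        codons = _random_codons(rng, n_codons)
        motif_codon = n_codons - 5
        codons[motif_codon] = rng.choice(("TTT", "TTC", "TGG"))
        codons[motif_codon + 1] = rng.choice(("GGT", "GGC", "GGA", "GGG"))
        codons[motif_codon + 3] = rng.choice(("GGT", "GGC", "GGA", "GGG"))
        entries.append(
            SegmentLibraryEntry(
                name=f"{spec.locus}J{i + 1}",
                locus=spec.locus,
                seg_type="J",
                seq="".join(codons),
                motif_codon=motif_codon,
            )
        )
    for i in range(totals["C"]):
        entries.append(
            SegmentLibraryEntry(
                name=f"{spec.locus}C{i + 1}",
                locus=spec.locus,
                seg_type="C",
                seq="".join(_random_codons(rng, rng.randint(100, 140))),
            )
        )
    return entries


# ---------------------------------------------------------------------------
# locus planting
# ---------------------------------------------------------------------------

def _mutate_motif(rng: random.Random, motif: str, n_changes: int) -> str:
    positions = rng.sample(range(len(motif)), n_changes)
    out = list(motif)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def _segment_order(spec: LocusSpec, library: list[SegmentLibraryEntry]) -> list[SegmentLibraryEntry]:
    by_type: dict[str, list[SegmentLibraryEntry]] = {"V": [], "D": [], "J": [], "C": []}
    for e in library:
        by_type[e.seg_type].append(e)
    order = list(by_type["V"])
    if spec.cassette is not None:
        cursors = {t: 0 for t in "DJC"}
        for c in range(spec.cassette.copies):
            for seg_type, counts in spec.cassette.elements:
                for _ in range(counts[c]):
                    order.append(by_type[seg_type][cursors[seg_type]])
                    cursors[seg_type] += 1
    else:
        order += by_type["D"] + by_type["J"] + by_type["C"]
    return order


def plant_locus(
    library: list[SegmentLibraryEntry],
    spec: LocusSpec,
    seed: int,
    chrom_id: str | None = None,
    max_length: int = 5_000_000,
) -> tuple[SeqRecord, TruthSet]:
    """Embed the locus in a chromosome with RSS flanks and planted defects.

    Segments appear in order (V block, then cassette copies or D/J/C blocks)
    separated by random spacer DNA.  Each V is followed by its RSS (heptamer
    ``CACAGTG``, locus-rule spacer, nonamer ``ACAAAAACC``); J segments carry a
    5' RSS and D segments both.  Defects are injected per ``defect_rates`` and
    the truth functionality recorded: stop codon or frameshift -> ``P``, RSS
    mutation -> ``ORF``.  Minus-strand loci are emitted reverse-complemented
    with truth coordinates flipped accordingly.
    """
    mismatched = [e for e in library if e.locus != spec.locus]
    if mismatched:
        raise ParameterError(f"library entries for wrong locus: {mismatched[0].name}")
    rng = random.Random(seed)
    chrom_id = chrom_id or f"chr_{spec.locus}"
    order = _segment_order(spec, library)

    pieces: list[str] = [random_dna(rng, rng.randint(spec.spacing, 2 * spec.spacing))]
    pos = len(pieces[0])
    truth_segments: list[GeneSegment] = []
    rates = spec.defect_rates

    for entry in order:
        seq = entry.seq
        flags: set[str] = set()
        if entry.seg_type == "V":
            if rng.random() < rates.stop_codon:
                codon_idx = rng.randint(5, (entry.cys_codon or 30) - 2)
                seq = seq[: 3 * codon_idx] + rng.choice(STOP_CODONS) + seq[3 * codon_idx + 3 :]
                flags.add("internal_stop")
            elif rng.random() < rates.frameshift:
                cut = rng.randint(len(seq) // 3, 2 * len(seq) // 3)
                seq = seq[:cut] + seq[cut + 1 :]
                flags.add("frameshift")
        rss_broken = entry.seg_type in "VDJ" and rng.random() < rates.rss_mutation
        if rss_broken:
            flags.add("bad_rss")

        def rss_block(spacer_len: int) -> str:
            hept, non = RSS_HEPTAMER, RSS_NONAMER
            if rss_broken:
                hept = _mutate_motif(rng, hept, 3)
                non = _mutate_motif(rng, non, 4)
            return hept + random_dna(rng, spacer_len) + non

        prefix = ""
        suffix = ""
        if entry.seg_type == "V":
            suffix = rss_block(spec.v_spacer_len)
        elif entry.seg_type == "J":
            prefix = revcomp(rss_block(spec.j_spacer))
        elif entry.seg_type == "D":
            prefix = revcomp(rss_block(spec.d_spacer))
            suffix = rss_block(spec.d_spacer)

        pieces.append(prefix)
        pos += len(prefix)
        start = pos
        pieces.append(seq)
        pos += len(seq)
        pieces.append(suffix)
        pos += len(suffix)

        if flags & GeneSegment.P_DEFECTS:
            functionality = "P"
        elif flags:
            functionality = "ORF"
        else:
            functionality = "F"
        truth_segments.append(
            GeneSegment(
                name=entry.name,
                locus=entry.locus,
                seg_type=entry.seg_type,
                interval=GenomicInterval(chrom_id, start, start + len(seq)),
                functionality=functionality,
                defect_flags=frozenset(flags),
            )
        )
        spacer = random_dna(rng, rng.randint(spec.spacing // 2, 3 * spec.spacing // 2))
        pieces.append(spacer)
        pos += len(spacer)

    seq = "".join(pieces)
    if len(seq) > max_length:
        raise ParameterError(f"locus length {len(seq)} exceeds budget {max_length}")

    if spec.strand == "-":
        length = len(seq)
        seq = revcomp(seq)
        truth_segments = [
            replace(
                s,
                interval=GenomicInterval(
                    chrom_id, length - s.interval.end, length - s.interval.start, "-"
                ),
            )
            for s in truth_segments
        ]
        # locus orientation order: reversed genomic coordinates
        truth_segments.sort(key=lambda s: -s.interval.start)

    chrom = SeqRecord(id=chrom_id, seq=seq)
    return chrom, TruthSet(segments=truth_segments)


# ---------------------------------------------------------------------------
# chromosome ends
# ---------------------------------------------------------------------------

def plant_chromosome_ends(
    chromosome: SeqRecord,
    telomere_units: int,
    satdna_pattern: str | None = None,
    satdna_copies: int = 0,
    seed: int = 0,
) -> tuple[SeqRecord, TruthSet]:
    """Append a (TTAGGG)n telomere at the 3' end and a satDNA array near the
    5' end; truth intervals are recorded against the returned sequence."""
    rng = random.Random(seed)
    truth = TruthSet()
    prefix = ""
    if satdna_pattern and satdna_copies > 0:
        pad = random_dna(rng, 200)
        array = satdna_pattern * satdna_copies
        prefix = pad + array
        truth.satdna.append(
            GenomicInterval(chromosome.id, len(pad), len(pad) + len(array))
        )
    suffix = "TTAGGG" * telomere_units
    seq = prefix + chromosome.seq + suffix
    if telomere_units > 0:
        truth.telomeres.append(
            GenomicInterval(chromosome.id, len(seq) - len(suffix), len(seq))
        )
    return SeqRecord(id=chromosome.id, seq=seq, description=chromosome.description), truth


# ---------------------------------------------------------------------------
# assembly degradation (old-assembly emulation)
# ---------------------------------------------------------------------------

def degrade_assembly(
    genome: list[SeqRecord],
    n_gaps: int,
    gap_len_range: tuple[int, int],
    n_excised_scaffolds: int,
    seed: int,
    scaffold_len_range: tuple[int, int] = (5_000, 20_000),
    end_margin: int = 1_000,
) -> tuple[list[SeqRecord], list[SeqRecord], TruthSet]:
    """Produce an N-gapped "old" assembly plus excised unplaced scaffolds.

    Random intervals are replaced by N-runs of the same length (so the truth
    gap span equals the N-run length); further intervals are excised into
    separate scaffold records whose true origin is recorded.  All chosen
    intervals are mutually disjoint and keep ``end_margin`` distance from
    sequence ends and from each other.
    """
    rng = random.Random(seed)
    truth = TruthSet()
    chosen: dict[str, list[tuple[int, int, str]]] = {r.id: [] for r in genome}

    weights = [len(r.seq) for r in genome]

    def pick(length: int, kind: str) -> None:
        for _ in range(500):
            chrom = rng.choices(genome, weights=weights)[0]
            hi = len(chrom.seq) - end_margin - length
            if hi < end_margin:
                continue  # chromosome too short for this event
            start = rng.randint(end_margin, hi)
            if all(
                start + length + end_margin <= s or e + end_margin <= start
                for s, e, _k in chosen[chrom.id]
            ):
                chosen[chrom.id].append((start, start + length, kind))
                return
        raise ParameterError(f"could not place {kind}; genome too small")

    for _ in range(n_excised_scaffolds):
        pick(rng.randint(*scaffold_len_range), "excise")
    for _ in range(n_gaps):
        pick(rng.randint(*gap_len_range), "gap")

    old: list[SeqRecord] = []
    scaffolds: list[SeqRecord] = []
    scaffold_n = 0
    for chrom in genome:
        events = sorted(chosen[chrom.id])
        parts: list[str] = []
        cursor = 0
        old_pos = 0
        for start, end, kind in events:
            parts.append(chrom.seq[cursor:start])
            old_pos += start - cursor
            if kind == "gap":
                parts.append("N" * (end - start))
                truth.gaps.append(
                    GapTruth(
                        old_interval=GenomicInterval(chrom.id, old_pos, old_pos + (end - start)),
                        new_interval=GenomicInterval(chrom.id, start, end),
                    )
                )
                old_pos += end - start
            else:
                scaffold_n += 1
                sid = f"scaffold_{scaffold_n}"
                scaffolds.append(SeqRecord(id=sid, seq=chrom.seq[start:end]))
                truth.placements.append(
                    PlacementTruth(
                        scaffold_id=sid,
                        new_interval=GenomicInterval(chrom.id, start, end),
                    )
                )
            cursor = end
        parts.append(chrom.seq[cursor:])
        old.append(SeqRecord(id=chrom.id, seq="".join(parts)))
    return old, scaffolds, truth


# ---------------------------------------------------------------------------
# diploid region + long reads
# ---------------------------------------------------------------------------

def make_diploid_region(
    length: int,
    snp_density: float,
    seed: int,
    region_id: str = "mhc_region",
) -> tuple[SeqRecord, SeqRecord, list[VcfVariant]]:
    """Two haplotypes differing by Binomial(length, snp_density) substitutions.

    Haplotype 1 is the reference (allele 0); the truth VCF carries phased
    ``0|1`` genotypes at every planted site.
    """
    rng = random.Random(seed)
    hap1 = random_dna(rng, length)
    hap2 = list(hap1)
    variants: list[VcfVariant] = []
    for pos in range(length):
        if rng.random() < snp_density:
            ref = hap1[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            hap2[pos] = alt
            variants.append(
                VcfVariant(
                    chrom=region_id,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gt=(0, 1),
                    phased=True,
                    phase_set=1,
                )
            )
    return (
        SeqRecord(id=f"{region_id}_hap1", seq=hap1),
        SeqRecord(id=f"{region_id}_hap2", seq="".join(hap2)),
        variants,
    )


def simulate_long_reads(
    haplotypes: tuple[SeqRecord, SeqRecord],
    depth: float,
    mean_len: int,
    error_rate: float,
    seed: int,
    min_len: int = 200,
) -> tuple[list[SeqRecord], list[PafRow]]:
    """Long reads drawn alternately from the two haplotypes.

    Uniform start positions, exponential (geometric-tail) lengths around
    ``mean_len``, substitution errors at ``error_rate``.  Reads overhanging
    the region end are truncated (squeezing starts leftward instead would
    inflate interior coverage under the heavy-tailed length law).  The truth
    PAF records each read's origin haplotype and interval (``ha:i`` tag).
    """
    rng = random.Random(seed)
    region_len = len(haplotypes[0].seq)
    n_reads = max(1, round(depth * region_len / mean_len))
    reads: list[SeqRecord] = []
    paf: list[PafRow] = []
    for i in range(n_reads):
        h = i % 2
        hap = haplotypes[h]
        drawn = max(min_len, int(rng.expovariate(1.0 / mean_len)))
        start = rng.randint(0, region_len - min(min_len, region_len))
        length = min(drawn, region_len - start)
        seq = list(hap.seq[start : start + length])
        n_err = 0
        for p in range(length):
            if rng.random() < error_rate:
                seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
                n_err += 1
        read_id = f"read_{i}"
        reads.append(SeqRecord(id=read_id, seq="".join(seq)))
        paf.append(
            PafRow(
                query_name=read_id,
                query_len=length,
                query_start=0,
                query_end=length,
                strand="+",
                target_name=hap.id,
                target_len=region_len,
                target_start=start,
                target_end=start + length,
                matches=length - n_err,
                block_length=length,
                mapq=60,
                tags=(f"ha:i:{h}",),
            )
        )
    return reads, paf


# ---------------------------------------------------------------------------
# V(D)J transcripts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionModel:
    """Junctional diversity model for recombined transcripts.

    ``trim_max`` bounds exonucleolytic trimming of V 3' / D both / J 5' ends;
    N-region lengths are uniform on [0, n_max].  A fraction
    ``productive_fraction`` of transcripts is forced in frame and stop-free
    through the J motif, emulating the selection acting on an expressed
    repertoire; the rest recombine blindly.
    """

    trim_max: int = 6
    n_max: int = 6
    productive_fraction: float = 0.95

    def __post_init__(self) -> None:
        if self.trim_max < 0 or self.n_max < 0:
            raise ParameterError("trim_max and n_max must be >= 0")
        if not (0.0 <= self.productive_fraction <= 1.0):
            raise ParameterError("productive_fraction outside [0, 1]")


def _check_weights(weights: dict[str, float], label: str) -> None:
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ParameterError(f"{label} weights sum to {total}, expected 1")


def simulate_transcripts(
    library: list[SegmentLibraryEntry],
    usage_weights: dict[str, dict[str, float]],
    junction_model: JunctionModel,
    n: int,
    seed: int,
    id_prefix: str = "tx",
    utr_len: int = 0,
) -> tuple[list[SeqRecord], list[TranscriptTruth]]:
    """Recombined full-length transcripts: trimmed V + N + (D + N) + trimmed J + C.

    ``usage_weights`` maps "V"/"J" (and optionally "D") to name->probability
    dictionaries, each summing to 1.  Truth records the chosen segments, the
    junction string (2nd-CYS codon through the base before the J motif codon)
    and intended productivity.
    """
    by_name = {e.name: e for e in library}
    v_weights = usage_weights["V"]
    j_weights = usage_weights["J"]
    _check_weights(v_weights, "V")
    _check_weights(j_weights, "J")
    d_weights = usage_weights.get("D")
    if d_weights:
        _check_weights(d_weights, "D")
    locus = by_name[next(iter(v_weights))].locus
    has_d = locus in D_BEARING_LOCI and (
        d_weights or any(e.seg_type == "D" and e.locus == locus for e in library)
    )
    d_names = (
        list(d_weights)
        if d_weights
        else [e.name for e in library if e.seg_type == "D" and e.locus == locus]
    )
    c_entries = [e for e in library if e.seg_type == "C" and e.locus == locus]

    rng = random.Random(seed)
    jm = junction_model
    transcripts: list[SeqRecord] = []
    truths: list[TranscriptTruth] = []

    v_names, v_p = list(v_weights), list(v_weights.values())
    j_names, j_p = list(j_weights), list(j_weights.values())
    d_p = list(d_weights.values()) if d_weights else None

    for i in range(n):
        v = by_name[rng.choices(v_names, weights=v_p)[0]]
        j = by_name[rng.choices(j_names, weights=j_p)[0]]
        d = None
        if has_d and d_names:
            d = by_name[rng.choices(d_names, weights=d_p)[0]]
        c = rng.choice(c_entries) if c_entries else None

        force_productive = rng.random() < jm.productive_fraction
        assert j.motif_codon is not None and v.cys_codon is not None
        motif_in_j = 3 * j.motif_codon

        for attempt in range(60):
            v_trim = rng.randint(0, jm.trim_max)
            j_trim = rng.randint(0, min(jm.trim_max, motif_in_j))
            vt = v.seq[: len(v.seq) - v_trim]
            if d is not None:
                d5 = rng.randint(0, min(jm.trim_max // 2, len(d.seq) // 3))
                d3 = rng.randint(0, min(jm.trim_max // 2, len(d.seq) // 3))
                dt = d.seq[d5 : len(d.seq) - d3]
            else:
                dt = ""
            n1 = random_dna(rng, rng.randint(0, jm.n_max), gc=0.5)
            n2 = random_dna(rng, rng.randint(0, jm.n_max), gc=0.5) if dt else ""
            if not dt:
                n1, n2 = n1, ""

            motif_abs = len(vt) + len(n1) + len(dt) + len(n2) + (motif_in_j - j_trim)
            if force_productive:
                pad = (3 - motif_abs % 3) % 3
                if dt:
                    n2 += random_dna(rng, pad, gc=0.5)
                else:
                    n1 += random_dna(rng, pad, gc=0.5)
                motif_abs += pad
            jt = j.seq[j_trim:]
            body = vt + n1 + dt + n2 + jt
            if force_productive:
                aa = translate(body[: len(body) - len(body) % 3])
                if "*" in aa:
                    continue
            break

        cseq = c.seq if c else ""
        body_full = body + cseq
        flank5 = random_dna(rng, utr_len) if utr_len else ""
        flank3 = random_dna(rng, utr_len) if utr_len else ""
        seq = flank5 + body_full + flank3

        cys_start = len(flank5) + 3 * v.cys_codon
        junction = seq[cys_start : len(flank5) + motif_abs]
        in_frame = (motif_abs - 3 * v.cys_codon) % 3 == 0
        aa_body = translate(body[: len(body) - len(body) % 3])
        productive = in_frame and "*" not in aa_body

        transcripts.append(SeqRecord(id=f"{id_prefix}_{i}", seq=seq))
        truths.append(
            TranscriptTruth(
                transcript_id=f"{id_prefix}_{i}",
                locus=locus,
                v_name=v.name,
                d_name=d.name if d else None,
                j_name=j.name,
                c_name=c.name if c else None,
                junction_nt=junction,
                productive=productive,
            )
        )
    return transcripts, truths
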