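"""Readers and writers for the on-disk formats used across the pipeline.

All coordinates are 0-based half-open internally.  GFF3 is converted from its
native 1-based inclusive convention on read and back on write; BED, PAF and the
internal interval type share the 0-based half-open convention.  Sequences are
uppercase DNA over ``{A, C, G, T, N}``; ``N`` is a valid assembly base
everywhere except gene-segment libraries (gaps are runs of ``N``).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

log = logging.getLogger("immloci")

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Well-formed input that violates a semantic constraint."""


class ParameterError(ValueError):
    """An argument outside its documented domain."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    """A named uppercase DNA sequence."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValidationError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self, new_id: str | None = None) -> "SeqRecord":
        return replace(self, id=new_id or self.id, seq=revcomp(self.seq))


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValidationError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SegmentLibraryEntry:
    """One reference gene segment (IMGT-style library entry).

    ``cys_codon`` marks the codon index of the conserved second cysteine for V
    segments (0-based, in the segment's own reading frame); ``motif_codon``
    marks the codon index of the F/W-G-X-G motif for J segments.  Both are
    ``None`` where they do not apply.
    """

    name: str
    locus: str
    seg_type: str
    seq: str
    subgroup: str = ""
    cys_codon: int | None = None
    motif_codon: int | None = None

    VALID_LOCI = ("IGH", "IGK", "IGL", "TRA", "TRB", "TRD", "TRG")

    def __post_init__(self) -> None:
        if self.locus not in self.VALID_LOCI:
            raise ValidationError(f"unknown locus {self.locus!r}")
        if self.seg_type not in ("V", "D", "J", "C"):
            raise ValidationError(f"unknown segment type {self.seg_type!r}")
        bad = set(self.seq) - (DNA_ALPHABET - {"N"})
        if bad:
            raise ValidationError(
                f"library entry {self.name!r} contains {sorted(bad)}; "
                "N is not allowed in segment libraries"
            )


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into validated, uppercased records."""
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "U" in seq:
            raise ValidationError(f"RNA base U in record {rec.id!r}")
        if rec.id in seen:
            raise ValidationError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecord(id=rec.id, seq=seq, description=rec.description))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, wrap_width: int = 70) -> None:
    if wrap_width < 1:
        raise ParameterError("wrap_width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), wrap_width):
                fh.write(rec.seq[i : i + wrap_width] + "\n")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    records = [
        SeqRecord(id=r.id, seq=str(r.seq).upper(), description=r.description)
        for r in SeqIO.parse(str(path), "fastq")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTQ records")
    return records


def write_fastq(records: Iterable[SeqRecord], path: str | Path, quality_char: str = "I") -> None:
    qv = ord(quality_char) - 33
    bio = []
    for rec in records:
        b = _BioSeqRecord(Seq(rec.seq), id=rec.id, description="")
        b.letter_annotations["phred_quality"] = [qv] * len(rec.seq)
        bio.append(b)
    SeqIO.write(bio, str(path), "fastq")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gff3Feature:
    interval: GenomicInterval
    source: str
    type: str
    score: str
    attributes: Mapping[str, str]

    @property
    def id(self) -> str:
        return self.attributes["ID"]


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    """Read GFF3, converting 1-based inclusive coordinates to 0-based half-open."""
    feats: list[Gff3Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, source, ftype, start, end, score, strand, _phase, attrs = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start_i > end_i:
                raise FormatError(f"{path}:{lineno}: start > end")
            attributes = {}
            for pair in attrs.split(";"):
                if not pair:
                    continue
                key, _, value = pair.partition("=")
                attributes[key] = value
            if "ID" not in attributes:
                raise ValidationError(f"{path}:{lineno}: missing ID attribute")
            feats.append(
                Gff3Feature(
                    interval=GenomicInterval(seqid, start_i - 1, end_i, strand if strand in "+-" else "+"),
                    source=source,
                    type=ftype,
                    score=score,
                    attributes=attributes,
                )
            )
    return feats


def write_gff3(features: Iterable[Gff3Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items())
            fh.write(
                "\t".join(
                    [
                        f.interval.seq_id,
                        f.source,
                        f.type,
                        str(f.interval.start + 1),
                        str(f.interval.end),
                        f.score,
                        f.interval.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PafRow:
    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    matches: int
    block_length: int
    mapq: int
    tags: tuple[str, ...] = ()

    @property
    def identity(self) -> float:
        """Percent identity = residue matches / alignment block length."""
        if self.block_length == 0:
            return 0.0
        return 100.0 * self.matches / self.block_length


def read_paf(path: str | Path) -> list[PafRow]:
    rows: list[PafRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}:{lineno}: PAF requires >=12 columns, got {len(cols)}")
            try:
                rows.append(
                    PafRow(
                        query_name=cols[0],
                        query_len=int(cols[1]),
                        query_start=int(cols[2]),
                        query_end=int(cols[3]),
                        strand=cols[4],
                        target_name=cols[5],
                        target_len=int(cols[6]),
                        target_start=int(cols[7]),
                        target_end=int(cols[8]),
                        matches=int(cols[9]),
                        block_length=int(cols[10]),
                        mapq=int(cols[11]),
                        tags=tuple(cols[12:]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate field") from exc
    return rows


def write_paf(rows: Iterable[PafRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in rows:
            cols = [
                r.query_name,
                str(r.query_len),
                str(r.query_start),
                str(r.query_end),
                r.strand,
                r.target_name,
                str(r.target_len),
                str(r.target_start),
                str(r.target_end),
                str(r.matches),
                str(r.block_length),
                str(r.mapq),
                *r.tags,
            ]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# VCF (single-sample SNPs)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VcfVariant:
    chrom: str
    pos: int  # 0-based internally
    ref: str
    alt: str
    gt: tuple[int, int]
    phased: bool = False
    phase_set: int | None = None

    @property
    def is_het(self) -> bool:
        return self.gt[0] != self.gt[1]


def read_vcf(path: str | Path) -> list[VcfVariant]:
    """Read a single-sample SNP VCF; POS becomes 0-based internally."""
    variants: list[VcfVariant] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 10:
                raise FormatError(f"{path}:{lineno}: expected FORMAT and one sample column")
            chrom, pos, _id, ref, alt = cols[0], cols[1], cols[2], cols[3], cols[4]
            fmt_keys = cols[8].split(":")
            sample_vals = cols[9].split(":")
            sample = dict(zip(fmt_keys, sample_vals))
            if "GT" not in sample:
                raise ValidationError(f"{path}:{lineno}: record without GT")
            gt_raw = sample["GT"]
            phased = "|" in gt_raw
            sep = "|" if phased else "/"
            try:
                a, b = (int(x) for x in gt_raw.split(sep))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable GT {gt_raw!r}") from exc
            ps = None
            if "PS" in sample:
                ps = int(sample["PS"])
            variants.append(
                VcfVariant(
                    chrom=chrom,
                    pos=int(pos) - 1,
                    ref=ref,
                    alt=alt,
                    gt=(a, b),
                    phased=phased,
                    phase_set=ps,
                )
            )
    return variants


def write_vcf(variants: Sequence[VcfVariant], path: str | Path, sample: str = "sample") -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in variants:
            sep = "|" if v.phased else "/"
            gt = f"{v.gt[0]}{sep}{v.gt[1]}"
            if v.phase_set is not None:
                fmt, val = "GT:PS", f"{gt}:{v.phase_set}"
            else:
                fmt, val = "GT", gt
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t{fmt}\t{val}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "+"
            out.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else "."
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Segment library sidecar metadata
# ---------------------------------------------------------------------------

def read_segment_library(fasta_path: str | Path, meta_path: str | Path) -> list[SegmentLibraryEntry]:
    """Load a segment library from FASTA plus a sidecar TSV.

    The TSV has header columns: name, locus, seg_type, subgroup, cys_codon,
    motif_codon (empty cells mean "not applicable").
    """
    seqs = {r.id: r.seq for r in read_fasta(fasta_path)}
    entries: list[SegmentLibraryEntry] = []
    with open(meta_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {h: i for i, h in enumerate(header)}
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if not cols or not cols[0]:
                continue
            name = cols[idx["name"]]
            if name not in seqs:
                raise ValidationError(f"library metadata names {name!r} absent from FASTA")
            cys = cols[idx["cys_codon"]] if "cys_codon" in idx else ""
            motif = cols[idx["motif_codon"]] if "motif_codon" in idx else ""
            entries.append(
                SegmentLibraryEntry(
                    name=name,
                    locus=cols[idx["locus"]],
                    seg_type=cols[idx["seg_type"]],
                    subgroup=cols[idx["subgroup"]] if "subgroup" in idx else "",
                    seq=seqs[name],
                    cys_codon=int(cys) if cys else None,
                    motif_codon=int(motif) if motif else None,
                )
            )
    names = [(e.locus, e.name) for e in entries]
    if len(names) != len(set(names)):
        raise ValidationError("duplicate (locus, name) in segment library")
    return entries


def write_segment_library(entries: Sequence[SegmentLibraryEntry], fasta_path: str | Path, meta_path: str | Path) -> None:
    write_fasta([SeqRecord(id=e.name, seq=e.seq) for e in entries], fasta_path)
    with open(meta_path, "w") as fh:
        fh.write("name\tlocus\tseg_type\tsubgroup\tcys_codon\tmotif_codon\n")
        for e in entries:
            cys = "" if e.cys_codon is None else str(e.cys_codon)
            motif = "" if e.motif_codon is None else str(e.motif_codon)
            fh.write(f"{e.name}\t{e.locus}\t{e.seg_type}\t{e.subgroup}\t{cys}\t{motif}\n")


# ---------------------------------------------------------------------------
# Flat key=value config
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict[str, float] = {
    # align_core
    "align.match": 2,
    "align.mismatch": -4,
    "align.gap_open": -4,
    "align.gap_extend": -2,
    "align.k": 13,
    "align.unique_ratio": 1.2,
    # locus_annotation
    "annotate.min_identity": 80.0,
    "annotate.min_coverage": 90.0,
    "annotate.rss_min_score": 0.7,
    "annotate.rss_window": 60,
    # assembly_qc
    "qc.qv_cap": 99.0,
    "qc.telomere_min_len": 15000,
    "qc.telomere_end_slack": 1000,
    "qc.satdna_min_identity": 80.0,
    "qc.tr_min_copies": 3,
    "qc.tr_min_purity": 85.0,
    # gap_patch
    "gapfill.flank_len": 10000,
    "gapfill.min_identity": 90.0,
    "gapfill.max_span": 10_000_000,
    "place.min_fraction": 50.0,
    "place.min_piece_identity": 90.0,
    # mhc_phase
    "phase.min_depth": 10,
    "phase.min_alt_frac": 0.25,
    "phase.max_dp_reads": 15,
    "mhc.min_locus_identity": 80.0,
    "mhc.min_transcript_identity": 95.0,
    "mhc.min_transcripts": 2,
    # repertoire
    "repertoire.min_v_score": 100,
    "repertoire.d_min_match": 8,
    "repertoire.ultralong_aa": 40,
}


def read_config(path: str | Path | None) -> dict[str, float]:
    cfg = dict(DEFAULT_CONFIG)
    if path is None:
        return cfg
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if not value:
                raise FormatError(f"{path}:{lineno}: missing value for {key!r}")
            cfg[key] = float(value)
    return cfg


def config_digest(cfg: Mapping[str, float]) -> str:
    payload = ";".join(f"{k}={cfg[k]}" for k in sorted(cfg))
    return hashlib.sha1(payload.encode()).hexdigest()[:12]
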