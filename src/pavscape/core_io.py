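"""Readers and writers for the on-disk formats the pipeline touches.

Every format with 1-based inclusive coordinates on disk (GFF3, AGP,
BLAST-style 12-column tabular) is converted at this boundary to the single
internal convention: 0-based, half-open, end-exclusive.  Nothing outside
this module performs coordinate arithmetic between conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "ParseError",
    "SeqRecord",
    "Interval",
    "AlignmentHit",
    "Feature",
    "CoverageTrack",
    "ScaffoldPlacement",
    "GapPlacement",
    "read_sequences",
    "write_sequences",
    "read_annotation",
    "write_annotation",
    "read_coverage",
    "write_coverage",
    "read_tabular_hits",
    "write_tabular_hits",
    "write_agp",
    "read_agp",
    "to_one_based",
    "from_one_based",
    "reverse_complement",
    "ambiguity_fraction",
]

# Characters that are not plain unambiguous nucleotides.  N and every IUPAC
# degeneracy code count as "ambiguity characters" for the 10%/40% filters.
UNAMBIGUOUS = frozenset("ACGT")
AMBIGUITY_CODES = frozenset("NRYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


class ParseError(ValueError):
    """Malformed input file; carries the offending path and line number."""

    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide (or protein) sequence, upper-cased on ingest."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a query and a subject sequence.

    Coordinates follow the internal convention; minus-strand hits are
    normalized so that subject_start < subject_end and the strand flag
    carries the orientation.
    """

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    strand: str
    identity: float
    aligned_length: int
    score: float
    evalue: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity {self.identity} outside [0,1]")
        if self.aligned_length < 1:
            raise ValueError("aligned_length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class Feature:
    """An annotation entry (gene, exon, transposable_element, ...)."""

    seq_id: str
    interval: Interval
    type: str
    id: str


@dataclass
class CoverageTrack:
    """Dense per-base read depth over one assembly sequence."""

    seq_id: str
    depth: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    @property
    def length(self) -> int:
        return int(self.depth.size)


@dataclass(frozen=True)
class ScaffoldPlacement:
    """A component (W) line of an AGP file, internal coordinates."""

    object_id: str
    object_start: int
    object_end: int
    component_id: str
    component_start: int
    component_end: int
    strand: str

    def __post_init__(self):
        if self.object_end - self.object_start != self.component_end - self.component_start:
            raise ValueError("object and component spans differ in length")


@dataclass(frozen=True)
class GapPlacement:
    """A gap (N/U) line of an AGP file, internal coordinates."""

    object_id: str
    object_start: int
    object_end: int
    gap_type: str = "scaffold"  # "scaffold" or "contig"
    known_size: bool = False    # False -> component type U, True -> N
    linkage: bool = True


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open -> on-disk 1-based inclusive."""
    return start + 1, end


def from_one_based(start: int, end: int) -> tuple[int, int]:
    """On-disk 1-based inclusive -> internal 0-based half-open."""
    return start - 1, end


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def ambiguity_fraction(seq: str) -> float:
    """Fraction of characters that are not plain A/C/G/T."""
    if not seq:
        return 0.0
    n = sum(1 for c in seq if c not in UNAMBIGUOUS)
    return n / len(seq)


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_sequences(path, format: str = "fasta") -> list[SeqRecord]:
    """Read FASTA or FASTQ into SeqRecords (upper-cased, order preserved)."""
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported sequence format {format!r}")
    records: list[SeqRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), format):
            if rec.id in seen:
                raise ParseError(path, 0, f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            records.append(SeqRecord(rec.id, str(rec.seq).upper()))
    except ParseError:
        raise
    except ValueError as exc:
        raise ParseError(path, _offending_line(path, len(records), format), str(exc))
    return records


def _offending_line(path, n_records_ok, format) -> int:
    # Best-effort line number for the record at which parsing failed.
    per_record = 4 if format == "fastq" else 2
    return n_records_ok * per_record + 1


def write_sequences(records, path, format: str = "fasta", line_width: int = 80):
    with open(path, "w") as fh:
        for rec in records:
            if format == "fasta":
                fh.write(f">{rec.id}\n")
                for i in range(0, rec.length, line_width):
                    fh.write(rec.sequence[i:i + line_width] + "\n")
            elif format == "fastq":
                fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{'I' * rec.length}\n")
            else:
                raise ValueError(f"unsupported sequence format {format!r}")


# ---------------------------------------------------------------------------
# GFF3

def read_annotation(path) -> list[Feature]:
    """Read GFF3 (1-based inclusive on disk) into internal Features.

    Records with start > end are rejected; one summary warning reports the
    rejected count.
    """
    feats: list[Feature] = []
    rejected = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(path, line_no, f"expected 9 columns, got {len(cols)}")
            seq_id, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(path, line_no, "non-numeric coordinate")
            if start1 > end1:
                rejected += 1
                continue
            start, end = from_one_based(start1, end1)
            fid = _gff_attribute(attrs, "ID") or f"{ftype}:{seq_id}:{start}"
            feats.append(
                Feature(seq_id, Interval(seq_id, start, end, strand if strand in "+-" else "."), ftype, fid)
            )
    if rejected:
        warnings.warn(f"{path}: rejected {rejected} GFF3 records with start > end")
    return feats


def _gff_attribute(attrs: str, key: str):
    for part in attrs.split(";"):
        if part.startswith(key + "="):
            return part[len(key) + 1:]
    return None


def write_annotation(features, path, source: str = "pavscape"):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            start1, end1 = to_one_based(f.interval.start, f.interval.end)
            strand = f.interval.strand if f.interval.strand in "+-" else "."
            fh.write(
                f"{f.seq_id}\t{source}\t{f.type}\t{start1}\t{end1}\t.\t{strand}\t.\tID={f.id}\n"
            )


# ---------------------------------------------------------------------------
# BedGraph depth exchange

def read_coverage(path, seq_lengths: dict[str, int]) -> dict[str, CoverageTrack]:
    """Read a BedGraph (0-based half-open) into dense coverage tracks.

    Positions absent from the file get depth 0; every sequence named in
    ``seq_lengths`` yields a track even if the file never mentions it.
    """
    depths = {sid: np.zeros(n, dtype=np.int64) for sid, n in seq_lengths.items()}
    filled = {sid: np.zeros(n, dtype=bool) for sid, n in seq_lengths.items()}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            cols = line.split()
            if len(cols) != 4:
                raise ParseError(path, line_no, f"expected 4 columns, got {len(cols)}")
            sid, start_s, end_s, depth_s = cols
            if sid not in depths:
                raise ParseError(path, line_no, f"unknown sequence {sid!r}")
            try:
                start, end, depth = int(start_s), int(end_s), int(depth_s)
            except ValueError:
                raise ParseError(path, line_no, "non-numeric field")
            if not (0 <= start < end <= seq_lengths[sid]):
                raise ParseError(path, line_no, "interval outside sequence bounds")
            if filled[sid][start:end].any():
                raise ParseError(path, line_no, "overlapping intervals")
            filled[sid][start:end] = True
            depths[sid][start:end] = depth
    return {sid: CoverageTrack(sid, arr) for sid, arr in depths.items()}


def write_coverage(tracks, path):
    """Write coverage tracks as BedGraph, run-length encoded, zeros omitted."""
    with open(path, "w") as fh:
        for track in tracks:
            d = track.depth
            if d.size == 0:
                continue
            change = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [d.size]))
            for s, e in zip(starts, ends):
                if d[s]:
                    fh.write(f"{track.seq_id}\t{s}\t{e}\t{d[s]}\n")


# ---------------------------------------------------------------------------
# BLAST outfmt-6-style 12-column tabular

def read_tabular_hits(path) -> list[AlignmentHit]:
    """Read 12-column tabular hits (1-based inclusive; sstart > send = minus)."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 12:
                raise ParseError(path, line_no, f"expected 12 columns, got {len(cols)}")
            (q, s, pident, alen, _mm, _gaps, qs, qe, ss, se, ev, bits) = cols
            try:
                pident = float(pident)
                alen = int(alen)
                qs, qe, ss, se = int(qs), int(qe), int(ss), int(se)
                ev, bits = float(ev), float(bits)
            except ValueError:
                raise ParseError(path, line_no, "non-numeric field")
            strand = "+"
            if ss > se:
                strand = "-"
                ss, se = se, ss
            if qs > qe:
                raise ParseError(path, line_no, "query start > end")
            hits.append(
                AlignmentHit(
                    query_id=q,
                    subject_id=s,
                    query_start=qs - 1,
                    query_end=qe,
                    subject_start=ss - 1,
                    subject_end=se,
                    strand=strand,
                    identity=pident / 100.0,
                    aligned_length=alen,
                    score=bits,
                    evalue=ev,
                )
            )
    return hits


def write_tabular_hits(hits, path):
    with open(path, "w") as fh:
        for h in hits:
            qs1, qe1 = to_one_based(h.query_start, h.query_end)
            ss1, se1 = to_one_based(h.subject_start, h.subject_end)
            if h.strand == "-":
                ss1, se1 = se1, ss1
            mism = round(h.aligned_length * (1.0 - h.identity))
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity * 100:.2f}\t{h.aligned_length}\t"
                f"{mism}\t0\t{qs1}\t{qe1}\t{ss1}\t{se1}\t{h.evalue:.2g}\t{h.score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# AGP v2.0

def write_agp(placements, path):
    """Write component and gap placements as AGP v2.0 (1-based inclusive).

    Placements per object must be non-overlapping and, once sorted by object
    coordinate, contiguous (gap rows included explicitly).
    """
    by_object: dict[str, list] = {}
    for p in placements:
        by_object.setdefault(p.object_id, []).append(p)
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        for obj in by_object:
            rows = sorted(by_object[obj], key=lambda p: p.object_start)
            pos = rows[0].object_start
            for part, p in enumerate(rows, 1):
                if p.object_start < pos:
                    raise ValueError(f"overlapping placements on object {obj!r}")
                pos = p.object_end
                ob1, oe1 = to_one_based(p.object_start, p.object_end)
                if isinstance(p, GapPlacement):
                    ctype = "N" if p.known_size else "U"
                    gap_len = p.object_end - p.object_start
                    linkage = "yes" if p.linkage else "no"
                    evidence = "paired-ends" if p.linkage else "na"
                    fh.write(
                        f"{obj}\t{ob1}\t{oe1}\t{part}\t{ctype}\t{gap_len}\t{p.gap_type}\t{linkage}\t{evidence}\n"
                    )
                else:
                    cb1, ce1 = to_one_based(p.component_start, p.component_end)
                    fh.write(
                        f"{obj}\t{ob1}\t{oe1}\t{part}\tW\t{p.component_id}\t{cb1}\t{ce1}\t{p.strand}\n"
                    )


def read_agp(path):
    """Parse AGP v2.0 back into ScaffoldPlacement / GapPlacement lists."""
    placements = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(path, line_no, f"expected 9 columns, got {len(cols)}")
            obj, ob1, oe1, _part, ctype = cols[0], int(cols[1]), int(cols[2]), cols[3], cols[4]
            ostart, oend = from_one_based(ob1, oe1)
            if ctype in ("N", "U"):
                placements.append(
                    GapPlacement(
                        object_id=obj,
                        object_start=ostart,
                        object_end=oend,
                        gap_type=cols[6],
                        known_size=(ctype == "N"),
                        linkage=(cols[7] == "yes"),
                    )
                )
            elif ctype == "W":
                cstart, cend = from_one_based(int(cols[6]), int(cols[7]))
                placements.append(
                    ScaffoldPlacement(
                        object_id=obj,
                        object_start=ostart,
                        object_end=oend,
                        component_id=cols[5],
                        component_start=cstart,
                        component_end=cend,
                        strand=cols[8],
                    )
                )
            else:
                raise ParseError(path, line_no, f"unsupported component type {ctype!r}")
    return placements
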