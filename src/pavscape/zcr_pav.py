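"""Zero-coverage-region detection and PAV/HDR classification.

The core procedure: map the reads of accession A onto the assembly of
accession B, find maximal runs of zero depth (ZCRs, >= 5 bp), drop runs
with > 10% ambiguity characters, and classify each remaining ZCR >= 100 bp
by anchoring its 1 kbp flanks back onto the A assembly.  Directly adjacent
flank anchors (same subject, same strand, correct order, inner-end distance
within tolerance) mean the ZCR sequence is absent from A: a presence/absence
variant (PAV), i.e. a deletion in A and simultaneously an insertion in B.
Non-adjacent anchors mean the sequence is present but too diverged for
reads to map: a highly diverged region (HDR).  PAV candidates are further
checked against the mate-pair distance signal: read pairs spanning the ZCR
should deviate from the library-wide mean inner distance by more than
100 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _align
from .core_io import AlignmentHit, CoverageTrack, Interval, SeqRecord, ambiguity_fraction
from .read_mapping import (
    GenomeIndex,
    MappingParams,
    map_reads,
    compute_coverage,
    pair_distance_stats,
    _pair_key,
)

__all__ = [
    "ZcrParams",
    "ZcrRecord",
    "SvCall",
    "SizeBinSummary",
    "DirectionResult",
    "ReciprocalResult",
    "detect_zcrs",
    "extract_flanks",
    "anchor_flanks",
    "classify_zcr",
    "validate_by_pair_distance",
    "run_direction",
    "run_reciprocal",
    "coverage_titration",
    "summarize_bins",
]


@dataclass
class ZcrParams:
    min_zcr_len: int = 5
    report_min_len: int = 100
    max_ambiguity: float = 0.10
    flank_len: int = 1000
    pav_min_len: int = 100
    base_adjacency_tol: int = 100
    rel_tol: float = 0.10          # for ZCRs > 1 kbp
    pair_dev_cutoff: float = 100.0
    min_spanning_pairs: int = 3

    def __post_init__(self):
        if self.min_zcr_len < 1:
            raise ValueError("min_zcr_len must be >= 1")
        if not 0.0 <= self.max_ambiguity <= 1.0:
            raise ValueError("max_ambiguity must be in [0,1]")
        if min(self.base_adjacency_tol, self.rel_tol, self.pair_dev_cutoff) <= 0:
            raise ValueError("tolerances must be > 0")

    def adjacency_tolerance(self, zcr_length: int) -> float:
        if zcr_length <= 1000:
            return float(self.base_adjacency_tol)
        return self.rel_tol * zcr_length


@dataclass(frozen=True)
class ZcrRecord:
    """A maximal zero-coverage run on the mapping-target assembly."""

    interval: Interval
    ambiguity_fraction: float
    at_sequence_edge: bool

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class SvCall:
    """Classification of one ZCR.

    A PAV is one event with two names: a deletion in the read-source
    accession and an insertion in the mapping-target accession.
    """

    zcr: ZcrRecord
    classification: str  # pav | hdr | unresolved
    flank_hits: tuple[AlignmentHit | None, AlignmentHit | None] = (None, None)
    inner_end_distance: int | None = None
    pair_distance_supported: str = "indeterminate"  # supported|unsupported|indeterminate
    read_source: str = ""
    target: str = ""

    @property
    def sv_type(self) -> str | None:
        if self.classification != "pav":
            return None
        return "deletion_in_read_source"  # equivalently insertion_in_target


_BIN_BOUNDS = [(100, 200), (201, 400), (401, 800), (801, 1600), (1601, 3200),
               (3201, 6400), (6401, 12800), (12801, 25600)]
BIN_LABELS = [f"{lo}-{hi}" for lo, hi in _BIN_BOUNDS] + [">25600"]


@dataclass
class SizeBinSummary:
    """Doubling-size-bin summary (count and cumulative bp per bin)."""

    counts: list[int]
    bps: list[int]

    @property
    def total_count(self) -> int:
        return sum(self.counts)

    @property
    def total_bp(self) -> int:
        return sum(self.bps)

    @classmethod
    def from_rows(cls, counts, bps) -> "SizeBinSummary":
        counts, bps = list(counts), list(bps)
        if len(counts) != len(BIN_LABELS) or len(bps) != len(BIN_LABELS):
            raise ValueError(f"expected {len(BIN_LABELS)} bins")
        return cls(counts, bps)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin": BIN_LABELS, "count": self.counts, "bp": self.bps})
        df.loc[len(df)] = ["Total", self.total_count, self.total_bp]
        return df


def _bin_index(length: int) -> int:
    if length < 100:
        raise ValueError(f"length {length} below the 100 bp reporting floor")
    for i, (lo, hi) in enumerate(_BIN_BOUNDS):
        if lo <= length <= hi:
            return i
    return len(_BIN_BOUNDS)


def summarize_bins(items) -> SizeBinSummary:
    """Bin SvCalls / ZcrRecords / plain lengths into the doubling bins."""
    counts = [0] * len(BIN_LABELS)
    bps = [0] * len(BIN_LABELS)
    for item in items:
        if isinstance(item, SvCall):
            length = item.zcr.length
        elif isinstance(item, ZcrRecord):
            length = item.length
        else:
            length = int(item)
        i = _bin_index(length)
        counts[i] += 1
        bps[i] += length
    return SizeBinSummary(counts, bps)


# ---------------------------------------------------------------------------

def detect_zcrs(track: CoverageTrack, target: SeqRecord, params: ZcrParams | None = None):
    """Maximal zero-depth runs >= min_zcr_len, ambiguity-filtered."""
    params = params or ZcrParams()
    if track.length != target.length:
        raise ValueError(
            f"coverage track length {track.length} != sequence length {target.length}"
        )
    zero = track.depth == 0
    if not zero.any():
        return []
    padded = np.concatenate(([False], zero, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    records = []
    for s, e in zip(starts, ends):
        if e - s < params.min_zcr_len:
            continue
        frac = ambiguity_fraction(target.sequence[s:e])
        if frac > params.max_ambiguity:
            continue
        records.append(
            ZcrRecord(
                interval=Interval(target.id, int(s), int(e)),
                ambiguity_fraction=frac,
                at_sequence_edge=(s == 0 or e == target.length),
            )
        )
    return records


def extract_flanks(zcr: ZcrRecord, target: SeqRecord, params: ZcrParams | None = None):
    """1 kbp flanks either side of a ZCR, clipped at sequence boundaries.

    Returns (left, right, (left_clipped, right_clipped)); a flank that is
    clipped to zero length is returned as None.
    """
    params = params or ZcrParams()
    s, e = zcr.interval.start, zcr.interval.end
    ls = max(0, s - params.flank_len)
    re_ = min(target.length, e + params.flank_len)
    left_clipped = (s - ls) < params.flank_len
    right_clipped = (re_ - e) < params.flank_len
    tag = f"{target.id}:{s}-{e}"
    left = SeqRecord(f"{tag}:L", target.sequence[ls:s]) if s > ls else None
    right = SeqRecord(f"{tag}:R", target.sequence[e:re_]) if re_ > e else None
    return left, right, (left_clipped, right_clipped)


def anchor_flanks(flanks, counterpart, index: GenomeIndex | None = None,
                  external_hits: dict[str, AlignmentHit] | None = None):
    """Best counterpart hit per flank (None where no hit covers >= 50%).

    ``external_hits`` (flank id -> hit) bypasses the built-in aligner, for
    externally computed BLAST-style tables.
    """
    out = []
    for flank in flanks:
        if flank is None:
            out.append(None)
        elif external_hits is not None:
            out.append(external_hits.get(flank.id))
        else:
            out.append(_align.best_local_hit(flank, counterpart, index=index, min_query_cov=0.5))
    return tuple(out)


def classify_zcr(zcr: ZcrRecord, left_hit, right_hit, params: ZcrParams | None = None,
                 flanks_clipped=(False, False)) -> SvCall:
    """PAV / HDR / unresolved classification from flank anchors.

    PAV requires both anchors on one subject sequence, same strand, in the
    order the flanks have on the target under that strand, with the signed
    inner-end distance within the length-dependent tolerance.  ZCRs at
    sequence edges or with clipped/absent flanks are unresolved.
    """
    params = params or ZcrParams()
    if zcr.length < params.report_min_len:
        raise ValueError("classification is defined for ZCRs >= report_min_len")
    if zcr.at_sequence_edge or left_hit is None or right_hit is None or any(flanks_clipped):
        return SvCall(zcr, "unresolved", (left_hit, right_hit))
    inner = None
    if left_hit.subject_id == right_hit.subject_id and left_hit.strand == right_hit.strand:
        if left_hit.strand == "+":
            inner = right_hit.subject_start - left_hit.subject_end
        else:
            inner = left_hit.subject_start - right_hit.subject_end
    if (
        inner is not None
        and abs(inner) <= params.adjacency_tolerance(zcr.length)
        and zcr.length >= params.pav_min_len
    ):
        return SvCall(zcr, "pav", (left_hit, right_hit), inner)
    return SvCall(zcr, "hdr", (left_hit, right_hit), inner)


def validate_by_pair_distance(call: SvCall, placements, global_stats,
                              params: ZcrParams | None = None) -> SvCall:
    """Check a call against the spanning-mate-pair distance signal.

    Spanning pairs have one mate entirely left of the ZCR and the other
    entirely right of it, on the ZCR's sequence.  Supported means the mean
    spanning inner distance deviates from the library mean by more than the
    cutoff (two-sided); fewer than min_spanning_pairs leaves the call
    indeterminate.
    """
    params = params or ZcrParams()
    mean_g, _sd_g, _n = global_stats
    s, e = call.zcr.interval.start, call.zcr.interval.end
    sid = call.zcr.interval.seq_id
    pairs: dict[str, list] = {}
    for p in placements:
        if p.mate_inner_distance is None or p.interval.seq_id != sid:
            continue
        base, _ = _pair_key(p.read_id)
        pairs.setdefault(base, []).append(p)
    spans = []
    for mates in pairs.values():
        if len(mates) != 2:
            continue
        left, right = sorted(mates, key=lambda p: p.interval.start)
        if left.interval.end <= s and right.interval.start >= e:
            spans.append(left.mate_inner_distance)
    if len(spans) < params.min_spanning_pairs:
        return replace(call, pair_distance_supported="indeterminate")
    dev = abs(float(np.mean(spans)) - mean_g)
    status = "supported" if dev > params.pair_dev_cutoff else "unsupported"
    return replace(call, pair_distance_supported=status)


# ---------------------------------------------------------------------------

@dataclass
class DirectionResult:
    """One mapping direction: reads of ``read_source`` on ``target``."""

    read_source: str
    target: str
    placements: list
    tracks: dict[str, CoverageTrack]
    zcrs: list[ZcrRecord]
    calls: list[SvCall]
    pair_stats: tuple[float, float, int] | None

    @property
    def pav_calls(self):
        return [c for c in self.calls if c.classification == "pav"]

    @property
    def hdr_calls(self):
        return [c for c in self.calls if c.classification == "hdr"]

    def calls_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            iv = c.zcr.interval
            rows.append(
                {
                    "target_seq": iv.seq_id,
                    "start": iv.start + 1,  # 1-based for reporting
                    "end": iv.end,
                    "length": c.zcr.length,
                    "classification": c.classification,
                    "inner_end_distance": c.inner_end_distance,
                    "pair_distance_supported": c.pair_distance_supported,
                    "read_source": self.read_source,
                    "target": self.target,
                }
            )
        return pd.DataFrame(rows)


def run_direction(reads_of_source, target_assembly, source_assembly,
                  mapping_params: MappingParams | None = None,
                  zcr_params: ZcrParams | None = None,
                  read_source: str = "A", target: str = "B") -> DirectionResult:
    """map -> coverage -> ZCRs -> flank anchoring -> classify -> validate."""
    mapping_params = mapping_params or MappingParams()
    zcr_params = zcr_params or ZcrParams()
    if isinstance(target_assembly, SeqRecord):
        target_assembly = [target_assembly]
    if isinstance(source_assembly, SeqRecord):
        source_assembly = [source_assembly]

    index = GenomeIndex(target_assembly, k=mapping_params.seed_k)
    placements = map_reads(reads_of_source, index, mapping_params)
    tracks = compute_coverage(placements, target_assembly)
    try:
        stats = pair_distance_stats(placements)
    except ValueError:
        stats = None

    src_index = GenomeIndex(source_assembly, k=15)
    zcrs: list[ZcrRecord] = []
    calls: list[SvCall] = []
    for rec in target_assembly:
        seq_zcrs = detect_zcrs(tracks[rec.id], rec, zcr_params)
        zcrs.extend(seq_zcrs)
        for zcr in seq_zcrs:
            if zcr.length < zcr_params.report_min_len:
                continue
            left, right, clipped = extract_flanks(zcr, rec, zcr_params)
            lh, rh = anchor_flanks((left, right), source_assembly, index=src_index)
            call = classify_zcr(zcr, lh, rh, zcr_params, flanks_clipped=clipped)
            call.read_source, call.target = read_source, target
            if call.classification == "pav" and stats is not None:
                call = validate_by_pair_distance(call, placements, stats, zcr_params)
            calls.append(call)
    return DirectionResult(read_source, target, placements, tracks, zcrs, calls, stats)


@dataclass
class ReciprocalResult:
    """Both mapping directions of one accession pair.

    A PAV found with A reads on the B assembly is a deletion in A and an
    insertion in B; the reciprocal direction labels the mirror events.
    """

    a_reads_on_b: DirectionResult
    b_reads_on_a: DirectionResult

    def deletions_in(self, accession: str):
        for d in (self.a_reads_on_b, self.b_reads_on_a):
            if d.read_source == accession:
                return d.pav_calls
        raise KeyError(accession)

    def insertions_in(self, accession: str):
        for d in (self.a_reads_on_b, self.b_reads_on_a):
            if d.target == accession:
                return d.pav_calls
        raise KeyError(accession)


def run_reciprocal(reads_a, reads_b, assembly_a, assembly_b,
                   mapping_params: MappingParams | None = None,
                   zcr_params: ZcrParams | None = None,
                   name_a: str = "A", name_b: str = "B") -> ReciprocalResult:
    ab = run_direction(reads_a, assembly_b, assembly_a, mapping_params, zcr_params,
                       read_source=name_a, target=name_b)
    ba = run_direction(reads_b, assembly_a, assembly_b, mapping_params, zcr_params,
                       read_source=name_b, target=name_a)
    return ReciprocalResult(ab, ba)


def coverage_titration(reads, target_assembly, source_assembly, fractions,
                       seed: int = 0,
                       mapping_params: MappingParams | None = None,
                       zcr_params: ZcrParams | None = None) -> pd.DataFrame:
    """Variant yield as a function of read coverage.

    Reads are subsampled per pair with nested seeded draws (every smaller
    fraction is a subset of every larger one) and the direction pipeline is
    re-run per fraction.  Per-read placements do not depend on the rest of
    the read set, so the full mapping is computed once and filtered.
    """
    fractions = sorted(fractions)
    if not fractions or fractions[0] <= 0 or fractions[-1] > 1:
        raise ValueError("fractions must lie in (0, 1]")
    mapping_params = mapping_params or MappingParams()
    zcr_params = zcr_params or ZcrParams()
    if isinstance(target_assembly, SeqRecord):
        target_assembly = [target_assembly]
    if isinstance(source_assembly, SeqRecord):
        source_assembly = [source_assembly]

    rng = np.random.default_rng(seed)
    bases = sorted({_pair_key(r.id)[0] or r.id for r in reads})
    draw = {b: rng.random() for b in bases}

    index = GenomeIndex(target_assembly, k=mapping_params.seed_k)
    all_placements = map_reads(reads, index, mapping_params)
    src_index = GenomeIndex(source_assembly, k=15)

    rows = []
    for frac in fractions:
        keep = {b for b, u in draw.items() if u < frac}
        placements = [
            p for p in all_placements if (_pair_key(p.read_id)[0] or p.read_id) in keep
        ]
        tracks = compute_coverage(placements, target_assembly)
        try:
            stats = pair_distance_stats(placements)
        except ValueError:
            stats = None
        n_zcr = zcr_bp = n_pav = pav_bp = n_hdr = hdr_bp = 0
        for rec in target_assembly:
            for zcr in detect_zcrs(tracks[rec.id], rec, zcr_params):
                if zcr.length < zcr_params.report_min_len:
                    continue
                n_zcr += 1
                zcr_bp += zcr.length
                left, right, clipped = extract_flanks(zcr, rec, zcr_params)
                lh, rh = anchor_flanks((left, right), source_assembly, index=src_index)
                call = classify_zcr(zcr, lh, rh, zcr_params, flanks_clipped=clipped)
                if call.classification == "pav":
                    n_pav += 1
                    pav_bp += zcr.length
                elif call.classification == "hdr":
                    n_hdr += 1
                    hdr_bp += zcr.length
        rows.append(
            {
                "fraction": frac,
                "n_pairs": len(keep),
                "n_zcr": n_zcr,
                "zcr_bp": zcr_bp,
                "n_pav": n_pav,
                "pav_bp": pav_bp,
                "n_hdr": n_hdr,
                "hdr_bp": hdr_bp,
            }
        )
    return pd.DataFrame(rows)
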