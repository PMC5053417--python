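"""Desk-scale seed-and-extend read mapper.

The mapping acceptance contract has two normative knobs: a placement is
emitted only if it aligns at least ``length_fraction`` of the read at an
identity of at least ``similarity_fraction`` (defaults 0.9 / 0.95).  Reads
matching equally well at several loci are either placed uniformly at random
(``random`` policy, used to keep duplicated regions covered so that only
true absence produces zero coverage) or discarded (``unique`` policy).

Seeding uses exact 15-mers at a few fixed read offsets against a sorted
k-mer index of the target; extension aligns the read against the candidate
window with edlib (edit-distance, extended CIGAR) and then soft-clips
terminal junk by keeping the maximal-scoring contiguous run of CIGAR
columns.  Identity is matches over the kept aligned columns and
aligned_fraction is the kept read fraction, so a read hanging a few bases
over a variant breakpoint is clipped at the junction (and still subject to
the length-fraction floor) instead of smearing mismatches across it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .core_io import CoverageTrack, Interval, SeqRecord, reverse_complement

__all__ = [
    "MappingParams",
    "ReadPlacement",
    "GenomeIndex",
    "CoverageTrack",
    "map_reads",
    "compute_coverage",
    "pair_distance_stats",
    "InsufficientPairsError",
]

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENC[_c] = _i


class InsufficientPairsError(ValueError):
    """Fewer proper pairs than the statistic requires."""


@dataclass
class MappingParams:
    length_fraction: float = 0.9
    similarity_fraction: float = 0.95
    multi_mapper_policy: str = "random"  # or "unique"
    seed: int = 0
    seed_k: int = 15
    max_candidates: int = 8

    def __post_init__(self):
        for f in (self.length_fraction, self.similarity_fraction):
            if not 0.0 < f <= 1.0:
                raise ValueError("fractions must be in (0,1]")
        if self.multi_mapper_policy not in ("random", "unique"):
            raise ValueError(f"unknown policy {self.multi_mapper_policy!r}")


@dataclass
class ReadPlacement:
    read_id: str
    interval: Interval
    identity: float
    aligned_fraction: float
    is_unique: bool
    mate_inner_distance: int | None = None


class GenomeIndex:
    """Sorted exact k-mer index over one or more target sequences."""

    def __init__(self, sequences, k: int = 15):
        if isinstance(sequences, SeqRecord):
            sequences = [sequences]
        self.k = k
        self.sequences = {rec.id: rec for rec in sequences}
        self._encoded = {}
        self._sorted_codes = {}
        self._sorted_pos = {}
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        for rec in sequences:
            enc = _ENC[np.frombuffer(rec.sequence.encode(), dtype=np.uint8)]
            self._encoded[rec.id] = enc
            if rec.length < k:
                self._sorted_codes[rec.id] = np.empty(0, dtype=np.int64)
                self._sorted_pos[rec.id] = np.empty(0, dtype=np.int64)
                continue
            win = np.lib.stride_tricks.sliding_window_view(enc, k)
            codes = win.astype(np.int64) @ powers
            valid = win.max(axis=1) < 4
            codes = np.where(valid, codes, -1)
            order = np.argsort(codes, kind="stable")
            self._sorted_codes[rec.id] = codes[order]
            self._sorted_pos[rec.id] = order.astype(np.int64)

    def lookup(self, seq_id: str, code: int) -> np.ndarray:
        codes = self._sorted_codes[seq_id]
        lo = np.searchsorted(codes, code, side="left")
        hi = np.searchsorted(codes, code, side="right")
        return self._sorted_pos[seq_id][lo:hi]


def _encode_read(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _seed_codes(enc: np.ndarray, k: int, powers: np.ndarray):
    L = enc.size
    offsets = sorted({0, (L - k) // 3, 2 * (L - k) // 3, L - k})
    out = []
    for off in offsets:
        win = enc[off:off + k]
        if win.max() < 4:
            out.append((off, int(win.astype(np.int64) @ powers)))
    return out


def _cigar_columns(cigar: str):
    """Per-column operations ('=', 'X', 'I', 'D') from an extended CIGAR."""
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.extend(ch * int(num))
            num = ""
    return ops


def _trim_alignment(cigar: str):
    """Soft-clip terminal junk: keep the maximal-scoring contiguous segment.

    Columns score +1 for a match and -2 for mismatch/indel; the best-sum
    segment (Kadane) is the placement, so a read hanging a few bases over a
    breakpoint is clipped at the junction instead of smearing mismatched
    bases across it.  Returns (matches, columns, query_consumed,
    target_offset, target_consumed) of the kept segment.
    """
    ops = _cigar_columns(cigar)
    best_sum = cur_sum = 0.0
    best_lo = best_hi = cur_lo = 0
    for i, op in enumerate(ops):
        s = 1.0 if op == "=" else -2.0
        if cur_sum <= 0:
            cur_sum, cur_lo = s, i
        else:
            cur_sum += s
        if cur_sum > best_sum:
            best_sum, best_lo, best_hi = cur_sum, cur_lo, i + 1
    kept = ops[best_lo:best_hi]
    matches = sum(1 for op in kept if op == "=")
    q_cons = sum(1 for op in kept if op in "=XI")
    t_off = sum(1 for op in ops[:best_lo] if op in "=XD")
    t_cons = sum(1 for op in kept if op in "=XD")
    return matches, len(kept), q_cons, t_off, t_cons


def map_reads(reads, genome, params: MappingParams | None = None, index: GenomeIndex | None = None):
    """Map reads to a genome; returns accepted ReadPlacements.

    ``genome`` may be a SeqRecord, a list of SeqRecords, or a prebuilt
    GenomeIndex.  Reads shorter than the seed length are counted as
    unmapped, not errors.  Mate inner distances are attached afterwards for
    proper pairs (ids differing only in a ``/1``/``/2`` suffix, mapped to
    the same sequence on opposite strands).
    """
    params = params or MappingParams()
    if isinstance(genome, GenomeIndex):
        index = genome
    elif index is None:
        index = GenomeIndex(genome, k=params.seed_k)
    k = index.k
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    rng = np.random.default_rng(params.seed)
    placements: list[ReadPlacement] = []

    seq_cache = {sid: rec.sequence for sid, rec in index.sequences.items()}

    for read in reads:
        rseq = read.sequence
        L = len(rseq)
        if L < k:
            continue
        # gather candidate (seq_id, start, strand)
        cand: dict[tuple[str, int, str], int] = {}
        oriented = {"+": rseq, "-": reverse_complement(rseq)}
        enc_by_strand = {s: _encode_read(q) for s, q in oriented.items()}
        for strand, enc in enc_by_strand.items():
            for off, code in _seed_codes(enc, k, powers):
                for sid in index.sequences:
                    for pos in index.lookup(sid, code):
                        start = int(pos) - off
                        key = (sid, start, strand)
                        cand[key] = cand.get(key, 0) + 1
        if not cand:
            continue

        # exact-match fast path over every candidate
        perfect = []
        for (sid, start, strand) in cand:
            if start < 0:
                continue
            if seq_cache[sid][start:start + L] == oriented[strand]:
                perfect.append((sid, start, start + L, strand, 1.0, 1.0))
        if perfect:
            ties = perfect
        else:
            ranked = sorted(cand.items(), key=lambda kv: -kv[1])[: params.max_candidates]
            pad = int(0.15 * L) + 16
            scored = []
            for (sid, start, strand), _votes in ranked:
                seq = seq_cache[sid]
                ws = max(0, start - pad)
                we = min(len(seq), start + L + pad)
                res = edlib.align(oriented[strand], seq[ws:we], mode="HW", task="path")
                if res["editDistance"] < 0:
                    continue
                loc = res["locations"][0]
                matches, columns, q_cons, t_off, t_cons = _trim_alignment(res["cigar"])
                if columns == 0:
                    continue
                seg_score = matches - 2 * (columns - matches)
                s0 = ws + loc[0] + t_off
                scored.append(
                    (seg_score, sid, s0, s0 + t_cons, strand, matches / columns, q_cons / L)
                )
            if not scored:
                continue
            scored.sort(key=lambda t: -t[0])
            ties = [
                (sid, s, e, st, ident, af)
                for sc, sid, s, e, st, ident, af in scored
                if sc == scored[0][0]
            ]
            # same locus may be reached via several candidate starts
            ties = list({t[:4]: t for t in ties}.values())

        if params.multi_mapper_policy == "unique" and len(ties) > 1:
            continue
        sid, s, e, strand, ident, aligned_fraction = (
            ties[int(rng.integers(len(ties)))] if len(ties) > 1 else ties[0]
        )
        if ident < params.similarity_fraction:
            continue
        if aligned_fraction < params.length_fraction:
            continue
        placements.append(
            ReadPlacement(
                read_id=read.id,
                interval=Interval(sid, s, e, strand),
                identity=ident,
                aligned_fraction=aligned_fraction,
                is_unique=len(ties) == 1,
            )
        )

    _attach_mate_distances(placements)
    return placements


def _pair_key(read_id: str):
    if read_id.endswith(("/1", "/2")):
        return read_id[:-2], read_id[-1]
    return None, None


def _attach_mate_distances(placements):
    by_pair: dict[str, dict[str, ReadPlacement]] = {}
    for p in placements:
        base, mate = _pair_key(p.read_id)
        if base is not None:
            by_pair.setdefault(base, {})[mate] = p
    for mates in by_pair.values():
        if len(mates) != 2:
            continue
        p1, p2 = mates["1"], mates["2"]
        if p1.interval.seq_id != p2.interval.seq_id:
            continue
        if p1.interval.strand == p2.interval.strand:
            continue
        left, right = sorted((p1, p2), key=lambda p: p.interval.start)
        inner = right.interval.start - left.interval.end
        p1.mate_inner_distance = inner
        p2.mate_inner_distance = inner


def compute_coverage(placements, genome) -> dict[str, CoverageTrack]:
    """Per-base depth: depth[i] = number of placements covering i."""
    if isinstance(genome, SeqRecord):
        genome = [genome]
    if isinstance(genome, GenomeIndex):
        genome = list(genome.sequences.values())
    diffs = {rec.id: np.zeros(rec.length + 1, dtype=np.int64) for rec in genome}
    for p in placements:
        d = diffs.get(p.interval.seq_id)
        if d is None:
            raise ValueError(f"placement on unknown sequence {p.interval.seq_id!r}")
        if p.interval.end > d.size - 1:
            raise ValueError("placement outside sequence bounds")
        d[p.interval.start] += 1
        d[p.interval.end] -= 1
    return {sid: CoverageTrack(sid, np.cumsum(d[:-1])) for sid, d in diffs.items()}


def pair_distance_stats(placements):
    """(mean, sample sd, n) of mate inner distances over proper pairs."""
    seen = set()
    dists = []
    for p in placements:
        base, _ = _pair_key(p.read_id)
        if p.mate_inner_distance is None or base in seen:
            continue
        seen.add(base)
        dists.append(p.mate_inner_distance)
    if len(dists) < 2:
        raise InsufficientPairsError(
            f"need >= 2 proper pairs for distance statistics, got {len(dists)}"
        )
    arr = np.asarray(dists, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)
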