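"""Synthetic accession pairs with a known divergence ledger.

The generator emulates the comparison of two inbred accessions of one
species: an ancestor sequence is mutated into a derived accession by SNPs,
small InDels, large (>= 100 bp) insertions and deletions, locally
hyper-diverged blocks (HDRs, modelled as an elevated SNP/InDel density
rather than unalignable sequence), tandem repeat arrays and an optional
collapsed-duplicate (CNV) locus.  Every change is recorded in a
TruthRegistry whose replay onto the ancestor reproduces the derived genome
exactly; downstream recovery tests use the registry as their oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core_io import Interval, SeqRecord, reverse_complement

__all__ = [
    "Ancestor",
    "DivergenceConfig",
    "TruthVariant",
    "TruthRegistry",
    "ReadSimConfig",
    "SimulatedReads",
    "generate_ancestor",
    "derive_accession",
    "simulate_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Margins used when placing large events: keeps 1 kbp flanks of any event
# clear of every other event and of the sequence ends.
EVENT_SEPARATION = 2000
END_MARGIN = 3000


@dataclass(frozen=True)
class Ancestor:
    """Ancestor sequence plus the recorded tandem-repeat array positions."""

    record: SeqRecord
    repeat_arrays: tuple[Interval, ...] = ()


@dataclass
class DivergenceConfig:
    """Divergence between the two accessions of a synthetic pair.

    Defaults mirror the genome-wide rates measured between two natural
    accessions of a selfing plant: one SNP per 292 bp and roughly one small
    InDel (1-20 bp) per 1,500 bp.  Large events default to a log-uniform
    length distribution over 100 bp - 25.6 kbp so that every doubling
    reporting bin is exercised.
    """

    snp_rate: float = 1.0 / 292.0
    small_indel_rate: float = 1.0 / 1500.0
    small_indel_max_len: int = 20
    n_insertions: int = 0
    n_deletions: int = 0
    large_event_len_range: tuple[int, int] = (100, 25600)
    n_hdr_blocks: int = 0
    hdr_len_range: tuple[int, int] = (100, 10000)
    hdr_multiplier: float = 10.0
    collapsed_duplicate: tuple[int, int] | None = None  # (gene length, copies)
    seed: int = 0

    def __post_init__(self):
        for r in (self.snp_rate, self.small_indel_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must be in [0,1)")
        if min(self.n_insertions, self.n_deletions, self.n_hdr_blocks) < 0:
            raise ValueError("event counts must be >= 0")


@dataclass(frozen=True)
class TruthVariant:
    """One recorded difference; a/b coordinates are 0-based half-open.

    Zero-length sides (insertion point on A, deletion point on B) have
    start == end.  ``detail`` carries the replacement sequence for types
    that edit the genome; ``hdr`` entries are annotations only (their
    sequence changes are recorded as individual snp/small_indel entries).
    """

    type: str  # snp | small_indel | insertion | deletion | hdr | cnv_collapse
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    detail: str = ""

    @property
    def length(self) -> int:
        return max(self.a_end - self.a_start, self.b_end - self.b_start)


@dataclass
class TruthRegistry:
    """Ground-truth variant ledger for one synthetic accession pair."""

    variants: list[TruthVariant] = field(default_factory=list)

    def by_type(self, *types: str) -> list[TruthVariant]:
        return [v for v in self.variants if v.type in types]

    def apply(self, ancestor_sequence: str) -> str:
        """Replay every sequence-editing variant onto the ancestor."""
        edits = sorted(
            (v for v in self.variants if v.type != "hdr"),
            key=lambda v: (v.a_start, v.a_end),
        )
        out = []
        cursor = 0
        for v in edits:
            if v.a_start < cursor:
                raise ValueError("overlapping edit variants in registry")
            out.append(ancestor_sequence[cursor:v.a_start])
            out.append(v.detail)
            cursor = v.a_end
        out.append(ancestor_sequence[cursor:])
        return "".join(out)

    def write_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("type\ta_start\ta_end\tb_start\tb_end\tdetail\n")
            for v in self.variants:
                fh.write(
                    f"{v.type}\t{v.a_start}\t{v.a_end}\t{v.b_start}\t{v.b_end}\t{v.detail}\n"
                )

    @classmethod
    def read_tsv(cls, path) -> "TruthRegistry":
        variants = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                t, a0, a1, b0, b1, *rest = line.rstrip("\n").split("\t")
                detail = rest[0] if rest else ""
                variants.append(TruthVariant(t, int(a0), int(a1), int(b0), int(b1), detail))
        return cls(variants)


@dataclass
class ReadSimConfig:
    """Paired-read simulation.

    ``insert_mean``/``insert_sd`` parametrize the inner (between-mate)
    distance; the sequenced fragment is inner + 2 x read_length.  Defaults
    follow a 2 x 250 nt paired-end library with ~700 bp fragments.
    """

    read_length: int = 250
    coverage: float = 30.0
    layout: str = "paired_end"  # or "mate_pair"
    insert_mean: float = 200.0
    insert_sd: float = 40.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.layout not in ("paired_end", "mate_pair"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.insert_mean < 0:
            raise ValueError("insert_mean must be >= 0")


@dataclass
class SimulatedReads:
    """Reads plus their true placements (read id -> (start, end, strand))."""

    records: list[SeqRecord]
    truth: dict[str, tuple[int, int, str]]
    config: ReadSimConfig

    @property
    def n_pairs(self) -> int:
        return len(self.records) // 2


# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    idx = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return _BASES[idx].tobytes().decode()


def generate_ancestor(length, gc=0.36, repeat_specs=(), seed=0) -> Ancestor:
    """Random ancestor with target GC and embedded exact tandem arrays.

    ``repeat_specs`` is a list of (unit length bp, copy number); each array
    is written over the background at a recorded, well-separated position.
    The default GC of 0.36 matches a typical small plant genome.
    """
    if length < 10_000:
        raise ValueError("ancestor length must be >= 10 kbp")
    rng = np.random.default_rng(seed)
    seq = np.frombuffer(_random_seq(rng, length, gc).encode(), dtype=np.uint8).copy()
    arrays: list[Interval] = []
    total_repeat = sum(u * c for u, c in repeat_specs)
    if total_repeat > length // 2:
        raise ValueError("repeat arrays exceed half the genome length")
    cursor = END_MARGIN
    for unit_len, copies in repeat_specs:
        arr_len = unit_len * copies
        lo = cursor
        hi = length - END_MARGIN - arr_len
        if hi < lo:
            raise ValueError("repeat arrays do not fit in genome length")
        start = int(rng.integers(lo, min(hi, lo + max(1, (hi - lo) // max(1, len(repeat_specs))))))
        unit = np.frombuffer(_random_seq(rng, unit_len, gc).encode(), dtype=np.uint8)
        tiled = np.tile(unit, copies)
        seq[start:start + arr_len] = tiled
        arrays.append(Interval("ancestor", start, start + arr_len))
        cursor = start + arr_len + EVENT_SEPARATION
    return Ancestor(SeqRecord("ancestor", seq.tobytes().decode()), tuple(arrays))


def _log_uniform(rng, lo, hi, n):
    return np.rint(np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))).astype(int)


def _place_events(rng, length, span_lengths, occupied):
    """Choose non-overlapping start positions with EVENT_SEPARATION margins.

    ``occupied`` is a list of (start, end) intervals already taken (repeat
    arrays and previously placed events).  Raises if an event cannot be
    placed after bounded retries.
    """
    placed = []
    taken = sorted(occupied)
    for span in span_lengths:
        ok = False
        for _ in range(2000):
            start = int(rng.integers(END_MARGIN, length - END_MARGIN - span))
            lo, hi = start - EVENT_SEPARATION, start + span + EVENT_SEPARATION
            if all(e <= lo or s >= hi for s, e in taken):
                taken.append((start, start + span))
                taken.sort()
                placed.append(start)
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place a {span} bp event after bounded retries; "
                "reduce event load or enlarge the genome"
            )
    return placed, taken


def derive_accession(ancestor, config: DivergenceConfig):
    """Mutate the ancestor into a derived accession; return it + the ledger.

    Accepts an Ancestor (repeat arrays are then excluded from large-event
    placement) or a bare SeqRecord.
    """
    if isinstance(ancestor, Ancestor):
        record, repeat_arrays = ancestor.record, ancestor.repeat_arrays
    else:
        record, repeat_arrays = ancestor, ()
    seq = record.sequence
    length = len(seq)
    rng = np.random.default_rng(config.seed)

    # -- large events -------------------------------------------------------
    lo, hi = config.large_event_len_range
    del_lens = _log_uniform(rng, lo, hi, config.n_deletions)
    ins_lens = _log_uniform(rng, lo, hi, config.n_insertions)
    hdr_lens = _log_uniform(rng, *config.hdr_len_range, config.n_hdr_blocks)
    cnv_len = config.collapsed_duplicate[0] if config.collapsed_duplicate else 0

    mean_len = float(np.mean(np.concatenate([del_lens, ins_lens, hdr_lens, [cnv_len]])))
    n_events = config.n_deletions + config.n_insertions + config.n_hdr_blocks
    if n_events and n_events * mean_len >= 0.2 * length:
        raise ValueError("large-event load exceeds 20% of the ancestor length")

    occupied = [(iv.start - 1000, iv.end + 1000) for iv in repeat_arrays]
    spans = (
        [int(x) for x in del_lens]
        + [1] * config.n_insertions
        + [int(x) for x in hdr_lens]
        + ([cnv_len] if cnv_len else [])
    )
    starts, _ = _place_events(rng, length, spans, occupied)
    i = 0
    del_iv = [(starts[i + j], starts[i + j] + int(del_lens[j])) for j in range(config.n_deletions)]
    i += config.n_deletions
    ins_pos = [starts[i + j] for j in range(config.n_insertions)]
    i += config.n_insertions
    hdr_iv = [(starts[i + j], starts[i + j] + int(hdr_lens[j])) for j in range(config.n_hdr_blocks)]
    i += config.n_hdr_blocks
    cnv_iv = (starts[i], starts[i] + cnv_len) if cnv_len else None

    # -- point-event rate fields -------------------------------------------
    snp_rate = np.full(length, config.snp_rate)
    indel_rate = np.full(length, config.small_indel_rate)
    for s, e in hdr_iv:
        snp_rate[s:e] *= config.hdr_multiplier
        indel_rate[s:e] *= config.hdr_multiplier
    blocked = np.zeros(length, dtype=bool)
    for s, e in del_iv:
        blocked[s:e] = True
    if cnv_iv:
        blocked[cnv_iv[0]:cnv_iv[1]] = True  # keep duplicate copies identical
    snp_rate[blocked] = 0.0
    indel_rate[blocked] = 0.0

    u = rng.random(length)
    snp_pos = np.flatnonzero(u < snp_rate)
    u2 = rng.random(length)
    indel_pos = np.flatnonzero(u2 < indel_rate)

    # -- assemble the edit list --------------------------------------------
    # Each edit: (a_start, a_end, b_replacement, type)
    edits: list[tuple[int, int, str, str]] = []
    for s, e in del_iv:
        edits.append((s, e, "", "deletion"))
    for p, ln in zip(ins_pos, ins_lens):
        edits.append((p, p, _random_seq(rng, int(ln)), "insertion"))
    if cnv_iv:
        s, e = cnv_iv
        edits.append((e, e, seq[s:e], "cnv_collapse"))

    claimed = sorted((s, e) for s, e, _, _ in edits)

    def free(s, e):
        return all(ce <= s or cs >= e for cs, ce in claimed)

    geo_p = 0.4
    for p in indel_pos:
        ln = min(int(rng.geometric(geo_p)), config.small_indel_max_len)
        if rng.random() < 0.5:
            s, e, repl = p, p + ln, ""  # small deletion
        else:
            s, e, repl = p, p, _random_seq(rng, ln)  # small insertion
        if e <= length and free(max(0, s - 2), e + 2):
            edits.append((s, e, repl, "small_indel"))
            claimed.append((s, max(e, s + 1)))
            claimed.sort()
    for p in snp_pos:
        ref = seq[p]
        if ref not in "ACGT" or not free(p, p + 1):
            continue
        alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
        edits.append((p, p + 1, alt, "snp"))
        claimed.append((p, p + 1))
        claimed.sort()

    edits.sort(key=lambda t: (t[0], t[1]))

    # -- walk A -> B, recording b coordinates -------------------------------
    out = []
    variants: list[TruthVariant] = []
    cursor = 0
    out_len = 0
    offsets: list[tuple[int, int]] = [(0, 0)]  # (a position, cumulative b-a offset)
    for a_start, a_end, repl, vtype in edits:
        out.append(seq[cursor:a_start])
        out_len += a_start - cursor
        b_start = out_len
        out.append(repl)
        out_len += len(repl)
        variants.append(TruthVariant(vtype, a_start, a_end, b_start, out_len, repl))
        cursor = a_end
        offsets.append((a_end, out_len - a_end))
    out.append(seq[cursor:])

    # HDR annotation entries (no edit of their own).
    off_pos = np.array([p for p, _ in offsets])
    off_val = np.array([o for _, o in offsets])

    def b_of(a):
        i = np.searchsorted(off_pos, a, side="right") - 1
        return int(a + off_val[i])

    for s, e in hdr_iv:
        variants.append(TruthVariant("hdr", s, e, b_of(s), b_of(e), ""))

    variants.sort(key=lambda v: (v.a_start, v.a_end))
    derived = SeqRecord(record.id + "_derived", "".join(out))
    return derived, TruthRegistry(variants)


# ---------------------------------------------------------------------------

def simulate_reads(genome: SeqRecord, config: ReadSimConfig) -> SimulatedReads:
    """Simulate paired reads with recorded true placements.

    Fragment starts are uniform over the genome; the inner distance is
    Normal(insert_mean, insert_sd) truncated at >= 0.  paired_end reads face
    inward (FR), mate_pair reads outward (RF).  Substitution errors are
    i.i.d. at ``error_rate``.
    """
    rng = np.random.default_rng(config.seed)
    L = genome.length
    rl = config.read_length
    n_pairs = int(round(config.coverage * L / (2 * rl)))
    inner = rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)
    inner = np.clip(np.rint(inner), 0, None).astype(int)
    frag = inner + 2 * rl
    max_frag = int(frag.max()) if n_pairs else 0
    if L <= max_frag:
        raise ValueError("genome shorter than the largest simulated fragment")
    starts = np.floor(rng.random(n_pairs) * (L - frag)).astype(int)

    gbytes = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    records: list[SeqRecord] = []
    truth: dict[str, tuple[int, int, str]] = {}
    err = config.error_rate

    def finish(arr, n_err_positions):
        if err > 0 and n_err_positions.size:
            arr = arr.copy()
            cur = arr[n_err_positions]
            shift = rng.integers(1, 4, size=n_err_positions.size)
            lut = {65: 0, 67: 1, 71: 2, 84: 3}
            idx = np.array([lut.get(c, 0) for c in cur])
            arr[n_err_positions] = _BASES[(idx + shift) % 4]
        return arr.tobytes().decode()

    for i in range(n_pairs):
        s = int(starts[i])
        f = int(frag[i])
        r1 = gbytes[s:s + rl]
        r2 = gbytes[s + f - rl:s + f]
        if err > 0:
            e1 = np.flatnonzero(rng.random(rl) < err)
            e2 = np.flatnonzero(rng.random(rl) < err)
        else:
            e1 = e2 = np.empty(0, dtype=int)
        seq1 = finish(r1, e1)
        seq2 = finish(r2, e2)
        if config.layout == "paired_end":
            seq2 = reverse_complement(seq2)
            strands = ("+", "-")
        else:  # mate_pair: outward-facing
            seq1 = reverse_complement(seq1)
            strands = ("-", "+")
        rid = f"{genome.id}_p{i}"
        records.append(SeqRecord(rid + "/1", seq1))
        records.append(SeqRecord(rid + "/2", seq2))
        truth[rid + "/1"] = (s, s + rl, strands[0])
        truth[rid + "/2"] = (s + f - rl, s + f, strands[1])
    return SimulatedReads(records, truth, config)
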