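"""Assembly statistics, k-mer genome-size estimation and completeness filters.

Genome size is estimated from the k-mer multiplicity histogram of raw
reads (canonical k-mers, default k = 25): the error tail is cut at the
first local minimum, the coverage peak above that boundary is located, and
the total k-mer observations above the boundary are normalized by the peak
depth.  Coverage-based repeat copy number and the genome-composition
reconciliation (estimate = assembly + NOR + centromeres) follow the same
read-depth bookkeeping.  The exon and EST filters quantify assembly
completeness: an exon counts as present when its best hit in the assembly
reaches half of its self-score, one hit allowed per region; an EST counts
as mapped at >= 95% query coverage and >= 90% identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import _align
from .core_io import Feature, SeqRecord

__all__ = [
    "KmerHistogram",
    "AssemblyStats",
    "CompositionEstimate",
    "assembly_stats",
    "kmer_histogram",
    "estimate_genome_size",
    "repeat_copy_number",
    "composition_reconcile",
    "exon_presence",
    "est_mapping_filter",
    "scaffold_end_te_overlap",
]


@dataclass
class KmerHistogram:
    """Multiplicity -> number of distinct k-mers at that multiplicity."""

    k: int
    counts: dict[int, int]

    def __post_init__(self):
        if any(m < 1 for m in self.counts):
            raise ValueError("multiplicities must be >= 1")

    @property
    def total_observations(self) -> int:
        return sum(m * c for m, c in self.counts.items())

    def write_text(self, path):
        """Two-column text (multiplicity, count), ascending."""
        with open(path, "w") as fh:
            for m in sorted(self.counts):
                fh.write(f"{m} {self.counts[m]}\n")


@dataclass(frozen=True)
class AssemblyStats:
    n_sequences: int
    total_bp: int
    mean_length: float
    min_length: int
    max_length: int
    gc_fraction: float
    n25: int
    n50: int
    n75: int
    n90: int


@dataclass(frozen=True)
class CompositionEstimate:
    """Genome composition: estimate = assembly + NOR + centromeres."""

    genome_size_est: int
    assembly_len: int
    nor_size: int

    @property
    def unassembled(self) -> int:
        return self.genome_size_est - self.assembly_len

    @property
    def centromeric_total(self) -> int:
        return self.genome_size_est - (self.assembly_len + self.nor_size)

    @property
    def per_centromere(self) -> float:
        return self.centromeric_total / 5.0


# ---------------------------------------------------------------------------

def assembly_stats(sequences) -> AssemblyStats:
    """Length, GC and Nxx statistics of an assembly.

    Nxx is the length of the shortest sequence in the smallest set of
    longest sequences whose summed length reaches xx% of the total; the GC
    denominator excludes ambiguity characters.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("empty sequence set")
    lengths = np.sort(np.array([s.length for s in seqs]))[::-1]
    total = int(lengths.sum())
    cum = np.cumsum(lengths)

    def nxx(xx):
        return int(lengths[np.searchsorted(cum, xx / 100.0 * total)])

    gc = at = 0
    for s in seqs:
        gc += s.sequence.count("G") + s.sequence.count("C")
        at += s.sequence.count("A") + s.sequence.count("T")
    return AssemblyStats(
        n_sequences=len(seqs),
        total_bp=total,
        mean_length=total / len(seqs),
        min_length=int(lengths[-1]),
        max_length=int(lengths[0]),
        gc_fraction=gc / (gc + at) if gc + at else 0.0,
        n25=nxx(25),
        n50=nxx(50),
        n75=nxx(75),
        n90=nxx(90),
    )


_ENC = np.full(256, 4, dtype=np.int64)
for _i, _c in enumerate(b"ACGT"):
    _ENC[_c] = _i


def kmer_histogram(reads, k: int = 25) -> KmerHistogram:
    """Canonical k-mer multiplicity histogram over a read set.

    Canonical = lexicographic minimum of a k-mer and its reverse
    complement (in 2-bit encoding); k-mers containing ambiguity characters
    are skipped; reads shorter than k contribute nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("k > 31 exceeds the 2-bit code width")
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    rpowers = powers[::-1]
    chunks = []
    for read in reads:
        if read.length < k:
            continue
        enc = _ENC[np.frombuffer(read.sequence.encode(), dtype=np.uint8)]
        win = np.lib.stride_tricks.sliding_window_view(enc, k)
        valid = win.max(axis=1) < 4
        fwd = win @ powers
        rev = (3 - win) @ rpowers  # reverse complement code
        canon = np.minimum(fwd, rev)[valid]
        chunks.append(canon)
    if not chunks:
        return KmerHistogram(k, {})
    codes = np.concatenate(chunks)
    _, mult = np.unique(codes, return_counts=True)
    ms, cs = np.unique(mult, return_counts=True)
    return KmerHistogram(k, {int(m): int(c) for m, c in zip(ms, cs)})


def estimate_genome_size(hist: KmerHistogram) -> float:
    """Genome size from the k-mer histogram's coverage peak.

    The error-tail boundary is the first multiplicity after which the
    (3-bin-smoothed, edge-replicated) histogram rises again; the peak depth
    is the count-weighted centroid of the single-copy peak region, taken as
    multiplicities within [0.5x, 1.75x] of the modal bin above the boundary
    (wide enough to average out per-bin sampling noise, yet below the
    two-copy repeat peak at 2x); size = total observations above the
    boundary divided by the peak depth.  A histogram with no rise (only an
    error tail) is rejected.
    """
    if not hist.counts:
        raise ValueError("empty k-mer histogram")
    max_m = max(hist.counts)
    dense = np.zeros(max_m + 2, dtype=float)
    for m, c in hist.counts.items():
        dense[m] = c
    sm = dense.copy()
    if max_m >= 3:
        body = dense[1:max_m + 1]
        padded = np.concatenate(([body[0]], body, [body[-1]]))
        sm[1:max_m + 1] = np.convolve(padded, np.ones(3) / 3, mode="valid")
    boundary = None
    for m in range(1, max_m):
        if sm[m + 1] > sm[m]:
            boundary = m
            break
    if boundary is None:
        raise ValueError("no coverage peak separable from the error tail")
    peak_bin = boundary + int(np.argmax(dense[boundary:max_m + 1]))
    lo = max(boundary, int(np.ceil(0.5 * peak_bin)))
    hi = min(max_m, int(np.floor(1.75 * peak_bin)))
    window = np.arange(lo, hi + 1)
    wcounts = dense[lo:hi + 1]
    peak_depth = float((window * wcounts).sum() / wcounts.sum())
    total = sum(m * c for m, c in hist.counts.items() if m >= boundary)
    return total / peak_depth


def repeat_copy_number(repeat_mean_depth: float, single_copy_depth: float,
                       repeat_ref_len: int, unit_len: int):
    """Tandem-repeat copy number from relative read depth.

    Reads are mapped to a short reference of one or a few adjacent repeat
    units; copies = (mean depth x reference length / unit length) /
    single-copy depth.  Returns (copies, total bp = copies x unit length).
    """
    if single_copy_depth <= 0:
        raise ValueError("single-copy depth must be > 0")
    copies = (repeat_mean_depth * repeat_ref_len / unit_len) / single_copy_depth
    return copies, copies * unit_len


def composition_reconcile(genome_size_est: int, assembly_len: int,
                          nor_size: int) -> CompositionEstimate:
    """Split the unassembled genome fraction into NOR and centromeres."""
    if genome_size_est < assembly_len:
        raise ValueError(
            f"genome size estimate {genome_size_est} below assembly length {assembly_len}"
        )
    est = CompositionEstimate(genome_size_est, assembly_len, nor_size)
    if est.centromeric_total < 0:
        raise ValueError(
            "inconsistent inputs: assembly + NOR exceed the genome size estimate"
        )
    return est


# ---------------------------------------------------------------------------

def exon_presence(exons, assembly, self_hit_scores: dict[str, float],
                  min_exon_len: int = 50, score_ratio: float = 0.5):
    """Which exons of one accession are present in the other's assembly.

    An exon (> ``min_exon_len`` bp) is detected when its best assembly hit
    scores at least ``score_ratio`` of its self-score, under a greedy
    one-hit-per-region assignment (highest score first; a claimed region is
    closed to overlapping later hits).  Returns (per-exon DataFrame,
    detected fraction).
    """
    if isinstance(assembly, SeqRecord):
        assembly = [assembly]
    from .read_mapping import GenomeIndex

    index = GenomeIndex(list(assembly), k=15)
    candidates = []  # (score, exon_id, hit)
    considered = []
    for exon in exons:
        if exon.length <= min_exon_len:
            continue
        if exon.id not in self_hit_scores:
            warnings.warn(f"no self-score for exon {exon.id!r}; skipped")
            continue
        considered.append(exon.id)
        threshold = score_ratio * self_hit_scores[exon.id]
        for hit in _align.window_hits(exon, assembly, index=index)[:4]:
            if hit.score >= threshold:
                candidates.append((hit.score, exon.id, hit))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    claimed: dict[str, IntervalTree] = {}
    assigned: set[str] = set()
    for score, exon_id, hit in candidates:
        if exon_id in assigned:
            continue
        tree = claimed.setdefault(hit.subject_id, IntervalTree())
        if tree.overlaps(hit.subject_start, hit.subject_end):
            continue
        tree[hit.subject_start:hit.subject_end] = exon_id
        assigned.add(exon_id)
    df = pd.DataFrame(
        {"exon": considered, "detected": [e in assigned for e in considered]}
    )
    fraction = float(df["detected"].mean()) if len(df) else float("nan")
    return df, fraction


def est_mapping_filter(hits_by_query: dict, query_lengths: dict[str, int],
                       min_coverage: float = 0.95, min_identity: float = 0.90):
    """'Mapped' flag per EST: some hit covers >= 95% of the query at >= 90%
    identity.  ``hits_by_query``: query id -> list of AlignmentHits."""
    flags = {}
    for qid, qlen in query_lengths.items():
        mapped = False
        for h in hits_by_query.get(qid, []):
            cov = (h.query_end - h.query_start) / qlen
            if cov >= min_coverage and h.identity >= min_identity:
                mapped = True
                break
        flags[qid] = mapped
    return flags


def scaffold_end_te_overlap(scaffold_lengths: dict[str, int], end_anchor_hits: dict,
                            te_features, min_scaffold_len: int = 4000):
    """TE overlap of anchored terminal-2 kbp scaffold windows.

    Scaffolds of more than ``min_scaffold_len`` bp qualify;
    ``end_anchor_hits`` maps (scaffold, 'left'|'right') to the counterpart
    AlignmentHit of that terminal window (or None).  A flagged end's
    anchored interval intersects at least one transposable-element feature.
    Returns (per-end DataFrame, fraction of analyzed scaffolds with a
    flagged end).
    """
    trees: dict[str, IntervalTree] = {}
    for f in te_features:
        trees.setdefault(f.seq_id, IntervalTree())[f.interval.start:f.interval.end] = f.id
    rows = []
    for scaf, length in scaffold_lengths.items():
        if length <= min_scaffold_len:
            continue
        for end in ("left", "right"):
            hit = end_anchor_hits.get((scaf, end))
            flagged = False
            if hit is not None:
                tree = trees.get(hit.subject_id)
                flagged = bool(tree and tree.overlaps(hit.subject_start, hit.subject_end))
            rows.append({"scaffold": scaf, "end": end, "anchored": hit is not None,
                         "te_overlap": flagged})
    df = pd.DataFrame(rows)
    if df.empty:
        return df, float("nan")
    per_scaffold = df.groupby("scaffold")["te_overlap"].any()
    return df, float(per_scaffold.mean())
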