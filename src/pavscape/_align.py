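"""Local alignment helpers shared by flank anchoring, RBH scoring and the
completeness filters.

Nucleotide scoring is match +1 / mismatch -2 with affine gaps costing
5 + 2 per gap column; protein scoring is BLOSUM62 with gaps costing
11 + 1 per column.  The DP itself is Bio.Align.PairwiseAligner; this module
contributes the seed-and-extend window selection that makes aligning a
1 kbp query against a megabase-scale target practical, and the e-value
surrogate used for the protein-hit cutoff.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .core_io import AlignmentHit, SeqRecord, reverse_complement
from .read_mapping import GenomeIndex

__all__ = [
    "nucleotide_aligner",
    "protein_aligner",
    "best_local_hit",
    "window_hits",
    "protein_score",
    "protein_evalue",
]

# Karlin-Altschul parameters for the ungapped BLOSUM62 e-value surrogate.
_LAMBDA = 0.267
_K = 0.041

# Targets at or below this size are aligned whole, no seeding.
_DIRECT_ALIGN_MAX = 20_000


def nucleotide_aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -7   # first gap column: open 5 + extend 2
    al.extend_gap_score = -2
    return al


def protein_aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -12  # first gap column: open 11 + extend 1
    al.extend_gap_score = -1
    return al


def _alignment_stats(aln):
    c = aln.counts()
    columns = c.aligned + c.gaps
    identity = (c.identities / columns) if columns else 0.0
    t_blocks, q_blocks = aln.aligned
    t_start, t_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    return identity, columns, t_start, t_end, q_start, q_end


def _candidate_windows(query_enc, index: GenomeIndex, seq_id, qlen, stride, k, powers):
    """Diagonal-voted candidate window start positions on one target."""
    votes: dict[int, int] = {}
    bin_w = max(qlen // 2, 100)
    for off in range(0, query_enc.size - k + 1, stride):
        win = query_enc[off:off + k]
        if win.max() >= 4:
            continue
        code = int(win.astype(np.int64) @ powers)
        for pos in index.lookup(seq_id, code):
            diag = (int(pos) - off) // bin_w
            votes[diag] = votes.get(diag, 0) + 1
    ranked = sorted(votes.items(), key=lambda kv: -kv[1])
    return [d * bin_w for d, _ in ranked]


def window_hits(query: SeqRecord, targets, index: GenomeIndex | None = None,
                max_windows: int = 4, min_query_cov: float = 0.0,
                aligner: PairwiseAligner | None = None):
    """Best local hits of a nucleotide query against each candidate window.

    Returns AlignmentHits sorted by descending score (deterministic
    tie-break: subject id, then subject coordinate).  Windows come from
    exact-seed diagonal voting on both strands; small targets are aligned
    directly so the result equals exhaustive local alignment there.
    """
    from .read_mapping import _ENC  # byte->code table

    if isinstance(targets, SeqRecord):
        targets = [targets]
    if index is None:
        index = GenomeIndex(list(targets), k=15)
    al = aligner or nucleotide_aligner()
    k = index.k
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    qlen = query.length
    stride = max(1, min(qlen // 8, 50))
    hits = []
    for sid, rec in index.sequences.items():
        tlen = rec.length
        for strand, qseq in (("+", query.sequence), ("-", reverse_complement(query.sequence))):
            if tlen <= _DIRECT_ALIGN_MAX:
                window_starts = [0]
                wsize = tlen
            else:
                enc = _ENC[np.frombuffer(qseq.encode(), dtype=np.uint8)]
                window_starts = _candidate_windows(enc, index, sid, qlen, stride, k, powers)[:max_windows]
                wsize = 2 * qlen + 200
            for wstart in window_starts:
                ws = max(0, wstart - qlen // 2)
                we = min(tlen, ws + wsize + qlen)
                target = rec.sequence[ws:we]
                alns = al.align(target, qseq)
                if len(alns) == 0 or alns.score <= 0:
                    continue
                aln = alns[0]
                identity, columns, ts, te, qs, qe = _alignment_stats(aln)
                if (qe - qs) < min_query_cov * qlen:
                    continue
                if strand == "-":
                    qs, qe = qlen - qe, qlen - qs
                hits.append(
                    AlignmentHit(
                        query_id=query.id,
                        subject_id=sid,
                        query_start=qs,
                        query_end=qe,
                        subject_start=ws + ts,
                        subject_end=ws + te,
                        strand=strand,
                        identity=identity,
                        aligned_length=columns,
                        score=float(aln.score),
                    )
                )
    hits.sort(key=lambda h: (-h.score, h.subject_id, h.subject_start))
    # drop duplicate placements found via several windows
    seen = set()
    out = []
    for h in hits:
        key = (h.subject_id, h.subject_start, h.subject_end, h.strand)
        if key not in seen:
            seen.add(key)
            out.append(h)
    return out


def best_local_hit(query: SeqRecord, targets, index: GenomeIndex | None = None,
                   min_query_cov: float = 0.5):
    """Single best-scoring local hit, or None below the coverage floor."""
    hits = window_hits(query, targets, index=index, min_query_cov=min_query_cov)
    return hits[0] if hits else None


def protein_score(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    al = aligner or protein_aligner()
    return float(al.score(a, b))


def protein_evalue(score: float, m: int, n: int) -> float:
    """Karlin-Altschul e-value surrogate: E = m*n*2^(-bitscore)."""
    bit = (_LAMBDA * score - math.log(_K)) / math.log(2.0)
    # cap the exponent to avoid overflow on tiny scores
    return float(m) * float(n) * 2.0 ** (-min(bit, 10_000.0))
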