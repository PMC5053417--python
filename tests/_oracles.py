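"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most direct method available
(full DP, exhaustive scan, hash counting) and stay independent of the
package code paths they check.
"""

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def smith_waterman_score(query, target, match=1, mismatch=-2, gap_open=5, gap_extend=2,
                         matrix=None):
    """Exhaustive local-alignment score, affine gaps costing open + extend*L.

    Vectorized Gotoh over target columns; with ``matrix`` set, query/target
    are proteins scored by the substitution matrix instead of
    match/mismatch.
    """
    m, n = len(query), len(target)
    first_col = gap_open + gap_extend  # cost of the first gap column
    H_prev = np.zeros(n + 1)
    F = np.full(n + 1, -np.inf)
    best = 0.0
    ext = float(gap_extend)
    ar = np.arange(n + 1) * ext
    if matrix is None:
        tarr = np.frombuffer(target.encode(), dtype=np.uint8)
    for i in range(1, m + 1):
        if matrix is None:
            q = query[i - 1].encode()[0]
            subst = np.where(tarr == q, float(match), float(mismatch))
        else:
            row = matrix[query[i - 1]]
            subst = np.array([row[c] for c in target])
        diag = H_prev[:-1] + subst
        F = np.maximum(H_prev - first_col, F - ext)
        base = np.maximum.reduce([np.zeros(n + 1), np.concatenate(([0.0], diag)), F])
        # within-row gap: E[j] = max_{k<j}(base[k] + ext*k) - open - ext*j - ...
        run = np.maximum.accumulate(base + ar)
        E = np.concatenate(([-np.inf], run[:-1])) - first_col - ar + ext
        H = np.maximum(base, E)
        H[0] = 0.0
        best = max(best, H.max())
        H_prev = H
    return float(best)


def protein_sw_score(a, b, gap_open=11, gap_extend=1):
    return smith_waterman_score(a, b, gap_open=gap_open, gap_extend=gap_extend, matrix=_B62)


def zero_runs(depth, min_len):
    """Maximal runs of zeros of length >= min_len, by linear scan."""
    runs = []
    start = None
    for i, d in enumerate(list(depth) + [1]):
        if d == 0 and start is None:
            start = i
        elif d != 0 and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    return runs


def bin_lengths(lengths):
    """Doubling-bin counts/bp by explicit range checks (100-200, 201-400, ...)."""
    edges = [(100, 200), (201, 400), (401, 800), (801, 1600), (1601, 3200),
             (3201, 6400), (6401, 12800), (12801, 25600)]
    counts = [0] * 9
    bps = [0] * 9
    for ln in lengths:
        assert ln >= 100
        placed = False
        for i, (lo, hi) in enumerate(edges):
            if lo <= ln <= hi:
                counts[i] += 1
                bps[i] += ln
                placed = True
                break
        if not placed:
            counts[8] += 1
            bps[8] += ln
    return counts, bps


def reciprocal_pairs(best_ab, best_ba):
    """Brute-force reciprocal intersection of two best-hit maps."""
    return sorted(
        (a, b) for a, b in best_ab.items()
        for b2, a2 in [(b, best_ba.get(b))] if a2 == a
    )


def exact_occurrences(read, genome, revcomp):
    """All exact placements of a read on either strand, by full scan."""
    hits = []
    for strand, seq in (("+", read), ("-", revcomp(read))):
        start = genome.find(seq)
        while start != -1:
            hits.append((start, start + len(seq), strand))
            start = genome.find(seq, start + 1)
    return sorted(hits)


def count_kmers(reads, k, revcomp):
    """Canonical k-mer counting with a plain dict of strings."""
    counts = {}
    for seq in reads:
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if any(c not in "ACGT" for c in kmer):
                continue
            canon = min(kmer, revcomp(kmer))
            counts[canon] = counts.get(canon, 0) + 1
    return counts
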