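"""Reciprocal-best-hit orthology, synteny dot plots and assembly polishing.

Protein sets of the two assemblies are scored all-vs-all (BLOSUM62 local
alignment with a Karlin-Altschul e-value surrogate, cutoff 0.001, one best
target per query); reciprocal best hits (RBHs) proxy one-to-one orthologs.
Sorting each assembly's RBH genes by genomic position gives every pair a
rank in each genome; colinear genomes put all pairs on the dot-plot
diagonal.  Rank outliers are typed "random" (a member has several near-best
hits: ambiguous pairing, typically a gene family) or "real" (a unique hit
at a truly different position).  Runs of RBHs that jump chromosome or rank
mid-scaffold yield split hints for assembly polishing; per-scaffold
evidence drives chromosome anchoring with AGP output; genic read coverage
against the RBH reference level flags collapsed duplicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from ._align import protein_aligner, protein_evalue
from .core_io import CoverageTrack, Feature, GapPlacement, Interval, ScaffoldPlacement

__all__ = [
    "RbhParams",
    "GeneModel",
    "RbhPair",
    "OutlierCall",
    "SplitHint",
    "AnchorEvidence",
    "ChromosomeAssignment",
    "score_proteins",
    "best_hits",
    "compute_rbhs",
    "dot_plot_data",
    "detect_outliers",
    "classify_outlier",
    "scaffold_split_hints",
    "anchor_scaffolds",
    "genic_coverage",
]


@dataclass
class RbhParams:
    evalue_max: float = 0.001
    max_targets: int = 1
    near_best_ratio: float = 0.95   # score ratio defining an "equally good" hit
    outlier_window: int = 5         # genes
    outlier_rank_dev: int = 20      # ranks
    majority_fraction: float = 0.6  # chromosome-assignment evidence majority
    agp_gap_len: int = 100

    def __post_init__(self):
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if not 0.0 < self.near_best_ratio <= 1.0:
            raise ValueError("near_best_ratio must be in (0,1]")
        if self.outlier_window < 1:
            raise ValueError("outlier_window must be >= 1")


@dataclass(frozen=True)
class GeneModel:
    """One gene with its locus and the protein of its major transcript."""

    id: str
    locus: Interval
    protein: str

    def __post_init__(self):
        if not self.protein:
            raise ValueError(f"empty protein for gene {self.id!r}")


@dataclass(frozen=True)
class RbhPair:
    gene_a: str
    gene_b: str
    score_ab: float
    score_ba: float
    rank_a: int = -1
    rank_b: int = -1


@dataclass(frozen=True)
class OutlierCall:
    rbh: RbhPair
    kind: str  # "random" or "real"


@dataclass(frozen=True)
class SplitHint:
    scaffold: str
    breakpoint_start: int
    breakpoint_end: int
    left_gene: str
    right_gene: str
    evidence: str


@dataclass(frozen=True)
class AnchorEvidence:
    """One piece of placement evidence for a scaffold."""

    scaffold: str
    scaffold_pos: int
    chromosome: str
    chromosome_pos: int
    weight_bp: int = 1


@dataclass(frozen=True)
class ChromosomeAssignment:
    scaffold: str
    chromosome: str | None  # None = unplaced
    orientation: str        # '+', '-'
    order_key: float
    reason: str = ""


# ---------------------------------------------------------------------------

def score_proteins(set_a, set_b, params: RbhParams | None = None) -> pd.DataFrame:
    """All-vs-all local protein scores, both query directions.

    Columns: direction ('ab'|'ba'), query, subject, score, evalue.  Scores
    are symmetric so each unordered pair is aligned once and mirrored; the
    e-value surrogate uses the total residue counts of both sets.
    """
    set_a = [g for g in set_a if _nonempty(g)]
    set_b = [g for g in set_b if _nonempty(g)]
    if not set_a or not set_b:
        raise ValueError("protein sets must be non-empty")
    m = sum(len(g.protein) for g in set_a)
    n = sum(len(g.protein) for g in set_b)
    al = protein_aligner()
    rows = []
    for ga in set_a:
        for gb in set_b:
            s = float(al.score(ga.protein, gb.protein))
            e = protein_evalue(s, m, n)
            rows.append(("ab", ga.id, gb.id, s, e))
            rows.append(("ba", gb.id, ga.id, s, e))
    return pd.DataFrame(rows, columns=["direction", "query", "subject", "score", "evalue"])


def _nonempty(gene) -> bool:
    if getattr(gene, "protein", ""):
        return True
    warnings.warn(f"skipping gene {getattr(gene, 'id', '?')!r} with empty protein")
    return False


def best_hits(hits: pd.DataFrame, params: RbhParams | None = None,
              direction: str | None = None) -> dict[str, str]:
    """Best subject per query among hits with e-value <= cutoff.

    Best = highest score; ties broken by lowest e-value, then
    lexicographically smallest subject id.
    """
    params = params or RbhParams()
    df = hits
    if direction is not None and "direction" in df.columns:
        df = df[df["direction"] == direction]
    df = df[df["evalue"] <= params.evalue_max]
    if df.empty:
        return {}
    df = df.sort_values(
        ["query", "score", "evalue", "subject"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    first = df.groupby("query", sort=False).head(1)
    return dict(zip(first["query"], first["subject"]))


def compute_rbhs(best_ab: dict[str, str], best_ba: dict[str, str],
                 order_a, order_b,
                 scores: pd.DataFrame | None = None) -> list[RbhPair]:
    """Reciprocal intersection of the two best-hit maps, with ranks.

    ``order_a``/``order_b`` are the position-sorted gene-id lists of the two
    assemblies; ranks are 0-based positions within each assembly's
    position-sorted list of RBH genes.
    """
    pairs = [(a, b) for a, b in best_ab.items() if best_ba.get(b) == a]
    members_a = {a for a, _ in pairs}
    members_b = {b for _, b in pairs}
    rank_a = {g: i for i, g in enumerate(g for g in order_a if g in members_a)}
    rank_b = {g: i for i, g in enumerate(g for g in order_b if g in members_b)}
    score_of = {}
    if scores is not None:
        for d, q, s, sc in zip(scores["direction"], scores["query"], scores["subject"], scores["score"]):
            score_of[(d, q, s)] = sc
    out = []
    for a, b in pairs:
        out.append(
            RbhPair(
                gene_a=a,
                gene_b=b,
                score_ab=score_of.get(("ab", a, b), np.nan),
                score_ba=score_of.get(("ba", b, a), np.nan),
                rank_a=rank_a[a],
                rank_b=rank_b[b],
            )
        )
    out.sort(key=lambda p: p.rank_a)
    return out


def dot_plot_data(rbhs) -> pd.DataFrame:
    """One (rank_a, rank_b) row per RBH pair, for the synteny dot plot."""
    return pd.DataFrame(
        {
            "gene_a": [p.gene_a for p in rbhs],
            "gene_b": [p.gene_b for p in rbhs],
            "rank_a": [p.rank_a for p in rbhs],
            "rank_b": [p.rank_b for p in rbhs],
        }
    )


def plot_dot_plot(rbhs, path, guides_a=(), guides_b=()):
    """Render the rank dot plot to ``path`` (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = dot_plot_data(rbhs)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.plot(df["rank_a"], df["rank_b"], ".", ms=2, color="black")
    for g in guides_a:
        ax.axvline(g, color="purple", lw=0.5)
    for g in guides_b:
        ax.axhline(g, color="purple", lw=0.5)
    ax.set_xlabel("gene rank, assembly A")
    ax.set_ylabel("gene rank, assembly B")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def detect_outliers(rbhs, params: RbhParams | None = None) -> list[RbhPair]:
    """Pairs whose rank offset deviates from their neighborhood median.

    The rank offset of a pair is rank_b - rank_a (zero everywhere on a
    colinear diagonal); the neighborhood is the ``outlier_window`` nearest
    pairs by rank_a, excluding the pair itself.  A candidate's offset
    deviates from the neighborhood median offset by more than
    ``outlier_rank_dev`` ranks.  Using offsets rather than raw rank_b keeps
    the test exact at the ends of the gene list, where the neighborhood is
    one-sided.
    """
    params = params or RbhParams()
    pairs = sorted(rbhs, key=lambda p: p.rank_a)
    n = len(pairs)
    if n <= 1:
        return []
    offset = np.array([p.rank_b - p.rank_a for p in pairs])
    w = min(params.outlier_window, n - 1)
    out = []
    for i, p in enumerate(pairs):
        lo = max(0, i - w)
        hi = min(n, i + w + 1)
        # the w nearest neighbors by rank_a distance, excluding the pair itself
        idx = sorted((j for j in range(lo, hi) if j != i), key=lambda j: abs(j - i))[:w]
        med = float(np.median(offset[idx]))
        if abs(offset[i] - med) > params.outlier_rank_dev:
            out.append(p)
    return out


def classify_outlier(candidate: RbhPair, hits: pd.DataFrame,
                     params: RbhParams | None = None) -> OutlierCall:
    """Type an outlier: 'random' if either member has >= 2 near-best hits
    (score >= near_best_ratio x its best score), else 'real'."""
    params = params or RbhParams()

    def n_good(direction, query):
        sub = hits[(hits["direction"] == direction) & (hits["query"] == query)]
        sub = sub[sub["evalue"] <= params.evalue_max]
        if sub.empty:
            return 0
        best = sub["score"].max()
        return int((sub["score"] >= params.near_best_ratio * best).sum())

    ambiguous = n_good("ab", candidate.gene_a) >= 2 or n_good("ba", candidate.gene_b) >= 2
    return OutlierCall(candidate, "random" if ambiguous else "real")


# ---------------------------------------------------------------------------

def scaffold_split_hints(rbhs, locs_a: dict, locs_b: dict,
                         params: RbhParams | None = None) -> list[SplitHint]:
    """Chimeric-junction hints from RBH succession along scaffolds.

    ``locs_a``: gene_a id -> (scaffold, position); ``locs_b``: gene_b id ->
    (chromosome, position).  A hint falls between consecutive genes on one
    scaffold whose counterparts sit on different chromosomes or more than
    ``outlier_rank_dev`` ranks apart, provided each side is backed by a
    consistent run of at least 2 genes.
    """
    params = params or RbhParams()
    by_scaffold: dict[str, list] = {}
    for p in rbhs:
        if p.gene_a not in locs_a or p.gene_b not in locs_b:
            continue
        scaf, pos = locs_a[p.gene_a]
        chrom, _cpos = locs_b[p.gene_b]
        by_scaffold.setdefault(scaf, []).append((pos, p, chrom))

    def consistent(x, y):
        return x[2] == y[2] and abs(x[1].rank_b - y[1].rank_b) <= params.outlier_rank_dev

    hints = []
    for scaf, genes in by_scaffold.items():
        genes.sort(key=lambda t: t[0])
        if len(genes) < 2:
            continue
        for i in range(len(genes) - 1):
            g, h = genes[i], genes[i + 1]
            if consistent(g, h):
                continue
            # maximal consistent runs ending at i and starting at i+1
            left_run = 1
            j = i
            while j > 0 and consistent(genes[j], genes[j - 1]):
                left_run += 1
                j -= 1
            right_run = 1
            j = i + 1
            while j < len(genes) - 1 and consistent(genes[j], genes[j + 1]):
                right_run += 1
                j += 1
            if left_run < 2 or right_run < 2:
                continue
            evidence = (
                f"{g[2]}->{h[2]}" if g[2] != h[2]
                else f"rank jump {abs(g[1].rank_b - h[1].rank_b)}"
            )
            hints.append(
                SplitHint(
                    scaffold=scaf,
                    breakpoint_start=g[0],
                    breakpoint_end=h[0],
                    left_gene=g[1].gene_a,
                    right_gene=h[1].gene_a,
                    evidence=evidence,
                )
            )
    return hints


def anchor_scaffolds(scaffold_lengths: dict[str, int], evidence,
                     params: RbhParams | None = None):
    """Assign scaffolds to chromosomes and emit AGP placements.

    Per scaffold: chromosome = weighted (bp) majority of evidence, requiring
    at least ``majority_fraction`` of the weight (otherwise unplaced with a
    reason); orientation = sign of the rank correlation between scaffold
    and chromosome positions; order along the chromosome = median
    counterpart coordinate.  Consecutive scaffolds are separated by
    ``agp_gap_len`` bp gaps of unknown size.
    """
    params = params or RbhParams()
    by_scaffold: dict[str, list[AnchorEvidence]] = {}
    for ev in evidence:
        by_scaffold.setdefault(ev.scaffold, []).append(ev)

    assignments: list[ChromosomeAssignment] = []
    for scaf in scaffold_lengths:
        evs = by_scaffold.get(scaf, [])
        if not evs:
            assignments.append(ChromosomeAssignment(scaf, None, "+", np.inf, "no evidence"))
            continue
        weight: dict[str, float] = {}
        for ev in evs:
            weight[ev.chromosome] = weight.get(ev.chromosome, 0.0) + ev.weight_bp
        total = sum(weight.values())
        chrom, w = max(weight.items(), key=lambda kv: (kv[1], kv[0]))
        if w < params.majority_fraction * total:
            assignments.append(
                ChromosomeAssignment(
                    scaf, None, "+", np.inf,
                    f"conflicting evidence ({w / total:.0%} majority)",
                )
            )
            continue
        on = [ev for ev in evs if ev.chromosome == chrom]
        spos = [ev.scaffold_pos for ev in on]
        cpos = [ev.chromosome_pos for ev in on]
        orient = "+"
        if len(on) >= 2 and len(set(spos)) > 1 and len(set(cpos)) > 1:
            rho = sp_stats.spearmanr(spos, cpos).statistic
            if np.isfinite(rho) and rho < 0:
                orient = "-"
        assignments.append(
            ChromosomeAssignment(scaf, chrom, orient, float(np.median(cpos)))
        )

    placements = []
    by_chrom: dict[str, list[ChromosomeAssignment]] = {}
    for a in assignments:
        key = a.chromosome if a.chromosome is not None else "unplaced"
        by_chrom.setdefault(key, []).append(a)
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda a: (a.order_key, a.scaffold))
        pos = 0
        for i, a in enumerate(members):
            if i > 0:
                placements.append(
                    GapPlacement(chrom, pos, pos + params.agp_gap_len, "scaffold", False, True)
                )
                pos += params.agp_gap_len
            ln = scaffold_lengths[a.scaffold]
            placements.append(
                ScaffoldPlacement(chrom, pos, pos + ln, a.scaffold, 0, ln, a.orientation)
            )
            pos += ln
    return assignments, placements


def genic_coverage(tracks: dict[str, CoverageTrack], genes, rbh_gene_ids,
                   collapse_factor: float = 2.0):
    """Per-gene mean depth and collapsed-duplicate flags.

    The genome-wide reference level is the median of the RBH genes' mean
    depths; a non-RBH gene at >= ``collapse_factor`` x that level is flagged
    as a collapsed-duplicate candidate.  Returns (DataFrame, reference
    level).
    """
    rows = []
    for g in genes:
        iv = g.interval if isinstance(g, Feature) else g.locus
        gid = g.id
        track = tracks[iv.seq_id]
        if iv.length == 0:
            raise ValueError(f"zero-length gene {gid!r}")
        if iv.end > track.length:
            raise ValueError(f"gene {gid!r} outside track bounds")
        mean_depth = float(track.depth[iv.start:iv.end].mean())
        rows.append({"gene": gid, "mean_depth": mean_depth, "is_rbh": gid in rbh_gene_ids})
    df = pd.DataFrame(rows)
    rbh_means = df.loc[df["is_rbh"], "mean_depth"]
    if rbh_means.empty:
        raise ValueError("no RBH genes to define the reference coverage level")
    reference = float(rbh_means.median())
    df["collapsed_candidate"] = (~df["is_rbh"]) & (df["mean_depth"] >= collapse_factor * reference)
    return df, reference
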