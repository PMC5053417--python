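import random

import numpy as np
import pandas as pd
import pytest

from pavscape.core_io import CoverageTrack, Feature, Interval, read_agp, write_agp
from pavscape.rbh_synteny import (
    AnchorEvidence,
    GeneModel,
    RbhParams,
    anchor_scaffolds,
    best_hits,
    classify_outlier,
    compute_rbhs,
    detect_outliers,
    dot_plot_data,
    genic_coverage,
    scaffold_split_hints,
    score_proteins,
)

from conftest import random_protein
from _oracles import protein_sw_score, reciprocal_pairs


def make_proteomes(n, rng, mutate=0.0):
    """Paired colinear proteomes: gene i of A is homologous to gene i of B."""
    genes_a, genes_b = [], []
    for i in range(n):
        prot = random_protein(rng, 60)
        pb = list(prot)
        for j in range(len(pb)):
            if rng.random() < mutate:
                pb[j] = random_protein(rng, 1)
        genes_a.append(GeneModel(f"a{i:03d}", Interval("chrA", 1000 * i, 1000 * i + 500), prot))
        genes_b.append(GeneModel(f"b{i:03d}", Interval("chrB", 1000 * i, 1000 * i + 500), "".join(pb)))
    return genes_a, genes_b


def order_ids(genes):
    return [g.id for g in sorted(genes, key=lambda g: (g.locus.seq_id, g.locus.start))]


@pytest.fixture(scope="module")
def colinear():
    rng = random.Random(1)
    genes_a, genes_b = make_proteomes(25, rng, mutate=0.05)
    hits = score_proteins(genes_a, genes_b)
    params = RbhParams()
    pairs = compute_rbhs(
        best_hits(hits, params, "ab"), best_hits(hits, params, "ba"),
        order_ids(genes_a), order_ids(genes_b), scores=hits,
    )
    return genes_a, genes_b, hits, pairs


class TestScoring:
    def test_identical_protein_self_score_is_maximal(self, colinear):
        genes_a, genes_b, hits, _ = colinear
        sub = hits[(hits.direction == "ab") & (hits["query"] == "a000")]
        assert sub.loc[sub.score.idxmax(), "subject"] == "b000"

    def test_unrelated_proteins_exceed_evalue_cutoff(self):
        rng = random.Random(2)
        params = RbhParams()
        n_above = 0
        trials = 200
        for _ in range(trials):
            a = [GeneModel("a", Interval("c", 0, 10), random_protein(rng, 100))]
            b = [GeneModel("b", Interval("c", 0, 10), random_protein(rng, 100))]
            ev = score_proteins(a, b).evalue.iloc[0]
            if ev > params.evalue_max:
                n_above += 1
        assert n_above >= 0.95 * trials

    def test_scores_equal_smith_waterman_oracle(self):
        rng = random.Random(3)
        genes_a = [GeneModel(f"a{i}", Interval("c", i, i + 1), random_protein(rng, 40))
                   for i in range(10)]
        genes_b = [GeneModel(f"b{i}", Interval("c", i, i + 1), random_protein(rng, 40))
                   for i in range(10)]
        hits = score_proteins(genes_a, genes_b)
        ab = hits[hits.direction == "ab"]
        for _, row in ab.iterrows():
            pa = next(g.protein for g in genes_a if g.id == row["query"])
            pb = next(g.protein for g in genes_b if g.id == row["subject"])
            assert row["score"] == protein_sw_score(pa, pb)


class TestBestHits:
    def test_evalue_cutoff_excludes_hit(self):
        df = pd.DataFrame(
            [{"direction": "ab", "query": "q", "subject": "s", "score": 50.0, "evalue": 0.01}]
        )
        assert best_hits(df, RbhParams(), "ab") == {}

    def test_tie_broken_lexicographically(self):
        rows = [
            {"direction": "ab", "query": "q", "subject": "z", "score": 50.0, "evalue": 1e-10},
            {"direction": "ab", "query": "q", "subject": "b", "score": 50.0, "evalue": 1e-10},
        ]
        assert best_hits(pd.DataFrame(rows), RbhParams(), "ab") == {"q": "b"}

    def test_random_tables_match_brute_force_argmax(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            rows = []
            for q in range(8):
                for s in rng.choice(10, size=5, replace=False):
                    rows.append({
                        "direction": "ab", "query": f"q{q}", "subject": f"s{s}",
                        "score": float(rng.integers(10, 200)), "evalue": 1e-12,
                    })
            df = pd.DataFrame(rows)
            got = best_hits(df, RbhParams(), "ab")
            for q, sub in df.groupby("query"):
                top = sub.sort_values(["score", "evalue", "subject"],
                                      ascending=[False, True, True]).iloc[0]
                assert got[q] == top["subject"]


class TestComputeRbhs:
    def test_colinear_proteomes_pair_up_on_the_diagonal(self, colinear):
        genes_a, _, _, pairs = colinear
        assert len(pairs) == len(genes_a)
        assert all(p.rank_a == p.rank_b for p in pairs)

    def test_non_reciprocal_hit_is_dropped(self):
        best_ab = {"a": "b"}
        best_ba = {"b": "c"}
        assert compute_rbhs(best_ab, best_ba, ["a", "c"], ["b"]) == []

    def test_random_maps_match_brute_force_intersection(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            qa = [f"a{i}" for i in range(12)]
            qb = [f"b{i}" for i in range(12)]
            best_ab = {a: str(rng.choice(qb)) for a in qa if rng.random() < 0.8}
            best_ba = {b: str(rng.choice(qa)) for b in qb if rng.random() < 0.8}
            pairs = compute_rbhs(best_ab, best_ba, qa, qb)
            assert sorted((p.gene_a, p.gene_b) for p in pairs) == reciprocal_pairs(best_ab, best_ba)

    def test_symmetry_under_role_swap(self, colinear):
        genes_a, genes_b, hits, pairs = colinear
        params = RbhParams()
        swapped = compute_rbhs(
            best_hits(hits, params, "ba"), best_hits(hits, params, "ab"),
            order_ids(genes_b), order_ids(genes_a),
        )
        assert sorted((p.gene_b, p.gene_a) for p in swapped) == sorted(
            (p.gene_a, p.gene_b) for p in pairs
        )

    def test_ranks_are_permutations(self, colinear):
        _, _, _, pairs = colinear
        n = len(pairs)
        assert sorted(p.rank_a for p in pairs) == list(range(n))
        assert sorted(p.rank_b for p in pairs) == list(range(n))


class TestDotPlot:
    def test_row_count_and_diagonal(self, colinear):
        _, _, _, pairs = colinear
        df = dot_plot_data(pairs)
        assert len(df) == len(pairs)
        assert (df.rank_a == df.rank_b).all()

    def test_tsv_round_trip(self, colinear, tmp_path):
        _, _, _, pairs = colinear
        df = dot_plot_data(pairs)
        p = tmp_path / "dots.tsv"
        df.to_csv(p, sep="\t", index=False)
        back = pd.read_csv(p, sep="\t")
        pd.testing.assert_frame_equal(back, df)


def _pairs_from_ranks(rank_b_by_index):
    from pavscape.rbh_synteny import RbhPair

    return [RbhPair(f"a{i}", f"b{rb}", 100.0, 100.0, i, rb)
            for i, rb in enumerate(rank_b_by_index)]


class TestOutliers:
    def test_colinear_ranks_give_no_candidates(self):
        pairs = _pairs_from_ranks(list(range(200)))
        assert detect_outliers(pairs, RbhParams()) == []

    def test_relocated_gene_with_unique_hit_is_real(self):
        ranks = list(range(300))
        ranks[50] = 280  # one gene moved far away
        ranks[280] = 50
        pairs = _pairs_from_ranks(ranks)
        cands = detect_outliers(pairs, RbhParams())
        assert {p.rank_a for p in cands} == {50, 280}
        hits = pd.DataFrame([
            {"direction": "ab", "query": "a050", "subject": "x", "score": 100.0, "evalue": 1e-20},
            {"direction": "ba", "query": pairs[50].gene_b, "subject": "a050", "score": 100.0, "evalue": 1e-20},
        ])
        # classify needs the candidate's own ids in the hit table
        hits.loc[0, "query"] = pairs[50].gene_a
        call = classify_outlier(pairs[50], hits, RbhParams())
        assert call.kind == "real"

    def test_two_copy_family_swap_is_random(self):
        ranks = list(range(100))
        ranks[10], ranks[80] = 80, 10
        pairs = _pairs_from_ranks(ranks)
        cands = detect_outliers(pairs, RbhParams())
        assert len(cands) == 2
        rows = []
        for cand in cands:
            # each member has two near-best hits (the two family copies)
            rows += [
                {"direction": "ab", "query": cand.gene_a, "subject": "c1", "score": 100.0, "evalue": 1e-20},
                {"direction": "ab", "query": cand.gene_a, "subject": "c2", "score": 98.0, "evalue": 1e-20},
            ]
        hits = pd.DataFrame(rows)
        for cand in cands:
            assert classify_outlier(cand, hits, RbhParams()).kind == "random"


class TestSplitHints:
    def _chimera(self, n_left=6, n_right=6):
        """A scaffold whose left half maps chr1, right half chr3."""
        from pavscape.rbh_synteny import RbhPair

        pairs, locs_a, locs_b = [], {}, {}
        for i in range(n_left + n_right):
            a, b = f"a{i}", f"b{i}"
            chrom = "chr1" if i < n_left else "chr3"
            pairs.append(RbhPair(a, b, 10.0, 10.0, i, i))
            locs_a[a] = ("scf1", 2000 * i)
            locs_b[b] = (chrom, 5000 * i)
        return pairs, locs_a, locs_b, n_left

    def test_colinear_scaffold_has_no_hints(self):
        pairs, locs_a, locs_b, _ = self._chimera(12, 0)
        assert scaffold_split_hints(pairs, locs_a, locs_b) == []

    def test_chimeric_scaffold_yields_one_hint_at_junction(self):
        pairs, locs_a, locs_b, n_left = self._chimera()
        (hint,) = scaffold_split_hints(pairs, locs_a, locs_b)
        assert hint.scaffold == "scf1"
        assert hint.left_gene == f"a{n_left - 1}" and hint.right_gene == f"a{n_left}"
        assert "chr1->chr3" in hint.evidence


class TestAnchorScaffolds:
    def _evidence(self, scaf, chrom, positions, ascending=True):
        cpos = sorted(positions) if ascending else sorted(positions, reverse=True)
        return [
            AnchorEvidence(scaf, sp, chrom, cp, weight_bp=500)
            for sp, cp in zip(sorted(positions), cpos)
        ]

    def test_ascending_evidence_gives_plus_orientation(self):
        ev = self._evidence("s1", "chr2", [100, 5000, 9000])
        (a,), placements = anchor_scaffolds({"s1": 10_000}, ev)
        assert (a.chromosome, a.orientation) == ("chr2", "+")

    def test_descending_evidence_gives_minus_orientation(self):
        ev = self._evidence("s1", "chr2", [100, 5000, 9000], ascending=False)
        (a,), _ = anchor_scaffolds({"s1": 10_000}, ev)
        assert (a.chromosome, a.orientation) == ("chr2", "-")

    def test_conflicting_evidence_is_unplaced(self):
        ev = self._evidence("s1", "chr1", [0, 1000]) + self._evidence("s1", "chr2", [2000, 3000])
        (a,), _ = anchor_scaffolds({"s1": 5000}, ev)
        assert a.chromosome is None and "conflicting" in a.reason

    def test_agp_round_trip_reproduces_placements(self, tmp_path):
        lengths = {"s1": 4000, "s2": 6000, "s3": 3000}
        ev = (
            self._evidence("s1", "chr1", [0, 2000])
            + self._evidence("s2", "chr1", [20_000, 25_000])
            + self._evidence("s3", "chr2", [100, 800], ascending=False)
        )
        _, placements = anchor_scaffolds(lengths, ev)
        p = tmp_path / "anchored.agp"
        write_agp(placements, p)
        assert read_agp(p) == placements

    def test_shredded_reference_recovery(self):
        rng = np.random.default_rng(6)
        n_frag = 50
        frag_len = 30_000
        lengths, evidence, truth = {}, [], {}
        for i in range(n_frag):
            scaf = f"f{i:02d}"
            chrom = f"chr{i % 2 + 1}"
            start = (i // 2) * frag_len
            flip = bool(rng.random() < 0.5)
            lengths[scaf] = frag_len
            truth[scaf] = (chrom, start, "-" if flip else "+")
            gene_pos = np.sort(rng.choice(frag_len - 500, size=4, replace=False))
            for gp in gene_pos:
                sp = frag_len - 500 - gp if flip else gp
                evidence.append(AnchorEvidence(scaf, int(sp), chrom, int(start + gp), 500))
        assignments, _ = anchor_scaffolds(lengths, evidence)
        ok = 0
        for a in assignments:
            chrom, start, orient = truth[a.scaffold]
            if a.chromosome == chrom and a.orientation == orient:
                ok += 1
        assert ok >= 0.95 * n_frag
        # recovered order along each chromosome matches the truth order
        for chrom in ("chr1", "chr2"):
            members = [a for a in assignments if a.chromosome == chrom]
            recovered = [a.scaffold for a in sorted(members, key=lambda a: a.order_key)]
            expected = sorted((truth[s][1], s) for s in lengths if truth[s][0] == chrom)
            assert recovered == [s for _, s in expected]


class TestGenicCoverage:
    def _genes(self, n, length=200, step=500):
        return [
            Feature("g", Interval("g", i * step, i * step + length), "gene", f"gene{i}")
            for i in range(n)
        ]

    def test_uniform_depth_no_flags(self):
        tracks = {"g": CoverageTrack("g", np.full(10_000, 100))}
        genes = self._genes(10)
        df, ref = genic_coverage(tracks, genes, {f"gene{i}" for i in range(5)})
        assert ref == 100.0
        assert not df.collapsed_candidate.any()

    def test_doubled_depth_non_rbh_gene_is_flagged(self):
        depth = np.full(10_000, 112)
        depth[0:200] = 250  # gene0, not in the RBH set
        tracks = {"g": CoverageTrack("g", depth)}
        genes = self._genes(10)
        df, ref = genic_coverage(tracks, genes, {f"gene{i}" for i in range(1, 10)})
        assert ref == 112.0
        flagged = df[df.collapsed_candidate]
        assert flagged.gene.tolist() == ["gene0"]

    def test_rbh_gene_never_flagged(self):
        depth = np.full(5_000, 50)
        depth[0:200] = 400
        tracks = {"g": CoverageTrack("g", depth)}
        genes = self._genes(5)
        df, _ = genic_coverage(tracks, genes, {f"gene{i}" for i in range(5)})
        assert not df.collapsed_candidate.any()
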