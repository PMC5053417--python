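import random

import numpy as np
import pytest

from pavscape.core_io import AlignmentHit, CoverageTrack, Interval, SeqRecord
from pavscape.read_mapping import MappingParams, ReadPlacement
from pavscape.synthetic_data import (
    DivergenceConfig,
    ReadSimConfig,
    derive_accession,
    generate_ancestor,
    simulate_reads,
)
from pavscape.zcr_pav import (
    SizeBinSummary,
    SvCall,
    ZcrParams,
    ZcrRecord,
    anchor_flanks,
    classify_zcr,
    coverage_titration,
    detect_zcrs,
    extract_flanks,
    run_reciprocal,
    summarize_bins,
    validate_by_pair_distance,
)

from conftest import random_dna
from _oracles import bin_lengths, zero_runs


def _track(depth):
    return CoverageTrack("s", np.asarray(depth))


def _seq(n, rng=None, fill=None):
    if fill is not None:
        return SeqRecord("s", fill * n)
    return SeqRecord("s", random_dna(rng or random.Random(0), n))


class TestDetectZcrs:
    def test_full_coverage_yields_nothing(self):
        assert detect_zcrs(_track([1] * 50), _seq(50)) == []

    def test_five_bp_cutoff(self):
        depth = [1] * 10 + [0] * 4 + [1] * 10 + [0] * 5 + [1] * 10
        (z,) = detect_zcrs(_track(depth), _seq(39))
        assert (z.interval.start, z.interval.end) == (24, 29)
        assert z.length == 5

    def test_ambiguity_filter(self):
        seq = "A" * 10 + "N" * 3 + "A" * 7  # 30% N in the zero run
        depth = [1] * 8 + [0] * 10 + [1] * 2
        assert detect_zcrs(_track(depth), SeqRecord("s", seq)) == []
        clean = detect_zcrs(_track(depth), _seq(20, fill="A"))
        assert len(clean) == 1

    def test_edge_flag(self):
        depth = [0] * 8 + [1] * 20 + [0] * 8
        left, right = detect_zcrs(_track(depth), _seq(36))
        assert left.at_sequence_edge and right.at_sequence_edge

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(1)
        params = ZcrParams()
        for _ in range(100):
            depth = (rng.random(200) < 0.4).astype(int)
            target = _seq(200, fill="A")
            got = [(z.interval.start, z.interval.end)
                   for z in detect_zcrs(_track(depth), target, params)]
            assert got == zero_runs(depth, params.min_zcr_len)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detect_zcrs(_track([0] * 10), _seq(12))


class TestExtractFlanks:
    def _zcr(self, s, e, n):
        return ZcrRecord(Interval("s", s, e), 0.0, s == 0 or e == n)

    def test_flank_arithmetic(self):
        rng = random.Random(2)
        target = _seq(10_000, rng)
        left, right, clipped = extract_flanks(self._zcr(5000, 5500, 10_000), target)
        assert left.sequence == target.sequence[4000:5000]
        assert right.sequence == target.sequence[5500:6500]
        assert clipped == (False, False)

    def test_edge_clipping(self):
        target = _seq(5000, random.Random(3))
        left, right, clipped = extract_flanks(self._zcr(300, 600, 5000), target)
        assert left.sequence == target.sequence[0:300]
        assert clipped == (True, False)

    def test_flanks_are_substrings(self):
        rng = random.Random(4)
        target = _seq(8000, rng)
        for _ in range(20):
            s = rng.randint(1, 7000)
            e = min(7999, s + rng.randint(5, 900))
            left, right, _ = extract_flanks(self._zcr(s, e, 8000), target)
            for f in (left, right):
                if f is not None:
                    assert f.sequence in target.sequence


class TestClassify:
    def _zcr(self, length, edge=False):
        return ZcrRecord(Interval("t", 5000, 5000 + length), 0.0, edge)

    def _hit(self, start, end, strand="+", qid="f"):
        return AlignmentHit(qid, "scf1", 0, end - start, start, end, strand, 1.0, end - start, float(end - start))

    def test_exact_adjacency_is_pav(self):
        call = classify_zcr(self._zcr(500), self._hit(1000, 2000), self._hit(2000, 3000))
        assert call.classification == "pav"
        assert call.inner_end_distance == 0

    def test_distance_beyond_tolerance_is_hdr(self):
        call = classify_zcr(self._zcr(500), self._hit(1000, 2000), self._hit(2500, 3500))
        assert call.classification == "hdr"
        assert call.inner_end_distance == 500

    def test_relative_tolerance_above_1kbp(self):
        # 5,000 bp ZCR: tolerance 10% = 500, so 400 qualifies, 600 does not
        ok = classify_zcr(self._zcr(5000), self._hit(1000, 2000), self._hit(2400, 3400))
        bad = classify_zcr(self._zcr(5000), self._hit(1000, 2000), self._hit(2600, 3600))
        assert ok.classification == "pav" and bad.classification == "hdr"

    def test_minus_strand_adjacency(self):
        # flank order reverses under '-': right hit must precede the left one
        call = classify_zcr(self._zcr(300), self._hit(2000, 3000, "-"), self._hit(1000, 2000, "-"))
        assert call.classification == "pav"

    def test_subject_or_strand_mismatch_is_hdr(self):
        other = AlignmentHit("f", "scf2", 0, 1000, 2000, 3000, "+", 1.0, 1000, 1000.0)
        call = classify_zcr(self._zcr(500), self._hit(1000, 2000), other)
        assert call.classification == "hdr"
        mixed = classify_zcr(self._zcr(500), self._hit(1000, 2000), self._hit(2000, 3000, "-"))
        assert mixed.classification == "hdr"

    def test_edge_and_missing_hits_are_unresolved(self):
        assert classify_zcr(self._zcr(500, edge=True), self._hit(0, 1000), self._hit(1000, 2000)).classification == "unresolved"
        assert classify_zcr(self._zcr(500), None, self._hit(1000, 2000)).classification == "unresolved"
        clipped = classify_zcr(self._zcr(500), self._hit(0, 1000), self._hit(1000, 2000),
                               flanks_clipped=(True, False))
        assert clipped.classification == "unresolved"


class TestAnchorFlanks:
    def test_exact_flank_anchors_uniquely(self):
        rng = random.Random(5)
        counterpart = SeqRecord("c", random_dna(rng, 12_000))
        flank = SeqRecord("f", counterpart.sequence[4000:5000])
        hit, = anchor_flanks([flank], [counterpart])
        assert hit.identity == 1.0
        assert (hit.subject_start, hit.subject_end) == (4000, 5000)

    def test_all_n_flank_is_absent(self):
        counterpart = SeqRecord("c", random_dna(random.Random(6), 5000))
        flank = SeqRecord("f", "N" * 1000)
        (hit,) = anchor_flanks([flank], [counterpart])
        assert hit is None


class TestPairDistanceValidation:
    def _call(self, s=4000, e=4500):
        return SvCall(ZcrRecord(Interval("t", s, e), 0.0, False), "pav")

    def _pair(self, i, left_end, right_start, inner):
        p1 = ReadPlacement(f"v{i}/1", Interval("t", left_end - 100, left_end, "+"), 1.0, 1.0, True, inner)
        p2 = ReadPlacement(f"v{i}/2", Interval("t", right_start, right_start + 100, "-"), 1.0, 1.0, True, inner)
        return [p1, p2]

    def test_no_spanning_pairs_is_indeterminate(self):
        call = validate_by_pair_distance(self._call(), [], (200.0, 10.0, 50))
        assert call.pair_distance_supported == "indeterminate"

    def test_zero_deviation_is_unsupported(self):
        placements = sum((self._pair(i, 3900, 4600, 200) for i in range(5)), [])
        call = validate_by_pair_distance(self._call(), placements, (200.0, 10.0, 50))
        assert call.pair_distance_supported == "unsupported"

    def test_large_deviation_is_supported(self):
        placements = sum((self._pair(i, 3900, 4600, 700) for i in range(5)), [])
        call = validate_by_pair_distance(self._call(), placements, (200.0, 10.0, 50))
        assert call.pair_distance_supported == "supported"


class TestSummarizeBins:
    def test_reported_deletion_bins_reproduce_totals(self):
        counts = [227, 207, 121, 99, 41, 42, 8, 1, 0]
        bps = [31_974, 58_734, 67_725, 110_558, 91_758, 195_585, 56_713, 13_487, 0]
        summary = SizeBinSummary.from_rows(counts, bps)
        assert summary.total_count == 746
        assert summary.total_bp == 626_534

    def test_empty_input(self):
        s = summarize_bins([])
        assert s.total_count == 0 and s.total_bp == 0

    def test_random_lengths_match_brute_force(self):
        rng = random.Random(7)
        lengths = [rng.randint(100, 60_000) for _ in range(1000)]
        s = summarize_bins(lengths)
        counts, bps = bin_lengths(lengths)
        assert s.counts == counts and s.bps == bps

    def test_sub_floor_length_rejected(self):
        with pytest.raises(ValueError):
            summarize_bins([99])


@pytest.fixture(scope="module")
def flm_like_pair():
    """One implanted 6.8 kbp deletion, mirroring a known flowering-time
    locus loss between two accessions."""
    ancestor = generate_ancestor(120_000, seed=31)
    cfg = DivergenceConfig(
        n_deletions=1, large_event_len_range=(6800, 6800), seed=32
    )
    derived, registry = derive_accession(ancestor, cfg)
    acc_a = SeqRecord("accA", ancestor.record.sequence)
    acc_b = SeqRecord("accB", derived.sequence)
    reads_a = simulate_reads(acc_a, ReadSimConfig(coverage=25, seed=33))
    reads_b = simulate_reads(acc_b, ReadSimConfig(coverage=25, seed=34))
    result = run_reciprocal(reads_a.records, reads_b.records, acc_a, acc_b,
                            MappingParams(seed=35), ZcrParams(),
                            name_a="accA", name_b="accB")
    return result, registry


class TestEndToEnd:

    def test_single_deletion_recovered_as_pav(self, flm_like_pair):
        result, registry = flm_like_pair
        (truth,) = registry.by_type("deletion")
        params = ZcrParams()
        pavs = result.b_reads_on_a.pav_calls
        assert len(pavs) == 1
        (call,) = pavs
        tol = params.adjacency_tolerance(6800)
        assert abs(call.zcr.length - 6800) <= tol
        assert abs(call.zcr.interval.start - truth.a_start) <= tol
        assert call.pair_distance_supported == "supported"

    def test_no_opposite_direction_call_at_locus(self, flm_like_pair):
        result, registry = flm_like_pair
        (truth,) = registry.by_type("deletion")
        for call in result.a_reads_on_b.pav_calls:
            # the deleted locus is a point at b_start on accession B
            assert not (
                call.zcr.interval.start - 1000 <= truth.b_start <= call.zcr.interval.end + 1000
            )


class TestCoverageTitration:
    def test_full_fraction_reproduces_and_left_edge_saturates(self, small_pair, small_pair_reads):
        acc_a, acc_b, _ = small_pair
        sim_a, _ = small_pair_reads
        reads = sim_a.records
        df = coverage_titration(reads, acc_b, acc_a, [0.01, 1.0], seed=41,
                                mapping_params=MappingParams(seed=42))
        full = df[df.fraction == 1.0].iloc[0]
        tiny = df[df.fraction == 0.01].iloc[0]
        # expected depth << 1 at 1%: ZCRs blanket most of the genome
        assert tiny.zcr_bp > 0.5 * acc_b.length
        assert full.zcr_bp < tiny.zcr_bp
        assert full.n_pav >= 1
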