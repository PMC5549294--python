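"""Genome-wide calling: window merge, DHS validation, states, eRNA, metagene."""

import numpy as np
import pytest

from enhancerkit import (
    Config,
    CoverageTrack,
    Genome,
    Interval,
    Window,
    call_enhancers,
    classify_states,
    erna_coverage,
    make_windows,
    metagene_matrix,
    overlap_bp,
    scan_genome,
    validate_with_dhs,
)
from enhancerkit.caller import EnhancerCall, ScoredWindow, read_calls_tsv, write_calls_tsv
from enhancerkit.track_io import Peak, PeakSet

from .test_genome_model import merge_oracle


def _scored(genome, enhancer_windows, window_size=200, prob=0.9):
    windows = make_windows(genome, window_size)
    return [
        ScoredWindow(w, prob if w.index in enhancer_windows else 0.1, w.index in enhancer_windows)
        for w in windows
    ]


@pytest.fixture
def small_genome():
    return Genome([("chrT", 10_000)])


class TestCallEnhancers:
    def test_adjacent_windows_merge(self, small_genome):
        calls = call_enhancers(_scored(small_genome, {10, 11}), Config())
        assert [(c.interval.start, c.interval.end) for c in calls] == [(2000, 2400)]

    def test_isolated_window_width(self, small_genome):
        calls = call_enhancers(_scored(small_genome, {5}), Config())
        assert calls[0].interval.width == 200

    def test_probability_is_max_over_member_windows(self, small_genome):
        windows = make_windows(small_genome, 200)
        scored = [
            ScoredWindow(w, {10: 0.7, 11: 0.95, 12: 0.6}.get(w.index, 0.0), w.index in (10, 11, 12))
            for w in windows
        ]
        calls = call_enhancers(scored, Config())
        assert len(calls) == 1 and calls[0].probability == 0.95

    def test_random_patterns_match_per_base_merge_oracle(self, small_genome):
        rng = np.random.default_rng(31)
        for _ in range(100):
            hot = set(rng.choice(50, size=rng.integers(0, 25), replace=False).tolist())
            calls = call_enhancers(_scored(small_genome, hot), Config())
            want = merge_oracle(
                [Interval("chrT", 200 * i, 200 * (i + 1)) for i in hot], 1, length=10_000
            )
            assert [(c.interval.start, c.interval.end) for c in calls] == [
                (iv.start, iv.end) for iv in want
            ]

    def test_no_enhancer_windows(self, small_genome):
        assert call_enhancers(_scored(small_genome, set()), Config()) == []


def _peakset(genome, spans, q=3.0):
    return PeakSet(
        genome,
        [Peak(Interval(genome.names[0], s, e), f"p{i}", 0, 1.0, q + 1, q, (e - s) // 2)
         for i, (s, e) in enumerate(spans)],
    )


class TestValidateWithDhs:
    def test_single_bp_overlap_is_enough(self, small_genome):
        calls = [EnhancerCall(Interval("chrT", 0, 400), 0.9)]
        ok = validate_with_dhs(calls, _peakset(small_genome, [(399, 500)]), Config())
        assert len(ok) == 1 and ok[0].validated

    def test_half_open_boundary_fails(self, small_genome):
        calls = [EnhancerCall(Interval("chrT", 0, 400), 0.9)]
        assert validate_with_dhs(calls, _peakset(small_genome, [(400, 500)]), Config()) == []

    def test_empty_peak_set_warns_and_empties(self, small_genome, caplog):
        calls = [EnhancerCall(Interval("chrT", 0, 400), 0.9)]
        with caplog.at_level("WARNING"):
            assert validate_with_dhs(calls, PeakSet(small_genome), Config()) == []
        assert "empty DHS" in caplog.text

    def test_matches_brute_force_pairwise_filter(self, small_genome):
        rng = np.random.default_rng(33)
        cfg = Config()
        for _ in range(100):
            calls = []
            for _ in range(rng.integers(1, 15)):
                s = int(rng.integers(0, 9000))
                calls.append(EnhancerCall(Interval("chrT", s, s + int(rng.integers(1, 600))), 0.9))
            spans = []
            for _ in range(rng.integers(0, 10)):
                s = int(rng.integers(0, 9500))
                spans.append((s, s + int(rng.integers(1, 400))))
            got = validate_with_dhs(calls, _peakset(small_genome, spans), cfg)
            want = [
                c.interval
                for c in calls
                if any(
                    overlap_bp(c.interval, Interval("chrT", s, e)) >= cfg.min_dhs_overlap
                    for s, e in spans
                )
            ]
            assert [c.interval for c in got] == want

    def test_monotone_in_peaks(self, small_genome):
        rng = np.random.default_rng(34)
        calls = [
            EnhancerCall(Interval("chrT", int(s), int(s) + 200), 0.9)
            for s in rng.choice(9000, 10, replace=False)
        ]
        spans = [(100, 300), (5000, 5200)]
        base = validate_with_dhs(calls, _peakset(small_genome, spans), Config())
        more = validate_with_dhs(calls, _peakset(small_genome, spans + [(7000, 7400)]), Config())
        assert {c.interval for c in base} <= {c.interval for c in more}


class TestClassifyStates:
    def test_zero_coverage_is_primed(self, small_genome):
        track = CoverageTrack.from_segments(small_genome, [("chrT", 5000, 6000, 2.0)])
        calls = [EnhancerCall(Interval("chrT", 0, 400), 0.9, validated=True)]
        out, thr = classify_states(calls, track, threshold=0.5)
        assert out[0].state == "primed" and thr == 0.5

    def test_threshold_above_all_means_all_primed(self, small_genome):
        track = CoverageTrack.from_segments(small_genome, [("chrT", 0, 10_000, 1.0)])
        calls = [EnhancerCall(Interval("chrT", 200 * i, 200 * i + 100), 0.9) for i in range(5)]
        out, _ = classify_states(calls, track, threshold=100.0)
        assert all(c.state == "primed" for c in out)

    def test_partition_into_active_plus_primed(self, small_genome):
        track = CoverageTrack.from_segments(small_genome, [("chrT", 0, 5000, 3.0)])
        calls = [EnhancerCall(Interval("chrT", 1000 * i, 1000 * i + 500), 0.9) for i in range(10)]
        out, _ = classify_states(calls, track)  # default threshold: genome-wide mean (1.5)
        states = [c.state for c in out]
        assert states.count("active") + states.count("primed") == len(calls)
        assert states[:5] == ["active"] * 5 and states[5:] == ["primed"] * 5


class TestErnaCoverage:
    def test_zero_tracks(self, small_genome):
        zero = CoverageTrack.from_segments(small_genome, [])
        calls = [EnhancerCall(Interval("chrT", 0, 400), 0.9)]
        out = erna_coverage(calls, zero, zero)
        assert out[0].erna == (0.0, 0.0)

    def test_exact_strand_means(self, small_genome):
        plus = CoverageTrack.from_segments(small_genome, [("chrT", 100, 500, 6.0)])
        minus = CoverageTrack.from_segments(small_genome, [("chrT", 100, 500, 5.0)])
        calls = [EnhancerCall(Interval("chrT", 100, 500), 0.9)]
        out = erna_coverage(calls, plus, minus)
        assert out[0].erna == (6.0, 5.0)

    def test_missing_track_leaves_fields_empty(self, small_genome, caplog):
        calls = [EnhancerCall(Interval("chrT", 0, 400), 0.9)]
        with caplog.at_level("WARNING"):
            out = erna_coverage(calls, None, None)
        assert out[0].erna is None and "missing GRO" in caplog.text


class TestMetageneMatrix:
    def test_uniform_field_gives_constant_matrix(self, uniform_track):
        calls = [EnhancerCall(Interval("chrT", 4000, 4400), 0.9)]
        mm = metagene_matrix(calls, uniform_track, flank=3000, bin_size=50)
        assert mm.values.shape == (1, 120)
        assert np.allclose(mm.values, 1.0)

    def test_column_count_arithmetic(self, uniform_track):
        calls = [EnhancerCall(Interval("chrT", 5000, 5200), 0.9)]
        mm = metagene_matrix(calls, uniform_track, flank=3000, bin_size=50)
        assert mm.values.shape[1] == 2 * 3000 // 50

    def test_rows_ranked_by_decreasing_signal(self, toy_genome):
        track = CoverageTrack.from_segments(
            toy_genome, [("chrT", 1000, 1200, 1.0), ("chrT", 5000, 5200, 9.0)]
        )
        calls = [
            EnhancerCall(Interval("chrT", 1000, 1200), 0.9),
            EnhancerCall(Interval("chrT", 5000, 5200), 0.9),
        ]
        mm = metagene_matrix(calls, track, flank=1000, bin_size=100)
        assert mm.call_order == [1, 0]

    def test_edge_clipping_contributes_clipped_mean(self, toy_genome):
        track = CoverageTrack.from_segments(toy_genome, [("chrT", 0, 10_000, 2.0)])
        calls = [EnhancerCall(Interval("chrT", 0, 200), 0.9)]  # midpoint 100 < flank
        mm = metagene_matrix(calls, track, flank=3000, bin_size=50)
        # bins entirely before base 0 are zero; in-range bins see the value
        assert mm.values[0, 0] == 0.0
        assert mm.values[0, -1] == 2.0

    def test_bin_size_must_divide_span(self, uniform_track):
        calls = [EnhancerCall(Interval("chrT", 4000, 4400), 0.9)]
        with pytest.raises(ValueError, match="divide"):
            metagene_matrix(calls, uniform_track, flank=3000, bin_size=77)

    def test_peak_valley_peak_shape_on_planted_enhancers(self, noise_free):
        truth, tracks = noise_free
        active = [EnhancerCall(iv, 1.0) for iv, s in truth.enhancers if s == "active"]
        mm = metagene_matrix(active, tracks["H3K4me1"], flank=1000, bin_size=50)
        center = mm.values[:, 19:21].mean(axis=1)
        flankv = (mm.values[:, 14:16].mean(axis=1) + mm.values[:, 24:26].mean(axis=1)) / 2
        assert np.all(center < flankv)


class TestScanGenome:
    def test_all_zero_tracks_yield_no_enhancer_windows(self, small_genome):
        from .test_enhancer_model import _separable_training_set
        from enhancerkit import train_classifier

        model = train_classifier(_separable_training_set(), n_trees=50, seed=0)
        zero = CoverageTrack.from_segments(small_genome, [])
        tracks = {"H3K4me1": zero, "H3K4me3": zero}
        scored = scan_genome(model, small_genome, tracks, Config())
        assert len(scored) == 50
        assert not any(s.is_enhancer for s in scored)

    def test_scan_invariant_under_chromosome_order(self, bench):
        from enhancerkit import build_training_set, split_train_test, train_classifier
        from enhancerkit import simulate as sim

        truth, tracks, _ = bench
        marks = {m: tracks[m] for m in sim.MARKERS}
        cfg = Config()
        ts = build_training_set(truth.enhancer_intervals(), truth.genes, marks, cfg, seed=1)
        model = train_classifier(split_train_test(ts, cfg.test_fraction, seed=1)[0], n_trees=100, seed=1)
        scored = scan_genome(model, truth.genome, marks, cfg)
        flipped = Genome(list(reversed(truth.genome.chroms)))
        scored_flipped = scan_genome(model, flipped, marks, cfg)
        by_iv = {(s.window.interval.chrom, s.window.interval.start): s.probability for s in scored}
        by_iv_f = {(s.window.interval.chrom, s.window.interval.start): s.probability for s in scored_flipped}
        assert by_iv == by_iv_f


def test_calls_tsv_round_trip(toy_genome, tmp_path):
    calls = [
        EnhancerCall(Interval("chrT", 100, 500), 0.875, True, "active",
                     {"DNase": 1.5, "H3K27ac": 2.25}, (6.0, 5.0)),
        EnhancerCall(Interval("chrU", 0, 300), 0.625, True, "primed", {"DNase": 0.5}, None),
    ]
    p = tmp_path / "calls.tsv"
    write_calls_tsv(calls, p, toy_genome)
    back = read_calls_tsv(p, toy_genome)
    assert [(c.interval, c.probability, c.state, c.erna) for c in back] == [
        (c.interval, c.probability, c.state, c.erna) for c in calls
    ]
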