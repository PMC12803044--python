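import itertools
from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

from ndjmap.xo_caller import (DEFAULT_STATES, CrossoverCall, GenotypeState,
                              SegmentationParams, annotate_double_crossovers,
                              calls_from_segmentation, detect_gap_shift,
                              emission_loglik, segment_track, viterbi_path)


def make_track(states_freqs, depth=40, spacing=50_000, start=0, rng=None,
               exact=True):
    """A track whose markers sit at the given expected frequencies."""
    pos, freq, dep = [], [], []
    p = start
    for n, f in states_freqs:
        for _ in range(n):
            d = depth if rng is None else max(1, rng.poisson(depth))
            k = round(f * d) if exact else rng.binomial(d, f)
            pos.append(p)
            freq.append(k / d)
            dep.append(d)
            p += spacing
    return pd.DataFrame({"pos": pos, "freq": freq, "depth": dep})


class TestSegmentTrack:
    def test_clean_two_state_track_has_one_boundary(self):
        track = make_track([(500, 0.25), (500, 0.5)])
        seg = segment_track(track, contig="2L")
        assert [s.state for s in seg.segments] == ["HET", "HOM_P2"]
        assert seg.segments[0].stop == 500

    def test_constant_track_is_single_segment(self):
        track = make_track([(800, 0.25)])
        seg = segment_track(track)
        assert len(seg.segments) == 1 and seg.segments[0].state == "HET"

    def test_single_outlier_absorbed(self):
        track = make_track([(499, 0.25), (1, 0.5), (500, 0.25)])
        params = SegmentationParams(min_segment_markers=10)
        seg = segment_track(track, params)
        assert len(seg.segments) == 1 and seg.segments[0].state == "HET"

    def test_short_track_single_segment_fallback(self):
        track = make_track([(4, 0.5)])
        with pytest.warns(UserWarning, match="single segment"):
            seg = segment_track(track)
        assert len(seg.segments) == 1 and seg.segments[0].state == "HOM_P2"

    def test_noisy_recovery(self):
        rng = np.random.default_rng(3)
        track = make_track([(300, 0.25), (200, 0.0), (300, 0.25)], depth=20,
                           rng=rng, exact=False)
        seg = segment_track(track)
        assert [s.state for s in seg.segments] == ["HET", "HOM_P1", "HET"]
        assert abs(seg.segments[1].start - 300) <= 2
        assert abs(seg.segments[1].stop - 500) <= 2


def brute_force_best_path(ll, tau):
    """Independent exhaustive minimum-cost search over all state paths."""
    n, k = ll.shape
    best, best_score = None, -np.inf
    for path in itertools.product(range(k), repeat=n):
        score = sum(ll[i, s] for i, s in enumerate(path))
        score += tau * sum(a != b for a, b in zip(path, path[1:]))
        if score > best_score:
            best, best_score = path, score
    return np.array(best), best_score


def recursive_best_score(ll, tau):
    """Second independent coding: memoized recursion on (marker, state)."""
    n, k = ll.shape

    @lru_cache(maxsize=None)
    def f(t, s):
        if t == 0:
            return ll[0, s]
        return ll[t, s] + max(f(t - 1, j) + (0 if j == s else tau) for j in range(k))

    return max(f(n - 1, s) for s in range(k))


@pytest.mark.parametrize("n_markers", [2, 5, 8, 10])
def test_viterbi_equals_exhaustive_search(n_markers):
    rng = np.random.default_rng(n_markers)
    for rep in range(5):
        depth = rng.poisson(15, size=n_markers) + 1
        alt = rng.binomial(depth, rng.choice([0.02, 0.25, 0.5], size=n_markers))
        track = pd.DataFrame({"pos": np.arange(n_markers) * 1000,
                              "freq": alt / depth, "depth": depth})
        params = SegmentationParams()
        ll = emission_loglik(track, params)
        got = viterbi_path(ll.copy(), params.switch_penalty)
        want, want_score = brute_force_best_path(ll, params.switch_penalty)
        got_score = sum(ll[i, s] for i, s in enumerate(got)) + params.switch_penalty * sum(
            a != b for a, b in zip(got, got[1:])
        )
        assert got_score == pytest.approx(want_score, abs=1e-9)
        assert np.array_equal(got, want)


def test_viterbi_matches_independent_recursion_at_30_markers():
    rng = np.random.default_rng(30)
    depth = rng.poisson(20, size=30) + 1
    alt = rng.binomial(depth, rng.choice([0.02, 0.25, 0.5], size=30))
    track = pd.DataFrame({"pos": np.arange(30) * 1000, "freq": alt / depth,
                          "depth": depth})
    params = SegmentationParams()
    ll = emission_loglik(track, params)
    path = viterbi_path(ll.copy(), params.switch_penalty)
    score = sum(ll[i, s] for i, s in enumerate(path)) + params.switch_penalty * sum(
        a != b for a, b in zip(path, path[1:])
    )
    assert score == pytest.approx(recursive_best_score(ll, params.switch_penalty), abs=1e-9)


def test_allele_label_symmetry():
    """Swapping ref/alt mirrors the segmentation HOM_P1 <-> HOM_P2."""
    rng = np.random.default_rng(7)
    track = make_track([(100, 0.0), (100, 0.25), (100, 0.5)], depth=25, rng=rng,
                       exact=False)
    seg = segment_track(track, contig="2L")

    swapped = track.copy()
    swapped["freq"] = 1.0 - swapped["freq"]
    mirror_states = (
        GenotypeState("HOM_P2", 0.5),
        GenotypeState("HET", 0.75),
        GenotypeState("HOM_P1", 1.0),
    )
    seg2 = segment_track(swapped, SegmentationParams(states=mirror_states), contig="2L")
    assert [s.state for s in seg.segments] == [s.state for s in seg2.segments]
    assert [(s.start, s.stop) for s in seg.segments] == [
        (s.start, s.stop) for s in seg2.segments
    ]


class TestCalls:
    def test_mid_arm_call_has_no_zone_flags(self, chr2_model):
        track = make_track([(200, 0.25), (200, 0.5)], start=5_000_000)
        seg = segment_track(track, contig="2L")
        calls = calls_from_segmentation(seg, chr2_model, individual="i1")
        assert len(calls) == 1
        c = calls[0]
        assert c.arm == "2L" and c.from_state == "HET" and c.to_state == "HOM_P2"
        assert c.left_snp < c.right_snp
        assert not ({"heterochromatic", "pericentric"} & c.flags)

    def test_heterochromatic_boundary_flagged(self, chr2_model):
        # boundary at ~22.75 Mb, inside 2L heterochromatin (22.0-23.5 Mb)
        track = make_track([(35, 0.25), (15, 0.5)], start=21_000_000)
        seg = segment_track(track, contig="2L")
        calls = calls_from_segmentation(seg, chr2_model)
        assert len(calls) == 1
        assert {"heterochromatic", "pericentric"} <= calls[0].flags

    def test_double_crossover_annotation(self, chr2_model):
        # two boundaries on 2L ~5 Mb apart in the high-cM region (7.5 -> 12.5 Mb)
        track = make_track([(50, 0.25), (100, 0.5), (200, 0.25)], start=5_000_000)
        seg = segment_track(track, contig="2L")
        calls = calls_from_segmentation(seg, chr2_model)
        assert len(calls) == 2
        assert all("double_CO_member" in c.flags for c in calls)
        assert calls[0].cM_span is not None and calls[0].cM_span > 10
        annotate_double_crossovers(calls, chr2_model)
        assert calls[0].within_normal_range is True
        assert calls[0].bp_sep == pytest.approx(5_000_000, rel=0.01)

    def test_close_pair_below_normal_range(self, chr2_model):
        track = make_track([(200, 0.25), (20, 0.5), (200, 0.25)], start=5_000_000)
        seg = segment_track(track, contig="2L")
        calls = calls_from_segmentation(seg, chr2_model)
        annotate_double_crossovers(calls, chr2_model)
        assert calls[0].bp_sep < 2_000_000
        assert calls[0].within_normal_range is False

    def test_single_call_not_annotated(self, chr2_model):
        track = make_track([(200, 0.25), (200, 0.5)], start=5_000_000)
        calls = calls_from_segmentation(segment_track(track, contig="2L"), chr2_model)
        annotate_double_crossovers(calls, chr2_model)
        assert calls[0].within_normal_range is None and calls[0].bp_sep is None

    def test_call_interval_requires_positive_width(self):
        with pytest.raises(ValueError):
            CrossoverCall(chrom="2L", arm="2L", left_snp=10, right_snp=10,
                          from_state="HET", to_state="HOM_P2")


class TestGapShift:
    def _segs(self, chr2_model, left_states, right_states):
        tl = make_track([(50, f) for f in left_states], start=20_000_000)
        tr = make_track([(50, f) for f in right_states], start=0)
        return (segment_track(tl, contig="2L"), segment_track(tr, contig="2R"))

    def test_same_proximal_state_no_call(self, chr2_model):
        sl, sr = self._segs(chr2_model, [0.25], [0.25])
        assert detect_gap_shift(sl, sr, chr2_model) is None

    def test_differing_proximal_states_emit_gap_call(self, chr2_model):
        sl, sr = self._segs(chr2_model, [0.5], [0.25])
        call = detect_gap_shift(sl, sr, chr2_model)
        assert call is not None and call.arm == "gap"
        assert call.from_state == "HOM_P2" and call.to_state == "HET"
        assert "gap_shift" in call.flags and "pericentric" in call.flags

    def test_proximal_state_uses_centromere_side_of_each_arm(self, chr2_model):
        # 2L distal HOM_P2 but proximal HET must not trigger a gap call
        sl, sr = self._segs(chr2_model, [0.5, 0.25], [0.25])
        assert detect_gap_shift(sl, sr, chr2_model) is None
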