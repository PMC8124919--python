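"""High-pass filtering, SMV, moving windows and peak-based candidate selection."""

import dataclasses

import numpy as np
import pytest

from kicksense.candidates import (
    CandidateParams,
    detect_peaks,
    highpass_gyro,
    moving_windows,
    select_candidates,
    smv,
)
from kicksense.core import SensorStream, scale_stream
from kicksense.synth import SynthConfig, generate_session
from kicksense.datasets import scaled


def _butter_gain(f, fc=20.0, order=2, fs=200.0):
    """Closed-form magnitude of the digital Butterworth high-pass: the analog
    response evaluated at bilinear-warped frequency (tan-prewarped cutoff)."""
    r = np.tan(np.pi * f / fs) / np.tan(np.pi * fc / fs)
    return r**order / np.sqrt(1 + r ** (2 * order))


class TestHighpass:
    def test_dc_is_killed(self):
        g = np.full((2000, 3), 7.5)
        out = highpass_gyro(g)
        assert np.max(np.abs(out[400:])) < 1e-6

    @pytest.mark.parametrize("f", [50.0, 35.0, 10.0])
    def test_sine_gain_matches_analytic_response(self, f):
        t = np.arange(6000) / 200.0
        g = np.column_stack([np.sin(2 * np.pi * f * t)] * 3)
        out = highpass_gyro(g)
        amp = np.sqrt(2.0) * np.sqrt(np.mean(out[2000:, 0] ** 2))
        assert amp == pytest.approx(_butter_gain(f), rel=0.01)

    def test_one_hertz_attenuated_below_one_percent(self):
        t = np.arange(6000) / 200.0
        g = np.column_stack([np.sin(2 * np.pi * 1.0 * t)] * 3)
        out = highpass_gyro(g)
        assert np.max(np.abs(out[2000:])) < 0.01

    def test_too_short_stream_raises(self):
        with pytest.raises(ValueError, match="warm-up"):
            highpass_gyro(np.zeros((5, 3)))


class TestSmv:
    @pytest.mark.parametrize(
        "vec,value",
        [((0, 0, 0), 0.0), ((3, 4, 0), 5.0), ((1, 1, 1), np.sqrt(3))],
    )
    def test_euclidean_norm(self, vec, value):
        assert smv(np.array([vec], dtype=float))[0] == pytest.approx(value)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="gyro"):
            smv(np.zeros((10, 2)))


class TestMovingWindows:
    @pytest.mark.parametrize(
        "n,expected",
        [(1000, [0, 300, 600]), (400, [0]), (399, [])],
    )
    def test_start_indices(self, n, expected):
        assert moving_windows(n).tolist() == expected

    def test_stride_is_three_quarters_of_length(self):
        starts = moving_windows(10_000)
        assert np.all(np.diff(starts) == 300)


class TestDetectPeaks:
    def test_all_zero_window_has_no_peaks(self):
        assert detect_peaks(np.zeros(400)).size == 0

    def test_single_bump_yields_its_apex(self):
        x = np.zeros(400)
        x[150:171] = np.sin(np.linspace(0, np.pi, 21))
        peaks = detect_peaks(x)
        assert peaks.tolist() == [160]

    def test_two_bumps_at_350_samples_both_retained(self):
        """Cross-check against a brute-force enumeration of super-threshold
        local maxima with pairwise distance filtering."""
        x = np.zeros(800)
        x[95:106] = 1.0 * np.sin(np.linspace(0, np.pi, 11))
        x[445:456] = 0.5 * np.sin(np.linspace(0, np.pi, 11))
        peaks = detect_peaks(x, threshold_frac=0.3, min_distance=300)

        thr = 0.3 * x.max()
        brute = [
            i for i in range(1, len(x) - 1)
            if x[i] >= thr and x[i] >= x[i - 1] and x[i] > x[i + 1]
        ]
        brute = [i for i in brute if all(abs(i - j) >= 300 or i == j for j in brute)]
        assert peaks.tolist() == brute == [100, 450]

    def test_min_distance_keeps_higher_peak(self):
        x = np.zeros(400)
        x[100:111] = 1.0 * np.sin(np.linspace(0, np.pi, 11))
        x[200:211] = 0.8 * np.sin(np.linspace(0, np.pi, 11))
        assert detect_peaks(x, min_distance=300).tolist() == [105]

    def test_absolute_floor_suppresses_weak_windows(self):
        x = np.zeros(400)
        x[100:111] = 0.01 * np.sin(np.linspace(0, np.pi, 11))
        assert detect_peaks(x, min_height=0.025).size == 0
        assert detect_peaks(x, min_height=0.0).size == 1


@pytest.fixture(scope="module")
def selection(scaled_session):
    return select_candidates(scaled_session)


class TestSelectCandidates:

    def test_every_shot_and_pass_is_covered(self, scaled_session, selection):
        centers = np.array([c.center_index for c in selection])
        for ev in scaled_session.events:
            if ev.class_label in ("shot", "pass"):
                i = ev.time * 200
                assert np.min(np.abs(centers - i)) <= 100

    def test_blocks_are_fixed_shape_and_peak_centered(self, selection, scaled_session):
        from kicksense.candidates import highpass_gyro as hp, smv as _smv

        stream = scaled_session.streams["right"]
        magnitude = _smv(hp(stream))
        for cand in selection:
            assert cand.block.shape == (400, 6)
            if not cand.edge_padded:
                lo = max(0, cand.center_index - 50)
                hi = cand.center_index + 50
                local_max = magnitude[lo:hi].max()
                assert magnitude[cand.center_index] == pytest.approx(local_max)

    def test_candidate_spacing_respects_merge_distance(self, selection):
        centers = sorted(c.center_index for c in selection)
        assert np.all(np.diff(centers) >= 100)

    def test_pure_standing_noise_has_zero_candidates(self):
        cfg = SynthConfig(seed=71, counts={}, background_mix=(1.0, 0.0, 0.0))
        sel = select_candidates(scaled(generate_session(cfg)))
        assert len(sel) == 0
        assert sel.windows_rejected == sel.windows_total

    def test_unknown_only_candidates_are_marked_excluded(self):
        cfg = SynthConfig(seed=72, counts={"unknown": 4})
        sel = select_candidates(scaled(generate_session(cfg)))
        labelled = [c for c in sel if c.events]
        assert labelled and all(c.label == "excluded" for c in labelled)

    def test_rejection_is_monotone_in_activity(self):
        """Adding a super-threshold impact to a quiet stream can only create
        candidates, never remove existing ones."""
        cfg = SynthConfig(seed=73, counts={"shot": 2}, background_mix=(1.0, 0, 0))
        base = generate_session(cfg)
        sel_before = select_candidates(scaled(base))
        stream = base.streams["right"]
        g = stream.gyro.copy()
        i = 6000
        t = np.arange(60) / 200.0
        g[i : i + 60, :] += 900.0 * np.exp(-t / 0.04)[:, None] * np.sin(
            2 * np.pi * 45 * t
        )[:, None]
        boosted = dataclasses.replace(base, streams={
            "right": dataclasses.replace(stream, gyro=np.clip(g, -2000, 2000))
        }, events=list(base.events))
        sel_after = select_candidates(scaled(boosted))
        before = {c.center_index for c in sel_before}
        after = {c.center_index for c in sel_after}
        assert len(after) >= len(before)
        assert any(abs(c - (i + 1)) <= 100 for c in after)

    def test_label_precedence_prefers_rare_classes(self):
        """Multiple events inside one 1 s label window: shot > pass > null,
        and events outside the window are ignored."""
        from kicksense.candidates import _label_for_peak
        from kicksense.core import BallContactEvent as E

        events = [
            E(time=10.1, fine_type="light contact"),
            E(time=10.3, fine_type="short pass medial"),
            E(time=10.4, fine_type="shot"),
            E(time=11.2, fine_type="long pass"),  # outside the 1 s window
        ]
        label, fine, inside = _label_for_peak(events, 10.2, 0.5)
        assert label == "shot" and fine == "shot" and len(inside) == 3
        label, fine, _ = _label_for_peak(events[:2], 10.2, 0.5)
        assert label == "pass" and fine == "short pass medial"
        label, fine, _ = _label_for_peak(events[:1], 10.2, 0.5)
        assert label == "null" and fine == "light contact"
        label, fine, _ = _label_for_peak([], 10.2, 0.5)
        assert label == "null" and fine == "none"

    def test_stats_are_consistent(self, selection):
        assert selection.windows_total == (
            selection.windows_rejected + selection.windows_with_peaks
        )
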