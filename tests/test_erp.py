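"""ERP preprocessing: filtering, artifact rules, epoching, areas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memtrace import erp
from memtrace.erp import (
    Epoch, Recording, average_and_area, bandpass_filter, detect_artifacts,
    epoch_and_baseline, read_recording, write_recording,
)
from memtrace.synthetic_data import (
    ErpComponentGen, ErpGenParams, generate_eeg, make_event_schedule,
)

FS = 256.0


def flat_recording(duration=10.0, events=()):
    n = int(duration * FS)
    return Recording(np.zeros(n), FS, events=list(events))


class TestBandpassFilter:
    def _attenuation(self, freq):
        t = np.arange(int(20 * FS)) / FS
        rec = Recording(np.sin(2 * np.pi * freq * t), FS)
        out = bandpass_filter(rec).samples
        mid = slice(int(5 * FS), int(15 * FS))
        return np.abs(out[mid]).max()

    def test_passband_center_preserved(self):
        assert self._attenuation(5.0) > 0.95

    def test_line_frequency_strongly_attenuated(self):
        assert self._attenuation(60.0) < 0.10

    def test_dc_offset_removed(self):
        rec = Recording(np.full(int(10 * FS), 50.0), FS)
        out = bandpass_filter(rec).samples
        assert abs(out[int(2 * FS):int(8 * FS)].mean()) < 0.5

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(Recording(np.zeros(100), 50.0))


def oracle_masks(x, fs):
    """Brute-force reimplementation of the three rejection rules."""
    n = len(x)
    pad_abs = int(round(0.300 * fs))
    pad_rng = int(round(0.200 * fs))
    pad_stp = int(round(0.300 * fs))
    w = int(np.floor(0.050 * fs)) + 1

    def spread(centers, pad):
        m = np.zeros(n, bool)
        for c in centers:
            m[max(c - pad, 0):min(c + pad + 1, n)] = True
        return m

    abs_centers = [i for i in range(n) if abs(x[i]) > 100.0]
    rng_centers = []
    half = w // 2
    for i in range(n):
        lo, hi = max(i - half, 0), min(i - half + w, n)
        seg = x[lo:hi]
        if seg.max() - seg.min() > 100.0:
            rng_centers.append(i)
    stp_centers = []
    for i in range(n - 1):
        if abs(x[i + 1] - x[i]) > 50.0:
            stp_centers.extend([i, i + 1])
    return (spread(abs_centers, pad_abs), spread(rng_centers, pad_rng),
            spread(stp_centers, pad_stp))


class TestArtifactRules:
    def test_absolute_amplitude_rule_sample_exact(self):
        rec = flat_recording()
        i = int(2.0 * FS)
        rec.samples[i] = 120.0
        mask = detect_artifacts(rec)
        o_abs, _, o_stp = oracle_masks(rec.samples, FS)
        assert np.array_equal(mask.by_rule["abs"], o_abs)
        # a 120 uV spike also trips the step rule; union still matches
        expected_union = o_abs | o_stp | oracle_masks(rec.samples, FS)[1]
        assert np.array_equal(mask.flags, expected_union)

    def test_range_rule_fires_without_amplitude_rule(self):
        # slow ramp from -20 to +90 uV over ~40 ms: |x| < 100 (rule 1 quiet),
        # adjacent steps 11 uV (rule 3 quiet), 50 ms range 110 uV (rule 2 fires)
        rec = flat_recording()
        i0 = int(3.0 * FS)
        ramp = np.r_[np.linspace(-20.0, 90.0, 11), [60.0, 30.0]]
        rec.samples[i0:i0 + 13] = ramp
        mask = detect_artifacts(rec)
        o_abs, o_rng, o_stp = oracle_masks(rec.samples, FS)
        assert not o_abs.any() and not o_stp.any()
        assert o_rng.any()
        assert np.array_equal(mask.by_rule["range"], o_rng)
        assert np.array_equal(mask.flags, o_rng)

    def test_step_rule_sample_exact(self):
        rec = flat_recording()
        i = int(4.0 * FS)
        rec.samples[i:] = 60.0          # one 60 uV jump
        mask = detect_artifacts(rec)
        o_abs, o_rng, o_stp = oracle_masks(rec.samples, FS)
        assert o_stp.any()
        assert np.array_equal(mask.by_rule["step"], o_stp)
        assert np.array_equal(mask.flags, o_abs | o_rng | o_stp)

    def test_union_on_noisy_trace_matches_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 30, int(8 * FS))
        x[1000] = 150.0
        x[1500:1504] = [0, 80, -40, 10]
        mask = detect_artifacts(Recording(x, FS))
        o = oracle_masks(x, FS)
        assert np.array_equal(mask.flags, o[0] | o[1] | o[2])

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(pos=st.floats(min_value=1.0, max_value=7.0),
           amp=st.floats(min_value=110.0, max_value=500.0))
    def test_rejection_monotonicity(self, pos, amp):
        """Adding an artifact never decreases the rejected-sample count."""
        rng = np.random.default_rng(1)
        x = rng.normal(0, 20, int(8 * FS))
        before = detect_artifacts(Recording(x, FS)).n_rejected
        y = x.copy()
        y[int(pos * FS)] += amp
        after = detect_artifacts(Recording(y, FS)).n_rejected
        assert after >= before


class TestEpoching:
    def test_constant_offset_baselined_to_zero(self):
        rec = flat_recording(events=[(2.0, "tone1")])
        rec.samples += 10.0
        ep = epoch_and_baseline(rec)[0]
        t = ep.times
        pre = ep.samples[(t >= -0.5) & (t <= -0.15)]
        assert abs(pre.mean()) < 1e-12

    def test_boundary_epochs_dropped(self):
        # epoch needs 0.5 s before and 1.5 s after the onset
        rec = flat_recording(duration=4.0,
                             events=[(0.3, "tone1"), (0.6, "tone1"), (3.0, "tone1")])
        eps = epoch_and_baseline(rec)
        assert len(eps) == 1            # only the 0.6 s event fits fully

    def test_epochs_overlapping_mask_dropped_exhaustively(self):
        events = [(1.0 + i * 2.0, "tone1") for i in range(12)]
        rec = flat_recording(duration=28.0, events=events)
        rec.samples[int(5.3 * FS)] = 150.0
        rec.samples[int(13.7 * FS)] = -140.0
        mask = detect_artifacts(rec)
        eps = epoch_and_baseline(rec, mask)
        # brute-force overlap count
        n_expected = 0
        for onset, _ in events:
            i0 = int(round(onset * FS)) - int(round(0.5 * FS))
            i1 = i0 + int(round(2.0 * FS))
            if i0 >= 0 and i1 <= len(rec.samples) and not mask.flags[i0:i1].any():
                n_expected += 1
        assert len(eps) == n_expected
        assert n_expected < len(events)

    def test_epoch_count_equals_event_count_when_clean(self):
        events = [(1.0 + i * 2.0, "tone1") for i in range(8)]
        rec = flat_recording(duration=20.0, events=events)
        assert len(epoch_and_baseline(rec)) == len(events)


class TestAreas:
    def test_rectangle_areas(self):
        assert average_and_area([Epoch(np.ones(512), FS)], "p2"
                                ).area_uv_ms == pytest.approx(100.0)
        assert average_and_area([Epoch(-2 * np.ones(512), FS)], "n1"
                                ).area_uv_ms == pytest.approx(-120.0)

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            average_and_area([], "p2")

    def test_area_linearity_in_signal_scale(self):
        p = ErpGenParams(n1=ErpComponentGen(-131, 497, 5.1),
                         p2=ErpComponentGen(396, -696, 8.5),
                         noise_sd=0.0, artifact_rate=0.0)
        rec = generate_eeg(make_event_schedule(10, 3.5), p, seed=0)
        k = 2.5
        scaled = Recording(k * rec.samples, rec.sampling_rate, rec.events)
        for r, factor in ((rec, 1.0), (scaled, k)):
            eps = epoch_and_baseline(bandpass_filter(r))
            a1 = average_and_area(eps, "p2").area_uv_ms
            if factor == 1.0:
                base = a1
            else:
                assert a1 == pytest.approx(k * base, rel=1e-9)


class TestGeneratorRoundTrip:
    @pytest.mark.parametrize("condition,soas,t_of", [
        ("passive", (2.0, 3.5, 6.5, 9.5), lambda s: s),
        ("active", (2.0, 3.5, 6.5, 9.5), lambda s: s - 0.6),
    ])
    def test_planted_area_curve_recovered_within_one_percent(self, condition,
                                                             soas, t_of):
        """Noise- and artifact-free recordings reproduce the planted
        recovery curves through the full pipeline within 1% relative."""
        p = ErpGenParams(n1=ErpComponentGen(-131.0, 497.0, 5.1),
                         p2=ErpComponentGen(396.0, -696.0, 8.5),
                         noise_sd=0.0, artifact_rate=0.0)
        for soa in soas:
            sched = make_event_schedule(40, soa, paired=condition == "active")
            rec = generate_eeg(sched, p, seed=0)
            filt = bandpass_filter(rec)
            eps = epoch_and_baseline(filt, detect_artifacts(filt))
            for comp in ("n1", "p2"):
                gen = getattr(p, comp)
                expected = np.mean([gen.area_at(None)]
                                   + [gen.area_at(t_of(soa))] * 39)
                measured = average_and_area(eps, comp).area_uv_ms
                assert measured == pytest.approx(expected, rel=0.01, abs=1.0)

    def test_first_event_fully_recovered(self):
        p = ErpGenParams(n1=ErpComponentGen(-131.0, 497.0, 5.1),
                         p2=ErpComponentGen(396.0, -696.0, 8.5),
                         noise_sd=0.0, artifact_rate=0.0)
        rec = generate_eeg([(2.0, "tone1")], p, seed=0)
        filt = bandpass_filter(rec)
        eps = epoch_and_baseline(filt)
        assert average_and_area(eps, "p2").area_uv_ms == pytest.approx(396.0, rel=0.01)
        assert average_and_area(eps, "n1").area_uv_ms == pytest.approx(-131.0, rel=0.01)

    def test_artifacts_injected_when_requested(self):
        p = ErpGenParams(n1=ErpComponentGen(-131.0, 497.0, 5.1),
                         p2=ErpComponentGen(396.0, -696.0, 8.5),
                         noise_sd=0.0, artifact_rate=10.0)
        rec = generate_eeg(make_event_schedule(60, 3.5), p, seed=1)
        assert np.any(np.abs(rec.samples) > 100.0)

    def test_close_events_warn(self):
        p = ErpGenParams(n1=ErpComponentGen(-131.0, 497.0, 5.1),
                         p2=ErpComponentGen(396.0, -696.0, 8.5))
        with pytest.warns(UserWarning):
            generate_eeg([(1.0, "tone1"), (1.3, "tone1")], p, seed=0)

    def test_recording_io_round_trip(self, tmp_path):
        p = ErpGenParams(n1=ErpComponentGen(-131.0, 497.0, 5.1),
                         p2=ErpComponentGen(396.0, -696.0, 8.5))
        rec = generate_eeg(make_event_schedule(5, 2.0), p, seed=3)
        for fmt in ("csv", "raw"):
            path = tmp_path / f"rec_{fmt}.dat"
            write_recording(rec, path, fmt=fmt)
            back = read_recording(path)
            tol = 1e-4 if fmt == "csv" else 1e-3
            assert np.allclose(back.samples, rec.samples, atol=tol)
            assert back.events == rec.events
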