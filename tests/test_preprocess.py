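"""Filtering, decimation, and the epoch-assembly rules."""

import numpy as np
import pytest
from scipy import signal as sps

from oracles import count_expected_epochs
from tstn_bci import PreprocConfig, RawRecording, bandpass, downsample, preprocess
from tstn_bci.io import ConfigurationError, DataError
from tstn_bci.preprocess import assemble_epochs, extract_task_epochs
from tstn_bci.synth import (
    BLOCK_AO_MI,
    BLOCK_MI,
    BLOCK_MI_FB_TASK,
    BLOCK_REST,
    Block,
    ErdModel,
    SessionSpec,
    TrialTimeline,
    generate_session,
)


def _sine_raw(freq, fs=1000.0, dur=20.0, n_ch=1):
    t = np.arange(int(dur * fs)) / fs
    return RawRecording(
        signal=np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1)),
        sampling_rate=fs,
        channel_labels=tuple(f"C{i}" for i in range(n_ch)),
    )


def _forward_backward_gain(freq, cfg, fs):
    """Analytic amplitude response of the zero-phase Butterworth band-pass."""
    sos = sps.butter(cfg.filter_order, cfg.band, btype="bandpass",
                     fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
    return float(np.abs(h[0]) ** 2)  # forward-backward squares the magnitude


class TestBandpass:
    @pytest.mark.parametrize("freq", [10.0, 20.0, 0.5, 2.0, 60.0])
    def test_sinusoid_gain_matches_analytic_response(self, freq):
        """Measured steady-state gain matches |H(f)|^2 of the 3rd-order
        Butterworth applied forward-backward, within 1 dB."""
        cfg = PreprocConfig()
        raw = _sine_raw(freq)
        out = bandpass(raw, cfg)
        mid = slice(raw.n_samples // 4, 3 * raw.n_samples // 4)
        measured = np.sqrt(2) * np.std(out.signal[0, mid])
        expected = _forward_backward_gain(freq, cfg, raw.sampling_rate)
        if expected < 1e-6:
            assert measured < 1e-3
        else:
            assert 10 * abs(np.log10(measured / expected)) < 1.0

    def test_zero_signal_stays_zero(self):
        raw = RawRecording(np.zeros((3, 5000)), 1000.0, ("a", "b", "c"))
        out = bandpass(raw)
        assert np.all(out.signal == 0)
        assert out.signal.shape == raw.signal.shape

    def test_band_outside_nyquist_rejected(self):
        raw = _sine_raw(10.0, fs=60.0, dur=5.0)
        with pytest.raises(ConfigurationError):
            bandpass(raw, PreprocConfig())

    def test_invalid_band_rejected(self):
        with pytest.raises(ConfigurationError):
            PreprocConfig(band=(40.0, 4.0))
        with pytest.raises(ConfigurationError):
            PreprocConfig(band=(4.0, 200.0))


class TestDownsample:
    def test_two_seconds_at_1khz_becomes_500_samples(self):
        raw = _sine_raw(5.0, fs=1000.0, dur=2.0)
        out = downsample(raw, PreprocConfig())
        assert out.n_samples == 500
        assert out.sampling_rate == 250.0

    def test_constant_signal_preserved(self):
        raw = RawRecording(np.full((2, 4000), 3.25), 1000.0, ("a", "b"))
        out = downsample(raw, PreprocConfig())
        mid = slice(50, -50)
        np.testing.assert_allclose(out.signal[:, mid], 3.25, rtol=1e-6)

    def test_sinusoid_matches_ideal_resampling(self):
        raw = _sine_raw(5.0, fs=1000.0, dur=10.0)
        out = downsample(raw, PreprocConfig())
        t = np.arange(out.n_samples) / 250.0
        ideal = np.sin(2 * np.pi * 5.0 * t)
        mid = slice(out.n_samples // 10, -out.n_samples // 10)
        rms_err = np.sqrt(np.mean((out.signal[0, mid] - ideal[mid]) ** 2))
        assert rms_err < 0.01 * np.sqrt(0.5)  # 1% of signal RMS

    def test_non_integer_ratio_rejected(self):
        raw = _sine_raw(5.0, fs=600.0, dur=2.0)
        with pytest.raises(ConfigurationError):
            downsample(raw, PreprocConfig())

    def test_unit_ratio_is_identity(self):
        raw = _sine_raw(5.0, fs=250.0, dur=2.0)
        out = downsample(raw, PreprocConfig())
        np.testing.assert_array_equal(out.signal, raw.signal)


class TestAssembly:
    def test_full_session_epoch_counts(self, full_aomi_epochs):
        """300-trial calibration session: 900 training epochs (300/class)
        and a separate 300-epoch feedback-free MI test set."""
        asm = full_aomi_epochs
        assert len(asm.train) == 900
        assert asm.train.class_counts() == {"left": 300, "right": 300, "rest": 300}
        assert len(asm.mi) == 300
        assert set(asm.mi.provenance["block_kind"]) == {BLOCK_MI}
        assert asm.train.n_samples == 500

    def test_mi_fb_session_epoch_counts(self, preproc_cfg):
        spec = SessionSpec(session_kind="mi_fb", n_trials=15,
                           sampling_rate=250.0, seed=3)
        raw, timeline, _ = generate_session(spec, ErdModel())
        asm = assemble_epochs(preprocess(raw, preproc_cfg), timeline, preproc_cfg)
        assert asm.mi is None
        assert len(asm.train) == 15
        assert sorted(asm.train.class_counts().values()) == [5, 5, 5]

    def test_short_task_block_skips_exactly_one_trial(self, preproc_cfg):
        fs = 250.0
        blocks, t = [], 0.0
        for i in range(5):
            blocks.append(Block(BLOCK_REST, t, 5.0)); t += 5.0
            dur = 1.0 if i == 2 else 3.0  # trial 2 too short for a 2-s epoch
            blocks.append(Block(BLOCK_MI_FB_TASK, t, dur, i % 3)); t += dur
        timeline = TrialTimeline(blocks=blocks)
        raw = RawRecording(np.random.default_rng(0).normal(size=(2, int(t * fs) + 1)),
                           fs, ("a", "b"))
        asm = assemble_epochs(raw, timeline, preproc_cfg)
        assert len(asm.train) == 4

    def test_epoch_counts_match_counting_oracle(self, preproc_cfg, rng):
        """Counts over randomized timelines (including too-short blocks)
        equal the direct counting rule."""
        fs = preproc_cfg.target_rate
        for trial_count in (3, 7, 12):
            blocks, t = [], 0.0
            for k in range(trial_count):
                for kind in (BLOCK_AO_MI, BLOCK_AO_MI, BLOCK_MI):
                    rest = float(rng.uniform(2.5, 7.0))
                    blocks.append(Block(BLOCK_REST, t, rest)); t += rest
                    dur = float(rng.choice([2.0, 2.0, 2.0, 1.2]))
                    blocks.append(Block(kind, t, dur, int(rng.integers(0, 2))))
                    t += dur
            timeline = TrialTimeline(blocks=blocks)
            raw = RawRecording(rng.normal(size=(3, int(t * fs) + 10)),
                               fs, ("x", "y", "z"))
            asm = assemble_epochs(raw, timeline, preproc_cfg)
            want_train, want_mi = count_expected_epochs(
                timeline, preproc_cfg.epoch_len_s, is_ao_mi=True
            )
            assert len(asm.train) == want_train
            assert len(asm.mi) == want_mi

    def test_wrong_rate_rejected(self, preproc_cfg, rng):
        raw = RawRecording(rng.normal(size=(2, 1000)), 1000.0, ("a", "b"))
        timeline = TrialTimeline([Block(BLOCK_REST, 0.0, 5.0)])
        with pytest.raises(ConfigurationError):
            assemble_epochs(raw, timeline, preproc_cfg)

    def test_filter_commutes_with_cutting_away_from_edges(self, preproc_cfg):
        """Zero-phase filtering the whole recording then cutting an interior
        epoch equals filtering a generously padded segment then trimming."""
        rng = np.random.default_rng(1)
        fs = 1000.0
        raw = RawRecording(rng.normal(size=(2, int(40 * fs))), fs, ("a", "b"))
        full = bandpass(raw, preproc_cfg)
        t0, t1 = 18.0, 20.0
        cut_after = full.signal[:, int(t0 * fs) : int(t1 * fs)]
        pad = 6.0
        segment = RawRecording(
            raw.signal[:, int((t0 - pad) * fs) : int((t1 + pad) * fs)],
            fs, raw.channel_labels,
        )
        seg_f = bandpass(segment, preproc_cfg)
        cut_before = seg_f.signal[:, int(pad * fs) : int((pad + (t1 - t0)) * fs)]
        rms = np.sqrt(np.mean((cut_after - cut_before) ** 2))
        assert rms < 1e-6 * np.sqrt(np.mean(cut_after**2)) + 1e-9


class TestTaskEpochExtraction:
    def test_window_with_context(self, small_aomi, preproc_cfg):
        raw, timeline, _ = small_aomi
        prep = preprocess(raw, preproc_cfg)
        ep = extract_task_epochs(prep, timeline, window=(-2.0, 2.0))
        assert ep.n_samples == 1000
        assert ep.epoch_window == (-2.0, 2.0)
        assert len(ep) == 60  # 3 task blocks per trial

    def test_empty_window_rejected(self, small_aomi, preproc_cfg):
        raw, timeline, _ = small_aomi
        with pytest.raises(ConfigurationError):
            extract_task_epochs(preprocess(raw, preproc_cfg), timeline,
                                window=(1.0, 1.0))

    def test_out_of_range_window_drops_or_errors(self, preproc_cfg, rng):
        fs = preproc_cfg.target_rate
        timeline = TrialTimeline(
            [Block(BLOCK_REST, 0.0, 0.5), Block(BLOCK_MI_FB_TASK, 0.5, 3.0, 0)]
        )
        raw = RawRecording(rng.normal(size=(2, int(4 * fs))), fs, ("a", "b"))
        with pytest.raises(DataError):
            extract_task_epochs(raw, timeline, window=(-2.0, 2.0))
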