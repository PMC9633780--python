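"""Planted-code generator: superposition, drift geometry, determinism."""

import numpy as np
import pytest

from phonoseq.lexicon import annotate_stream
from phonoseq.simulate import (
    Recording,
    SensorLayout,
    SimulationConfig,
    default_layout,
    make_code,
    read_recording,
    sample_stream,
    simulate_audio_branch,
    simulate_recording,
    write_recording,
)


class TestLayout:
    def test_default_layout_on_unit_disc(self):
        lay = default_layout(208)
        assert lay.n_channels == 208
        assert np.all(np.linalg.norm(lay.coords, axis=1) <= 1 + 1e-9)

    def test_rejects_bad_coordinates(self):
        with pytest.raises(ValueError):
            SensorLayout(np.array([[0.0, np.inf], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            SensorLayout(np.array([[0.0, 0.0]]))


class TestCode:
    def test_static_limit_patterns_identical(self):
        code = make_code(default_layout(32), ["a"], 0.0, np.random.default_rng(0))
        p = code.patterns(np.array([0.0, 0.1, 0.25]))
        assert np.allclose(p[:, :, 0], p[:, :, 1])
        assert np.allclose(p[:, :, 0], p[:, :, 2])

    def test_drift_decorrelates_within_80ms(self):
        # the dynamic preset: quarter rotation (on average) by 40 ms
        code = make_code(default_layout(208), ["a"], 6.25, np.random.default_rng(1))
        p = code.patterns(np.array([0.0, 0.08]))
        r = np.corrcoef(p[0, :, 0], p[0, :, 1])[0, 1]
        assert r < 0.5

    def test_drift_is_smooth_and_norm_preserving(self):
        code = make_code(default_layout(64), ["a"], 6.25, np.random.default_rng(2))
        taus = np.arange(0, 0.3, 0.004)
        p = code.patterns(taus)[0]
        norms = np.linalg.norm(p, axis=0)
        assert np.allclose(norms, 1.0)
        step_corr = [np.corrcoef(p[:, k], p[:, k + 1])[0, 1] for k in range(p.shape[1] - 1)]
        assert min(step_corr) > 0.95  # adjacent 4 ms patterns nearly identical

    def test_feature_patterns_nearly_orthogonal(self):
        code = make_code(default_layout(208), ["a", "b"], 0.0, np.random.default_rng(3))
        r = np.corrcoef(code.base[0], code.base[1])[0, 1]
        assert abs(r) < 0.2

    def test_fewer_channels_than_features_raises(self):
        with pytest.raises(ValueError, match="fewer channels"):
            make_code(default_layout(2), ["a", "b", "c"], 0.0, np.random.default_rng(0))


class TestStream:
    def test_single_word_contiguous(self, toy_lex):
        cfg = SimulationConfig()
        events, words = sample_stream(toy_lex, 1, cfg, np.random.default_rng(0))
        assert len(words) == 1
        seq = toy_lex.entries[words[0]].phonemes
        assert len(events) == len(seq)
        for a, b in zip(events, events[1:]):
            assert b.onset == pytest.approx(a.onset + a.duration)

    def test_duration_distribution_mean(self, toy_lex):
        cfg = SimulationConfig()
        rng = np.random.default_rng(1)
        events, _ = sample_stream(toy_lex, 3500, cfg, rng)
        durs = np.array([e.duration for e in events])
        assert len(durs) > 10_000
        assert abs(durs.mean() - 0.078) < 0.002
        assert durs.min() >= cfg.duration_min

    def test_seed_reproducibility(self, toy_lex):
        cfg = SimulationConfig()
        e1, w1 = sample_stream(toy_lex, 30, cfg, np.random.default_rng(7))
        e2, w2 = sample_stream(toy_lex, 30, cfg, np.random.default_rng(7))
        assert w1 == w2
        assert e1 == e2

    def test_invalid_word_count(self, toy_lex):
        with pytest.raises(ValueError):
            sample_stream(toy_lex, 0, SimulationConfig(), np.random.default_rng(0))


class TestRecording:
    @pytest.fixture(scope="class")
    def one_word(self, toy_lex, feature_table):
        cfg = SimulationConfig(snr=None, confound_gain=0.0)
        events, _ = sample_stream(toy_lex, 1, cfg, np.random.default_rng(5))
        ann = annotate_stream(events, toy_lex, feature_table)
        return events, ann, cfg

    def test_single_event_equals_weighted_template(self, one_word):
        events, ann, cfg = one_word
        ev, ann1 = [events[0]], ann.iloc[:1]
        code = make_code(default_layout(16), ["voicing", "plosive"], 0.0,
                         np.random.default_rng(0))
        rec = simulate_recording(ev, ann1, code, cfg, np.random.default_rng(0))
        W = code.tensor(cfg.fs)
        expected = np.tensordot(ann1[["voicing", "plosive"]].to_numpy()[0], W, axes=(0, 0))
        i0 = int(round(ev[0].onset * cfg.fs))
        np.testing.assert_allclose(rec.data[:, i0 : i0 + W.shape[2]], expected, atol=1e-12)

    def test_superposition_of_two_events(self, toy_lex, feature_table):
        # linearity oracle: two events 80 ms apart = sum of shifted singles
        from phonoseq.lexicon import PhonemeEvent

        cfg = SimulationConfig(snr=None, confound_gain=0.0)
        code = make_code(default_layout(16), ["voicing", "plosive"], 6.25,
                         np.random.default_rng(1))
        ev_b = PhonemeEvent("b", 0.1, 0.08, 0, "back", 1, -3)
        ev_ae = PhonemeEvent("ae", 0.18, 0.08, 0, "back", 2, -2)
        ev_k = PhonemeEvent("k", 0.26, 0.08, 0, "back", 3, -1)
        ann = annotate_stream([ev_b, ev_ae, ev_k], toy_lex, feature_table)
        both = simulate_recording([ev_b, ev_ae], ann.iloc[:2], code, cfg,
                                  np.random.default_rng(0), duration=1.0)
        a = simulate_recording([ev_b], ann.iloc[:1], code, cfg,
                               np.random.default_rng(0), duration=1.0)
        b = simulate_recording([ev_ae], ann.iloc[1:2], code, cfg,
                               np.random.default_rng(0), duration=1.0)
        np.testing.assert_allclose(both.data, a.data + b.data, atol=1e-12)

    def test_snr_zero_is_noise_only(self, toy_lex, feature_table):
        cfg = SimulationConfig(snr=0.0, confound_gain=0.0)
        events, _ = sample_stream(toy_lex, 60, cfg, np.random.default_rng(2))
        ann = annotate_stream(events, toy_lex, feature_table)
        code = make_code(default_layout(16), ["voicing"], 0.0, np.random.default_rng(2))
        rec = simulate_recording(events, ann, code, cfg, np.random.default_rng(2))
        # correlate each channel with the planted pattern time-locked signal
        clean = simulate_recording(events, ann, code,
                                   SimulationConfig(snr=None, confound_gain=0.0),
                                   np.random.default_rng(2),
                                   duration=rec.n_samples / cfg.fs)
        r = np.corrcoef(rec.data.ravel(), clean.data.ravel())[0, 1]
        assert abs(r) < 0.05

    def test_events_past_duration_raise(self, one_word):
        events, ann, cfg = one_word
        code = make_code(default_layout(8), ["voicing"], 0.0, np.random.default_rng(0))
        with pytest.raises(ValueError, match="extend past"):
            simulate_recording(events, ann, code, cfg, np.random.default_rng(0),
                               duration=0.01)

    def test_bit_identical_under_same_seed(self, toy_lex, feature_table):
        cfg = SimulationConfig(snr=1.0)
        events, _ = sample_stream(toy_lex, 20, cfg, np.random.default_rng(9))
        ann = annotate_stream(events, toy_lex, feature_table)
        code = make_code(default_layout(12), ["voicing"], 6.25, np.random.default_rng(4))
        r1 = simulate_recording(events, ann, code, cfg, np.random.default_rng(11))
        r2 = simulate_recording(events, ann, code, cfg, np.random.default_rng(11))
        np.testing.assert_array_equal(r1.data, r2.data)

    def test_hdf5_roundtrip(self, tmp_path, toy_lex, feature_table):
        cfg = SimulationConfig(snr=1.0, seed=42)
        events, _ = sample_stream(toy_lex, 5, cfg, np.random.default_rng(0))
        ann = annotate_stream(events, toy_lex, feature_table)
        code = make_code(default_layout(8), ["voicing"], 0.0, np.random.default_rng(0))
        rec = simulate_recording(events, ann, code, cfg, np.random.default_rng(0))
        rec.layout = default_layout(8)
        path = tmp_path / "rec.h5"
        write_recording(rec, path)
        back = read_recording(path)
        np.testing.assert_array_equal(back.data, rec.data)
        assert back.fs == rec.fs and back.seed == 42


class TestAudioBranch:
    def test_static_pattern_confined_to_phoneme_extent(self, toy_lex, feature_table):
        from phonoseq.lexicon import PhonemeEvent

        ev = [PhonemeEvent("b", 0.1, 0.08, 0, "back", 1, -3)]
        # complete the word for annotation purposes, then simulate only 'b'
        evs = ev + [PhonemeEvent("ae", 0.18, 0.08, 0, "back", 2, -2),
                    PhonemeEvent("k", 0.26, 0.08, 0, "back", 3, -1)]
        ann = annotate_stream(evs, toy_lex, feature_table)
        rec = simulate_audio_branch(ev, ann.iloc[:1], np.random.default_rng(0),
                                    n_bands=16,
                                    config=SimulationConfig(snr=None))
        fs = rec.fs
        i0, i1 = int(0.1 * fs), int(0.18 * fs)
        inside = rec.data[:, i0:i1]
        # pattern is constant across the phoneme's extent (static code)
        np.testing.assert_allclose(inside - inside[:, :1], 0, atol=1e-12)
        assert np.abs(inside).max() > 0
        # and silent outside it
        assert np.abs(rec.data[:, : i0 - 1]).max() == 0
        assert np.abs(rec.data[:, i1 + 1 :]).max() == 0
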