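"""Temporal generalisation: geometry of static vs dynamic codes."""

import numpy as np
import pandas as pd
import pytest

from phonoseq.b2b import b2b_timecourse
from phonoseq.preprocess import EpochSet
from phonoseq.tempgen import (
    align_to_word_clock,
    diag_vs_rows,
    generalize_across_positions,
    overlap_fraction,
    pairwise_overlap,
    ridge_angle,
    subset_compare,
    subset_masks,
    tg_fit_eval,
)


class TestFitEval:
    def test_diagonal_equals_b2b_timecourse(self, planted_study):
        epochs, Y, _, _, _ = planted_study(0.0, seed=42, n_words=60, n_channels=12)
        # restrict to a short window to keep the grid small
        sub = EpochSet(X=epochs.X[:, :, 40:81], times=epochs.times[40:81], fs=epochs.fs)
        tg = tg_fit_eval(sub, Y, n_splits=3, seed=9)
        res = b2b_timecourse(sub, Y, n_splits=3, seed=9)
        np.testing.assert_allclose(
            np.diagonal(tg.surface()), res.beta.mean(axis=0), atol=1e-10
        )

    def test_square_axes_match_epoch_times(self, planted_study):
        epochs, Y, _, _, _ = planted_study(0.0, seed=42, n_words=60, n_channels=12)
        tg = tg_fit_eval(epochs, Y, n_splits=1, seed=0, decim=10)
        assert tg.surface().shape[0] == tg.surface().shape[1]
        np.testing.assert_array_equal(tg.times_train, tg.times_test)
        np.testing.assert_array_equal(tg.times_train, epochs.times[::10])

    def test_noise_input_has_no_suprathreshold_structure(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 8, 31))
        ep = EpochSet(X=X, times=np.arange(31) / 250.0, fs=250.0)
        Y = rng.choice([-1.0, 1.0], size=(80, 2))
        tg = tg_fit_eval(ep, Y, n_splits=4, seed=1, decim=2)
        surf = tg.surface()
        # null betas fluctuate around zero: no cell clears a generous margin
        assert np.abs(surf).max() < 0.25
        assert abs(surf.mean()) < 0.02


class TestDissociation:
    """A static planted code yields a square TG surface (rows as long as the
    diagonal); a code drifting every ~80 ms yields a narrow diagonal."""

    def test_static_code_square(self, tg_group_study):
        tmaps, times = tg_group_study(0.0)
        st = diag_vs_rows(_as_tg(tmaps["all"], times), 4.0, surface=tmaps["all"])
        assert st.diag_duration_ms > 150
        assert st.ratio > 0.8

    def test_dynamic_code_diagonal(self, tg_group_study):
        tmaps, times = tg_group_study(6.25)
        st = diag_vs_rows(_as_tg(tmaps["all"], times), 4.0, surface=tmaps["all"])
        assert st.diag_duration_ms > 150
        assert st.ratio < 0.4
        # the planted 80 ms drift: each decoder informative for 60-100 ms
        assert 60 <= st.mean_row_duration_ms <= 100

    def test_empty_surface_flagged(self):
        tg = _as_tg(np.zeros((20, 20)), np.arange(20) / 250.0)
        st = diag_vs_rows(tg, 1.0)
        assert st.diag_duration_ms == 0 and np.isnan(st.t)


def _as_tg(surface, times):
    from phonoseq.tempgen import TGMatrix

    return TGMatrix(surface[None], times, times, ["avg"])


class TestPositionGeneralisation:
    def _epochs_with_positions(self, shared_pattern, rng, n=360, C=12, T=9):
        """Synthetic epochs where the code either shares or splits patterns
        across phoneme positions."""
        pos = rng.integers(1, 3, size=n)  # positions 1 and 2
        y = rng.choice([-1.0, 1.0], n)
        p1 = rng.standard_normal(C)
        p2 = p1 if shared_pattern else rng.standard_normal(C)
        pat = np.where(pos[:, None] == 1, p1, p2)
        X = np.repeat((y[:, None] * pat)[:, :, None], T, axis=2)
        X = X + 0.5 * rng.standard_normal((n, C, T))
        ep = EpochSet(X=X, times=np.arange(T) / 250.0, fs=250.0)
        ann = pd.DataFrame({"pos_from_onset": pos,
                            "pos_from_offset": pos - 3})
        return ep, y[:, None], ann

    def test_invariant_code_generalises(self):
        rng = np.random.default_rng(11)
        ep, Y, ann = self._epochs_with_positions(True, rng)
        curves, _ = generalize_across_positions(
            ep, Y, ann, train_group="P1", test_groups=("P2",), n_splits=8, seed=0)
        within = curves["P1"].mean()
        cross = curves["P2"].mean()
        assert within > 0.2
        assert cross > 0.6 * within

    def test_position_specific_code_fails_to_generalise(self):
        rng = np.random.default_rng(12)
        ep, Y, ann = self._epochs_with_positions(False, rng)
        curves, _ = generalize_across_positions(
            ep, Y, ann, train_group="P1", test_groups=("P2",), n_splits=8, seed=0)
        assert curves["P1"].mean() > 0.2
        assert abs(curves["P2"].mean()) < 0.3 * curves["P1"].mean()

    def test_empty_group_raises(self):
        rng = np.random.default_rng(13)
        ep, Y, ann = self._epochs_with_positions(True, rng)
        with pytest.raises(ValueError, match="empty group: P-5"):
            generalize_across_positions(ep, Y, ann, test_groups=("P-5",), n_splits=1)


class TestWordClock:
    def _fake_tgs(self, labels, T=20):
        surf = np.zeros((T, T))
        times = np.arange(T) * 0.02 - 0.1
        return {l: _as_tg(surf, times) for l in labels}

    def test_p1_unshifted_p3_plus_160(self):
        comp = align_to_word_clock(self._fake_tgs(["P1", "P2", "P3"]), step_ms=80)
        assert comp.shifts_ms["P1"] == 0
        assert comp.shifts_ms["P2"] == 80
        assert comp.shifts_ms["P3"] == 160

    def test_negative_positions_align_backwards_from_offset(self):
        comp = align_to_word_clock(
            self._fake_tgs(["P1", "P2", "P3", "P4", "P-1", "P-2"]), step_ms=80)
        # 4-phoneme word clock: P-1 coincides with P4
        assert comp.shifts_ms["P-1"] == comp.shifts_ms["P4"] == 240
        assert comp.shifts_ms["P-2"] == 160

    def test_surface_placement_preserves_values(self):
        tgs = self._fake_tgs(["P1", "P2"], T=10)
        tgs["P2"].scores[0, 3, 4] = 7.0
        comp = align_to_word_clock(tgs, step_ms=80)
        k0 = int(round(0.08 / 0.02))
        assert comp.surfaces["P2"][3, 4 + k0] == 7.0
        assert np.isnan(comp.surfaces["P1"][0, -1])  # beyond P1's support

    def test_invalid_step_raises(self):
        with pytest.raises(ValueError):
            align_to_word_clock(self._fake_tgs(["P1"]), step_ms=0)


class TestOverlap:
    def test_identical_masks_full_overlap(self):
        times = np.arange(30) / 250.0
        surf = np.zeros((30, 30))
        surf[10:20, 10:20] = 10.0
        # identical aligned masks (same shift) share every cell
        from phonoseq.tempgen import WordClockComposite

        comp = WordClockComposite({"P1": surf, "P2": surf.copy()},
                                  times, times, {"P1": 0.0, "P2": 0.0})
        stats = overlap_fraction(comp, t_threshold=4.0)
        assert stats.overall_pct == 100.0

    def test_disjoint_diagonals_zero_overlap(self):
        from phonoseq.tempgen import WordClockComposite

        times = np.arange(30) / 250.0
        a, b = np.zeros((30, 30)), np.zeros((30, 30))
        np.fill_diagonal(a, 10.0)
        b[np.arange(15), np.arange(15) + 15] = 10.0
        comp = WordClockComposite({"P1": a, "P2": b}, times, times,
                                  {"P1": 0.0, "P2": 80.0})
        assert overlap_fraction(comp, 4.0).overall_pct == 0.0

    def test_pairwise_overlap_symmetric_and_bounded(self):
        rng = np.random.default_rng(5)
        a = rng.random((20, 20)) > 0.7
        b = rng.random((20, 20)) > 0.7
        assert pairwise_overlap(a, b) == pairwise_overlap(b, a)
        assert 0 <= pairwise_overlap(a, b) <= 100

    def test_static_high_dynamic_low(self, tg_group_study):
        """Cross-position overlap dissociates static from dynamic codes.

        Interior positions of a static code share nearly all suprathreshold
        cells with their neighbours; a dynamic code's shifted diagonals are
        disjoint.  (With only four word positions at desk scale, the overall
        average is capped by the two edge positions, so the dissociation is
        asserted on the interior variant.)"""
        results = {}
        for drift, name in [(0.0, "static"), (6.25, "dynamic")]:
            tmaps, times = tg_group_study(drift)
            pos = {k: tmaps[k] for k in ("P1", "P2", "P3", "P4")}
            comp = align_to_word_clock(pos, step_ms=80, times=times)
            results[name] = overlap_fraction(comp, t_threshold=4.0)
        assert results["static"].inner_pct > 80
        assert results["dynamic"].inner_pct < 20
        assert results["static"].overall_pct > 3 * results["dynamic"].overall_pct + 50


class TestRidgeAngle:
    def _band_mask(self, T, slope, width=2):
        mask = np.zeros((T, T), bool)
        for i in range(T):
            j = int(round(i / slope))
            for w in range(-width, width + 1):
                if 0 <= j + w < T:
                    mask[i, j + w] = True
        return mask

    def test_diagonal_ridge_is_45_degrees(self):
        t = np.arange(60) / 250.0
        assert ridge_angle(self._band_mask(60, 1.0), t, t) == pytest.approx(45, abs=1.5)

    def test_double_speed_test_dynamics_about_27_degrees(self):
        # test axis moves twice as fast as train: slope 1/2 -> arctan(1/2)
        t = np.arange(60) / 250.0
        ang = ridge_angle(self._band_mask(60, 0.5), t, t)
        assert ang == pytest.approx(np.degrees(np.arctan(0.5)), abs=2.0)

    def test_horizontal_ridge_tends_to_zero(self):
        mask = np.zeros((40, 40), bool)
        mask[19:21, :] = True
        t = np.arange(40) / 250.0
        assert ridge_angle(mask, t, t) < 5

    def test_translation_invariance(self):
        t = np.arange(80) / 250.0
        m = np.zeros((80, 80), bool)
        m[10:40, 10:40]
        base = self._band_mask(80, 1.0)
        shifted = np.roll(base, 15, axis=1)
        shifted[:, :15] = False
        a1 = ridge_angle(base, t, t)
        a2 = ridge_angle(shifted[:60], t[:60], t)
        assert a1 == pytest.approx(a2, abs=1.5)

    def test_too_few_cells_raises(self):
        t = np.arange(20) / 250.0
        with pytest.raises(ValueError, match="degenerate ridge"):
            ridge_angle(np.zeros((20, 20), bool), t, t)


class TestSubsets:
    def test_subset_masks_cover_expected_bins(self, planted_study):
        _, _, ann, _, _ = planted_study(0.0, seed=42, n_words=60, n_channels=12)
        q = subset_masks(ann, "duration_quartiles")
        assert set(q) == {"short", "long"}
        assert ann["duration_s"][q["short"]].mean() < ann["duration_s"][q["long"]].mean()
        s = subset_masks(ann, "surprisal_median")
        assert not (ann["pos_from_onset"][s["low"] | s["high"]] == 1).any()
        w = subset_masks(ann, "word_length_median")
        assert (ann["pos_from_onset"][w["short_words"] | w["long_words"]] == 1).all()

    def test_duration_scaled_drift_longer_generalisation_for_long_phonemes(
        self, planted_study
    ):
        """With the drift clock running in units of phoneme duration, long
        phonemes evolve their pattern more slowly, so temporal decoders
        generalise longer for the long-duration bin."""
        epochs, Y, ann, _, _ = planted_study(
            6.25, seed=77, n_words=200, n_channels=24, duration_scaled=True)
        tgs = subset_compare(epochs, Y, ann, "duration_quartiles",
                             n_splits=3, seed=0, decim=4)
        rows = {}
        for name, tg in tgs.items():
            surf = tg.surface()
            thr = 0.5 * np.diagonal(surf).max()
            rows[name] = diag_vs_rows(tg, thr).mean_row_duration_ms
        assert rows["long"] > rows["short"]

    def test_latency_shifted_responses_separate_bins(self, planted_study):
        """If one bin's responses are delayed, its suprathreshold diagonal
        onset comes later (mirrors the surprisal latency shift)."""
        epochs, Y, ann, _, _ = planted_study(0.0, seed=42, n_words=120, n_channels=24)
        masks = subset_masks(ann, "surprisal_median")
        X = epochs.X.copy()
        shift = 6  # 24 ms delay for the high-surprisal bin
        X[masks["high"]] = np.roll(X[masks["high"]], shift, axis=2)
        ep2 = EpochSet(X=X, times=epochs.times, fs=epochs.fs)
        tgs = subset_compare(ep2, Y, ann, "surprisal_median",
                             n_splits=4, seed=0, decim=2)
        onsets = {}
        for name, tg in tgs.items():
            d = np.diagonal(tg.surface())
            thr = 0.5 * d.max()
            onsets[name] = tg.times_train[np.argmax(d > thr)]
        assert onsets["high"] > onsets["low"]

    def test_empty_bin_raises(self, planted_study):
        epochs, Y, ann, _, _ = planted_study(0.0, seed=42, n_words=60, n_channels=12)
        ann2 = ann.copy()
        ann2["duration_s"] = 0.08  # constant durations: quartile bins coincide
        q = subset_masks(ann2, "duration_quartiles")
        assert q["short"].all() and q["long"].all()  # degenerate but non-empty
        ann3 = ann.copy()
        ann3 = ann3.assign(pos_from_onset=1)
        with pytest.raises(ValueError, match="empty bin"):
            subset_compare(epochs, Y, ann3, "surprisal_median", n_splits=1)
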