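"""Cohort statistics, feature coding and stream annotation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phonoseq.lexicon import (
    ANNOTATION_FEATURES,
    PHONETIC_FEATURES,
    Lexicon,
    WordEntry,
    annotate_stream,
    build_feature_table,
    cohort_entropy,
    cohort_of,
    continuation_probability,
    lag_features,
    surprisal,
    toy_lexicon,
)
from phonoseq.simulate import SimulationConfig, sample_stream


@pytest.fixture(scope="module")
def kat_lexicon():
    return Lexicon({
        "kaet": WordEntry(("k", "ae", "t"), 2),
        "kaeb": WordEntry(("k", "ae", "b"), 1),
        "daog": WordEntry(("d", "ao", "g"), 1),
    })


class TestFeatureTable:
    def test_voicing_contrast_b_vs_p(self):
        ft = build_feature_table(["b", "p"])
        b, p = ft.row("b"), ft.row("p")
        names = dict(zip(PHONETIC_FEATURES, b))
        assert names["voicing"] == 1 and names["plosive"] == 1 and names["labial"] == 1
        assert all(names[f] == 0 for f in
                   ("vowel", "vowel_central", "vowel_low", "vowel_mid", "vowel_high"))
        # p differs from b only in voicing
        diff = np.flatnonzero(b != p)
        assert list(diff) == [PHONETIC_FEATURES.index("voicing")]

    def test_uncovered_symbol_is_named(self):
        with pytest.raises(ValueError, match="uncovered inventory.*'q'"):
            build_feature_table(["b", "q"])

    def test_exactly_14_dimensions_and_place_exclusivity(self, feature_table):
        t = feature_table.table
        assert t.shape[1] == 14
        vowels = t["vowel"] == 1
        assert t.loc[vowels, ["coronal", "glottal", "labial", "velar"]].sum().sum() == 0
        assert t.loc[~vowels, ["vowel_central", "vowel_low", "vowel_mid", "vowel_high"]].sum().sum() == 0


class TestCohorts:
    def test_prefix_matching(self, kat_lexicon):
        assert set(cohort_of(("k", "ae"), kat_lexicon)) == {"kaet", "kaeb"}
        assert set(cohort_of(("d", "ao", "g"), kat_lexicon)) == {"daog"}
        assert cohort_of(("z",), kat_lexicon) == {}

    def test_continuation_probability(self, kat_lexicon):
        assert continuation_probability(("k", "ae"), "t", kat_lexicon) == pytest.approx(2 / 3)
        assert continuation_probability(("d",), "ao", kat_lexicon) == 1.0
        assert continuation_probability(("k", "ae"), "z", kat_lexicon) == 0.0

    def test_empty_cohort_raises(self, kat_lexicon):
        with pytest.raises(ValueError, match="undefined cohort"):
            continuation_probability(("z",), "a", kat_lexicon)
        with pytest.raises(ValueError, match="undefined cohort"):
            cohort_entropy(("z",), kat_lexicon)

    def test_surprisal_values(self, kat_lexicon):
        assert surprisal(("d",), "ao", kat_lexicon) == 0.0
        assert surprisal(("k", "ae"), "t", kat_lexicon) == pytest.approx(-math.log2(2 / 3))
        with pytest.raises(ValueError, match="zero-probability"):
            surprisal(("k", "ae"), "z", kat_lexicon)

    def test_entropy_values(self, kat_lexicon):
        assert cohort_entropy(("d",), kat_lexicon) == 0.0
        assert cohort_entropy(("k", "ae"), kat_lexicon) == pytest.approx(0.9182958, abs=1e-6)
        uniform = Lexicon({f"w{i}": WordEntry(("a", str(i)), 1) for i in range(4)})
        assert cohort_entropy(("a",), uniform) == pytest.approx(2.0)

    def test_continuations_sum_to_one_and_entropy_matches_bruteforce(self, toy_lex):
        # property over all word-internal prefixes of the toy lexicon
        for word, entry in toy_lex.entries.items():
            for k in range(1, len(entry.phonemes)):
                prefix = entry.phonemes[:k]
                cohort = cohort_of(prefix, toy_lex)
                nexts = {toy_lex.entries[w].phonemes[k]
                         for w in cohort if len(toy_lex.entries[w].phonemes) > k}
                total = sum(continuation_probability(prefix, p, toy_lex) for p in nexts)
                ended = sum(f for w, f in cohort.items()
                            if len(toy_lex.entries[w].phonemes) == k)
                expected = 1.0 - ended / sum(cohort.values())
                assert total == pytest.approx(expected, abs=1e-12)
                # brute-force entropy oracle
                tot = sum(cohort.values())
                ent = -sum((f / tot) * math.log2(f / tot) for f in cohort.values())
                assert cohort_entropy(prefix, toy_lex) == pytest.approx(ent, abs=1e-12)

    @given(freqs=st.lists(st.integers(1, 50), min_size=2, max_size=6))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_entropy_bounded_and_maximal_for_uniform(self, freqs):
        lex = Lexicon({f"w{i}": WordEntry(("a", str(i)), float(f))
                       for i, f in enumerate(freqs)})
        h = cohort_entropy(("a",), lex)
        n = len(freqs)
        assert 0 <= h <= math.log2(n) + 1e-12
        uni = Lexicon({f"w{i}": WordEntry(("a", str(i)), 1.0) for i in range(n)})
        assert h <= cohort_entropy(("a",), uni) + 1e-12

    def test_surprisal_decreases_as_cohort_shrinks(self):
        # rare word onset, then fully deterministic continuations: each
        # successive phoneme narrows the cohort and becomes more predictable
        lex = Lexicon({
            "abc": WordEntry(("a", "b", "c"), 1),
            "dd": WordEntry(("d", "d"), 9),
        })
        s1 = surprisal((), "a", lex)
        s2 = surprisal(("a",), "b", lex)
        s3 = surprisal(("a", "b"), "c", lex)
        assert s1 > s2 >= s3
        assert s2 == 0.0


class TestAnnotation:
    @pytest.fixture(scope="class")
    def stream(self, toy_lex, feature_table):
        rng = np.random.default_rng(3)
        events, _ = sample_stream(toy_lex, 40, SimulationConfig(), rng)
        return events, annotate_stream(events, toy_lex, feature_table)

    def test_31_columns_no_missing(self, stream):
        _, ann = stream
        assert len(ANNOTATION_FEATURES) == 31
        feat = ann[ANNOTATION_FEATURES]
        assert not feat.isna().any().any()

    def test_binary_columns_are_pm1(self, stream):
        _, ann = stream
        from phonoseq.lexicon import BOUNDARY_FEATURES

        for col in PHONETIC_FEATURES + BOUNDARY_FEATURES:
            assert set(np.unique(ann[col])) <= {-1.0, 1.0}, col

    def test_word_edges(self, stream):
        events, ann = stream
        first = ann[ann["pos_from_onset"] == 1]
        assert (first["word_onset"] == 1.0).all()
        last = ann[ann["pos_from_offset"] == -1]
        assert (last["word_offset"] == 1.0).all()
        # positional identity: pos_from_onset + |pos_from_offset| - 1 = word length
        assert (
            ann["pos_from_onset"] + ann["pos_from_offset"].abs() - 1
            == ann["word_length"]
        ).all()

    def test_deterministic(self, toy_lex, feature_table, stream):
        events, ann = stream
        again = annotate_stream(events, toy_lex, feature_table)
        assert ann.equals(again)

    def test_unknown_word_raises(self, feature_table, toy_lex):
        from phonoseq.lexicon import PhonemeEvent

        ev = [PhonemeEvent("k", 0.0, 0.05, 0, "notaword", 1, -1)]
        with pytest.raises(ValueError, match="notaword"):
            annotate_stream(ev, toy_lex, feature_table)


class TestLagFeatures:
    def test_lag_zero_is_identity(self, toy_lex, feature_table):
        rng = np.random.default_rng(4)
        events, _ = sample_stream(toy_lex, 10, SimulationConfig(), rng)
        ann = annotate_stream(events, toy_lex, feature_table)
        lagged = lag_features(ann, 0)
        assert lagged.shape[1] == 14
        np.testing.assert_array_equal(
            lagged.to_numpy(), ann[PHONETIC_FEATURES].to_numpy()
        )

    def test_history_three_gives_56_columns_and_padding(self, toy_lex, feature_table):
        rng = np.random.default_rng(4)
        events, _ = sample_stream(toy_lex, 10, SimulationConfig(), rng)
        ann = annotate_stream(events, toy_lex, feature_table)
        lagged = lag_features(ann, 3)
        assert lagged.shape[1] == 56
        # first rows: missing history is padded with the 0 midpoint
        assert (lagged.iloc[0, 14:] == 0).all()
        assert (lagged.iloc[2, 42:] == 0).all()
        # lag-1 of row 1 equals phonetics of row 0
        np.testing.assert_array_equal(
            lagged.iloc[1, 14:28].to_numpy(), ann.iloc[0][PHONETIC_FEATURES].to_numpy()
        )

    def test_short_stream_padding(self, toy_lex, feature_table):
        from phonoseq.lexicon import PhonemeEvent

        events = [
            PhonemeEvent("g", 0.0, 0.08, 0, "go", 1, -2),
            PhonemeEvent("ow", 0.08, 0.08, 0, "go", 2, -1),
        ]
        ann = annotate_stream(events, toy_lex, feature_table)
        lagged = lag_features(ann, 3)
        assert (lagged.iloc[1, 28:] == 0).all()  # lag-2, lag-3 padded

    def test_negative_history_raises(self, toy_lex, feature_table):
        rng = np.random.default_rng(4)
        events, _ = sample_stream(toy_lex, 5, SimulationConfig(), rng)
        ann = annotate_stream(events, toy_lex, feature_table)
        with pytest.raises(ValueError):
            lag_features(ann, -1)
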