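"""Shared fixtures: small planted-code studies reused across test modules."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from phonoseq.lexicon import annotate_stream, build_feature_table, toy_lexicon
from phonoseq.preprocess import epoch_events
from phonoseq.simulate import (
    SimulationConfig,
    default_layout,
    make_code,
    sample_stream,
    simulate_recording,
)

CODE_FEATURES = ["voicing", "plosive"]


@lru_cache(maxsize=16)
def _planted_study(drift_rate, seed, n_words, n_channels, snr, duration_scaled,
                   features="phonetic", min_word_len=1):
    """Generate a small synthetic study and epoch it (cached per session).

    ``features="phonetic"`` plants the code on voicing/plosive;
    ``features="random"`` plants it on two i.i.d. ±1 labels drawn per event,
    which guarantees feature variance at every phoneme position (the strict
    consonant-vowel structure of the toy lexicon makes e.g. voicing constant
    among position-2 phonemes, which are almost all vowels).
    """
    lex = toy_lexicon()
    if min_word_len > 1:
        from phonoseq.lexicon import Lexicon

        lex = Lexicon({w: e for w, e in lex.entries.items()
                       if len(e.phonemes) >= min_word_len})
    ftable = build_feature_table(lex.inventory())
    cfg = SimulationConfig(snr=snr, confound_gain=0.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    events, _ = sample_stream(lex, n_words, cfg, rng)
    ann = annotate_stream(events, lex, ftable)
    if features == "random":
        names = ["featA", "featB"]
        for name in names:
            ann[name] = rng.choice([-1.0, 1.0], size=len(ann))
    else:
        names = CODE_FEATURES
    layout = default_layout(n_channels)
    code = make_code(layout, names, drift_rate, rng)
    rec = simulate_recording(events, ann, code, cfg, rng,
                             duration_scaled_drift=duration_scaled)
    rec.layout = layout
    epochs = epoch_events(rec, ann["onset_s"].to_numpy())
    ann_kept = ann.iloc[epochs.annotation_index].reset_index(drop=True)
    Y = ann_kept[names].to_numpy()
    return epochs, Y, ann_kept, code, layout


@pytest.fixture(scope="session")
def planted_study():
    """Factory: (drift_rate, seed, ...) -> (epochs, Y, annotation, code, layout)."""

    def factory(drift_rate, seed=0, n_words=120, n_channels=24, snr=2.0,
                duration_scaled=False, features="phonetic", min_word_len=1):
        return _planted_study(drift_rate, seed, n_words, n_channels, snr,
                              duration_scaled, features, min_word_len)

    return factory


@lru_cache(maxsize=4)
def _tg_group_study(drift_rate, n_subjects=6, decim=4, n_splits=3, base_seed=1):
    """Group-level TG surfaces (overall + positions P1-P4) for one condition."""
    from phonoseq.tempgen import group_tmap, tg_fit_eval

    per_group: dict[str, list] = {}
    times = None
    for s in range(n_subjects):
        epochs, Y, ann, _, _ = _planted_study(
            drift_rate, 1000 * base_seed + s, 120, 24, 2.0, False, "random", 4
        )
        pos = ann["pos_from_onset"].to_numpy()
        groups = {"all": np.ones(len(pos), bool)}
        for k in (1, 2, 3, 4):
            groups[f"P{k}"] = pos == k
        tgs = tg_fit_eval(epochs, Y, n_splits=n_splits, seed=0, decim=decim,
                          eval_groups=groups)
        for name, tg in tgs.items():
            per_group.setdefault(name, []).append(tg.surface())
        times = tgs["all"].times_train
    tmaps = {name: group_tmap(surfs) for name, surfs in per_group.items()}
    return tmaps, times


@pytest.fixture(scope="session")
def tg_group_study():
    """Factory: drift_rate -> ({'all'/'P1'..'P4': t-map}, times)."""
    return _tg_group_study


@lru_cache(maxsize=2)
def _trajectory_group(drift_rate, n_subjects=5, seed=0):
    """Subjects sharing one planted code (same brain organisation), used for
    the group coefficient-trajectory analysis."""
    from phonoseq.lexicon import toy_lexicon

    lex = toy_lexicon()
    ftable = build_feature_table(lex.inventory())
    layout = default_layout(24)
    code = make_code(layout, CODE_FEATURES, drift_rate,
                     np.random.default_rng(np.random.SeedSequence([seed, 77])))
    cfg = SimulationConfig(snr=2.0, confound_gain=0.0)
    studies = []
    for s in range(n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 78, s]))
        events, _ = sample_stream(lex, 150, cfg, rng)
        ann = annotate_stream(events, lex, ftable)
        rec = simulate_recording(events, ann, code, cfg, rng)
        epochs = epoch_events(rec, ann["onset_s"].to_numpy())
        y = ann.iloc[epochs.annotation_index]["voicing"].to_numpy()
        studies.append((epochs, y))
    return studies, layout


@pytest.fixture(scope="session")
def trajectory_group():
    """Factory: drift_rate -> (list of (epochs, voicing labels), layout)."""
    return _trajectory_group


@pytest.fixture(scope="session")
def toy_lex():
    return toy_lexicon()


@pytest.fixture(scope="session")
def feature_table(toy_lex):
    return build_feature_table(toy_lex.inventory())
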