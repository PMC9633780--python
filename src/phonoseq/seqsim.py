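"""Anagram simulation: how much phoneme history does an instantaneous
response contain?

Responses to every ordering of a small phoneme set (b, p, s, z by default)
are synthesised from spatiotemporal coefficient templates — each phoneme's
feature vector (voicing, plosive) weights the templates, successive
phonemes are shifted by 100 ms and summed, so neighbouring responses
overlap exactly as in continuous speech.  Ridge regression then
reconstructs, from each phoneme-locked epoch, the feature vector of the
phoneme h steps back; cosine similarity between true and reconstructed
vectors quantifies how far back the history remains readable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

__all__ = [
    "AnagramSet",
    "enumerate_anagrams",
    "feature_values_for",
    "synthesize_sequence_responses",
    "reconstruct_history",
    "HistoryResult",
]

#: ±1 feature coding (voicing, plosive) for the default anagram phonemes.
DEFAULT_ANAGRAM_FEATURES = {
    "b": (1.0, 1.0),
    "p": (-1.0, 1.0),
    "s": (-1.0, -1.0),
    "z": (1.0, -1.0),
}


def enumerate_anagrams(phonemes=("b", "p", "s", "z")) -> list[tuple[str, ...]]:
    """All orderings of the phoneme set, lexicographically sorted.

    4 distinct phonemes yield the 24 unique sequences without repetition.
    """
    phonemes = tuple(phonemes)
    if len(set(phonemes)) != len(phonemes):
        raise ValueError("anagram phonemes must be distinct")
    return sorted(permutations(phonemes))


def feature_values_for(phonemes, features=("voicing", "plosive")) -> dict[str, np.ndarray]:
    """±1 feature vectors per phoneme, from the package's feature scheme."""
    from .lexicon import DEFAULT_FEATURE_SCHEME

    out = {}
    for ph in phonemes:
        if ph in DEFAULT_FEATURE_SCHEME:
            row = DEFAULT_FEATURE_SCHEME[ph]
            out[ph] = np.array([row[f] * 2.0 - 1.0 for f in features])
        elif ph in DEFAULT_ANAGRAM_FEATURES:
            out[ph] = np.asarray(DEFAULT_ANAGRAM_FEATURES[ph], dtype=float)
        else:
            raise ValueError(f"no feature values for phoneme {ph!r}")
    return out


@dataclass
class AnagramSet:
    """Configuration of the sequence-reconstruction simulation."""

    phonemes: tuple[str, ...] = ("b", "p", "s", "z")
    shift_ms: float = 100.0
    noise_sd: float = 0.1  # multiplicative noise factor SD; 0 = ideal conditions
    n_repetitions: int = 10
    sequences: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequences:
            self.sequences = enumerate_anagrams(self.phonemes)


def synthesize_sequence_responses(
    anagrams: AnagramSet,
    templates: np.ndarray,
    fs: float,
    feature_values: dict[str, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
):
    """Continuous responses to every anagram sequence.

    ``templates`` is (F, channels, L): one spatiotemporal coefficient
    template per feature.  Within a repetition the 24 sequences run back to
    back with a constant 100 ms (``shift_ms``) onset-to-onset spacing, so
    the history of a phoneme extends into the previous sequence ("previous
    word").  Each phoneme's contribution is its feature-weighted template,
    multiplied by a noise factor ~ Normal(1, noise_sd), placed at its onset;
    overlapping responses sum.

    Returns ``(data, onsets_s, labels)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    feature_values = feature_values or feature_values_for(anagrams.phonemes)
    F, C, L = templates.shape
    for ph in anagrams.phonemes:
        if len(feature_values[ph]) != F:
            raise ValueError(f"missing feature coefficients for phoneme {ph!r}")
    shift = int(round(anagrams.shift_ms / 1000 * fs))
    stream = [ph for _ in range(anagrams.n_repetitions)
              for seq in anagrams.sequences for ph in seq]
    n_samples = shift * len(stream) + L
    data = np.zeros((C, n_samples))
    onsets = np.arange(len(stream)) * shift
    for k, ph in enumerate(stream):
        factor = 1.0 if anagrams.noise_sd == 0 else rng.normal(1.0, anagrams.noise_sd)
        resp = np.tensordot(feature_values[ph] * factor, templates, axes=(0, 0))
        data[:, onsets[k] : onsets[k] + L] += resp
    return data, onsets / fs, stream


@dataclass
class HistoryResult:
    table: pd.DataFrame  # columns lag, cosine_similarity, p_value
    predictions: dict[int, np.ndarray]


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def reconstruct_history(
    data: np.ndarray,
    onsets_s: np.ndarray,
    labels,
    fs: float,
    max_history: int = 6,
    window_s: float | None = None,
    feature_values: dict[str, np.ndarray] | None = None,
    alpha: float = 1e-6,
    n_folds: int = 5,
    n_perm: int = 10_000,
    seed: int = 0,
) -> HistoryResult:
    """Reconstruct the feature vector of the phoneme h steps back, per lag.

    For each history lag h = 0 (current phoneme) .. ``max_history``, each
    phoneme-locked epoch (flattened channels x window) is regressed onto the
    feature vector of the phoneme h positions earlier in the stream with
    small-alpha ridge under shuffled 5-fold cross-validation.  Lags reaching
    past a sequence boundary resolve against the previous sequence; only the
    first h epochs of the whole stream are dropped.  The cosine similarity
    between the concatenated true and reconstructed vectors summarises each
    lag, with a label-shuffling permutation p-value (floor 1/(n_perm+1)).
    """
    feature_values = feature_values or feature_values_for(sorted(set(labels)))
    rng = np.random.default_rng(seed)
    C, N = data.shape
    onsets = np.round(np.asarray(onsets_s) * fs).astype(int)
    if window_s is None:
        win = int(np.min(np.diff(onsets))) * 3  # cover the template overlap span
    else:
        win = int(round(window_s * fs))
    valid = onsets + win <= N
    onsets, labels = onsets[valid], [l for l, v in zip(labels, valid) if v]
    epochs = np.stack([data[:, o : o + win].ravel() for o in onsets])
    Yall = np.stack([feature_values[l] for l in labels])

    rows, preds = [], {}
    for lag in range(max_history + 1):
        keep = np.arange(lag, len(onsets))
        X = epochs[keep]
        Y = Yall[keep - lag]
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        pred = np.empty_like(Y)
        for tr, te in kf.split(X):
            model = Ridge(alpha=alpha)
            model.fit(X[tr], Y[tr])
            pred[te] = model.predict(X[te])
        obs = _cosine(Y.ravel(), pred.ravel())
        # permutation null: shuffle which epoch carries which true vector
        flat_pred = pred.ravel()
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(Y))
            if _cosine(Y[perm].ravel(), flat_pred) >= obs:
                count += 1
        rows.append({
            "lag": lag,
            "cosine_similarity": obs,
            "p_value": (count + 1) / (n_perm + 1),
        })
        preds[lag] = pred
    return HistoryResult(pd.DataFrame(rows), preds)
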