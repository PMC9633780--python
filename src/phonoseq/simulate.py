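"""Synthetic multichannel recordings with planted phonetic-feature codes.

The generator is the test bed for the whole pipeline.  It emulates the
structure of phoneme-evoked sensor recordings:

* a phoneme stream sampled from a lexicon, with ~78 ms phonemes whose evoked
  responses last ~300 ms and therefore overlap across neighbours;
* a *planted code*: each binary phonetic feature is carried by a spatial
  channel pattern.  With ``drift_rate = 0`` the pattern is fixed over
  latency (a static code, as carried by an acoustic spectrogram); with a
  positive drift rate the pattern rotates smoothly through channel space as
  latency since phoneme onset grows (a dynamic code, which jointly encodes
  content and elapsed time);
* acoustic confounds (envelope and a pitch proxy) injected through their own
  spatial patterns, plus white sensor noise at a configurable SNR.

Superposition is exact: the recording is the linear sum of each phoneme's
response placed at its onset, so downstream decoders face genuinely
overlapping evoked responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

from .lexicon import (
    Lexicon,
    PhonemeEvent,
    build_feature_table,
    syllabify,
)

__all__ = [
    "SensorLayout",
    "SimulationConfig",
    "DynamicCode",
    "Recording",
    "default_layout",
    "make_code",
    "sample_stream",
    "simulate_recording",
    "simulate_audio_branch",
    "write_recording",
    "read_recording",
]


@dataclass(frozen=True)
class SensorLayout:
    """Sensor positions on the unit disc.

    ``coords`` is (n_channels, 2); x is the left/right axis (right positive),
    y the posterior/anterior axis (anterior positive).
    """

    coords: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 2:
            raise ValueError("layout requires an (n_channels >= 2, 2) coordinate array")
        if not np.isfinite(c).all():
            raise ValueError("layout coordinates must be finite")
        object.__setattr__(self, "coords", c)

    @property
    def n_channels(self) -> int:
        return self.coords.shape[0]

    def anterior_mask(self) -> np.ndarray:
        return (self.coords[:, 1] >= 0).astype(float)

    def right_mask(self) -> np.ndarray:
        return (self.coords[:, 0] >= 0).astype(float)


def default_layout(n_channels: int = 208) -> SensorLayout:
    """Deterministic sunflower (Fibonacci-spiral) layout on the unit disc."""
    k = np.arange(n_channels) + 0.5
    r = np.sqrt(k / n_channels)
    theta = np.pi * (1 + 5**0.5) * k
    return SensorLayout(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    ``snr`` is the amplitude ratio of the planted signal (scaled to the given
    RMS) against unit-variance white sensor noise.  ``snr=None`` disables
    noise entirely and leaves the signal unscaled (useful for exact oracle
    tests); ``snr=0`` yields pure noise.

    Phoneme durations are drawn from a normal(78 ms, 34 ms) truncated to
    [20, 136] ms; the symmetric truncation preserves the 78 ms mean.
    """

    fs: float = 1000.0
    fs_epoch: float = 250.0
    snr: float | None = 2.0
    duration_mean: float = 0.078
    duration_sd: float = 0.034
    duration_min: float = 0.020
    max_silence: float = 0.150
    response_window: float = 0.300
    confound_gain: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.fs <= 0 or self.fs_epoch <= 0:
            raise ValueError("sampling rates must be positive")

    @property
    def duration_max(self) -> float:
        # symmetric truncation about the mean
        return 2 * self.duration_mean - self.duration_min


@dataclass
class DynamicCode:
    """Per-feature spatial patterns that drift with latency since onset.

    The base pattern of each feature is a unit-norm random channel vector.
    Drift is a Givens-rotation cascade: channels are grouped into disjoint
    pairs, and at latency tau each pair-plane is rotated by the angle
    ``2*pi*drift_rate*pair_rate*tau``, where the per-plane ``pair_rates``
    are jittered uniformly in [0.5, 1.5] around 1.  The rotation is
    norm-preserving and smooth; the expected correlation between the
    pattern at latency 0 and latency tau is the mean of the plane cosines,
    which starts at ``cos(2*pi*drift_rate*tau)``-like decay, so
    ``drift_rate`` (rotations per second) sets the decorrelation time.  The
    rate jitter keeps the cascade from being exactly periodic — a single
    shared rate would make every pattern recur after a full rotation, which
    no evolving neural code does.  ``drift_rate = 0`` is the static limit:
    identical patterns at all latencies.

    The response amplitude envelope is a half-cosine rise/fall (Hann window)
    over ``response_window`` seconds.
    """

    feature_names: list[str]
    base: np.ndarray  # (F, C) unit-norm rows
    pairs: np.ndarray  # (P, 2) disjoint channel index pairs
    drift_rate: float  # rotations per second
    response_window: float = 0.300
    pair_rates: np.ndarray | None = None  # (P,) multipliers, default all 1

    @property
    def n_features(self) -> int:
        return self.base.shape[0]

    @property
    def n_channels(self) -> int:
        return self.base.shape[1]

    def envelope(self, taus: np.ndarray) -> np.ndarray:
        amp = np.sin(np.pi * np.clip(taus / self.response_window, 0, 1)) ** 2
        amp[(taus < 0) | (taus > self.response_window)] = 0.0
        return amp

    def patterns(self, taus, speed: float = 1.0) -> np.ndarray:
        """Unit-norm spatial patterns at the given latencies: (F, C, L).

        ``speed`` scales the drift clock (used for duration-scaled drift:
        speed < 1 means the pattern evolves more slowly).
        """
        taus = np.atleast_1d(np.asarray(taus, dtype=float))
        out = np.repeat(self.base[:, :, None], len(taus), axis=2)
        if self.drift_rate == 0 or len(self.pairs) == 0:
            return out
        rates = np.ones(len(self.pairs)) if self.pair_rates is None else self.pair_rates
        theta = 2 * np.pi * self.drift_rate * speed * np.outer(rates, taus)  # (P, L)
        c, s = np.cos(theta), np.sin(theta)
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        wi = self.base[:, i][:, :, None]  # (F, P, 1)
        wj = self.base[:, j][:, :, None]
        out[:, i, :] = wi * c[None] - wj * s[None]
        out[:, j, :] = wi * s[None] + wj * c[None]
        return out

    def tensor(self, fs: float, speed: float = 1.0) -> np.ndarray:
        """Amplitude-weighted response tensor W[f, channel, latency]."""
        taus = np.arange(0, self.response_window + 0.5 / fs, 1.0 / fs)
        return self.patterns(taus, speed=speed) * self.envelope(taus)[None, None, :]


def make_code(
    layout: SensorLayout,
    feature_names,
    drift_rate: float,
    rng: np.random.Generator,
    response_window: float = 0.300,
) -> DynamicCode:
    """Draw a planted code: random orthogonal-in-expectation feature patterns.

    Raises if there are fewer channels than features (patterns could not be
    linearly separated) or if ``drift_rate`` is negative.
    """
    feature_names = list(feature_names)
    n_f, n_c = len(feature_names), layout.n_channels
    if drift_rate < 0:
        raise ValueError("drift_rate must be >= 0")
    if n_c < n_f:
        raise ValueError(f"fewer channels ({n_c}) than features ({n_f})")
    base = rng.standard_normal((n_f, n_c))
    base /= np.linalg.norm(base, axis=1, keepdims=True)
    perm = rng.permutation(n_c)
    pairs = perm[: 2 * (n_c // 2)].reshape(-1, 2)
    rates = rng.uniform(0.5, 1.5, size=len(pairs))
    return DynamicCode(feature_names, base, pairs, float(drift_rate), response_window, rates)


# ---------------------------------------------------------------------------
# Stream sampling
# ---------------------------------------------------------------------------

def sample_stream(
    lexicon: Lexicon,
    n_words: int,
    config: SimulationConfig,
    rng: np.random.Generator,
):
    """Sample a continuous phoneme stream from the lexicon.

    Words are drawn i.i.d. proportional to their lexicon frequency and
    grouped into sentences of 3-8 words.  Phoneme durations are drawn from
    the configured truncated normal; words are separated by silences drawn
    uniformly from [0, ``max_silence``].

    Returns ``(events, words)`` where ``events`` is a list of
    :class:`~phonoseq.lexicon.PhonemeEvent` with full positional, syllabic
    and stress metadata.
    """
    if n_words <= 0:
        raise ValueError("n_words must be positive")
    if len(lexicon) == 0:
        raise ValueError("lexicon is empty")
    words = lexicon.words()
    freqs = np.array([lexicon.entries[w].frequency for w in words], dtype=float)
    choice = rng.choice(len(words), size=n_words, p=freqs / freqs.sum())
    ftable = build_feature_table(lexicon.inventory())

    a = (config.duration_min - config.duration_mean) / config.duration_sd
    b = (config.duration_max - config.duration_mean) / config.duration_sd
    tn = stats.truncnorm(a, b, loc=config.duration_mean, scale=config.duration_sd)

    events: list[PhonemeEvent] = []
    t = 0.0
    sent_id, w_in_sent = 0, 0
    sent_len = int(rng.integers(3, 9))
    word_seq = []
    for wid, wi in enumerate(choice):
        word = words[wi]
        word_seq.append(word)
        entry = lexicon.entries[word]
        seq = entry.phonemes
        syls = syllabify(seq, ftable)
        durs = tn.rvs(size=len(seq), random_state=rng)
        for k, ph in enumerate(seq):
            events.append(
                PhonemeEvent(
                    label=ph,
                    onset=t,
                    duration=float(durs[k]),
                    word_id=wid,
                    word=word,
                    pos_from_onset=k + 1,
                    pos_from_offset=k - len(seq),
                    sentence_id=sent_id,
                    word_in_sentence=w_in_sent,
                    syllable_in_word=syls[k],
                    is_syllable_onset=(k == 0 or syls[k] != syls[k - 1]),
                    is_syllable_offset=(k == len(seq) - 1 or syls[k] != syls[k + 1]),
                    primary_stress=(k == entry.stress_idx),
                    secondary_stress=(entry.stress2_idx is not None and k == entry.stress2_idx),
                    is_morpheme_onset=(k == 0 or k == entry.affix_onset_idx),
                    is_morpheme_offset=(
                        k == len(seq) - 1
                        or (entry.affix_onset_idx is not None and k == entry.affix_onset_idx - 1)
                    ),
                )
            )
            t += float(durs[k])
        t += float(rng.uniform(0, config.max_silence))
        w_in_sent += 1
        if w_in_sent >= sent_len:
            sent_id += 1
            w_in_sent = 0
            sent_len = int(rng.integers(3, 9))
    return events, word_seq


# ---------------------------------------------------------------------------
# Recording synthesis
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Continuous multichannel data plus the confound regressors."""

    data: np.ndarray  # (channels, samples)
    fs: float
    layout: SensorLayout | None = None
    envelope: np.ndarray | None = None
    pitch: np.ndarray | None = None
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def _confound_regressors(events, n_samples, fs, rng):
    """Envelope (per-phoneme Hann bumps) and a smooth pitch proxy."""
    env = np.zeros(n_samples)
    for ev in events:
        i0 = int(round(ev.onset * fs))
        n = max(int(round(ev.duration * fs)), 2)
        bump = np.sin(np.pi * np.arange(n) / n) ** 2
        amp = rng.uniform(0.5, 1.5)
        env[i0 : i0 + n] += amp * bump[: max(0, n_samples - i0)]
    pitch = ndimage.gaussian_filter1d(rng.standard_normal(n_samples), sigma=0.05 * fs)
    sd = pitch.std()
    if sd > 0:
        pitch /= sd
    return env, pitch


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x**2)))


def simulate_recording(
    events,
    annotation,
    code: DynamicCode,
    config: SimulationConfig,
    rng: np.random.Generator,
    duration: float | None = None,
    duration_scaled_drift: bool = False,
) -> Recording:
    """Synthesise a continuous recording from a planted code.

    Each phoneme event contributes the code tensor weighted by its ±1
    feature values (taken from the matching ``annotation`` rows), placed at
    its onset; overlapping responses sum linearly.  Confounds are injected
    through fixed random spatial patterns with RMS ``confound_gain`` (in
    noise-SD units), and white sensor noise is added according to
    ``config.snr`` (see :class:`SimulationConfig`).

    With ``duration_scaled_drift=True`` the drift clock of each response
    runs in units of that phoneme's duration (reference: the configured mean
    duration), so long phonemes evolve their pattern more slowly.
    """
    events = list(events)
    if len(events) != len(annotation):
        raise ValueError("annotation row count does not match event count")
    fs = config.fs
    t_end = max(ev.onset + ev.duration for ev in events) + code.response_window
    if duration is None:
        duration = t_end + 0.2
    elif t_end > duration:
        raise ValueError("events extend past the requested recording duration")
    n_samples = int(round(duration * fs))
    n_c = code.n_channels

    Y = annotation[code.feature_names].to_numpy(dtype=float)  # (n_events, F)
    signal = np.zeros((n_c, n_samples))
    W_static = None if duration_scaled_drift else code.tensor(fs)
    for row, ev in enumerate(events):
        if duration_scaled_drift:
            speed = config.duration_mean / ev.duration
            W = code.tensor(fs, speed=speed)
        else:
            W = W_static
        resp = np.tensordot(Y[row], W, axes=(0, 0))  # (C, L)
        i0 = int(round(ev.onset * fs))
        i1 = min(i0 + resp.shape[1], n_samples)
        signal[:, i0:i1] += resp[:, : i1 - i0]

    env, pitch = _confound_regressors(events, n_samples, fs, rng)

    if config.snr is None:
        data = signal
    else:
        rms = _rms(signal)
        if rms > 0 and config.snr > 0:
            data = signal * (config.snr / rms)
        else:
            data = np.zeros_like(signal)
        if config.confound_gain > 0:
            for reg in (env, pitch):
                pat = rng.standard_normal(n_c)
                pat /= np.linalg.norm(pat)
                reg_rms = _rms(reg)
                if reg_rms > 0:
                    data = data + np.outer(pat, reg) * (config.confound_gain / reg_rms)
        data = data + rng.standard_normal((n_c, n_samples))
    return Recording(data=data, fs=fs, layout=None, envelope=env, pitch=pitch,
                     seed=config.seed)


def simulate_audio_branch(
    events,
    annotation,
    rng: np.random.Generator,
    code: DynamicCode | None = None,
    n_bands: int = 208,
    config: SimulationConfig | None = None,
) -> Recording:
    """Pseudo-spectrogram branch: a *static* code active only during the phoneme.

    The acoustic signal carries stationary cues: each phoneme's feature
    pattern is constant over latency (drift forced to 0) and present only
    for the phoneme's acoustic extent, after which it vanishes.  Downstream,
    this produces a square temporal-generalisation matrix confined to the
    phoneme duration.
    """
    config = config or SimulationConfig()
    events = list(events)
    if len(events) != len(annotation):
        raise ValueError("annotation row count does not match event count")
    if code is None:
        layout = default_layout(n_bands)
        feats = [c for c in annotation.columns if c in
                 ("voicing", "fricative", "nasal", "plosive", "approximant", "vowel")]
        code = make_code(layout, feats or list(annotation.columns), 0.0, rng)
    else:
        code = replace(code, drift_rate=0.0)
    fs = config.fs
    t_end = max(ev.onset + ev.duration for ev in events) + 0.05
    n_samples = int(round((t_end + 0.2) * fs))
    Y = annotation[code.feature_names].to_numpy(dtype=float)
    signal = np.zeros((code.n_channels, n_samples))
    for row, ev in enumerate(events):
        pat = Y[row] @ code.base  # static spatial pattern
        i0 = int(round(ev.onset * fs))
        n = max(int(round(ev.duration * fs)), 2)
        i1 = min(i0 + n, n_samples)
        signal[:, i0:i1] += pat[:, None]
    if config.snr is None:
        data = signal
    else:
        rms = _rms(signal)
        scale = (config.snr / rms) if (rms > 0 and config.snr > 0) else 0.0
        data = signal * scale + rng.standard_normal(signal.shape)
    env, pitch = _confound_regressors(events, n_samples, fs, rng)
    return Recording(data=data, fs=fs, envelope=env, pitch=pitch, seed=config.seed)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.create_dataset("sfreq", data=recording.fs)
        if recording.layout is not None:
            f.create_dataset("layout", data=recording.layout.coords)
        if recording.envelope is not None:
            f.create_dataset("envelope", data=recording.envelope)
        if recording.pitch is not None:
            f.create_dataset("pitch", data=recording.pitch)
        if recording.seed is not None:
            f.create_dataset("seed", data=recording.seed)


def read_recording(path) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        layout = SensorLayout(f["layout"][()]) if "layout" in f else None
        return Recording(
            data=f["data"][()],
            fs=float(f["sfreq"][()]),
            layout=layout,
            envelope=f["envelope"][()] if "envelope" in f else None,
            pitch=f["pitch"][()] if "pitch" in f else None,
            seed=int(f["seed"][()]) if "seed" in f else None,
        )
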