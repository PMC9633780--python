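"""Confound removal, epoching, and the auditory (mel-spectrogram) branch.

The temporal-receptive-field (TRF) stage regresses out of every channel the
variance predictable from the acoustic envelope and pitch over the preceding
200 ms, using ridge regression with the regularisation strength chosen from
ten log-spaced values in [1e-6, 1e+6] by 3-fold cross-validated predictive
score.  All downstream decoding runs on the residuals, so decoded features
cannot be reduced to loudness or pitch.

Epochs span -200..600 ms around each phoneme onset at 250 Hz (201 samples);
no baseline correction is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .simulate import Recording, SensorLayout

__all__ = [
    "TRFModel",
    "EpochSet",
    "fit_trf",
    "residualize",
    "epoch_events",
    "mel_spectrogram",
    "write_epochs",
    "read_epochs",
]

TRF_ALPHAS = np.logspace(-6, 6, 10)


def _lag_matrix(regressors: np.ndarray, n_lags: int) -> np.ndarray:
    """Causal lag embedding: column block l holds the regressors l samples back."""
    n, r = regressors.shape
    padded = np.vstack([np.zeros((n_lags - 1, r)), regressors])
    win = np.lib.stride_tricks.sliding_window_view(padded, n_lags, axis=0)
    # win: (n, r, n_lags); lag l = n_lags-1-l index
    return win[:, :, ::-1].reshape(n, r * n_lags)


@dataclass
class TRFModel:
    """Lagged ridge model mapping envelope+pitch history onto each channel."""

    n_lags: int
    alpha: float
    weights: list[np.ndarray]  # per fold, fitted on the complement
    fold_bounds: np.ndarray  # (n_folds + 1,) sample boundaries
    reg_mean: np.ndarray
    reg_sd: np.ndarray
    data_mean: np.ndarray
    data_sd: np.ndarray
    scores: np.ndarray  # per-alpha mean CV predictive correlation
    alphas: np.ndarray

    @property
    def score(self) -> float:
        return float(self.scores.max())


def fit_trf(
    data: np.ndarray,
    envelope: np.ndarray,
    pitch: np.ndarray | None = None,
    fs: float = 1000.0,
    lag_window: float = 0.200,
    alphas: np.ndarray = TRF_ALPHAS,
    n_folds: int = 3,
) -> TRFModel:
    """Fit the acoustic-confound TRF.

    Each channel at time t is modelled from the preceding ``lag_window``
    seconds of envelope (and pitch, if given).  Regressors and data are
    standardised before fitting; lambda is selected by the mean held-out
    Pearson correlation across channels over ``n_folds`` contiguous folds.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    regs = [np.asarray(envelope, dtype=float)]
    if pitch is not None:
        regs.append(np.asarray(pitch, dtype=float))
    R = np.column_stack(regs)
    if R.shape[0] != data.shape[1]:
        raise ValueError("regressors must have the same length as the recording")
    sd = R.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant regressor: cannot standardise")
    mu = R.mean(axis=0)
    Rz = (R - mu) / sd
    dmu, dsd = data.mean(axis=1), data.std(axis=1)
    dsd = np.where(dsd == 0, 1.0, dsd)
    Dz = (data - dmu[:, None]) / dsd[:, None]

    n_lags = int(round(lag_window * fs)) + 1
    X = _lag_matrix(Rz, n_lags)
    n = X.shape[0]
    bounds = np.linspace(0, n, n_folds + 1).astype(int)
    alphas = np.asarray(alphas, dtype=float)

    # precompute per-fold Gram blocks so every alpha reuses them
    XtX_f, XtY_f = [], []
    for k in range(n_folds):
        s = slice(bounds[k], bounds[k + 1])
        Xf = X[s]
        XtX_f.append(Xf.T @ Xf)
        XtY_f.append(Xf.T @ Dz[:, s].T)
    XtX = np.sum(XtX_f, axis=0)
    XtY = np.sum(XtY_f, axis=0)

    eye = np.eye(X.shape[1])
    scores = np.zeros(len(alphas))
    for ai, a in enumerate(alphas):
        rs = []
        for k in range(n_folds):
            W = np.linalg.solve(XtX - XtX_f[k] + a * eye, XtY - XtY_f[k])
            s = slice(bounds[k], bounds[k + 1])
            pred = X[s] @ W  # (n_k, C)
            true = Dz[:, s].T
            pc = pred - pred.mean(0)
            tc = true - true.mean(0)
            denom = np.sqrt((pc**2).sum(0) * (tc**2).sum(0))
            denom[denom == 0] = np.inf
            rs.append(np.mean((pc * tc).sum(0) / denom))
        scores[ai] = np.mean(rs)
    best = int(np.argmax(scores))
    alpha = float(alphas[best])
    weights = [
        np.linalg.solve(XtX - XtX_f[k] + alpha * eye, XtY - XtY_f[k])
        for k in range(n_folds)
    ]
    return TRFModel(n_lags, alpha, weights, bounds, mu, sd, dmu, dsd, scores, alphas)


def trf_predict(trf: TRFModel, envelope, pitch=None, held_out: bool = True) -> np.ndarray:
    """Channel predictions in original units, (channels, samples)."""
    regs = [np.asarray(envelope, dtype=float)]
    if pitch is not None:
        regs.append(np.asarray(pitch, dtype=float))
    R = (np.column_stack(regs) - trf.reg_mean) / trf.reg_sd
    X = _lag_matrix(R, trf.n_lags)
    n = X.shape[0]
    pred = np.zeros((n, len(trf.data_mean)))
    if held_out:
        if n != trf.fold_bounds[-1]:
            raise ValueError("held-out prediction requires the recording the TRF was fit on")
        for k, W in enumerate(trf.weights):
            s = slice(trf.fold_bounds[k], trf.fold_bounds[k + 1])
            pred[s] = X[s] @ W
    else:
        W = np.mean(trf.weights, axis=0)
        pred = X @ W
    return (pred * trf.data_sd + trf.data_mean).T


def residualize(recording: Recording, trf: TRFModel, held_out: bool = True) -> Recording:
    """Subtract the TRF-predicted confound contribution from every channel.

    With ``held_out=True`` (default) the prediction for each fold comes from
    the model fitted on the complementary folds, so no sample is residualised
    against an in-sample fit.
    """
    pred = trf_predict(trf, recording.envelope, recording.pitch, held_out=held_out)
    if pred.shape != recording.data.shape:
        raise ValueError("TRF prediction shape does not match the recording")
    return Recording(
        data=recording.data - pred,
        fs=recording.fs,
        layout=recording.layout,
        envelope=recording.envelope,
        pitch=recording.pitch,
        seed=recording.seed,
    )


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Trials x channels x time tensor around phoneme onsets.

    ``X`` spans ``tmin..tmax`` inclusive (default -0.2..0.6 s at 250 Hz,
    i.e. exactly 201 samples).  ``annotation_index`` maps each trial back to
    its row in the annotation table; ``dropped`` lists the event indices that
    fell too close to a recording edge.
    """

    X: np.ndarray
    times: np.ndarray
    fs: float
    layout: SensorLayout | None = None
    annotation_index: np.ndarray | None = None
    dropped: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    @property
    def n_times(self) -> int:
        return self.X.shape[2]


def epoch_events(
    recording: Recording,
    onsets,
    fs_out: float = 250.0,
    tmin: float = -0.200,
    tmax: float = 0.600,
    highpass: float | None = 0.1,
    lowpass: float | None = 50.0,
    filter_length: int = 1001,
) -> EpochSet:
    """Band-pass, decimate and segment a recording around phoneme onsets.

    The recording is zero-phase FIR filtered (default band 0.1-50 Hz, which
    band-limits it below the post-decimation Nyquist), decimated to
    ``fs_out``, and cut into epochs of exactly
    ``round((tmax - tmin) * fs_out) + 1`` samples.  Events whose window
    extends past an edge are dropped and reported in ``dropped``.
    """
    data = recording.data
    fs = recording.fs
    q = fs / fs_out
    if abs(q - round(q)) > 1e-9:
        raise ValueError("fs_out must divide the recording sampling rate")
    q = int(round(q))
    if highpass or lowpass:
        nyq = fs / 2
        if lowpass and highpass:
            taps = sp_signal.firwin(filter_length, [highpass, lowpass],
                                    pass_zero=False, fs=fs)
        elif lowpass:
            taps = sp_signal.firwin(filter_length, lowpass, fs=fs)
        else:
            taps = sp_signal.firwin(filter_length, highpass, pass_zero=False, fs=fs)
        data = sp_signal.filtfilt(taps, [1.0], data, axis=1)
    data = data[:, ::q]

    n_pre = int(round(-tmin * fs_out))
    n_post = int(round(tmax * fs_out))
    n_times = n_pre + n_post + 1
    onsets = np.asarray(onsets, dtype=float)
    kept, dropped, epochs = [], [], []
    for i, t in enumerate(onsets):
        c = int(round(t * fs_out))
        if c - n_pre < 0 or c + n_post >= data.shape[1]:
            dropped.append(i)
            continue
        kept.append(i)
        epochs.append(data[:, c - n_pre : c + n_post + 1])
    if not epochs:
        raise ValueError("no valid events to epoch")
    X = np.stack(epochs)
    times = (np.arange(n_times) - n_pre) / fs_out
    return EpochSet(
        X=X,
        times=times,
        fs=fs_out,
        layout=recording.layout,
        annotation_index=np.asarray(kept, dtype=int),
        dropped=np.asarray(dropped, dtype=int),
    )


# ---------------------------------------------------------------------------
# Auditory branch
# ---------------------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_bands: int, n_fft: int, sr: float, fmin: float, fmax: float) -> np.ndarray:
    """Triangular filters with centres equally spaced on the mel scale."""
    fmax = min(fmax, sr / 2)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / sr)
    edges = _mel_to_hz(np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_bands + 2))
    fb = np.zeros((n_bands, len(freqs)))
    for b in range(n_bands):
        lo, mid, hi = edges[b], edges[b + 1], edges[b + 2]
        up = (freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - freqs) / max(hi - mid, 1e-12)
        fb[b] = np.clip(np.minimum(up, down), 0, None)
    return fb


def mel_spectrogram(
    audio: np.ndarray,
    sr: float,
    n_bands: int = 208,
    win_length: int = 2048,
    overlap: int = 128,
    fmin: float = 1.0,
    fmax: float = 11250.0,
    fs_out: float = 250.0,
):
    """Mel power spectrogram: (n_bands, frames) resampled to ``fs_out``.

    A Hamming window of ``win_length`` samples is applied with ``overlap``
    samples shared between successive frames (hop = win_length - overlap);
    power passes through ``n_bands`` triangular filters spaced non-linearly
    (mel scale) between ``fmin`` and ``fmax`` Hz, then each band is linearly
    interpolated onto a uniform ``fs_out`` grid.

    Returns ``(mel, times)``.
    """
    audio = np.asarray(audio, dtype=float).ravel()
    if audio.size == 0:
        raise ValueError("empty audio")
    hop = win_length - overlap
    if hop <= 0:
        raise ValueError("overlap must be smaller than the window length")
    freqs, frame_times, Z = sp_signal.stft(
        audio,
        fs=sr,
        window="hamming",
        nperseg=win_length,
        noverlap=overlap,
        boundary=None,
        padded=False,
    )
    power = np.abs(Z) ** 2
    fb = mel_filterbank(n_bands, win_length, sr, fmin, fmax)
    mel = fb @ power  # (n_bands, frames)
    t_out = np.arange(0, audio.size / sr, 1.0 / fs_out)
    out = np.empty((n_bands, len(t_out)))
    for b in range(n_bands):
        out[b] = np.interp(t_out, frame_times, mel[b])
    return out, t_out


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_epochs(epochs: EpochSet, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=epochs.X)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("sfreq", data=epochs.fs)
        if epochs.layout is not None:
            f.create_dataset("layout", data=epochs.layout.coords)
        if epochs.annotation_index is not None:
            f.create_dataset("annotation_index", data=epochs.annotation_index)


def read_epochs(path) -> EpochSet:
    import h5py

    with h5py.File(path, "r") as f:
        return EpochSet(
            X=f["X"][()],
            times=f["times"][()],
            fs=float(f["sfreq"][()]),
            layout=SensorLayout(f["layout"][()]) if "layout" in f else None,
            annotation_index=f["annotation_index"][()] if "annotation_index" in f else None,
        )
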