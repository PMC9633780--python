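"""Coefficient-topography trajectories and the latency-since-onset decoder.

If the channel pattern carrying a feature evolves systematically with time
since phoneme onset, that evolution should be visible in the decoder
coefficients (a smooth, structured path through sensor space) and it should
be possible to decode elapsed latency itself from single responses — the
signature of a code that jointly represents content and order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .preprocess import EpochSet
from .simulate import SensorLayout

__all__ = [
    "Trajectory",
    "LatencyResult",
    "unregularized_coefficients",
    "project_trajectory",
    "trajectory_structure",
    "trajectory_null_metrics",
    "permutation_p",
    "decode_latency",
]


def unregularized_coefficients(epochs: EpochSet, Y: np.ndarray) -> np.ndarray:
    """Per-timepoint least-squares decoding weights, (F, channels, times).

    Plain linear regression (no regularisation) fit on *all* trials — the
    goal is interpretable coefficient topographies, not out-of-sample
    prediction.  Channels are standardised per time sample.  Requires more
    trials than channels; otherwise the problem is rank deficient and a
    regularised decoder should be used instead.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, C, T = epochs.X.shape
    if n <= C:
        raise ValueError(
            "rank-deficient fit: need more trials than channels for "
            "unregularised coefficients (use a regularised decoder instead)"
        )
    F = Y.shape[1]
    W = np.empty((F, C, T))
    Yc = Y - Y.mean(axis=0)
    for t in range(T):
        Xt = epochs.X[:, :, t]
        mu, sd = Xt.mean(0), Xt.std(0)
        sd[sd == 0] = 1.0
        Xc = (Xt - mu) / sd
        coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        W[:, :, t] = coef.T
    return W


@dataclass
class Trajectory:
    """Per-time (x, y) cosine-distance projections of a coefficient topography.

    x: left/right axis, y: posterior/anterior axis; both are cosine
    distances between the (absolute) topography and the corresponding
    unit-norm binary sensor mask.
    """

    x: np.ndarray
    y: np.ndarray
    times: np.ndarray | None = None


def _cosine_distance(topo: np.ndarray, mask: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(topo, axis=0) * np.linalg.norm(mask)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (mask @ topo) / norm
    return 1.0 - sim


def project_trajectory(weights: np.ndarray, layout: SensorLayout) -> Trajectory:
    """Project coefficient topographies onto orthogonal sensor-axis masks.

    ``weights`` is (channels, times) for one feature, or
    (subjects, channels, times), in which case the root mean square across
    subjects is taken first.  Topographies are sign-ambiguous after RMS, so
    the projection uses absolute magnitudes.  Times where the topography is
    all-zero yield NaN projections (flagged undefined).
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim == 3:
        W = np.sqrt(np.mean(W**2, axis=0))
    topo = np.abs(W)  # (C, T)
    masks = {}
    for name, m in (("x", layout.right_mask()), ("y", layout.anterior_mask())):
        nrm = np.linalg.norm(m)
        if nrm == 0:
            raise ValueError(f"empty {name} mask")
        masks[name] = m / nrm
    return Trajectory(
        x=_cosine_distance(topo, masks["x"]),
        y=_cosine_distance(topo, masks["y"]),
    )


def trajectory_structure(traj: Trajectory) -> float:
    """Structure metric (m/s)*v, averaged over the x and y axes.

    m is the range of movement (max minus min cosine distance), s the mean
    absolute step between successive time samples (small for smooth paths)
    and v the standard deviation across time.  Smooth, far-ranging,
    structured paths score high; white jitter of the same range scores low.
    A constant trajectory (s = 0) scores 0 by definition.  Reflecting either
    sensor mask leaves the metric unchanged.
    """
    vals = []
    for axis in (traj.x, traj.y):
        a = np.asarray(axis, dtype=float)
        a = a[np.isfinite(a)]
        if len(a) < 10:
            raise ValueError("trajectory too short: need at least 10 defined timepoints")
        s = np.mean(np.abs(np.diff(a)))
        if s == 0:
            vals.append(0.0)
            continue
        m = a.max() - a.min()
        v = a.std()
        vals.append((m / s) * v)
    return float(np.mean(vals))


def trajectory_null_metrics(
    epochs: EpochSet,
    y: np.ndarray,
    layout: SensorLayout,
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Structure metrics of shuffled-label null trajectories.

    The decoding analysis is repeated with the feature labels randomly
    permuted across trials; because only the labels change, the per-time
    least-squares projector is computed once and applied to every
    permutation.
    """
    rng = np.random.default_rng() if rng is None else rng
    y = np.asarray(y, dtype=float).ravel()
    n, C, T = epochs.X.shape
    if n <= C:
        raise ValueError("rank-deficient fit: need more trials than channels")
    pinvs = np.empty((T, C, n))
    for t in range(T):
        Xt = epochs.X[:, :, t]
        mu, sd = Xt.mean(0), Xt.std(0)
        sd[sd == 0] = 1.0
        pinvs[t] = np.linalg.pinv((Xt - mu) / sd)
    out = np.empty(n_perm)
    for p in range(n_perm):
        yp = rng.permutation(y)
        yc = yp - yp.mean()
        W = np.einsum("tcn,n->ct", pinvs, yc)
        out[p] = trajectory_structure(project_trajectory(W, layout))
    return out


def group_trajectory_test(
    studies: list[tuple[EpochSet, np.ndarray]],
    layout: SensorLayout,
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray]:
    """Observed and null structure metrics for a group of subjects.

    ``studies`` is a list of (epochs, single-feature labels) pairs, one per
    subject.  Decoder weights are estimated per subject, combined by root
    mean square across subjects (reducing estimation noise while preserving
    shared topographic structure), projected, and scored; the null repeats
    this with labels shuffled independently within each subject.

    Returns ``(observed_metric, null_metrics)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    pinvs, ys = [], []
    for epochs, y in studies:
        y = np.asarray(y, dtype=float).ravel()
        n, C, T = epochs.X.shape
        if n <= C:
            raise ValueError("rank-deficient fit: need more trials than channels")
        P = np.empty((T, C, n))
        for t in range(T):
            Xt = epochs.X[:, :, t]
            mu, sd = Xt.mean(0), Xt.std(0)
            sd[sd == 0] = 1.0
            P[t] = np.linalg.pinv((Xt - mu) / sd)
        pinvs.append(P)
        ys.append(y)

    def metric(labels):
        Ws = [np.einsum("tcn,n->ct", P, yv - yv.mean())
              for P, yv in zip(pinvs, labels)]
        return trajectory_structure(project_trajectory(np.stack(Ws), layout))

    observed = metric(ys)
    null = np.array([metric([rng.permutation(y) for y in ys])
                     for _ in range(n_perm)])
    return observed, null


def permutation_p(observed: float, null: np.ndarray) -> float:
    """Permutation p-value with a 1/(n+1) reporting floor."""
    null = np.asarray(null, dtype=float)
    return float((np.sum(null >= observed) + 1) / (len(null) + 1))


@dataclass
class LatencyResult:
    """Held-out latency predictions from the time-since-onset decoder."""

    true_ms: np.ndarray
    predicted_ms: np.ndarray
    fold: np.ndarray
    r: float  # Pearson r over all held-out predictions
    per_fold_r: np.ndarray
    latencies_ms: np.ndarray


def decode_latency(
    epochs: EpochSet,
    crop: tuple[float, float] = (0.100, 0.400),
    n_latency: int = 16,
    n_folds: int = 5,
    seed: int = 0,
    alpha: float = 1.0,
) -> LatencyResult:
    """Decode elapsed time since phoneme onset from instantaneous responses.

    The epoch is cropped to ``crop`` (default 100-400 ms, the window of
    strongest phonetic decoding) and sampled at ``n_latency`` equally spaced
    timepoints (16 by default, i.e. ~53.3 Hz).  Trial and latency dimensions
    are collapsed: each (trial, latency) pair is one observation, labelled
    with its latency.  Inputs and targets are standardised by training-fold
    statistics; ridge regression with 5-fold shuffled cross-validation
    produces held-out predictions, returned in ms.

    With inputs carrying no latency information the coefficients shrink to
    zero and every prediction collapses to the training-label mean — 250 ms
    for the default grid.
    """
    t = epochs.times
    if crop[0] < t[0] or crop[1] > t[-1]:
        raise ValueError("crop window extends beyond the epoch")
    idx = np.round(np.linspace(
        np.searchsorted(t, crop[0] - 1e-9),
        np.searchsorted(t, crop[1] - 1e-9),
        n_latency,
    )).astype(int)
    lat_ms = t[idx] * 1000
    n, C, _ = epochs.X.shape
    Xl = epochs.X[:, :, idx]  # (n, C, L)
    X = np.transpose(Xl, (0, 2, 1)).reshape(n * n_latency, C)
    y = np.tile(lat_ms, n)
    if len(y) < 2 * n_folds:
        raise ValueError("too few observations for the requested folds")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y))
    fold_id = np.empty(len(y), dtype=int)
    per_fold_r = []
    for k, (tr, te) in enumerate(kf.split(X)):
        xm, xs = X[tr].mean(0), X[tr].std(0)
        xs[xs == 0] = 1.0
        ym, ys = y[tr].mean(), y[tr].std()
        model = Ridge(alpha=alpha)
        model.fit((X[tr] - xm) / xs, (y[tr] - ym) / ys)
        p = model.predict((X[te] - xm) / xs) * ys + ym
        pred[te] = p
        fold_id[te] = k
        if np.std(p) > 0:
            per_fold_r.append(sp_stats.pearsonr(y[te], p)[0])
        else:
            per_fold_r.append(0.0)
    r = sp_stats.pearsonr(y, pred)[0] if np.std(pred) > 0 else 0.0
    return LatencyResult(y, pred, fold_id, float(r), np.asarray(per_fold_r), lat_ms)
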