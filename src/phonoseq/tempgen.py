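"""Temporal generalisation (TG) analysis of decoder stability.

A decoder trained at time t is evaluated (with the B2B encoder stage) at
every test time t', yielding a square train-time x test-time surface per
feature.  A *static* code — the same spatial pattern at every latency —
produces a square suprathreshold region (a decoder trained anywhere works
everywhere); a *dynamic* code, whose pattern drifts with latency since
onset, produces a narrow diagonal: each decoder is only informative for the
short period during which the pattern resembles the one it was trained on.

The module also provides the derived analyses: diagonal-versus-row duration
statistics, generalisation across phoneme positions, alignment of
per-position surfaces to the word clock, cross-position overlap of
suprathreshold cells, the principal-axis ("ridge") angle, and trial-subset
comparisons (duration, surprisal, entropy, word length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import RidgeCV

from .b2b import B2B_ALPHAS, _fit_G, _ridge_closed_form, _split_indices, _standardize, _time_rng, check_features
from .preprocess import EpochSet

__all__ = [
    "TGMatrix",
    "tg_fit_eval",
    "group_tmap",
    "diag_vs_rows",
    "position_mask",
    "generalize_across_positions",
    "WordClockComposite",
    "align_to_word_clock",
    "overlap_fraction",
    "pairwise_overlap",
    "ridge_angle",
    "subset_masks",
    "subset_compare",
]


@dataclass
class TGMatrix:
    """Train-time x test-time decoding surface.

    ``scores`` is (F, T_train, T_test): the B2B beta of each feature for a
    decoder trained at one time and evaluated at another.  Both axes share
    the same (possibly decimated) time grid.
    """

    scores: np.ndarray
    times_train: np.ndarray
    times_test: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    subset: str = ""

    def surface(self) -> np.ndarray:
        """Feature-averaged (T_train, T_test) surface."""
        return self.scores.mean(axis=0)

    def diagonal(self) -> np.ndarray:
        return np.diagonal(self.surface())

    def mask(self, threshold: float) -> np.ndarray:
        return self.surface() > threshold


def _eval_H_all_times(Yte, Yhat, alphas, diag_idx):
    """Encoder betas for every test time, with alpha selected at the diagonal.

    ``Yhat`` is (n, F, Te).  Returns beta (F, Te).
    """
    n, F, Te = Yhat.shape
    sel = RidgeCV(alphas=alphas, alpha_per_target=True, fit_intercept=True)
    sel.fit(Yte, Yhat[:, :, diag_idx])
    alpha_h = np.atleast_1d(sel.alpha_)

    zmu = Yte.mean(0)
    Zc = Yte - zmu
    ZtZ = Zc.T @ Zc
    flat = Yhat.reshape(n, F * Te)
    Tc = flat - flat.mean(0)
    ZtT = Zc.T @ Tc  # (F, F*Te)
    beta = np.empty((F, Te))
    for a in np.unique(alpha_h):
        feats = np.flatnonzero(alpha_h == a)
        cols = (feats[:, None] * Te + np.arange(Te)[None, :]).ravel()
        sol = np.linalg.solve(ZtZ + a * np.eye(F), ZtT[:, cols])  # (F, len(cols))
        sol = sol.reshape(F, len(feats), Te)
        for k, f in enumerate(feats):
            beta[f] = sol[f, k, :]
    return beta


def tg_fit_eval(
    epochs: EpochSet,
    Y: np.ndarray,
    n_splits: int = 100,
    seed: int = 0,
    decim: int = 1,
    train_mask: np.ndarray | None = None,
    eval_groups: dict[str, np.ndarray] | None = None,
    alphas_G: np.ndarray = B2B_ALPHAS,
    alphas_H: np.ndarray = B2B_ALPHAS,
    feature_names=None,
):
    """Fit decoders at every train time and evaluate them at every test time.

    Standardisation statistics always come from the training half, per time
    sample.  The encoder regularisation is selected at the diagonal test
    time and reused along the row.  With ``decim`` > 1 both axes use every
    ``decim``-th sample of the epoch grid.

    ``train_mask`` restricts the trials eligible for training (e.g. first-
    position phonemes); the held-out evaluation pool is every trial not used
    for training.  ``eval_groups`` maps labels to boolean trial masks; one
    TGMatrix per group is returned as a dict.  Without groups a single
    TGMatrix is returned and, with ``decim=1`` and no ``train_mask``, its
    diagonal reproduces :func:`phonoseq.b2b.b2b_timecourse` exactly (same
    seed convention).
    """
    Y = check_features(Y, feature_names)
    n, F = Y.shape
    if n != epochs.n_trials:
        raise ValueError("Y rows must align with epochs trials")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(F)]
    t_idx = np.arange(epochs.n_times)[::decim]
    times = epochs.times[t_idx]
    Tg = len(t_idx)

    if eval_groups is not None:
        for name, m in eval_groups.items():
            if not np.any(m):
                raise ValueError(f"empty group: {name}")
        out = {g: np.zeros((F, Tg, Tg)) for g in eval_groups}
    else:
        out = {None: np.zeros((F, Tg, Tg))}

    pool = np.arange(n) if train_mask is None else np.flatnonzero(train_mask)
    if len(pool) == 0:
        raise ValueError("empty group: train_mask selects no trials")
    if F > len(pool) // 2:
        raise ValueError(f"too few trials: {F} features need at least {2 * F} training trials")

    X = epochs.X
    for gi, tfull in enumerate(t_idx):
        rng = _time_rng(seed, int(tfull))
        acc = {g: np.zeros((F, Tg)) for g in out}
        for _ in range(n_splits):
            if train_mask is None:
                tr_loc, te_loc = _split_indices(n, rng)
                tr, te = tr_loc, te_loc
            else:
                tr_loc, _ = _split_indices(len(pool), rng)
                tr = pool[tr_loc]
                te = np.setdiff1d(np.arange(n), tr, assume_unique=False)
            # standardise every time sample by the training-half statistics
            mu = X[tr][:, :, t_idx].mean(axis=0)  # (C, Tg)
            sd = X[tr][:, :, t_idx].std(axis=0)
            sd[sd == 0] = 1.0
            ti = np.searchsorted(t_idx, tfull)
            Xtr_t = (X[tr][:, :, tfull] - mu[:, ti]) / sd[:, ti]
            Gc, Gi = _fit_G(Xtr_t, Y[tr], alphas_G, True)
            Xte = (X[te][:, :, t_idx] - mu) / sd  # (n_te, C, Tg)
            Yhat = np.einsum("nct,fc->nft", Xte, Gc) + Gi[None, :, None]
            for g in out:
                if g is None:
                    sel = np.arange(len(te))
                else:
                    sel = np.flatnonzero(eval_groups[g][te])
                if len(sel) < max(2, F):
                    continue
                acc[g] += _eval_H_all_times(Y[te][sel], Yhat[sel], alphas_H, ti)
        for g in out:
            out[g][:, gi, :] = acc[g] / n_splits

    results = {
        g: TGMatrix(out[g], times.copy(), times.copy(), list(feature_names),
                    subset="" if g is None else g)
        for g in out
    }
    return results[None] if eval_groups is None else results


def group_tmap(surfaces) -> np.ndarray:
    """One-sample t map (against 0) across subjects' surfaces."""
    S = np.stack(surfaces)
    n = S.shape[0]
    sd = S.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    return S.mean(axis=0) / (sd / np.sqrt(n))


@dataclass
class DiagRowStats:
    diag_duration_ms: float
    mean_row_duration_ms: float  # over informative rows (>= 1 suprathreshold cell)
    t: float
    df: int
    row_durations_ms: np.ndarray  # all train times
    n_informative_rows: int

    @property
    def ratio(self) -> float:
        """(mean row duration) / (diagonal duration); ~1 for a static code."""
        return self.mean_row_duration_ms / self.diag_duration_ms


def _longest_run(above: np.ndarray) -> int:
    best = cur = 0
    for a in above:
        cur = cur + 1 if a else 0
        best = max(best, cur)
    return best


def diag_vs_rows(tg: TGMatrix, threshold: float, surface: np.ndarray | None = None) -> DiagRowStats:
    """Duration of above-threshold decoding: diagonal versus rows.

    Durations are the longest contiguous suprathreshold run, in ms.  The
    diagonal duration is how long phonetic information is present at all;
    the row duration of a temporal decoder is how long *its* spatial pattern
    stays informative.  The mean row duration summarises the informative
    rows only (decoders trained at latencies that never decode contribute
    duration 0 to ``row_durations_ms`` but are excluded from the mean, which
    would otherwise be diluted by pre-onset train times).  The t statistic
    tests the per-train-time row durations against the (single) diagonal
    duration; with the full 201-sample grid its df is 200.
    """
    surf = tg.surface() if surface is None else surface
    dt_ms = float(np.mean(np.diff(tg.times_test))) * 1000
    diag_dur = _longest_run(np.diagonal(surf) > threshold) * dt_ms
    rows = np.array([_longest_run(row > threshold) for row in surf]) * dt_ms
    n = len(rows)
    informative = rows[rows > 0]
    if diag_dur == 0 and len(informative) == 0:
        return DiagRowStats(0.0, 0.0, np.nan, n - 1, rows, 0)
    sd = rows.std(ddof=1)
    t = (rows.mean() - diag_dur) / (sd / np.sqrt(n)) if sd > 0 else np.nan
    mean_row = float(informative.mean()) if len(informative) else 0.0
    return DiagRowStats(float(diag_dur), mean_row, float(t), n - 1, rows, len(informative))


# ---------------------------------------------------------------------------
# Position generalisation and the word clock
# ---------------------------------------------------------------------------

def _align_annotation(epochs: EpochSet, annotation):
    """Annotation rows aligned with trials: pass through if already aligned,
    otherwise select the epoched rows via ``annotation_index``."""
    if len(annotation) == epochs.n_trials:
        return annotation
    if epochs.annotation_index is not None and len(annotation) > epochs.n_trials:
        return annotation.iloc[epochs.annotation_index]
    raise ValueError("annotation rows do not align with epochs trials")


def position_mask(annotation, label: str) -> np.ndarray:
    """Boolean trial mask for a position label like 'P1', 'P3', 'P-2'."""
    k = int(label[1:])
    if k > 0:
        return (annotation["pos_from_onset"].to_numpy() == k)
    return (annotation["pos_from_offset"].to_numpy() == k)


def generalize_across_positions(
    epochs: EpochSet,
    Y: np.ndarray,
    annotation,
    train_group: str = "P1",
    test_groups=("P2", "P3", "P-1", "P-2"),
    n_splits: int = 100,
    seed: int = 0,
    decim: int = 1,
    **kw,
):
    """Train on one phoneme position, evaluate on others.

    Returns a dict label -> diagonal timecourse (feature-averaged beta),
    including the held-out same-position timecourse under ``train_group``'s
    own label.  A position-invariant code generalises across positions; a
    position-specific code drops to chance off the training position.
    """
    ann = _align_annotation(epochs, annotation)
    tmask = position_mask(ann, train_group)
    if not tmask.any():
        raise ValueError(f"empty group: {train_group}")
    groups = {train_group: tmask}
    for g in test_groups:
        m = position_mask(ann, g)
        if not m.any():
            raise ValueError(f"empty group: {g}")
        groups[g] = m
    tgs = tg_fit_eval(
        epochs, Y, n_splits=n_splits, seed=seed, decim=decim,
        train_mask=tmask, eval_groups=groups, **kw,
    )
    return {g: np.diagonal(tg.surface()).copy() for g, tg in tgs.items()}, tgs


@dataclass
class WordClockComposite:
    """Per-position TG surfaces on a common word-clock test axis."""

    surfaces: dict[str, np.ndarray]  # label -> (T_train, T_ext), NaN off-support
    times_train: np.ndarray
    times_test: np.ndarray  # extended axis, seconds relative to word onset
    shifts_ms: dict[str, float]

    def stack_diagonals(self) -> np.ndarray:
        """Positions x extended-time matrix of shifted diagonals (for stack plots)."""
        out = np.full((len(self.surfaces), len(self.times_test)), np.nan)
        dt = float(np.mean(np.diff(self.times_test)))
        for i, (label, surf) in enumerate(self.surfaces.items()):
            shift = int(round(self.shifts_ms[label] / 1000 / dt))
            for j in range(surf.shape[0]):
                k = j + shift
                if 0 <= k < surf.shape[1]:
                    out[i, k] = surf[j, k]
        return out


def align_to_word_clock(
    tg_per_position: dict[str, TGMatrix | np.ndarray],
    step_ms: float = 80.0,
    offset_ms: float | None = None,
    times: np.ndarray | None = None,
) -> WordClockComposite:
    """Shift each position's TG surface along the test axis by its word-clock lag.

    Position Pk is shifted by (k-1)*step_ms; P-k is aligned backwards from
    the average word offset: shift = offset_ms - k*step_ms, so that P-1 sits
    one step before the offset.  ``offset_ms`` defaults to step_ms times the
    largest positive position present (i.e. the average word duration).
    Values may be raw surfaces or group t maps.
    """
    if step_ms <= 0:
        raise ValueError("step_ms must be positive")
    labels = list(tg_per_position)
    pos_nums = [int(l[1:]) for l in labels]
    if offset_ms is None:
        positive = [k for k in pos_nums if k > 0]
        if not positive and any(k < 0 for k in pos_nums):
            raise ValueError("offset_ms required when only negative positions are given")
        offset_ms = step_ms * max(positive) if positive else 0.0

    first = next(iter(tg_per_position.values()))
    if isinstance(first, TGMatrix):
        times_train = first.times_train
        times_test = first.times_test
        get = lambda v: v.surface()
    else:
        if times is None:
            raise ValueError("times required when passing raw surfaces")
        times_train = times_test = np.asarray(times)
        get = lambda v: np.asarray(v)

    dt = float(np.mean(np.diff(times_test)))
    shifts = {}
    for label, k in zip(labels, pos_nums):
        shifts[label] = (k - 1) * step_ms if k > 0 else offset_ms + k * step_ms
    min_s = min(shifts.values())
    max_s = max(shifts.values())
    n_ext = len(times_test) + int(round((max_s - min_s) / 1000 / dt))
    t_ext = times_test[0] + min_s / 1000 + np.arange(n_ext) * dt

    surfaces = {}
    for label in labels:
        surf = get(tg_per_position[label])
        k0 = int(round((shifts[label] - min_s) / 1000 / dt))
        ext = np.full((surf.shape[0], n_ext), np.nan)
        ext[:, k0 : k0 + surf.shape[1]] = surf
        surfaces[label] = ext
    return WordClockComposite(surfaces, times_train.copy(), t_ext, shifts)


@dataclass
class OverlapStats:
    overall_pct: float
    inner_pct: float  # first/last positions excluded
    per_position_pct: dict[str, float]


def pairwise_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Symmetric shared-suprathreshold percentage between two masks."""
    a, b = np.asarray(mask_a, bool), np.asarray(mask_b, bool)
    na, nb = a.sum(), b.sum()
    if na == 0 or nb == 0:
        return 0.0
    inter = (a & b).sum()
    return 100.0 * 0.5 * (inter / na + inter / nb)


def overlap_fraction(aligned: WordClockComposite, t_threshold: float = 4.0) -> OverlapStats:
    """Percentage of suprathreshold cells shared with adjacent positions.

    For each position (ordered along the word clock), the fraction of its
    suprathreshold (train, test) cells that are also suprathreshold for at
    least one adjacent position; percentages are averaged across positions.
    ``inner_pct`` repeats the computation excluding the first and last
    positions of the word.  Returns 0 with empty masks.
    """
    order = sorted(aligned.surfaces, key=lambda l: aligned.shifts_ms[l])
    masks = {}
    for label in order:
        s = aligned.surfaces[label]
        masks[label] = np.where(np.isnan(s), False, s > t_threshold)
    per_pos = {}
    for i, label in enumerate(order):
        m = masks[label]
        if m.sum() == 0:
            per_pos[label] = 0.0
            continue
        nb = np.zeros_like(m)
        if i > 0:
            nb |= masks[order[i - 1]]
        if i + 1 < len(order):
            nb |= masks[order[i + 1]]
        per_pos[label] = 100.0 * (m & nb).sum() / m.sum()
    vals = list(per_pos.values())
    inner = [per_pos[l] for l in order[1:-1]] or vals
    return OverlapStats(float(np.mean(vals)), float(np.mean(inner)), per_pos)


def ridge_angle(
    mask: np.ndarray,
    times_train: np.ndarray,
    times_test: np.ndarray,
    min_cells: int = 10,
    largest_component: bool = True,
) -> float:
    """Angle (degrees) of the first principal axis of the suprathreshold cells.

    Coordinates are (test ms, train ms).  45 deg means test-time dynamics
    proceed at training speed; < 45 deg means faster at test (the ridge is
    shallower), approaching 0 for a static code's horizontal ridge.
    Invariant to translating the ridge along either time axis.

    By default the angle is computed on the largest 8-connected
    suprathreshold component — the ridge proper — so that isolated
    false-positive cells scattered over the surface cannot tilt the
    principal axis.
    """
    mask = np.asarray(mask, bool)
    if largest_component and mask.any():
        from scipy import ndimage

        lab, n = ndimage.label(mask, structure=np.ones((3, 3), int))
        if n > 1:
            sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
            mask = lab == (1 + int(np.argmax(sizes)))
    ii, jj = np.nonzero(mask)
    if len(ii) < min_cells:
        raise ValueError(f"degenerate ridge: fewer than {min_cells} suprathreshold cells")
    y = times_train[ii] * 1000
    x = times_test[jj] * 1000
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate ridge: all cells in one row or column")
    pts = np.column_stack([x, y])
    pts = pts - pts.mean(0)
    cov = pts.T @ pts / len(pts)
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    return float(np.degrees(np.arctan2(abs(axis[1]), abs(axis[0]))))


# ---------------------------------------------------------------------------
# Trial-subset comparisons
# ---------------------------------------------------------------------------

def subset_masks(annotation, grouping: str) -> dict[str, np.ndarray]:
    """Boolean trial masks for the standard subset analyses.

    Supported groupings: ``duration_quartiles`` (shortest vs longest
    quartile), ``surprisal_median``, ``entropy_median`` (both on non-onset
    phonemes, matching the word-boundary control), ``word_length_median``
    (word-onset phonemes of short vs long words).
    """
    if grouping == "duration_quartiles":
        d = annotation["duration_s"].to_numpy()
        q1, q3 = np.quantile(d, [0.25, 0.75])
        return {"short": d <= q1, "long": d >= q3}
    non_onset = annotation["pos_from_onset"].to_numpy() > 1
    if grouping in ("surprisal_median", "entropy_median"):
        col = "raw_surprisal" if grouping.startswith("surprisal") else "raw_entropy"
        v = annotation[col].to_numpy()
        med = np.median(v[non_onset])
        return {"low": non_onset & (v <= med), "high": non_onset & (v > med)}
    if grouping == "word_length_median":
        onset = annotation["pos_from_onset"].to_numpy() == 1
        wl = annotation["word_length"].to_numpy()
        med = np.median(wl[onset])
        return {"short_words": onset & (wl <= med), "long_words": onset & (wl > med)}
    raise ValueError(f"unknown grouping {grouping!r}")


def subset_compare(
    epochs: EpochSet,
    Y: np.ndarray,
    annotation,
    grouping: str,
    n_splits: int = 100,
    seed: int = 0,
    decim: int = 1,
    **kw,
) -> dict[str, TGMatrix]:
    """TG surfaces per trial subset, trained on the full training split.

    Decoders are fit on the unrestricted training half; only the evaluation
    trials are grouped, so subset differences reflect the test responses
    rather than training-set size.  Group differences are assessed
    downstream with the cluster tests in :mod:`phonoseq.stats`.
    """
    ann = _align_annotation(epochs, annotation)
    groups = subset_masks(ann, grouping)
    for name, m in groups.items():
        if not m.any():
            raise ValueError(f"empty bin: {name}")
    return tg_fit_eval(
        epochs, Y, n_splits=n_splits, seed=seed, decim=decim, eval_groups=groups, **kw
    )
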