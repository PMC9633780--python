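"""Back-to-back (B2B) ridge regression for covariate-controlled decoding.

B2B measures the *specific* contribution of each stimulus feature to the
multichannel signal, in two stages per random half-split of trials:

1. **Decoding** (G): for every feature f, a ridge decoder is trained across
   channels on one half of trials to predict y_f in {±1} (alpha chosen from
   20 log-spaced values in [1e-5, 1e+5] by cross-validation within the
   training half).
2. **Encoding** (H): on the held-out half, each decoded feature y_hat_f is
   regressed on *all* true features jointly (ridge, alpha by CV).  The
   diagonal entry H[f, f] — the "beta" — is positive only if feature f is
   linearly encoded in the signal over and above its covariates.

Betas are averaged across shuffled splits (100 by default), which stabilises
the coefficients of correlated features.  Normalising the beta timecourses
by the noise ceiling (the maximum over time of the betas summed across
features) yields per-feature shares of explainable variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import RidgeCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .preprocess import EpochSet

__all__ = [
    "B2B_ALPHAS",
    "B2BResult",
    "fit_b2b_at_time",
    "b2b_timecourse",
    "variance_shares",
    "auc_decode",
    "write_b2b",
    "read_b2b",
]

#: 20 log-spaced regularisation strengths in [1e-5, 1e+5].
B2B_ALPHAS = np.logspace(-5, 5, 20)


def check_features(Y: np.ndarray, feature_names=None) -> np.ndarray:
    """Validate the feature matrix; name any constant column in the error."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    sd = Y.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.argmin(sd))
        name = feature_names[bad] if feature_names is not None else f"column {bad}"
        raise ValueError(f"constant feature column: {name}")
    return Y


def _standardize(train: np.ndarray, *others):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return tuple((a - mu) / sd for a in (train, *others))


def _fit_G(Xtr, Ytr, alphas, fit_intercept):
    """Per-feature ridge decoders; returns (coef (F, C), intercept (F,))."""
    model = RidgeCV(alphas=alphas, alpha_per_target=True, fit_intercept=fit_intercept)
    model.fit(Xtr, Ytr)
    coef = np.atleast_2d(model.coef_)
    intercept = np.atleast_1d(np.asarray(model.intercept_, dtype=float))
    if intercept.size == 1 and coef.shape[0] > 1:
        intercept = np.full(coef.shape[0], intercept.item())
    return coef, intercept


def _ridge_closed_form(Z, T, alphas_per_target, fit_intercept):
    """Ridge solutions per target with individual alphas (matches sklearn)."""
    Z = np.asarray(Z, dtype=float)
    T = np.asarray(T, dtype=float)
    if fit_intercept:
        zmu, tmu = Z.mean(0), T.mean(0)
        Zc, Tc = Z - zmu, T - tmu
    else:
        zmu = np.zeros(Z.shape[1])
        tmu = np.zeros(T.shape[1])
        Zc, Tc = Z, T
    ZtZ = Zc.T @ Zc
    ZtT = Zc.T @ Tc
    p = Z.shape[1]
    coef = np.empty((T.shape[1], p))
    alphas_per_target = np.asarray(alphas_per_target, dtype=float)
    for a in np.unique(alphas_per_target):
        cols = np.flatnonzero(alphas_per_target == a)
        sol = np.linalg.solve(ZtZ + a * np.eye(p), ZtT[:, cols])
        coef[cols] = sol.T
    intercept = tmu - coef @ zmu
    return coef, intercept


def _fit_H(Yte, Yhat, alphas, fit_intercept):
    """Encoder stage: regress each decoded feature on all true features."""
    sel = RidgeCV(alphas=alphas, alpha_per_target=True, fit_intercept=fit_intercept)
    sel.fit(Yte, Yhat)
    alpha_h = np.atleast_1d(sel.alpha_)
    coef, intercept = _ridge_closed_form(Yte, Yhat, alpha_h, fit_intercept)
    return coef, intercept, alpha_h


def _split_indices(n: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    half = n // 2
    return idx[:half], idx[half : 2 * half]


def fit_b2b_at_time(
    X: np.ndarray,
    Y: np.ndarray,
    n_splits: int = 100,
    rng: np.random.Generator | None = None,
    alphas_G: np.ndarray = B2B_ALPHAS,
    alphas_H: np.ndarray = B2B_ALPHAS,
    fit_intercept: bool = True,
    feature_names=None,
    direction: str = "yhat_on_true",
    return_splits: bool = False,
) -> np.ndarray:
    """B2B betas for a single time sample.

    Parameters
    ----------
    X : (trials, channels)
        Signal at one time sample; standardised internally by training-split
        mean/SD within each split.
    Y : (trials, F)
        True features (±1 binary, z-scored continuous).
    direction : "yhat_on_true" | "true_on_yhat"
        The published method regresses each decoded feature on all true
        features ("yhat_on_true", default).  "true_on_yhat" implements the
        reverse mapping for comparison.

    Returns the length-F beta vector (diag of H) averaged over splits, or
    the (n_splits, F) per-split array when ``return_splits`` is true.
    """
    rng = np.random.default_rng() if rng is None else rng
    X = np.asarray(X, dtype=float)
    Y = check_features(Y, feature_names)
    n, F = Y.shape
    if F > n // 2:
        raise ValueError(f"too few trials: {F} features need at least {2 * F} trials")
    betas = np.empty((n_splits, F))
    for s in range(n_splits):
        tr, te = _split_indices(n, rng)
        Xtr, Xte = _standardize(X[tr], X[te])
        Gc, Gi = _fit_G(Xtr, Y[tr], alphas_G, fit_intercept)
        Yhat = Xte @ Gc.T + Gi
        if direction == "yhat_on_true":
            H, _, _ = _fit_H(Y[te], Yhat, alphas_H, fit_intercept)
        elif direction == "true_on_yhat":
            H, _, _ = _fit_H(Yhat, Y[te], alphas_H, fit_intercept)
        else:
            raise ValueError(f"unknown direction {direction!r}")
        betas[s] = np.diag(H)
    return betas if return_splits else betas.mean(axis=0)


@dataclass
class B2BResult:
    """Per-feature beta timecourses and their variance-share normalisation."""

    beta: np.ndarray  # (F, T)
    times: np.ndarray
    feature_names: list[str]
    n_splits: int
    seed: int | None = None
    ceiling: float | None = None
    rhat: np.ndarray | None = None


def _time_rng(seed: int | None, t_index: int) -> np.random.Generator:
    """Reproducible per-timepoint stream, independent of execution order."""
    return np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, t_index]))


def b2b_timecourse(
    epochs: EpochSet,
    Y: np.ndarray,
    n_splits: int = 100,
    seed: int = 0,
    alphas_G: np.ndarray = B2B_ALPHAS,
    alphas_H: np.ndarray = B2B_ALPHAS,
    feature_names=None,
    n_jobs: int = 1,
) -> B2BResult:
    """Independent B2B fit at each epoch time sample.

    Per-timepoint RNG streams are derived from ``seed`` by counter, so any
    single timepoint can be recomputed in isolation and results do not
    depend on execution order.
    """
    Y = check_features(Y, feature_names)
    if Y.shape[0] != epochs.n_trials:
        raise ValueError("Y rows must align with epochs trials")
    T = epochs.n_times
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(Y.shape[1])]

    def one(t):
        return fit_b2b_at_time(
            epochs.X[:, :, t], Y, n_splits=n_splits, rng=_time_rng(seed, t),
            alphas_G=alphas_G, alphas_H=alphas_H,
        )

    if n_jobs == 1:
        cols = [one(t) for t in range(T)]
    else:
        from joblib import Parallel, delayed

        cols = Parallel(n_jobs=n_jobs)(delayed(one)(t) for t in range(T))
    beta = np.column_stack(cols)
    return B2BResult(beta, epochs.times.copy(), list(feature_names), n_splits, seed)


def variance_shares(result: B2BResult) -> np.ndarray:
    """Noise-ceiling normalisation of the beta timecourses.

    The ceiling is the maximum over time of the betas summed across
    features; dividing every beta timecourse by it yields shares that sum
    to exactly 1 at the ceiling time.  Modifies ``result`` in place and
    returns the share matrix.
    """
    if result.beta is None or result.beta.size == 0:
        raise ValueError("no beta coefficients present")
    total = result.beta.sum(axis=0)
    ceiling = float(total.max())
    if ceiling <= 0:
        raise ValueError("uninformative fit: non-positive noise ceiling")
    result.ceiling = ceiling
    result.rhat = result.beta / ceiling
    return result.rhat


def auc_decode(
    epochs: EpochSet,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    alphas: np.ndarray = B2B_ALPHAS,
) -> np.ndarray:
    """Cross-validated AUC timecourse for one binary feature (chance 0.5).

    A ridge decoder is trained per fold and time sample on standardised
    channels; its continuous prediction scores the held-out trials.
    """
    y = np.asarray(y, dtype=float).ravel()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("auc_decode requires exactly two classes")
    y01 = (y == classes.max()).astype(int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    T = epochs.n_times
    auc = np.zeros(T)
    folds = list(skf.split(np.zeros(len(y)), y01))
    for tr, te in folds:
        if len(np.unique(y01[tr])) < 2 or len(np.unique(y01[te])) < 2:
            raise ValueError("single-class fold: too few trials per class")
    for t in range(T):
        Xt = epochs.X[:, :, t]
        scores = np.zeros(len(y))
        for tr, te in folds:
            Xtr, Xte = _standardize(Xt[tr], Xt[te])
            ypm = np.where(y01[tr] == 1, 1.0, -1.0)[:, None]
            Gc, Gi = _fit_G(Xtr, ypm, alphas, True)
            scores[te] = (Xte @ Gc.T + Gi).ravel()
        parts = [roc_auc_score(y01[te], scores[te]) for _, te in folds]
        auc[t] = np.mean(parts)
    return auc


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def write_b2b(result: B2BResult, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("b2b")
        g.create_dataset("beta", data=result.beta)
        g.create_dataset("times", data=result.times)
        g.create_dataset("feature_names", data=np.array(result.feature_names, dtype="S"))
        g.create_dataset("n_splits", data=result.n_splits)
        if result.seed is not None:
            g.create_dataset("seed", data=result.seed)
        if result.ceiling is not None:
            g.create_dataset("ceiling", data=result.ceiling)
            g.create_dataset("rhat", data=result.rhat)


def read_b2b(path) -> B2BResult:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["b2b"]
        res = B2BResult(
            beta=g["beta"][()],
            times=g["times"][()],
            feature_names=[s.decode() for s in g["feature_names"][()]],
            n_splits=int(g["n_splits"][()]),
            seed=int(g["seed"][()]) if "seed" in g else None,
        )
        if "ceiling" in g:
            res.ceiling = float(g["ceiling"][()])
            res.rhat = g["rhat"][()]
        return res
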