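"""Group-level nonparametric inference for decoding timecourses.

The workhorse is the one-sample sign-flip cluster permutation test: a
t-statistic timecourse across subjects is thresholded into contiguous
clusters, each summarised by its summed t; the null distribution of the
maximum cluster sum is built by randomly negating whole subjects' scores.
This controls the family-wise error over time without assuming a sampling
distribution for the decoding scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

__all__ = [
    "Cluster",
    "ClusterResult",
    "one_sample_cluster_test",
    "two_condition_cluster_test",
    "rank_correlation",
]


@dataclass(frozen=True)
class Cluster:
    start: float  # ms (or sample index when no times are given)
    end: float
    sum_t: float
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_permutations: int
    threshold: float
    tail: int
    t_obs: np.ndarray

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]


def _t_timecourse(scores: np.ndarray) -> np.ndarray:
    n = scores.shape[0]
    sd = scores.std(axis=0, ddof=1)
    sd = np.where(sd == 0, np.inf, sd)
    return scores.mean(axis=0) / (sd / np.sqrt(n))


def _find_clusters(t: np.ndarray, threshold: float, tail: int):
    """Contiguous suprathreshold runs as (start_idx, end_idx, sum_t)."""
    out = []
    masks = []
    if tail >= 0:
        masks.append(t > threshold)
    if tail <= 0:
        masks.append(t < -threshold)
    for m in masks:
        if not m.any():
            continue
        d = np.diff(m.astype(int))
        starts = list(np.flatnonzero(d == 1) + 1)
        ends = list(np.flatnonzero(d == -1) + 1)
        if m[0]:
            starts.insert(0, 0)
        if m[-1]:
            ends.append(len(m))
        for s, e in zip(starts, ends):
            out.append((s, e, float(t[s:e].sum())))
    return sorted(out)


def _null_max_sums(scores, threshold, tail, flips):
    """Max |cluster sum| per sign-flip permutation (vectorised t-computation)."""
    n, T = scores.shape
    m = flips @ scores / n  # (P, T)
    q = np.mean(scores**2, axis=0)  # invariant under sign flips
    var = (q - m**2) * n / (n - 1)
    sd = np.sqrt(np.maximum(var, 0))
    sd[sd == 0] = np.inf
    t_null = m / (sd / np.sqrt(n))
    out = np.zeros(flips.shape[0])
    for i, row in enumerate(t_null):
        sums = [abs(s) for *_, s in _find_clusters(row, threshold, tail)]
        out[i] = max(sums) if sums else 0.0
    return out


def one_sample_cluster_test(
    scores: np.ndarray,
    n_perm: int = 10_000,
    threshold: float | None = None,
    tail: int = 0,
    times_ms: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    exact: bool = False,
) -> ClusterResult:
    """Sign-flip cluster permutation test of subjects x time scores against 0.

    The cluster-forming threshold defaults to the t value of two-tailed
    p = 0.05 at df = n_subjects - 1.  ``tail`` selects positive (+1),
    negative (-1) or two-sided (0) clusters; the null statistic is the
    maximum absolute cluster t-sum under random subject sign flips
    (exhaustive over all 2^n patterns when ``exact``).  Cluster p-values use
    a 1/(n_perm + 1) floor and are invariant to uniform scaling of the
    scores.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be subjects x time")
    n, T = scores.shape
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if np.all(scores.std(axis=0) == 0):
        raise ValueError("constant scores: no within-subject variability")
    import warnings

    if n_perm < 100 and not exact:
        warnings.warn("fewer than 100 permutations: p-values are coarse")
    if threshold is None:
        threshold = float(sp_stats.t.ppf(0.975, df=n - 1))
    rng = np.random.default_rng() if rng is None else rng

    t_obs = _t_timecourse(scores)
    raw = _find_clusters(t_obs, threshold, tail)

    if exact or 2**n <= n_perm:
        bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :]
        flips = np.where(bits & 1, -1.0, 1.0)
        n_eff = flips.shape[0]
    else:
        flips = rng.choice([-1.0, 1.0], size=(n_perm, n))
        n_eff = n_perm
    null = _null_max_sums(scores, threshold, tail, flips)

    dt = 1.0
    t0 = 0.0
    if times_ms is not None:
        dt = float(np.mean(np.diff(times_ms)))
        t0 = float(times_ms[0])
    clusters = []
    for s, e, sumt in raw:
        p = (np.sum(null >= abs(sumt)) + 1) / (n_eff + 1)
        clusters.append(Cluster(t0 + s * dt, t0 + (e - 1) * dt, sumt, float(p)))
    return ClusterResult(clusters, n_eff, threshold, tail, t_obs)


def two_condition_cluster_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    n_perm: int = 10_000,
    threshold: float | None = None,
    tail: int = 0,
    times_ms: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> ClusterResult:
    """Paired two-condition cluster test via sign flips on a - b differences."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired conditions must have identical subjects x time shapes")
    return one_sample_cluster_test(
        a - b, n_perm=n_perm, threshold=threshold, tail=tail, times_ms=times_ms, rng=rng
    )


def rank_correlation(
    x, y, n_perm: int = 10_000, rng: np.random.Generator | None = None
) -> tuple[float, float]:
    """Spearman rank correlation with a permutation p-value (midrank ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length inputs of at least 4 values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: rank correlation undefined")
    rng = np.random.default_rng() if rng is None else rng
    rx = sp_stats.rankdata(x)
    ry = sp_stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    count = 0
    for _ in range(n_perm):
        rp = rng.permutation(ry)
        if abs(np.corrcoef(rx, rp)[0, 1]) >= abs(rho) - 1e-12:
            count += 1
    return rho, (count + 1) / (n_perm + 1)
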