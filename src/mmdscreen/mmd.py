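"""Gaussian-kernel maximum mean discrepancy: statistics, bandwidth heuristic,
permutation tests and witness functions.

The squared MMD between samples X and Y is estimated as the squared RKHS norm
of the difference of their empirical kernel mean embeddings (the biased
V-statistic),

    MMD^2 = mean_{x,x'} k(x, x') + mean_{y,y'} k(y, y') - 2 mean_{x,y} k(x, y),

with the Gaussian kernel k(u, v) = exp(-||u - v||^2 / (2 h^2)) and length
scale h set by the median pairwise-distance heuristic over the aggregate
sample. The control-centered variant subtracts each sample's batch-specific
control mean embedding before taking the norm, which removes additive batch
structure shared by all populations of one experimental set.

Significance against the null of equal distributions comes from label
permutations of the pooled sample; the p-value is (#{perm stats > observed}
+ 1) / (M + 1), so the smallest attainable p is 1 / (M + 1).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.base import BaseEstimator

from .preprocessing import FeatureMatrix
from .univariate import bh_fdr


def _as_points(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("samples must be 1-D or (n, d) arrays")
    return arr


def median_bandwidth(
    points, *, max_pairs: int = 2_000_000, seed: int = 0
) -> float:
    """Median pairwise Euclidean distance of an aggregate sample.

    All C(n, 2) pairs are used when that is at most ``max_pairs``; beyond the
    cap, a seeded uniform subsample of ``max_pairs`` distinct-index pairs is
    used instead.
    """
    pts = _as_points(points)
    n = pts.shape[0]
    if n < 2:
        raise ValueError("median heuristic needs at least 2 points")
    n_pairs = n * (n - 1) // 2
    if n_pairs <= max_pairs:
        dists = pdist(pts)
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=max_pairs)
        j = rng.integers(0, n - 1, size=max_pairs)
        j = np.where(j >= i, j + 1, j)  # distinct indices, uniform over pairs
        dists = np.linalg.norm(pts[i] - pts[j], axis=1)
    h = float(np.median(dists))
    if h <= 0:
        raise ValueError("median pairwise distance is 0 (degenerate point set)")
    return h


def gaussian_kernel(u, v, h: float):
    """k(u, v) = exp(-||u - v||^2 / (2 h^2)) for single vectors or stacks."""
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    sq = np.sum((u - v) ** 2, axis=-1)
    return np.exp(-sq / (2.0 * h * h))


def gram_matrix(x, y, h: float) -> np.ndarray:
    """Gaussian Gram matrix k(x_i, y_j) between two point stacks."""
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    sq = cdist(_as_points(x), _as_points(y), "sqeuclidean")
    return np.exp(-sq / (2.0 * h * h))


def mmd_squared(x, y, h: float, *, unbiased: bool = False) -> float:
    """Squared MMD estimate between two samples.

    The default biased V-statistic equals the squared norm of the difference
    of empirical mean embeddings and is nonnegative by construction (clipped
    at 0 against rounding). The unbiased U-statistic (``unbiased=True``,
    needs >= 2 points per sample) removes the diagonal terms and may be
    negative.
    """
    x, y = _as_points(x), _as_points(y)
    if x.shape[0] == 0 or y.shape[0] == 0:
        raise ValueError("both samples must be nonempty")
    kxx = gram_matrix(x, x, h)
    kyy = gram_matrix(y, y, h)
    kxy = gram_matrix(x, y, h)
    n, m = x.shape[0], y.shape[0]
    if unbiased:
        if n < 2 or m < 2:
            raise ValueError("unbiased estimator needs >= 2 points per sample")
        term_x = (kxx.sum() - np.trace(kxx)) / (n * (n - 1))
        term_y = (kyy.sum() - np.trace(kyy)) / (m * (m - 1))
        return float(term_x + term_y - 2.0 * kxy.mean())
    value = kxx.mean() + kyy.mean() - 2.0 * kxy.mean()
    return float(max(value, 0.0))


def centered_mmd_squared(x, a, y, b, h: float) -> float:
    """Squared MMD between control-centered mean embeddings.

    Computes ||(mu_x - mu_a) - (mu_y - mu_b)||^2 in the RKHS, where a and b
    are the set-specific control samples of x and y. When a and b are the
    same sample this reduces exactly to ``mmd_squared(x, y, h)``.
    """
    samples = [_as_points(s) for s in (x, a, y, b)]
    if any(s.shape[0] == 0 for s in samples):
        raise ValueError("all four samples must be nonempty")
    signs = (1.0, -1.0, -1.0, 1.0)  # +x -a -y +b
    value = 0.0
    for si, sign_i in zip(samples, signs):
        for sj, sign_j in zip(samples, signs):
            value += sign_i * sign_j * gram_matrix(si, sj, h).mean()
    return float(max(value, 0.0))


def witness_function(x, y, grid, h: float) -> np.ndarray:
    """Empirical witness f(t) = mean_x k(x, t) - mean_y k(y, t) on a grid.

    The witness attains the MMD supremum over the RKHS unit ball (up to
    normalisation); its extrema show where the two distributions differ.
    """
    grid = _as_points(grid)
    if grid.shape[0] == 0:
        raise ValueError("grid must be nonempty")
    return gram_matrix(grid, x, h).mean(axis=1) - gram_matrix(grid, y, h).mean(axis=1)


@dataclasses.dataclass
class MMDTestResult:
    population_id: str
    set_id: str
    mmd2: float
    mmd: float
    M: int
    p_value: float
    q_value: float = float("nan")
    significant: bool = False
    seed: int = 0
    bandwidth: float = float("nan")


def permutation_test(
    x,
    control,
    *,
    h: float,
    M: int = 10_000,
    seed: int = 0,
    tie_rule: str = ">",
    population_id: str = "",
    set_id: str = "",
) -> MMDTestResult:
    """Permutation two-sample MMD test of a knockdown against its control.

    Pools the samples, recomputes the biased MMD^2 under ``M`` seeded random
    relabelings preserving group sizes, and reports
    p = (sum_i I(MMD_i^2 > MMD^2) + 1) / (M + 1). ``tie_rule=">="`` counts
    ties in favour of larger p (more conservative).
    """
    x, c = _as_points(x), _as_points(control)
    if x.shape[0] < 2 or c.shape[0] < 2:
        raise ValueError("permutation test needs >= 2 structures per group")
    if M < 1:
        raise ValueError("M must be >= 1")
    if tie_rule not in (">", ">="):
        raise ValueError("tie_rule must be '>' or '>='")
    nx, nc = x.shape[0], c.shape[0]
    pooled = np.vstack([x, c])
    K = gram_matrix(pooled, pooled, h)

    w_obs = np.concatenate([np.full(nx, 1.0 / nx), np.full(nc, -1.0 / nc)])
    rng = np.random.default_rng(seed)
    n = nx + nc
    # M random permutations at once: row-wise argsort of uniforms
    order = np.argsort(rng.random((M, n)), axis=1)
    in_x = np.zeros((M, n), dtype=bool)
    np.put_along_axis(in_x, order[:, :nx], True, axis=1)
    W = np.where(in_x, 1.0 / nx, -1.0 / nc)
    # the observed statistic goes through the identical arithmetic path
    # (row 0) so permutations that reproduce the original labelling tie it
    # bit for bit
    W = np.vstack([w_obs, W])
    stats = np.maximum(np.einsum("mi,mi->m", W @ K, W), 0.0)
    observed = float(stats[0])
    perm_stats = stats[1:]

    exceed = perm_stats > observed if tie_rule == ">" else perm_stats >= observed
    p = (int(exceed.sum()) + 1) / (M + 1)
    return MMDTestResult(
        population_id=population_id,
        set_id=set_id,
        mmd2=observed,
        mmd=float(np.sqrt(observed)),
        M=M,
        p_value=p,
        seed=seed,
        bandwidth=h,
    )


class MMDScreen(BaseEstimator):
    """Permutation MMD screen of every knockdown against its set control.

    One Gaussian-kernel bandwidth is computed by the median heuristic over
    the aggregate of all structures of the condition, so all MMD values in a
    screen share a scale; each knockdown is then permutation-tested against
    the internal control of its own experimental set, and BH-FDR is applied
    over all resulting p-values.

    Parameters
    ----------
    permutations : int, default 10000
        Number of label permutations M per test.
    seed : int, default 0
        Master seed; per-test generators are spawned from it, so results do
        not depend on evaluation order.
    fdr_threshold : float, default 0.05
        BH false-discovery-rate cut defining significant populations.
    bandwidth : float or None
        Fixed kernel length scale; ``None`` (default) applies the median
        heuristic over the aggregate sample.
    tie_rule : {">", ">="}, default ">"
        How permutation statistics tying the observed one count.

    Attributes
    ----------
    bandwidth_ : float
        Kernel length scale actually used.
    results_ : DataFrame
        One row per knockdown with mmd2, mmd, p, q and significance.
    tests_ : list of MMDTestResult
    """

    def __init__(
        self,
        permutations: int = 10_000,
        seed: int = 0,
        fdr_threshold: float = 0.05,
        bandwidth: float | None = None,
        tie_rule: str = ">",
    ):
        self.permutations = permutations
        self.seed = seed
        self.fdr_threshold = fdr_threshold
        self.bandwidth = bandwidth
        self.tie_rule = tie_rule

    def fit(self, fm: FeatureMatrix, y=None):
        if self.bandwidth is not None:
            self.bandwidth_ = float(self.bandwidth)
        else:
            self.bandwidth_ = median_bandwidth(fm.aggregate(), seed=self.seed)
        knockdowns = fm.knockdowns()
        seeds = np.random.SeedSequence(self.seed).generate_state(max(len(knockdowns), 1))
        tests: list[MMDTestResult] = []
        for (set_id, pop), sub_seed in zip(knockdowns, seeds):
            res = permutation_test(
                fm.values(set_id, pop),
                fm.control_values(set_id),
                h=self.bandwidth_,
                M=self.permutations,
                seed=int(sub_seed % (2**31)),
                tie_rule=self.tie_rule,
                population_id=pop,
                set_id=set_id,
            )
            tests.append(res)
        if tests:
            q = bh_fdr([t.p_value for t in tests])
            for t, qv in zip(tests, q):
                t.q_value = float(qv)
                t.significant = bool(qv < self.fdr_threshold)
        self.tests_ = tests
        self.results_ = pd.DataFrame([dataclasses.asdict(t) for t in tests])
        return self

    def hit_populations(self) -> set[tuple[str, str]]:
        return {(t.set_id, t.population_id) for t in self.tests_ if t.significant}

    def significant_populations(self) -> list[tuple[str, str]]:
        """Significant (set, population) pairs in screen order."""
        return [(t.set_id, t.population_id) for t in self.tests_ if t.significant]


def mmd_screen(
    fm: FeatureMatrix,
    M: int = 10_000,
    seed: int = 0,
    fdr_threshold: float = 0.05,
    **kwargs,
) -> list[MMDTestResult]:
    """Functional wrapper over :class:`MMDScreen`."""
    screen = MMDScreen(
        permutations=M, seed=seed, fdr_threshold=fdr_threshold, **kwargs
    ).fit(fm)
    return screen.tests_
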