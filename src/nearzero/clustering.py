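"""k-means clustering of expression profiles with correlation distance.

Genes with growth-rate-dependent expression are grouped by the *shape*
of their mean-normalized profiles: the distance between two profiles is
``d = 1 - r`` with ``r`` the Pearson correlation ("positive correlation
as distance metric"), so perfectly correlated profiles are at distance 0
and anticorrelated ones at distance 2.

Lloyd iterations assign each gene to the nearest centroid and update
each centroid as the arithmetic mean of its member profiles,
re-mean-normalized to stay on the profile scale.  Seeding is
distance-weighted (k-means++-style with d = 1 - r) and the best of
``n_restarts`` runs by total objective is kept; everything is
deterministic at a fixed seed.  Input rows are mean-normalized first,
which makes cluster labels invariant to positive per-gene scaling of the
raw profiles.

Also provided: a breakpoint detector for the "constant below a threshold
growth rate" profile shape, fitting flat-then-linear models in log10(mu)
against a single-line alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusteringConfig",
    "ClusterAssignment",
    "ThresholdEstimate",
    "correlation_distance",
    "kmeans_correlation",
    "detect_threshold",
]


@dataclass
class ClusteringConfig:
    k: int = 7
    max_iterations: int = 1000
    n_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class ClusterAssignment:
    """Labels (1..k per gene), centroids (k x conditions) and objective."""

    labels: pd.Series
    centroids: pd.DataFrame
    objective: float
    n_iterations: int
    objective_history: list

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class ThresholdEstimate:
    """Breakpoint below which a profile is flat (in growth rate).

    ``has_threshold`` is False when a single line explains the profile as
    well as the best flat-then-linear model (F test at alpha)."""

    breakpoint: float | None
    direction: str | None
    plateau_level: float | None
    has_threshold: bool
    p_value: float


def correlation_distance(x, y) -> float:
    """d = 1 - Pearson r, in [0, 2].

    Convention for degenerate (constant) profiles: two constants are at
    distance 0 if equal after mean-normalization (which any two positive
    constants are) and 1 otherwise; a constant vs a non-constant profile
    is at distance 1 (zero correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("profiles must be 1-d, equal length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 and ny == 0:
        mx, my = x.mean(), y.mean()
        if mx != 0 and my != 0:
            return 0.0  # both mean-normalize to the flat unit profile
        return 0.0 if np.allclose(x, y) else 1.0
    if nx == 0 or ny == 0:
        return 1.0
    return float(1.0 - (xc @ yc) / (nx * ny))


def _unit_rows(M: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm; zero-variance rows become 0."""
    Mc = M - M.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Mc, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(norms > 0, Mc / norms, 0.0)
    return Z


def _mean_normalize_rows(M: np.ndarray) -> np.ndarray:
    means = M.mean(axis=1, keepdims=True)
    safe = np.where(means != 0, means, 1.0)
    return M / safe


def _lloyd(
    X: np.ndarray,
    k: int,
    max_iterations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float, int, list]:
    n = X.shape[0]
    Z = _unit_rows(X)

    # distance-weighted seeding with d = 1 - r
    centers = [int(rng.integers(n))]
    for _ in range(1, k):
        Cz = Z[centers]
        dmin = (1.0 - Z @ Cz.T).min(axis=1)
        dmin = np.clip(dmin, 0.0, None)
        total = dmin.sum()
        if total <= 0:
            probs = np.full(n, 1.0 / n)
        else:
            probs = dmin / total
        centers.append(int(rng.choice(n, p=probs)))
    centroids = _mean_normalize_rows(X[centers].copy())

    labels = None
    history: list = []
    objective = np.inf
    it = 0
    for it in range(1, max_iterations + 1):
        D = 1.0 - Z @ _unit_rows(centroids).T
        new_labels = D.argmin(axis=1)

        # re-seed empty clusters with the point farthest from its centroid
        for c in range(k):
            if not np.any(new_labels == c):
                far = int(np.argmax(D[np.arange(n), new_labels]))
                new_labels[far] = c
        new_objective = float(D[np.arange(n), new_labels].sum())

        if new_objective > objective + 1e-12:
            # the mean-based centroid update is not guaranteed to decrease
            # the 1-r objective; keep the previous (better) state
            it -= 1
            break
        converged = labels is not None and np.array_equal(new_labels, labels)
        labels, objective = new_labels, new_objective
        history.append(objective)
        centroids = np.vstack(
            [_mean_normalize_rows(X[labels == c].mean(axis=0, keepdims=True))[0] for c in range(k)]
        )
        if converged:
            # objective now pairs the stable labels with their own centroids
            break
    return labels, centroids, objective, it, history


def kmeans_correlation(
    profiles: pd.DataFrame,
    config: ClusteringConfig | None = None,
) -> ClusterAssignment:
    """Cluster genes x conditions profiles with 1 - r distance.

    Rows are mean-normalized internally; the best of ``n_restarts``
    seeded runs by total within-cluster distance is returned, with
    cluster labels 1..k.
    """
    config = config or ClusteringConfig()
    n = profiles.shape[0]
    if n < config.k:
        raise ValueError(f"need at least k={config.k} genes, got {n}")
    X = _mean_normalize_rows(profiles.to_numpy(dtype=float))

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_restarts)
    best = None
    for ss in seeds:
        rng = np.random.default_rng(ss)
        labels, centroids, objective, n_iter, history = _lloyd(
            X, config.k, config.max_iterations, rng
        )
        if best is None or objective < best[2] - 1e-12:
            best = (labels, centroids, objective, n_iter, history)
    labels, centroids, objective, n_iter, history = best
    return ClusterAssignment(
        labels=pd.Series(labels + 1, index=profiles.index, name="cluster"),
        centroids=pd.DataFrame(
            centroids, index=pd.RangeIndex(1, config.k + 1, name="cluster"),
            columns=profiles.columns,
        ),
        objective=objective,
        n_iterations=n_iter,
        objective_history=history,
    )


def detect_threshold(
    profile,
    growth_rates,
    alpha: float = 0.05,
) -> ThresholdEstimate:
    """Find the growth rate below which a profile is flat.

    Fits, for every interior condition, a model that is constant below
    the breakpoint and linear in log10(mu) above it; the breakpoint
    minimizing total SSE is kept if the piecewise model beats a single
    line in an F test at ``alpha``.  Direction is the sign of the sloped
    segment.  Globally flat or strictly log-linear profiles report no
    threshold.
    """
    y = np.asarray(profile, dtype=float)
    rates = np.asarray(growth_rates, dtype=float)
    if y.shape != rates.shape or y.ndim != 1:
        raise ValueError("profile and growth_rates must be 1-d and equal length")
    n = len(y)
    if n < 5:
        raise ValueError("need >= 5 conditions to detect a threshold")
    order = np.argsort(rates)
    rates, y = rates[order], y[order]
    x = np.log10(rates)

    slope1, icpt1 = np.polyfit(x, y, 1)
    sse_line = float(np.sum((y - (slope1 * x + icpt1)) ** 2))

    eps = 1e-12 * (float(np.sum(y**2)) + 1e-30)
    if sse_line <= eps:
        # a single line (possibly flat) already explains the profile
        return ThresholdEstimate(None, None, None, False, 1.0)

    best = None
    for j in range(1, n - 2):  # breakpoint at interior conditions, >=3 points above
        plateau = float(y[: j + 1].mean())
        sse_lo = float(np.sum((y[: j + 1] - plateau) ** 2))
        s, b = np.polyfit(x[j:], y[j:], 1)
        sse_hi = float(np.sum((y[j:] - (s * x[j:] + b)) ** 2))
        sse = sse_lo + sse_hi
        if best is None or sse < best[0]:
            best = (sse, j, plateau, float(s))
    sse_pw, j, plateau, slope = best

    p_full, p_line = 4, 2  # plateau + slope + intercept + breakpoint vs line
    if n <= p_full or sse_pw <= eps:
        f_p = 0.0 if sse_pw < sse_line else 1.0
    else:
        fstat = ((sse_line - sse_pw) / (p_full - p_line)) / (sse_pw / (n - p_full))
        f_p = float(stats.f.sf(max(fstat, 0.0), p_full - p_line, n - p_full))
    if f_p >= alpha:
        return ThresholdEstimate(None, None, None, False, f_p)
    return ThresholdEstimate(
        breakpoint=float(rates[j]),
        direction="up" if slope > 0 else "down",
        plateau_level=plateau,
        has_threshold=True,
        p_value=f_p,
    )
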