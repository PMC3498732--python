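"""Time-course / growth-rate differential expression testing.

Per-gene significance of growth-rate-dependent expression is assessed
with a two-model F statistic: the full model regresses a gene's profile
on a natural cubic spline in the covariate (log10 specific growth rate by
default, spanning ~2.5 orders of magnitude across the combined
chemostat + retentostat design), the null model is intercept-only:

    F = [(RSS0 - RSS1) / (d1 - d0)] / [RSS1 / (n - d1)]

The null distribution is obtained by permuting whole sample columns (the
same permutation set for every gene, preserving gene-gene correlation)
and p-values use the add-one estimator p = (1 + #{F_perm >= F_obs})/(B+1),
which never returns 0.  False-discovery rates are estimated with the
Storey q-value procedure (pi0 from a cubic-polynomial smoother over a
lambda grid, falling back to pi0 = 1, i.e. Benjamini-Hochberg, when the
smoother is unstable).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TestConfig",
    "natural_spline_basis",
    "build_design",
    "fit_spline_fstat",
    "permutation_pvalues",
    "estimate_pi0",
    "estimate_qvalues",
    "call_significant",
    "differential_expression",
]

_RSS_TINY = 1e-12


@dataclass
class TestConfig:
    """Settings for the permutation F test.

    ``covariate`` selects the per-sample regressor: "log10_growth_rate"
    (default, appropriate for the combined chemostat/retentostat series)
    or "time" (retentostat day).  ``q_threshold`` is reported alongside
    the p-value cut-off; the printed pairing of the two on any given
    dataset is data-dependent, not a contract.
    """

    df_full: int = 3
    covariate: str = "log10_growth_rate"
    n_permutations: int = 1000
    seed: int = 0
    p_threshold: float = 0.01
    q_threshold: float = 1.88e-4

    def __post_init__(self) -> None:
        if self.df_full < 1:
            raise ValueError("df_full must be >= 1")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


def natural_spline_basis(
    x: np.ndarray,
    df: int = 3,
    interior_knots: np.ndarray | None = None,
    boundary_knots: tuple[float, float] | None = None,
) -> np.ndarray:
    """Natural (restricted) cubic spline basis with ``df`` columns.

    Linear beyond the boundary knots; interior knots default to the
    ``df - 1`` equally spaced quantiles of ``x``.  Column 1 is ``x``
    itself; the remaining columns are the usual truncated-power
    differences that enforce the natural boundary constraints.  An
    intercept is NOT included.
    """
    x = np.asarray(x, dtype=float)
    if boundary_knots is None:
        boundary_knots = (float(np.min(x)), float(np.max(x)))
    if interior_knots is None:
        probs = np.linspace(0, 1, df + 1)[1:-1]
        interior_knots = np.quantile(x, probs)
    knots = np.unique(
        np.concatenate([[boundary_knots[0]], np.atleast_1d(interior_knots), [boundary_knots[1]]])
    )
    last = knots[-1]

    def d(knot: float) -> np.ndarray:
        if last == knot:
            return np.zeros_like(x)
        return (
            np.clip(x - knot, 0, None) ** 3 - np.clip(x - last, 0, None) ** 3
        ) / (last - knot)

    d_penult = d(knots[-2])
    cols = [x] + [d(k) - d_penult for k in knots[:-2]]
    return np.column_stack(cols)


def build_design(covariate: np.ndarray, df_full: int = 3) -> np.ndarray:
    """Full-model design matrix: intercept + natural cubic spline columns."""
    basis = natural_spline_basis(covariate, df=df_full)
    return np.column_stack([np.ones(len(basis)), basis])


def _fstats(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """Row-wise F statistics of full model X vs intercept-only.

    Y is genes x samples.  A rank-deficient basis silently reduces the
    full-model degrees of freedom (least-squares via lstsq).
    """
    n = Y.shape[1]
    coef, _, rank, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ coef).T
    rss1 = np.einsum("ij,ij->i", resid, resid)
    centered = Y - Y.mean(axis=1, keepdims=True)
    rss0 = np.einsum("ij,ij->i", centered, centered)
    d1, d0 = int(rank), 1
    if n <= d1:
        raise ValueError("need more samples than full-model parameters")
    scale = rss0.mean() if rss0.size else 1.0
    tiny = _RSS_TINY * max(scale, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / (d1 - d0)) / (rss1 / (n - d1))
    F = np.where(rss1 <= tiny, np.where(rss0 - rss1 <= tiny, 0.0, np.inf), F)
    F = np.where(np.isnan(F), 0.0, F)
    return F, d1


def fit_spline_fstat(
    profile: np.ndarray,
    covariate: np.ndarray,
    df_full: int = 3,
) -> float:
    """F statistic of a single gene's profile against the spline model."""
    profile = np.asarray(profile, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if profile.shape != covariate.shape:
        raise ValueError("profile and covariate must have equal length")
    if len(profile) <= df_full + 1:
        raise ValueError("need n_samples > df_full + 1")
    X = build_design(covariate, df_full)
    F, _ = _fstats(profile[None, :], X)
    return float(F[0])


def permutation_pvalues(
    Y: np.ndarray | pd.DataFrame,
    covariate: np.ndarray,
    config: TestConfig,
    exhaustive: bool | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-values of the spline F statistic for every gene.

    Sample columns are permuted (identically for all genes) ``B`` times
    with a seeded generator; ``p = (1 + #{F_perm >= F_obs}) / (B + 1)``.
    When ``exhaustive`` (default: automatic for small n), all n!
    orderings are enumerated instead of sampled.

    Returns ``(F_obs, p)``.
    """
    Y_arr = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    n = Y_arr.shape[1]
    if covariate.shape != (n,):
        raise ValueError("covariate length must match the number of samples")
    X = build_design(covariate, config.df_full)
    # route the observed statistic through the same indexed-copy path as
    # the permuted ones so that the identity permutation ties bit-exactly
    F_obs, _ = _fstats(Y_arr[:, np.arange(n)], X)

    if exhaustive is None:
        exhaustive = math.factorial(n) <= config.n_permutations
    if exhaustive:
        perms = [np.asarray(p) for p in itertools.permutations(range(n))]
    else:
        rng = np.random.default_rng(config.seed)
        perms = [rng.permutation(n) for _ in range(config.n_permutations)]

    count = np.zeros(Y_arr.shape[0], dtype=np.int64)
    for perm in perms:
        F_perm, _ = _fstats(Y_arr[:, perm], X)
        count += F_perm >= F_obs
    p = (1.0 + count) / (len(perms) + 1.0)
    return F_obs, p


def estimate_pi0(p: np.ndarray) -> float:
    """Storey estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) on the grid
    lambda = 0.05, 0.10, ..., 0.90 is smoothed with a cubic polynomial and
    evaluated at the largest lambda; unstable estimates (non-finite or
    <= 0) fall back to 1.
    """
    p = np.asarray(p, dtype=float)
    lam = np.arange(0.05, 0.95, 0.05)
    pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
    try:
        coef = np.polyfit(lam, pi0_lam, 3)
        pi0 = float(np.polyval(coef, lam.max()))
    except np.linalg.LinAlgError:
        pi0 = 1.0
    if not np.isfinite(pi0) or pi0 <= 0:
        pi0 = 1.0
    return min(pi0, 1.0)


def estimate_qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j).

    With ``pi0`` forced to 1 this reduces exactly to Benjamini-Hochberg
    adjusted p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_significant(results: pd.DataFrame, config: TestConfig) -> list:
    """Gene ids with p below the threshold, ordered by (p, gene_id)."""
    hits = results[results["p"] < config.p_threshold]
    hits = hits.sort_values(["p", "gene_id"], kind="stable")
    return list(hits["gene_id"])


def differential_expression(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    config: TestConfig | None = None,
) -> pd.DataFrame:
    """Run the permutation F test on a genes x samples matrix.

    The covariate is taken from the metadata (log10 growth rate, or
    retentostat day when ``config.covariate == "time"``).  Returns a
    DataFrame with columns gene_id, F, p, q, significant, in the input
    gene order.
    """
    from .preprocess import validate_metadata

    config = config or TestConfig()
    meta = validate_metadata(matrix, metadata)
    samples = list(matrix.columns)
    if config.covariate == "log10_growth_rate":
        cov = np.log10(meta.loc[samples, "growth_rate"].to_numpy(dtype=float))
    elif config.covariate == "time":
        cov = pd.to_numeric(meta.loc[samples, "time_d"], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(cov)):
            raise ValueError("time covariate requested but time_d missing for some samples")
    else:
        raise ValueError(f"unknown covariate {config.covariate!r}")
    F, p = permutation_pvalues(matrix, cov, config)
    q = estimate_qvalues(p)
    return pd.DataFrame(
        {
            "gene_id": matrix.index,
            "F": F,
            "p": p,
            "q": q,
            "significant": p < config.p_threshold,
        }
    ).reset_index(drop=True)
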