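"""Redundancy analysis, variance partitioning, trajectory comparison, PCA.

RDA here is multivariate least squares of a (column-centered) response
matrix on dummy-coded categorical constraints: R-squared is the fraction
of total response variance captured by the fitted values, adjusted with
the Ezekiel formula ``1 - (1 - R2)(n - 1)/(n - p - 1)``.  Partial RDA
removes a conditioning factor first (Peres-Neto convention for adjusted
fractions); significance is by permutation (of response rows, or of
residuals under the conditioning-only model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "RDAResult",
    "TrajectoryResult",
    "rda",
    "adjusted_r2",
    "partial_rda",
    "variance_partition",
    "trajectory_analysis",
    "pca_scores",
]


@dataclass(frozen=True)
class RDAResult:
    R2: float
    R2_adj: float
    P: float | None
    n: int
    p_x: int
    p_z: int = 0

    def to_row(self, **extra) -> dict:
        row = {"R2": self.R2, "R2_adj": self.R2_adj, "P": self.P, "n": self.n,
               "p_x": self.p_x, "p_z": self.p_z}
        row.update(extra)
        return row


def _dummy(X) -> np.ndarray:
    """Full-rank dummy coding (first level dropped) of a categorical
    factor; 2-D numeric input passes through unchanged."""
    X = np.asarray(X)
    if X.ndim == 2:
        return X.astype(float)
    levels = pd.unique(X)
    if len(levels) < 2:
        return np.zeros((len(X), 0))
    out = np.zeros((len(X), len(levels) - 1))
    index = {lv: i for i, lv in enumerate(levels)}
    for i, v in enumerate(X):
        j = index[v]
        if j > 0:
            out[i, j - 1] = 1.0
    return out


def _fit_r2(Yc: np.ndarray, X: np.ndarray) -> tuple[float, int, np.ndarray]:
    """R2 of centered response on centered predictors; returns
    (R2, rank, fitted)."""
    ss_tot = float(np.sum(Yc**2))
    if X.shape[1] == 0:
        return 0.0, 0, np.zeros_like(Yc)
    Xc = X - X.mean(axis=0)
    Q, R = np.linalg.qr(Xc)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max())))
    Q = Q[:, :rank]
    fitted = Q @ (Q.T @ Yc)
    return float(np.sum(fitted**2)) / ss_tot, rank, fitted


def adjusted_r2(R2: float, n: int, p: int) -> float:
    """Ezekiel-adjusted R-squared, ``1 - (1 - R2)(n - 1)/(n - p - 1)``.

    May legitimately be negative.  Requires ``n > p + 1``.
    """
    if n <= p + 1:
        raise ValueError(f"adjusted R2 needs n > p + 1 (n={n}, p={p})")
    if p == 0:
        return R2
    return 1.0 - (1.0 - R2) * (n - 1) / (n - p - 1)


def rda(Y, X, n_perm: int = 999, seed: int | None = None) -> RDAResult:
    """Redundancy analysis of ``Y`` (n x q, column-centered internally) on
    a categorical factor or dummy matrix ``X``.

    P is the permutation p-value of the R2 under row shuffling of the
    response, ``(b + 1)/(n_perm + 1)``.
    """
    Y = np.asarray(Y, dtype=float)
    Yc = Y - Y.mean(axis=0)
    if float(np.sum(Yc**2)) <= 0:
        raise ValueError("constant response matrix")
    Xd = _dummy(X)
    n = Y.shape[0]
    if Xd.shape[1] == 0:
        warnings.warn("single-level constraint: R2 = 0")
        return RDAResult(R2=0.0, R2_adj=0.0, P=None, n=n, p_x=0)
    r2, p_x, _ = _fit_r2(Yc, Xd)
    r2_adj = adjusted_r2(r2, n, p_x)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r2_star, _, _ = _fit_r2(Yc[rng.permutation(n)], Xd)
        if r2_star >= r2 - 1e-12:
            count += 1
    return RDAResult(R2=r2, R2_adj=r2_adj, P=(count + 1) / (n_perm + 1), n=n, p_x=p_x)


def partial_rda(Y, X, Z=None, n_perm: int = 999, seed: int | None = None) -> RDAResult:
    """Pure effect of ``X`` on ``Y`` after conditioning on ``Z``.

    The pure fraction is ``R2(X+Z) - R2(Z)`` and its adjusted version the
    difference of the Ezekiel-adjusted terms.  P comes from permuting the
    residuals of the conditioning-only model.  With ``Z=None`` this is
    exactly :func:`rda` (same seed, same draws).
    """
    if Z is None:
        return rda(Y, X, n_perm=n_perm, seed=seed)
    Zd = _dummy(Z)
    if Zd.shape[1] == 0:
        return rda(Y, X, n_perm=n_perm, seed=seed)
    Y = np.asarray(Y, dtype=float)
    Yc = Y - Y.mean(axis=0)
    if float(np.sum(Yc**2)) <= 0:
        raise ValueError("constant response matrix")
    Xd = _dummy(X)
    n = Y.shape[0]
    XZ = np.hstack([Xd, Zd])
    r2_z, p_z, fitted_z = _fit_r2(Yc, Zd)
    r2_xz, p_xz, _ = _fit_r2(Yc, XZ)
    p_x = p_xz - p_z
    pure = r2_xz - r2_z
    if p_x == 0:
        warnings.warn("constraint nested within the conditioning factor: pure fraction 0")
        return RDAResult(R2=0.0, R2_adj=0.0, P=None, n=n, p_x=0, p_z=p_z)
    pure_adj = adjusted_r2(r2_xz, n, p_xz) - adjusted_r2(r2_z, n, p_z)
    resid = Yc - fitted_z
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        Y_star = fitted_z + resid[rng.permutation(n)]
        r2_z_s, _, _ = _fit_r2(Y_star, Zd)
        r2_xz_s, _, _ = _fit_r2(Y_star, XZ)
        if (r2_xz_s - r2_z_s) >= pure - 1e-12:
            count += 1
    return RDAResult(
        R2=pure, R2_adj=pure_adj, P=(count + 1) / (n_perm + 1), n=n, p_x=p_x, p_z=p_z
    )


def variance_partition(
    Y, X1, X2, n_perm: int = 999, seed: int | None = None
) -> pd.DataFrame:
    """Two-factor variance partition of ``Y`` into pure, shared and
    residual fractions (adjusted R2 scale; Peres-Neto convention).

    Pure fractions are tested by partial RDA; the shared fraction is not
    permutable and carries no P.  On the unadjusted scale the fractions
    sum to ``R2(X1+X2)`` exactly.
    """
    Y = np.asarray(Y, dtype=float)
    Yc = Y - Y.mean(axis=0)
    X1d, X2d = _dummy(X1), _dummy(X2)
    n = Y.shape[0]
    r2_1, p1, _ = _fit_r2(Yc, X1d)
    r2_2, p2, _ = _fit_r2(Yc, X2d)
    r2_12, p12, _ = _fit_r2(Yc, np.hstack([X1d, X2d]))
    a1, a2, a12 = (
        adjusted_r2(r2_1, n, p1),
        adjusted_r2(r2_2, n, p2),
        adjusted_r2(r2_12, n, p12),
    )
    pure1 = partial_rda(Y, X1, X2, n_perm=n_perm, seed=seed)
    pure2 = partial_rda(Y, X2, X1, n_perm=n_perm, seed=seed)
    rows = [
        {"fraction": "total[X1]", "R2": r2_1, "R2_adj": a1,
         "P": rda(Y, X1, n_perm=n_perm, seed=seed).P},
        {"fraction": "total[X2]", "R2": r2_2, "R2_adj": a2,
         "P": rda(Y, X2, n_perm=n_perm, seed=seed).P},
        {"fraction": "pure[X1]", "R2": pure1.R2, "R2_adj": pure1.R2_adj, "P": pure1.P},
        {"fraction": "pure[X2]", "R2": pure2.R2, "R2_adj": pure2.R2_adj, "P": pure2.P},
        {"fraction": "shared", "R2": r2_1 + r2_2 - r2_12, "R2_adj": a1 + a2 - a12,
         "P": None},
        {"fraction": "residual", "R2": 1.0 - r2_12, "R2_adj": 1.0 - a12, "P": None},
    ]
    return pd.DataFrame(rows)


@dataclass
class TrajectoryResult:
    """Pairwise comparison of group mean-difference vectors.

    ``pairs`` lists the group contrasts; ``magnitudes`` their Euclidean
    norms.  ``p_size[i, j]`` tests the magnitude difference between
    contrasts i and j, ``theta``/``p_theta`` the angle (degrees) between
    them.  Letters group contrasts whose differences are not significant
    at ``alpha`` (single linkage).
    """

    pairs: list[tuple[str, str]]
    magnitudes: np.ndarray
    p_size: np.ndarray
    theta: np.ndarray
    p_theta: np.ndarray
    letters_size: list[str]
    letters_theta: list[str]
    alpha: float
    n_perm: int
    exhaustive: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, b in combinations(range(len(self.pairs)), 2):
            rows.append(
                {
                    "contrast_1": "-".join(self.pairs[a]),
                    "contrast_2": "-".join(self.pairs[b]),
                    "size_diff": abs(self.magnitudes[a] - self.magnitudes[b]),
                    "P_size": self.p_size[a, b],
                    "theta_deg": self.theta[a, b],
                    "P_theta": self.p_theta[a, b],
                }
            )
        return pd.DataFrame(rows)


def _pair_stats(means: np.ndarray, pair_idx: list[tuple[int, int]]):
    vecs = np.array([means[j] - means[i] for i, j in pair_idx])
    mags = np.linalg.norm(vecs, axis=1)
    m = len(pair_idx)
    size_diff = np.abs(mags[:, None] - mags[None, :])
    norms = np.where(mags > 0, mags, 1.0)
    cos = (vecs @ vecs.T) / np.outer(norms, norms)
    theta = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return vecs, mags, size_diff, theta


def _letters(p_matrix: np.ndarray, alpha: float) -> list[str]:
    """Single-linkage homogeneous subsets: contrasts joined whenever their
    pairwise difference is not significant share a letter."""
    m = p_matrix.shape[0]
    parent = list(range(m))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(m), 2):
        if p_matrix[i, j] > alpha:
            parent[find(i)] = find(j)
    roots: dict[int, str] = {}
    letters = []
    for i in range(m):
        r = find(i)
        if r not in roots:
            roots[r] = chr(ord("a") + len(roots))
        letters.append(roots[r])
    return letters


def _group_means(Y: np.ndarray, codes: np.ndarray, g: int) -> np.ndarray:
    means = np.zeros((g, Y.shape[1]))
    np.add.at(means, codes, Y)
    return means / np.bincount(codes, minlength=g)[:, None]


def trajectory_analysis(
    tangent,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    exhaustive: bool = False,
) -> TrajectoryResult:
    """Compare magnitudes and directions of between-group shape differences.

    For each pair of groups the difference vector between group mean
    shapes is formed; its norm is the contrast magnitude and angles are
    measured between contrast vectors.  Null distributions come from
    reshuffling group labels (or, with ``exhaustive=True``, enumerating
    every distinct label assignment, feasible only for tiny samples).
    """
    Y = np.asarray(tangent, dtype=float)
    labels = np.asarray(groups)
    levels = list(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    codes = np.array([levels.index(v) for v in labels])
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise ValueError("every group needs n >= 2")
    g = len(levels)
    pair_idx = list(combinations(range(g), 2))
    means = _group_means(Y, codes, g)
    _, mags, size_diff, theta = _pair_stats(means, pair_idx)
    m = len(pair_idx)

    count_size = np.zeros((m, m))
    count_theta = np.zeros((m, m))
    if exhaustive:
        from sympy.utilities.iterables import multiset_permutations

        total = 0
        for perm_labels in multiset_permutations(list(codes)):
            total += 1
            mstar = _group_means(Y, np.asarray(perm_labels), g)
            _, _, sd, th = _pair_stats(mstar, pair_idx)
            count_size += sd >= size_diff - 1e-12
            count_theta += th >= theta - 1e-9
        p_size = count_size / total
        p_theta = count_theta / total
        n_eff = total - 1
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            mstar = _group_means(Y, codes[rng.permutation(len(codes))], g)
            _, _, sd, th = _pair_stats(mstar, pair_idx)
            count_size += sd >= size_diff - 1e-12
            count_theta += th >= theta - 1e-9
        p_size = (count_size + 1) / (n_perm + 1)
        p_theta = (count_theta + 1) / (n_perm + 1)
        n_eff = n_perm
    np.fill_diagonal(p_size, 1.0)
    np.fill_diagonal(p_theta, 1.0)
    pairs = [(str(levels[i]), str(levels[j])) for i, j in pair_idx]
    return TrajectoryResult(
        pairs=pairs,
        magnitudes=mags,
        p_size=p_size,
        theta=theta,
        p_theta=p_theta,
        letters_size=_letters(p_size, alpha),
        letters_theta=_letters(p_theta, alpha),
        alpha=alpha,
        n_perm=n_eff,
        exhaustive=exhaustive,
    )


def pca_scores(tangent) -> tuple[np.ndarray, np.ndarray]:
    """Centered principal-component scores of shape variables.

    Returns ``(scores, explained)`` where ``explained`` are variance
    fractions summing to 1 (over components with nonzero variance).
    """
    Y = np.asarray(tangent, dtype=float)
    if Y.shape[0] < 2:
        raise ValueError("PCA needs at least two observations")
    Yc = Y - Y.mean(axis=0)
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    scores = U * s
    var = s**2
    total = var.sum()
    explained = var / total if total > 0 else var
    return scores, explained
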