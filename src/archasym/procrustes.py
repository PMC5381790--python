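"""Generalised Procrustes superimposition and sliding semi-landmarks.

GPA iteratively translates, scales (optionally) and rotates a set of
landmark configurations to a common consensus so that summed squared
distances to the consensus are minimised.  Semi-landmarks are then slid
along their curve tangents to minimise the thin-plate-spline bending
energy of each configuration relative to the consensus, alternating with
re-superimposition.  Only proper rotations are used; reflection is an
explicit operation (see :mod:`archasym.asymmetry`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import AlignedSet, Configuration, ConfigurationSet, LandmarkScheme

__all__ = [
    "DegenerateConfigurationError",
    "ConvergenceError",
    "BendingEnergyMatrix",
    "center_and_scale",
    "centroid_size",
    "optimal_rotation",
    "gpa",
    "bending_energy",
    "slide_semilandmarks",
    "project_to_tangent",
]


class DegenerateConfigurationError(ValueError):
    """All points coincident (or otherwise unusable) in a configuration."""


class ConvergenceError(RuntimeError):
    """Iterative superimposition failed to converge."""

    def __init__(self, message: str, residual: float | None = None, trace=None):
        super().__init__(message)
        self.residual = residual
        self.trace = trace


def centroid_size(coords: np.ndarray) -> float:
    """Root summed squared distances of the points to their centroid."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def center_and_scale(config: Configuration, do_scale: bool = True):
    """Translate the centroid to the origin and optionally scale to unit
    centroid size.

    Returns ``(configuration, centroid_size)`` where the size is that of
    the *input* configuration.
    """
    coords = np.asarray(config.coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    size = float(np.sqrt(np.sum(centered**2)))
    if size < 1e-12:
        raise DegenerateConfigurationError(
            f"configuration {config.key}: all points coincident (centroid size ~ 0)"
        )
    if do_scale:
        centered = centered / size
    return config.with_coords(centered), size


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation ``R`` (det = +1) minimising ``||A - B R||_F`` over
    rotations, for centered configurations ``A`` and ``B``.

    Kabsch/SVD solution with determinant correction; improper rotations
    (reflections) are never returned.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    M = B.T @ A
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.eye(A.shape[1])
    D[-1, -1] = d
    return U @ D @ Vt


def _rotate_all_to(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotate each centered configuration in ``X`` (n x k x d) onto ``target``."""
    M = np.swapaxes(X, 1, 2) @ target  # n x d x d
    U, _, Vt = np.linalg.svd(M)
    det = np.linalg.det(U @ Vt)
    D = np.repeat(np.eye(target.shape[1])[None], X.shape[0], axis=0)
    D[:, -1, -1] = np.sign(det)
    R = U @ D @ Vt
    return X @ R


def gpa(
    cset: ConfigurationSet,
    do_scale: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> AlignedSet:
    """Generalised Procrustes Analysis of a configuration set.

    Configurations are centered, optionally scaled to unit centroid size,
    and iteratively rotated to the running consensus (the re-standardised
    arithmetic mean) until the consensus root-mean-square change drops
    below ``tol``.

    Raises
    ------
    ConvergenceError
        If the consensus has not stabilised after ``max_iter`` iterations.
    """
    if len(cset) < 2:
        raise ValueError("GPA needs at least two configurations")
    sizes = np.empty(len(cset))
    stack = np.empty((len(cset), cset.scheme.n_points, cset.scheme.dims))
    for i, c in enumerate(cset.configs):
        centered, sizes[i] = center_and_scale(c, do_scale=do_scale)
        stack[i] = centered.coords

    consensus = stack[0].copy()
    if not do_scale:
        consensus = consensus / centroid_size(consensus)
    last_change = np.inf
    for _ in range(max_iter):
        stack = _rotate_all_to(stack, consensus)
        new_consensus = stack.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= centroid_size(new_consensus)
        last_change = float(
            np.sqrt(np.mean((new_consensus - consensus) ** 2))
        )
        consensus = new_consensus
        if last_change < tol:
            break
    else:
        raise ConvergenceError(
            f"GPA did not converge in {max_iter} iterations", residual=last_change
        )
    if not do_scale:
        # consensus on the mean scale of the data rather than unit size
        consensus = stack.mean(axis=0)
        consensus -= consensus.mean(axis=0)
    return AlignedSet(
        source=cset,
        proc_coords=stack,
        centroid_sizes=sizes,
        consensus=consensus,
        scaled=do_scale,
    )


@dataclass(frozen=True)
class BendingEnergyMatrix:
    """Thin-plate-spline bending-energy matrix for a reference configuration.

    ``matrix`` is the k x k upper-left block of the inverted TPS system;
    it is symmetric positive-semidefinite and annihilates displacement
    fields that are affine functions of the reference coordinates.  The
    bending energy of a target ``Y`` (k x d) relative to the reference is
    ``sum_dims |y_d^T B y_d|``.
    """

    reference: np.ndarray
    matrix: np.ndarray

    def energy(self, target: np.ndarray) -> float:
        Y = np.asarray(target, dtype=float)
        return float(abs(np.einsum("kd,kl,ld->", Y, self.matrix, Y)))


def _tps_kernel(r: np.ndarray, dims: int) -> np.ndarray:
    if dims == 2:
        out = np.zeros_like(r)
        mask = r > 0
        out[mask] = r[mask] ** 2 * np.log(r[mask])
        return out
    return -r


def bending_energy(reference) -> BendingEnergyMatrix:
    """Bending-energy matrix of the thin-plate spline anchored at
    ``reference`` (a Configuration or k x d array).

    Kernel ``U(r) = r^2 log r`` in 2D and ``U(r) = -r`` in 3D.
    """
    P = np.asarray(getattr(reference, "coords", reference), dtype=float)
    k, d = P.shape
    r = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=-1)
    if np.any((r + np.eye(k)) < 1e-12):
        raise DegenerateConfigurationError("coincident reference points: singular TPS system")
    K = _tps_kernel(r, d)
    Q = np.hstack([np.ones((k, 1)), P])
    L = np.zeros((k + d + 1, k + d + 1))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    Linv = np.linalg.inv(L)
    B = Linv[:k, :k]
    B = 0.5 * (B + B.T)
    return BendingEnergyMatrix(reference=P, matrix=B)


def _chain_tangents(coords: np.ndarray, scheme: LandmarkScheme) -> tuple[np.ndarray, np.ndarray]:
    """Unit tangent direction at each semi-landmark, estimated by central
    difference between its chain neighbours (anchors included).

    Returns (semi-landmark 0-based indices, m x d unit tangents).
    """
    idx: list[int] = []
    tang: list[np.ndarray] = []
    for chain in scheme.chains:
        path = [chain.start - 1] + [s - 1 for s in chain.semis] + [chain.end - 1]
        for j in range(1, len(path) - 1):
            t = coords[path[j + 1]] - coords[path[j - 1]]
            norm = np.linalg.norm(t)
            if norm < 1e-12:
                t = np.zeros_like(t)
            else:
                t = t / norm
            idx.append(path[j])
            tang.append(t)
    return np.asarray(idx, dtype=int), np.asarray(tang)


def _slide_one(
    coords: np.ndarray, bem: BendingEnergyMatrix, scheme: LandmarkScheme
) -> np.ndarray:
    """Slide one configuration's semi-landmarks along their tangents to
    minimise bending energy relative to ``bem``'s reference.

    Linearised: each semi-landmark moves only along its unit tangent; the
    optimal slide amounts solve the normal equations of the quadratic
    energy.  Fixed landmarks never move.  The move is accepted only if it
    does not increase the energy (it cannot, up to round-off).
    """
    B = bem.matrix
    s_idx, U = _chain_tangents(coords, scheme)
    if len(s_idx) == 0:
        return coords
    # M[j,l] = B[sj,sl] * (u_j . u_l);  rhs_j = sum_d u_jd * (B Y)[sj, d]
    M = B[np.ix_(s_idx, s_idx)] * (U @ U.T)
    BY = B @ coords
    rhs = np.einsum("jd,jd->j", U, BY[s_idx])
    try:
        t = -np.linalg.solve(M + 1e-12 * np.eye(len(s_idx)), rhs)
    except np.linalg.LinAlgError:
        t, *_ = np.linalg.lstsq(M, -rhs, rcond=None)
    new = coords.copy()
    new[s_idx] += t[:, None] * U
    if bem.energy(new) > bem.energy(coords) + 1e-12:
        return coords
    return new


def slide_semilandmarks(
    aligned: AlignedSet,
    scheme: LandmarkScheme | None = None,
    max_iter: int = 5,
    tol: float = 1e-6,
) -> AlignedSet:
    """Alternate semi-landmark sliding (minimum bending energy) with
    re-superimposition until the consensus stabilises.

    Within each cycle the bending energy of every configuration relative
    to the current consensus is non-increasing; fixed landmarks never
    move.  Returns a new :class:`AlignedSet`.
    """
    scheme = scheme or aligned.scheme
    if not scheme.chains:
        return aligned
    stack = aligned.proc_coords.copy()
    consensus = aligned.consensus.copy()
    trace: list[float] = []
    for _ in range(max_iter):
        bem = bending_energy(consensus)
        for i in range(stack.shape[0]):
            stack[i] = _slide_one(stack[i], bem, scheme)
        # re-superimpose the slid configurations
        stack -= stack.mean(axis=1, keepdims=True)
        if aligned.scaled:
            norms = np.sqrt((stack**2).sum(axis=(1, 2)))[:, None, None]
            stack = stack / norms
        stack = _rotate_all_to(stack, consensus)
        new_consensus = stack.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= centroid_size(new_consensus)
        change = float(np.sqrt(np.mean((new_consensus - consensus) ** 2)))
        trace.append(change)
        consensus = new_consensus
        if change < tol:
            break
    if not aligned.scaled:
        consensus = stack.mean(axis=0)
        consensus -= consensus.mean(axis=0)
    return AlignedSet(
        source=aligned.source,
        proc_coords=stack,
        centroid_sizes=aligned.centroid_sizes,
        consensus=consensus,
        scaled=aligned.scaled,
    )


def project_to_tangent(aligned: AlignedSet) -> AlignedSet:
    """Project superimposed configurations orthogonally to the tangent
    space at the consensus.

    Each configuration is flattened and the component along the (unit)
    consensus vector removed; the consensus itself maps to the zero
    vector.  The projection is idempotent.
    """
    n = len(aligned)
    flat = aligned.proc_coords.reshape(n, -1)
    c = aligned.consensus.reshape(-1)
    c_hat = c / np.linalg.norm(c)
    tangent = flat - np.outer(flat @ c_hat, c_hat)
    return AlignedSet(
        source=aligned.source,
        proc_coords=aligned.proc_coords,
        centroid_sizes=aligned.centroid_sizes,
        consensus=aligned.consensus,
        tangent=tangent,
        scaled=aligned.scaled,
    )
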