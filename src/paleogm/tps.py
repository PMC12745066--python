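"""Thin-plate spline interpolation and bending energy.

The TPS is the smoothest (minimum bending energy) interpolant mapping one
landmark configuration onto another. It underlies both missing-landmark
estimation (warping a reference mean onto a damaged specimen) and
semilandmark sliding (whose objective is the bending energy of the
deformation from the sample consensus to each specimen).

Kernels: ``U(r) = r^2 log(r^2)`` in 2D and ``U(r) = -r`` in 3D. With these
(conditionally positive-definite) choices the bending energy quadratic form
is non-negative and vanishes exactly on affine maps.
"""

from __future__ import annotations

import numpy as np


class DegenerateLandmarksError(ValueError):
    """Raised when source landmarks cannot support a TPS (coincident points,
    collinear in 2D / coplanar in 3D)."""


def _kernel(r, dim):
    if dim == 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(r > 0.0, r * r * np.log(r * r), 0.0)
        return u
    return -r


def _kernel_matrix(a, b, dim):
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return _kernel(d, dim)


def _check_source(source):
    source = np.asarray(source, dtype=float)
    k, dim = source.shape
    if dim not in (2, 3):
        raise ValueError(f"dim must be 2 or 3, got {dim}")
    if k < dim + 1:
        raise DegenerateLandmarksError(
            f"need at least dim+1={dim + 1} source points, got {k}"
        )
    dists = np.linalg.norm(source[:, None, :] - source[None, :, :], axis=-1)
    np.fill_diagonal(dists, np.inf)
    if dists.min() < 1e-12:
        raise DegenerateLandmarksError("coincident source landmarks")
    # rank of centred source detects collinear (2D) / coplanar (3D) input
    centred = source - source.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-10 * max(1.0, np.abs(centred).max())) < dim:
        raise DegenerateLandmarksError(
            "source landmarks are collinear/coplanar; TPS system singular"
        )
    return source


def _tps_system(source, dim):
    k = source.shape[0]
    K = _kernel_matrix(source, source, dim)
    P = np.hstack([np.ones((k, 1)), source])
    L = np.zeros((k + dim + 1, k + dim + 1))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    return L, K


def bending_energy_matrix(source):
    """k x k bending-energy matrix of a source configuration.

    For target coordinates Y (k x dim), the TPS bending energy of the map
    source -> Y is ``trace(Y.T @ B @ Y)``. B is positive semidefinite with
    the affine maps of the source in its null space.
    """
    source = _check_source(source)
    k, dim = source.shape
    L, _ = _tps_system(source, dim)
    Linv = np.linalg.inv(L)
    B = Linv[:k, :k]
    return (B + B.T) / 2.0


class ThinPlateSpline:
    """Interpolating TPS warp fitted between paired landmark sets.

    Parameters are set at fit time: ``fit(source, target)`` solves the
    spline system so that every source landmark maps exactly onto its
    target. After fitting, the instance is callable on arbitrary points and
    exposes ``bending_energy_``.
    """

    def fit(self, source, target):
        source = _check_source(source)
        target = np.asarray(target, dtype=float)
        if target.shape != source.shape:
            raise ValueError(
                f"target shape {target.shape} != source shape {source.shape}"
            )
        k, dim = source.shape
        L, K = _tps_system(source, dim)
        rhs = np.zeros((k + dim + 1, dim))
        rhs[:k] = target
        try:
            sol = np.linalg.solve(L, rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise DegenerateLandmarksError(str(exc)) from exc
        self.source_ = source
        self.target_ = target
        self.weights_ = sol[:k]
        self.affine_ = sol[k:]
        energy = float(np.trace(self.weights_.T @ K @ self.weights_))
        # clip tiny negative round-off; the form is PSD by construction
        self.bending_energy_ = max(energy, 0.0)
        return self

    def __call__(self, points):
        points = np.atleast_2d(np.asarray(points, dtype=float))
        U = _kernel_matrix(points, self.source_, self.source_.shape[1])
        P = np.hstack([np.ones((points.shape[0], 1)), points])
        return U @ self.weights_ + P @ self.affine_

    transform = __call__


def tps_warp(source, target):
    """Fit a TPS and return ``(warp_function, bending_energy)``."""
    spline = ThinPlateSpline().fit(source, target)
    return spline, spline.bending_energy_
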