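"""Procrustes superimposition primitives and generalized Procrustes analysis.

Functions here operate on bare ``k x dim`` coordinate arrays (or
:class:`~paleogm.template.Configuration` objects where noted); the
:class:`GPA` estimator superimposes whole samples, optionally sliding
semilandmarks against the recursively updated consensus, and yields
Procrustes shape coordinates ready for principal component analysis.

Conventions
-----------
* Partial Procrustes fitting: configurations are centred, scaled to unit
  centroid size (when ``scale=True``) and rotated; no post-hoc rescaling by
  the cosine of the Procrustes angle.
* Reflections are never applied during superimposition; antimeres are
  handled explicitly with :func:`mirror` beforehand.
* The fitted consensus is rotated into a canonical principal-axes
  orientation with a deterministic sign rule, so results are invariant
  (to ~1e-8) under arbitrary rigid motions of the input data.
"""

from __future__ import annotations

import numpy as np

from .template import AlignedDataset, Configuration, LandmarkTemplate
from .tps import bending_energy_matrix


class EmptyConfigurationError(ValueError):
    pass


class DegenerateShapeError(ValueError):
    pass


class ShapeMismatchError(ValueError):
    pass


class MissingDataError(ValueError):
    pass


def _coords(x):
    if isinstance(x, Configuration):
        return x.coords, x.present
    return np.asarray(x, dtype=float), None


def centroid_size(config):
    """Centroid size: sqrt of summed squared distances of landmarks from
    their centroid. Uses only present landmarks for a masked configuration.
    """
    coords, present = _coords(config)
    if present is not None:
        coords = coords[present]
    if coords.shape[0] == 0:
        raise EmptyConfigurationError("no present landmarks")
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centred**2)))


def normalize(config):
    """Centre on the landmark centroid and scale to unit centroid size."""
    coords, _ = _coords(config)
    cs = centroid_size(coords)
    if cs <= 1e-300:
        raise DegenerateShapeError("zero centroid size; cannot normalize")
    return (coords - coords.mean(axis=0)) / cs


def optimal_rotation(moving, target, allow_reflection=False):
    """Orthogonal matrix R minimizing ||moving @ R - target||_F (Kabsch).

    Constrained to det(R) = +1 unless ``allow_reflection``.
    """
    H = moving.T @ target
    U, s, Vt = np.linalg.svd(H)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        U[:, -1] *= -1.0
        R = U @ Vt
    return R


def opa_align(moving, target, allow_reflection=False):
    """Ordinary Procrustes alignment of two configurations.

    Both are centred and scaled to unit centroid size, then the rotation
    minimizing the residual sum of squares is found. Returns
    ``(rotation, residual_distance)`` where the residual is the Frobenius
    norm of the remaining difference.
    """
    a, _ = _coords(moving)
    b, _ = _coords(target)
    if a.shape != b.shape:
        raise ShapeMismatchError(f"configurations differ: {a.shape} vs {b.shape}")
    an = normalize(a)
    bn = normalize(b)
    R = optimal_rotation(an, bn, allow_reflection=allow_reflection)
    residual = float(np.linalg.norm(an @ R - bn))
    return R, residual


def procrustes_distance(a, b, allow_reflection=False):
    """Partial Procrustes distance between two shapes (residual norm after
    optimal superimposition of unit-size centred configurations)."""
    _, residual = opa_align(a, b, allow_reflection=allow_reflection)
    return residual


def mirror(config):
    """Reflect a configuration to its antimere by negating the x coordinate.

    For a :class:`Configuration` the side label is flipped; the operation
    is an involution.
    """
    if isinstance(config, Configuration):
        out = config.copy()
        out.coords[:, 0] *= -1.0
        out.side = {"left": "right", "right": "left", "n/a": "n/a"}[config.side]
        return out
    coords = np.asarray(config, dtype=float).copy()
    coords[:, 0] *= -1.0
    return coords


def _canonical_rotation(consensus):
    """Proper rotation taking a centred consensus to principal axes with a
    deterministic sign convention (largest-|coordinate| positive per axis).
    """
    _, _, Vt = np.linalg.svd(consensus, full_matrices=True)
    V = Vt.T
    for j in range(V.shape[1]):
        col = consensus @ V[:, j]
        if col.shape[0] and col[np.argmax(np.abs(col))] < 0:
            V[:, j] *= -1.0
    if np.linalg.det(V) < 0:
        V[:, -1] *= -1.0
    return V


def _as_shape_array(dataset):
    if isinstance(dataset, np.ndarray):
        arr = np.asarray(dataset, dtype=float)
        if arr.ndim != 3:
            raise ValueError("expected an n x k x dim array")
        return arr, None, None
    configs = list(dataset)
    for c in configs:
        if not c.is_complete:
            raise MissingDataError(
                f"specimen {c.specimen_id!r} has missing landmarks; estimate "
                "them before superimposition"
            )
    arr = np.stack([c.coords for c in configs])
    labels = np.array([c.group for c in configs])
    ids = [c.specimen_id for c in configs]
    return arr, labels, ids


class GPA:
    """Generalized Procrustes analysis, optionally with semilandmark sliding.

    Parameters
    ----------
    scale : bool, default True
        Scale every configuration (and the consensus) to unit centroid size.
    slide : bool, default False
        After initial superimposition, let semilandmarks slide to minimize
        the bending energy of the deformation from the consensus, with the
        consensus recursively updated between passes. Requires ``template``.
    template : LandmarkTemplate, optional
        Landmark roles and curve adjacency used for sliding.
    n_slide_passes : int, default 3
    tol : float, default 1e-10
        Convergence threshold on the change of the least-squares criterion.
    max_iter : int, default 100

    Attributes
    ----------
    consensus_ : (k, dim) ndarray
    shapes_ : (n, k, dim) ndarray of Procrustes coordinates
    centroid_sizes_ : (n,) ndarray, mm
    n_iter_ : int
    converged_ : bool
    criterion_history_ : ndarray, non-increasing
    """

    def __init__(self, scale=True, slide=False, template=None,
                 n_slide_passes=3, tol=1e-10, max_iter=100):
        self.scale = scale
        self.slide = slide
        self.template = template
        self.n_slide_passes = n_slide_passes
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep=True):
        return {
            "scale": self.scale,
            "slide": self.slide,
            "template": self.template,
            "n_slide_passes": self.n_slide_passes,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params):
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- core iteration ---------------------------------------------------

    def _superimpose(self, shapes, history):
        """Alternate rotation and mean steps until the criterion settles."""
        n = shapes.shape[0]
        ref = shapes[0]
        for i in range(n):
            R = optimal_rotation(shapes[i], ref)
            shapes[i] = shapes[i] @ R
        prev = np.inf
        n_iter = 0
        converged = False
        for n_iter in range(1, self.max_iter + 1):
            consensus = shapes.mean(axis=0)
            for i in range(n):
                R = optimal_rotation(shapes[i], consensus)
                shapes[i] = shapes[i] @ R
            crit = float(np.sum((shapes - shapes.mean(axis=0)) ** 2))
            history.append(crit)
            if prev - crit < self.tol:
                converged = True
                break
            prev = crit
        return shapes, n_iter, converged

    def fit(self, X, y=None):
        shapes, labels, ids = _as_shape_array(X)
        if shapes.shape[0] < 2:
            raise ValueError("GPA needs at least 2 configurations")
        if not np.all(np.isfinite(shapes)):
            raise MissingDataError("non-finite coordinates in input")
        shapes = shapes.copy()
        sizes = np.array([centroid_size(s) for s in shapes])
        shapes -= shapes.mean(axis=1, keepdims=True)
        if self.scale:
            shapes /= sizes[:, None, None]

        history = []
        shapes, n_iter, converged = self._superimpose(shapes, history)

        if self.slide:
            if self.template is None:
                raise ValueError("sliding requires a template")
            for _ in range(self.n_slide_passes):
                consensus = shapes.mean(axis=0)
                shapes = slide_semilandmarks(shapes, self.template, consensus)
                # re-centre/re-scale: sliding moves points off unit size
                shapes -= shapes.mean(axis=1, keepdims=True)
                if self.scale:
                    shapes /= np.array(
                        [centroid_size(s) for s in shapes]
                    )[:, None, None]
                shapes, it, converged = self._superimpose(shapes, history)
                n_iter += it

        consensus = shapes.mean(axis=0)
        V = _canonical_rotation(consensus)
        consensus = consensus @ V
        shapes = shapes @ V
        if self.scale:
            consensus = consensus / centroid_size(consensus)

        self.consensus_ = consensus
        self.shapes_ = shapes
        self.centroid_sizes_ = sizes
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.criterion_history_ = np.asarray(history)
        self.labels_ = labels
        self.specimen_ids_ = ids
        return self

    def transform(self, X):
        """OPA-align new configurations onto the fitted consensus.

        The training sample is not refitted; this is how query specimens
        (e.g. a reconstructed fossil) enter an existing shape space.
        """
        single = False
        if isinstance(X, Configuration):
            X, single = [X], True
        elif isinstance(X, np.ndarray) and X.ndim == 2:
            X, single = X[None], True
        shapes, _, _ = _as_shape_array(X)
        out = np.empty_like(shapes, dtype=float)
        for i, s in enumerate(shapes):
            if s.shape != self.consensus_.shape:
                raise ShapeMismatchError(
                    f"configuration {i} shape {s.shape} != consensus "
                    f"{self.consensus_.shape}"
                )
            sn = normalize(s) if self.scale else s - s.mean(axis=0)
            R = optimal_rotation(sn, self.consensus_)
            out[i] = sn @ R
        return out[0] if single else out

    def fit_transform(self, X, y=None):
        return self.fit(X).shapes_

    def to_dataset(self):
        return AlignedDataset(
            shapes=self.shapes_,
            centroid_sizes=self.centroid_sizes_,
            consensus=self.consensus_,
            iterations=self.n_iter_,
            converged=self.converged_,
            criterion_history=self.criterion_history_,
            labels=self.labels_,
            specimen_ids=self.specimen_ids_,
        )


def gpa(dataset, scale=True, slide=False, template=None, **kwargs):
    """Functional wrapper: superimpose a sample and return an
    :class:`~paleogm.template.AlignedDataset`."""
    est = GPA(scale=scale, slide=slide, template=template, **kwargs)
    est.fit(dataset)
    return est.to_dataset()


# -- semilandmark sliding -------------------------------------------------


def _curve_tangents(coords, template):
    """Unit tangent per curve semilandmark from central differences of its
    template neighbours, evaluated on the specimen's own coordinates."""
    tangents = {}
    for i in template.curve_indices:
        nb = template.curves[i]
        if len(nb) == 2:
            t = coords[nb[1]] - coords[nb[0]]
        else:
            t = coords[nb[0]] - coords[i]
        norm = np.linalg.norm(t)
        if norm < 1e-12:
            raise ValueError(f"degenerate tangent at curve semilandmark {i}")
        tangents[i] = t / norm
    return tangents


def _surface_tangent_planes(coords, template, n_neighbors=6):
    """Two orthonormal tangent vectors per surface semilandmark from a local
    PCA of its nearest neighbours."""
    planes = {}
    k = coords.shape[0]
    nn = min(n_neighbors, k - 1)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    for i in template.surface_indices:
        order = np.argsort(d2[i])
        idx = order[1 : nn + 1]
        local = coords[idx] - coords[idx].mean(axis=0)
        _, _, Vt = np.linalg.svd(local, full_matrices=False)
        planes[i] = Vt[:2]
    return planes


def slide_semilandmarks(shapes, template, consensus=None):
    """One bending-energy sliding pass of every specimen against the
    consensus.

    Each curve semilandmark is displaced along its estimated tangent and
    each surface semilandmark within its estimated tangent plane so as to
    minimize the TPS bending energy of the deformation consensus ->
    specimen. Fixed landmarks never move. The minimization is an exact
    linear solve, so the per-specimen energy cannot increase.
    """
    shapes = np.asarray(shapes, dtype=float)
    single = shapes.ndim == 2
    if single:
        shapes = shapes[None]
    if consensus is None:
        consensus = shapes.mean(axis=0)
    if not isinstance(template, LandmarkTemplate):
        raise TypeError("template must be a LandmarkTemplate")
    sliders = template.curve_indices + template.surface_indices
    if not sliders:
        return shapes[0].copy() if single else shapes.copy()

    k, dim = consensus.shape
    B = bending_energy_matrix(consensus)
    out = shapes.copy()
    for s in range(shapes.shape[0]):
        Y = shapes[s]
        tangents = _curve_tangents(Y, template)
        planes = _surface_tangent_planes(Y, template)
        # parameter -> vectorized displacement map (column-major by dim)
        dirs = []  # (landmark index, direction vector)
        for i in template.curve_indices:
            dirs.append((i, tangents[i]))
        for i in template.surface_indices:
            dirs.append((i, planes[i][0]))
            dirs.append((i, planes[i][1]))
        p = len(dirs)
        # energy E(t) = sum_d (y_d + U_d t - c_d)^T B (y_d + U_d t - c_d)
        # with U mapping params to per-dimension displacements.
        U = np.zeros((k, dim, p))
        for j, (i, v) in enumerate(dirs):
            U[i, :, j] = v
        D0 = Y - consensus
        # gradient: 2 * U^T B (D0 + U t) summed over dims
        A = np.einsum("kdp,kl,ldq->pq", U, B, U)
        b = -np.einsum("kdp,kl,ld->p", U, B, D0)
        t, *_ = np.linalg.lstsq(A, b, rcond=None)
        disp = np.einsum("kdp,p->kd", U, t)
        out[s] = Y + disp
    return out[0] if single else out


def bending_energy_to_consensus(shapes, consensus):
    """Total TPS bending energy of the deformations consensus -> specimen,
    summed over specimens (the sliding objective)."""
    B = bending_energy_matrix(consensus)
    shapes = np.asarray(shapes, dtype=float)
    if shapes.ndim == 2:
        shapes = shapes[None]
    total = 0.0
    for Y in shapes:
        D = Y - consensus
        total += float(np.trace(D.T @ B @ D))
    return total
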