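"""Shape spaces: PCA of Procrustes coordinates and between-group PCA.

Both estimators follow the fit/transform contract. :class:`ShapePCA` is a
covariance PCA (divisor n-1) of the vectorized Procrustes coordinates with
a deterministic sign convention (the largest-magnitude loading of each axis
is positive). Query specimens — e.g. a fossil completed on a reference
mean — are never refitted into the space: they are aligned to the consensus
and projected with :meth:`ShapePCA.transform`.

:class:`BetweenGroupPCA` runs the PCA on the g (equally weighted) group
mean vectors, yielding at most g-1 axes, and projects every specimen and
query onto them; this is the standard dimension-reduction device when the
smallest group would otherwise have fewer cases than retained PCs.
"""

from __future__ import annotations

import numpy as np


def _flatten(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 3:
        return X.reshape(X.shape[0], -1), X.shape[1:]
    if X.ndim == 2:
        return X, None
    raise ValueError("expected n x k x dim shapes or an n x p matrix")


class ShapePCA:
    """Principal component analysis of vectorized shape coordinates.

    Attributes (after ``fit``)
    --------------------------
    mean_ : (p,) ndarray — consensus as a flat vector
    components_ : (m, p) ndarray, orthonormal rows
    explained_variance_ : (m,) eigenvalues (divisor n-1)
    explained_variance_ratio_ : (m,) variance fractions (sum 1 over all
        nonzero components)
    scores_ : (n, m) training-specimen scores, column means 0
    shape_ : original (k, dim) of one specimen, if shapes were passed
    """

    def __init__(self, n_components=None):
        self.n_components = n_components

    def get_params(self, deep=True):
        return {"n_components": self.n_components}

    def set_params(self, **params):
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        flat, shape = _flatten(X)
        n = flat.shape[0]
        if n < 3:
            raise ValueError(f"PCA of shapes needs n >= 3 specimens, got {n}")
        self.shape_ = shape
        self.mean_ = flat.mean(axis=0)
        centred = flat - self.mean_
        U, s, Vt = np.linalg.svd(centred, full_matrices=False)
        eigvals = s**2 / (n - 1)
        nonzero = eigvals > eigvals[0] * 1e-12 if eigvals.size else eigvals > 0
        m = int(nonzero.sum())
        if self.n_components is not None:
            m = min(m, int(self.n_components))
        comps = Vt[:m]
        # sign convention: largest-|loading| positive per axis
        for j in range(m):
            i = np.argmax(np.abs(comps[j]))
            if comps[j, i] < 0:
                comps[j] *= -1.0
        self.components_ = comps
        self.explained_variance_ = eigvals[:m]
        total = eigvals[nonzero].sum()
        self.explained_variance_ratio_ = eigvals[:m] / total
        self.scores_ = centred @ comps.T
        return self

    def transform(self, X):
        """Project specimens (already aligned to the consensus) into the
        fitted space; the training sample is not refitted."""
        flat, _ = _flatten(X)
        if flat.shape[1] != self.mean_.shape[0]:
            raise ValueError(
                f"specimen has {flat.shape[1]} shape variables; space was "
                f"fitted with {self.mean_.shape[0]}"
            )
        return (flat - self.mean_) @ self.components_.T

    def fit_transform(self, X, y=None):
        return self.fit(X).scores_

    def inverse_transform(self, scores):
        """Shapes corresponding to score vectors (mean + scores . axes)."""
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        flat = self.mean_ + scores @ self.components_[: scores.shape[1]]
        if self.shape_ is not None:
            return flat.reshape((scores.shape[0],) + self.shape_)
        return flat

    def warp_along_pc(self, axis, score):
        """Consensus warped along one PC by a given score (figure-style
        extreme shapes at the max observed score)."""
        if not 0 <= axis < self.components_.shape[0]:
            raise IndexError(f"axis {axis} out of range")
        flat = self.mean_ + float(score) * self.components_[axis]
        if self.shape_ is not None:
            return flat.reshape(self.shape_)
        return flat


class BetweenGroupPCA:
    """PCA of group mean shapes with all specimens projected onto the axes.

    ``fit(X, y)`` computes the g equally weighted group means, runs a PCA
    on them (at most g-1 nonzero axes) and stores the projections of all
    training specimens in ``scores_``. Queries are projected with
    ``transform``.
    """

    def __init__(self):
        pass

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        if params:
            raise ValueError(f"invalid parameters {sorted(params)!r}")
        return self

    def fit(self, X, y):
        flat, shape = _flatten(X)
        y = np.asarray(y)
        groups = np.unique(y)
        if groups.size < 2:
            raise ValueError("between-group PCA needs >= 2 groups")
        means = []
        for g in groups:
            members = flat[y == g]
            if members.shape[0] == 0:
                raise ValueError(f"empty group {g!r}")
            means.append(members.mean(axis=0))
        means = np.stack(means)
        self.shape_ = shape
        self.groups_ = groups
        self.group_means_ = means
        self.mean_ = means.mean(axis=0)  # grand mean of group means
        centred = means - self.mean_
        U, s, Vt = np.linalg.svd(centred, full_matrices=False)
        g = groups.size
        eigvals = s**2 / max(g - 1, 1)
        keep = min(g - 1, Vt.shape[0])
        comps = Vt[:keep]
        for j in range(keep):
            i = np.argmax(np.abs(comps[j]))
            if comps[j, i] < 0:
                comps[j] *= -1.0
        self.components_ = comps
        self.explained_variance_ = eigvals[:keep]
        self.scores_ = (flat - self.mean_) @ comps.T
        self.labels_ = y
        return self

    def transform(self, X):
        flat, _ = _flatten(X)
        return (flat - self.mean_) @ self.components_.T

    def fit_transform(self, X, y):
        return self.fit(X, y).scores_


def pca_shapes(aligned):
    """Fit a :class:`ShapePCA` on an aligned dataset (array or
    ``AlignedDataset``) and return it."""
    shapes = getattr(aligned, "shapes", aligned)
    return ShapePCA().fit(shapes)


def project_specimen(space, new_shape):
    """Predicted PC scores of one aligned shape in an existing space."""
    arr = np.asarray(new_shape, dtype=float)
    return space.transform(arr[None])[0]


def bg_pca(aligned, labels, queries=None):
    """Between-group PCA; returns the fitted estimator and, if ``queries``
    are given, their projected scores."""
    shapes = getattr(aligned, "shapes", aligned)
    est = BetweenGroupPCA().fit(shapes, labels)
    if queries is None:
        return est
    return est, est.transform(np.asarray(queries, dtype=float))


def scree_inflection(variance_fractions):
    """Component count at the scree-plot elbow.

    Operationalized as the interior position j (1-based, 2 <= j <= m-1)
    maximizing the discrete curvature f(j-1) - 2 f(j) + f(j+1); ties take
    the smallest j. Fractions must be sorted descending.
    """
    f = np.asarray(variance_fractions, dtype=float)
    if f.size < 3:
        raise ValueError("need at least 3 variance fractions")
    if np.any(np.diff(f) > 1e-12):
        raise ValueError("variance fractions must be sorted descending")
    curv = f[:-2] - 2.0 * f[1:-1] + f[2:]
    j = int(np.argmax(curv))  # smallest index on ties (argmax convention)
    return j + 2  # convert to 1-based component count at the interior point
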