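"""Missing-landmark estimation against reference mean shapes.

A damaged specimen (worn facet, crack, eroded surface) is completed by
warping a complete reference configuration — typically a group mean or the
overall sample mean — onto the specimen's present landmarks with a
thin-plate spline, and reading the missing positions off the warp. The
multi-reference sensitivity check completes the specimen against several
candidate means and compares where each completion lands in a fixed shape
space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gpa import centroid_size, optimal_rotation
from .template import Configuration
from .tps import ThinPlateSpline


class UnderdeterminedError(ValueError):
    pass


def estimate_missing(config, reference):
    """Complete a masked configuration by TPS-warping a reference onto it.

    The reference is first superimposed (ordinary Procrustes with scaling)
    on the specimen's present landmarks, then a TPS fitted from the
    reference's present-landmark positions to the specimen's is evaluated
    at the reference's missing-landmark positions. Present landmarks are
    returned unchanged.

    Parameters
    ----------
    config : Configuration
        Specimen with ``present`` mask; needs at least dim+2 present points.
    reference : ndarray or Configuration
        Complete k x dim mean shape on the same template.
    """
    ref = reference.coords if isinstance(reference, Configuration) else np.asarray(
        reference, dtype=float
    )
    if ref.shape != config.coords.shape:
        raise ValueError(
            f"reference shape {ref.shape} != specimen shape {config.coords.shape}"
        )
    mask = config.present
    if mask.all():
        return config.copy()
    n_present = int(mask.sum())
    dim = config.dim
    if n_present < dim + 2:
        raise UnderdeterminedError(
            f"only {n_present} present landmarks; need >= {dim + 2}"
        )

    target = config.coords[mask]
    # superimpose the full reference on the present landmarks
    t_centre = target.mean(axis=0)
    t_cs = centroid_size(target)
    r_sub = ref[mask]
    r_centre = r_sub.mean(axis=0)
    r_cs = centroid_size(r_sub)
    ref_al = (ref - r_centre) * (t_cs / r_cs)
    R = optimal_rotation(ref_al[mask], target - t_centre)
    ref_al = ref_al @ R + t_centre

    spline = ThinPlateSpline().fit(ref_al[mask], target)
    completed = config.copy()
    completed.coords[~mask] = spline(ref_al[~mask])
    completed.present[:] = True
    return completed


def reconstruction_sensitivity(config, references, shape_space, n_scores=3):
    """Complete a specimen against several reference means and project each
    completion into a fixed shape space.

    Returns ``(scores_table, pairwise_distances)`` where the table holds
    one row of the first ``n_scores`` projected PC scores per reference and
    the distance matrix gives Euclidean distances between those rows. Small
    pairwise distances (relative to between-group separation) indicate the
    choice of reference mean does not drive the result.
    """
    names, rows = [], []
    for name, ref in references.items():
        completed = estimate_missing(config, ref)
        scores = shape_space.transform(completed.coords[None])[0]
        names.append(name)
        rows.append(scores[:n_scores])
    table = pd.DataFrame(rows, index=names,
                         columns=[f"PC{i + 1}" for i in range(n_scores)])
    arr = table.to_numpy()
    dist = np.linalg.norm(arr[:, None, :] - arr[None, :, :], axis=-1)
    dist = pd.DataFrame(dist, index=names, columns=names)
    return table, dist


class MissingLandmarkEstimator:
    """Estimator-style wrapper: ``fit`` stores the reference mean,
    ``transform`` completes masked configurations against it."""

    def __init__(self, reference=None):
        self.reference = reference

    def get_params(self, deep=True):
        return {"reference": self.reference}

    def set_params(self, **params):
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        """X: complete configurations (list or n x k x dim array) whose mean
        becomes the reference, unless one was given explicitly."""
        if self.reference is not None:
            self.reference_ = np.asarray(
                self.reference.coords
                if isinstance(self.reference, Configuration)
                else self.reference,
                dtype=float,
            )
            return self
        if isinstance(X, np.ndarray):
            self.reference_ = X.mean(axis=0)
        else:
            self.reference_ = np.stack([c.coords for c in X]).mean(axis=0)
        return self

    def transform(self, X):
        if isinstance(X, Configuration):
            return estimate_missing(X, self.reference_)
        return [estimate_missing(c, self.reference_) for c in X]
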