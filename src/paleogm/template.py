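"""Landmark schemes and per-specimen landmark configurations.

A :class:`LandmarkTemplate` describes the (semi)landmark scheme shared by
every specimen in an analysis: how many points there are, whether each one
is a fixed anatomical landmark, a curve semilandmark (free to slide along a
curve) or a surface semilandmark (free to slide within a tangent plane),
and, for curve points, which neighbours define the local tangent.

A :class:`Configuration` couples one specimen's raw coordinates (in mm)
with a presence mask and the metadata used downstream: group label, side,
geography and chronology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROLE_FIXED = "fixed"
ROLE_CURVE = "curve_semilandmark"
ROLE_SURFACE = "surface_semilandmark"
_ROLES = (ROLE_FIXED, ROLE_CURVE, ROLE_SURFACE)


@dataclass
class LandmarkTemplate:
    """Shared (semi)landmark scheme.

    Parameters
    ----------
    k : int
        Number of landmarks; at least 3.
    dim : int
        2 or 3.
    roles : sequence of str, optional
        One of ``"fixed"``, ``"curve_semilandmark"``,
        ``"surface_semilandmark"`` per landmark. Defaults to all fixed.
    curves : dict, optional
        Maps the index of each curve semilandmark to its 1-2 ordered
        neighbour indices, used for tangent estimation during sliding.
    names : sequence of str, optional
    """

    k: int
    dim: int
    roles: tuple = None
    curves: dict = field(default_factory=dict)
    names: tuple = None

    def __post_init__(self):
        if self.k < 3:
            raise ValueError(f"template needs k >= 3 landmarks, got {self.k}")
        if self.dim not in (2, 3):
            raise ValueError(f"dim must be 2 or 3, got {self.dim}")
        if self.roles is None:
            self.roles = tuple([ROLE_FIXED] * self.k)
        else:
            self.roles = tuple(self.roles)
        if len(self.roles) != self.k:
            raise ValueError("roles must cover all k landmarks")
        for r in self.roles:
            if r not in _ROLES:
                raise ValueError(f"unknown landmark role {r!r}")
        for i, r in enumerate(self.roles):
            if r == ROLE_CURVE:
                nb = self.curves.get(i, ())
                if not 1 <= len(nb) <= 2:
                    raise ValueError(
                        f"curve semilandmark {i} needs 1-2 neighbours, got {len(nb)}"
                    )
        if self.names is not None:
            self.names = tuple(self.names)
            if len(self.names) != self.k:
                raise ValueError("names length must equal k")

    @property
    def curve_indices(self):
        return [i for i, r in enumerate(self.roles) if r == ROLE_CURVE]

    @property
    def surface_indices(self):
        return [i for i, r in enumerate(self.roles) if r == ROLE_SURFACE]

    @property
    def fixed_indices(self):
        return [i for i, r in enumerate(self.roles) if r == ROLE_FIXED]


@dataclass
class Configuration:
    """One specimen's landmark coordinates plus metadata.

    ``coords`` is a k x dim array in mm; ``present`` masks digitized
    landmarks (False where worn, cracked or otherwise missing). ``side``
    is ``"left"``, ``"right"`` or ``"n/a"``; ``group`` is a taxon label
    such as NEA, RHS, UPHS, EHS. ``meta`` carries latitude/longitude in
    decimal degrees and ``mis_group`` ("early" or "classic") where known.
    """

    specimen_id: str
    coords: np.ndarray
    present: np.ndarray = None
    side: str = "n/a"
    group: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be a k x dim matrix")
        k = self.coords.shape[0]
        if self.present is None:
            self.present = np.ones(k, dtype=bool)
        else:
            self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (k,):
            raise ValueError("present mask length must equal landmark count")
        if not np.all(np.isfinite(self.coords[self.present])):
            raise ValueError(
                f"specimen {self.specimen_id!r}: non-finite coordinates at "
                "present landmarks"
            )
        if self.side not in ("left", "right", "n/a"):
            raise ValueError(f"invalid side {self.side!r}")

    @property
    def k(self):
        return self.coords.shape[0]

    @property
    def dim(self):
        return self.coords.shape[1]

    @property
    def is_complete(self):
        return bool(self.present.all())

    def copy(self):
        return Configuration(
            self.specimen_id,
            self.coords.copy(),
            self.present.copy(),
            self.side,
            self.group,
            dict(self.meta),
        )


@dataclass
class AlignedDataset:
    """Procrustes-superimposed sample.

    ``shapes`` holds the n x k x dim Procrustes shape coordinates (centred,
    unit centroid size when scaling was enabled), ``centroid_sizes`` the
    original sizes in mm, ``consensus`` the sample mean shape, and
    ``criterion_history`` the (non-increasing) sum of squared deviations
    from the consensus across superimposition iterations.
    """

    shapes: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    iterations: int
    converged: bool
    criterion_history: np.ndarray
    labels: np.ndarray = None
    specimen_ids: list = None

    @property
    def n(self):
        return self.shapes.shape[0]
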