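"""Synthetic group-structured landmark data and radiocarbon measurements.

The generators emulate the structure of the comparative samples every
pipeline stage expects: per-group mean shapes, smooth group-difference
deformations, isotropic Gaussian landmark noise, lognormal-free size
variation, known labels with geographic/chronological metadata, and
missing-landmark knockouts with the ground truth retained for recovery
scoring. Two fixture templates ship with the package as CSV: a 24-point
molar-like crown outline (a superellipse whose disto-lingual quadrant can
bulge, echoing a protruding hypocone) and a 30-point 3D talus-like block
(fixed anatomical points, an equatorial curve of sliding semilandmarks and
surface semilandmarks on an ellipsoid).

Isotropic noise (no covariance structure between landmarks) is a
deliberate simplification: it matches the assumptions of the downstream
analyses while making effect sizes interpretable in units of the noise sd.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
from scipy.stats import special_ortho_group

from .gpa import centroid_size
from .template import Configuration, LandmarkTemplate
from .radiocarbon import CalCurve, CoverageError

N_OUTLINE = 24


# -- fixture templates ----------------------------------------------------


def _outline_angles(n=N_OUTLINE):
    # clockwise from the buccal +y ray, matching the pseudolandmark scheme
    return np.pi / 2.0 - 2.0 * np.pi * np.arange(n) / n


def _superellipse_radius(theta, a, b, p):
    c, s = np.cos(theta), np.sin(theta)
    return (np.abs(c / a) ** p + np.abs(s / b) ** p) ** (-1.0 / p)


def outline_template_coords(a=6.8, b=6.45, p=3.5):
    """24-point molar-like crown outline (mm), buccal towards +y."""
    theta = _outline_angles()
    r = _superellipse_radius(theta, a, b, p)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def outline_bulge_effect(center_deg=225.0, width_deg=28.0, amplitude=0.12):
    """Unit-norm radial deformation bulging the disto-lingual quadrant
    (the protruding-hypocone contrast between the group means)."""
    theta = _outline_angles()
    base = outline_template_coords()
    ang = np.degrees(np.mod(theta, 2 * np.pi))
    bump = amplitude * np.exp(-0.5 * ((ang - center_deg) / width_deg) ** 2)
    radial = base / np.linalg.norm(base, axis=1, keepdims=True)
    effect = radial * bump[:, None]
    return effect / np.linalg.norm(effect)


def _ellipsoid_point(lon, lat, a, b, c):
    return np.array([a * np.cos(lat) * np.cos(lon),
                     b * np.cos(lat) * np.sin(lon),
                     c * np.sin(lat)])


def talus_template_coords(a=28.0, b=22.0, c=16.0):
    """30-point talus-like 3D block (mm): 6 fixed extremal points, a
    12-point equatorial curve, 12 surface points at +-45 deg latitude."""
    pts = [np.array([a, 0, 0]), np.array([-a, 0, 0]),
           np.array([0, b, 0]), np.array([0, -b, 0]),
           np.array([0, 0, c]), np.array([0, 0, -c])]
    for j in range(12):
        lon = np.radians(15.0 + 30.0 * j)
        pts.append(_ellipsoid_point(lon, 0.0, a, b, c))
    for lat in (np.radians(45.0), np.radians(-45.0)):
        for j in range(6):
            lon = np.radians(30.0 + 60.0 * j)
            pts.append(_ellipsoid_point(lon, lat, a, b, c))
    return np.asarray(pts)


def talus_template():
    """LandmarkTemplate for the talus-like block (fixed/curve/surface roles
    with ring adjacency for the equatorial curve)."""
    roles = (["fixed"] * 6
             + ["curve_semilandmark"] * 12
             + ["surface_semilandmark"] * 12)
    curves = {}
    for j in range(12):
        i = 6 + j
        curves[i] = (6 + (j - 1) % 12, 6 + (j + 1) % 12)
    return LandmarkTemplate(k=30, dim=3, roles=roles, curves=curves)


def outline_template():
    """LandmarkTemplate for the 24-point crown outline (all fixed
    pseudolandmarks; outline points are geometric, not slid)."""
    return LandmarkTemplate(k=N_OUTLINE, dim=2)


def talus_bulge_effect(center_lon_deg=90.0, amplitude=1.0):
    """Unit-norm outward deformation of the talus block centred on one
    side of the equator (a smooth group-difference vector)."""
    base = talus_template_coords()
    normals = base / np.linalg.norm(base, axis=1, keepdims=True)
    lon = np.degrees(np.arctan2(base[:, 1], base[:, 0]))
    d = np.abs((lon - center_lon_deg + 180.0) % 360.0 - 180.0)
    bump = amplitude * np.exp(-0.5 * (d / 40.0) ** 2)
    effect = normals * bump[:, None]
    return effect / np.linalg.norm(effect)


def _load_csv(name):
    with resources.files("paleogm.data").joinpath(name).open() as fh:
        return np.loadtxt(fh, delimiter=",", skiprows=1)


def load_outline_template_csv():
    """The checked-in copy of :func:`outline_template_coords`."""
    return _load_csv("outline_template.csv")


def load_talus_template_csv():
    """The checked-in copy of :func:`talus_template_coords`."""
    return _load_csv("talus_template.csv")


# -- shape simulation -----------------------------------------------------


def _shape_tangent_projection(base, vec):
    """Remove the similarity-group components (translation, scaling,
    rotation at ``base``) from a deformation so that ``effect_scale``
    equals the realized Procrustes shape separation to first order."""
    k, dim = base.shape
    directions = []
    for d in range(dim):
        e = np.zeros((k, dim))
        e[:, d] = 1.0
        directions.append(e.ravel())
    directions.append(base.ravel())  # scaling
    if dim == 2:
        rot = np.column_stack([-base[:, 1], base[:, 0]])
        directions.append(rot.ravel())
    else:
        for axis in np.eye(3):
            directions.append(np.cross(axis, base).ravel())
    v = vec.ravel().astype(float).copy()
    Q, _ = np.linalg.qr(np.column_stack(directions))
    v -= Q @ (Q.T @ v)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("effect vector lies entirely in the similarity group")
    return (v / norm).reshape(k, dim)


def make_group_means(base, effects, effect_scale=1.0):
    """Group mean shapes: unit-CS base plus named deformations scaled by
    ``effect_scale`` (units of Procrustes shape distance).

    Nonzero effect vectors are projected into the shape tangent space at
    the base (orthogonal to translation, scaling and rotation) and
    renormalized, so the stated scale is the separation the analyses see.
    """
    base = np.asarray(base, dtype=float)
    base = (base - base.mean(axis=0)) / centroid_size(base)
    means = {}
    for name, vec in effects.items():
        vec = np.asarray(vec, dtype=float)
        if np.linalg.norm(vec) > 0:
            vec = _shape_tangent_projection(base, vec)
        m = base + effect_scale * vec
        means[name] = (m - m.mean(axis=0)) / centroid_size(m)
    return means


def simulate_shapes(group_means, n_per_group, noise_sd=0.01, size_mean=12.0,
                    size_sd=1.0, seed=None, rotate=True,
                    geography=None, mis_groups=("early", "classic")):
    """Draw labelled specimens around per-group mean shapes.

    Each specimen is a similarity transform (random proper rotation,
    translation, size) of (group mean + isotropic Gaussian landmark noise
    of sd ``noise_sd`` in unit-CS shape units). ``geography`` optionally
    maps group -> (lat_mean, lon_mean); specimen coordinates are drawn
    around them (sd 5 deg) and a random MIS group is attached, so the
    geography/chronology tests have inputs. Reproducible by seed.

    Returns a list of :class:`Configuration`.
    """
    rng = np.random.default_rng(seed)
    configs = []
    for group, mean in group_means.items():
        mean = np.asarray(mean, dtype=float)
        k, dim = mean.shape
        if np.linalg.matrix_rank(mean - mean.mean(axis=0)) < dim:
            raise ValueError(f"degenerate template for group {group!r}")
        n = n_per_group[group] if isinstance(n_per_group, dict) else n_per_group
        for i in range(n):
            shape = mean + rng.normal(0.0, noise_sd, size=(k, dim))
            size = max(rng.normal(size_mean, size_sd), 0.1 * size_mean)
            coords = shape * size
            if rotate:
                R = special_ortho_group.rvs(dim, random_state=rng)
                coords = coords @ R.T
            coords = coords + rng.normal(0.0, 5.0, size=dim)
            meta = {"mis_group": mis_groups[int(rng.integers(len(mis_groups)))]}
            if geography and group in geography:
                lat0, lon0 = geography[group]
                meta["latitude"] = float(lat0 + rng.normal(0, 5.0))
                meta["longitude"] = float(lon0 + rng.normal(0, 5.0))
            configs.append(Configuration(
                specimen_id=f"{group}_{i:03d}", coords=coords,
                side="left", group=group, meta=meta,
            ))
    return configs


def knockout(configs, fraction=None, indices=None, seed=None):
    """Mask landmarks, retaining the originals as recovery ground truth.

    Either a per-specimen ``fraction`` (< 0.5) of landmarks drawn at
    random, or an explicit ``indices`` list applied to every specimen.
    Returns ``(masked_configs, truth)`` with truth mapping specimen_id to
    the original coordinates of the masked landmarks.
    """
    rng = np.random.default_rng(seed)
    if (fraction is None) == (indices is None):
        raise ValueError("give exactly one of fraction or indices")
    out, truth = [], {}
    for c in configs:
        k = c.k
        if indices is not None:
            idx = np.asarray(indices, dtype=int)
        else:
            if not 0 <= fraction < 0.5:
                raise ValueError("fraction must lie in [0, 0.5)")
            n_mask = int(round(fraction * k))
            idx = rng.choice(k, size=n_mask, replace=False)
        m = c.copy()
        m.present[idx] = False
        truth[c.specimen_id] = c.coords[idx].copy()
        out.append(m)
    return out, truth


# -- radiocarbon simulation ----------------------------------------------


def simulate_14c(true_cal_ages, curve: CalCurve, sigma_meas, seed=None):
    """Measured 14C ages for known calendar ages under a curve.

    age ~ Normal(mu(theta), sqrt(sigma_meas^2 + sigma_curve(theta)^2)).
    """
    rng = np.random.default_rng(seed)
    ages = np.asarray(true_cal_ages, dtype=float)
    if np.any(ages < curve.grid[0]) or np.any(ages > curve.grid[-1]):
        raise CoverageError("true calendar age outside curve coverage")
    mu, sc = curve(ages)
    sd = np.sqrt(sigma_meas**2 + sc**2)
    return mu + rng.normal(0.0, 1.0, size=ages.shape) * sd


def make_linear_curve(cal_lo=0.0, cal_hi=8000.0, step=5.0, sigma=10.0,
                      slope=1.0, intercept=0.0):
    """Synthetic calibration curve with mu(theta) = intercept +
    slope*theta and constant knot error (test fixture; clearly not a real
    atmospheric curve)."""
    grid = np.arange(cal_lo, cal_hi + step / 2, step)
    return CalCurve(grid=grid, mu=intercept + slope * grid,
                    sigma_curve=np.full(grid.size, sigma))


def make_wiggly_curve(cal_lo=0.0, cal_hi=8000.0, step=5.0, sigma=12.0,
                      amplitude=40.0, period=900.0):
    """Synthetic curve with sinusoidal wiggles superimposed on the 1:1
    trend, for exercising multi-modal posteriors (test fixture)."""
    grid = np.arange(cal_lo, cal_hi + step / 2, step)
    mu = grid + amplitude * np.sin(2 * np.pi * grid / period)
    return CalCurve(grid=grid, mu=mu, sigma_curve=np.full(grid.size, sigma))
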