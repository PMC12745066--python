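"""Collagen quality control and radiocarbon calibration.

Collagen QC follows the conventional screening arithmetic: extraction
yield as a percentage of the dry sample weight (minimum ~1%) and the
atomic C:N ratio, (%C / %N) * (14.007 / 12.011), acceptable inside
[2.9, 3.6] for well-preserved collagen.

Calibration maps a conventional radiocarbon determination (age +- sigma,
yr BP) onto the calendar axis through a calibration curve in the IntCal
``.14c`` layout. Under a uniform calendar prior the posterior density at
calendar age theta is proportional to a normal likelihood with combined
variance sigma^2 + sigma_curve(theta)^2. Highest-posterior-density (HPD)
sets are reported at 68.2% and 95.4% and rendered in cal BC/AD
(cal BC = cal BP - 1950 for ages older than 1950 cal BP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

C_ATOMIC_MASS = 12.011
N_ATOMIC_MASS = 14.007
MIN_YIELD_PCT = 1.0
CN_WINDOW = (2.9, 3.6)
HPD_LEVELS = (0.682, 0.954)


class CurveFormatError(ValueError):
    pass


class CoverageError(ValueError):
    pass


@dataclass
class RadiocarbonSample:
    """One dated sample: collagen analytics plus the AMS determination."""

    name: str
    description: str = ""
    lab_code: str = ""
    ams_code: str = ""
    sample_mg: float = np.nan
    collagen_mg: float = np.nan
    d13C: float = np.nan
    d15N: float = np.nan
    pctC: float = np.nan
    pctN: float = np.nan
    age_14c: float = np.nan
    sigma: float = np.nan

    @property
    def yield_pct(self):
        return 100.0 * self.collagen_mg / self.sample_mg

    @property
    def cn_atomic(self):
        return (self.pctC / self.pctN) * (N_ATOMIC_MASS / C_ATOMIC_MASS)


def collagen_metrics(sample_mg, collagen_mg, pctC, pctN):
    """Collagen yield %, atomic C:N and QC flags.

    QC passes when yield >= 1% and C:N lies in [2.9, 3.6].
    """
    if sample_mg <= 0 or collagen_mg <= 0:
        raise ValueError("masses must be positive")
    if not (0 < pctC < 100 and 0 < pctN < 100):
        raise ValueError("elemental percentages must lie in (0, 100)")
    yield_pct = 100.0 * collagen_mg / sample_mg
    cn_atomic = (pctC / pctN) * (N_ATOMIC_MASS / C_ATOMIC_MASS)
    flags = {
        "yield_ok": yield_pct >= MIN_YIELD_PCT,
        "cn_ok": CN_WINDOW[0] <= cn_atomic <= CN_WINDOW[1],
    }
    flags["pass"] = flags["yield_ok"] and flags["cn_ok"]
    return yield_pct, cn_atomic, flags


@dataclass
class CalCurve:
    """Calibration curve knots: cal BP grid, 14C age mu and 1-sigma error."""

    grid: np.ndarray
    mu: np.ndarray
    sigma_curve: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma_curve = np.asarray(self.sigma_curve, dtype=float)
        if not (self.grid.shape == self.mu.shape == self.sigma_curve.shape):
            raise CurveFormatError("curve columns differ in length")
        if self.grid.size < 2:
            raise CurveFormatError("curve needs >= 2 knots")
        d = np.diff(self.grid)
        if np.any(d <= 0):
            raise CurveFormatError(
                "cal BP knots must be strictly increasing (no duplicates)"
            )
        if np.any(self.sigma_curve <= 0):
            raise CurveFormatError("curve errors must be positive")

    def __call__(self, cal_bp):
        """Linear interpolation: (mu, sigma_curve) at arbitrary cal BP."""
        cal_bp = np.asarray(cal_bp, dtype=float)
        mu = np.interp(cal_bp, self.grid, self.mu)
        sig = np.interp(cal_bp, self.grid, self.sigma_curve)
        return mu, sig


def read_cal_curve(path_or_buffer):
    """Read a calibration curve in the IntCal ``.14c`` dialect.

    Header lines start with ``#``; data rows are comma- (or whitespace-)
    separated with at least three columns: cal BP, 14C age BP, error.
    IntCal files list knots in descending cal BP order; knots are sorted
    ascending here. Non-monotone (duplicate) knots raise a format error.
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer) as fh:
            text = fh.read()
    rows = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 3:
            raise CurveFormatError(
                f"line {ln}: expected >= 3 columns (cal BP, 14C age, error)"
            )
        try:
            rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
        except ValueError as exc:
            raise CurveFormatError(f"line {ln}: non-numeric value") from exc
    if len(rows) < 2:
        raise CurveFormatError("curve needs >= 2 knots")
    arr = np.asarray(rows)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) <= 0):
        raise CurveFormatError("duplicate cal BP knots")
    # ascending-sort is part of the reader contract; but a file whose rows
    # are neither ascending nor descending is malformed
    raw = np.asarray(rows)[:, 0]
    if not (np.all(np.diff(raw) > 0) or np.all(np.diff(raw) < 0)):
        raise CurveFormatError("cal BP knots are not monotone in the file")
    return CalCurve(grid=arr[:, 0], mu=arr[:, 1], sigma_curve=arr[:, 2])


@dataclass
class CalibrationPosterior:
    """Normalized calendar-age posterior with HPD intervals."""

    grid: np.ndarray
    density: np.ndarray
    hpd: dict = field(default_factory=dict)
    age_14c: float = np.nan
    sigma: float = np.nan

    def hpd_bounds(self, level=0.954):
        """Overall (min, max) cal BP bounds of the HPD set at a level."""
        intervals = self.hpd[level]
        lo = min(a for a, _ in intervals)
        hi = max(_b for _, _b in intervals)
        return lo, hi

    def render_bc_ad(self, level=0.954):
        """Printed-style range, e.g. '1613-1499 cal BC' (older bound
        first)."""
        lo, hi = self.hpd_bounds(level)

        def fmt(cal_bp):
            if cal_bp > 1950:
                return f"{cal_bp - 1950:.0f}", "BC"
            return f"{1950 - cal_bp:.0f}", "AD"

        (old_v, old_e) = fmt(hi)
        (new_v, new_e) = fmt(lo)
        era = old_e if old_e == new_e else f"{old_e}/{new_e}"
        return f"{old_v}–{new_v} cal {era}"


def _hpd_intervals(grid, density, level, step):
    """HPD by descending-density accumulation; contiguous runs merged."""
    order = np.argsort(density)[::-1]
    csum = np.cumsum(density[order])
    n_in = int(np.searchsorted(csum, level) + 1)
    # include density ties at the cutoff so symmetric posteriors get
    # symmetric intervals
    d_last = density[order[n_in - 1]]
    while n_in < order.size and density[order[n_in]] >= d_last - 1e-15 * d_last:
        n_in += 1
    members = np.zeros(grid.size, dtype=bool)
    members[order[:n_in]] = True
    intervals = []
    i = 0
    idx = np.nonzero(members)[0]
    while i < idx.size:
        j = i
        while j + 1 < idx.size and idx[j + 1] == idx[j] + 1:
            j += 1
        # endpoints at grid resolution, rounded outward to whole years
        intervals.append((float(np.floor(grid[idx[i]])),
                          float(np.ceil(grid[idx[j]]))))
        i = j + 1
    return intervals


def calibrate(age_14c, sigma, curve, grid_step=1.0, levels=HPD_LEVELS):
    """Calibrate a radiocarbon determination against a curve.

    Returns a :class:`CalibrationPosterior` on a 1-yr cal BP grid spanning
    the curve, with the density normalized to sum to 1 and HPD sets at
    68.2% and 95.4%.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    lo, hi = curve.grid[0], curve.grid[-1]
    mu_lo, s_lo = curve(lo)
    mu_hi, s_hi = curve(hi)
    mu_min, mu_max = min(mu_lo, mu_hi), max(mu_lo, mu_hi)
    smax = float(curve.sigma_curve.max())
    if not (mu_min - 5 * (sigma + smax) <= age_14c <= mu_max + 5 * (sigma + smax)):
        raise CoverageError(
            f"age {age_14c} BP outside curve coverage "
            f"[{mu_min:.0f}, {mu_max:.0f}] +- 5 sigma"
        )
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    mu, sc = curve(grid)
    var = sigma**2 + sc**2
    loglik = -0.5 * (age_14c - mu) ** 2 / var - 0.5 * np.log(var)
    loglik -= loglik.max()
    density = np.exp(loglik)
    total = density.sum()
    if total <= 0:
        raise CoverageError("posterior mass vanishes on the curve grid")
    density /= total
    hpd = {lv: _hpd_intervals(grid, density, lv, grid_step) for lv in levels}
    for a68, b68 in hpd.get(0.682, []):
        if 0.954 in hpd and not any(a95 <= a68 and b68 <= b95
                                    for a95, b95 in hpd[0.954]):
            raise AssertionError("HPD nesting violated")  # pragma: no cover
    return CalibrationPosterior(grid=grid, density=density, hpd=hpd,
                                age_14c=float(age_14c), sigma=float(sigma))
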