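"""Species-level senescence profiles and their phenological parameters.

Per shoot, the declining part of the size trajectory is smoothed with a
cubic smoothing spline whose roughness is set on the conventional ``spar``
scale (default 0.5).  The per-shoot splines are evaluated on a common
daily grid, normalized by each shoot's own maximum size, and averaged
pointwise into a species profile.  From the profile come

* senescence date  — first day the profile reaches 50 % of maximum,
* senescence pace  — 1 / (days between the last 95 % and first 5 % value),
* senescence shape — log(C/D) with C the 50 %→5 % and D the 95 %→50 %
  duration (a config flag flips the ratio; the default follows the printed
  convention C = late / D = early),
* season end       — first day the profile reaches 25 % of maximum.

Species whose profile never falls below 25 % within the observation span
overwinter and receive no season end here (season length is assigned 365 d
downstream).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ProfileError
from .trajectory import ShootSeries

log = logging.getLogger(__name__)

#: fractions extracted from every profile
PROFILE_FRACTIONS = (0.95, 0.50, 0.25, 0.05)

#: sub-day resolution of interpolated crossing dates
CROSSING_RESOLUTION = 0.1


# ---------------------------------------------------------------------------
# spar-parameterised cubic smoothing spline
# ---------------------------------------------------------------------------


class SmoothingSpline:
    """Cubic smoothing spline with the conventional ``spar`` penalty scale.

    Fits a cubic B-spline with knots at every data point on the abscissa
    rescaled to [0, 1], minimizing

        sum (y_i - g(u_i))^2 + lam * int g''(u)^2 du,
        lam = r * 256**(3*spar - 1),

    where r is the design-dependent ratio of the diagonal sums of the
    basis cross-product and roughness matrices (interior basis functions
    only), which makes ``spar`` scale-free.  This reproduces the standard
    spar parameterisation: at spar = 0.5 the fitted values agree with R's
    ``stats::smooth.spline(all.knots=TRUE)`` to ~1e-4 of the data range.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, spar: float = 0.5):
        from numpy.polynomial.legendre import leggauss
        from scipy.interpolate import BSpline

        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be equal-length 1-D arrays")
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
        if np.any(np.diff(x) <= 0):
            # average duplicate abscissae
            ux, inverse = np.unique(x, return_inverse=True)
            uy = np.zeros_like(ux)
            counts = np.zeros_like(ux)
            np.add.at(uy, inverse, y)
            np.add.at(counts, inverse, 1.0)
            x, y = ux, uy / counts
        n = x.size
        if n < 4:
            raise ValueError("need >= 4 distinct points for a cubic spline")
        span = x[-1] - x[0]
        u = (x - x[0]) / span
        knots = np.concatenate([[0.0] * 4, u[1:-1], [1.0] * 4])
        nb = knots.size - 4
        design = BSpline.design_matrix(u, knots, 3).toarray()
        # roughness matrix int B_j'' B_k'' du by 3-point Gauss per interval
        # (exact: second derivatives are piecewise linear)
        gx, gw = leggauss(3)
        mids = 0.5 * (u[:-1] + u[1:])
        halves = 0.5 * np.diff(u)
        pts = (mids[:, None] + halves[:, None] * gx[None, :]).ravel()
        wts = (halves[:, None] * gw[None, :]).ravel()
        d2 = BSpline(knots, np.eye(nb), 3)(pts, nu=2)
        omega = (d2.T * wts) @ d2
        xtx = design.T @ design
        # interior diagonal sums, as in the standard parameterisation
        sl = slice(2, nb - 3)
        ratio = np.diag(xtx)[sl].sum() / np.diag(omega)[sl].sum()
        lam = ratio * 256.0 ** (3.0 * spar - 1.0)
        # augmented least squares: sqrt(w*lam) * B'' rows are an exact
        # square root of lam*omega; stable even for very large spar
        aug = np.vstack([design, np.sqrt(wts[:, None] * lam) * d2])
        rhs = np.concatenate([y, np.zeros(pts.size)])
        coef = np.linalg.lstsq(aug, rhs, rcond=None)[0]
        self.x = x
        self.fitted = design @ coef
        self.spar = spar
        self.lam = lam
        self._spline = BSpline(knots, coef, 3)
        self._scale = (float(x[0]), float(span))
        self.domain = (float(x[0]), float(x[-1]))

    def _eval(self, t, nu: int = 0):
        x0, span = self._scale
        return self._spline((np.asarray(t, dtype=float) - x0) / span, nu=nu) / (
            span**nu
        )

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        out = self._eval(np.clip(t, lo, hi))
        # linear continuation outside the data span
        left = t < lo
        right = t > hi
        if np.any(left):
            out = np.where(left, self._eval(lo) + self._eval(lo, 1) * (t - lo), out)
        if np.any(right):
            out = np.where(
                right, self._eval(hi) + self._eval(hi, 1) * (t - hi), out
            )
        return out if out.ndim else float(out)


def fit_decline_spline(
    days: Sequence[float], sizes: Sequence[float], spar: float = 0.5
) -> Callable:
    """Smooth one shoot's declining sizes; returns an evaluable function.

    Falls back (with a warning) to linear interpolation when fewer than
    four decline-phase points are available.
    """
    days = np.asarray(days, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if days.size < 4:
        warnings.warn(
            "fewer than 4 decline points; falling back to linear interpolation",
            stacklevel=2,
        )
        order = np.argsort(days)
        d, s = days[order], sizes[order]

        def interp(t, d=d, s=s):
            out = np.interp(np.asarray(t, dtype=float), d, s)
            return out if np.ndim(t) else float(out)

        interp.domain = (float(d[0]), float(d[-1]))  # type: ignore[attr-defined]
        return interp
    return SmoothingSpline(days, sizes, spar=spar)


# ---------------------------------------------------------------------------
# species profile
# ---------------------------------------------------------------------------


@dataclass
class SenescenceProfile:
    """Averaged normalized decline curve of one species."""

    species_id: str
    grid_days: np.ndarray
    mean_fraction: np.ndarray
    crossings: Dict[float, Optional[float]]
    overwinters: bool
    n_shoots: int = 0


def average_profile(
    splines: Sequence[Callable],
    maxima: Sequence[float],
    species_id: str = "",
) -> SenescenceProfile:
    """Average per-shoot decline splines into a species profile.

    Each spline is evaluated on the common daily grid spanning the union
    of the shoot domains, normalized by that shoot's own maximum size, and
    averaged over the shoots defined at each grid day (shoots with shorter
    observation spans are dropped from the average there rather than
    extrapolated).
    """
    if len(splines) == 0:
        raise ProfileError("no decline splines to average")
    if len(splines) != len(maxima):
        raise ProfileError("splines and maxima must align")
    domains = [getattr(s, "domain") for s in splines]
    start = math.floor(min(d[0] for d in domains))
    stop = math.ceil(max(d[1] for d in domains))
    if stop <= start:
        raise ProfileError("empty grid overlap between shoots")
    grid = np.arange(start, stop + 1, dtype=float)
    total = np.zeros(grid.size)
    count = np.zeros(grid.size)
    for spline, peak in zip(splines, maxima):
        if peak <= 0:
            continue
        lo, hi = spline.domain
        mask = (grid >= lo) & (grid <= hi)
        if not mask.any():
            continue
        total[mask] += np.asarray(spline(grid[mask])) / peak
        count[mask] += 1.0
    defined = count > 0
    if not defined.any():
        raise ProfileError("no shoot defined on the common grid")
    grid = grid[defined]
    mean_fraction = total[defined] / count[defined]
    crossings: Dict[float, Optional[float]] = {}
    for q in PROFILE_FRACTIONS:
        mode = "last" if q == 0.95 else "first"
        crossings[q] = _crossing(grid, mean_fraction, q, mode)
    overwinters = crossings[0.25] is None
    return SenescenceProfile(
        species_id=species_id,
        grid_days=grid,
        mean_fraction=mean_fraction,
        crossings=crossings,
        overwinters=overwinters,
        n_shoots=int(len(splines)),
    )


def _crossing(
    grid: np.ndarray, fraction: np.ndarray, q: float, mode: str
) -> Optional[float]:
    if mode == "first":
        hits = np.nonzero(fraction <= q)[0]
        if hits.size == 0:
            return None
        i = int(hits[0])
        if i == 0:
            return float(grid[0])
        f0, f1 = fraction[i - 1], fraction[i]
        t = grid[i - 1] + (f0 - q) / (f0 - f1) * (grid[i] - grid[i - 1])
    elif mode == "last":
        hits = np.nonzero(fraction >= q)[0]
        if hits.size == 0:
            return None
        i = int(hits[-1])
        if i == grid.size - 1:
            return float(grid[-1])
        f0, f1 = fraction[i], fraction[i + 1]
        t = grid[i] + (f0 - q) / (f0 - f1) * (grid[i + 1] - grid[i])
    else:
        raise ValueError("mode must be 'first' or 'last'")
    return float(np.round(t / CROSSING_RESOLUTION) * CROSSING_RESOLUTION)


def crossing_date(
    profile: SenescenceProfile, fraction: float, mode: str = "first"
) -> Optional[float]:
    """Day the averaged profile crosses ``fraction`` of maximum size.

    ``mode='first'``: earliest day with mean fraction <= ``fraction``;
    ``mode='last'``: latest day with mean fraction >= ``fraction``.
    Linear interpolation between grid days to 0.1-day resolution; ``None``
    when the level is never crossed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    return _crossing(profile.grid_days, profile.mean_fraction, fraction, mode)


# ---------------------------------------------------------------------------
# parameter extraction
# ---------------------------------------------------------------------------


@dataclass
class SenescenceParams:
    """Senescence date / pace / shape and season end for one species."""

    species_id: str
    sen_date: Optional[float]
    sen_pace: Optional[float]
    sen_shape: Optional[float]
    season_end: Optional[float]
    overwinters: bool
    C: Optional[float] = None  # days from 50 % down to 5 %
    D: Optional[float] = None  # days from 95 % down to 50 %


def extract_senescence_params(
    profile: SenescenceProfile, shape_late_over_early: bool = True
) -> SenescenceParams:
    """Extract the senescence parameter vector from a species profile.

    sen_date  = first(0.50)
    sen_pace  = 1 / (first(0.05) - last(0.95))
    C         = first(0.05) - first(0.50)   (late half of the decline)
    D         = first(0.50) - last(0.95)    (early half)
    sen_shape = log(C/D)  (``shape_late_over_early=False`` flips the ratio)
    season_end = first(0.25); undefined for overwintering species.

    Undefined 95 %/5 % crossings leave the dependent parameters undefined
    (logged); a missing 50 % crossing makes the species ineligible.
    """
    t50 = crossing_date(profile, 0.50, "first")
    if t50 is None:
        raise ProfileError(
            f"species {profile.species_id}: profile never reaches 50 %"
        )
    t95 = crossing_date(profile, 0.95, "last")
    t05 = crossing_date(profile, 0.05, "first")
    t25 = crossing_date(profile, 0.25, "first")
    pace = shape = C = D = None
    if t95 is not None and t05 is not None and t05 > t95:
        pace = 1.0 / (t05 - t95)
        C = t05 - t50
        D = t50 - t95
        if C > 0 and D > 0:
            ratio = C / D if shape_late_over_early else D / C
            shape = math.log(ratio)
    else:
        log.info(
            "species %s: 95%%/5%% crossing undefined; pace and shape dropped",
            profile.species_id,
        )
    return SenescenceParams(
        species_id=profile.species_id,
        sen_date=t50,
        sen_pace=pace,
        sen_shape=shape,
        season_end=t25,
        overwinters=profile.overwinters,
        C=C,
        D=D,
    )


# ---------------------------------------------------------------------------
# convenience: whole-species pipeline from split shoot series
# ---------------------------------------------------------------------------


def species_senescence(
    series: Sequence[ShootSeries],
    spar: float = 0.5,
    shape_late_over_early: bool = True,
) -> SenescenceParams:
    """Decline splines -> averaged profile -> parameters for one species."""
    if not series:
        raise ProfileError("no shoot series supplied")
    species_id = series[0].species_id
    splines, maxima = [], []
    for s in series:
        if s.decline_points.size == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spline = fit_decline_spline(s.decline_days, s.decline_sizes, spar)
        splines.append(spline)
        # normalize by the decline spline's own maximum: fractions are then
        # taken on the same smoothed prediction the crossings come from
        lo, hi = spline.domain
        grid = np.arange(math.floor(lo), math.ceil(hi) + 1, dtype=float)
        maxima.append(float(np.max(spline(grid))) if grid.size else s.peak_size)
    profile = average_profile(splines, maxima, species_id=species_id)
    return extract_senescence_params(
        profile, shape_late_over_early=shape_late_over_early
    )


def senescence_table(
    series: Sequence[ShootSeries],
    spar: float = 0.5,
    shape_late_over_early: bool = True,
) -> pd.DataFrame:
    """Per-species senescence parameter table from split shoot series."""
    by_species: Dict[str, List[ShootSeries]] = {}
    for s in series:
        by_species.setdefault(s.species_id, []).append(s)
    rows = []
    for species_id in sorted(by_species):
        try:
            p = species_senescence(
                by_species[species_id],
                spar=spar,
                shape_late_over_early=shape_late_over_early,
            )
        except ProfileError as exc:
            log.warning("%s", exc)
            continue
        rows.append(
            {
                "species_id": p.species_id,
                "sen_date": p.sen_date,
                "sen_pace": p.sen_pace,
                "sen_shape": p.sen_shape,
                "season_end": p.season_end,
                "overwinters": p.overwinters,
            }
        )
    return pd.DataFrame(rows)
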