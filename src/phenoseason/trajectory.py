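"""Scalar plant size and growth/decline splitting of shoot trajectories.

Plant size is the cube root of the volume occupied by the vegetative part
of the shoot.  The three measured dimensions (upper width, lower width,
vegetative length) are combined as a conical frustum by default; the
volume formula is pluggable so alternative solids can be swapped in.

Each shoot's seasonal trajectory is split into its growing and declining
parts by fitting a cubic smoothing spline (roughness chosen by generalized
cross-validation by default), locating its maximum on a dense 0.1-day
grid, and partitioning the measurement points around that day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .errors import DomainError, EmptyTrajectoryError, InsufficientDataError

#: grid step (days) used to locate the spline maximum
GRID_STEP = 0.1


def frustum_volume(upper_width, lower_width, length):
    """Conical-frustum volume from the measured dimension triplet.

    V = pi * L / 12 * (w_u**2 + w_u*w_l + w_l**2); reduces to a cylinder
    for equal widths and to a cone when one width is zero.
    """
    u = np.asarray(upper_width, dtype=float)
    l = np.asarray(lower_width, dtype=float)
    h = np.asarray(length, dtype=float)
    if np.any(u < 0) or np.any(l < 0) or np.any(h < 0):
        raise DomainError("shoot dimensions must be non-negative")
    return np.pi * h / 12.0 * (u * u + u * l + l * l)


def compute_size(upper_width, lower_width, length, volume=frustum_volume):
    """Scalar plant size: cube root of the shoot volume (cm)."""
    return np.cbrt(volume(upper_width, lower_width, length))


@dataclass
class ShootSeries:
    """One shoot's dated sizes with its growth/decline partition."""

    species_id: str
    shoot_id: str
    days: np.ndarray
    sizes: np.ndarray
    split_day: float
    growth_points: np.ndarray  # indices into days/sizes
    decline_points: np.ndarray
    peak_size: float  # spline maximum used for normalization downstream
    #: True when a measured day coincides with the split and is shared by
    #: both partitions.
    shared_peak_point: bool = field(default=False)

    @property
    def growth_days(self) -> np.ndarray:
        return self.days[self.growth_points]

    @property
    def growth_sizes(self) -> np.ndarray:
        return self.sizes[self.growth_points]

    @property
    def decline_days(self) -> np.ndarray:
        return self.days[self.decline_points]

    @property
    def decline_sizes(self) -> np.ndarray:
        return self.sizes[self.decline_points]


def split_trajectory(
    days: Sequence[float],
    sizes: Sequence[float],
    smoothing: float | None = None,
    species_id: str = "",
    shoot_id: str = "",
) -> ShootSeries:
    """Split one shoot's trajectory into growing and declining parts.

    A cubic smoothing spline is fitted to (day, size); ``smoothing`` is
    the spline's roughness penalty ``lam`` (``None`` selects it by
    generalized cross-validation).  The split day is the argmax of the
    spline on a 0.1-day grid (ties broken toward the earliest day);
    measurement points with day <= split form the growth partition, day >=
    split the decline partition, and a point within half a grid step of the
    split is shared by both.

    Input rows may arrive in any order; they are canonicalized by day.
    """
    days = np.asarray(days, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if days.shape != sizes.shape or days.ndim != 1:
        raise DomainError("days and sizes must be 1-D and of equal length")
    order = np.argsort(days, kind="stable")
    days, sizes = days[order], sizes[order]
    if np.any(np.diff(days) <= 0):
        raise DomainError("days must be strictly increasing after sorting")
    if np.all(sizes <= 0):
        raise EmptyTrajectoryError(f"shoot {shoot_id or '<anon>'}: all sizes zero")
    if days.size < 4 or np.unique(sizes[sizes > 0]).size < 2:
        raise InsufficientDataError(
            "need >= 4 observations with >= 2 distinct positive sizes"
        )

    spline = make_smoothing_spline(days, sizes, lam=smoothing)
    grid = np.arange(days[0], days[-1] + GRID_STEP / 2, GRID_STEP)
    values = spline(grid)
    split_day = float(grid[int(np.argmax(values))])  # argmax -> earliest tie
    peak_size = float(np.max(values))

    tol = GRID_STEP / 2
    growth = np.nonzero(days <= split_day + tol)[0]
    decline = np.nonzero(days >= split_day - tol)[0]
    if growth.size == 0:
        growth = np.array([0])
    if decline.size == 0:
        decline = np.array([days.size - 1])
    shared = bool(np.intersect1d(growth, decline).size)
    return ShootSeries(
        species_id=species_id,
        shoot_id=shoot_id,
        days=days,
        sizes=sizes,
        split_day=split_day,
        growth_points=growth,
        decline_points=decline,
        peak_size=peak_size,
        shared_peak_point=shared,
    )


REQUIRED_COLUMNS = [
    "species_id",
    "shoot_id",
    "day_of_year",
    "upper_width_cm",
    "lower_width_cm",
    "length_cm",
]


def measurements_to_series(
    measurements: pd.DataFrame,
    smoothing: float | None = None,
    volume: Callable = frustum_volume,
    on_error: str = "raise",
) -> List[ShootSeries]:
    """Convert a long-format measurement table into split shoot series.

    ``on_error='skip'`` drops shoots that cannot be split (all-zero or too
    short) instead of raising; a ``warnings`` list is attached to the
    returned list object in either case via :func:`split_report`.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in measurements.columns]
    if missing:
        raise DomainError(f"measurement table lacks columns {missing}")
    series: List[ShootSeries] = []
    for (species_id, shoot_id), group in measurements.groupby(
        ["species_id", "shoot_id"], sort=True
    ):
        sizes = compute_size(
            group["upper_width_cm"].to_numpy(),
            group["lower_width_cm"].to_numpy(),
            group["length_cm"].to_numpy(),
            volume=volume,
        )
        try:
            series.append(
                split_trajectory(
                    group["day_of_year"].to_numpy(),
                    sizes,
                    smoothing=smoothing,
                    species_id=str(species_id),
                    shoot_id=str(shoot_id),
                )
            )
        except (EmptyTrajectoryError, InsufficientDataError):
            if on_error == "raise":
                raise
    return series


def series_to_frame(series: Sequence[ShootSeries]) -> pd.DataFrame:
    """Tidy per-point table with a growth/decline ``phase`` column."""
    rows = []
    for s in series:
        phases = {}
        for i in s.growth_points:
            phases[int(i)] = "growth"
        for i in s.decline_points:
            phases[int(i)] = "both" if int(i) in phases else "decline"
        for i, day in enumerate(s.days):
            rows.append(
                {
                    "species_id": s.species_id,
                    "shoot_id": s.shoot_id,
                    "day_of_year": day,
                    "size_cm": s.sizes[i],
                    "phase": phases.get(i, "growth"),
                    "split_day": s.split_day,
                }
            )
    return pd.DataFrame(rows)
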