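"""Occurrence-grid dispersal analysis.

Occurrence records are binned into a square grid (default 14 km cells)
in a local equirectangular projection; for each time period the
*geometric center* is the unweighted mean coordinate of the occupied
cells (presence/absence — duplicate records in a cell count once).
Consecutive-center step distances give a dispersal speed (mean +/- SD km
per interval) and a net first-to-last displacement, and an ordinary
least-squares regression of center longitude on period end-year
quantifies the east-west trend (negative slope = westward in
east-longitude degrees).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distance import haversine_km

EARTH_RADIUS_KM = 6371.0088

CUMULATIVE = "cumulative"
DISJOINT = "disjoint"


@dataclass
class GridSpec:
    """Square analysis grid in a local equirectangular projection
    anchored at the south-west corner of the data's bounding box."""

    cell_km: float = 14.0
    origin_lon: float = 0.0
    origin_lat: float = 0.0
    ref_lat: float = 0.0

    def __post_init__(self) -> None:
        if self.cell_km <= 0:
            raise ValueError("cell size must be positive")

    @classmethod
    def from_points(
        cls, lons: Sequence[float], lats: Sequence[float], cell_km: float = 14.0
    ) -> "GridSpec":
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        return cls(
            cell_km=cell_km,
            origin_lon=float(lons.min()),
            origin_lat=float(lats.min()),
            ref_lat=float((lats.min() + lats.max()) / 2.0),
        )

    def _scale(self) -> tuple[float, float]:
        ky = EARTH_RADIUS_KM * np.pi / 180.0
        kx = ky * np.cos(np.radians(self.ref_lat))
        return kx, ky

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        kx, ky = self._scale()
        col = int(np.floor((lon - self.origin_lon) * kx / self.cell_km))
        row = int(np.floor((lat - self.origin_lat) * ky / self.cell_km))
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        kx, ky = self._scale()
        lon = self.origin_lon + (col + 0.5) * self.cell_km / kx
        lat = self.origin_lat + (row + 0.5) * self.cell_km / ky
        return lon, lat


@dataclass
class CenterTrack:
    """Cumulative- or disjoint-period geometric centers."""

    labels: list[str]
    end_years: list[int]
    lons: list[float]
    lats: list[float]

    def __len__(self) -> int:
        return len(self.labels)


def assign_grid(
    occurrences: pd.DataFrame,
    grid: GridSpec,
    bounds: tuple[float, float, float, float] | None = None,
) -> pd.DataFrame:
    """Map each record to exactly one grid cell (adds row/col columns).

    Records outside ``bounds`` (lon_min, lat_min, lon_max, lat_max), when
    given, are excluded with a warning.
    """
    if occurrences.empty:
        raise ValueError("no occurrence records")
    df = occurrences.copy()
    if bounds is not None:
        lon0, lat0, lon1, lat1 = bounds
        inside = (
            df["lon"].between(lon0, lon1) & df["lat"].between(lat0, lat1)
        )
        if not inside.all():
            warnings.warn(
                f"excluding {(~inside).sum()} record(s) outside the bounding box"
            )
            df = df[inside]
    cells = [grid.cell_of(lon, lat) for lon, lat in zip(df["lon"], df["lat"])]
    df = df.assign(row=[c[0] for c in cells], col=[c[1] for c in cells])
    return df


def group_periods(
    years: Sequence[int],
    mode: str = CUMULATIVE,
    period_years: int = 3,
    start: int | None = None,
) -> list[tuple[str, tuple[int, int]]]:
    """Partition the year range into analysis periods.

    Disjoint mode yields consecutive ``period_years``-long blocks (the
    last block may be shorter, e.g. 2015-16 for 2003-2016); cumulative
    mode (default) keeps the same end years but starts every period at
    the first year.
    """
    if mode not in (CUMULATIVE, DISJOINT):
        raise ValueError(f"unknown period mode {mode!r}")
    years = sorted(set(int(y) for y in years))
    if not years:
        raise ValueError("no years supplied")
    y0 = years[0] if start is None else start
    y1 = years[-1]
    ends = list(range(y0 + period_years - 1, y1, period_years)) + [y1]
    ends = sorted(set(min(e, y1) for e in ends))
    if len(ends) < 2:
        raise ValueError("year range spans fewer than two periods")
    periods = []
    prev = y0
    for e in ends:
        if mode == CUMULATIVE:
            periods.append((f"{y0}-{e}", (y0, e)))
        else:
            periods.append((f"{prev}-{e}", (prev, e)))
            prev = e + 1
    return periods


def occupied_cells(
    gridded: pd.DataFrame, periods: Sequence[tuple[str, tuple[int, int]]]
) -> dict[str, set[tuple[int, int]]]:
    """Occupied (row, col) cells per period; duplicates collapse."""
    out: dict[str, set[tuple[int, int]]] = {}
    for label, (a, b) in periods:
        sel = gridded[(gridded["year"] >= a) & (gridded["year"] <= b)]
        out[label] = set(zip(sel["row"], sel["col"]))
    return out


def geometric_centers(
    cells_by_period: dict[str, set[tuple[int, int]]],
    grid: GridSpec,
    periods: Sequence[tuple[str, tuple[int, int]]],
) -> CenterTrack:
    """Unweighted mean of occupied-cell centers for each period."""
    labels, end_years, lons, lats = [], [], [], []
    for label, (_, end) in periods:
        cells = cells_by_period.get(label, set())
        if not cells:
            raise ValueError(f"period {label} has no occupied cells")
        centers = [grid.cell_center(r, c) for r, c in sorted(cells)]
        labels.append(label)
        end_years.append(end)
        lons.append(float(np.mean([c[0] for c in centers])))
        lats.append(float(np.mean([c[1] for c in centers])))
    return CenterTrack(labels=labels, end_years=end_years, lons=lons, lats=lats)


def dispersal_speed(track: CenterTrack) -> dict[str, float]:
    """Mean +/- sample-SD step distance between consecutive centers and
    the net first-to-last displacement, in km."""
    if len(track) < 2:
        raise ValueError("dispersal speed needs at least two centers")
    steps = [
        haversine_km(track.lons[i], track.lats[i], track.lons[i + 1], track.lats[i + 1])
        for i in range(len(track) - 1)
    ]
    return {
        "mean_step_km": float(np.mean(steps)),
        "sd_step_km": float(np.std(steps, ddof=1)) if len(steps) > 1 else 0.0,
        "net_displacement_km": haversine_km(
            track.lons[0], track.lats[0], track.lons[-1], track.lats[-1]
        ),
        "n_steps": float(len(steps)),
    }


def center_trend(track: CenterTrack) -> dict[str, float]:
    """OLS of center longitude on period end-year: slope (degrees east
    per year; negative = westward), R^2 and the two-sided slope p."""
    if len(track) < 3:
        raise ValueError("trend regression needs at least three centers")
    if np.ptp(track.lons) == 0.0:
        return {
            "slope_deg_per_year": 0.0,
            "intercept": float(track.lons[0]),
            "r_squared": 0.0,
            "p_value": 1.0,
        }
    res = stats.linregress(track.end_years, track.lons)
    return {
        "slope_deg_per_year": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
    }


def analyze_occurrences(
    occurrences: pd.DataFrame,
    cell_km: float = 14.0,
    mode: str = CUMULATIVE,
    bounds: tuple[float, float, float, float] | None = None,
) -> tuple[CenterTrack, dict[str, float], dict[str, float]]:
    """End-to-end dispersal analysis: grid, periods, centers, speed,
    trend."""
    grid = GridSpec.from_points(occurrences["lon"], occurrences["lat"], cell_km)
    gridded = assign_grid(occurrences, grid, bounds=bounds)
    periods = group_periods(gridded["year"], mode=mode)
    cells = occupied_cells(gridded, periods)
    track = geometric_centers(cells, grid, periods)
    return track, dispersal_speed(track), center_trend(track)
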