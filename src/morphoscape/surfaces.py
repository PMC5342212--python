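"""Spatial interpolation surfaces of diversity and differentiation.

Great-circle distances, Delaunay connectivity networks with edge midpoints,
residual distances from the regression of a response matrix on geographic
distance, inverse distance-weighted (IDW) interpolation rasters, point
extraction and cross-surface correlation statistics.

Differentiation surfaces interpolate residual inter-population distances
assigned to Delaunay edge midpoints; diversity/size surfaces interpolate
per-population values at the population locations.  Both use great-circle
kilometre distances in the IDW weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial import Delaunay

from .core import DistanceMatrix

__all__ = [
    "EARTH_RADIUS_KM",
    "InterpolationSettings",
    "Surface",
    "great_circle_km",
    "great_circle_matrix",
    "delaunay_edge_midpoints",
    "residual_distances",
    "idw_surface",
    "extract_at_points",
    "surface_correlation",
]

EARTH_RADIUS_KM = 6371.0

# snap threshold: a cell center within this great-circle distance of a data
# point takes that point's value exactly (avoids singular IDW weights)
SNAP_EPS_KM = 1e-6


@dataclass(frozen=True)
class InterpolationSettings:
    """IDW raster parameters.

    ``a`` is the distance-weighting exponent (study default set {1, 5, 10});
    ``resolution_arcmin`` the square cell size; ``extent`` is
    (lon_min, lon_max, lat_min, lat_max) or None to use the data bounding box
    plus ``margin_deg``.
    """

    a: float = 5.0
    resolution_arcmin: float = 10.0
    extent: tuple[float, float, float, float] | None = None
    margin_deg: float = 2.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("distance-weighting exponent a must be positive")
        if self.resolution_arcmin <= 0:
            raise ValueError("resolution must be positive")
        if self.extent is not None:
            lon_min, lon_max, lat_min, lat_max = self.extent
            if lon_min >= lon_max or lat_min >= lat_max:
                raise ValueError(f"degenerate extent {self.extent}")


@dataclass
class Surface:
    """Raster of interpolated values; cell registration at cell centers.

    Row 0 is the northernmost row (standard raster orientation).
    """

    values: np.ndarray  # (n_rows, n_cols), NaN = missing
    extent: tuple[float, float, float, float]  # lon_min, lon_max, lat_min, lat_max
    resolution_deg: float

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) 1-D coordinate arrays of cell centers."""
        lon_min, _, _, lat_max = self.extent
        lons = lon_min + (np.arange(self.n_cols) + 0.5) * self.resolution_deg
        lats = lat_max - (np.arange(self.n_rows) + 0.5) * self.resolution_deg
        return lons, lats

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        lon_min, lon_max, lat_min, lat_max = self.extent
        if not (lon_min <= lon <= lon_max and lat_min <= lat <= lat_max):
            raise ValueError(f"point ({lon}, {lat}) outside extent {self.extent}")
        col = int(np.clip((lon - lon_min) / self.resolution_deg, 0, self.n_cols - 1))
        row = int(np.clip((lat_max - lat) / self.resolution_deg, 0, self.n_rows - 1))
        return row, col

    def write_ascii_grid(self, path) -> None:
        """Write as an ESRI ASCII grid (plain-text raster)."""
        lon_min, _, lat_min, _ = self.extent
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {lon_min}\n"
            f"yllcorner {lat_min}\n"
            f"cellsize {self.resolution_deg}\n"
            f"NODATA_value -9999\n"
        )
        body = np.where(np.isfinite(self.values), self.values, -9999.0)
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt="%.10g")


def great_circle_km(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Haversine great-circle distance in kilometres (R = 6371 km)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def great_circle_matrix(
    points: Sequence[tuple[float, float]], labels: Sequence[str] | None = None
) -> DistanceMatrix:
    """Pairwise great-circle distances (km) among (lon, lat) points."""
    pts = np.asarray(points, dtype=float)
    if labels is None:
        labels = [str(i) for i in range(len(pts))]
    lon = pts[:, 0]
    lat = pts[:, 1]
    d = great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(labels), d, "great_circle_km")


def delaunay_edge_midpoints(
    points: Sequence[tuple[float, float]],
) -> list[tuple[tuple[int, int], tuple[float, float]]]:
    """Unique Delaunay edges and their coordinate midpoints.

    The triangulation treats (lon, lat) as planar coordinates.  Returns a
    sorted list of ((i, j), (mid_lon, mid_lat)) with i < j.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("Delaunay triangulation requires at least 3 points")
    try:
        tri = Delaunay(pts)
    except Exception as exc:  # scipy QhullError on collinear input
        raise ValueError(f"Delaunay triangulation failed: {exc}") from exc
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = sorted((int(simplex[a]), int(simplex[b])))
                edges.add((i, j))
    result = []
    for i, j in sorted(edges):
        mid = (pts[i] + pts[j]) / 2.0
        result.append(((i, j), (float(mid[0]), float(mid[1]))))
    return result


def residual_distances(response: DistanceMatrix, geo: DistanceMatrix) -> DistanceMatrix:
    """Signed residuals of the response matrix regressed on geographic distance.

    OLS (with intercept) of the unfolded response on the unfolded geographic
    distance; residuals are reassembled into a symmetric matrix with zero
    diagonal and may be negative.
    """
    if response.labels != geo.labels:
        geo = geo.submatrix(response.labels)
    y = response.condensed()
    x = geo.condensed()
    if np.ptp(x) == 0.0:
        raise ValueError("geographic distances have zero variance")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return DistanceMatrix.from_condensed(
        response.labels, resid, f"residual_{response.metric_name}"
    )


def _resolve_extent(
    pts: np.ndarray, settings: InterpolationSettings
) -> tuple[float, float, float, float]:
    if settings.extent is not None:
        return settings.extent
    m = settings.margin_deg
    return (
        float(pts[:, 0].min() - m),
        float(pts[:, 0].max() + m),
        float(pts[:, 1].min() - m),
        float(pts[:, 1].max() + m),
    )


def idw_surface(
    points: Sequence[tuple[float, float, float]],
    settings: InterpolationSettings = InterpolationSettings(),
) -> Surface:
    """Inverse distance-weighted interpolation raster.

    Cell value = sum(w_i v_i) / sum(w_i) with w_i = 1 / d_i^a, where d_i is
    the great-circle kilometre distance from the cell center to data point i.
    A cell center within the snap threshold of a data point takes that
    point's value exactly.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0 or pts.shape[1] != 3:
        raise ValueError("points must be a non-empty list of (lon, lat, value)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite point coordinates or values")
    extent = _resolve_extent(pts, settings)
    res_deg = settings.resolution_arcmin / 60.0
    lon_min, lon_max, lat_min, lat_max = extent
    n_cols = max(1, int(np.ceil((lon_max - lon_min) / res_deg - 1e-9)))
    n_rows = max(1, int(np.ceil((lat_max - lat_min) / res_deg - 1e-9)))
    surf = Surface(np.full((n_rows, n_cols), np.nan), extent, res_deg)
    lons, lats = surf.cell_centers()
    glon, glat = np.meshgrid(lons, lats)
    # (n_cells, n_points) distance matrix
    d = great_circle_km(
        glon.ravel()[:, None],
        glat.ravel()[:, None],
        pts[None, :, 0],
        pts[None, :, 1],
    )
    values = pts[:, 2]
    with np.errstate(divide="ignore", over="ignore"):
        w = 1.0 / np.maximum(d, SNAP_EPS_KM) ** settings.a
    cell_vals = (w @ values) / w.sum(axis=1)
    snapped = d <= SNAP_EPS_KM
    snap_rows = np.nonzero(snapped.any(axis=1))[0]
    for r in snap_rows:
        cell_vals[r] = values[np.argmax(snapped[r])]
    surf.values = cell_vals.reshape(n_rows, n_cols)
    return surf


def extract_at_points(
    s: Surface, points: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Value of the raster cell containing each (lon, lat) point."""
    outside = [
        p
        for p in points
        if not (
            s.extent[0] <= p[0] <= s.extent[1] and s.extent[2] <= p[1] <= s.extent[3]
        )
    ]
    if outside:
        raise ValueError(f"points outside surface extent: {outside}")
    return np.array([s.values[s.cell_index(lon, lat)] for lon, lat in points])


def surface_correlation(
    v1: Sequence[float], v2: Sequence[float]
) -> tuple[float, float, float]:
    """Pearson r, regression R² and the slope-test p-value between two series."""
    x = np.asarray(v1, dtype=float)
    y = np.asarray(v2, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("inputs must be equal-length 1-D series with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in correlation inputs")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero variance in correlation inputs")
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.rvalue**2), float(res.pvalue)
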