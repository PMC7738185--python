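"""Leaflet-scale morphology and histological thickness profiling.

Leaflet area, major cusp width and height are measured on a calibrated
outline polygon with labeled commissure points.  Section thickness is
measured between smooth curves fitted to the digitized atrialis and
ventricularis surfaces: normals are cast from equally spaced arc-length
stations on the atrialis curve to their first intersection with the
ventricularis curve, manually flagged intervals (chordae tendineae, annular
muscle) are excluded, and the profile is summarized into three equidistant
arc-length regions — near-annulus, belly, and free edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "LeafletOutline",
    "SectionGeometry",
    "FittedCurve",
    "ThicknessProfile",
    "leaflet_morphology",
    "fit_contours",
    "thickness_profile",
]

#: Number of equally spaced thickness stations along the atrialis curve.
DEFAULT_N_STATIONS = 100


@dataclass
class LeafletOutline:
    """Calibrated closed leaflet outline with labeled commissure points.

    Coordinates in mm (already calibrated); ``commissures`` holds the
    antero-septal and antero-posterior commissure points.
    """

    polygon_mm: np.ndarray  # (n, 2), ordered, implicitly closed
    commissures: np.ndarray  # (2, 2): AS, AP

    def __post_init__(self) -> None:
        self.polygon_mm = np.asarray(self.polygon_mm, float)
        self.commissures = np.asarray(self.commissures, float)
        if self.polygon_mm.shape[0] < 3:
            raise ValueError("outline needs at least 3 vertices")


@dataclass
class SectionGeometry:
    """Digitized atrialis/ventricularis contour pair of one radial strip.

    Both polylines are open, ordered annulus-to-free-edge, coordinates in mm.
    ``exclusion_intervals`` are (start, stop) arc-length fractions along the
    atrialis curve to ignore (chordae tendineae, annular muscle).
    """

    atrialis_mm: np.ndarray
    ventricularis_mm: np.ndarray
    exclusion_intervals: list[tuple[float, float]] = field(default_factory=list)
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atrialis_mm = np.asarray(self.atrialis_mm, float)
        self.ventricularis_mm = np.asarray(self.ventricularis_mm, float)
        for a, b in self.exclusion_intervals:
            if not (0 <= a < b <= 1):
                raise ValueError("exclusion intervals must be fractions with start < stop")


class FittedCurve:
    """Smoothing-spline curve with arc-length parameterization.

    Wraps a parametric spline fit of an ordered polyline; points, tangents
    and normals are evaluated at arc-length fractions in [0, 1].
    """

    _N_TABLE = 2000  # resolution of the internal arc-length lookup table

    def __init__(self, points: np.ndarray, smoothing: float = 0.0, k: int = 3):
        pts = np.asarray(points, float)
        if pts.shape[0] < 10:
            raise ValueError("need at least 10 points to fit a contour")
        # collapse consecutive duplicates, which splprep rejects
        keep = np.ones(len(pts), bool)
        keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
        pts = pts[keep]
        k = min(k, len(pts) - 1)
        self._tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], s=smoothing, k=k)
        self._input_points = pts
        u = np.linspace(0, 1, self._N_TABLE)
        xy = np.column_stack(interpolate.splev(u, self._tck))
        seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        self.length = float(arc[-1])
        self._u_of_s = interpolate.interp1d(arc / self.length, u, assume_sorted=True)
        self._table_xy = xy
        dev = self._deviation(pts)
        self.max_deviation = dev

    def _deviation(self, pts: np.ndarray) -> float:
        line = LineString(self._table_xy)
        return float(max(line.distance(Point(p)) for p in pts))

    def point(self, s_frac) -> np.ndarray:
        u = self._u_of_s(np.clip(s_frac, 0, 1))
        return np.column_stack(interpolate.splev(u, self._tck))

    def tangent(self, s_frac) -> np.ndarray:
        u = self._u_of_s(np.clip(s_frac, 0, 1))
        d = np.column_stack(interpolate.splev(u, self._tck, der=1))
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def normal(self, s_frac) -> np.ndarray:
        """Unit normal (tangent rotated +90 degrees)."""
        t = self.tangent(s_frac)
        return np.column_stack([-t[:, 1], t[:, 0]])

    def curvature(self, s_frac) -> np.ndarray:
        u = self._u_of_s(np.clip(s_frac, 0, 1))
        d1 = np.column_stack(interpolate.splev(u, self._tck, der=1))
        d2 = np.column_stack(interpolate.splev(u, self._tck, der=2))
        num = np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
        den = np.linalg.norm(d1, axis=1) ** 3
        return num / den

    def as_linestring(self, n: int = 500) -> LineString:
        s = np.linspace(0, 1, n)
        return LineString(self.point(s))


@dataclass
class ThicknessProfile:
    arc_fraction: np.ndarray
    thickness_mm: np.ndarray  # NaN where the station was dropped
    region_means_mm: dict[str, float]  # near_annulus / belly / free_edge
    pooled_mean_mm: float
    n_dropped: int
    flags: list[str] = field(default_factory=list)

    REGIONS = ("near_annulus", "belly", "free_edge")


def leaflet_morphology(outline: LeafletOutline) -> dict[str, float]:
    """Area (cm^2), major cusp width and height (cm) of a leaflet outline.

    Area by the shoelace formula (via shapely); width is the distance between
    the two commissure points; height is the maximal extent of the outline
    perpendicular to the commissure chord.
    """
    poly = Polygon(outline.polygon_mm)
    if not poly.is_valid:
        raise ValueError("outline polygon is self-intersecting or degenerate")
    area_cm2 = poly.area / 100.0
    c0, c1 = outline.commissures
    chord = c1 - c0
    width_cm = float(np.linalg.norm(chord)) / 10.0
    nrm = np.array([-chord[1], chord[0]]) / np.linalg.norm(chord)
    proj = (outline.polygon_mm - c0) @ nrm
    height_cm = float(np.ptp(proj)) / 10.0
    return {"area_cm2": float(area_cm2), "height_cm": height_cm, "width_cm": width_cm}


def fit_contours(
    section: SectionGeometry, smoothing: float = 0.0
) -> tuple[FittedCurve, FittedCurve]:
    """Fit arc-length-parameterized smooth curves to both surface polylines."""
    return (
        FittedCurve(section.atrialis_mm, smoothing=smoothing),
        FittedCurve(section.ventricularis_mm, smoothing=smoothing),
    )


def _in_exclusion(s: float, intervals: list[tuple[float, float]]) -> bool:
    return any(a <= s <= b for a, b in intervals)


def thickness_profile(
    section: SectionGeometry,
    n_stations: int = DEFAULT_N_STATIONS,
    smoothing: float = 0.0,
    curves: tuple[FittedCurve, FittedCurve] | None = None,
) -> ThicknessProfile:
    """Normal-ray thickness at equally spaced atrialis arc-length stations.

    At each station the atrialis normal ray is cast toward the ventricularis
    curve and the thickness is the distance to the nearest intersection.
    Stations inside exclusion intervals are dropped; stations whose ray
    misses the ventricularis curve (end effects) are dropped and counted.
    Region means are taken over arc-fraction thirds.
    """
    atr, ven = curves if curves is not None else fit_contours(section, smoothing)
    ven_line = ven.as_linestring(max(500, 4 * n_stations))
    # orient the normal toward the ventricularis side
    mid = atr.point(0.5)[0]
    nrm_mid = atr.normal(0.5)[0]
    ven_mid = ven.point(0.5)[0]
    sign = 1.0 if np.dot(ven_mid - mid, nrm_mid) >= 0 else -1.0
    ray_len = 4.0 * max(atr.length, ven.length)

    s = np.linspace(0, 1, n_stations)
    pts = atr.point(s)
    nrms = sign * atr.normal(s)
    thick = np.full(n_stations, np.nan)
    n_missed = 0
    for i in range(n_stations):
        if _in_exclusion(s[i], section.exclusion_intervals):
            continue
        ray = LineString([pts[i], pts[i] + ray_len * nrms[i]])
        hit = ray.intersection(ven_line)
        if hit.is_empty:
            n_missed += 1
            continue
        thick[i] = hit.distance(Point(pts[i]))

    flags = []
    n_dropped = int(np.sum(np.isnan(thick)))
    if n_missed > 0.2 * n_stations:
        flags.append("more_than_20pct_stations_dropped")

    regions = {}
    bounds = [(0, 1 / 3), (1 / 3, 2 / 3), (2 / 3, 1 + 1e-12)]
    for name, (a, b) in zip(ThicknessProfile.REGIONS, bounds):
        mask = (s >= a) & (s < b) & np.isfinite(thick)
        regions[name] = float(np.mean(thick[mask])) if mask.any() else np.nan
    pooled = float(np.nanmean(thick)) if np.isfinite(thick).any() else np.nan
    return ThicknessProfile(
        arc_fraction=s,
        thickness_mm=thick,
        region_means_mm=regions,
        pooled_mean_mm=pooled,
        n_dropped=n_dropped,
        flags=flags,
    )
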