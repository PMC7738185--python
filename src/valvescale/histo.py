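"""Regional immunohistochemistry quantification over a 3 x 10 region grid.

Each radial strip section is split into 3 equal arc-length segments along
the atrialis curve (near-annulus, belly, free edge) by 10 equally spaced
transmural layers blended linearly between matched atrialis/ventricularis
stations — 30 regions per section.  Positive and total pixels are counted
per region (positivity from a label channel on synthetic images, or a
chromogen threshold after stain separation on real RGB images), group
fold-change maps are computed as the ratio of mean positive-pixel
percentages (disease over control) with their base-2 logarithm, and nuclei
density is reported per region as count per square millimetre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon
from skimage import color, draw, measure

from valvescale.morphometry import FittedCurve, SectionGeometry, fit_contours

__all__ = [
    "RegionGrid",
    "StainedSection",
    "StainQuant",
    "FoldChangeMap",
    "build_region_grid",
    "quantify_stain",
    "fold_change_map",
    "nuclei_density",
]

N_LENGTH = 3  # near-annulus, belly, free edge
N_DEPTH = 10  # atrialis -> ventricularis layers
LENGTH_NAMES = ("near_annulus", "belly", "free_edge")


@dataclass
class RegionGrid:
    """30 quadrilateral-strip region polygons tiling the inter-contour band.

    ``polygons[i][j]`` covers length segment i (annulus to free edge) and
    transmural layer j (atrialis to ventricularis), in section coordinates
    (mm).  ``exclusions`` are polygons removed from every region.
    """

    polygons: list[list[Polygon]]
    n_length: int = N_LENGTH
    n_depth: int = N_DEPTH
    exclusions: list[Polygon] = field(default_factory=list)

    @property
    def band(self) -> Polygon:
        from shapely.ops import unary_union

        return unary_union([p for row in self.polygons for p in row])


@dataclass
class StainedSection:
    """Raster stain image registered to section coordinates.

    ``positive`` and ``tissue`` are boolean masks; pixel (r, c) center sits
    at physical position ``origin_mm + calibration_mm * (c, r)`` (x = column,
    y = row; the grid polygons are built in the same frame).
    """

    positive: np.ndarray
    tissue: np.ndarray
    calibration_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(2))
    marker: str = ""
    truth: dict = field(default_factory=dict)


@dataclass
class StainQuant:
    positive_pct: np.ndarray  # (3, 10), NaN where region empty
    positive_counts: np.ndarray
    total_counts: np.ndarray
    marker: str = ""
    flags: list[str] = field(default_factory=list)


@dataclass
class FoldChangeMap:
    fc: np.ndarray  # (3, 10), treatment over control mean percentage
    log2fc: np.ndarray
    undefined: np.ndarray  # bool mask where the ratio is undefined
    group_sizes: tuple[int, int] = (0, 0)


def build_region_grid(
    section: SectionGeometry,
    n_length: int = N_LENGTH,
    n_depth: int = N_DEPTH,
    stations_per_segment: int = 10,
    smoothing: float = 0.0,
    exclusions: list[Polygon] | None = None,
    curves: tuple[FittedCurve, FittedCurve] | None = None,
) -> RegionGrid:
    """Build the 3 x 10 region grid between the fitted surface curves.

    Matched stations are taken at equal arc-length fractions on both curves;
    layer boundaries blend linearly between them: P(s, t) = (1 - t) A(s) +
    t V(s).  Regions share boundaries and tile the band without overlap.
    """
    atr, ven = curves if curves is not None else fit_contours(section, smoothing)
    n_st = n_length * stations_per_segment + 1
    s = np.linspace(0.0, 1.0, n_st)
    A = atr.point(s)
    V = ven.point(s)
    if _contours_cross(A, V):
        raise ValueError("atrialis and ventricularis contours cross")
    t_edges = np.linspace(0.0, 1.0, n_depth + 1)
    layers = [(1 - t) * A + t * V for t in t_edges]  # (n_depth+1) x (n_st, 2)
    polys: list[list[Polygon]] = []
    for i in range(n_length):
        lo = i * stations_per_segment
        hi = (i + 1) * stations_per_segment
        row = []
        for j in range(n_depth):
            top = layers[j][lo : hi + 1]
            bot = layers[j + 1][lo : hi + 1]
            ring = np.vstack([top, bot[::-1]])
            poly = Polygon(ring)
            if not poly.is_valid:
                poly = poly.buffer(0)
            row.append(poly)
        polys.append(row)
    return RegionGrid(
        polygons=polys, n_length=n_length, n_depth=n_depth, exclusions=exclusions or []
    )


def _contours_cross(A: np.ndarray, V: np.ndarray) -> bool:
    from shapely.geometry import LineString

    return LineString(A).crosses(LineString(V))


def _region_label_image(
    grid: RegionGrid, shape: tuple[int, int], calibration_mm: float, origin_mm
) -> np.ndarray:
    """Assign each pixel to at most one region (first-come on shared edges).

    Returns an int image: -1 outside the band, -2 excluded, else
    ``i * n_depth + j``.
    """
    lab = np.full(shape, -1, dtype=np.int32)
    org = np.asarray(origin_mm, float)
    for i, row in enumerate(grid.polygons):
        for j, poly in enumerate(row):
            xs, ys = poly.exterior.coords.xy
            cc = (np.asarray(xs) - org[0]) / calibration_mm
            rr = (np.asarray(ys) - org[1]) / calibration_mm
            r_idx, c_idx = draw.polygon(rr, cc, shape=shape)
            sel = lab[r_idx, c_idx] == -1
            lab[r_idx[sel], c_idx[sel]] = i * grid.n_depth + j
    for ex in grid.exclusions:
        xs, ys = ex.exterior.coords.xy
        cc = (np.asarray(xs) - org[0]) / calibration_mm
        rr = (np.asarray(ys) - org[1]) / calibration_mm
        r_idx, c_idx = draw.polygon(rr, cc, shape=shape)
        lab[r_idx, c_idx] = -2
    return lab


def dab_positivity(rgb_image: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Chromogen positivity mask for real RGB images.

    Separates stains with the standard hematoxylin/eosin/DAB vectors and
    thresholds the DAB channel (Otsu when no threshold is given).  The rule
    is deliberately pluggable: synthetic label images bypass it entirely.
    """
    hed = color.rgb2hed(rgb_image)
    dab = hed[..., 2]
    if threshold is None:
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(dab))
    return dab > threshold


def quantify_stain(image: StainedSection, grid: RegionGrid) -> StainQuant:
    """Per-region positive-pixel percentages over non-excluded tissue pixels."""
    lab = _region_label_image(
        grid, image.tissue.shape, image.calibration_mm, image.origin_mm
    )
    pos = np.asarray(image.positive, bool)
    tis = np.asarray(image.tissue, bool)
    pos_counts = np.zeros((grid.n_length, grid.n_depth), dtype=np.int64)
    tot_counts = np.zeros_like(pos_counts)
    flags: list[str] = []
    for i in range(grid.n_length):
        for j in range(grid.n_depth):
            sel = (lab == i * grid.n_depth + j) & tis
            tot = int(sel.sum())
            tot_counts[i, j] = tot
            pos_counts[i, j] = int((sel & pos).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * pos_counts / tot_counts
    empty = tot_counts == 0
    if empty.any():
        flags.append(f"{int(empty.sum())}_empty_regions")
        pct = np.where(empty, np.nan, pct)
    return StainQuant(
        positive_pct=pct,
        positive_counts=pos_counts,
        total_counts=tot_counts,
        marker=image.marker,
        flags=flags,
    )


def fold_change_map(
    treated: list[StainQuant],
    control: list[StainQuant],
    summary: str = "mean",
) -> FoldChangeMap:
    """Cell-wise fold change of group-summarized positive percentages.

    fc = summary(treated %) / summary(control %) per cell; log2fc where both
    summaries are positive, otherwise flagged undefined (never silently
    zeroed).  Positive log2fc means higher expression in the treated group.
    """
    if not treated or not control:
        raise ValueError("need at least one subject per group")
    fn = np.nanmean if summary == "mean" else np.nanmedian
    t = fn(np.stack([q.positive_pct for q in treated]), axis=0)
    c = fn(np.stack([q.positive_pct for q in control]), axis=0)
    undefined = ~(np.isfinite(t) & np.isfinite(c)) | (c == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.where(undefined, np.nan, t / np.where(c == 0, np.nan, c))
        log2fc = np.where(fc > 0, np.log2(fc), np.nan)
    log2_undefined = undefined | ~(fc > 0)
    return FoldChangeMap(
        fc=fc,
        log2fc=np.where(log2_undefined, np.nan, log2fc),
        undefined=log2_undefined,
        group_sizes=(len(treated), len(control)),
    )


def nuclei_density(
    nuclei_mask: np.ndarray,
    grid: RegionGrid,
    calibration_mm: float,
    origin_mm=(0.0, 0.0),
) -> np.ndarray:
    """Connected-component count per region area (count / mm^2), (3, 10)."""
    labels = measure.label(np.asarray(nuclei_mask, bool))
    out = np.zeros((grid.n_length, grid.n_depth))
    counts = np.zeros_like(out)
    cents = [p.centroid for p in measure.regionprops(labels)]
    org = np.asarray(origin_mm, float)
    for r, c in cents:
        pt = Point(org[0] + c * calibration_mm, org[1] + r * calibration_mm)
        for i, row in enumerate(grid.polygons):
            done = False
            for j, poly in enumerate(row):
                if poly.covers(pt) and not any(ex.covers(pt) for ex in grid.exclusions):
                    counts[i, j] += 1
                    done = True
                    break
            if done:
                break
    for i, row in enumerate(grid.polygons):
        for j, poly in enumerate(row):
            area = poly.area
            for ex in grid.exclusions:
                area -= poly.intersection(ex).area
            out[i, j] = counts[i, j] / area if area > 0 else 0.0
    return out
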