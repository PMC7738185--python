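"""Synthetic-data generators with known ground truth for every pipeline input.

Every quantity the pipeline measures can be generated here with a planted
truth: biaxial marker records following a piecewise-linear (toe slope, calf
slope, transition stretch) membrane-tension law; section contour pairs with
a prescribed thickness profile; stained-section rasters with exact planted
positive fractions per region; depth-resolved fiber-orientation samples from
axial von Mises distributions; non-overlapping elliptical nuclei fields; and
two-group log-normal protein intensity matrices with planted signed log2
fold changes.  Defaults emulate an ovine tricuspid anterior leaflet: a
J-shaped tension–stretch response stiffer circumferentially than radially,
thickness decreasing from annulus to free edge (about 1.2 to 0.6 mm), mean
fiber angle near circumferential (90 degrees) with concentration decreasing
with depth, and elongated nuclei (aspect ratio about 1.8).

All generators are deterministic given a seed; pass an explicit
``numpy.random.Generator`` to share one stream across calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage import draw as skdraw

from valvescale.assays import IntensityMatrix
from valvescale.biax import PRELOAD_MN, BiaxRecord
from valvescale.histo import N_DEPTH, N_LENGTH, StainedSection
from valvescale.microstructure import (
    OrientationDepthProfile,
    _bin_centers,
    histogram_from_angles,
)
from valvescale.morphometry import LeafletOutline, SectionGeometry

__all__ = [
    "CurveLaw",
    "GroundTruth",
    "Subject",
    "Cohort",
    "default_truth",
    "gen_biax_record",
    "gen_section_geometry",
    "gen_ihc_image",
    "gen_fiber_stack",
    "gen_nuclei_field",
    "gen_intensity_matrix",
    "gen_cohort",
]

#: Rake-to-rake span of the mounted 7 x 7 mm specimen (mm).
RAKE_SPAN_MM = 7.0
#: Fiducial marker grid: corners of a 3 mm square centered in the specimen.
MARKER_GRID_MM = 3.0


@dataclass(frozen=True)
class CurveLaw:
    """Piecewise-linear membrane tension vs stretch law (one direction).

    Tension rises from zero at stretch 1 with the toe slope, then with the
    calf slope beyond the transition stretch.  Slopes in N/m per unit
    stretch.  The analytic form makes J-curve metric recovery exact.
    """

    toe_slope: float
    calf_slope: float
    transition_stretch: float

    def tension(self, stretch) -> np.ndarray:
        lam = np.asarray(stretch, float)
        t_t = self.toe_slope * (self.transition_stretch - 1.0)
        return np.where(
            lam <= self.transition_stretch,
            np.clip(self.toe_slope * (lam - 1.0), 0.0, None),
            t_t + self.calf_slope * (lam - self.transition_stretch),
        )

    def stretch_at(self, tension) -> np.ndarray:
        t = np.asarray(tension, float)
        t_t = self.toe_slope * (self.transition_stretch - 1.0)
        return np.where(
            t <= t_t,
            1.0 + t / self.toe_slope,
            self.transition_stretch + (t - t_t) / self.calf_slope,
        )


def _default_fractions(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.uniform(0.02, 0.4, size=(N_LENGTH, N_DEPTH))


@dataclass
class GroundTruth:
    """Planted parameters behind one synthetic specimen/subject.

    ``thickness_mm_annulus``/``thickness_mm_free_edge`` define a linear
    thickness profile in arc-length fraction; ``vm_mu_deg``/``vm_kappa`` are
    callables of normalized depth; ``de_log2fc`` maps planted protein ids to
    signed log2 fold changes.
    """

    seed: int = 0
    prescribed_F: np.ndarray = field(
        default_factory=lambda: np.array([[1.16, 0.0], [0.0, 1.37]])
    )
    law_circ: CurveLaw = field(default_factory=lambda: CurveLaw(25.0, 300.0, 1.10))
    law_rad: CurveLaw = field(default_factory=lambda: CurveLaw(12.0, 150.0, 1.25))
    thickness_mm_annulus: float = 1.2
    thickness_mm_free_edge: float = 0.6
    leaflet_width_cm: float = 3.2
    leaflet_height_cm: float = 1.8
    region_positive_fractions: np.ndarray | None = None
    vm_mu_deg: object = staticmethod(lambda z: np.full_like(np.asarray(z, float), 90.0))
    vm_kappa: object = staticmethod(lambda z: 5.0 - 3.0 * np.asarray(z, float))
    nuclei_mu_deg: float = 90.0
    nuclei_kappa: float = 3.0
    nar_mean: float = 1.8
    nar_sd: float = 0.2
    circularity_mean: float = 0.85
    circularity_sd: float = 0.05
    de_log2fc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.prescribed_F = np.asarray(self.prescribed_F, float)
        if np.linalg.det(self.prescribed_F) <= 0:
            raise ValueError("prescribed F must have positive determinant")
        if self.region_positive_fractions is None:
            self.region_positive_fractions = _default_fractions(self.seed)
        self.region_positive_fractions = np.asarray(self.region_positive_fractions, float)
        if np.any((self.region_positive_fractions < 0) | (self.region_positive_fractions > 1)):
            raise ValueError("positive fractions must lie in [0, 1]")
        if self.nar_mean < 1:
            raise ValueError("NAR must be >= 1")

    def thickness_profile(self, s) -> np.ndarray:
        s = np.asarray(s, float)
        th = self.thickness_mm_annulus + s * (
            self.thickness_mm_free_edge - self.thickness_mm_annulus
        )
        if np.any(th <= 0):
            raise ValueError("thickness profile must stay positive")
        return th

    def scaled(self, thickness=1.0, area=1.0, kappa_d1=1.0) -> "GroundTruth":
        """Copy with multiplicative effect factors applied (cohort plumbing)."""
        base_mu, base_kappa = self.vm_mu_deg, self.vm_kappa

        def kappa(z, _bk=base_kappa, _f=kappa_d1):
            z = np.asarray(z, float)
            return np.asarray(_bk(z), float) * np.where(z < 1 / 3, _f, 1.0)

        lin = np.sqrt(area)
        return replace(
            self,
            thickness_mm_annulus=self.thickness_mm_annulus * thickness,
            thickness_mm_free_edge=self.thickness_mm_free_edge * thickness,
            leaflet_width_cm=self.leaflet_width_cm * lin,
            leaflet_height_cm=self.leaflet_height_cm * lin,
            vm_kappa=kappa,
            vm_mu_deg=base_mu,
            region_positive_fractions=self.region_positive_fractions.copy(),
        )


def default_truth(seed: int = 0, **overrides) -> GroundTruth:
    return GroundTruth(seed=seed, **overrides)


def _rng_for(truth: GroundTruth, salt: int, rng: np.random.Generator | None):
    if rng is not None:
        return rng
    return np.random.default_rng(np.random.SeedSequence([truth.seed, salt]))


# --------------------------------------------------------------------------
# biaxial records
# --------------------------------------------------------------------------

def _reference_markers() -> np.ndarray:
    h = MARKER_GRID_MM / 2
    return np.array([[-h, -h], [h, -h], [h, h], [-h, h]])


def gen_biax_record(
    truth: GroundTruth,
    n_samples: int = 400,
    noise_sd_mm: float = 0.0,
    force_noise_sd_mN: float = 0.0,
    n_cycles: int = 2,
    path: str = "cycles",
    rng: np.random.Generator | None = None,
) -> BiaxRecord:
    """Generate a marker/force/rake time series from the prescribed truth.

    The deformation path interpolates F(t) = I + g(t) (F_target - I) with a
    triangle wave g per cycle (``path="cycles"``) or a single monotone ramp
    ending at the prescribed F (``path="ramp"``).  Marker positions are the
    affine image of the reference grid about its centroid plus isotropic
    Gaussian noise; forces follow each direction's piecewise-linear tension
    law times the deformed orthogonal rake span, offset by the 10 mN
    preload, plus Gaussian noise.  The noise-free stretch/tension path is
    stored in ``record.truth``.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    if noise_sd_mm < 0 or force_noise_sd_mN < 0:
        raise ValueError("noise levels must be nonnegative")
    Ft = truth.prescribed_F
    C_t = Ft.T @ Ft
    if np.any(np.linalg.eigvalsh(C_t) <= 0):
        raise ValueError("prescribed stretch must be positive definite")
    rng = _rng_for(truth, 1, rng)

    if path == "ramp":
        g = np.linspace(0.0, 1.0, n_samples)
    elif path == "cycles":
        per = n_samples // n_cycles
        half = per // 2
        one = np.concatenate(
            [np.linspace(0, 1, half, endpoint=False), np.linspace(1, 0, per - half)]
        )
        g = np.concatenate([one] * n_cycles)[:n_samples]
        if g.size < n_samples:
            g = np.pad(g, (0, n_samples - g.size), constant_values=0.0)
    else:
        raise ValueError("path must be 'cycles' or 'ramp'")

    eye = np.eye(2)
    ref = _reference_markers()
    cen = ref.mean(axis=0)
    markers = np.empty((n_samples, 4, 2))
    lam_c = np.empty(n_samples)
    lam_r = np.empty(n_samples)
    for i, gi in enumerate(g):
        F = eye + gi * (Ft - eye)
        markers[i] = (ref - cen) @ F.T + cen
        C = F.T @ F
        lam_c[i] = np.sqrt(C[0, 0])
        lam_r[i] = np.sqrt(C[1, 1])
    if noise_sd_mm > 0:
        markers = markers + rng.normal(0, noise_sd_mm, size=markers.shape)

    t_circ = truth.law_circ.tension(lam_c)
    t_rad = truth.law_rad.tension(lam_r)
    rake_c = lam_c * RAKE_SPAN_MM
    rake_r = lam_r * RAKE_SPAN_MM
    force_c = t_circ * rake_r + PRELOAD_MN  # mN: N/m times mm
    force_r = t_rad * rake_c + PRELOAD_MN
    if force_noise_sd_mN > 0:
        force_c = force_c + rng.normal(0, force_noise_sd_mN, n_samples)
        force_r = force_r + rng.normal(0, force_noise_sd_mN, n_samples)

    return BiaxRecord(
        reference_markers=ref,
        time_s=np.arange(n_samples) / 5.0,  # 5 Hz acquisition
        markers=markers,
        force_circ_mN=force_c,
        force_rad_mN=force_r,
        rake_dist_circ_mm=rake_c,
        rake_dist_rad_mm=rake_r,
        truth={
            "g": g,
            "lambda_circ": lam_c,
            "lambda_rad": lam_r,
            "tension_circ": t_circ,
            "tension_rad": t_rad,
            "law_circ": truth.law_circ,
            "law_rad": truth.law_rad,
        },
    )


# --------------------------------------------------------------------------
# section geometry
# --------------------------------------------------------------------------

def gen_section_geometry(
    truth: GroundTruth,
    n_points: int = 200,
    base: str = "arc",
    length_mm: float = 25.0,
    arc_radius_mm: float = 60.0,
    rigid_motion: tuple[float, np.ndarray] | None = None,
    thickness_scale: float = 1.0,
) -> SectionGeometry:
    """Contour pair: a base atrialis curve offset by the thickness profile.

    The ventricularis curve is the atrialis curve displaced along its
    normals by ``truth.thickness_profile(s)``.  ``base`` picks a straight
    line or a circular arc (radius ``arc_radius_mm``); an optional rigid
    motion (angle radians, translation mm) is applied to both curves.
    Offsets that would self-intersect (thickness exceeding the local radius
    of curvature) are rejected.
    """
    s = np.linspace(0.0, 1.0, n_points)
    th = truth.thickness_profile(s) * thickness_scale
    if np.any(th <= 0):
        raise ValueError("thickness profile must be strictly positive")
    if base == "line":
        pts = np.column_stack([s * length_mm, np.zeros(n_points)])
        normals = np.tile([0.0, -1.0], (n_points, 1))
    elif base == "arc":
        half_angle = length_mm / (2 * arc_radius_mm)
        ang = np.pi / 2 + half_angle - s * 2 * half_angle  # left to right
        center = np.array([0.0, -arc_radius_mm])
        pts = center + arc_radius_mm * np.column_stack([np.cos(ang), np.sin(ang)])
        normals = -np.column_stack([np.cos(ang), np.sin(ang)])  # inward
        if np.any(th >= arc_radius_mm):
            raise ValueError(
                "offset self-intersects: thickness exceeds the radius of curvature"
            )
    else:
        raise ValueError("base must be 'line' or 'arc'")
    ven = pts + normals * th[:, None]
    if rigid_motion is not None:
        angle, trans = rigid_motion
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        pts = pts @ R.T + np.asarray(trans, float)
        ven = ven @ R.T + np.asarray(trans, float)
    return SectionGeometry(
        atrialis_mm=pts,
        ventricularis_mm=ven,
        truth={
            "thickness_at": lambda q: truth.thickness_profile(q) * thickness_scale,
            "base": base,
            "length_mm": length_mm,
        },
    )


# --------------------------------------------------------------------------
# leaflet outlines
# --------------------------------------------------------------------------

def gen_leaflet_outline(
    truth: GroundTruth, n_points: int = 100, area_scale: float = 1.0
) -> LeafletOutline:
    """Half-ellipse leaflet outline between the two commissure points.

    Width and height come from the truth (cm, converted to mm); the area
    scales linearly with ``area_scale``.
    """
    lin = np.sqrt(area_scale)
    w = truth.leaflet_width_cm * 10.0 * lin
    h = truth.leaflet_height_cm * 10.0 * lin
    ang = np.linspace(0.0, np.pi, n_points)
    pts = np.column_stack([w / 2 * np.cos(ang), -h * np.sin(ang)])
    commissures = np.array([[w / 2, 0.0], [-w / 2, 0.0]])
    outline = LeafletOutline(polygon_mm=pts, commissures=commissures)
    return outline


# --------------------------------------------------------------------------
# stained sections (IHC)
# --------------------------------------------------------------------------

def gen_ihc_image(
    truth: GroundTruth,
    band_px: tuple[int, int] = (120, 900),
    calibration_mm: float = 0.02,
    marker: str = "synthetic",
    rng: np.random.Generator | None = None,
) -> tuple[StainedSection, SectionGeometry, np.ndarray]:
    """Rectangular-band stained section with exact planted region fractions.

    The band is ``band_px`` = (height, width) pixels at ``calibration_mm``
    per pixel; each of the 3 x 10 regions receives exactly
    ``round(fraction * n_pixels)`` positive pixels at random positions.
    Returns the raster, the matching contour pair, and the attainable
    (rounded) fraction grid actually planted.
    """
    H, W = band_px
    if H % N_DEPTH or W % N_LENGTH:
        raise ValueError("band size must be divisible by the region grid")
    rng = _rng_for(truth, 2, rng)
    positive = np.zeros((H, W), bool)
    tissue = np.ones((H, W), bool)
    attained = np.zeros((N_LENGTH, N_DEPTH))
    cw, rh = W // N_LENGTH, H // N_DEPTH
    for i in range(N_LENGTH):
        for j in range(N_DEPTH):
            n_pix = cw * rh
            want = float(truth.region_positive_fractions[i, j])
            k = int(round(want * n_pix))
            attained[i, j] = k / n_pix
            if k == 0:
                continue
            flat = rng.choice(n_pix, size=k, replace=False)
            rr = j * rh + flat // cw
            cc = i * cw + flat % cw
            positive[rr, cc] = True
    length_mm = W * calibration_mm
    thick_mm = H * calibration_mm
    xs = np.linspace(0.0, length_mm, 50)
    section = SectionGeometry(
        atrialis_mm=np.column_stack([xs, np.zeros_like(xs)]),
        ventricularis_mm=np.column_stack([xs, np.full_like(xs, thick_mm)]),
    )
    image = StainedSection(
        positive=positive,
        tissue=tissue,
        calibration_mm=calibration_mm,
        origin_mm=np.array([calibration_mm / 2, calibration_mm / 2]),
        marker=marker,
        truth={"planted": truth.region_positive_fractions.copy(), "attained": attained},
    )
    return image, section, attained


# --------------------------------------------------------------------------
# fiber orientation stacks
# --------------------------------------------------------------------------

def _sample_axial_vm(
    mu_deg: float, kappa: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample axial angles (degrees in [0, 180)) from von Mises(mu, kappa)."""
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    if kappa == 0:
        return rng.uniform(0.0, 180.0, n)
    phi = sps.vonmises.rvs(
        kappa, loc=np.radians(2 * mu_deg), size=n, random_state=rng
    )
    return np.mod(np.degrees(phi) / 2.0, 180.0)


def gen_fiber_stack(
    truth: GroundTruth,
    n_slices: int = 15,
    n_fibers_per_slice: int = 10_000,
    bin_deg: float = 1.0,
    as_images: bool = False,
    image_size: int = 256,
    fibers_drawn: int = 60,
    rng: np.random.Generator | None = None,
) -> OrientationDepthProfile | list[np.ndarray]:
    """Per-depth axial von Mises orientation samples, as histograms or images.

    Histogram mode returns an :class:`OrientationDepthProfile` whose per
    slice truth (mu(z), kappa(z)) and raw samples are kept in ``truth``.
    Image mode draws ``fibers_drawn`` straight fibers per slice at sampled
    orientations and returns the list of images.
    """
    rng = _rng_for(truth, 3, rng)
    z = np.linspace(0.0, 1.0, n_slices)
    mus = np.asarray(truth.vm_mu_deg(z), float)
    kappas = np.asarray(truth.vm_kappa(z), float)
    if np.any(kappas < 0):
        raise ValueError("kappa must be nonnegative")
    if as_images:
        images = []
        for mu, kappa in zip(mus, kappas):
            angles = _sample_axial_vm(mu, kappa, fibers_drawn, rng)
            img = np.zeros((image_size, image_size))
            for ang in angles:
                r0 = rng.integers(image_size // 8, 7 * image_size // 8)
                c0 = rng.integers(image_size // 8, 7 * image_size // 8)
                L = image_size // 4
                dr = -np.sin(np.radians(ang))  # y-up convention: row decreases
                dc = np.cos(np.radians(ang))
                r1, c1 = int(r0 + L * dr), int(c0 + L * dc)
                r2, c2 = int(r0 - L * dr), int(c0 - L * dc)
                rr, cc, val = skdraw.line_aa(r1, c1, r2, c2)
                ok = (rr >= 0) & (rr < image_size) & (cc >= 0) & (cc < image_size)
                img[rr[ok], cc[ok]] = np.maximum(img[rr[ok], cc[ok]], val[ok])
            images.append(img)
        return images

    centers = _bin_centers(bin_deg)
    hists = np.empty((n_slices, centers.size))
    samples = []
    for idx, (mu, kappa) in enumerate(zip(mus, kappas)):
        angles = _sample_axial_vm(mu, kappa, n_fibers_per_slice, rng)
        hists[idx], _ = histogram_from_angles(angles, bin_deg)
        samples.append(angles)
    return OrientationDepthProfile(
        depth_fraction=z,
        bin_centers_deg=centers,
        histograms=hists,
        truth={"mu": mus, "kappa": kappas, "samples": samples},
    )


# --------------------------------------------------------------------------
# nuclei fields
# --------------------------------------------------------------------------

def gen_nuclei_field(
    truth: GroundTruth,
    n_nuclei: int = 200,
    image_size: int = 1024,
    mean_minor_px: float = 6.0,
    rng: np.random.Generator | None = None,
    max_attempts: int = 50_000,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Non-overlapping filled-ellipse nuclei image with per-nucleus truth.

    Orientations are axial von Mises, aspect ratios and circularity targets
    normal (NAR truncated at 1).  Returns the binary image and a table of
    planted centers, axes, orientations and NARs.
    """
    rng = _rng_for(truth, 4, rng)
    img = np.zeros((image_size, image_size), dtype=np.uint8)
    rows = []
    placed = 0
    attempts = 0
    centers = np.empty((0, 2))
    radii = np.empty(0)
    while placed < n_nuclei and attempts < max_attempts:
        attempts += 1
        nar = max(1.0, rng.normal(truth.nar_mean, truth.nar_sd))
        minor = max(2.0, rng.normal(mean_minor_px, 0.5))
        major = nar * minor
        ori = _sample_axial_vm(truth.nuclei_mu_deg, truth.nuclei_kappa, 1, rng)[0]
        margin = int(np.ceil(major)) + 2
        r0 = rng.integers(margin, image_size - margin)
        c0 = rng.integers(margin, image_size - margin)
        # conservative non-overlap: bounding-circle separation with 2 px gap
        if centers.size:
            d = np.hypot(centers[:, 0] - r0, centers[:, 1] - c0)
            if np.any(d < radii + major + 2):
                continue
        # draw.ellipse with (minor, major) radii and rotation=+angle lands the
        # major axis at +angle in the y-up convention the measurements use
        rr, cc = skdraw.ellipse(
            r0, c0, minor, major, rotation=np.radians(ori), shape=img.shape
        )
        centers = np.vstack([centers, [r0, c0]])
        radii = np.append(radii, major)
        img[rr, cc] = 1
        rows.append(
            {"row": r0, "col": c0, "major_px": major, "minor_px": minor,
             "orientation_deg": ori, "nar": nar}
        )
        placed += 1
    if placed < n_nuclei:
        raise RuntimeError(f"placed only {placed}/{n_nuclei} nuclei; lower the density")
    return img, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# intensity matrices
# --------------------------------------------------------------------------

def gen_intensity_matrix(
    truth: GroundTruth,
    n_proteins: int = 100,
    n_per_group: int = 5,
    cv: float = 0.1,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> IntensityMatrix:
    """Two-group log-normal intensity matrix with planted fold changes.

    Per-protein base abundances are log-normal; each measurement multiplies
    the base by a log-normal factor with coefficient of variation ``cv``
    (cv = 0 gives exact bases).  Proteins listed in ``truth.de_log2fc`` are
    shifted by their signed log2 fold change in the disease (TIC) group.
    Missingness, when enabled, is at random per cell.
    """
    rng = _rng_for(truth, 5, rng)
    ids = [f"P{i:04d}" for i in range(n_proteins)]
    base = rng.lognormal(mean=np.log(1e6), sigma=1.0, size=n_proteins)
    sigma = np.sqrt(np.log1p(cv**2))
    cols, groups = [], {}
    data = {}
    for g, prefix in (("CTL", "CTL"), ("TIC", "TIC")):
        for k in range(n_per_group):
            name = f"{prefix}_{k + 1}"
            vals = base.copy()
            if sigma > 0:
                vals = vals * rng.lognormal(0.0, sigma, size=n_proteins)
            if g == "TIC":
                for pid, lfc in truth.de_log2fc.items():
                    idx = ids.index(pid)
                    vals[idx] = vals[idx] * 2.0**lfc
            if missing_rate > 0:
                miss = rng.random(n_proteins) < missing_rate
                vals = np.where(miss, np.nan, vals)
            data[name] = vals
            cols.append(name)
            groups[name] = g
    X = pd.DataFrame(data, index=ids)
    return IntensityMatrix(intensities=X, groups=pd.Series(groups))


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass
class Subject:
    subject_id: str
    group: str
    outline: LeafletOutline
    section: SectionGeometry
    fiber_profile: OrientationDepthProfile
    record: BiaxRecord | None = None
    truth: dict = field(default_factory=dict)


@dataclass
class Cohort:
    subjects: list[Subject]
    intensity_matrix: IntensityMatrix | None = None
    truth_ctl: GroundTruth | None = None
    truth_tic: GroundTruth | None = None

    def group(self, label: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == label]


def gen_cohort(
    truth_ctl: GroundTruth,
    truth_tic: GroundTruth,
    n_ctl: int = 10,
    n_tic: int = 10,
    between_subject_sd: float = 0.10,
    n_section_points: int = 120,
    n_fiber_slices: int = 12,
    n_fibers_per_slice: int = 1500,
    include_biax: bool = False,
    include_omics: bool = False,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> Cohort:
    """Per-subject bundles of all modality inputs with group labels.

    Each subject's generating parameters are the group truth times
    independent log-normal factors with coefficient of variation
    ``between_subject_sd`` (applied to leaflet area, thickness, and the
    fiber concentration profile), emulating between-animal variability.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([seed if seed is not None else truth_ctl.seed, 6])
        )
    sigma = np.sqrt(np.log1p(between_subject_sd**2)) if between_subject_sd > 0 else 0.0

    def factor() -> float:
        return float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0

    subjects = []
    for group, truth, n in (("CTL", truth_ctl, n_ctl), ("TIC", truth_tic, n_tic)):
        for k in range(n):
            f_area, f_thick, f_kappa = factor(), factor(), factor()
            outline = gen_leaflet_outline(truth, area_scale=f_area)
            section = gen_section_geometry(
                truth, n_points=n_section_points, thickness_scale=f_thick
            )
            base_kappa = truth.vm_kappa

            sub_truth = replace(truth, vm_kappa=lambda z, _b=base_kappa, _f=f_kappa: (
                np.asarray(_b(z), float) * _f
            ))
            profile = gen_fiber_stack(
                sub_truth,
                n_slices=n_fiber_slices,
                n_fibers_per_slice=n_fibers_per_slice,
                rng=rng,
            )
            record = (
                gen_biax_record(truth, noise_sd_mm=0.005, force_noise_sd_mN=1.0, rng=rng)
                if include_biax
                else None
            )
            subjects.append(
                Subject(
                    subject_id=f"{group}_{k + 1:02d}",
                    group=group,
                    outline=outline,
                    section=section,
                    fiber_profile=profile,
                    record=record,
                    truth={
                        "area_factor": f_area,
                        "thickness_factor": f_thick,
                        "kappa_factor": f_kappa,
                    },
                )
            )
    matrix = None
    if include_omics:
        matrix = gen_intensity_matrix(truth_tic, rng=rng)
    return Cohort(
        subjects=subjects,
        intensity_matrix=matrix,
        truth_ctl=truth_ctl,
        truth_tic=truth_tic,
    )
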