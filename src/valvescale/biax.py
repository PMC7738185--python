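"""Planar biaxial mechanics: kinematics from fiducial markers and J-curve metrics.

A specimen is tested on a biaxial device with its circumferential and radial
axes aligned to the device axes.  Four ink fiducial markers (an approximate
3 x 3 mm grid) are tracked relative to a floating stress-free reference
configuration.  This module estimates the in-plane deformation gradient F by
least squares over all affine maps, forms C = F^T F for the axial stretches,
converts forces and deformed rake-to-rake distances to membrane tension
(force per unit deformed orthogonal edge length, N/m), extracts the final
loading downstroke, and characterizes each J-shaped tension–stretch curve by
four metrics: toe stiffness, calf stiffness, transition stretch, and the
anisotropy index (circumferential over radial stretch at 20 N/m).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "BiaxRecord",
    "DeformationState",
    "TensionStretchCurve",
    "JCurveMetrics",
    "estimate_deformation",
    "membrane_tension",
    "extract_downstroke",
    "jcurve_metrics",
]

#: Membrane tension at which calf stiffness and the anisotropy index are
#: evaluated (N/m).
EVAL_TENSION = 20.0
#: Preload used to remove tissue slack; subtracted as the tension origin (mN).
PRELOAD_MN = 10.0
#: Default toe / calf fitting windows, in N/m of membrane tension.
TOE_WINDOW = (0.5, 4.0)
CALF_WINDOW = (16.0, 20.0)


@dataclass
class BiaxRecord:
    """One specimen's biaxial time series.

    ``reference_markers``: (4, 2) marker coordinates (mm) in the floating
    stress-free configuration.  ``markers``: (n, 4, 2) tracked positions per
    frame.  Forces in mN; rake-to-rake distances in mm.  Device axis 0 is
    circumferential, axis 1 radial (``axis_convention``).
    """

    reference_markers: np.ndarray
    time_s: np.ndarray
    markers: np.ndarray
    force_circ_mN: np.ndarray
    force_rad_mN: np.ndarray
    rake_dist_circ_mm: np.ndarray
    rake_dist_rad_mm: np.ndarray
    axis_convention: str = "x=circ,y=rad"
    truth: dict = field(default_factory=dict)  # generator ground truth, if synthetic

    def __post_init__(self) -> None:
        self.reference_markers = np.asarray(self.reference_markers, float)
        self.markers = np.asarray(self.markers, float)
        if self.reference_markers.shape != (4, 2):
            raise ValueError("reference_markers must be (4, 2)")
        t = np.asarray(self.time_s, float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        for name in ("rake_dist_circ_mm", "rake_dist_rad_mm"):
            d = np.asarray(getattr(self, name), float)
            if not np.all(np.isfinite(d)) or np.any(d <= 0):
                raise ValueError(f"{name} must be finite and positive")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)


@dataclass
class DeformationState:
    """Deformation gradient and derived stretches for one frame."""

    F: np.ndarray  # 2x2
    C: np.ndarray  # F^T F
    lambda_circ: float  # sqrt(C[0, 0]) along device axis 0
    lambda_rad: float  # sqrt(C[1, 1]) along device axis 1
    residual_rms_mm: float
    valid: bool  # det F > 0


@dataclass
class TensionStretchCurve:
    """Stretch vs membrane tension for one direction of the final downstroke."""

    direction: str  # "circ" | "rad"
    stretch: np.ndarray
    tension_N_per_m: np.ndarray
    segment: str = "final_downstroke"

    def __post_init__(self) -> None:
        self.stretch = np.asarray(self.stretch, float)
        self.tension_N_per_m = np.asarray(self.tension_N_per_m, float)
        if self.stretch.shape != self.tension_N_per_m.shape:
            raise ValueError("stretch and tension must be equal length")

    def stretch_at(self, tension: float) -> float:
        """Stretch at a given tension by monotone interpolation."""
        order = np.argsort(self.tension_N_per_m)
        return float(np.interp(tension, self.tension_N_per_m[order], self.stretch[order]))

    @property
    def max_tension(self) -> float:
        return float(np.max(self.tension_N_per_m))


@dataclass
class JCurveMetrics:
    toe_stiffness: float  # N/m per unit stretch
    calf_stiffness: float
    transition_stretch: float
    eval_tension: float = EVAL_TENSION
    flags: list[str] = field(default_factory=list)


def estimate_deformation(reference: np.ndarray, deformed: np.ndarray) -> DeformationState:
    """Least-squares deformation gradient from marker positions.

    Finds the affine map (2x2 linear part F plus translation) minimizing the
    squared marker misfit; with markers centered on their centroids this is
    F = (Y~^T X~) (X~^T X~)^{-1} with X~, Y~ the centered reference and
    deformed coordinates.  Stretches are the square roots of the normal
    components of C = F^T F along the device axes.
    """
    X = np.asarray(reference, float)
    Y = np.asarray(deformed, float)
    if X.shape != Y.shape or X.shape[1] != 2 or X.shape[0] < 3:
        raise ValueError("need matching (n>=3, 2) reference and deformed markers")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    G = Xc.T @ Xc
    if np.linalg.matrix_rank(G, tol=1e-10 * max(1.0, np.trace(G))) < 2:
        raise ValueError("reference markers are collinear or degenerate")
    F = (Yc.T @ Xc) @ np.linalg.inv(G)
    C = F.T @ F
    resid = Yc - Xc @ F.T
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    det = float(np.linalg.det(F))
    return DeformationState(
        F=F,
        C=C,
        lambda_circ=float(np.sqrt(C[0, 0])),
        lambda_rad=float(np.sqrt(C[1, 1])),
        residual_rms_mm=rms,
        valid=det > 0,
    )


def membrane_tension(force_mN: float, deformed_rake_orthogonal_mm: float) -> float:
    """Membrane tension in N/m: force over the deformed orthogonal edge length.

    mN / mm is numerically N/m, so no scale factor appears.
    """
    L = np.asarray(deformed_rake_orthogonal_mm, float)
    if np.any(L <= 0):
        raise ValueError("deformed rake distance must be positive")
    return np.asarray(force_mN, float) / L


def _frame_stretches(record: BiaxRecord) -> tuple[np.ndarray, np.ndarray]:
    lam_c = np.empty(record.n_frames)
    lam_r = np.empty(record.n_frames)
    for i in range(record.n_frames):
        st = estimate_deformation(record.reference_markers, record.markers[i])
        lam_c[i], lam_r[i] = st.lambda_circ, st.lambda_rad
    return lam_c, lam_r


def extract_downstroke(
    record: BiaxRecord,
    cycle: str | int = "last",
    preload_mN: float = PRELOAD_MN,
    control_axis: str = "circ",
    min_prominence_frac: float = 0.10,
    stretch_source: str = "markers",
) -> dict[str, TensionStretchCurve]:
    """Segment loading cycles and return the requested downstroke per direction.

    Cycles are segmented by prominence-filtered extrema of the force on the
    controlled axis.  The downstroke runs from a force peak to the following
    trough (or the record end).  The preload force is subtracted before
    conversion to tension so the tension origin sits at the slack-removal
    state; tensions are clipped at zero.  ``stretch_source`` selects
    marker-based stretches (default) or rake-distance stretches
    (deformed/initial rake distance).
    """
    force = {"circ": record.force_circ_mN, "rad": record.force_rad_mN}[control_axis]
    force = np.asarray(force, float)
    rng_f = float(np.ptp(force))
    if rng_f <= 0:
        raise ValueError("constant force record: no cycles detectable")
    prom = min_prominence_frac * rng_f
    peaks, _ = find_peaks(force, prominence=prom)
    troughs, _ = find_peaks(-force, prominence=prom)
    if peaks.size == 0:
        raise ValueError(
            f"no complete loading cycle detected (peaks={peaks.tolist()}, "
            f"troughs={troughs.tolist()})"
        )
    if cycle == "last" or cycle == -1:
        peak = int(peaks[-1])
    else:
        peak = int(peaks[int(cycle)])
    later_troughs = troughs[troughs > peak]
    end = int(later_troughs[0]) if later_troughs.size else record.n_frames - 1
    if end <= peak:
        raise ValueError("downstroke after final peak is empty")
    sl = slice(peak, end + 1)

    if stretch_source == "markers":
        lam_c, lam_r = _frame_stretches(record)
    elif stretch_source == "rake":
        lam_c = record.rake_dist_circ_mm / record.rake_dist_circ_mm[0]
        lam_r = record.rake_dist_rad_mm / record.rake_dist_rad_mm[0]
    else:
        raise ValueError("stretch_source must be 'markers' or 'rake'")

    curves: dict[str, TensionStretchCurve] = {}
    for direction, f_arr, orth in (
        ("circ", record.force_circ_mN, record.rake_dist_rad_mm),
        ("rad", record.force_rad_mN, record.rake_dist_circ_mm),
    ):
        f_corr = np.clip(np.asarray(f_arr, float)[sl] - preload_mN, 0.0, None)
        tension = membrane_tension(f_corr, np.asarray(orth, float)[sl])
        lam = (lam_c if direction == "circ" else lam_r)[sl]
        order = np.argsort(tension, kind="stable")
        curves[direction] = TensionStretchCurve(
            direction=direction, stretch=lam[order], tension_N_per_m=tension[order]
        )
    return curves


def _fit_line(curve: TensionStretchCurve, window: tuple[float, float]) -> tuple[float, float, int]:
    """OLS of tension on stretch over a tension window; returns (slope, intercept, n)."""
    t, s = curve.tension_N_per_m, curve.stretch
    mask = (t >= window[0]) & (t <= window[1])
    n = int(mask.sum())
    if n < 2:
        return np.nan, np.nan, n
    slope, intercept = np.polyfit(s[mask], t[mask], 1)
    return float(slope), float(intercept), n


def _bilinear_breakpoint(curve: TensionStretchCurve) -> int:
    """Index of the best two-segment (bilinear) split by total least squares SSE.

    Exhaustive search over interior split points; O(n^2) but n is a few
    hundred downstroke samples at most.
    """
    s, t = curve.stretch, curve.tension_N_per_m
    n = s.size
    if n < 6:
        return n // 2
    best_k, best_sse = n // 2, np.inf
    for k in range(2, n - 2):
        sse = 0.0
        for seg_s, seg_t in ((s[: k + 1], t[: k + 1]), (s[k:], t[k:])):
            A = np.vstack([seg_s, np.ones_like(seg_s)]).T
            _, res, rank, _ = np.linalg.lstsq(A, seg_t, rcond=None)
            sse += float(res[0]) if res.size else 0.0
        if sse < best_sse:
            best_sse, best_k = sse, k
    return best_k


def _auto_windows(
    curve: TensionStretchCurve, margin_frac: float = 0.10
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Toe/calf tension windows from a change-point fit of the curve itself.

    The curve is split at the bilinear breakpoint; the toe window spans from
    just above zero tension to a margin below the breakpoint tension, and the
    calf window from a margin above it to the curve maximum.
    """
    k = _bilinear_breakpoint(curve)
    t = curve.tension_N_per_m
    t_break = float(t[k])
    t_max = float(t[-1])
    lo_gap = margin_frac * t_break
    hi_gap = margin_frac * (t_max - t_break)
    # strictly positive toe floor excludes frames clipped to zero tension
    toe = (1e-9, max(t_break - lo_gap, t_break * 0.5))
    calf = (min(t_break + hi_gap, t_max), t_max)
    return toe, calf


def _metrics_one(
    curve: TensionStretchCurve,
    toe_window: tuple[float, float],
    calf_window: tuple[float, float],
    eval_tension: float,
) -> JCurveMetrics:
    flags: list[str] = []
    ev = eval_tension
    if curve.max_tension < eval_tension:
        ev = curve.max_tension
        flags.append("eval_tension_reduced")
        calf_window = (0.8 * ev, ev)
    toe_s, toe_b, n_toe = _fit_line(curve, toe_window)
    calf_s, calf_b, n_calf = _fit_line(curve, calf_window)
    if n_toe < 2 or n_calf < 2:
        flags.append("insufficient_window_samples")
    transition = np.nan
    if np.isfinite(toe_s) and np.isfinite(calf_s):
        if np.isclose(toe_s, calf_s, rtol=1e-6, atol=1e-12):
            flags.append("transition_undefined_parallel_lines")
        else:
            # intersection of the toe and calf lines in the (stretch, tension) plane
            s_x = (calf_b - toe_b) / (toe_s - calf_s)
            t_x = toe_s * s_x + toe_b
            # nearest data point, Euclidean after scaling both axes to unit range
            s_rng = max(float(np.ptp(curve.stretch)), 1e-12)
            t_rng = max(float(np.ptp(curve.tension_N_per_m)), 1e-12)
            d2 = ((curve.stretch - s_x) / s_rng) ** 2 + (
                (curve.tension_N_per_m - t_x) / t_rng
            ) ** 2
            transition = float(curve.stretch[int(np.argmin(d2))])
    return JCurveMetrics(
        toe_stiffness=toe_s,
        calf_stiffness=calf_s,
        transition_stretch=transition,
        eval_tension=ev,
        flags=flags,
    )


def jcurve_metrics(
    curve_circ: TensionStretchCurve,
    curve_rad: TensionStretchCurve,
    toe_window: tuple[float, float] | str = TOE_WINDOW,
    calf_window: tuple[float, float] = CALF_WINDOW,
    eval_tension: float = EVAL_TENSION,
) -> dict:
    """Per-direction J-curve metrics plus the shared anisotropy index.

    The anisotropy index is the circumferential stretch divided by the radial
    stretch at ``eval_tension`` (20 N/m by default); values below 1 read as
    circumferentially stiffer.

    Pass ``toe_window="auto"`` to derive toe and calf windows per curve from
    a bilinear change-point fit instead of the fixed tension windows.
    """
    out = {}
    for key, curve in (("circ", curve_circ), ("rad", curve_rad)):
        if toe_window == "auto":
            tw, cw = _auto_windows(curve)
        else:
            tw, cw = toe_window, calf_window
        out[key] = _metrics_one(curve, tw, cw, eval_tension)
    ev = min(out["circ"].eval_tension, out["rad"].eval_tension)
    lam_c = curve_circ.stretch_at(ev)
    lam_r = curve_rad.stretch_at(ev)
    out["anisotropy_index"] = lam_c / lam_r if lam_r > 0 else np.nan
    return out
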