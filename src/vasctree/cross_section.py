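"""Vessel cross-section measurement.

A measuring plane is oriented perpendicular to the local vessel axis; the
geometric center is the intensity-weighted centroid of the in-plane core
region, the border is traced by marching rays outward until the HU profile
drops below a threshold (with optional valley detection between abutting
vessels), and the border polygon yields min/max/average diameters and area:

    d_avg = sqrt(4 * PPP / pi)

where PPP is the triangle-fan area of the border polygon around the center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize_scalar

from .volume import TricubicSampler


@dataclass
class CrossSectionConfig:
    """HU thresholds and sampling parameters for border tracing.

    Defaults are the validated phantom set: core range [170, 1500] HU,
    neighbor-border threshold ``M_min`` 150 HU, region-growing stop
    ``O_dv`` 160 HU.
    """

    C_min: float = 170.0
    C_max: float = 1500.0
    M_min: float = 150.0
    O_dv: float = 160.0
    n_rays: int = 36
    neighbor_detection: bool = True
    smoothing_window: int = 5
    lookahead_mm: float = 2.0      # neighbor-valley search past the drop
    ray_step_mm: float = 0.1       # marching step along rays
    max_radius_mm: float = 8.0     # ray length bound
    grid_extent_mm: float = 12.0   # in-plane window for center finding
    grid_step_mm: float = 0.2      # in-plane grid for center finding

    def __post_init__(self):
        if self.C_min >= self.C_max:
            raise ValueError("C_min must be < C_max")
        if self.n_rays < 8:
            raise ValueError("n_rays must be >= 8")
        if self.smoothing_window % 2 != 1:
            raise ValueError("smoothing_window must be odd")


@dataclass
class CrossSection:
    """Measured cross-section: oriented plane, border polygon, diameters."""

    P_sc: np.ndarray
    normal: np.ndarray
    border: np.ndarray           # (n, 3)
    d_min: float
    d_max: float
    d_avg: float
    area_PPP: float
    flags: list = field(default_factory=list)


def plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane basis (e1, e2) for a unit normal."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def find_center(sampler: TricubicSampler, normal: np.ndarray,
                click: np.ndarray, cfg: CrossSectionConfig) -> np.ndarray:
    """Intensity-weighted centroid of the in-plane core component at ``click``.

    The core is the connected region of plane samples with HU in
    ``[C_min, C_max]`` containing the click point; other vessels crossing
    the plane do not contribute.
    """
    click = np.asarray(click, dtype=float)
    if not (cfg.C_min <= sampler(click) <= cfg.C_max):
        raise ValueError("initialization outside vessel core")
    e1, e2 = plane_basis(normal)
    half = cfg.grid_extent_mm / 2.0
    u = np.arange(-half, half + cfg.grid_step_mm / 2, cfg.grid_step_mm)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    pts = (click[None, :] + uu.ravel()[:, None] * e1[None, :]
           + vv.ravel()[:, None] * e2[None, :])
    vals = sampler(pts).reshape(uu.shape)
    core = (vals >= cfg.C_min) & (vals <= cfg.C_max)
    lab, _ = ndimage.label(core)
    ic = len(u) // 2
    want = lab[ic, ic]
    if want == 0:
        raise ValueError("initialization outside vessel core")
    sel = lab == want
    w = vals[sel]
    cu = float(np.sum(uu[sel] * w) / np.sum(w))
    cv = float(np.sum(vv[sel] * w) / np.sum(w))
    return click + cu * e1 + cv * e2


def trace_border(sampler: TricubicSampler, normal: np.ndarray,
                 P_sc: np.ndarray, cfg: CrossSectionConfig,
                 ) -> tuple[np.ndarray, list]:
    """March ``n_rays`` rays from the center; border at the O_dv drop.

    A vessel that merely lies close produces a saddle below ``O_dv``
    between the two lumina, so the march stops before it.  Vessels whose
    painted profiles touch keep the saddle above ``O_dv`` and the march
    would run straight through the neighbor; with ``neighbor_detection``
    on, a dip below the core range followed by a rise back above
    ``M_min`` marks that crossing and the border is pulled back to the
    inter-vessel valley (the dip minimum).
    Returns ``(border_points (n, 3), flags)``.
    """
    P_sc = np.asarray(P_sc, dtype=float)
    e1, e2 = plane_basis(normal)
    n = cfg.n_rays
    radii = np.arange(0.0, cfg.max_radius_mm + cfg.ray_step_mm / 2,
                      cfg.ray_step_mm)
    border = np.empty((n, 3))
    flags: list = []
    for k in range(n):
        ang = 2 * np.pi * k / n
        d = np.cos(ang) * e1 + np.sin(ang) * e2
        pts = P_sc[None, :] + radii[:, None] * d[None, :]
        vals = sampler(pts)
        below = np.nonzero(vals < cfg.O_dv)[0]
        if below.size == 0:
            i = len(vals) - 1
            r_cross = radii[-1]
            flags.append((k, "ray reached bounds"))
        else:
            i = int(below[0])
            if i == 0:
                border[k] = P_sc
                flags.append((k, "center below O_dv"))
                continue
            # sub-step crossing by linear interpolation of the profile
            r_cross = np.interp(cfg.O_dv, [vals[i], vals[i - 1]],
                                [radii[i], radii[i - 1]])
        if cfg.neighbor_detection:
            valley = _valley_before(vals[:i + 1], cfg)
            if valley is not None:
                r_cross = radii[valley]
                flags.append((k, "neighbor valley"))
        border[k] = P_sc + r_cross * d
    return border, flags


def _valley_before(seg: np.ndarray, cfg: CrossSectionConfig,
                   prominence: float = 25.0) -> int | None:
    """Index of the inter-vessel valley in a ray profile, if any.

    The signature of marching into an abutting vessel is a dip of at
    least ``prominence`` HU below the running maximum followed by a rise
    of the same prominence back above ``M_min``; interpolation ripple on
    sharp profiles stays well below this scale.  Returns the dip index.
    """
    run_max = seg[0]
    run_min = None
    run_idx = None
    for k in range(1, len(seg)):
        v = seg[k]
        if run_min is None:
            if v <= run_max - prominence:
                run_min, run_idx = v, k
            else:
                run_max = max(run_max, v)
        elif v < run_min:
            run_min, run_idx = v, k
        elif v >= max(cfg.M_min, run_min + prominence):
            return run_idx
    return None


def smooth_border(border: np.ndarray, P_sc: np.ndarray,
                  cfg: CrossSectionConfig) -> np.ndarray:
    """Circular moving average of border radii; ray directions preserved."""
    P_sc = np.asarray(P_sc, dtype=float)
    rel = border - P_sc
    r = np.linalg.norm(rel, axis=1)
    dirs = rel / np.where(r > 0, r, 1.0)[:, None]
    w = cfg.smoothing_window
    if len(r) < w:
        raise ValueError("fewer border points than smoothing window")
    kernel = np.ones(w) / w
    half = w // 2
    r_pad = np.concatenate([r[-half:], r, r[:half]]) if half else r
    r_s = np.convolve(r_pad, kernel, mode="valid")
    return P_sc + r_s[:, None] * dirs


def measure(border: np.ndarray, P_sc: np.ndarray,
            ) -> tuple[float, float, float, float]:
    """Diameters and area of a traced border polygon.

    Extremes are chord lengths between opposite rays (i paired with
    i + n/2); the area PPP is the fan of unsigned triangles around the
    center, and ``d_avg = sqrt(4 PPP / pi)``.
    """
    border = np.asarray(border, dtype=float)
    P_sc = np.asarray(P_sc, dtype=float)
    n = len(border)
    if n < 8:
        raise ValueError("need >= 8 border points")
    if n % 2:
        raise ValueError("need an even number of rays for opposite chords")
    chords = np.linalg.norm(border[:n // 2] - border[n // 2:], axis=1)
    rel = border - P_sc
    cross = np.cross(rel, np.roll(rel, -1, axis=0))
    area = 0.5 * float(np.sum(np.linalg.norm(cross, axis=1)))
    d_avg = float(np.sqrt(4.0 * area / np.pi))
    return float(chords.min()), float(chords.max()), d_avg, area


def measure_section(sampler: TricubicSampler, normal: np.ndarray,
                    click: np.ndarray, cfg: CrossSectionConfig | None = None,
                    ) -> CrossSection:
    """Full measurement at one site: center, border, smoothing, metrics."""
    cfg = cfg or CrossSectionConfig()
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    P_sc = find_center(sampler, normal, click, cfg)
    border, flags = trace_border(sampler, normal, P_sc, cfg)
    border = smooth_border(border, P_sc, cfg)
    d_min, d_max, d_avg, area = measure(border, P_sc)
    return CrossSection(P_sc, normal, border, d_min, d_max, d_avg, area,
                        flags)


def orient_plane(sampler: TricubicSampler, P: np.ndarray,
                 initial_direction: np.ndarray,
                 cfg: CrossSectionConfig | None = None,
                 max_tilt_deg: float = 35.0) -> np.ndarray:
    """Plane normal minimizing the cross-section area near ``P``.

    Two-stage search: starting from ``initial_direction`` (e.g. the
    tracking direction or a distance-map ridge direction), two tilt angles
    are refined alternately by bounded golden-section minimization of the
    fan area, to about 1 degree.  An oblique plane through a tube sees an
    elliptical, larger section, so the minimum is the perpendicular plane.
    """
    cfg = cfg or CrossSectionConfig()
    n0 = np.asarray(initial_direction, dtype=float)
    n0 = n0 / np.linalg.norm(n0)
    b1, b2 = plane_basis(n0)

    def make_normal(t1: float, t2: float) -> np.ndarray:
        n = n0 + np.tan(np.radians(t1)) * b1 + np.tan(np.radians(t2)) * b2
        return n / np.linalg.norm(n)

    def area_of(t1: float, t2: float) -> float:
        nrm = make_normal(t1, t2)
        try:
            P_sc = find_center(sampler, nrm, P, cfg)
            border, _ = trace_border(sampler, nrm, P_sc, cfg)
            return measure(border, P_sc)[3]
        except ValueError:
            return np.inf

    t1 = t2 = 0.0
    for _ in range(2):
        t1 = minimize_scalar(lambda t: area_of(t, t2), method="bounded",
                             bounds=(-max_tilt_deg, max_tilt_deg),
                             options={"xatol": 1.0}).x
        t2 = minimize_scalar(lambda t: area_of(t1, t), method="bounded",
                             bounds=(-max_tilt_deg, max_tilt_deg),
                             options={"xatol": 1.0}).x
    return make_normal(t1, t2)
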