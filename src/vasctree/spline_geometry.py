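"""Degree-6 Bezier-spline approximation of centerlines with C3 joints,
and Frenet curvature/torsion along the fitted curve.

Centerlines are resampled at an arc spacing proportional to the local
radius, grouped into degree-6 Bezier segments, and fitted by constrained
linear least squares: the spline interpolates the first and last point and
position plus first, second and third derivative are continuous across
every joint.  C3 continuity is what keeps the torsion function

    tau = ((r' x r'') . r''') / |r' x r''|^2,   kappa = |r' x r''| / |r'|^3

continuous at the joints; degree 6 is the lowest degree that admits C3
splines with any number of segments.  A useful side effect of the
least-squares fit is smoothing of tracking noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.linalg import lstsq, null_space

from .centerline import Centerline

KAPPA_FLOOR = 1e-6  # rad/mm below which the Frenet frame is undefined


def _bernstein(u: np.ndarray, degree: int = 6) -> np.ndarray:
    """Bernstein basis matrix, shape (len(u), degree + 1)."""
    u = np.asarray(u, dtype=float)[:, None]
    k = np.arange(degree + 1)[None, :]
    coef = np.array([comb(degree, i) for i in range(degree + 1)])[None, :]
    return coef * u ** k * (1.0 - u) ** (degree - k)


def _derivative_cps(cps: np.ndarray, order: int) -> np.ndarray:
    """Control points of the order-th derivative of a Bezier segment."""
    out = cps
    deg = len(cps) - 1
    for _ in range(order):
        out = deg * np.diff(out, axis=0)
        deg -= 1
    return out


@dataclass
class BezierSpline:
    """Piecewise degree-6 Bezier curve with C3 joints.

    ``segments[i]`` holds 7 control points; segment ``i`` spans the chord
    parameter interval ``[joints[i], joints[i+1]]``.  ``arc_map`` is built
    by Gauss-Legendre quadrature of the parametric speed and maps between
    the chord parameter and arc length in mm.
    """

    segments: np.ndarray             # (S, 7, 3)
    joints: np.ndarray               # (S + 1,) chord parameters
    residual_rms: float = 0.0
    _arc_t: np.ndarray = field(default=None, repr=False)
    _arc_s: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self._arc_t is None:
            self._build_arc_map()

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def length(self) -> float:
        return float(self._arc_s[-1])

    def _build_arc_map(self, per_segment: int = 64) -> None:
        # Gauss-Legendre speed quadrature, accumulated on a dense grid
        xg, wg = np.polynomial.legendre.leggauss(8)
        ts = [np.array([self.joints[0]])]
        ss = [np.array([0.0])]
        total = 0.0
        for i in range(self.n_segments):
            t0, t1 = self.joints[i], self.joints[i + 1]
            edges = np.linspace(t0, t1, per_segment + 1)
            d1 = _derivative_cps(self.segments[i], 1)
            seg_len = np.empty(per_segment)
            for j in range(per_segment):
                a, b = edges[j], edges[j + 1]
                um = ((0.5 * (b - a) * xg + 0.5 * (a + b)) - t0) / (t1 - t0)
                speed = np.linalg.norm(
                    _bernstein(um, 5) @ d1, axis=1) / (t1 - t0)
                seg_len[j] = 0.5 * (b - a) * np.sum(wg * speed)
            ts.append(edges[1:])
            ss.append(total + np.cumsum(seg_len))
            total += float(np.sum(seg_len))
        self._arc_t = np.concatenate(ts)
        self._arc_s = np.concatenate(ss)

    def _locate(self, s) -> tuple[np.ndarray, np.ndarray]:
        """Arc position(s) -> (segment index, local parameter u)."""
        s = np.asarray(s, dtype=float)
        if np.any(s < -1e-9) or np.any(s > self.length + 1e-9):
            raise ValueError("arc position outside the spline domain")
        t = np.interp(np.clip(s, 0, self.length), self._arc_s, self._arc_t)
        i = np.clip(np.searchsorted(self.joints, t, side="right") - 1,
                    0, self.n_segments - 1)
        u = (t - self.joints[i]) / (self.joints[i + 1] - self.joints[i])
        return np.atleast_1d(i), np.atleast_1d(np.clip(u, 0.0, 1.0))

    def _param_derivatives(self, s) -> tuple[np.ndarray, ...]:
        """r', r'', r''' w.r.t. the chord parameter at arc position(s) s."""
        i, u = self._locate(s)
        h = self.joints[i + 1] - self.joints[i]
        outs = []
        for order in (1, 2, 3):
            vals = np.empty((len(u), 3))
            for seg in np.unique(i):
                m = i == seg
                d = _derivative_cps(self.segments[seg], order)
                vals[m] = (_bernstein(u[m], 6 - order) @ d
                           / h[m][:, None] ** order)
            outs.append(vals)
        return tuple(outs)

    def evaluate(self, s, order: int = 0) -> np.ndarray:
        """Position or arc-length derivative (order <= 3) at arc position s."""
        if order < 0 or order > 3:
            raise ValueError("order must be in 0..3")
        scalar = np.isscalar(s)
        i, u = self._locate(s)
        if order == 0:
            pos = np.empty((len(u), 3))
            for seg in np.unique(i):
                m = i == seg
                pos[m] = _bernstein(u[m], 6) @ self.segments[seg]
            return pos[0] if scalar else pos
        r1, r2, r3 = self._param_derivatives(s)
        st = np.linalg.norm(r1, axis=1)
        if np.any(st <= 0):
            raise ValueError("degenerate parameterization: zero derivative")
        rs = r1 / st[:, None]
        if order == 1:
            return rs[0] if scalar else rs
        stt = np.einsum("ij,ij->i", r1, r2) / st
        rss = (r2 - rs * stt[:, None]) / st[:, None] ** 2
        if order == 2:
            return rss[0] if scalar else rss
        sttt = (np.einsum("ij,ij->i", r2, r2)
                + np.einsum("ij,ij->i", r1, r3) - stt ** 2) / st
        rsss = (r3 - 3.0 * rss * (st * stt)[:, None]
                - rs * sttt[:, None]) / st[:, None] ** 3
        return rsss[0] if scalar else rsss


def fit_spline(centerline: Centerline | np.ndarray,
               spacing_factor: float = 1.0,
               points_per_segment: int = 20,
               joint_arcs: list[float] | None = None,
               continuity: int = 3,
               min_spacing_mm: float = 0.05) -> BezierSpline:
    """Fit a C3 degree-6 Bezier spline to a centerline.

    The centerline is resampled at arc spacing ``spacing_factor`` times the
    local radius (so wide vessels get fewer control points); joints are
    placed every ``points_per_segment`` resampled points, plus at any arc
    positions in ``joint_arcs`` (e.g. division split points).  The fit is a
    linear least squares over all control points with endpoint
    interpolation and C0..C{continuity} equality constraints at joints.
    """
    if isinstance(centerline, Centerline):
        cl = centerline
    else:
        cl = Centerline.from_points(np.asarray(centerline, dtype=float))

    # radius-adaptive resampling along the polyline
    arcs = [0.0]
    while arcs[-1] < cl.length:
        step = max(spacing_factor * cl.radius_at_arc(arcs[-1]),
                   min_spacing_mm)
        arcs.append(arcs[-1] + step)
    arcs[-1] = cl.length
    # avoid a sliver at the end of the resampling
    if len(arcs) > 2 and arcs[-1] - arcs[-2] < 0.25 * (arcs[-2] - arcs[-3]):
        del arcs[-2]
    q = np.array([cl.point_at_arc(s) for s in arcs])
    n = len(q)
    if n < 8:
        warnings.warn("fewer than 8 resampled points: single-segment fit")

    # chord-length parameterization and joint placement
    chord = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(q, axis=0), axis=1))])
    joint_idx = set(range(0, n - 1, points_per_segment)) | {n - 1}
    if joint_arcs:
        for s in joint_arcs:
            joint_idx.add(int(np.argmin(np.abs(np.asarray(arcs) - s))))
    joint_idx = sorted(joint_idx)
    # drop joints that would leave a segment without data support
    cleaned = [joint_idx[0]]
    for j in joint_idx[1:]:
        if j - cleaned[-1] >= 4 or j == n - 1:
            cleaned.append(j)
    if len(cleaned) > 2 and cleaned[-1] - cleaned[-2] < 4:
        del cleaned[-2]
    joint_idx = cleaned
    sigma = chord[joint_idx]
    S = len(sigma) - 1
    h = np.diff(sigma)

    # design matrix: each data point row hits its segment's 7 columns
    seg_of = np.clip(np.searchsorted(sigma, chord, side="right") - 1, 0, S - 1)
    u = (chord - sigma[seg_of]) / h[seg_of]
    A = np.zeros((n, 7 * S))
    for i in range(S):
        m = seg_of == i
        A[np.nonzero(m)[0][:, None], 7 * i + np.arange(7)[None, :]] = \
            _bernstein(u[m], 6)

    # constraints: endpoint interpolation + C0..C{continuity} at joints
    rows = []
    r = np.zeros(7 * S)
    r[0] = 1.0
    rows.append(r)
    r = np.zeros(7 * S)
    r[7 * S - 1] = 1.0
    rows.append(r)
    diff_ops = {
        0: np.array([1.0]),
        1: np.array([-1.0, 1.0]) * 6,
        2: np.array([1.0, -2.0, 1.0]) * 30,
        3: np.array([-1.0, 3.0, -3.0, 1.0]) * 120,
    }
    # the order-k derivative at a Bezier end is the k-th forward difference
    # of the first/last k+1 control points (same ascending stencil at both
    # ends), scaled by the chord span of the segment
    for j in range(S - 1):
        for order in range(min(continuity, 3) + 1):
            op = diff_ops[order]
            r = np.zeros(7 * S)
            r[7 * j + 7 - len(op):7 * j + 7] = op / h[j] ** order
            r[7 * (j + 1):7 * (j + 1) + len(op)] -= op / h[j + 1] ** order
            rows.append(r)
    C = np.array(rows)

    N = null_space(C)
    segments = np.empty((S, 7, 3))
    resid = 0.0
    for dim in range(3):
        d = np.zeros(len(rows))
        d[0] = q[0, dim]
        d[1] = q[-1, dim]
        xp = lstsq(C, d)[0]
        z = lstsq(A @ N, q[:, dim] - A @ xp)[0]
        x = xp + N @ z
        segments[:, :, dim] = x.reshape(S, 7)
        resid += float(np.sum((A @ x - q[:, dim]) ** 2))
    rms = np.sqrt(resid / n)
    return BezierSpline(segments, sigma, residual_rms=rms)


def evaluate(spline: BezierSpline, s, order: int = 0) -> np.ndarray:
    """Position or arc-length derivative of the spline at arc position s."""
    return spline.evaluate(s, order)


def curvature_torsion(spline: BezierSpline, s,
                      kappa_floor: float = KAPPA_FLOOR,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Curvature and torsion (rad/mm) at arc position(s) ``s``.

    Where curvature falls below ``kappa_floor`` the Frenet frame is
    undefined and the torsion is reported as 0.
    """
    r1, r2, r3 = spline._param_derivatives(s)
    st = np.linalg.norm(r1, axis=1)
    if np.any(st <= 0):
        raise ValueError("degenerate parameterization: zero derivative")
    cr = np.cross(r1, r2)
    crn = np.linalg.norm(cr, axis=1)
    kappa = crn / st ** 3
    tau = np.zeros_like(kappa)
    ok = kappa >= kappa_floor
    tau[ok] = np.einsum("ij,ij->i", cr[ok], r3[ok]) / crn[ok] ** 2
    if np.isscalar(s):
        return float(kappa[0]), float(tau[0])
    return kappa, tau


@dataclass
class ArcStats:
    """Curvature/torsion statistics over an arc range (e.g. Arc P, the
    centerline arc spanning a vessel division)."""

    Kmax: float      # max curvature, rad/mm
    Kav: float       # mean curvature, rad/mm
    Tav: float       # mean absolute torsion, rad/mm
    arc_range: tuple[float, float]


def arc_stats(spline: BezierSpline, arc_range: tuple[float, float],
              step: float = 0.05) -> ArcStats:
    """Sample curvature/torsion over ``arc_range`` at ``step`` mm."""
    s0, s1 = arc_range
    if not (0 <= s0 < s1 <= spline.length + 1e-9):
        raise ValueError("empty or out-of-domain arc range")
    s = np.arange(s0, min(s1, spline.length) + step / 2, step)
    s = np.clip(s, 0, spline.length)
    kappa, tau = curvature_torsion(spline, s)
    return ArcStats(float(np.max(kappa)), float(np.mean(kappa)),
                    float(np.mean(np.abs(tau))), (float(s0), float(s1)))
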