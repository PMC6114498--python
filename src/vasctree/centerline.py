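"""Centerline tracking on the minimal-distance-from-edge map.

The tracker crawls from a start point toward an endpoint over the ridge of
the distance map: each step advances by

    delta_d = M(P) * f

(f = crawl rate, typically in [0.5, 1]) along the current direction and
then locates the local maximum of the distance map inside the
cross-section plane perpendicular to that direction.  The in-plane search
is a projected gradient ascent on the tricubic-interpolated map, clamped
to a forward cone of half-aperture ``dA`` so the curve cannot reverse or
hop between abutting vessels.  Cumulative arc length is the chordal sum

    L_i = sum_{n=1..i} |p_{n-1} p_n|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .volume import TricubicSampler, Volume


@dataclass
class TrackingConfig:
    """Crawl parameters; ``f`` outside [0.5, 1] warns (jumpy above ~2)."""

    f: float = 0.5
    dA: float = 3.0 / (2.0 * np.pi)   # forward-cone half-aperture, rad
    stop_distance: float | None = None  # default max(local radius, 0.4 mm)
    max_steps: int = 600
    min_step_mm: float = 0.2
    max_step_mm: float | None = None  # cap the radius-scaled step
    ascent_tol_mm: float = 1e-3
    turn_adaptive: bool = True        # halve the step when a turn strains

    def __post_init__(self):
        if self.f <= 0:
            raise ValueError("crawl rate f must be positive")
        if not (0.5 <= self.f <= 1.0):
            warnings.warn(
                f"crawl rate f={self.f} outside the typical [0.5, 1] range; "
                "values above 1 risk transitions between abutting vessels")
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")


@dataclass
class Centerline:
    """Ordered centerline points with local radius and arc length."""

    points: np.ndarray               # (m, 3) mm
    radius: np.ndarray               # (m,) local distance-map value, mm
    cum_length: np.ndarray           # (m,) mm, L_0 = 0
    curve_type: int = 0              # 1 = curve to aneurysm sac, 2.. branches
    topology: tuple[int, int] | None = None   # (level, branch_index)
    flags: list = field(default_factory=list)

    @classmethod
    def from_points(cls, points: np.ndarray,
                    radius: np.ndarray | None = None, **kw) -> "Centerline":
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if radius is None:
            radius = np.zeros(len(points))
        return cls(points, np.asarray(radius, dtype=float),
                   arc_length(points), **kw)

    @property
    def length(self) -> float:
        return float(self.cum_length[-1])

    def point_at_arc(self, s: float) -> np.ndarray:
        """Linear interpolation of position at arc distance ``s``."""
        s = float(np.clip(s, 0.0, self.length))
        return np.array([np.interp(s, self.cum_length, self.points[:, k])
                         for k in range(3)])

    def radius_at_arc(self, s: float) -> float:
        s = float(np.clip(s, 0.0, self.length))
        return float(np.interp(s, self.cum_length, self.radius))

    def reversed(self) -> "Centerline":
        return Centerline.from_points(self.points[::-1], self.radius[::-1],
                                      curve_type=self.curve_type,
                                      topology=self.topology,
                                      flags=list(self.flags))


class TrackingError(RuntimeError):
    """Tracking failure; ``partial`` holds the curve built so far."""

    def __init__(self, message: str, partial: Centerline | None = None):
        super().__init__(message)
        self.partial = partial


def arc_length(points: np.ndarray) -> np.ndarray:
    """Cumulative chordal arc length; single point gives [0]."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) == 1:
        return np.zeros(1)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _inplane_maximum(sampler: TricubicSampler, anchor: np.ndarray,
                     e1: np.ndarray, e2: np.ndarray, r_max: float,
                     tol: float, start_uv: np.ndarray | None = None,
                     ) -> np.ndarray:
    """Projected gradient ascent of the sampled map inside a plane disk.

    Starts at ``anchor`` offset by ``start_uv`` (used to select among
    multiple in-plane maxima, e.g. at a ridge bifurcation); displacement
    within the (e1, e2) plane is clamped to radius ``r_max`` around the
    anchor.  Converges to ~``tol`` mm.
    """
    uv = np.zeros(2) if start_uv is None else np.asarray(start_uv, float)
    step = max(0.25 * r_max, 2 * tol)
    h = 0.05

    def clamp(uv_):
        r = np.linalg.norm(uv_)
        if r > r_max:
            uv_ = uv_ * (r_max / r)
        return uv_

    def val(uv_):
        return float(sampler(anchor + uv_[0] * e1 + uv_[1] * e2))

    uv = clamp(uv)
    f0 = val(uv)
    for _ in range(80):
        p = anchor + uv[0] * e1 + uv[1] * e2
        probes = np.array([p + h * e1, p - h * e1, p + h * e2, p - h * e2])
        v = sampler(probes)
        g = np.array([v[0] - v[1], v[2] - v[3]]) / (2 * h)
        gn = np.linalg.norm(g)
        if gn < 1e-9:
            break
        cand = clamp(uv + step * g / gn)
        f1 = val(cand)
        if f1 > f0 + 1e-12:
            uv, f0 = cand, f1
        else:
            step *= 0.5
            if step < tol:
                break
    return anchor + uv[0] * e1 + uv[1] * e2


def _plane_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(direction[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    return e1, e2


def crawl_step(dmap: TricubicSampler | Volume, P: np.ndarray,
               direction: np.ndarray, cfg: TrackingConfig | None = None,
               target: np.ndarray | None = None,
               ) -> tuple[np.ndarray, np.ndarray]:
    """One crawl step: advance by ``M(P) * f`` and re-center on the ridge.

    Returns ``(next_point, next_direction)``.  The in-plane maximum is
    sought within a cone of half-aperture ``dA`` around ``direction``.
    When ``target`` is given, the ascent is seeded slightly toward it
    inside the plane; on a straight ridge the unique maximum is found
    regardless, but where the ridge bifurcates this selects the basin
    leading toward the indicated endpoint.  Raises :class:`TrackingError`
    if the map vanishes at the new point (the crawl left the vessel).
    """
    cfg = cfg or TrackingConfig()
    sampler = dmap if isinstance(dmap, TricubicSampler) else TricubicSampler(dmap)
    P = np.asarray(P, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    m = float(sampler(P))
    if m <= 0:
        raise TrackingError("current point outside the vessel")
    e1, e2 = _plane_basis(d)
    delta = max(m * cfg.f, cfg.min_step_mm)
    if cfg.max_step_mm is not None:
        delta = min(delta, cfg.max_step_mm)
    # adaptive step: a sharp turn (e.g. a steep branch take-off) strains
    # against the forward cone — the selected basin rides the disk edge
    # or the step leaves the vessel.  Halving the step doubles the turn
    # rate per mm of path, so tight corners are taken at finer arc scale.
    for attempt in range(5):
        anchor = P + delta * d
        r_max = delta * np.tan(cfg.dA)
        start_uv, ridge_uv = _select_basin(sampler, P, anchor, e1, e2, r_max,
                                           target)
        if (cfg.turn_adaptive and ridge_uv is not None
                and np.linalg.norm(ridge_uv) > 0.8 * r_max
                and delta > 0.3 and attempt < 4):
            delta /= 2.0
            continue
        if start_uv is not None:
            nxt = _inplane_maximum(sampler, anchor, e1, e2, r_max,
                                   cfg.ascent_tol_mm, start_uv)
            if float(sampler(nxt)) > 0:
                nd = nxt - P
                return nxt, nd / np.linalg.norm(nd)
        delta = max(delta / 2.0, cfg.min_step_mm / 2.0)
    raise TrackingError("left vessel: no in-plane maximum above zero")


def _select_basin(sampler: TricubicSampler, P: np.ndarray, anchor: np.ndarray,
                  e1: np.ndarray, e2: np.ndarray, r_max: float,
                  target: np.ndarray | None, rings: int = 4,
                  spokes: int = 12,
                  ) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Choose the ascent start inside the in-plane disk.

    The disk is sampled on a polar grid; samples outside the vessel or
    on thin wedge slivers are discarded.  Without a target the best
    sample wins; with a target (endpoint-steered tracking) the candidate
    whose direction from ``P`` best aligns with the target is chosen,
    which selects the correct ridge basin where a vessel divides.
    Returns the chosen start offset and the offset of the best-valued
    sample (the ridge position, used by the caller to detect a turn
    straining against the cone); both are ``None`` when the whole disk
    lies outside the vessel.
    """
    rr = np.linspace(0, r_max, rings + 1)[1:]
    th = np.linspace(0, 2 * np.pi, spokes, endpoint=False)
    uv = np.vstack([[0.0, 0.0],
                    np.stack([np.outer(rr, np.cos(th)).ravel(),
                              np.outer(rr, np.sin(th)).ravel()], axis=1)])
    pts = anchor[None, :] + uv[:, 0:1] * e1[None, :] + uv[:, 1:2] * e2[None, :]
    vals = sampler(pts)
    vmax = float(np.max(vals))
    if vmax <= 0:
        return None, None
    ridge_uv = uv[int(np.argmax(vals))]
    if target is None:
        return ridge_uv, ridge_uv
    good = vals >= min(0.3 * vmax, 0.25)
    if not np.any(good):
        good = vals > 0
    to_t = np.asarray(target, dtype=float) - P
    to_t /= np.linalg.norm(to_t)
    steps = pts - P[None, :]
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    score = steps @ to_t
    score[~good] = -np.inf
    return uv[int(np.argmax(score))], ridge_uv


def seed_direction(dmap: Volume, start: np.ndarray, end: np.ndarray,
                   sampler: TricubicSampler | None = None) -> np.ndarray:
    """Initial direction: local mask principal axis, signed toward the end."""
    sampler = sampler or TricubicSampler(dmap)
    r = max(float(sampler(start)), float(np.max(dmap.spacing)))
    lo = np.asarray(start) - 3 * r
    hi = np.asarray(start) + 3 * r
    i0 = np.maximum(np.floor((lo - dmap.origin) / dmap.spacing), 0).astype(int)
    i1 = np.minimum(np.ceil((hi - dmap.origin) / dmap.spacing),
                    np.array(dmap.shape) - 1).astype(int)
    sub = dmap.data[i0[0]:i1[0] + 1, i0[1]:i1[1] + 1, i0[2]:i1[2] + 1]
    idx = np.argwhere(sub > 0)
    fallback = np.asarray(end, dtype=float) - np.asarray(start, dtype=float)
    if len(idx) < 4:
        return fallback / np.linalg.norm(fallback)
    pts = (idx + i0) * dmap.spacing + dmap.origin
    cov = np.cov((pts - pts.mean(axis=0)).T)
    w, v = np.linalg.eigh(cov)
    axis = v[:, -1]
    if np.dot(axis, fallback) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def track_centerline(dmap: Volume, start: np.ndarray, end: np.ndarray,
                     cfg: TrackingConfig | None = None,
                     sampler: TricubicSampler | None = None) -> Centerline:
    """Track a single centerline between two user-indicated points.

    The start point is first re-centered on the ridge (in-plane maximum
    perpendicular to the seed direction); crawling stops within
    ``stop_distance`` of the end (default: the local radius, at least
    0.4 mm).  Exceeding ``max_steps`` raises :class:`TrackingError` with
    the partial curve attached.
    """
    cfg = cfg or TrackingConfig()
    sampler = sampler or TricubicSampler(dmap)
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if float(sampler(start)) <= 0 or float(sampler(end)) <= 0:
        raise TrackingError("start/end point outside the segmented vessel")
    if np.allclose(start, end):
        r = float(sampler(start))
        return Centerline.from_points(start[None, :], np.array([r]))

    d = seed_direction(dmap, start, end, sampler)
    e1, e2 = _plane_basis(d)
    P = _inplane_maximum(sampler, start, e1, e2,
                         2.0 * float(np.max(dmap.spacing)), cfg.ascent_tol_mm)
    pts = [P]
    radii = [float(sampler(P))]
    best_dist = np.linalg.norm(P - end)
    for _ in range(cfg.max_steps):
        try:
            P, d = crawl_step(sampler, P, d, cfg, target=end)
        except TrackingError as exc:
            exc.partial = Centerline.from_points(np.array(pts),
                                                 np.array(radii))
            raise
        pts.append(P)
        radii.append(float(sampler(P)))
        stop = cfg.stop_distance
        if stop is None:
            stop = max(radii[-1], 0.4)
        dist = np.linalg.norm(P - end)
        if dist < stop:
            return Centerline.from_points(np.array(pts), np.array(radii))
        best_dist = min(best_dist, dist)
        if dist > best_dist + 8.0:
            raise TrackingError(
                "tracking diverged away from the endpoint",
                Centerline.from_points(np.array(pts), np.array(radii)))
    partial = Centerline.from_points(np.array(pts), np.array(radii))
    raise TrackingError("tracking failed: max_steps reached before the end",
                        partial)


def _deloop(pts: np.ndarray) -> np.ndarray:
    """Drop points that fold the polyline back on itself.

    A crawl negotiating a tight junction can overshoot and double back,
    leaving a small knot; such points reverse the local direction
    (negative dot product of adjacent chords) and are removed until the
    polyline is fold-free.
    """
    pts = np.asarray(pts, dtype=float)
    changed = True
    while changed and len(pts) > 2:
        changed = False
        keep = np.ones(len(pts), dtype=bool)
        v = np.diff(pts, axis=0)
        dots = np.einsum("ij,ij->i", v[:-1], v[1:])
        bad = np.nonzero(dots < 0)[0]
        if bad.size:
            keep[bad[0] + 1] = False
            pts = pts[keep]
            changed = True
    return pts


def refine_centerline(dmap: TricubicSampler | Volume, curve: Centerline,
                      iterations: int = 2, tol: float = 1e-3) -> Centerline:
    """Re-center tracked points on the distance-map ridge.

    Fold-backs left by tight turns are removed first; each interior
    point is then moved to the local in-plane maximum of the distance
    map in the plane perpendicular to the local chord tangent, with no
    forward-cone clamp.  This enforces the tracker's ridge invariant
    exactly and removes the turn lag the clamped crawl leaves behind at
    sharp bends (e.g. branch take-offs).
    """
    sampler = dmap if isinstance(dmap, TricubicSampler) else TricubicSampler(dmap)
    pts = _deloop(curve.points)
    for _ in range(iterations):
        for i in range(1, len(pts) - 1):
            t = pts[i + 1] - pts[i - 1]
            nt = np.linalg.norm(t)
            if nt < 1e-9:
                continue
            e1, e2 = _plane_basis(t / nt)
            r_max = max(float(sampler(pts[i])), 0.5)
            pts[i] = _inplane_maximum(sampler, pts[i], e1, e2, r_max, tol)
    radii = np.asarray(sampler(pts), dtype=float)
    return Centerline.from_points(pts, radii, curve_type=curve.curve_type,
                                  topology=curve.topology,
                                  flags=list(curve.flags))


def assign_topology(tree: dict) -> dict:
    """Label a centerline tree with (level, branch index).

    ``tree`` maps an id to ``(centerline, parent_id or None, area_mm2)``.
    Levels rise distally from 0 at the roots; siblings are numbered 1, 2,
    ... by declining cross-section area, ties broken by lexicographic first
    point.  A cycle in the parent links raises ``ValueError``.
    """
    levels: dict = {}

    def level_of(k, seen=()):
        if k in seen:
            raise ValueError("cycle in centerline tree")
        if k not in levels:
            parent = tree[k][1]
            levels[k] = 0 if parent is None else level_of(parent,
                                                          seen + (k,)) + 1
        return levels[k]

    for k in tree:
        level_of(k)
    siblings: dict = {}
    for k, (cl, parent, area) in tree.items():
        siblings.setdefault(parent, []).append(k)
    for group in siblings.values():
        group.sort(key=lambda k: (-tree[k][2],
                                  tuple(np.round(tree[k][0].points[0], 6))))
        for i, k in enumerate(group, start=1):
            tree[k][0].topology = (levels[k], i)
    return tree
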