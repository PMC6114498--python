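"""Bifurcation (division) zone construction and morphometry.

From two centerlines that share a stem and diverge, the split point T0 is
the midpoint of the last points of each curve still within distance ``d``
(default 0.2 mm — the auxiliary voxel size) of the other curve.  Around T0
the zone collects trunk points Tr_0..Tr_n (numbered against the flow) and
branch points Br_0..Br_n (with the flow) at arc spacing proportional to
the local radius.  The division plane passes through the three 0-points;
vessel directional vectors (VDV) are Br_0->Br_1 for a branch and
Tr_1->Tr_0 (downstream) for the trunk, giving

    BA  = angle(VDV_1, VDV_2)          branching angle
    VA_i = angle(VDV_T, VDV_i)         vessel angles
    CoI_N = 1 - angle(VDV_N, DPN) / (pi/2)   coplanarity index

with the angle against the plane normal folded to [0, pi/2].  A vessel
parallel to the normal (perpendicular to the plane) thus scores 1 and a
vessel lying in the division plane scores 0; the opposite convention is
available via ``convention="in_plane"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .centerline import Centerline


@dataclass
class ZoneConfig:
    d: float = 0.2                      # split-distance threshold, mm
    point_spacing_factor: float = 3.0   # Tr/Br spacing in local radii
    n_points: int = 4                   # points per vessel (>= 2)
    # trim the shared stem past a direction change above this angle: the
    # threshold sits below the smallest anatomical branch take-off (15
    # degrees) and well above per-step trunk direction noise (a few degrees)
    stem_kink_deg: float | None = 12.0

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("d must be positive")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")


@dataclass
class BifurcationZone:
    T0: np.ndarray
    Tr: np.ndarray                      # (n, 3), Tr[0] = T0
    Br1: np.ndarray                     # (n, 3)
    Br2: np.ndarray
    Tr_radius: np.ndarray
    Br1_radius: np.ndarray
    Br2_radius: np.ndarray
    curve_types: tuple[int, int] = (0, 0)
    flags: list = field(default_factory=list)
    # filled by analyze_zone:
    DP_point: np.ndarray | None = None
    DPN: np.ndarray | None = None
    BA: float | None = None
    VA: np.ndarray | None = None        # (2,)
    CoI_T: float | None = None
    CoI: np.ndarray | None = None       # (2,)
    dominant: int | None = None

    @property
    def VDV_T(self) -> np.ndarray:
        v = self.Tr[0] - self.Tr[1]     # Tr1 -> Tr0, downstream
        return v / np.linalg.norm(v)

    def VDV_branch(self, i: int) -> np.ndarray:
        br = self.Br1 if i == 0 else self.Br2
        v = br[1] - br[0]
        return v / np.linalg.norm(v)


def _point_to_polyline(p: np.ndarray, poly: np.ndarray) -> float:
    """Exact distance from a point to a polyline (segment projections)."""
    if len(poly) == 1:
        return float(np.linalg.norm(p - poly[0]))
    a, b = poly[:-1], poly[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.where(denom > 0, denom, 1),
                0, 1)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(p - proj, axis=1)))


def find_split_point(curve_a: Centerline, curve_b: Centerline,
                     cfg: ZoneConfig | None = None,
                     ) -> tuple[np.ndarray, int, int]:
    """Split point of two diverging centerlines.

    For each curve, the last point (in flow order) closer than ``d`` to the
    other curve is found; T0 is the midpoint of the two.  Curves that never
    approach raise "no division"; identical curves raise "degenerate
    division".

    Near the division the tracked curves can share one or two final
    vertices that already turned into a branch root (the ridge of the
    merged lumen bulges toward the wider branch); a trunk never turns by
    tens of degrees in a single step, so the shared stem is trimmed back
    past the first vertex whose direction change exceeds
    ``stem_kink_deg``, which keeps the split point on the vessel axis.
    """
    cfg = cfg or ZoneConfig()
    if (curve_a.points.shape == curve_b.points.shape
            and np.allclose(curve_a.points, curve_b.points)):
        raise ValueError("degenerate division: curves are identical")

    def stem_end(src: Centerline, other: Centerline) -> int:
        # last point of the contiguous within-d stem (the first within-d
        # run; a leading overhang past the other curve's end is skipped).
        # Tracked curves can brush past each other again inside the
        # junction blob, which a plain "last point within d" would
        # mistake for shared stem.
        idx = -1
        started = False
        for i, p in enumerate(src.points):
            if _point_to_polyline(p, other.points) < cfg.d:
                idx = i
                started = True
            elif started:
                break
        return idx

    def first_kink(points: np.ndarray, last: int) -> int:
        if cfg.stem_kink_deg is None:
            return last
        limit = np.cos(np.radians(cfg.stem_kink_deg))
        for i in range(2, last + 1):
            u = points[i - 1] - points[i - 2]
            v = points[i] - points[i - 1]
            denom = np.linalg.norm(u) * np.linalg.norm(v)
            if denom > 0 and float(np.dot(u, v)) / denom < limit:
                return i - 1
        return last

    ia = stem_end(curve_a, curve_b)
    ib = stem_end(curve_b, curve_a)
    if ia < 0 or ib < 0:
        raise ValueError("no division: curves never within d of each other")
    ia = min(ia, first_kink(curve_a.points, ia))
    ib = min(ib, first_kink(curve_b.points, ib))
    T0 = 0.5 * (curve_a.points[ia] + curve_b.points[ib])
    return T0, ia, ib


def _walk(curve: Centerline, s0: float, factor: float, n: int,
          forward: bool) -> tuple[np.ndarray, np.ndarray, bool]:
    """Place n points along a centerline at radius-scaled arc spacing."""
    pts, radii = [], []
    s = s0
    truncated = False
    for k in range(n):
        if s < 0 or s > curve.length:
            truncated = True
            break
        pts.append(curve.point_at_arc(s))
        radii.append(max(curve.radius_at_arc(s), 1e-6))
        step = factor * radii[-1]
        s = s + step if forward else s - step
    return np.array(pts), np.array(radii), truncated


def build_zone(trunk_side: Centerline, branch1: Centerline,
               branch2: Centerline, cfg: ZoneConfig | None = None,
               T0: np.ndarray | None = None,
               curve_types: tuple[int, int] = (0, 0)) -> BifurcationZone:
    """Assemble the Tr/Br point sets of a division zone.

    ``trunk_side`` runs with the flow and ends at the split point;
    ``branch1``/``branch2`` start at the split and run with the flow.
    Tr_0 is the split point; Br_0 of each branch is its first point at
    least ``d`` away from the other branch; subsequent points follow the
    respective centerline at ``point_spacing_factor`` local radii.
    """
    cfg = cfg or ZoneConfig()
    if T0 is None:
        T0 = trunk_side.points[-1]
    flags: list = []

    def first_clear(branch: Centerline, other: Centerline) -> float:
        for i, p in enumerate(branch.points):
            if _point_to_polyline(p, other.points) >= cfg.d:
                return float(branch.cum_length[i])
        flags.append("branches never separate by d; Br_0 at branch end")
        return branch.length

    tr, tr_r, trunc = _walk(trunk_side, trunk_side.length, cfg.point_spacing_factor,
                            cfg.n_points, forward=False)
    tr[0] = T0
    if trunc:
        flags.append("trunk too short for n_points")
    br = []
    br_r = []
    for branch, other in ((branch1, branch2), (branch2, branch1)):
        s0 = first_clear(branch, other)
        p, r, trunc = _walk(branch, s0, cfg.point_spacing_factor,
                            cfg.n_points, forward=True)
        if trunc:
            flags.append("branch too short for n_points")
        br.append(p)
        br_r.append(r)
    for arr, name in ((tr, "trunk"), (br[0], "branch1"), (br[1], "branch2")):
        if len(arr) < 2:
            raise ValueError(f"{name} centerline too short for a VDV")
    return BifurcationZone(np.asarray(T0, dtype=float), tr, br[0], br[1],
                           tr_r, br_r[0], br_r[1], curve_types, flags)


def zone_from_curves(curve_a: Centerline, curve_b: Centerline,
                     cfg: ZoneConfig | None = None,
                     curve_types: tuple[int, int] = (0, 0)) -> BifurcationZone:
    """Build a zone from two tracked trunk-to-branch centerlines.

    The curves share the trunk stem and diverge into the branches; they are
    cut at the split point into the three vessel sides ``build_zone``
    expects.
    """
    cfg = cfg or ZoneConfig()
    T0, ia, ib = find_split_point(curve_a, curve_b, cfg)
    if ia + 2 >= len(curve_a.points) or ib + 2 >= len(curve_b.points):
        raise ValueError("branch centerline too short past the split point")
    trunk = Centerline.from_points(
        np.vstack([curve_a.points[:ia + 1], T0[None, :]]),
        np.append(curve_a.radius[:ia + 1], curve_a.radius[ia]))
    b1 = Centerline.from_points(curve_a.points[ia + 1:],
                                curve_a.radius[ia + 1:])
    b2 = Centerline.from_points(curve_b.points[ib + 1:],
                                curve_b.radius[ib + 1:])
    return build_zone(trunk, b1, b2, cfg, T0=T0, curve_types=curve_types)


def division_plane(zone: BifurcationZone) -> tuple[np.ndarray, np.ndarray]:
    """Plane through Tr_0, Br1_0, Br2_0; normal signed along trunk flow."""
    u = zone.Br1[0] - zone.Tr[0]
    v = zone.Br2[0] - zone.Tr[0]
    n = np.cross(u, v)
    nn = np.linalg.norm(n)
    if nn < 1e-9 * max(np.linalg.norm(u), np.linalg.norm(v)):
        raise ValueError("degenerate plane: zone 0-points are collinear")
    n = n / nn
    if np.dot(n, zone.VDV_T) < 0:
        n = -n
    return zone.Tr[0], n


def coplanarity_index(VDV: np.ndarray, DPN: np.ndarray,
                      convention: str = "literal") -> float:
    """CoI = 1 - angle(VDV, DPN) / (pi/2), angle folded acute.

    ``convention="in_plane"`` returns the complementary index (1 for a
    vessel lying in the division plane).
    """
    v = np.asarray(VDV, dtype=float)
    n = np.asarray(DPN, dtype=float)
    nv, nn = np.linalg.norm(v), np.linalg.norm(n)
    if nv == 0 or nn == 0:
        raise ValueError("zero vector has no coplanarity index")
    ang = np.arccos(np.clip(abs(np.dot(v, n)) / (nv * nn), -1.0, 1.0))
    coi = 1.0 - ang / (np.pi / 2.0)
    if convention == "in_plane":
        return 1.0 - coi
    return float(coi)


def angles(zone: BifurcationZone) -> tuple[float, float, float]:
    """(BA, VA_1, VA_2) in degrees from the zone's directional vectors."""
    d1 = zone.VDV_branch(0)
    d2 = zone.VDV_branch(1)
    dt = zone.VDV_T

    def ang(u, v):
        return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))

    return ang(d1, d2), ang(dt, d1), ang(dt, d2)


def analyze_zone(zone: BifurcationZone,
                 convention: str = "literal") -> BifurcationZone:
    """Fill plane, angles, coplanarity indices and dominance in place."""
    zone.DP_point, zone.DPN = division_plane(zone)
    ba, va1, va2 = angles(zone)
    zone.BA = ba
    zone.VA = np.array([va1, va2])
    zone.CoI_T = coplanarity_index(zone.VDV_T, zone.DPN, convention)
    zone.CoI = np.array([
        coplanarity_index(zone.VDV_branch(0), zone.DPN, convention),
        coplanarity_index(zone.VDV_branch(1), zone.DPN, convention)])
    zone.dominant = 0 if zone.Br1_radius.mean() >= zone.Br2_radius.mean() else 1
    return zone


def select_true_division(zones: list[BifurcationZone],
                         trunk_origin: np.ndarray,
                         curve_types: list[tuple[int, int]] | None = None,
                         ) -> tuple[BifurcationZone, BifurcationZone | None]:
    """Separate the actual vessel division from an aneurysm departure.

    A zone involving a type-1 curve (curve to the aneurysm sac) is an
    aneurysm-departure candidate; the candidate whose split point lies
    furthest from the trunk origin is the departure of the dome from the
    parent vessel.  The returned division is the furthest zone not
    involving the aneurysm curve.
    """
    if not zones:
        raise ValueError("no zones")
    origin = np.asarray(trunk_origin, dtype=float)
    if curve_types is None:
        curve_types = [z.curve_types for z in zones]

    def dist(z):
        return float(np.linalg.norm(z.T0 - origin))

    with_an = [z for z, ct in zip(zones, curve_types) if 1 in ct]
    without = [z for z, ct in zip(zones, curve_types) if 1 not in ct]
    if not without:
        raise ValueError("no non-aneurysm division among the zones")
    aneurysm = max(with_an, key=dist) if with_an else None
    return max(without, key=dist), aneurysm
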