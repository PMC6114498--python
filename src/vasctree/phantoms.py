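"""Synthetic vascular phantoms with analytic ground truth.

Volumes emulate contrast-enhanced CT: a vessel of radius ``R`` has the
sigmoid cross-profile

    HU(r) = C + C * (1/2 - 1/(1 + exp(-a (r - R))))

so the value is exactly ``C`` at the wall (r = R), approaches ``1.5 C`` on
the axis and ``C/2`` far away.  Tubes are painted by sweeping a cubic brush
along an analytic centerline and max-composing the profile into the volume,
which makes painting idempotent and order-independent.

Three families are provided: torus (planar circle sweep), helix (circular
helix sweep) and an artificial bifurcation zone (ABZ) — a straight trunk
splitting into two straight branches with optional out-of-plane tilts and an
optional spherical aneurysm at the apex.  Every generator returns the volume
together with the analytic geometry it was built from, which downstream
validation experiments use as ground truth.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import expit

from .volume import Volume

DEFAULT_C = 150.0     # HU at the vessel boundary, all synthetic models
DEFAULT_A = 10.0      # sigmoid slope coefficient, all synthetic models
DEFAULT_SIZE = 100.0  # mm, cubic synthetic volume
DEFAULT_SPACING = 0.6  # mm, isotropic

#: Anatomically motivated parameter ranges for artificial bifurcation zones.
ABZ_RANGES: dict[str, tuple[float, float]] = {
    "A1": (15.0, 80.0),
    "A2": (15.0, 80.0),
    "A1_pl": (-15.0, 15.0),
    "A2_pl": (-15.0, 15.0),
    "wAn": (0.0, 0.15),
    "D_T": (3.5, 4.5),
    "D_1": (2.5, 4.2),
    "D_2": (2.0, 3.0),
    "D_an": (2.0, 6.0),
}


def hu_profile(r, C: float = DEFAULT_C, R: float = 1.0, a: float = DEFAULT_A):
    """Sigmoid HU value at distance ``r`` (mm) from the vessel axis.

    Continuous, monotonically non-increasing in ``r``; equals ``C`` at
    ``r = R``, tends to ``1.5 C`` for ``r -> 0`` (when ``a R >> 1``) and to
    ``C / 2`` for ``r -> inf``.
    """
    if R <= 0 or a <= 0:
        raise ValueError("R and a must be positive")
    if C <= 0:
        raise ValueError("C must be positive")
    r = np.asarray(r, dtype=float)
    out = C + C * (0.5 - expit(a * (r - R)))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PhantomSpec:
    """Shape parameters of a swept-tube phantom (torus or helix)."""

    kind: str                 # "torus" | "helix"
    D: float                  # vessel diameter, mm
    R1: float                 # basal radius of the sweep, mm
    R2: float | None = None   # helix only: axial rise per turn, mm
    C: float = DEFAULT_C
    a: float = DEFAULT_A

    def __post_init__(self):
        if self.kind not in ("torus", "helix"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.D <= 0 or self.C <= 0 or self.a <= 0:
            raise ValueError("D, C, a must be positive")
        if self.R1 < 2 * self.D:
            raise ValueError("R1 < 2D: sweep would overlap itself")
        if self.kind == "helix":
            if self.R2 is None:
                raise ValueError("helix requires R2")
            if self.R2 < 2 * self.D:
                raise ValueError("R2 < 2D: helix turns would overlap")


@dataclass(frozen=True)
class ABZParams:
    """Construction parameters of an artificial bifurcation zone.

    Angles are in degrees: ``A1``/``A2`` from the trunk axis inside the
    nominal division plane, ``A1_pl``/``A2_pl`` out-of-plane tilts.
    ``D_*`` are diameters in mm; ``wAn`` is a stored aneurysm weight with no
    geometric effect in this implementation.
    """

    A1: float
    A2: float
    A1_pl: float = 0.0
    A2_pl: float = 0.0
    wAn: float = 0.0
    D_T: float = 4.0
    D_1: float = 3.5
    D_2: float = 2.5
    D_an: float = 4.0

    def __post_init__(self):
        for name, (lo, hi) in ABZ_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                warnings.warn(
                    f"ABZ parameter {name}={v} outside anatomical range "
                    f"[{lo}, {hi}]", stacklevel=2)


@dataclass
class CurveGroundTruth:
    """Analytic centerline of a swept phantom, arc-length parameterized."""

    kind: str
    curve: Callable[[np.ndarray], np.ndarray]   # s (mm) -> points (n, 3)
    length: float                               # domain is [0, length]
    radius: float                               # tube radius D/2, mm
    curvature: float
    torsion: float
    center: np.ndarray
    params: dict = field(default_factory=dict)
    _tree: cKDTree | None = field(default=None, repr=False)

    def sample(self, step: float = 0.1) -> np.ndarray:
        s = np.arange(0.0, self.length + step / 2, step)
        return self.curve(s)

    def distance_to(self, points: np.ndarray) -> np.ndarray:
        """Distance (mm) from each query point to the analytic curve."""
        pts = np.atleast_2d(points)
        if self.kind == "torus":
            rel = pts - self.center
            rho = np.hypot(rel[:, 0], rel[:, 1])
            return np.hypot(rho - self.params["R1"], rel[:, 2])
        if self._tree is None:
            # 0.02 mm chords: sampling error < 1e-5 mm for any curvature here
            self._tree = cKDTree(self.sample(0.02))
        d, _ = self._tree.query(pts, workers=-1)
        return d


@dataclass
class ABZGroundTruth:
    """Analytic geometry and reference angles of a bifurcation phantom."""

    apex: np.ndarray
    trunk_dir: np.ndarray              # unit, downstream (toward apex)
    branch_dirs: np.ndarray            # (2, 3) unit vectors, from the apex
    trunk_length: float
    branch_length: float
    diameters: dict
    ba: float                          # degrees, between the branch vectors
    va: np.ndarray                     # (2,) degrees, trunk vs each branch
    dpn: np.ndarray                    # unit normal of the division plane
    coi_trunk: float
    coi_branches: np.ndarray           # (2,), identically 0 by construction
    dominant: int                      # 0-based index of larger-D branch
    aneurysm_center: np.ndarray | None = None

    @property
    def trunk_start(self) -> np.ndarray:
        return self.apex - self.trunk_dir * self.trunk_length

    def branch_end(self, i: int) -> np.ndarray:
        return self.apex + self.branch_dirs[i] * self.branch_length


# --------------------------------------------------------------------------
# painting

def blank_volume(size: float = DEFAULT_SIZE, spacing: float = DEFAULT_SPACING,
                 C: float = DEFAULT_C) -> Volume:
    """Empty synthetic volume, background at the far-field value C/2."""
    n = int(round(size / spacing))
    data = np.full((n, n, n), C / 2.0, dtype=np.float32)
    return Volume(data, np.full(3, spacing), np.zeros(3))


def paint_brush(volume: Volume, center: Sequence[float], R: float,
                C: float = DEFAULT_C, a: float = DEFAULT_A) -> Volume:
    """Max-compose one sigmoid brush stroke into the volume, in place.

    The brush acts inside an axis-aligned cube of half-width ``1.5 R``
    centered on ``center``; each covered voxel receives
    ``max(current, hu_profile(|voxel - center|))``.  Re-applying the brush at
    the same center is a no-op.
    """
    lo, hi = volume.extent
    c = np.asarray(center, dtype=float)
    if np.any(c < lo) or np.any(c > hi):
        warnings.warn(f"brush center {c} outside volume extent; skipped")
        return volume
    half = 1.5 * R
    i0 = np.maximum(np.ceil((c - half - volume.origin) / volume.spacing), 0)
    i1 = np.minimum(np.floor((c + half - volume.origin) / volume.spacing),
                    np.array(volume.shape) - 1)
    i0 = i0.astype(int)
    i1 = i1.astype(int)
    if np.any(i1 < i0):
        return volume
    ax = [volume.origin[k] + volume.spacing[k] * np.arange(i0[k], i1[k] + 1)
          - c[k] for k in range(3)]
    d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
          + ax[2][None, None, :] ** 2)
    sub = volume.data[i0[0]:i1[0] + 1, i0[1]:i1[1] + 1, i0[2]:i1[2] + 1]
    np.maximum(sub, hu_profile(np.sqrt(d2), C, R, a), out=sub)
    return volume


def paint_curve(volume: Volume, points: np.ndarray, R: float,
                C: float = DEFAULT_C, a: float = DEFAULT_A) -> Volume:
    """Sweep the brush along pre-sampled curve points (one stroke each)."""
    for p in np.atleast_2d(points):
        paint_brush(volume, p, R, C, a)
    return volume


def _sweep_samples(curve: Callable, length: float, spacing: float) -> np.ndarray:
    """Arc-length sample positions at the 0.25-voxel brush stride."""
    stride = 0.25 * spacing
    n = max(int(np.ceil(length / stride)) + 1, 2)
    return curve(np.linspace(0.0, length, n))


# --------------------------------------------------------------------------
# swept-tube models

def make_torus(D: float, R1: float, C: float = DEFAULT_C, a: float = DEFAULT_A,
               size: float = DEFAULT_SIZE,
               spacing: float = DEFAULT_SPACING) -> tuple[Volume, CurveGroundTruth]:
    """Torus phantom: circle of radius ``R1`` in the mid-z plane, tube D."""
    if 2 * R1 + D >= size:
        raise ValueError("torus does not fit the volume")
    PhantomSpec("torus", D, R1, C=C, a=a)  # invariant check
    vol = blank_volume(size, spacing, C)
    center = (np.array(vol.shape) - 1) * vol.spacing / 2.0

    def curve(s):
        t = np.asarray(s, dtype=float) / R1
        return np.stack([center[0] + R1 * np.cos(t),
                         center[1] + R1 * np.sin(t),
                         np.full_like(t, center[2])], axis=-1)

    length = 2 * np.pi * R1
    paint_curve(vol, _sweep_samples(curve, length, spacing), D / 2, C, a)
    gt = CurveGroundTruth("torus", curve, length, D / 2, 1.0 / R1, 0.0,
                          center, {"D": D, "R1": R1})
    return vol, gt


def make_helix(D: float, R1: float, R2: float, C: float = DEFAULT_C,
               a: float = DEFAULT_A, size: float = DEFAULT_SIZE,
               spacing: float = DEFAULT_SPACING,
               max_turns: float = 1.5) -> tuple[Volume, CurveGroundTruth]:
    """Helix phantom: radius ``R1``, axial rise ``R2`` per full turn.

    The swept parameter range is clipped so the tube stays inside the
    volume (at most ``max_turns`` turns); ground truth covers exactly the
    swept arc.  With ``R2 = 0`` the sweep degenerates to a torus.
    """
    if 2 * R1 + D >= size:
        raise ValueError("helix does not fit the volume")
    if R2 > 0:
        PhantomSpec("helix", D, R1, R2, C=C, a=a)
    vol = blank_volume(size, spacing, C)
    center = (np.array(vol.shape) - 1) * vol.spacing / 2.0
    b = R2 / (2 * np.pi)
    z_half = (size - D) / 2.0 - 2.0
    t_half = np.pi * max_turns
    if b > 0:
        t_half = min(t_half, z_half / b)
    speed = np.hypot(R1, b)

    def curve(s):
        t = np.asarray(s, dtype=float) / speed - t_half
        return np.stack([center[0] + R1 * np.cos(t),
                         center[1] + R1 * np.sin(t),
                         center[2] + b * t], axis=-1)

    length = 2 * t_half * speed
    paint_curve(vol, _sweep_samples(curve, length, spacing), D / 2, C, a)
    kappa = R1 / (R1 ** 2 + b ** 2)
    tau = b / (R1 ** 2 + b ** 2)
    gt = CurveGroundTruth("helix", curve, length, D / 2, kappa, tau,
                          center, {"D": D, "R1": R1, "R2": R2, "b": b})
    return vol, gt


def _grid_values(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 10)


def enumerate_model_grid(kind: str,
                         D: tuple[float, float, float],
                         R1: tuple[float, float, float],
                         R2: tuple[float, float, float] | None = None,
                         ) -> list[PhantomSpec]:
    """Cartesian (D, R1[, R2]) grid with self-overlap rejection.

    Specs with ``R1 < 2 D`` (and ``R2 < 2 D`` for the helix) are removed;
    ordering is lexicographic by (D, R1, R2).
    """
    d_vals = _grid_values(*D)
    r1_vals = _grid_values(*R1)
    if kind == "helix":
        if R2 is None:
            raise ValueError("helix grid requires R2 ranges")
        r2_vals = _grid_values(*R2)
        combos = itertools.product(d_vals, r1_vals, r2_vals)
        return [PhantomSpec("helix", d, r1, r2)
                for d, r1, r2 in combos if r1 >= 2 * d and r2 >= 2 * d]
    combos = itertools.product(d_vals, r1_vals)
    return [PhantomSpec("torus", d, r1)
            for d, r1 in combos if r1 >= 2 * d]


# --------------------------------------------------------------------------
# artificial bifurcation zones

def _acute_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = abs(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def make_bifurcation(p: ABZParams, include_aneurysm: bool = False,
                     C: float = DEFAULT_C, a: float = DEFAULT_A,
                     size: float = DEFAULT_SIZE,
                     spacing: float = DEFAULT_SPACING,
                     trunk_length: float = 20.0, branch_length: float = 15.0,
                     ) -> tuple[Volume, ABZGroundTruth]:
    """Voxelize an artificial bifurcation zone and its reference geometry.

    The trunk runs along +z and ends at the apex (volume center); branch
    ``i`` leaves the apex at ``Ai`` degrees from the trunk axis inside the
    x-z plane (branch 1 toward +x, branch 2 toward -x) and is then tilted
    out of that plane by ``Ai_pl`` degrees (y component).  Reference BA, VA
    and CoI values are computed from the actual construction vectors, and
    the reference division plane is the plane through the apex spanned by
    the two branch directions.
    """
    vol = blank_volume(size, spacing, C)
    apex = (np.array(vol.shape) - 1) * vol.spacing / 2.0
    trunk_dir = np.array([0.0, 0.0, 1.0])

    dirs = []
    for ang, tilt, sign in ((p.A1, p.A1_pl, 1.0), (p.A2, p.A2_pl, -1.0)):
        ang, tilt = np.radians(ang), np.radians(tilt)
        d = np.array([sign * np.sin(ang) * np.cos(tilt),
                      np.sin(tilt),
                      np.cos(ang) * np.cos(tilt)])
        dirs.append(d / np.linalg.norm(d))
    dirs = np.array(dirs)

    def seg(p0, d, length):
        return lambda s: p0 + np.outer(np.asarray(s, dtype=float), d)

    paint_curve(vol, _sweep_samples(seg(apex - trunk_dir * trunk_length,
                                        trunk_dir, trunk_length),
                                    trunk_length, spacing), p.D_T / 2, C, a)
    for d, D in zip(dirs, (p.D_1, p.D_2)):
        paint_curve(vol, _sweep_samples(seg(apex, d, branch_length),
                                        branch_length, spacing), D / 2, C, a)

    an_center = None
    if include_aneurysm:
        bis = dirs[0] + dirs[1]
        bis /= np.linalg.norm(bis)
        an_center = apex + bis * (p.D_an / 2.0)
        paint_brush(vol, an_center, p.D_an / 2.0, C, a)

    dpn = np.cross(dirs[0], dirs[1])
    dpn /= np.linalg.norm(dpn)

    def coi(v):
        return 1.0 - _acute_angle_deg(v, dpn) / 90.0

    gt = ABZGroundTruth(
        apex=apex, trunk_dir=trunk_dir, branch_dirs=dirs,
        trunk_length=trunk_length, branch_length=branch_length,
        diameters={"D_T": p.D_T, "D_1": p.D_1, "D_2": p.D_2},
        ba=_angle_deg(dirs[0], dirs[1]),
        va=np.array([_angle_deg(trunk_dir, dirs[0]),
                     _angle_deg(trunk_dir, dirs[1])]),
        dpn=dpn, coi_trunk=coi(trunk_dir),
        coi_branches=np.array([coi(dirs[0]), coi(dirs[1])]),
        dominant=0 if p.D_1 >= p.D_2 else 1,
        aneurysm_center=an_center)
    return vol, gt


def sample_abz(n: int, ranges: dict | None = None,
               seed: int | np.random.Generator | None = None) -> list[ABZParams]:
    """Draw ``n`` ABZ parameter sets, uniform and independent per field."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ranges = {**ABZ_RANGES, **(ranges or {})}
    out = []
    for _ in range(n):
        vals = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
        out.append(ABZParams(**vals))
    return out
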