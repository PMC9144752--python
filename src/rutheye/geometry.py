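"""Parametric geometry of notched Ru/Rh-106 ophthalmic applicators.

A plaque is a spherical-cap shell of curvature radius ``R`` whose plan-view
footprint is a disc of diameter ``D``.  Asymmetric ("notched") types carry a
cutout that spares a critical structure adjacent to the tumor.  The cutout is
parameterized by three tangent circles in the projection plane:

* the *notch circle* of radius ``r1`` whose deepest intrusion lies ``a``
  millimetres inward from the outer rim along the notch symmetry axis, and
* two mirror-symmetric *fillet circles* of radius ``r2``, internally tangent
  to the outer circle and externally tangent to the notch circle, which round
  the entrance of the cutout.

The radioactive layer does not reach the boundary of the shell: an inactive
margin of width ``s`` is kept from the rim and from the cutout edge.

Frame convention: the curvature center sits at the origin, the plaque axis is
``z`` and the cap occupies ``z < 0``; in the projection plane the notch points
along ``-y``.  The angular coordinate ``phi`` of a surface point is measured
from ``+y`` (``phi = 0`` anti-notch, ``phi = 180`` toward the notch), so the
lowest surface doses occur at 180 degrees.

All parameters (``D``, ``a``, ``r1``, ``r2``, ``s``) are chord/projection-plane
distances, matching the plan-view photographic procedure they were fitted
with, not arc lengths along the cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

__all__ = [
    "PlaqueParams",
    "NotchConstruction",
    "PlaqueModel",
    "SurfacePointSet",
    "TangencyError",
    "build_plaque",
    "is_active",
    "cutout_distance",
    "active_area",
    "cap_lift",
    "cap_project",
    "surface_points",
    "cax_points",
]

#: tolerance for the tangent-circle construction residuals, mm
TANGENCY_EPS = 1e-9


class TangencyError(ValueError):
    """The requested (D, a, r1, r2) admit no fillet-circle solution."""


@dataclass(frozen=True)
class PlaqueParams:
    """Geometric parameters of one applicator, in millimetres.

    ``a``, ``r1`` and ``r2`` are ``None`` for symmetric (un-notched) types.
    """

    name: str
    D: float
    R: float
    s: float = 0.0
    a: float | None = None
    r1: float | None = None
    r2: float | None = None
    parameter_set: str = "custom"

    @property
    def is_notched(self) -> bool:
        return self.a is not None

    def validate(self) -> None:
        if not self.D > 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if not (0 < self.D / 2 <= self.R):
            raise ValueError(f"need 0 < D/2 <= R, got D={self.D}, R={self.R}")
        if not (0 <= self.s < self.D / 2):
            raise ValueError(f"rim width s={self.s} outside [0, D/2)")
        notch = (self.a, self.r1, self.r2)
        if any(v is not None for v in notch) and any(v is None for v in notch):
            raise ValueError("a, r1, r2 must be given together or not at all")
        if self.is_notched:
            if not (0 < self.a < self.D):
                raise ValueError(f"notch depth a={self.a} outside (0, D)")
            if not self.r1 > 0:
                raise ValueError(f"r1={self.r1} must be positive")
            if not self.r2 > 0:
                raise ValueError(f"r2={self.r2} must be positive")


@dataclass(frozen=True)
class NotchConstruction:
    """Solved tangent-circle construction of the cutout (projection plane)."""

    outer_radius: float
    notch_center: tuple[float, float]
    notch_radius: float
    fillet_centers: tuple[tuple[float, float], tuple[float, float]]
    fillet_radius: float

    def tangency_residuals(self) -> np.ndarray:
        """Absolute residuals (mm) of the two tangency conditions per fillet.

        Internal tangency to the outer circle: ``| |c_f| - (D/2 - r2) |``;
        external tangency to the notch circle: ``| |c_f - c_n| - (r1 + r2) |``.
        """
        nc = np.asarray(self.notch_center)
        rho = self.outer_radius - self.fillet_radius
        out = []
        for cf in self.fillet_centers:
            cf = np.asarray(cf)
            out.append(abs(np.hypot(*cf) - rho))
            out.append(abs(np.linalg.norm(cf - nc) - (self.notch_radius + self.fillet_radius)))
        return np.asarray(out)


@dataclass(frozen=True)
class PlaqueModel:
    """A fully constructed applicator: parameters plus solved cutout."""

    params: PlaqueParams
    construction: NotchConstruction | None = None

    @property
    def name(self) -> str:
        return self.params.name

    @property
    def outer_radius(self) -> float:
        return self.params.D / 2


@dataclass(frozen=True)
class SurfacePointSet:
    """Certificate-style evaluation points on the offset sphere.

    32 points on four concentric circles (8 per circle, 45-degree steps) plus
    the central-axis point, all at ``offset`` mm from the inner surface, i.e.
    on the sphere of radius ``R - offset``.
    """

    circle_radii: tuple[float, float, float, float]
    angles: tuple[int, ...]
    offset: float
    coordinates: np.ndarray = field(repr=False)  # (33, 3); last row is the CAX point

    def point(self, circle: int, angle: int) -> np.ndarray:
        """Coordinate of the point on circle 1..4 at the given angle (deg)."""
        i = (circle - 1) * len(self.angles) + self.angles.index(angle)
        return self.coordinates[i]

    @property
    def cax(self) -> np.ndarray:
        return self.coordinates[-1]


def build_plaque(params: PlaqueParams) -> PlaqueModel:
    """Construct a plaque model, solving the fillet tangency in closed form.

    With ``d1 = D/2 - a + r1`` (distance of the notch-circle center from the
    plaque axis) and ``rho = D/2 - r2`` (locus of internally tangent fillet
    centers), the fillet center ordinate follows from intersecting the circle
    ``|c| = rho`` with ``|c - c_n| = r1 + r2``::

        y = ((r1 + r2)**2 - rho**2 - d1**2) / (2 * d1)
        x = +/- sqrt(rho**2 - y**2)

    in the frame where the notch center lies at ``(0, -d1)``.

    Raises
    ------
    TangencyError
        If the parameter combination admits no fillet solution.
    ValueError
        If ``params`` violates its invariants.
    """
    params.validate()
    if not params.is_notched:
        return PlaqueModel(params=params, construction=None)

    half_d = params.D / 2
    d1 = half_d - params.a + params.r1
    rho = half_d - params.r2
    if d1 <= 0:
        raise TangencyError(f"tangency infeasible: d1 = {d1:.6g} <= 0")
    if rho <= 0:
        raise TangencyError(f"tangency infeasible: rho = {rho:.6g} <= 0")
    y = ((params.r1 + params.r2) ** 2 - rho**2 - d1**2) / (2 * d1)
    x_sq = rho**2 - y**2
    if x_sq < 0:
        raise TangencyError(
            f"tangency infeasible: rho^2 - y^2 = {x_sq:.6g} < 0 for {params.name}"
        )
    x = float(np.sqrt(x_sq))
    construction = NotchConstruction(
        outer_radius=half_d,
        notch_center=(0.0, -d1),
        notch_radius=params.r1,
        fillet_centers=((x, y), (-x, y)),
        fillet_radius=params.r2,
    )
    return PlaqueModel(params=params, construction=construction)


def _arc(center, radius, p0, p1, hint, step=0.01) -> np.ndarray:
    """Sample the circular arc from p0 to p1 whose midpoint is nearest hint.

    Of the two arcs joining p0 and p1 on the circle, the one facing the
    ``hint`` point is the boundary arc of the tangent-circle construction.
    Returns the sampled points excluding p1 (chains concatenate cleanly).
    """
    center = np.asarray(center, dtype=float)
    a0 = np.arctan2(p0[1] - center[1], p0[0] - center[0])
    a1 = np.arctan2(p1[1] - center[1], p1[0] - center[0])
    ccw = (a1 - a0) % (2 * np.pi)
    best = None
    for sweep in (ccw, ccw - 2 * np.pi):
        mid = a0 + sweep / 2
        m = center + radius * np.array([np.cos(mid), np.sin(mid)])
        d = np.hypot(m[0] - hint[0], m[1] - hint[1])
        if best is None or d < best[0]:
            best = (d, sweep)
    sweep = best[1]
    n = max(int(abs(sweep) * radius / step), 8)
    ang = a0 + sweep * np.arange(n) / n
    return center[None, :] + radius * np.column_stack([np.cos(ang), np.sin(ang)])


def _cutout_chain(con: NotchConstruction, step: float = 0.01) -> np.ndarray:
    """Closed boundary polygon of the cutout region.

    The material boundary of a notched plaque is the tangent chain
    rim arc -> fillet arc -> notch arc -> fillet arc -> rim arc; the cutout
    is the region enclosed by the complementary chain: the short rim arc
    across the cutout mouth, the two mouth-side fillet arcs, and the deep
    notch arc.  Tangency points follow from the construction:
    ``T_rim = (D/2) * c_f / |c_f|`` (fillet-rim) and
    ``T_notch = c_n + r1 * (c_f - c_n) / (r1 + r2)`` (fillet-notch).
    This covers both plaque families: notch circles that cross the rim
    (CI types) and interior notch circles reached through a channel between
    the fillets (CO types).
    """
    nc = np.asarray(con.notch_center)
    cf_p = np.asarray(con.fillet_centers[0])
    cf_m = np.asarray(con.fillet_centers[1])
    r_out = con.outer_radius
    t_rim_p = r_out * cf_p / np.hypot(*cf_p)
    t_rim_m = r_out * cf_m / np.hypot(*cf_m)
    w = con.notch_radius / (con.notch_radius + con.fillet_radius)
    t_notch_p = nc + w * (cf_p - nc)
    t_notch_m = nc + w * (cf_m - nc)
    mouth_hint = (0.0, -r_out)  # rim arc across the cutout mouth
    pieces = [
        _arc((0.0, 0.0), r_out, t_rim_p, t_rim_m, mouth_hint, step),
        _arc(cf_m, con.fillet_radius, t_rim_m, t_notch_m, nc, step),
        _arc(nc, con.notch_radius, t_notch_m, t_notch_p, (0.0, 0.0), step),
        _arc(cf_p, con.fillet_radius, t_notch_p, t_rim_p, nc, step),
    ]
    return np.vstack(pieces)


@lru_cache(maxsize=64)
def _cutout_polygon(con: NotchConstruction):
    """Shapely polygon of the cutout region (cached per construction)."""
    import shapely

    poly = shapely.Polygon(_cutout_chain(con))
    if not poly.is_valid:
        poly = shapely.make_valid(poly)
    shapely.prepare(poly)
    return poly


@lru_cache(maxsize=64)
def _active_polygon(model: PlaqueModel):
    """Shapely polygon of the active region: rim and cutout margins applied."""
    import shapely

    disc = shapely.Point(0.0, 0.0).buffer(
        model.outer_radius - model.params.s, quad_segs=512
    )
    if model.construction is None:
        return disc
    grown = _cutout_polygon(model.construction).buffer(model.params.s, quad_segs=64)
    active = disc.difference(grown)
    shapely.prepare(active)
    return active


def cutout_distance(model: PlaqueModel, pts: np.ndarray) -> np.ndarray:
    """Signed distance to the cutout region (negative inside it).

    The cutout is the region enclosed by the tangent boundary chain (see
    :func:`_cutout_chain`).  Returns +inf for symmetric plaques.
    """
    import shapely

    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    if model.construction is None:
        return np.full(pts.shape[0], np.inf)
    poly = _cutout_polygon(model.construction)
    points = shapely.points(pts)
    d = shapely.distance(points, poly.exterior)
    inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
    return np.where(inside, -d, d)


def is_active(model: PlaqueModel, pts) -> np.ndarray | bool:
    """Classify projection-plane points as lying on the active layer.

    A point is active iff it is at least ``s`` inside the outer rim
    (``|p| <= D/2 - s``) and at least ``s`` away from the cutout region.
    Accepts a single (x, y) pair or an (n, 2) array.
    """
    import shapely

    arr = np.asarray(pts, dtype=float)
    single = arr.ndim == 1
    pts2 = np.atleast_2d(arr)
    if model.construction is None:
        ok = np.hypot(pts2[:, 0], pts2[:, 1]) <= model.outer_radius - model.params.s
    else:
        ok = shapely.contains_xy(_active_polygon(model), pts2[:, 0], pts2[:, 1])
    return bool(ok[0]) if single else ok


def cap_lift(pts, R: float) -> np.ndarray:
    """Lift projection-plane points onto the spherical cap of radius ``R``.

    ``(x, y) -> (x, y, -sqrt(R^2 - x^2 - y^2))`` in the curvature-centered
    frame; raises for points outside the disc of radius ``R``.
    """
    arr = np.asarray(pts, dtype=float)
    single = arr.ndim == 1
    pts2 = np.atleast_2d(arr)
    rsq = pts2[:, 0] ** 2 + pts2[:, 1] ** 2
    if np.any(rsq > R**2 * (1 + 1e-12)):
        raise ValueError("point outside the sphere footprint |p| > R")
    z = -np.sqrt(np.maximum(R**2 - rsq, 0.0))
    out = np.column_stack([pts2, z])
    return out[0] if single else out


def cap_project(pts3) -> np.ndarray:
    """Inverse of :func:`cap_lift`: drop the z coordinate."""
    arr = np.asarray(pts3, dtype=float)
    return arr[..., :2]


def active_area(
    model: PlaqueModel,
    sphere_radius: float | None = None,
    radial_step: float = 0.01,
) -> float:
    """Area of the active region mapped onto the spherical cap, mm^2.

    Computed by midpoint quadrature on a polar grid in the projection plane
    with the cap area element ``R / sqrt(R^2 - r^2) * r dr dphi``.  The radial
    grid is aligned with the rim circle so only the cutout boundary
    contributes discretization error; the default 0.01 mm step keeps the
    relative error below 1e-3 for the packaged plaques.

    ``sphere_radius`` defaults to the inner-surface curvature radius ``R``;
    pass ``R + t_active`` to measure the source layer itself.
    """
    R = model.params.R if sphere_radius is None else sphere_radius
    r_out = model.outer_radius - model.params.s
    if model.construction is None:
        # exact spherical-cap zone area
        return float(2 * np.pi * R * (R - np.sqrt(R**2 - r_out**2)))
    n_r = max(int(np.ceil(r_out / radial_step)), 8)
    edges = np.linspace(0.0, r_out, n_r + 1)
    area = 0.0
    for r0, r1 in zip(edges[:-1], edges[1:]):
        rm = 0.5 * (r0 + r1)
        n_phi = max(int(np.ceil(2 * np.pi * rm / radial_step)), 8)
        phi = (np.arange(n_phi) + 0.5) * (2 * np.pi / n_phi)
        pts = np.column_stack([rm * np.sin(phi), rm * np.cos(phi)])
        frac = np.count_nonzero(is_active(model, pts)) / n_phi
        # exact zone area of the annulus, weighted by the active fraction
        ring = 2 * np.pi * R * (np.sqrt(R**2 - r0**2) - np.sqrt(R**2 - r1**2))
        area += frac * ring
    return float(area)


def _circle_coords(radius: float, angles_deg: np.ndarray, sphere_radius: float) -> np.ndarray:
    """3D coordinates of points at projected radius ``radius`` on the sphere.

    ``phi = 0`` maps to +y (anti-notch), ``phi = 180`` to -y (notch side);
    mirror-equivalent angles (45/315 etc.) are mirror images across the notch
    plane x = 0.
    """
    phi = np.deg2rad(angles_deg)
    xy = np.column_stack([radius * np.sin(phi), radius * np.cos(phi)])
    return cap_lift(xy, sphere_radius)


def surface_points(
    model: PlaqueModel,
    radii: Sequence[float],
    offset: float = 1.0,
    angles: Sequence[int] = (0, 45, 90, 135, 180, 225, 270, 315),
) -> SurfacePointSet:
    """Certificate evaluation points: 4 circles x 8 angles + the CAX point.

    The points lie on the sphere of radius ``R - offset`` (``offset`` mm from
    the inner surface); ``radii`` are the projected circle radii C1 < C2 < C3
    < C4.
    """
    radii = tuple(float(r) for r in radii)
    if len(radii) != 4 or np.any(np.diff(radii) <= 0):
        raise ValueError(f"need four strictly increasing radii, got {radii}")
    if offset <= 0:
        raise ValueError("offset must be positive")
    rs = model.params.R - offset
    if radii[-1] >= rs:
        raise ValueError(f"largest radius {radii[-1]} outside offset sphere {rs}")
    ang = np.asarray(angles)
    coords = np.vstack([_circle_coords(r, ang, rs) for r in radii])
    cax = np.array([[0.0, 0.0, -rs]])
    return SurfacePointSet(
        circle_radii=radii,
        angles=tuple(int(a) for a in angles),
        offset=offset,
        coordinates=np.vstack([coords, cax]),
    )


def cax_points(model: PlaqueModel, depths: Sequence[float]) -> np.ndarray:
    """Central-axis points at the given depths (mm) from the inner surface."""
    depths = np.asarray(depths, dtype=float)
    if np.any(depths <= 0):
        raise ValueError("depths must be positive")
    z = -(model.params.R - depths)
    return np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
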