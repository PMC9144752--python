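"""Parametric eye model, structure masks and dose-volume histograms.

A deliberately simple, literature-typical eye: a 24 mm-diameter globe
concentric with the plaque curvature center, with implicit-geometry ocular
structures (sclera, retina, cornea, lens, macula, optic nerve) and a
dome-shaped tumor under the plaque.  It is NOT patient-specific; it exists
to report structure mean doses, the tumor apex dose, and cumulative DVHs
from a relative dose grid, and to study how geometry changes (e.g. official
vs modified notch parameters) propagate to structures near the cutout.

Frame: the plaque frame (curvature center at origin, plaque at z < 0, notch
toward -y).  The plaque therefore sits at the posterior pole by convention
and the cornea/lens at +z; the optic nerve inserts on the notch side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose import DoseGrid

__all__ = ["EyeModel", "DVHResult", "build_eye", "structure_masks", "dvh", "apex_dose"]


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class EyeModel:
    """Geometric description of the eye and its structures (mm, degrees)."""

    eye_radius: float = 12.0
    sclera_thickness: float = 1.0
    retina_thickness: float = 0.3
    cornea_half_angle_deg: float = 40.0
    lens_center_z: float = 7.0
    lens_semi_axes: tuple[float, float, float] = (4.5, 4.5, 2.0)
    macula_radius: float = 1.5
    macula_direction: tuple[float, float, float] = (0.0, 0.35, -0.94)
    nerve_radius: float = 1.5
    nerve_length: float = 8.0
    nerve_direction: tuple[float, float, float] = (0.0, -0.42, -0.91)
    tumor_base_diameter: float = 10.0
    tumor_apex_height: float = 5.0
    tumor_direction: tuple[float, float, float] = (0.0, 0.0, -1.0)

    @property
    def tumor_apex(self) -> np.ndarray:
        """Apex of the tumor dome: on the tumor axis, apex_height above the
        inner sclera surface."""
        r_base = self.eye_radius - self.sclera_thickness
        return (r_base - self.tumor_apex_height) * _unit(self.tumor_direction)


def build_eye(**overrides) -> EyeModel:
    """EyeModel with defaults overridden by keyword; validates basic sanity."""
    eye = EyeModel(**overrides)
    if eye.eye_radius <= 0 or eye.sclera_thickness <= 0:
        raise ValueError("eye radius and sclera thickness must be positive")
    if eye.tumor_apex_height <= 0:
        raise ValueError("tumor apex height must be positive")
    if eye.tumor_apex_height >= eye.eye_radius:
        raise ValueError("tumor taller than the eye")
    return eye


def structure_masks(eye: EyeModel, grid: DoseGrid) -> dict[str, np.ndarray]:
    """Boolean occupancy mask per structure on the grid lattice.

    Masks are built by implicit-geometry tests at voxel centers.  The retina
    excludes the anterior (corneal) cap; the lens lies inside the vitreous,
    so it is disjoint from the sclera by construction.
    """
    pts = grid.centers()
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    r = np.sqrt(x**2 + y**2 + z**2)
    shape = grid.shape

    R = eye.eye_radius
    r_in = R - eye.sclera_thickness
    r_ret = r_in - eye.retina_thickness
    cos_cornea = np.cos(np.deg2rad(eye.cornea_half_angle_deg))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_polar = np.where(r > 0, z / np.maximum(r, 1e-12), 1.0)

    masks: dict[str, np.ndarray] = {}
    masks["eye"] = r <= R
    anterior = cos_polar >= cos_cornea
    masks["sclera"] = (r <= R) & (r > r_in) & ~anterior
    masks["cornea"] = (r <= R) & (r > r_in) & anterior
    masks["retina"] = (r <= r_in) & (r > r_ret) & ~anterior

    ax, ay, az = eye.lens_semi_axes
    masks["lens"] = ((x / ax) ** 2 + (y / ay) ** 2
                     + ((z - eye.lens_center_z) / az) ** 2) <= 1.0

    mac_c = r_ret * _unit(eye.macula_direction)
    masks["macula"] = (np.linalg.norm(pts - mac_c, axis=1) <= eye.macula_radius) & (
        r > r_ret - eye.macula_radius
    )

    # optic nerve: cylinder from the scleral insertion outward
    n_dir = _unit(eye.nerve_direction)
    t = pts @ n_dir  # coordinate along the nerve axis
    radial = np.linalg.norm(pts - np.outer(t, n_dir), axis=1)
    masks["optic_nerve"] = (
        (radial <= eye.nerve_radius)
        & (t >= R - 0.5)
        & (t <= R + eye.nerve_length)
        & (pts @ n_dir > 0)
    )

    # tumor: spherical dome of height h and base diameter d on the retina
    h = eye.tumor_apex_height
    half_base = eye.tumor_base_diameter / 2
    rho = (h**2 + half_base**2) / (2 * h)  # dome sphere radius
    u = _unit(eye.tumor_direction)
    dome_center = (r_in + rho - h) * u
    masks["tumor"] = (np.linalg.norm(pts - dome_center, axis=1) <= rho) & (r <= r_in)

    return {k: v.reshape(shape) for k, v in masks.items()}


@dataclass(frozen=True)
class DVHResult:
    """Cumulative dose-volume histogram of one structure."""

    dose_edges: np.ndarray = field(repr=False)
    volume_fraction: np.ndarray = field(repr=False)  # fraction receiving >= edge
    mean: float = 0.0
    minimum: float = 0.0
    maximum: float = 0.0
    n_voxels: int = 0

    def v_at(self, dose: float) -> float:
        """Volume fraction receiving at least ``dose`` (interpolated)."""
        return float(np.interp(dose, self.dose_edges, self.volume_fraction))


def dvh(grid: DoseGrid, mask: np.ndarray, n_bins: int = 256,
        dose_max: float | None = None) -> DVHResult:
    """Cumulative DVH, mean and extrema of the masked voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask and grid lattices differ")
    vals = grid.values[mask]
    if vals.size == 0:
        raise ValueError("empty structure mask")
    hi = float(dose_max if dose_max is not None else vals.max())
    hi = hi if hi > 0 else 1.0
    edges = np.linspace(0.0, hi, n_bins)
    frac = (vals[None, :] >= edges[:, None]).mean(axis=1)
    return DVHResult(
        dose_edges=edges,
        volume_fraction=frac,
        mean=float(vals.mean()),
        minimum=float(vals.min()),
        maximum=float(vals.max()),
        n_voxels=int(vals.size),
    )


def apex_dose(grid: DoseGrid, eye: EyeModel) -> float:
    """Dose at the tumor apex point (trilinear interpolation)."""
    apex = eye.tumor_apex
    lo = grid.origin
    hi = grid.origin + grid.spacing * (np.array(grid.shape) - 1)
    if np.any(apex < lo) or np.any(apex > hi):
        raise ValueError("tumor apex lies outside the dose grid")
    return float(grid.interp(apex)[0])
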