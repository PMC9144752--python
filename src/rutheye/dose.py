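"""Kernel-superposition dose engine for the uniform active-surface source.

The active layer is modeled as a uniform surface source on the sphere of
radius ``R + t_active`` (a small configurable encapsulation offset behind the
inner surface).  Dose at a target point is the weighted sum of kernel values
over source nodes,

    D(t) = sum_i w_i * k(|t - q_i|),

with nodes either an equal-area quadrature tessellation of the spherical cap
(deterministic; the default) or uniform random samples on the cap (mirroring
a surface-sampling Monte Carlo source).  All results are relative; use
:func:`normalize` to express them as percent of the central-axis dose at a
reference depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .geometry import PlaqueModel, active_area, cax_points, is_active
from .kernels import KernelTable

__all__ = [
    "SourceNodes",
    "DoseGrid",
    "DEFAULT_T_ACTIVE",
    "make_nodes",
    "dose_at_points",
    "dose_grid",
    "normalize",
]

#: default outward offset of the active layer behind the inner surface, mm
DEFAULT_T_ACTIVE = 0.1


@dataclass(frozen=True)
class SourceNodes:
    """Emission nodes on the active layer with per-node area weights (mm^2)."""

    positions: np.ndarray = field(repr=False)  # (M, 3)
    weights: np.ndarray = field(repr=False)  # (M,)
    mode: str = "quadrature"
    seed: int | None = None
    sphere_radius: float = 0.0

    def __len__(self) -> int:
        return self.positions.shape[0]


def _cap_theta_max(model: PlaqueModel, sphere_radius: float) -> float:
    return float(np.arcsin(min(model.outer_radius / sphere_radius, 1.0)))


def make_nodes(
    model: PlaqueModel,
    resolution: float = 0.1,
    mode: str = "quadrature",
    n: int | None = None,
    seed: int | None = None,
    t_active: float = DEFAULT_T_ACTIVE,
) -> SourceNodes:
    """Generate source nodes on the active layer.

    Quadrature mode tessellates the spherical cap into near-equal-area cells
    of side ``resolution`` (mm): rings of equal polar-angle width, each split
    azimuthally so cells are roughly square; cell centers are kept iff their
    projection lies on the active region, with the exact ring-zone area as
    weight (rescaled so weights sum to the active-layer area).  Random mode
    draws ``n`` uniform points on the cap by rejection against the active
    classifier, each weighted ``active_area / n``.
    """
    rs = model.params.R + t_active
    area = active_area(model, sphere_radius=rs)
    theta_max = _cap_theta_max(model, rs)

    if mode == "quadrature":
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        n_t = max(int(np.ceil(rs * theta_max / resolution)), 2)
        edges = np.linspace(0.0, theta_max, n_t + 1)
        pos, wts = [], []
        for t0, t1 in zip(edges[:-1], edges[1:]):
            tc = 0.5 * (t0 + t1)
            n_phi = max(int(np.ceil(2 * np.pi * rs * np.sin(tc) / resolution)), 1)
            ring_area = 2 * np.pi * rs**2 * (np.cos(t0) - np.cos(t1))
            phi = (np.arange(n_phi) + 0.5) * (2 * np.pi / n_phi)
            x = rs * np.sin(tc) * np.sin(phi)
            y = rs * np.sin(tc) * np.cos(phi)
            keep = is_active(model, np.column_stack([x, y]))
            if np.any(keep):
                z = -rs * np.cos(tc) * np.ones(np.count_nonzero(keep))
                pos.append(np.column_stack([x[keep], y[keep], z]))
                wts.append(np.full(z.size, ring_area / n_phi))
        if not pos:
            raise ValueError("no active source nodes — check the geometry")
        positions = np.vstack(pos)
        weights = np.concatenate(wts)
        weights *= area / weights.sum()
        return SourceNodes(positions, weights, "quadrature", None, rs)

    if mode == "random":
        if not n or n <= 0:
            raise ValueError("random mode needs a positive sample count n")
        rng = np.random.default_rng(seed)
        cos_min = np.cos(theta_max)
        acc = []
        got = 0
        while got < n:
            m = max(int(1.5 * (n - got)) + 64, 256)
            cos_t = rng.uniform(cos_min, 1.0, m)
            sin_t = np.sqrt(1.0 - cos_t**2)
            phi = rng.uniform(0.0, 2 * np.pi, m)
            x = rs * sin_t * np.sin(phi)
            y = rs * sin_t * np.cos(phi)
            keep = is_active(model, np.column_stack([x, y]))
            pts = np.column_stack([x[keep], y[keep], -rs * cos_t[keep]])
            acc.append(pts)
            got += pts.shape[0]
        positions = np.vstack(acc)[:n]
        weights = np.full(n, area / n)
        return SourceNodes(positions, weights, "random", seed, rs)

    raise ValueError(f"unknown node mode {mode!r}")


def dose_at_points(
    kernel: KernelTable,
    nodes: SourceNodes,
    targets,
    target_chunk: int = 8192,
    node_chunk: int = 4096,
) -> np.ndarray:
    """Superpose the kernel over all source nodes at each target point."""
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if len(nodes) == 0:
        raise ValueError("empty source nodes")
    angular = hasattr(kernel, "evaluate")  # EncapsulatedKernel
    out = np.zeros(targets.shape[0])
    pos, wts = nodes.positions, nodes.weights
    if angular:
        # outward surface normal of the concave source cap points toward the
        # curvature center (the eye side)
        nhat = -pos / np.linalg.norm(pos, axis=1)[:, None]
    for i0 in range(0, targets.shape[0], target_chunk):
        t = targets[i0 : i0 + target_chunk]
        acc = np.zeros(t.shape[0])
        for j0 in range(0, pos.shape[0], node_chunk):
            q = pos[j0 : j0 + node_chunk]
            w = wts[j0 : j0 + node_chunk]
            diff = t[:, None, :] - q[None, :, :]
            d = np.sqrt((diff**2).sum(axis=2))
            if angular:
                cos = (diff * nhat[None, j0 : j0 + node_chunk, :]).sum(axis=2)
                cos /= np.maximum(d, 1e-9)
                sec = 1.0 / np.clip(cos, 1e-2, 1.0)
                acc += kernel.evaluate(d, sec) @ w
            else:
                acc += kernel(d) @ w
        out[i0 : i0 + target_chunk] = acc
    return out


@dataclass(frozen=True)
class DoseGrid:
    """Regular 3D voxel grid of (relative) dose in the plaque frame.

    ``origin`` is the center of voxel (0, 0, 0); voxels are cubes of side
    ``spacing``.  ``normalization`` records the reference point/depth once
    :func:`normalize` has been applied (values then in percent).
    """

    origin: np.ndarray = field(repr=False)
    spacing: float
    values: np.ndarray = field(repr=False)
    normalization: dict | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing * np.arange(self.shape[axis])

    def centers(self) -> np.ndarray:
        """All voxel centers, shape (nx*ny*nz, 3), x fastest last index C-order."""
        ax = [self.axis_coords(i) for i in range(3)]
        g = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([a.ravel() for a in g])

    def interp(self, points) -> np.ndarray:
        """Trilinear interpolation of grid values at arbitrary points."""
        from scipy.ndimage import map_coordinates

        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = (pts - self.origin[None, :]) / self.spacing
        return map_coordinates(self.values, idx.T, order=1, mode="nearest")

    def save(self, path, provenance: dict | None = None) -> None:
        """Persist as flat little-endian float32 binary + JSON sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.values.astype("<f4").tofile(path)
        sidecar = {
            "origin": list(map(float, self.origin)),
            "spacing": self.spacing,
            "shape": list(self.shape),
            "frame": "plaque (curvature center at origin, cap at z<0, notch -y)",
            "normalization": self.normalization,
            "provenance": provenance,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "DoseGrid":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        values = np.fromfile(path, dtype="<f4").astype(float).reshape(meta["shape"])
        return cls(
            origin=np.asarray(meta["origin"], dtype=float),
            spacing=float(meta["spacing"]),
            values=values,
            normalization=meta.get("normalization"),
        )


def dose_grid(
    kernel: KernelTable,
    nodes: SourceNodes,
    origin,
    spacing: float,
    shape,
) -> DoseGrid:
    """Score dose on a regular grid (point estimate at each voxel center)."""
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    grid = DoseGrid(origin=np.asarray(origin, dtype=float), spacing=float(spacing),
                    values=np.zeros(tuple(shape)))
    vals = dose_at_points(kernel, nodes, grid.centers())
    return replace(grid, values=vals.reshape(grid.shape))


def normalize(
    dose,
    model: PlaqueModel,
    kernel: KernelTable,
    nodes: SourceNodes,
    depth: float = 1.0,
):
    """Express dose in percent of the central-axis dose at ``depth`` mm.

    ``dose`` may be an array of point doses or a :class:`DoseGrid`; the CAX
    reference is recomputed with the same kernel and nodes.
    """
    ref = float(dose_at_points(kernel, nodes, cax_points(model, [depth]))[0])
    if ref <= 0:
        raise ValueError("zero CAX reference dose")
    if isinstance(dose, DoseGrid):
        return replace(
            dose,
            values=dose.values / ref * 100.0,
            normalization={"point": "CAX", "depth_mm": depth, "reference": ref},
        )
    return np.asarray(dose, dtype=float) / ref * 100.0
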