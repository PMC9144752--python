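"""Comparison machinery against certificate-style reference surface data.

The manufacturer's calibration certificates report relative surface dose (in
percent of the CAX dose at 1 mm depth) at 33 points: four concentric circles
C1..C4 with eight 45-degree-spaced angles, plus the CAX point.  Mirror
equivalent angles (45/315, 90/270, 135/225) are averaged ("symmetric
folding") so tables carry five angles 0..180.  The exact circle radii are
vendor data; :func:`calibrate_radii` estimates them per plaque from the
non-notch columns (0/45/90 degrees) of the reference table, leaving the
notch-direction columns (135/180) untouched as validation data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dose import SourceNodes, dose_at_points
from .geometry import PlaqueModel, cax_points, surface_points
from .kernels import KernelTable

__all__ = [
    "ComparisonTable",
    "fold_symmetric",
    "simulate_surface",
    "surface_table",
    "calibrate_radii",
    "cax_table",
    "PlanarDose",
    "extract_plane",
    "isodose_contours",
    "profile",
]

FOLD_PAIRS = {45: 315, 90: 270, 135: 225}
FOLDED_ANGLES = (0, 45, 90, 135, 180)
ALL_ANGLES = (0, 45, 90, 135, 180, 225, 270, 315)


def fold_symmetric(values_by_angle: Mapping[int, float]) -> dict[int, float]:
    """Average mirror-equivalent angles: 45/315, 90/270, 135/225.

    0 and 180 lie on the symmetry plane and pass through unchanged.
    """
    missing = set(ALL_ANGLES) - set(values_by_angle)
    if missing:
        raise ValueError(f"missing angles: {sorted(missing)}")
    out = {0: float(values_by_angle[0]), 180: float(values_by_angle[180])}
    for a, b in FOLD_PAIRS.items():
        out[a] = 0.5 * (float(values_by_angle[a]) + float(values_by_angle[b]))
    return dict(sorted(out.items()))


def simulate_surface(
    model: PlaqueModel,
    kernel: KernelTable,
    nodes: SourceNodes,
    radii: Sequence[float],
    offset: float = 1.0,
    norm_depth: float = 1.0,
) -> pd.DataFrame:
    """Simulate the 32 surface points + CAX, normalize, fold.

    Returns a DataFrame with columns circle (1..4), angle_deg (0..180) and
    simulated_pct — 20 rows per plaque, certificate layout.
    """
    sps = surface_points(model, radii, offset=offset)
    doses = dose_at_points(kernel, nodes, sps.coordinates)
    cax_ref = dose_at_points(kernel, nodes, cax_points(model, [norm_depth]))[0]
    if cax_ref <= 0:
        raise ValueError("zero CAX reference dose")
    rel = doses / cax_ref * 100.0
    rows = []
    for ci in range(4):
        by_angle = {a: rel[ci * 8 + j] for j, a in enumerate(sps.angles)}
        for ang, val in fold_symmetric(by_angle).items():
            rows.append({"circle": ci + 1, "angle_deg": ang, "simulated_pct": val})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonTable:
    """Simulated-vs-reference surface table for one plaque/parameter set."""

    plaque: str
    parameter_set: str
    df: pd.DataFrame = field(repr=False)  # circle, angle_deg, simulated_pct,
    # reference_pct, sd_pct, difference, exceeds_sd

    def summary(self) -> dict[str, float]:
        d = self.df["difference"].to_numpy()
        return {"mean_abs_difference": float(np.mean(np.abs(d))),
                "max_abs_difference": float(np.max(np.abs(d)))}

    def cell(self, circle: int, angle: int, column: str = "difference") -> float:
        m = (self.df["circle"] == circle) & (self.df["angle_deg"] == angle)
        return float(self.df.loc[m, column].iloc[0])


def surface_table(
    model: PlaqueModel,
    kernel: KernelTable,
    nodes: SourceNodes,
    radii: Sequence[float],
    reference: pd.DataFrame,
    offset: float = 1.0,
    norm_depth: float = 1.0,
) -> ComparisonTable:
    """Build the simulated-vs-reference comparison for one plaque.

    ``reference`` must carry columns circle, angle_deg, mean_pct, sd_pct
    (already restricted to this plaque).  Differences are simulated minus
    reference, in percentage points; ``exceeds_sd`` flags cells whose
    absolute difference exceeds the reference standard deviation.
    """
    sim = simulate_surface(model, kernel, nodes, radii, offset, norm_depth)
    ref = reference[["circle", "angle_deg", "mean_pct", "sd_pct"]].rename(
        columns={"mean_pct": "reference_pct", "sd_pct": "sd_pct"}
    )
    df = sim.merge(ref, on=["circle", "angle_deg"], how="inner", validate="1:1")
    if len(df) != 20:
        raise ValueError(f"reference table incomplete: matched {len(df)} of 20 rows")
    df["difference"] = df["simulated_pct"] - df["reference_pct"]
    df["exceeds_sd"] = df["difference"].abs() > df["sd_pct"]
    return ComparisonTable(model.name, model.params.parameter_set, df)


#: certificate-circle template: fractions of the active radius D/2 - s.
#: C3 sits just inside the active edge (the circle "closest to the plaque
#: edge") and C4 beyond the active surface; C1/C2 split the inner face.
RADII_TEMPLATE = (0.35, 0.625, 0.90, 1.25)
#: half-width of the per-circle search window, as a fraction of D/2 - s
RADII_WINDOW = (0.15, 0.125, 0.15, 0.20)


def calibrate_radii(
    model: PlaqueModel,
    kernel: KernelTable,
    nodes: SourceNodes,
    reference: pd.DataFrame,
    angles_used: Sequence[int] = (0, 45, 90),
    offset: float = 1.0,
    norm_depth: float = 1.0,
    prior_weight: float = 100.0,
    grid_step: float = 0.02,
) -> np.ndarray:
    """Estimate the four measurement-circle radii for one plaque.

    Each circle radius is searched over a window centered on a
    diameter-proportional template (``RADII_TEMPLATE`` fractions of the
    active radius), minimizing the squared difference between simulated and
    reference relative doses at the ``angles_used`` (non-notch) columns,
    plus a quadratic pull of weight ``prior_weight`` (%^2 per mm^2) toward
    the template center.  The relative-dose surface is radially flat over
    the inner plateau, so C1/C2 are only weakly identified by the non-notch
    columns and the template prior resolves the degeneracy there; C3/C4 sit
    on the steep lateral falloff and are data-determined.  C1 < C2 < C3 < C4
    is enforced sequentially; the search is a deterministic grid scan at
    ``grid_step`` mm.  Notch-direction columns (135/180 degrees) are never
    used, so they remain untouched validation data.
    """
    angles_used = tuple(angles_used)
    if set(angles_used) & {135, 180}:
        raise ValueError("calibration must not use notch-direction columns")
    cax_ref = dose_at_points(kernel, nodes, cax_points(model, [norm_depth]))[0]
    if cax_ref <= 0:
        raise ValueError("zero CAX reference dose")
    rs_sphere = model.params.R - offset
    r_act = model.outer_radius - model.params.s
    out: list[float] = []
    lo_prev = 0.0
    for circle in (1, 2, 3, 4):
        ref_vals = np.array([
            float(reference.loc[(reference["circle"] == circle)
                                & (reference["angle_deg"] == a), "mean_pct"].iloc[0])
            for a in angles_used
        ])
        center = RADII_TEMPLATE[circle - 1] * r_act
        half = RADII_WINDOW[circle - 1] * r_act
        lo = max(center - half, lo_prev + 0.05, 0.3)
        hi = min(center + half, rs_sphere - 0.05)
        if hi <= lo:
            raise ValueError(f"empty search window for circle {circle}")
        grid = np.arange(lo, hi + grid_step / 2, grid_step)
        phi = np.deg2rad(np.asarray(angles_used, dtype=float))
        xy = np.concatenate([
            np.column_stack([g * np.sin(phi), g * np.cos(phi)]) for g in grid
        ])
        z = -np.sqrt(rs_sphere**2 - (xy**2).sum(axis=1))
        sim = dose_at_points(kernel, nodes, np.column_stack([xy, z]))
        sim = (sim / cax_ref * 100.0).reshape(len(grid), len(angles_used))
        costs = ((sim - ref_vals[None, :]) ** 2).sum(axis=1)
        costs += prior_weight * (grid - center) ** 2
        out.append(float(grid[int(np.argmin(costs))]))
        lo_prev = out[-1]
    return np.asarray(out)


def cax_table(
    model: PlaqueModel,
    kernel: KernelTable,
    nodes: SourceNodes,
    depths: Sequence[float] = tuple(range(1, 11)),
    norm_depth: float = 2.0,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Relative central-axis depth doses normalized at ``norm_depth`` mm.

    If ``reference`` (columns depth_mm, reference_pct) is supplied, a
    difference column (simulated minus reference, percentage points) is added.
    """
    depths = np.asarray(depths, dtype=float)
    doses = dose_at_points(kernel, nodes, cax_points(model, depths))
    ref = dose_at_points(kernel, nodes, cax_points(model, [norm_depth]))[0]
    df = pd.DataFrame({"depth_mm": depths, "relative_pct": doses / ref * 100.0})
    if reference is not None:
        df = df.merge(reference, on="depth_mm", how="left")
        df["difference"] = df["relative_pct"] - df["reference_pct"]
    return df


def certificate_benchmark(
    kernel: KernelTable | None = None,
    resolution: float = 0.1,
    plaques: Sequence[str] = ("CIA", "CIB", "COB", "COC"),
) -> dict[str, dict]:
    """Full certificate comparison for every plaque, both parameter sets.

    For each plaque: build the modified and official models, calibrate the
    measurement-circle radii with the modified geometry on the non-notch
    reference columns, and produce both comparison tables with the same
    radii.  Returns ``{plaque: {"radii": ..., "modified": ComparisonTable,
    "official": ComparisonTable, "n_nodes": int}}``.  Deterministic.
    """
    from .dose import make_nodes
    from .io import get_params, load_reference
    from .geometry import build_plaque
    from .kernels import encapsulated_kernel

    if kernel is None:
        kernel = encapsulated_kernel()
    reference = load_reference()
    out: dict[str, dict] = {}
    for name in plaques:
        ref = reference[reference["plaque"] == name]
        modified = build_plaque(get_params(name, "modified"))
        official = build_plaque(get_params(name, "official"))
        nodes_mod = make_nodes(modified, resolution=resolution)
        nodes_off = make_nodes(official, resolution=resolution)
        radii = calibrate_radii(modified, kernel, nodes_mod, ref)
        out[name] = {
            "radii": radii,
            "modified": surface_table(modified, kernel, nodes_mod, radii, ref),
            "official": surface_table(official, kernel, nodes_off, radii, ref),
            "n_nodes": len(nodes_mod),
        }
    return out


@dataclass(frozen=True)
class PlanarDose:
    """Dose resampled on a (possibly tilted) plane; values[iy, ix]."""

    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)
    depth: float = 0.0
    tilt_notch: float = 0.0
    tilt_perp: float = 0.0


def extract_plane(
    grid,
    depth: float,
    R: float,
    tilt_notch: float = 0.0,
    tilt_perp: float = 0.0,
) -> PlanarDose:
    """Resample the grid on a plane at ``depth`` mm from the plaque apex.

    The plane is rotated about the apex (0, 0, -R): ``tilt_notch`` degrees
    about the x axis (tipping the plane along the notch direction y) and
    ``tilt_perp`` degrees about the y axis.  Trilinear resampling.
    """
    apex = np.array([0.0, 0.0, -R])
    x = grid.axis_coords(0)
    y = grid.axis_coords(1)
    X, Y = np.meshgrid(x, y)  # values[iy, ix]
    rel = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, depth)])
    tn, tp = np.deg2rad(tilt_notch), np.deg2rad(tilt_perp)
    rx = np.array([[1, 0, 0],
                   [0, np.cos(tn), -np.sin(tn)],
                   [0, np.sin(tn), np.cos(tn)]])
    ry = np.array([[np.cos(tp), 0, np.sin(tp)],
                   [0, 1, 0],
                   [-np.sin(tp), 0, np.cos(tp)]])
    pts = rel @ (rx @ ry).T + apex
    zmin, zmax = grid.origin[2], grid.origin[2] + grid.spacing * (grid.shape[2] - 1)
    if pts[:, 2].min() > zmax or pts[:, 2].max() < zmin:
        raise ValueError("requested plane lies outside the dose grid")
    vals = grid.interp(pts).reshape(Y.shape)
    return PlanarDose(x=x, y=y, values=vals, depth=depth,
                      tilt_notch=tilt_notch, tilt_perp=tilt_perp)


def isodose_contours(plane: PlanarDose, levels: Sequence[float]) -> dict[float, list]:
    """Marching-squares isodose polylines, in mm, per requested level.

    Levels outside the data range yield empty lists.
    """
    from skimage import measure

    out: dict[float, list] = {}
    dx = plane.x[1] - plane.x[0] if len(plane.x) > 1 else 1.0
    dy = plane.y[1] - plane.y[0] if len(plane.y) > 1 else 1.0
    for level in levels:
        polys = []
        if plane.values.min() < level < plane.values.max():
            for c in measure.find_contours(plane.values, level):
                xs = plane.x[0] + c[:, 1] * dx
                ys = plane.y[0] + c[:, 0] * dy
                polys.append(np.column_stack([xs, ys]))
        out[float(level)] = polys
    return out


def profile(plane: PlanarDose, axis: str = "x") -> tuple[np.ndarray, np.ndarray]:
    """1D lateral profile through the plane center along x or y."""
    if axis == "x":
        iy = np.argmin(np.abs(plane.y))
        return plane.x, plane.values[iy, :]
    if axis == "y":
        ix = np.argmin(np.abs(plane.x))
        return plane.y, plane.values[:, ix]
    raise ValueError("axis must be 'x' or 'y'")
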