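"""Dose engine: node generation, superposition, grids, normalization."""

import numpy as np
import pytest

import rutheye as re
from rutheye.dose import DEFAULT_T_ACTIVE, SourceNodes, dose_grid, make_nodes, normalize


def hand_nodes(positions, weights):
    positions = np.asarray(positions, dtype=float)
    return SourceNodes(positions=positions, weights=np.asarray(weights, dtype=float),
                       mode="quadrature", sphere_radius=0.0)


def test_three_node_hand_computed_oracle(toy_kernel):
    """Superposition over a 3-node toy source matches an explicit hand sum."""
    nodes = hand_nodes([[0, 0, 0], [3, 0, 0], [0, 4, 0]], [1.0, 2.0, 0.5])
    target = [[0, 0, 1]]  # distances: 1, sqrt(10), sqrt(17)
    d2, d3 = np.sqrt(10.0), np.sqrt(17.0)

    def loglin(r):  # hand-computed log-linear interpolation on the toy table
        rad, val = [1.0, 2.0, 4.0, 8.0], [8.0, 4.0, 2.0, 1.0]
        i = np.searchsorted(rad, r) - 1
        f = (r - rad[i]) / (rad[i + 1] - rad[i])
        return np.exp((1 - f) * np.log(val[i]) + f * np.log(val[i + 1]))

    expected = 1.0 * 8.0 + 2.0 * loglin(d2) + 0.5 * loglin(d3)
    got = re.dose_at_points(toy_kernel, nodes, target)[0]
    assert got == pytest.approx(expected, rel=1e-12)


def test_single_node_base_case(toy_kernel):
    nodes = hand_nodes([[0, 0, 0]], [1.0])
    assert re.dose_at_points(toy_kernel, nodes, [[2, 0, 0]])[0] == pytest.approx(4.0)


def test_linearity_of_split_sources(bare_kernel, cia_mod, cia_mod_nodes):
    half = len(cia_mod_nodes) // 2
    a = SourceNodes(cia_mod_nodes.positions[:half], cia_mod_nodes.weights[:half],
                    "quadrature", None, cia_mod_nodes.sphere_radius)
    b = SourceNodes(cia_mod_nodes.positions[half:], cia_mod_nodes.weights[half:],
                    "quadrature", None, cia_mod_nodes.sphere_radius)
    t = re.cax_points(cia_mod, [1.0, 3.0])
    full = re.dose_at_points(bare_kernel, cia_mod_nodes, t)
    assert np.allclose(re.dose_at_points(bare_kernel, a, t)
                       + re.dose_at_points(bare_kernel, b, t), full)


def test_targets_beyond_range_get_zero(bare_kernel, cia_mod_nodes):
    far = [[0.0, 0.0, 40.0]]
    assert re.dose_at_points(bare_kernel, cia_mod_nodes, far)[0] == 0.0


def test_quadrature_weights_sum_to_active_area(cia_mod, cia_mod_nodes):
    area = re.active_area(cia_mod, sphere_radius=cia_mod.params.R + DEFAULT_T_ACTIVE)
    assert cia_mod_nodes.weights.sum() == pytest.approx(area, rel=1e-3)
    assert np.all(re.is_active(cia_mod, cia_mod_nodes.positions[:, :2]))


def test_random_nodes_uniform_on_cap():
    model = re.build_plaque(re.PlaqueParams(name="CCB", D=15.3, R=12, s=0.0))
    n = 100_000
    nodes = make_nodes(model, mode="random", n=n, seed=11)
    z = nodes.positions[:, 2]
    rs = nodes.sphere_radius
    # equal-z bands on a sphere have equal area: octiles of cos(theta)
    cos_min = np.sqrt(1 - (model.outer_radius / rs) ** 2)
    edges = np.linspace(cos_min, 1.0, 9)
    counts, _ = np.histogram(-z / rs, bins=edges)
    expected = n / 8
    sigma = np.sqrt(n * (1 / 8) * (7 / 8))
    assert np.all(np.abs(counts - expected) < 3 * sigma)
    # azimuthal octants
    phi = np.arctan2(nodes.positions[:, 1], nodes.positions[:, 0])
    counts, _ = np.histogram(phi, bins=np.linspace(-np.pi, np.pi, 9))
    assert np.all(np.abs(counts - expected) < 3 * sigma)


def test_random_nodes_respect_cutout(cia_mod):
    nodes = make_nodes(cia_mod, mode="random", n=20_000, seed=3)
    con = cia_mod.construction
    d = np.linalg.norm(nodes.positions[:, :2] - np.asarray(con.notch_center), axis=1)
    assert np.all(d >= con.notch_radius)
    assert np.all(re.is_active(cia_mod, nodes.positions[:, :2]))


def test_random_mode_converges_to_quadrature(bare_kernel, cia_mod,
                                             cia_mod_nodes_fine):
    """Monte Carlo estimate agrees with quadrature within 3 standard errors."""
    target = re.cax_points(cia_mod, [1.0])
    ref = re.dose_at_points(bare_kernel, cia_mod_nodes_fine, target)[0]
    for n in (10_000, 100_000):
        nodes = make_nodes(cia_mod, mode="random", n=n, seed=5)
        est = re.dose_at_points(bare_kernel, nodes, target)[0]
        d = np.linalg.norm(nodes.positions - target[0], axis=1)
        contrib = bare_kernel(d)
        se = nodes.weights[0] * contrib.std() * np.sqrt(n)  # area/n * sd * sqrt(n)
        assert abs(est - ref) < 3 * se


def test_cax_monotone_beyond_1mm(bare_kernel, cia_mod, cia_mod_nodes):
    d = re.dose_at_points(bare_kernel, cia_mod_nodes,
                          re.cax_points(cia_mod, np.arange(1.0, 10.5, 0.5)))
    assert np.all(np.diff(d) < 0)


@pytest.fixture(scope="module")
def small_grid(bare_kernel, cia_mod, cia_mod_nodes):
    origin = (-6.0, -6.0, -12.1)
    return dose_grid(bare_kernel, cia_mod_nodes, origin, 0.5, (25, 25, 9))


def test_grid_matches_point_evaluation(bare_kernel, cia_mod_nodes, small_grid):
    idx = (12, 7, 4)
    center = small_grid.origin + small_grid.spacing * np.array(idx)
    direct = re.dose_at_points(bare_kernel, cia_mod_nodes, [center])[0]
    assert small_grid.values[idx] == pytest.approx(direct, rel=1e-12)


def test_grid_mirror_symmetry(small_grid):
    """Dose is mirror-symmetric across the notch plane x = 0 (< 0.5%)."""
    v = small_grid.values
    flipped = v[::-1, :, :]  # x axis reversed about the grid center
    denom = np.maximum(v.max(), 1e-12)
    assert np.max(np.abs(v - flipped)) / denom < 0.005


def test_grid_refinement_consistency(bare_kernel, cia_mod_nodes, small_grid):
    coarse = dose_grid(bare_kernel, cia_mod_nodes, small_grid.origin, 1.0,
                       (13, 13, 5))
    # shared centers: every other voxel of the fine grid
    assert np.allclose(coarse.values, small_grid.values[::2, ::2, ::2], rtol=1e-12)


def test_grid_save_load_round_trip(tmp_path, small_grid):
    path = tmp_path / "dose.grid"
    small_grid.save(path)
    loaded = re.DoseGrid.load(path)
    assert loaded.shape == small_grid.shape
    assert np.allclose(loaded.values, small_grid.values, rtol=1e-6)


def test_normalization_conventions(bare_kernel, cia_mod, cia_mod_nodes, small_grid):
    g1 = normalize(small_grid, cia_mod, bare_kernel, cia_mod_nodes, depth=1.0)
    ref_pt = [0.0, 0.0, -(cia_mod.params.R - 1.0)]
    assert g1.interp([ref_pt])[0] == pytest.approx(100.0, rel=0.02)
    g2 = normalize(small_grid, cia_mod, bare_kernel, cia_mod_nodes, depth=2.0)
    ratio = g2.values / np.maximum(g1.values, 1e-300)
    finite = small_grid.values > small_grid.values.max() * 1e-6
    assert np.allclose(ratio[finite], ratio[finite].flat[0])
    vals = np.array([1.0, 2.0, 4.0])
    out = normalize(vals, cia_mod, bare_kernel, cia_mod_nodes, depth=1.0)
    assert out[1] / out[0] == pytest.approx(2.0)


def test_make_nodes_errors(cia_mod):
    with pytest.raises(ValueError):
        make_nodes(cia_mod, resolution=-1.0)
    with pytest.raises(ValueError):
        make_nodes(cia_mod, mode="random", n=0)
    with pytest.raises(ValueError):
        make_nodes(cia_mod, mode="bogus")
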