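import numpy as np
import pytest

import phylogm as pg
from phylogm.superimposition import BendingEnergyModel, _slide_one, total_bending_energy


# ---------------------------------------------------------------------------
# centroid size
# ---------------------------------------------------------------------------


def test_centroid_size_unit_square():
    pts = np.array([[0.5, 0.5, 0], [0.5, -0.5, 0], [-0.5, 0.5, 0], [-0.5, -0.5, 0]])
    assert pg.centroid_size(pts) == pytest.approx(np.sqrt(2))


def test_centroid_size_homogeneous_and_matches_brute_force(rng):
    conf = rng.standard_normal((60, 3))
    cs = pg.centroid_size(conf)
    assert pg.centroid_size(conf * 3.5) == pytest.approx(3.5 * cs)
    brute = np.sqrt(sum(np.sum((p - conf.mean(axis=0)) ** 2) for p in conf))
    assert cs == pytest.approx(brute)


def test_centroid_size_degenerate():
    with pytest.raises(ValueError, match="degenerate"):
        pg.centroid_size(np.ones((5, 3)))


# ---------------------------------------------------------------------------
# GPA
# ---------------------------------------------------------------------------


def _rigid_copy(conf, rng, scale=2.0):
    M = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(M)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return scale * conf @ Q + rng.uniform(-5, 5, 3)


def test_gpa_identical_configurations(rng):
    conf = rng.standard_normal((10, 3))
    land = pg.LandmarkSet(["a", "b"], np.stack([conf, conf]))
    aligned = pg.gpa(land)
    assert np.allclose(aligned.coords[0], aligned.coords[1], atol=1e-10)
    centered = conf - conf.mean(axis=0)
    centered /= np.linalg.norm(centered)
    assert pg.procrustes_distance(aligned.consensus, centered) < 1e-8


def test_gpa_removes_rigid_motion_and_scale(rng):
    conf = rng.standard_normal((12, 3))
    land = pg.LandmarkSet(["a", "b"], np.stack([conf, _rigid_copy(conf, rng)]))
    aligned = pg.gpa(land)
    assert np.linalg.norm(aligned.coords[0] - aligned.coords[1]) < 1e-8


def test_gpa_planar_triangles_match_rotation_grid_oracle(rng):
    """Full Procrustes distances between planar triangles agree with a
    brute-force minimisation over the SO(2) rotation angle."""

    def brute_distance(a, b):
        A = a - a.mean(axis=0)
        B = b - b.mean(axis=0)
        A /= np.linalg.norm(A)
        B /= np.linalg.norm(B)
        best = np.inf
        angles = np.linspace(0, 2 * np.pi, 3600, endpoint=False)
        for _ in range(3):  # refine grid around the best angle
            ds = []
            for th in angles:
                R = np.array(
                    [
                        [np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0],
                        [0, 0, 1],
                    ]
                )
                ds.append(np.linalg.norm(A @ R - B))
            i = int(np.argmin(ds))
            best = min(best, ds[i])
            width = angles[1] - angles[0]
            angles = np.linspace(angles[i] - width, angles[i] + width, 200)
        return best

    tris = [np.column_stack([rng.standard_normal((3, 2)), np.zeros(3)]) for _ in range(3)]
    for i in range(3):
        for j in range(i + 1, 3):
            assert pg.procrustes_distance(tris[i], tris[j]) == pytest.approx(
                brute_distance(tris[i], tris[j]), abs=1e-6
            )


def test_gpa_order_invariance_and_centering(rng):
    coords = rng.standard_normal((6, 9, 3))
    land = pg.LandmarkSet([f"s{i}" for i in range(6)], coords)
    a1 = pg.gpa(land)
    perm = [3, 0, 5, 1, 4, 2]
    a2 = pg.gpa(pg.LandmarkSet([f"s{i}" for i in perm], coords[perm]))
    d = min(
        np.linalg.norm(a1.consensus - a2.consensus),
        np.linalg.norm(a1.consensus + a2.consensus),
    )
    assert pg.procrustes_distance(a1.consensus, a2.consensus) < 1e-8 or d < 1e-8
    assert np.abs(a1.coords.mean(axis=1)).max() < 1e-10


# ---------------------------------------------------------------------------
# bending energy
# ---------------------------------------------------------------------------


def test_bending_energy_form_is_psd_and_affine_null(rng):
    ref = rng.standard_normal((20, 3))
    be = BendingEnergyModel(ref)
    w = np.linalg.eigvalsh(be.bending_energy)
    assert w.min() > -1e-9
    assert np.allclose(be.bending_energy, be.bending_energy.T)
    A = rng.standard_normal((3, 3))
    b = rng.standard_normal(3)
    assert abs(be.energy(ref @ A + b)) < 1e-9
    assert be.energy(ref) == 0.0
    assert be.energy(ref + 0.1 * rng.standard_normal((20, 3))) > 0


# ---------------------------------------------------------------------------
# sliding
# ---------------------------------------------------------------------------


def test_slide_zero_displacement_at_reference(tiny_dataset):
    tpl = tiny_dataset.template
    be = BendingEnergyModel(tpl.coords)
    out = _slide_one(tpl.coords, tpl.coords, be, tpl.sliders.triples)
    assert np.allclose(out, tpl.coords, atol=1e-8)


def test_slide_one_semilandmark_matches_grid_search(rng):
    """5-point toy with a single slider: the closed-form tangent
    displacement agrees with a dense 1-D grid search."""
    ref = np.array(
        [[0, 0, 0], [1, 0, 0.3], [2, 0, 0], [1, 1, 0.6], [1, -1, 1.0]], dtype=float
    )
    config = ref.copy()
    config[1] = [0.7, 0.25, 0.1]  # displaced slider between points 0 and 2
    triples = np.array([[0, 1, 2]])
    be = BendingEnergyModel(ref)
    out = _slide_one(config, ref, be, triples, ridge=0.0)
    tangent = config[2] - config[0]
    tangent /= np.linalg.norm(tangent)
    ts = np.linspace(-2, 2, 40001)
    energies = []
    for t in ts:
        c = config.copy()
        c[1] += t * tangent
        energies.append(be.energy(c))
    t_best = ts[int(np.argmin(energies))]
    expected = config.copy()
    expected[1] += t_best * tangent
    assert np.allclose(out, expected, atol=1e-3)
    assert be.energy(out) <= min(energies) + 1e-10


def test_sliding_never_increases_total_bending_energy(tiny_dataset):
    raw = pg.simulate_landmarks(tiny_dataset, np.random.default_rng(3))
    pre = total_bending_energy(raw)
    slid = pg.slide_semilandmarks(raw, tiny_dataset.template.sliders)
    assert total_bending_energy(slid) <= pre + 1e-12


# ---------------------------------------------------------------------------
# symmetric component
# ---------------------------------------------------------------------------


def _mirror(coords, sym, axis=0):
    swap = np.arange(coords.shape[-2])
    swap[sym.pairs[:, 0]] = sym.pairs[:, 1]
    swap[sym.pairs[:, 1]] = sym.pairs[:, 0]
    out = coords.copy()
    out[..., axis] *= -1
    return out[..., swap, :]


def test_symmetric_configuration_is_its_own_symmetric_component(tiny_dataset, rng):
    tpl = tiny_dataset.template
    # template is exactly bilaterally symmetric; add symmetric noise only
    noise = rng.standard_normal((2,) + tpl.coords.shape) * 0.05
    noise = (noise + _mirror(noise, tpl.symmetry)) / 2
    coords = tpl.coords[None] + noise
    land = pg.LandmarkSet(["a", "b"], coords, tpl.point_roles, tpl.curve_membership)
    aligned = pg.symmetric_component(land, tpl.symmetry)
    plain = pg.gpa(land)
    for i in range(2):
        assert pg.procrustes_distance(aligned.coords[i], plain.coords[i]) < 1e-8


def test_symmetric_component_output_is_bilaterally_symmetric(tiny_dataset, rng):
    tpl = tiny_dataset.template
    coords = tpl.coords[None] + rng.standard_normal((3,) + tpl.coords.shape) * 0.08
    land = pg.LandmarkSet(["a", "b", "c"], coords, tpl.point_roles, tpl.curve_membership)
    aligned = pg.symmetric_component(land, tpl.symmetry, axis=0)
    for i in range(3):
        mirrored = _mirror(aligned.coords[i], tpl.symmetry)
        assert pg.procrustes_distance(aligned.coords[i], mirrored) < 1e-8


def test_symmetric_component_invariant_to_left_right_labelling(tiny_dataset, rng):
    tpl = tiny_dataset.template
    coords = tpl.coords[None] + rng.standard_normal((2,) + tpl.coords.shape) * 0.05
    land = pg.LandmarkSet(["a", "b"], coords, tpl.point_roles, tpl.curve_membership)
    sym_swapped = pg.SymmetryMap(tpl.symmetry.pairs[:, ::-1], tpl.symmetry.midline)
    a1 = pg.symmetric_component(land, tpl.symmetry, axis=0)
    a2 = pg.symmetric_component(land, sym_swapped, axis=0)
    assert np.allclose(a1.coords, a2.coords, atol=1e-10)
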