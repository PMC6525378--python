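import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phylogm as pg
from phylogm.data_io import ParseError


# ---------------------------------------------------------------------------
# landmark reading / writing
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("fmt", ["matrix", "tps"])
def test_landmark_round_trip_is_bit_identical(tmp_path, rng, fmt):
    coords = rng.standard_normal((3, 7, 3)) * 40
    land = pg.LandmarkSet(["a", "b", "c"], coords)
    path = tmp_path / "lms.txt"
    pg.write_landmarks(land, path, fmt=fmt)
    back = pg.read_landmarks(path, n_fixed=7, n_semi=0, specimen_ids=["a", "b", "c"])
    assert back.n_specimens == 3
    assert np.array_equal(back.coords, coords)


def test_read_landmarks_two_specimens_sixty_points(tmp_path, rng):
    coords = rng.standard_normal((2, 60, 3))
    pg.write_landmarks(pg.LandmarkSet(["x", "y"], coords), tmp_path / "f.txt")
    land = pg.read_landmarks(tmp_path / "f.txt", n_fixed=20, n_semi=40)
    assert land.n_specimens == 2 and land.n_points == 60
    assert (land.point_roles == "semilandmark").sum() == 40


def test_read_landmarks_errors(tmp_path):
    empty = tmp_path / "empty.txt"
    empty.write_text("")
    with pytest.raises(ParseError, match="no specimens"):
        pg.read_landmarks(empty, 20, 40)
    short = tmp_path / "short.txt"
    short.write_text("1 2 3\n" * 59)
    with pytest.raises(ParseError, match="specimen 1"):
        pg.read_landmarks(short, 20, 40)
    bad = tmp_path / "bad.txt"
    bad.write_text("1 2 3\n1 x 3\n")
    with pytest.raises(ParseError, match="line 2"):
        pg.read_landmarks(bad, 1, 1)


def test_tps_blocks_carry_ids(tmp_path, rng):
    coords = rng.standard_normal((2, 4, 3))
    land = pg.LandmarkSet(["Ara macao", "Nestor notabilis"], coords)
    pg.write_landmarks(land, tmp_path / "t.tps", fmt="tps")
    back = pg.read_landmarks(tmp_path / "t.tps", 4, 0)
    assert back.specimen_ids == ["Ara macao", "Nestor notabilis"]


# ---------------------------------------------------------------------------
# curve resampling
# ---------------------------------------------------------------------------


def test_resample_straight_line_equal_spacing():
    pts = np.column_stack([np.arange(11.0), np.zeros(11), np.zeros(11)])
    out = pg.resample_curve(pts[:10], 10)
    assert np.allclose(out[:, 0], np.arange(10.0))


def test_resample_k2_returns_endpoints(rng):
    pts = np.cumsum(rng.random((8, 3)), axis=0)
    out = pg.resample_curve(pts, 2)
    assert np.allclose(out, pts[[0, -1]])


def test_resample_l_shape_corner():
    # arc length 2; midpoint of an L-shaped polyline is the corner
    pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float)
    out = pg.resample_curve(pts, 3)
    assert np.allclose(out[1], [1, 0, 0])


def test_resample_zero_length_errors():
    with pytest.raises(ValueError, match="zero length"):
        pg.resample_curve(np.zeros((3, 3)), 5)


@settings(max_examples=40, deadline=None)
@given(
    xs=st.lists(st.floats(0.01, 2.0), min_size=2, max_size=12),
    k=st.integers(3, 15),
)
def test_resample_spacings_equal_for_monotone_polylines(xs, k):
    pts = np.column_stack([np.cumsum(xs), np.zeros(len(xs)), np.zeros(len(xs))])
    pts = np.vstack([[0, 0, 0], pts])
    out = pg.resample_curve(pts, k)
    gaps = np.linalg.norm(np.diff(out, axis=0), axis=1)
    assert np.allclose(gaps, gaps[0], rtol=1e-9)


# ---------------------------------------------------------------------------
# diet recoding
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "raw,expected",
    [("plant/seed", "MMR"), ("omnivore", "mixed"), ("fruit/nectar", "LMR")],
)
def test_recode_diet(raw, expected):
    assert pg.recode_diet(raw) == expected


def test_recode_diet_unknown_lists_accepted():
    with pytest.raises(ValueError, match="plant/seed"):
        pg.recode_diet("granivore")


def test_recode_diet_surjective():
    assert {pg.recode_diet(c) for c in ["plant/seed", "omnivore", "fruit/nectar"]} == {
        "MMR",
        "mixed",
        "LMR",
    }


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def test_read_tree_two_tips(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("(A:1,B:1);\n")
    phy = pg.read_tree(p, ["A", "B"])
    assert np.allclose(np.diag(phy.C), [1, 1])


def test_read_tree_pruning_preserves_path_lengths(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((A:1,B:1):1,C:2);\n")
    phy = pg.read_tree(p, ["A", "C"])
    assert phy.n_tips == 2
    assert np.allclose(np.diag(phy.C), [2, 2])


def test_read_tree_missing_tip_is_hard_error(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("(A:1,B:1);\n")
    with pytest.raises(ValueError, match="Zeta"):
        pg.read_tree(p, ["A", "Zeta"])


def test_read_tree_name_normalization(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("(Ara_macao:1,Nestor_notabilis:1);\n")
    phy = pg.read_tree(p, ["ara macao", "NESTOR NOTABILIS"])
    assert phy.tip_order == ["ara macao", "NESTOR NOTABILIS"]


# ---------------------------------------------------------------------------
# sliders, symmetry pairs, metadata
# ---------------------------------------------------------------------------


def test_read_sliders_skips_header_and_converts_to_zero_based(tmp_path):
    p = tmp_path / "sliders.txt"
    p.write_text("before slide after\n1 2 3\n2 3 4\n")
    sl = pg.read_sliders(p)
    assert np.array_equal(sl.triples, [[0, 1, 2], [1, 2, 3]])


def test_symmetry_map_must_cover_all_points(tmp_path):
    p = tmp_path / "pairs.txt"
    p.write_text("1 2\n")
    sym = pg.read_symmetry_pairs(p, n_points=4)
    assert set(sym.midline.tolist()) == {2, 3}
    with pytest.raises(ValueError, match="exactly once"):
        pg.data_io.SymmetryMap(np.array([[0, 1]]), np.array([1, 2])).validate(3)


def test_read_metadata_recodes_and_validates(tmp_path):
    p = tmp_path / "meta.csv"
    p.write_text("species,clade,diet\nA,cockatoo,plant/seed\nB,lory,fruit/nectar\n")
    meta = pg.read_metadata(p, recode=True)
    assert list(meta["diet"]) == ["MMR", "LMR"]
    bad = tmp_path / "bad.csv"
    bad.write_text("species,clade,diet\nA,cockatoo,granivore\n")
    with pytest.raises(ValueError):
        pg.read_metadata(bad, recode=True)
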