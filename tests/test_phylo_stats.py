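import numpy as np
import pandas as pd
import pytest

import phylogm as pg


# ---------------------------------------------------------------------------
# phylogenetic covariance and transform
# ---------------------------------------------------------------------------


def test_phylo_cov_two_tips_identity():
    phy = pg.Phylogeny.from_newick("(A:1,B:1);", ["A", "B"])
    assert np.allclose(phy.C, np.eye(2))


def test_phylo_cov_three_tips_path_enumeration():
    phy = pg.Phylogeny.from_newick("((A:1,B:1):1,C:2);", ["A", "B", "C"])
    assert np.allclose(phy.C, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])


def test_phylo_cov_ultrametric_constant_diagonal(tree50):
    d = np.diag(tree50.C)
    assert np.allclose(d, d[0], atol=1e-10)
    w = np.linalg.eigvalsh(tree50.C)
    assert w.min() > -1e-10  # positive semi-definite


@pytest.mark.parametrize("C,expected", [(np.eye(3), np.eye(3)), (4 * np.eye(3), 0.5 * np.eye(3))])
def test_phylo_transform_scalar_cases(C, expected):
    assert np.allclose(pg.phylo_transform(C), expected)


def test_phylo_transform_whitens_random_spd(rng):
    M = rng.standard_normal((5, 5))
    C = M @ M.T + 5 * np.eye(5)
    P = pg.phylo_transform(C)
    assert np.allclose(P @ C @ P.T, np.eye(5), atol=1e-10)


def test_phylo_transform_rejects_singular():
    C = np.ones((3, 3))
    with pytest.raises(ValueError, match="eigenvalue"):
        pg.phylo_transform(C)


# ---------------------------------------------------------------------------
# Kmult
# ---------------------------------------------------------------------------


def test_kmult_near_one_under_brownian_motion(tree50):
    rng = np.random.default_rng(0)
    L = np.linalg.cholesky(tree50.C)
    ks = [pg.kmult_statistic(L @ rng.standard_normal((50, 20)), tree50.C) for _ in range(200)]
    assert 0.9 <= np.mean(ks) <= 1.1


def test_kmult_low_and_nonsignificant_for_tree_independent_data(tree50):
    rng = np.random.default_rng(1)
    Y = rng.standard_normal((50, 20))
    res = pg.kmult(Y, tree50, n_perm=999, seed=11)
    assert res.observed < 0.5
    assert res.p > 0.05


def test_kmult_invariant_to_branch_length_rescaling(tree50, rng):
    Y = rng.standard_normal((50, 8))
    k1 = pg.kmult_statistic(Y, tree50.C)
    k2 = pg.kmult_statistic(Y, 7.3 * tree50.C)
    assert k1 == pytest.approx(k2, rel=1e-10)


def test_kmult_requires_three_tips():
    with pytest.raises(ValueError, match="3 tips"):
        pg.kmult(np.zeros((2, 4)), C=np.eye(2), n_perm=9)


def test_kmult_p_floor_and_reproducibility(tree50):
    rng = np.random.default_rng(2)
    L = np.linalg.cholesky(tree50.C)
    Y = L @ rng.standard_normal((50, 10))
    r1 = pg.kmult(Y, tree50, n_perm=99, seed=5)
    r2 = pg.kmult(Y, tree50, n_perm=99, seed=5)
    assert r1.p == r2.p and np.array_equal(r1.null_values, r2.null_values)
    assert r1.p >= 1 / 100


# ---------------------------------------------------------------------------
# Procrustes linear models
# ---------------------------------------------------------------------------


def _toy_data(rng, n=40):
    logcs = rng.standard_normal(n)
    diet = rng.choice(["MMR", "mixed", "LMR"], n)
    return pd.DataFrame({"logCS": logcs, "diet": diet})


def test_lm_constant_response_errors(rng):
    data = _toy_data(rng)
    with pytest.raises(ValueError, match="constant"):
        pg.procrustes_lm(np.ones((40, 6)), data, ["logCS"], n_perm=0)


def test_lm_perfect_allometry_gives_unit_r2(rng):
    data = _toy_data(rng)
    beta = rng.standard_normal(9)
    Y = np.outer(data["logCS"], beta)
    fit = pg.procrustes_lm(Y, data, ["logCS"], n_perm=0)
    assert fit.R2[0] == pytest.approx(1.0, abs=1e-10)
    assert fit.SS_residual == pytest.approx(0.0, abs=1e-9)


def test_lm_sequential_ss_partitions_total(rng):
    data = _toy_data(rng)
    Y = rng.standard_normal((40, 15))
    fit = pg.procrustes_lm(Y, data, ["logCS", "diet"], n_perm=0)
    assert fit.SS.sum() + fit.SS_residual == pytest.approx(fit.SS_total, rel=1e-8)
    assert np.all((fit.R2 >= 0) & (fit.R2 <= 1))


def test_lm_term_r2_invariant_to_factor_relabelling(rng):
    data = _toy_data(rng)
    Y = rng.standard_normal((40, 12))
    fit1 = pg.procrustes_lm(Y, data, ["logCS", "diet"], n_perm=0)
    relabel = {"MMR": "zz_hard", "mixed": "aa_mixed", "LMR": "mm_soft"}
    data2 = data.assign(diet=data["diet"].map(relabel))
    fit2 = pg.procrustes_lm(Y, data2, ["logCS", "diet"], n_perm=0)
    assert np.allclose(fit1.R2, fit2.R2, atol=1e-10)
    assert np.allclose(fit1.F, fit2.F, atol=1e-8)


def test_lm_rank_deficient_design_errors(rng):
    data = _toy_data(rng)
    data["dup"] = data["logCS"]
    with pytest.raises(ValueError, match="rank"):
        pg.procrustes_lm(np.random.default_rng(0).standard_normal((40, 6)), data, ["logCS", "dup"], n_perm=0)


def test_pgls_equals_ols_on_star_tree(rng):
    data = _toy_data(rng, n=30)
    Y = rng.standard_normal((30, 12))
    ols = pg.procrustes_lm(Y, data, ["logCS", "diet"], n_perm=0)
    star = np.eye(30)
    pgls = pg.procrustes_pgls(Y, data, ["logCS", "diet"], C=star, n_perm=0)
    assert np.allclose(ols.F, pgls.F, atol=1e-8)
    assert np.allclose(ols.R2, pgls.R2, atol=1e-8)


def test_pgls_scale_invariant_in_C(rng):
    data = _toy_data(rng, n=30)
    Y = rng.standard_normal((30, 12))
    f1 = pg.procrustes_pgls(Y, data, ["logCS", "diet"], C=np.eye(30), n_perm=0)
    f2 = pg.procrustes_pgls(Y, data, ["logCS", "diet"], C=9.0 * np.eye(30), n_perm=0)
    assert np.allclose(f1.R2, f2.R2, atol=1e-10)


def test_pgls_residuals_orthogonal_in_transformed_metric(tree50, rng):
    L = np.linalg.cholesky(tree50.C)
    Y = L @ rng.standard_normal((50, 9))
    data = pd.DataFrame({"logCS": rng.standard_normal(50)})
    fit = pg.procrustes_pgls(Y, data, ["logCS"], phy=tree50, n_perm=0)
    P = pg.phylo_transform(tree50.C)
    Rt = P @ fit.residuals
    Xt = P @ np.column_stack([np.ones(50), data["logCS"]])
    assert np.abs(Xt.T @ Rt).max() < 1e-8


def test_rrpp_p_values_reproducible_and_floored(rng):
    data = _toy_data(rng, n=25)
    Y = np.outer(data["logCS"], rng.standard_normal(6)) + 0.1 * rng.standard_normal((25, 6))
    f1 = pg.procrustes_lm(Y, data, ["logCS"], n_perm=999, seed=3)
    f2 = pg.procrustes_lm(Y, data, ["logCS"], n_perm=999, seed=3)
    assert f1.p_perm[0] == f2.p_perm[0]
    assert f1.p_perm[0] == pytest.approx(1 / 1000)


# ---------------------------------------------------------------------------
# phylogenetic PLS
# ---------------------------------------------------------------------------


def test_pls_duplicated_block_gives_unit_rpls(tree50, rng):
    L = np.linalg.cholesky(tree50.C)
    Y = L @ rng.standard_normal((50, 8))
    res = pg.phylo_pls(Y, Y.copy(), tree50, n_perm=0)
    assert res.rPLS == pytest.approx(1.0, abs=1e-10)


def test_pls_independent_blocks_nonsignificant_on_star_tree():
    rng = np.random.default_rng(8)
    Y1 = rng.standard_normal((100, 12))
    Y2 = rng.standard_normal((100, 12))
    res = pg.phylo_pls(Y1, Y2, C=np.eye(100), n_perm=999, seed=21)
    assert res.p_perm > 0.05


def test_rpls_invariant_to_block_rotation(tree50, rng):
    L = np.linalg.cholesky(tree50.C)
    Y1 = L @ rng.standard_normal((50, 6))
    Y2 = 0.5 * Y1[:, ::-1] + L @ rng.standard_normal((50, 6))
    base = pg.phylo_pls(Y1, Y2, tree50, n_perm=0).rPLS
    Q1, _ = np.linalg.qr(rng.standard_normal((6, 6)))
    Q2, _ = np.linalg.qr(rng.standard_normal((6, 6)))
    rot = pg.phylo_pls(Y1 @ Q1, Y2 @ Q2, tree50, n_perm=0).rPLS
    assert rot == pytest.approx(base, abs=1e-8)


def test_pls_singular_values_non_increasing_and_r_bounded(tree50, rng):
    L = np.linalg.cholesky(tree50.C)
    Y1 = L @ rng.standard_normal((50, 7))
    Y2 = L @ rng.standard_normal((50, 5))
    res = pg.phylo_pls(Y1, Y2, tree50, n_perm=0)
    assert np.all(np.diff(res.singular_values) <= 1e-12)
    assert -1 <= res.rPLS <= 1


def test_pls_rejects_single_column_block(tree50):
    with pytest.raises(ValueError, match="2 columns"):
        pg.phylo_pls(np.zeros((50, 1)), np.zeros((50, 4)), tree50, n_perm=0)
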