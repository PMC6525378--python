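"""Phylogenetic comparative statistics for multivariate shape data.

Implements the Brownian-motion phylogenetic covariance matrix and the
statistics built on it: the multivariate phylogenetic-signal ratio K
(Blomberg's K generalised to high-dimensional traits), Procrustes linear
and phylogenetic generalised least squares (PGLS) regression with
residual-randomisation permutation tests (RRPP), and two-block
within-configuration phylogenetic partial least squares (PLS).

All permutation tests draw from a :class:`numpy.random.Generator` seeded
explicitly, report ``p = (b + 1) / (n_perm + 1)`` where ``b`` counts null
statistics at least as extreme as the observed one, and are bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Phylogeny container
# ---------------------------------------------------------------------------


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths and a fixed tip ordering.

    The phylogenetic covariance matrix ``C`` has ``C[i, j]`` equal to the
    root-to-MRCA path length of tips *i* and *j* (so the diagonal holds
    root-to-tip distances), which is the tip covariance implied by Brownian
    motion with unit rate.
    """

    tree: dendropy.Tree
    tip_order: list[str]

    def __post_init__(self) -> None:
        self._C: np.ndarray | None = None

    @classmethod
    def from_newick(cls, newick: str, tip_order: list[str] | None = None) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
        return cls(tree, tip_order if tip_order is not None else tips)

    @property
    def n_tips(self) -> int:
        return len(self.tip_order)

    @property
    def C(self) -> np.ndarray:
        if self._C is None:
            self._C = phylo_cov(self)
        return self._C

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def prune_to(self, tips: list[str]) -> "Phylogeny":
        """Return a copy pruned to ``tips`` (order preserved as given)."""
        missing = [t for t in tips if t not in self.tip_order]
        if missing:
            raise ValueError(f"tips not in tree: {missing}")
        tree = self.tree.clone(depth=1)
        keep = set(tips)
        taxa = [tx for tx in tree.taxon_namespace if tx.label in keep]
        tree.retain_taxa(taxa)
        return Phylogeny(tree, list(tips))


def phylo_cov(phy: Phylogeny) -> np.ndarray:
    """Brownian-motion tip covariance: shared root-to-MRCA path lengths."""
    tree = phy.tree
    if tree.seed_node is None:
        raise ValueError("tree must be rooted")
    # depth of every node measured from the root
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        el = node.edge.length or 0.0
        depth[id(node)] = (depth[id(parent)] if parent is not None else 0.0) + (
            el if parent is not None else 0.0
        )
    # map each tip label to its leaf node
    leaf_by_label = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    missing = [t for t in phy.tip_order if t not in leaf_by_label]
    if missing:
        raise ValueError(f"tip_order labels missing from tree: {missing}")
    n = phy.n_tips
    # bitmask-based MRCA lookup via dendropy
    pdm = tree.phylogenetic_distance_matrix()
    C = np.zeros((n, n))
    for i, a in enumerate(phy.tip_order):
        ta = leaf_by_label[a].taxon
        C[i, i] = depth[id(leaf_by_label[a])]
        for j in range(i + 1, n):
            tb = leaf_by_label[phy.tip_order[j]].taxon
            mrca = pdm.mrca(ta, tb)
            C[i, j] = C[j, i] = depth[id(mrca)]
    return C


def phylo_transform(C: np.ndarray) -> np.ndarray:
    """Inverse square root ``P`` of an SPD covariance, with ``P C P' = I``.

    Pre-multiplying data and design by ``P`` turns the GLS problem with
    residual covariance proportional to ``C`` into ordinary least squares.
    """
    C = np.asarray(C, dtype=float)
    w, V = np.linalg.eigh((C + C.T) / 2.0)
    if w.min() <= 0:
        raise ValueError(f"C is not positive definite (smallest eigenvalue {w.min():.3e})")
    return (V / np.sqrt(w)) @ V.T


def _gls_mean(Y: np.ndarray, Cinv: np.ndarray) -> np.ndarray:
    one = np.ones(Y.shape[0])
    w = Cinv @ one
    return (w @ Y) / (one @ w)


# ---------------------------------------------------------------------------
# Permutation-test result
# ---------------------------------------------------------------------------


@dataclass
class PermutationTestResult:
    observed: float
    null_values: np.ndarray
    p: float
    n_perm: int
    seed: int | None = None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PermutationTestResult(observed={self.observed:.4g}, p={self.p:.4g}, n_perm={self.n_perm})"


# ---------------------------------------------------------------------------
# Kmult
# ---------------------------------------------------------------------------


def kmult_statistic(Y: np.ndarray, C: np.ndarray, _Cinv: np.ndarray | None = None) -> float:
    """Multivariate phylogenetic-signal ratio K.

    The ratio of the mean squared tip deviation from the phylogenetic GLS
    mean to the phylogenetically corrected mean squared deviation, divided
    by its expectation under Brownian motion,
    ``(tr(C) - n / (1' C^-1 1)) / (n - 1)``.  K is about 1 for data evolved
    by Brownian motion on the tree, below 1 when relatives resemble each
    other less than Brownian motion predicts.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = Y.shape[0]
    Cinv = np.linalg.inv(C) if _Cinv is None else _Cinv
    one = np.ones(n)
    a = _gls_mean(Y, Cinv)
    D = Y - one[:, None] * a
    num = float(np.sum(D * D))
    den = float(np.sum(D * (Cinv @ D)))
    expectation = (np.trace(C) - n / (one @ Cinv @ one)) / (n - 1)
    return (num / den) / expectation


def kmult(
    Y: np.ndarray,
    phy: Phylogeny | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    C: np.ndarray | None = None,
) -> PermutationTestResult:
    """Permutation test of multivariate phylogenetic signal.

    The null distribution permutes tip identities (rows of ``Y``) relative
    to the tree; ``p`` is the upper-tail probability of the observed K.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] < 3:
        raise ValueError("kmult requires at least 3 tips")
    if C is None:
        if phy is None:
            raise ValueError("either phy or C must be given")
        C = phy.C
    Cinv = np.linalg.inv(C)
    obs = kmult_statistic(Y, C, _Cinv=Cinv)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = kmult_statistic(Y[rng.permutation(Y.shape[0])], C, _Cinv=Cinv)
    p = (np.sum(null >= obs) + 1) / (n_perm + 1)
    return PermutationTestResult(obs, null, float(p), n_perm, seed)


# ---------------------------------------------------------------------------
# Procrustes linear models (OLS and PGLS) with RRPP
# ---------------------------------------------------------------------------


@dataclass
class GLSModelFit:
    """Sequential (Type I) multivariate linear-model fit in trace form.

    ``SS[k]`` is the reduction in residual sum of squares when term *k* is
    added to the model containing all earlier terms; ``R2[k] = SS[k] /
    SS_total`` where ``SS_total`` is the residual SS of the intercept-only
    model (in the GLS-transformed metric for PGLS fits).
    """

    terms: list[str]
    SS: np.ndarray
    df: np.ndarray
    F: np.ndarray
    R2: np.ndarray
    SS_total: float
    SS_residual: float
    df_residual: int
    coefficients: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    p_perm: np.ndarray | None = None
    n_perm: int = 0
    seed: int | None = None
    term_columns: list[np.ndarray] = field(default_factory=list, repr=False)

    def table(self) -> pd.DataFrame:
        rows = {
            "term": self.terms,
            "df": self.df,
            "SS": self.SS,
            "F": self.F,
            "R2": self.R2,
        }
        if self.p_perm is not None:
            rows["p"] = self.p_perm
        return pd.DataFrame(rows)


def design_matrix(data: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[np.ndarray]]:
    """Build [intercept | term blocks] with treatment contrasts.

    Categorical terms use the alphabetically first level as reference.
    Returns the full matrix and the per-term column index arrays (the
    intercept is block 0).
    """
    cols: list[np.ndarray] = [np.ones((len(data), 1))]
    blocks: list[np.ndarray] = [np.array([0])]
    start = 1
    for t in terms:
        v = data[t]
        if pd.api.types.is_numeric_dtype(v):
            X = np.asarray(v, dtype=float)[:, None]
        else:
            levels = sorted(pd.unique(v.astype(str)))
            X = np.column_stack([(v.astype(str) == lv).astype(float) for lv in levels[1:]])
            if X.shape[1] == 0:
                raise ValueError(f"term '{t}' has a single level; design is rank-deficient")
        cols.append(X)
        blocks.append(np.arange(start, start + X.shape[1]))
        start += X.shape[1]
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design for terms {terms}")
    return X, blocks


def _hat(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


def _sequential_fit(
    Y: np.ndarray,
    X: np.ndarray,
    blocks: list[np.ndarray],
    term_names: list[str],
    n_perm: int,
    rng: np.random.Generator | None,
) -> GLSModelFit:
    """Shared engine for OLS and (pre-transformed) PGLS sequential fits.

    Block 0 of ``X`` is the intercept; SS_total is the residual SS after
    fitting it alone.  RRPP permutes, for each term, the residual rows of
    the reduced model containing all earlier terms.
    """
    n = Y.shape[0]
    k = len(term_names)
    # nested hat matrices H_0 (intercept) .. H_k (full)
    hats = []
    for j in range(len(blocks)):
        idx = np.concatenate(blocks[: j + 1])
        hats.append(_hat(X[:, idx]))
    H_full = hats[-1]
    I = np.eye(n)
    SS_total = float(np.sum(((I - hats[0]) @ Y) ** 2))
    if SS_total <= 1e-14 * max(1.0, float(np.sum(Y * Y))):
        raise ValueError("total sum of squares is zero: response is constant")
    SSE = float(np.sum(((I - H_full) @ Y) ** 2))
    df_res = n - sum(len(b) for b in blocks)
    SS = np.empty(k)
    df = np.empty(k, dtype=int)
    for j in range(k):
        P = hats[j + 1] - hats[j]
        SS[j] = float(np.sum((P @ Y) ** 2))
        df[j] = len(blocks[j + 1])
    F = (SS / df) / (SSE / df_res)
    R2 = SS / SS_total
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ beta
    fit = GLSModelFit(
        terms=list(term_names),
        SS=SS,
        df=df,
        F=F,
        R2=R2,
        SS_total=SS_total,
        SS_residual=SSE,
        df_residual=df_res,
        coefficients=beta,
        fitted=fitted,
        residuals=Y - fitted,
        term_columns=[X[:, b] for b in blocks[1:]],
    )
    if n_perm > 0 and rng is not None:
        ge = np.zeros(k)
        for j in range(k):
            H_red = hats[j]
            E_red = (I - H_red) @ Y
            F_red = H_red @ Y
            P = hats[j + 1] - hats[j]
            R_full = I - H_full
            for _ in range(n_perm):
                Yp = F_red + E_red[rng.permutation(n)]
                ss = float(np.sum((P @ Yp) ** 2))
                sse = float(np.sum((R_full @ Yp) ** 2))
                f = (ss / df[j]) / (sse / df_res)
                if f >= F[j] - 1e-12:
                    ge[j] += 1
        fit.p_perm = (ge + 1) / (n_perm + 1)
        fit.n_perm = n_perm
    return fit


def procrustes_lm(
    Y: np.ndarray,
    data: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> GLSModelFit:
    """Multivariate regression of a flattened shape matrix on model terms.

    Sequential (Type I) sums of squares in trace form, with significance by
    residual randomisation (RRPP): for each term, residuals of the reduced
    model are permuted across specimens and the F statistic recomputed.
    """
    Y = np.asarray(Y, dtype=float)
    X, blocks = design_matrix(data, terms)
    rng = np.random.default_rng(seed) if n_perm > 0 else None
    fit = _sequential_fit(Y, X, blocks, terms, n_perm, rng)
    fit.seed = seed
    return fit


def procrustes_pgls(
    Y: np.ndarray,
    data: pd.DataFrame,
    terms: list[str],
    phy: Phylogeny | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    C: np.ndarray | None = None,
) -> GLSModelFit:
    """Phylogenetic GLS shape regression under Brownian residual covariance.

    Identical to :func:`procrustes_lm` after pre-multiplying the response
    and the full design (intercept included) by the inverse square root of
    the phylogenetic covariance; permutations act on transformed-scale
    residuals.  Coefficients/fitted/residuals are reported on the original
    scale (GLS coefficients).
    """
    Y = np.asarray(Y, dtype=float)
    if C is None:
        if phy is None:
            raise ValueError("either phy or C must be given")
        C = phy.C
    if C.shape[0] != Y.shape[0]:
        raise ValueError("tree tip count does not match number of specimens")
    P = phylo_transform(C)
    X, blocks = design_matrix(data, terms)
    rng = np.random.default_rng(seed) if n_perm > 0 else None
    fit = _sequential_fit(P @ Y, P @ X, blocks, terms, n_perm, rng)
    fit.seed = seed
    # re-express coefficients/fitted/residuals on the original scale
    beta = fit.coefficients
    fit.fitted = X @ beta
    fit.residuals = Y - fit.fitted
    return fit


# ---------------------------------------------------------------------------
# Two-block phylogenetic PLS
# ---------------------------------------------------------------------------


@dataclass
class PLSResult:
    singular_values: np.ndarray
    block1_scores: np.ndarray
    block2_scores: np.ndarray
    left_vectors: np.ndarray
    right_vectors: np.ndarray
    rPLS: float
    p_perm: float | None = None
    n_perm: int = 0
    seed: int | None = None

    def prediction_scores(self) -> np.ndarray:
        """Fitted values from the OLS regression of block-1 on block-2
        first-dimension scores."""
        x = self.block2_scores[:, 0]
        y = self.block1_scores[:, 0]
        xc = x - x.mean()
        b = float(xc @ (y - y.mean())) / float(xc @ xc)
        return y.mean() + b * xc


def _pls_core(Y1: np.ndarray, Y2: np.ndarray, P: np.ndarray, Cinv: np.ndarray):
    a1 = _gls_mean(Y1, Cinv)
    a2 = _gls_mean(Y2, Cinv)
    Z1 = Y1 - a1
    Z2 = Y2 - a2
    n = Y1.shape[0]
    R12 = (P @ Z1).T @ (P @ Z2) / (n - 1)
    U, s, Vt = np.linalg.svd(R12, full_matrices=False)
    S1 = Z1 @ U
    S2 = Z2 @ Vt.T
    r = float(np.corrcoef(S1[:, 0], S2[:, 0])[0, 1])
    return s, S1, S2, U, Vt.T, r


def phylo_pls(
    Y1: np.ndarray,
    Y2: np.ndarray,
    phy: Phylogeny | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    C: np.ndarray | None = None,
) -> PLSResult:
    """Two-block within-configuration phylogenetic partial least squares.

    The evolutionary cross-covariance of the two landmark blocks is taken
    after centering each on its phylogenetic GLS mean and whitening by the
    phylogenetic transform; its SVD yields paired axes.  Scores are the
    centered (untransformed) block data projected on those axes, and rPLS
    is the Pearson correlation of the paired first-dimension scores.  The
    null permutes tip rows of block 2.
    """
    Y1 = np.asarray(Y1, dtype=float)
    Y2 = np.asarray(Y2, dtype=float)
    if Y1.shape[1] < 2 or Y2.shape[1] < 2:
        raise ValueError("each block needs at least 2 columns")
    if C is None:
        if phy is None:
            C = np.eye(Y1.shape[0])
        else:
            C = phy.C
    P = phylo_transform(C)
    Cinv = P @ P
    s, S1, S2, U, V, r = _pls_core(Y1, Y2, P, Cinv)
    if not np.isfinite(r):
        raise ValueError("rPLS undefined: constant first-dimension scores")
    res = PLSResult(s, S1, S2, U, V, r, n_perm=n_perm, seed=seed)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        ge = 0
        for _ in range(n_perm):
            perm = rng.permutation(Y2.shape[0])
            *_, rp = _pls_core(Y1, Y2[perm], P, Cinv)
            if rp >= r - 1e-12:
                ge += 1
        res.p_perm = (ge + 1) / (n_perm + 1)
    return res
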