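"""Principal-component ordination of shapes and phylomorphospace support.

Covers PCA of flattened Procrustes coordinates, maximum-likelihood Brownian
ancestral-state estimation (equivalent to weighted squared-change parsimony
on the rooted tree), projection of ancestral shapes into the tip PCA space,
and TPS-style warped configurations along PC axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo_stats import Phylogeny
from .superimposition import AlignedShapes


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    scores: np.ndarray
    vectors: np.ndarray  # (n_axes, n_features) orthonormal rows
    mean: np.ndarray

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    def project(self, flat_shapes: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(flat_shapes) - self.mean) @ self.vectors.T

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis": np.arange(1, self.n_axes + 1),
                "eigenvalue": self.eigenvalues,
                "percent_variance": self.percent_variance,
            }
        )


def shape_pca(aligned: AlignedShapes | np.ndarray, tol: float = 1e-12) -> PCAResult:
    """PCA of flattened, mean-centered shape coordinates.

    Axes are ordered by decreasing eigenvalue; null axes (eigenvalue below
    ``tol`` times the leading one) are dropped.  Eigenvector sign is
    undefined, so each axis is oriented to give the specimen of largest
    absolute score a positive score.
    """
    flat = aligned.flattened if isinstance(aligned, AlignedShapes) else np.asarray(aligned, float)
    n = flat.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    mean = flat.mean(axis=0)
    Xc = flat - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    if eig.size == 0 or eig[0] <= 0:
        raise ValueError("zero shape variance: all specimens identical")
    keep = eig > tol * eig[0]
    eig, s, U, Vt = eig[keep], s[keep], U[:, keep], Vt[keep]
    scores = U * s
    # sign convention: largest-|score| specimen positive on each axis
    flips = np.sign(scores[np.argmax(np.abs(scores), axis=0), np.arange(scores.shape[1])])
    flips[flips == 0] = 1.0
    scores *= flips
    Vt = Vt * flips[:, None]
    return PCAResult(eig, 100.0 * eig / eig.sum(), scores, Vt, mean)


def warp_along_axis(pca: PCAResult, axis: int, score: float, n_points: int | None = None) -> np.ndarray:
    """Configuration at ``mean + score * loading`` on a PC axis, reshaped to
    (n_points, 3); the end-member warps used to visualise PC extremes."""
    if not 0 <= axis < pca.n_axes:
        raise IndexError(f"axis {axis} out of range (have {pca.n_axes})")
    flat = pca.mean + score * pca.vectors[axis]
    if n_points is None:
        n_points = flat.size // 3
    return flat.reshape(n_points, 3)


@dataclass
class AncestralStates:
    node_ids: list[str]
    node_coords: np.ndarray  # (n_internal, n_features)
    root_index: int
    edges: list[tuple[str, str]]  # (parent_id, child_id) over all nodes+tips


def ancestral_states(phy: Phylogeny, tip_shapes: np.ndarray, epsilon: float = 1e-8) -> AncestralStates:
    """ML Brownian-motion ancestral estimates for every internal node.

    Minimises the branch-length-weighted sum of squared changes over the
    rooted tree (each coordinate independently), which for Brownian motion
    coincides with the maximum-likelihood / GLS estimates; in particular the
    root estimate equals the phylogenetic GLS mean of the tips.
    Zero-length internal branches receive a small ``epsilon``.
    """
    Y = np.atleast_2d(np.asarray(tip_shapes, dtype=float))
    tree = phy.tree
    tips = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    if Y.shape[0] != len(phy.tip_order):
        raise ValueError("tip_shapes rows must match phy.tip_order")
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    idx = {id(nd): i for i, nd in enumerate(internal)}
    tip_idx = {id(tips[lbl]): r for r, lbl in enumerate(phy.tip_order)}
    m = len(internal)
    L = np.zeros((m, m))
    B = np.zeros((m, Y.shape[1]))
    for nd in internal:
        i = idx[id(nd)]
        for child in nd.child_nodes():
            w = 1.0 / max(child.edge.length or 0.0, epsilon)
            L[i, i] += w
            if child.is_leaf():
                B[i] += w * Y[tip_idx[id(child)]]
            else:
                j = idx[id(child)]
                L[i, j] -= w
                L[j, i] -= w  # symmetric: child's own row gets the parent term below
        parent = nd.parent_node
        if parent is not None:
            w = 1.0 / max(nd.edge.length or 0.0, epsilon)
            L[i, i] += w
    X = np.linalg.solve(L, B)
    node_ids = [f"node_{i}" for i in range(m)]
    edges: list[tuple[str, str]] = []
    for nd in internal:
        pid = node_ids[idx[id(nd)]]
        for child in nd.child_nodes():
            cid = phy.tip_order[tip_idx[id(child)]] if child.is_leaf() else node_ids[idx[id(child)]]
            edges.append((pid, cid))
    return AncestralStates(node_ids, X, idx[id(tree.seed_node)], edges)


def phylomorphospace(
    pca: PCAResult,
    phy: Phylogeny,
    tip_shapes: np.ndarray,
    axes: tuple[int, int] = (0, 1),
) -> pd.DataFrame:
    """Tip and ancestral-node coordinates in a PC plane, plus the branch
    segments connecting them, as one tidy table ready to plot or export.

    Ancestral states are estimated on the full shapes and projected with
    the tip PCA mean and vectors (no re-centering), so tips keep their
    ordinary PC scores.
    """
    anc = ancestral_states(phy, tip_shapes)
    tip_proj = pca.project(tip_shapes)[:, list(axes)]
    node_proj = pca.project(anc.node_coords)[:, list(axes)]
    rows = []
    for lbl, xy in zip(phy.tip_order, tip_proj):
        rows.append({"id": lbl, "kind": "tip", "x": xy[0], "y": xy[1]})
    for lbl, xy in zip(anc.node_ids, node_proj):
        rows.append({"id": lbl, "kind": "node", "x": xy[0], "y": xy[1]})
    pos = {r["id"]: (r["x"], r["y"]) for r in rows}
    for parent, child in anc.edges:
        x0, y0 = pos[parent]
        x1, y1 = pos[child]
        rows.append(
            {"id": f"{parent}->{child}", "kind": "edge", "x": x0, "y": y0, "x2": x1, "y2": y1}
        )
    return pd.DataFrame(rows)
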