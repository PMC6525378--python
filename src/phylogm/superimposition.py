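"""Generalized Procrustes analysis with bending-energy semilandmark sliding.

The superimposition pipeline is: (optionally) slide semilandmarks along
their curve tangents so that each specimen's thin-plate-spline bending
energy relative to the sample mean is minimal, re-superimpose, iterate;
then, for object-symmetric configurations, extract the symmetric component
by averaging each specimen with its reflected-and-relabelled copy after a
joint superimposition.

Conventions follow common geometric-morphometrics practice: full Procrustes
(configurations scaled to unit centroid size), rotations restricted to
determinant +1, and a final orthogonal projection into the tangent space at
the consensus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import LandmarkSet, SliderDefinition, SymmetryMap


# ---------------------------------------------------------------------------
# Centroid size and basic alignment
# ---------------------------------------------------------------------------


def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared distances of points from their
    centroid — the standard size measure for allometric regressions."""
    config = np.asarray(config, dtype=float)
    d = config - config.mean(axis=0)
    cs = float(np.sqrt(np.sum(d * d)))
    if cs <= 0:
        raise ValueError("degenerate configuration: all points identical")
    return cs


def _optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimising ||A R - B||_F for centered A, B."""
    U, _, Vt = np.linalg.svd(A.T @ B)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return R


@dataclass
class AlignedShapes:
    """Procrustes-aligned configurations with sizes and consensus."""

    specimen_ids: list[str]
    coords: np.ndarray  # (n, p, 3) aligned, unit centroid size
    centroid_size: np.ndarray  # (n,) sizes of the raw configurations
    consensus: np.ndarray  # (p, 3)

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def flattened(self) -> np.ndarray:
        return self.coords.reshape(self.n_specimens, -1)

    @property
    def log_centroid_size(self) -> np.ndarray:
        return np.log(self.centroid_size)


def gpa(
    shapes: LandmarkSet,
    tol: float = 1e-10,
    max_iter: int = 100,
    project: bool = True,
) -> AlignedShapes:
    """Generalized Procrustes analysis.

    Each configuration is centered, scaled to unit centroid size and
    rotated (orthogonal, reflections disallowed) to the iteratively
    re-estimated mean shape; on convergence the aligned shapes are
    orthogonally projected into the tangent space at the consensus.
    """
    X = shapes.coords.astype(float).copy()
    n = X.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least 2 specimens")
    cs = np.array([centroid_size(c) for c in X])
    X -= X.mean(axis=1, keepdims=True)
    X /= cs[:, None, None]
    ref = X[0].copy()
    ref /= np.linalg.norm(ref)
    for it in range(max_iter):
        for i in range(n):
            X[i] = X[i] @ _optimal_rotation(X[i], ref)
        mean = X.mean(axis=0)
        mean -= mean.mean(axis=0)
        mean /= np.linalg.norm(mean)
        change = np.linalg.norm(mean - ref)
        ref = mean
        if change < tol:
            break
    else:
        raise RuntimeError(f"GPA did not converge in {max_iter} iterations (last change {change:.2e})")
    if project:
        X = _tangent_project(X, ref)
    return AlignedShapes(list(shapes.specimen_ids), X, cs, ref)


def _tangent_project(X: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Orthogonal projection of aligned shapes onto the plane tangent to the
    unit pre-shape sphere at the consensus."""
    c = consensus.ravel()
    c = c / np.linalg.norm(c)
    flat = X.reshape(X.shape[0], -1)
    proj = flat + np.outer(1.0 - flat @ c, c)
    return proj.reshape(X.shape)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations (after centering,
    unit-size scaling and optimal rotation of ``a`` onto ``b``)."""
    A = a - a.mean(axis=0)
    B = b - b.mean(axis=0)
    A /= np.linalg.norm(A)
    B /= np.linalg.norm(B)
    A = A @ _optimal_rotation(A, B)
    return float(np.linalg.norm(A - B))


# ---------------------------------------------------------------------------
# Thin-plate-spline bending energy
# ---------------------------------------------------------------------------


class BendingEnergyModel:
    """Thin-plate-spline bending-energy form anchored at a reference.

    For a 3D reference configuration the TPS kernel is U(r) = -r (the
    sign making the quadratic form positive semi-definite); the bending
    energy of a displacement field v (one column per coordinate axis) is
    ``sum_axis v' L_k v`` with ``L_k`` the landmark block of the inverse of
    the bordered kernel system.  Affine displacement fields have zero
    bending energy.
    """

    def __init__(self, reference: np.ndarray, ridge: float = 0.0):
        R = np.asarray(reference, dtype=float)
        p = R.shape[0]
        d = np.linalg.norm(R[:, None, :] - R[None, :, :], axis=2)
        K = -d
        Q = np.column_stack([np.ones(p), R])
        L = np.zeros((p + 4, p + 4))
        L[:p, :p] = K + ridge * np.eye(p)
        L[:p, p:] = Q
        L[p:, :p] = Q.T
        try:
            Linv = np.linalg.inv(L)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                "singular bending-energy system; consider a small ridge term"
            ) from e
        self.reference = R
        Lk = Linv[:p, :p]
        self.bending_energy = (Lk + Lk.T) / 2.0

    def energy(self, target: np.ndarray) -> float:
        """Bending energy of the deformation taking the reference onto
        ``target`` (translation/rotation/affine parts contribute nothing)."""
        V = np.asarray(target, dtype=float) - self.reference
        return float(np.sum(V * (self.bending_energy @ V)))


# ---------------------------------------------------------------------------
# Semilandmark sliding
# ---------------------------------------------------------------------------


def _slide_one(
    config: np.ndarray,
    reference: np.ndarray,
    be: BendingEnergyModel,
    triples: np.ndarray,
    ridge: float = 1e-10,
) -> np.ndarray:
    """Optimal tangent displacements of one specimen's semilandmarks.

    Each slider moves only along the unit chord between its before/after
    neighbours; the displacement vector t solves the quadratic program
    min_t BE(config + T t - reference), a small symmetric linear system.
    """
    m = triples.shape[0]
    E = be.bending_energy
    tangents = config[triples[:, 2]] - config[triples[:, 0]]
    norms = np.linalg.norm(tangents, axis=1)
    if np.any(norms <= 0):
        raise ValueError("coincident slider neighbours give a zero tangent")
    tangents /= norms[:, None]
    delta = config - reference  # (p, 3)
    sl = triples[:, 1]
    # A[j,k] = sum_d u_j[d] E[sl_j, sl_k] u_k[d];  b[j] = sum_d u_j[d] (E delta_d)[sl_j]
    Esub = E[np.ix_(sl, sl)]
    A = (tangents @ tangents.T) * Esub
    b = np.einsum("jd,jd->j", tangents, (E @ delta)[sl])
    try:
        t = np.linalg.solve(A + ridge * np.eye(m), -b)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular sliding system; increase the ridge stabiliser"
        ) from e
    out = config.copy()
    out[sl] += t[:, None] * tangents
    return out


def slide_semilandmarks(
    shapes: LandmarkSet,
    sliders: SliderDefinition,
    n_passes: int = 5,
    tol: float = 1e-6,
    ridge: float = 1e-10,
    verbose: bool = False,
) -> LandmarkSet:
    """Slide semilandmarks to minimise bending energy against the mean.

    Each pass: superimpose, rebuild the TPS bending-energy form on the
    current consensus, displace every specimen's semilandmarks along their
    neighbour-chord tangents to the bending-energy minimum, and iterate
    until the consensus stabilises (or ``n_passes`` passes).  Returned
    coordinates are in the aligned orientation, rescaled to each specimen's
    original centroid size so sizes are preserved for allometry.
    """
    sliders.validate(shapes)
    triples = sliders.triples
    current = shapes.coords.astype(float).copy()
    work = LandmarkSet(
        list(shapes.specimen_ids), current, shapes.point_roles, shapes.curve_membership
    )
    prev_consensus = None
    for pass_no in range(n_passes):
        aligned = gpa(work, project=False)
        ref = aligned.consensus
        be = BendingEnergyModel(ref)
        slid = np.empty_like(aligned.coords)
        pre = post = 0.0
        for i in range(aligned.n_specimens):
            pre += be.energy(aligned.coords[i])
            slid[i] = _slide_one(aligned.coords[i], ref, be, triples, ridge)
            post += be.energy(slid[i])
        if verbose:  # pragma: no cover - logging only
            print(f"slide pass {pass_no + 1}: bending energy {pre:.6g} -> {post:.6g}")
        work = LandmarkSet(
            list(shapes.specimen_ids),
            slid * aligned.centroid_size[:, None, None],
            shapes.point_roles,
            shapes.curve_membership,
        )
        if prev_consensus is not None and np.linalg.norm(ref - prev_consensus) < tol:
            break
        prev_consensus = ref
    return work


def total_bending_energy(shapes: LandmarkSet) -> float:
    """Summed TPS bending energy of all specimens against the current
    Procrustes consensus (a diagnostic for the sliding iteration)."""
    aligned = gpa(shapes, project=False)
    be = BendingEnergyModel(aligned.consensus)
    return float(sum(be.energy(c) for c in aligned.coords))


# ---------------------------------------------------------------------------
# Symmetric component
# ---------------------------------------------------------------------------


def detect_reflection_axis(consensus: np.ndarray, sym: SymmetryMap) -> int:
    """Axis of smallest variance of the midline landmarks — the normal of
    the (approximate) plane of bilateral symmetry."""
    if sym.midline.size == 0:
        return 0
    mid = consensus[sym.midline]
    return int(np.argmin(mid.var(axis=0)))


def symmetric_component(
    shapes: LandmarkSet,
    sym: SymmetryMap,
    axis: int | None = None,
) -> AlignedShapes:
    """Extract the symmetric component of shape variation.

    A mirrored copy of each specimen is produced by reflecting one
    coordinate axis and swapping the paired left/right landmark labels;
    originals and mirrored copies are superimposed jointly and each
    specimen's symmetric shape is the average of its two aligned copies.
    Centroid sizes are those of the original configurations.
    """
    sym.validate(shapes.n_points)
    X = shapes.coords.astype(float)
    n = X.shape[0]
    if axis is None:
        mean = X.mean(axis=0)
        axis = detect_reflection_axis(mean - mean.mean(axis=0), sym)
    mirrored = X.copy()
    mirrored[:, :, axis] *= -1.0
    swap = np.arange(shapes.n_points)
    swap[sym.pairs[:, 0]] = sym.pairs[:, 1]
    swap[sym.pairs[:, 1]] = sym.pairs[:, 0]
    mirrored = mirrored[:, swap, :]
    joint = LandmarkSet(
        [f"{s}::orig" for s in shapes.specimen_ids]
        + [f"{s}::mirror" for s in shapes.specimen_ids],
        np.concatenate([X, mirrored]),
        shapes.point_roles,
        shapes.curve_membership,
    )
    aligned = gpa(joint, project=False)
    symm = (aligned.coords[:n] + aligned.coords[n:]) / 2.0
    consensus = symm.mean(axis=0)
    consensus -= consensus.mean(axis=0)
    consensus /= np.linalg.norm(consensus)
    symm = _tangent_project(symm, consensus)
    return AlignedShapes(
        list(shapes.specimen_ids), symm, aligned.centroid_size[:n], consensus
    )
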