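"""Synthetic trees, landmark datasets and metadata with known ground truth.

Every stage of the pipeline is testable by parameter recovery on data from
this module: tip shapes evolve by multivariate Brownian motion on a
simulated pure-birth tree, an allometric shape vector scaled by log
centroid size is injected, a shared latent factor (itself Brownian on the
tree, so integration survives phylogenetic correction) loads on the beak
and braincase blocks, optional diet-group mean shifts and independent
noise are added, and the analytic variance share of every component is
recorded alongside its realised value.

Variance shares are defined in the phylogenetically transformed metric
(sums of squares about the GLS mean after whitening by the inverse square
root of the Brownian covariance), which is the metric in which the
pipeline's PGLS fractions live.  Because every stochastic ingredient is
either Brownian on the tree or i.i.d., the expectations are exact:

* a Brownian component of per-coordinate rate ``s**2`` contributes
  ``q * s**2 * (n - 1)`` over ``q`` coordinates;
* an i.i.d. component of variance ``s**2`` contributes
  ``q * s**2 * tr(A)`` with ``A`` the whitened centering form.

The default generator parameters mirror the study design this package is
built around: 170 tip species on a unit-depth ultrametric tree, skull
configurations of 20 fixed landmarks and 40 semilandmarks (four curves of
ten), diet classes MMR/mixed/LMR in proportions 72:40:58, a strongly
phylogenetically structured log centroid size, and allometric plus
integration variance shares of roughly 0.30 and 0.25.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .data_io import (
    FIXED,
    SEMILANDMARK,
    LandmarkSet,
    SliderDefinition,
    SymmetryMap,
    write_landmarks,
)
from .phylo_stats import Phylogeny
from .superimposition import AlignedShapes, centroid_size

DIET_LEVELS = ("MMR", "mixed", "LMR")
#: study diet composition (MMR : mixed : LMR)
DIET_PROBS = np.array([72, 40, 58], dtype=float) / 170.0


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


def simulate_tree(n_tips: int, seed: int | None = None, rng: np.random.Generator | None = None) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree rescaled to unit root-to-tip depth.

    Lineages split at exponential waiting times with per-lineage rate 1;
    the splitting lineage is chosen uniformly.  Reproducible bit-for-bit
    from the seed.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed) if rng is None else rng
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    t = 0.0
    active: list = []
    for _ in range(2):
        ch = dendropy.Node()
        root.add_child(ch)
        active.append((ch, t))
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.edge.length = t - born
        for _ in range(2):
            ch = dendropy.Node()
            node.add_child(ch)
            active.append((ch, t))
        k += 1
    t_end = t + rng.exponential(1.0 / k)
    depth = t_end if t_end > 0 else 1.0
    tips = sorted(active, key=lambda nb: id(nb[0]))
    order: list[str] = []
    for j, (node, born) in enumerate(active):
        node.edge.length = t_end - born
        node.taxon = taxa.new_taxon(label=f"sp{j + 1:03d}")
        order.append(node.taxon.label)
    # rescale to unit depth
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length /= depth
    return Phylogeny(tree, order)


def clade_partition(phy: Phylogeny, k: int) -> pd.Series:
    """Partition tips into ``k`` monophyletic groups by repeatedly splitting
    the largest subtree; used to emulate clade metadata."""
    groups = [list(phy.tree.seed_node.leaf_iter())]
    nodes = [phy.tree.seed_node]
    while len(groups) < k:
        sizes = [len(g) for g in groups]
        i = int(np.argmax(sizes))
        node = nodes.pop(i)
        groups.pop(i)
        children = node.child_nodes()
        if not children:
            raise ValueError(f"cannot split tips into {k} clades")
        for ch in children:
            nodes.append(ch)
            groups.append(list(ch.leaf_iter()))
    names = [f"clade{j + 1}" for j in range(len(groups))]
    lab = {}
    for name, g in zip(names, groups):
        for lf in g:
            lab[lf.taxon.label] = name
    return pd.Series([lab[t] for t in phy.tip_order], index=phy.tip_order, name="clade")


# ---------------------------------------------------------------------------
# Landmark template geometry
# ---------------------------------------------------------------------------


@dataclass
class Template:
    """A skull-like landmark template with curves, symmetry and blocks.

    x is mediolateral (the symmetry axis), y dorsoventral, z
    anteroposterior.  ``blocks`` are flattened-coordinate column indices
    for the beak and braincase modules.
    """

    coords: np.ndarray
    point_roles: np.ndarray
    curve_membership: np.ndarray
    sliders: SliderDefinition
    symmetry: SymmetryMap
    beak_points: np.ndarray
    braincase_points: np.ndarray

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def blocks(self) -> tuple[np.ndarray, np.ndarray]:
        def cols(pts: np.ndarray) -> np.ndarray:
            return (3 * pts[:, None] + np.arange(3)[None, :]).ravel()

        return cols(self.beak_points), cols(self.braincase_points)

    def reflect_permutation(self) -> np.ndarray:
        swap = np.arange(self.n_points)
        swap[self.symmetry.pairs[:, 0]] = self.symmetry.pairs[:, 1]
        swap[self.symmetry.pairs[:, 1]] = self.symmetry.pairs[:, 0]
        return swap

    def symmetrize(self, flat_vector: np.ndarray) -> np.ndarray:
        """Average a flattened displacement vector with its mirrored,
        relabelled copy so injected effects survive the symmetric-component
        step of the pipeline."""
        v = flat_vector.reshape(self.n_points, 3).copy()
        m = v.copy()
        m[:, 0] *= -1
        m = m[self.reflect_permutation()]
        return ((v + m) / 2.0).ravel()


def _arc(a: np.ndarray, b: np.ndarray, k: int, bulge: np.ndarray) -> np.ndarray:
    """k interior points of a quadratic arc from a to b bulging by ``bulge``."""
    t = np.linspace(0.0, 1.0, k + 2)[1:-1]
    return (1 - t)[:, None] * a + t[:, None] * b + (4 * t * (1 - t))[:, None] * bulge


def skull_template(size: str = "full") -> Template:
    """Build the default landmark template.

    ``full`` — 60 points: 20 fixed landmarks plus four curves of 10
    semilandmarks (midline dorsal beak and braincase profiles, bilateral
    tomial edges).  ``tiny`` — 12 points: 4 fixed plus a midline curve of 4
    and bilateral tomial curves of 2.
    """
    if size == "full":
        n_semi_mid, n_semi_tom = 10, 10
        mid_fixed = np.array(
            [
                [0.0, 0.0, 0.0],   # 0 beak tip
                [0.0, 1.5, 3.0],   # 1 craniofacial hinge
                [0.0, -1.0, 2.5],  # 2 anterior palate
                [0.0, 2.5, 6.5],   # 3 vault apex
                [0.0, 0.5, 10.0],  # 4 occipital
                [0.0, -0.5, 9.5],  # 5 foramen magnum
            ]
        )
        pair_fixed = np.array(
            [
                [1.2, 0.2, 2.8],   # lateral beak base
                [1.4, -0.6, 3.2],  # jugal anterior
                [1.6, -0.4, 7.0],  # jugal posterior
                [1.3, 1.2, 4.0],   # orbit anterior
                [1.5, 1.0, 6.0],   # orbit posterior
                [1.5, -0.8, 7.5],  # quadrate
                [1.0, -1.0, 8.5],  # basitemporal
            ]
        )
        beak_fixed_local = [0, 1, 2]  # midline indices belonging to the beak
        beak_pairs_local = [0, 1]  # pair indices (lateral beak base, jugal anterior)
    elif size == "tiny":
        n_semi_mid, n_semi_tom = 4, 2
        mid_fixed = np.array([[0.0, 0.0, 0.0], [0.0, 1.0, 3.0]])
        pair_fixed = np.array([[1.0, -0.3, 2.0]])
        beak_fixed_local = [0]
        beak_pairs_local = [0]
    else:
        raise ValueError(f"unknown template size {size!r}")

    n_mid = len(mid_fixed)
    pts: list[np.ndarray] = [mid_fixed]
    left = pair_fixed.copy()
    left[:, 0] *= -1
    pts += [pair_fixed, left]
    n_pairf = len(pair_fixed)
    # fixed landmark indices
    idx_pair_r = n_mid + np.arange(n_pairf)
    idx_pair_l = n_mid + n_pairf + np.arange(n_pairf)
    n_fixed = n_mid + 2 * n_pairf

    curves: list[np.ndarray] = []
    curve_anchor: list[tuple[int, int]] = []
    if size == "full":
        curves.append(_arc(mid_fixed[0], mid_fixed[1], n_semi_mid, np.array([0, 0.9, 0.0])))
        curve_anchor.append((0, 1))
        curves.append(_arc(mid_fixed[1], mid_fixed[4], n_semi_mid, np.array([0, 1.4, 0.0])))
        curve_anchor.append((1, 4))
        tom_r = _arc(mid_fixed[0], pair_fixed[0], n_semi_tom, np.array([0.25, -0.5, 0.0]))
        tom_l = tom_r.copy()
        tom_l[:, 0] *= -1
        curves += [tom_r, tom_l]
        curve_anchor += [(0, int(idx_pair_r[0])), (0, int(idx_pair_l[0]))]
    else:
        curves.append(_arc(mid_fixed[0], mid_fixed[1], n_semi_mid, np.array([0, 0.5, 0.0])))
        curve_anchor.append((0, 1))
        tom_r = _arc(mid_fixed[0], pair_fixed[0], n_semi_tom, np.array([0.15, -0.3, 0.0]))
        tom_l = tom_r.copy()
        tom_l[:, 0] *= -1
        curves += [tom_r, tom_l]
        curve_anchor += [(0, int(idx_pair_r[0])), (0, int(idx_pair_l[0]))]

    coords = np.vstack([np.vstack(pts)] + curves)
    n_points = coords.shape[0]
    roles = np.array([FIXED] * n_fixed + [SEMILANDMARK] * (n_points - n_fixed))
    membership = np.full(n_points, -1, dtype=int)
    triples = []
    pos = n_fixed
    sym_semi_pairs = []
    for c, (curve, (a0, a1)) in enumerate(zip(curves, curve_anchor)):
        k = curve.shape[0]
        membership[pos : pos + k] = c
        for j in range(k):
            before = a0 if j == 0 else pos + j - 1
            after = a1 if j == k - 1 else pos + j + 1
            triples.append((before, pos + j, after))
        pos += k
    # symmetry: fixed pairs + tomial curve pairs (last two curves mirror)
    n_tom = curves[-1].shape[0]
    tom_r_start = n_points - 2 * n_tom
    tom_l_start = n_points - n_tom
    for j in range(n_tom):
        sym_semi_pairs.append((tom_r_start + j, tom_l_start + j))
    pairs = np.vstack(
        [np.column_stack([idx_pair_r, idx_pair_l]), np.asarray(sym_semi_pairs, dtype=int)]
    )
    paired = set(pairs.ravel().tolist())
    midline = np.array([i for i in range(n_points) if i not in paired], dtype=int)

    beak_pts = sorted(
        set(beak_fixed_local)
        | {int(idx_pair_r[j]) for j in beak_pairs_local}
        | {int(idx_pair_l[j]) for j in beak_pairs_local}
        | set(range(n_fixed, n_fixed + n_semi_mid))  # dorsal beak curve
        | set(range(tom_r_start, n_points))  # tomial curves
    )
    braincase_pts = sorted(set(range(n_points)) - set(beak_pts))
    return Template(
        coords=coords,
        point_roles=roles,
        curve_membership=membership,
        sliders=SliderDefinition(np.asarray(triples, dtype=int)),
        symmetry=SymmetryMap(pairs, midline),
        beak_points=np.asarray(beak_pts, dtype=int),
        braincase_points=np.asarray(braincase_pts, dtype=int),
    )


# ---------------------------------------------------------------------------
# Ground truth and shape simulation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Generating parameters plus their analytic variance shares."""

    beta_size: np.ndarray  # allometric displacement per unit logCS, (3p,)
    latent_loadings: np.ndarray  # shared-factor loadings, (3p,)
    diet_effects: dict[str, np.ndarray]
    sigma_bm: float
    sigma_noise: float
    sigma_logcs_bm: float = 0.35
    sigma_logcs_jitter: float = 0.05
    mean_logcs: float = 3.2
    expected_fractions: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def to_json(self) -> str:
        payload = {
            "sigma_bm": self.sigma_bm,
            "sigma_noise": self.sigma_noise,
            "sigma_logcs_bm": self.sigma_logcs_bm,
            "sigma_logcs_jitter": self.sigma_logcs_jitter,
            "mean_logcs": self.mean_logcs,
            "expected_fractions": self.expected_fractions,
            "seed": self.seed,
            "beta_size": self.beta_size.tolist(),
            "latent_loadings": self.latent_loadings.tolist(),
            "diet_effects": {k: v.tolist() for k, v in self.diet_effects.items()},
        }
        return json.dumps(payload, indent=1)


def _whitened_centering_form(C: np.ndarray) -> tuple[np.ndarray, float]:
    """A = C^-1 - C^-1 1 1' C^-1 / (1' C^-1 1) and its trace.

    ``tr(X' A X)`` is the transformed-metric SS of tip data ``X`` about the
    phylogenetic GLS mean; tr(A C) = n - 1 exactly.
    """
    Cinv = np.linalg.inv(C)
    w = Cinv @ np.ones(C.shape[0])
    A = Cinv - np.outer(w, w) / w.sum()
    return A, float(np.trace(A))


def make_truth(
    C: np.ndarray,
    template: Template,
    frac_allometric: float = 0.30,
    frac_integration: float = 0.25,
    frac_diet: float = 0.0,
    frac_noise: float = 0.05,
    sigma_bm: float = 0.02,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    symmetric_effects: bool = True,
) -> SyntheticTruth:
    """Construct generating parameters hitting target variance shares.

    Effect directions are drawn at random (optionally symmetrised so they
    survive the symmetric-component step); magnitudes are solved from the
    exact transformed-metric variance expectations so that
    ``expected_fractions`` holds analytically, with Brownian motion of
    per-coordinate rate ``sigma_bm**2`` absorbing the remaining share.
    """
    if frac_allometric + frac_integration + frac_diet + frac_noise >= 1.0:
        raise ValueError("component fractions must sum to < 1 (the rest is Brownian)")
    rng = np.random.default_rng(seed) if rng is None else rng
    n = C.shape[0]
    q = 3 * template.n_points
    A, trA = _whitened_centering_form(C)
    sig_s, tau_s = 0.35, 0.05
    v_bm = q * sigma_bm**2 * (n - 1)
    frac_bm = 1.0 - frac_allometric - frac_integration - frac_diet - frac_noise
    T = v_bm / frac_bm
    v_logcs = sig_s**2 * (n - 1) + tau_s**2 * trA

    def direction(block_cols: np.ndarray | None = None) -> np.ndarray:
        v = np.zeros(q)
        cols = np.arange(q) if block_cols is None else block_cols
        v[cols] = rng.standard_normal(len(cols))
        if symmetric_effects:
            v = template.symmetrize(v)
        return v / np.linalg.norm(v)

    beta = direction() * np.sqrt(frac_allometric * T / v_logcs)
    b1, b2 = template.blocks
    u1, u2 = direction(b1), direction(b2)
    loadings = (u1 + u2) / np.linalg.norm(u1 + u2) * np.sqrt(frac_integration * T / (n - 1))
    diet_effects: dict[str, np.ndarray] = {}
    if frac_diet > 0:
        denom = trA * float(np.sum(DIET_PROBS * (1 - DIET_PROBS)))
        c = np.sqrt(frac_diet * T / denom)
        dirs = [direction() for _ in DIET_LEVELS]
        # orthogonalise so cross terms vanish in the variance accounting
        Q, _ = np.linalg.qr(np.column_stack(dirs))
        diet_effects = {lvl: c * Q[:, j] for j, lvl in enumerate(DIET_LEVELS)}
    sigma_noise = np.sqrt(frac_noise * T / (q * trA)) if frac_noise > 0 else 0.0
    return SyntheticTruth(
        beta_size=beta,
        latent_loadings=loadings,
        diet_effects=diet_effects,
        sigma_bm=sigma_bm,
        sigma_noise=float(sigma_noise),
        sigma_logcs_bm=sig_s,
        sigma_logcs_jitter=tau_s,
        expected_fractions={
            "allometric": frac_allometric,
            "integration": frac_integration,
            "diet": frac_diet,
            "noise": frac_noise,
            "brownian": frac_bm,
        },
        seed=seed,
    )


@dataclass
class SimulatedDataset:
    aligned: AlignedShapes
    metadata: pd.DataFrame
    log_cs: np.ndarray
    realized_fractions: dict[str, float]
    truth: SyntheticTruth
    template: Template
    phy: Phylogeny


def simulate_aligned(
    phy: Phylogeny,
    truth: SyntheticTruth,
    template: Template,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Simulate tip shapes directly in the aligned (tangent) space.

    tip shape = template + BM + beta_size * (logCS - mean) + latent *
    loadings + diet effect + i.i.d. noise, with logCS and the latent factor
    both Brownian on the tree (plus jitter for logCS).  Realised
    transformed-metric variance shares of each component are recorded.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    C = phy.C
    n = phy.n_tips
    q = 3 * template.n_points
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
    A, _ = _whitened_centering_form(C)

    bm = truth.sigma_bm * (L @ rng.standard_normal((n, q)))
    s = truth.sigma_logcs_bm * (L @ rng.standard_normal(n)) + truth.sigma_logcs_jitter * rng.standard_normal(n)
    log_cs = truth.mean_logcs + s
    allo = np.outer(s, truth.beta_size)
    latent = L @ rng.standard_normal(n)
    integ = np.outer(latent, truth.latent_loadings)
    diets = pd.Series(rng.choice(DIET_LEVELS, size=n, p=DIET_PROBS), index=phy.tip_order)
    if truth.diet_effects:
        diet_comp = np.vstack([truth.diet_effects[d] for d in diets])
    else:
        diet_comp = np.zeros((n, q))
    noise = truth.sigma_noise * rng.standard_normal((n, q))

    flat = template.coords.ravel()[None, :] + bm + allo + integ + diet_comp + noise

    def share(X: np.ndarray) -> float:
        return float(np.sum(X * (A @ X)))

    parts = {
        "brownian": share(bm),
        "allometric": share(allo),
        "integration": share(integ),
        "diet": share(diet_comp),
        "noise": share(noise),
    }
    tot = sum(parts.values())
    realized = {k: v / tot for k, v in parts.items()}

    n_clades = 4 if n >= 20 else 2
    clades = clade_partition(phy, n_clades)
    meta = pd.DataFrame({"species": phy.tip_order, "clade": clades.values, "diet": diets.values})
    aligned = AlignedShapes(
        specimen_ids=list(phy.tip_order),
        coords=flat.reshape(n, template.n_points, 3),
        centroid_size=np.exp(log_cs),
        consensus=flat.mean(axis=0).reshape(template.n_points, 3),
    )
    return SimulatedDataset(aligned, meta, log_cs, realized, truth, template, phy)


def simulate_landmarks(ds: SimulatedDataset, rng: np.random.Generator) -> LandmarkSet:
    """Re-express a simulated dataset as raw digitised configurations:
    each specimen is scaled to its centroid size and given a random
    rotation and translation, as a digitiser would record it."""
    n, p = ds.aligned.n_specimens, ds.template.n_points
    out = np.empty((n, p, 3))
    for i in range(n):
        conf = ds.aligned.coords[i]
        conf = conf - conf.mean(axis=0)
        conf = conf / centroid_size(conf) * float(np.exp(ds.log_cs[i]))
        M = rng.standard_normal((3, 3))
        Q, R = np.linalg.qr(M)
        Q *= np.sign(np.diag(R))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        out[i] = conf @ Q + rng.uniform(-50, 50, size=3)
    return LandmarkSet(
        list(ds.aligned.specimen_ids), out, ds.template.point_roles, ds.template.curve_membership
    )


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

FIXTURE_SPECS: dict[str, dict] = {
    "tiny": dict(n_tips=8, size="tiny", frac_allometric=0.30, frac_integration=0.20, frac_diet=0.0, frac_noise=0.05),
    "null": dict(n_tips=150, size="full", frac_allometric=0.0, frac_integration=0.0, frac_diet=0.0, frac_noise=0.05),
    "allometric": dict(n_tips=150, size="full", frac_allometric=0.40, frac_integration=0.0, frac_diet=0.0, frac_noise=0.05),
    "integrated": dict(n_tips=150, size="full", frac_allometric=0.0, frac_integration=0.35, frac_diet=0.0, frac_noise=0.05),
    "full": dict(n_tips=170, size="full", frac_allometric=0.30, frac_integration=0.25, frac_diet=0.02, frac_noise=0.05),
}


def make_dataset(name: str, seed: int = 0) -> SimulatedDataset:
    """Simulate one of the named study designs (see ``FIXTURE_SPECS``)."""
    if name not in FIXTURE_SPECS:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURE_SPECS)}")
    spec = FIXTURE_SPECS[name]
    rng = np.random.default_rng(seed)
    phy = simulate_tree(spec["n_tips"], rng=rng)
    template = skull_template(spec["size"])
    truth = make_truth(
        phy.C,
        template,
        frac_allometric=spec["frac_allometric"],
        frac_integration=spec["frac_integration"],
        frac_diet=spec["frac_diet"],
        frac_noise=spec["frac_noise"],
        rng=rng,
        seed=seed,
    )
    return simulate_aligned(phy, truth, template, rng=rng)


def make_fixture(name: str, outdir: str | Path, seed: int = 0) -> Path:
    """Write a complete on-disk dataset (landmarks, tree, sliders, symmetry
    pairs, metadata, ground-truth JSON) in the formats the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = make_dataset(name, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    raw = simulate_landmarks(ds, rng)
    write_landmarks(raw, outdir / "landmarks.txt", fmt="matrix")
    (outdir / "tree.nwk").write_text(ds.phy.newick() + "\n")
    tpl = ds.template
    with (outdir / "sliders.txt").open("w") as fh:
        fh.write("before slide after\n")
        for b, s, a in tpl.sliders.triples + 1:
            fh.write(f"{b} {s} {a}\n")
    with (outdir / "landpairs.txt").open("w") as fh:
        for l, r in tpl.symmetry.pairs + 1:
            fh.write(f"{l} {r}\n")
    ds.metadata.to_csv(outdir / "metadata.csv", index=False)
    (outdir / "truth.json").write_text(ds.truth.to_json() + "\n")
    manifest = {
        "name": name,
        "seed": seed,
        "n_specimens": ds.aligned.n_specimens,
        "n_fixed": int(np.sum(tpl.point_roles == FIXED)),
        "n_semi": int(np.sum(tpl.point_roles == SEMILANDMARK)),
        "beak_points_1based": (tpl.beak_points + 1).tolist(),
        "realized_fractions": ds.realized_fractions,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    config = {
        "landmarks": "landmarks.txt",
        "tree": "tree.nwk",
        "metadata": "metadata.csv",
        "sliders": "sliders.txt",
        "symmetry_pairs": "landpairs.txt",
        "n_fixed": manifest["n_fixed"],
        "n_semi": manifest["n_semi"],
        "beak_points": manifest["beak_points_1based"],
        "n_perm": 99 if name == "tiny" else 999,
        "seed": seed,
        "output_dir": str(outdir / "run"),
    }
    import yaml

    (outdir / "config.yaml").write_text(yaml.safe_dump(config))
    return outdir
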