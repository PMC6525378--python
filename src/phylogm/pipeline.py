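"""End-to-end pipeline: files in, one JSON report plus per-stage CSVs out.

Stages: read inputs -> slide semilandmarks -> Procrustes superimposition ->
symmetric component -> PCA / phylomorphospace -> phylogenetic signal ->
shape ~ logCS + diet regressions (OLS and PGLS) -> beak/braincase
phylogenetic PLS -> allometry/integration/NANI decomposition -> pairwise
PERMANOVA of PC scores by clade and diet.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import read_landmarks, read_metadata, read_sliders, read_symmetry_pairs, read_tree
from .decomposition import decompose
from .group_tests import pairwise_permanova, subset_rerun
from .ordination import phylomorphospace, shape_pca
from .phylo_stats import kmult, phylo_pls, procrustes_lm, procrustes_pgls
from .superimposition import gpa, slide_semilandmarks, symmetric_component


@dataclass
class PipelineConfig:
    landmarks: str
    tree: str
    metadata: str
    sliders: str | None = None
    symmetry_pairs: str | None = None
    n_fixed: int = 20
    n_semi: int = 40
    beak_points: list[int] = field(default_factory=list)  # 1-based point indices
    n_perm: int = 999
    seed: int = 1
    grouping: str = "clade"
    exclude_clades: list[str] = field(default_factory=list)
    fraction_basis: str = "total"
    slide_first: bool = True
    output_dir: str = "phylogm_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        obj = cls(**cfg)
        base = Path(path).parent
        for attr in ("landmarks", "tree", "metadata", "sliders", "symmetry_pairs"):
            v = getattr(obj, attr)
            if v is not None:
                p = Path(v)
                if not p.is_absolute():
                    p = base / p
                if not p.exists():
                    raise FileNotFoundError(f"{attr}: {p}")
                setattr(obj, attr, str(p))
        if obj.n_perm < 99:
            raise ValueError("n_perm must be at least 99")
        return obj


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write ``summary.json`` plus stage CSVs.

    Returns the summary dictionary.  Any stage failure raises with the
    stage name; outputs written so far are left in place.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
    }
    stage = "data_io"
    try:
        meta = read_metadata(config.metadata)
        land = read_landmarks(
            config.landmarks,
            config.n_fixed,
            config.n_semi,
            specimen_ids=list(meta["species"]),
        )
        phy = read_tree(config.tree, tip_labels=list(meta["species"]))
        sliders = read_sliders(config.sliders) if config.sliders else None
        sym = (
            read_symmetry_pairs(config.symmetry_pairs, land.n_points)
            if config.symmetry_pairs
            else None
        )
        summary["n_specimens"] = land.n_specimens
        summary["n_points"] = land.n_points

        stage = "superimposition"
        if sliders is not None and config.slide_first:
            land = slide_semilandmarks(land, sliders)
        if sym is not None:
            aligned = symmetric_component(land, sym)
        else:
            aligned = gpa(land)
        C = phy.C

        stage = "ordination"
        pca = shape_pca(aligned)
        pca.table().to_csv(out / "pca_variance.csv", index=False)
        pd.DataFrame(pca.scores, index=aligned.specimen_ids).to_csv(out / "pc_scores.csv")
        summary["pc_percent_variance"] = pca.percent_variance[:5].tolist()
        phylomorphospace(pca, phy, aligned.flattened).to_csv(
            out / "phylomorphospace.csv", index=False
        )

        stage = "phylo_stats"
        k = kmult(aligned.flattened, n_perm=config.n_perm, seed=config.seed, C=C)
        summary["kmult"] = {"K": k.observed, "p": k.p, "n_perm": k.n_perm}
        data = pd.DataFrame(
            {"logCS": aligned.log_centroid_size, "diet": meta["diet"].to_numpy()}
        )
        ols = procrustes_lm(
            aligned.flattened, data, ["logCS", "diet"], n_perm=config.n_perm, seed=config.seed
        )
        pgls = procrustes_pgls(
            aligned.flattened,
            data,
            ["logCS", "diet"],
            n_perm=config.n_perm,
            seed=config.seed,
            C=C,
        )
        ols.table().to_csv(out / "lm_shape_logCS_diet.csv", index=False)
        pgls.table().to_csv(out / "pgls_shape_logCS_diet.csv", index=False)
        summary["lm"] = _jsonable(ols.table().to_dict(orient="records"))
        summary["pgls"] = _jsonable(pgls.table().to_dict(orient="records"))

        stage = "decomposition"
        beak_pts = np.asarray(config.beak_points, dtype=int) - 1
        beak_cols = (3 * beak_pts[:, None] + np.arange(3)).ravel()
        brain_cols = np.setdiff1d(np.arange(3 * land.n_points), beak_cols)
        full_pls = phylo_pls(
            aligned.flattened[:, beak_cols],
            aligned.flattened[:, brain_cols],
            n_perm=config.n_perm,
            seed=config.seed,
            C=C,
        )
        summary["pls_full"] = {"rPLS": full_pls.rPLS, "p": full_pls.p_perm}
        dec = decompose(
            aligned,
            blocks=(beak_cols, brain_cols),
            diet=meta["diet"].to_numpy(),
            n_perm=config.n_perm,
            seed=config.seed,
            C=C,
            fraction_basis=config.fraction_basis,
        )
        summary["decomposition"] = _jsonable(dec.summary())
        pd.DataFrame(dec.nani_shapes, index=aligned.specimen_ids).to_csv(
            out / "nani_shapes.csv"
        )

        stage = "group_tests"
        clade = meta["clade"].to_numpy()
        keep = ~np.isin(clade, config.exclude_clades)
        counts = pd.Series(clade[keep]).value_counts()
        usable = counts[counts >= 2].index.to_numpy()
        keep &= np.isin(clade, usable)
        if len(usable) >= 2:
            ptab = pairwise_permanova(
                pca.scores[keep], clade[keep], n_perm=config.n_perm, seed=config.seed
            )
            ptab.to_csv(out / "pairwise_clade.csv", index=False)
            summary["pairwise_clade"] = _jsonable(ptab.to_dict(orient="records"))
        diet_counts = meta["diet"].value_counts()
        if (diet_counts >= 2).all() and diet_counts.size >= 2:
            dtab = pairwise_permanova(
                pca.scores, meta["diet"].to_numpy(), n_perm=config.n_perm, seed=config.seed
            )
            dtab.to_csv(out / "pairwise_diet.csv", index=False)
            summary["pairwise_diet"] = _jsonable(dtab.to_dict(orient="records"))
    except Exception as e:
        (out / "error.log").write_text(f"stage {stage}: {e}\n")
        raise RuntimeError(f"pipeline failed at stage {stage}: {e}") from e

    (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=1, sort_keys=True) + "\n")
    return summary
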