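"""Variance partitioning of skull shape into allometric, integrated, and
residual (non-allometric, non-integrated — "NANI") components.

The cascade has three stages:

1. *Allometric stage* — phylogenetic GLS regression of shape on log
   centroid size; the term R² is the allometric fraction and the GLS
   residuals are the non-allometric shapes.
2. *Integration stage* — two-block phylogenetic PLS of the non-allometric
   beak and braincase blocks; the first-dimension block-1 scores are
   regressed (ordinary least squares) on the block-2 scores, and the
   fitted "prediction scores" of that regression are used as the single
   predictor in a PGLS of the full non-allometric shape.  Its residuals
   are the NANI shapes.
3. *Summary* — the integration R² is expressed on the same basis as the
   allometric one (total variance of the original shape matrix, in the
   phylogenetically transformed metric) so the two fractions add; the
   NANI shapes are tested for phylogenetic signal and for diet effects.

Fractions measured against the total variance of the *original* shape
matrix are additive by construction (sequential sums of squares share one
denominator); the integration R² relative to the non-allometric variance
is also reported for audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo_stats import (
    GLSModelFit,
    PermutationTestResult,
    Phylogeny,
    PLSResult,
    kmult,
    phylo_pls,
    procrustes_pgls,
)
from .superimposition import AlignedShapes


@dataclass
class DecompositionResult:
    allometric_fraction: float
    integration_fraction: float
    combined_fraction: float
    integration_fraction_of_nonallometric: float
    nani_shapes: np.ndarray
    residual_kmult: PermutationTestResult | None
    allometric_fit: GLSModelFit
    pls: PLSResult
    integration_fit: GLSModelFit
    diet_fit: GLSModelFit | None = None
    rpls_full: float | None = None

    def summary(self) -> dict:
        out = {
            "allometric_fraction": self.allometric_fraction,
            "integration_fraction": self.integration_fraction,
            "combined_fraction": self.combined_fraction,
            "integration_fraction_of_nonallometric": self.integration_fraction_of_nonallometric,
            "allometric_F": float(self.allometric_fit.F[0]),
            "allometric_p": None
            if self.allometric_fit.p_perm is None
            else float(self.allometric_fit.p_perm[0]),
            "rPLS_nonallometric": self.pls.rPLS,
            "rPLS_nonallometric_p": self.pls.p_perm,
            "integration_F": float(self.integration_fit.F[0]),
            "integration_p": None
            if self.integration_fit.p_perm is None
            else float(self.integration_fit.p_perm[0]),
        }
        if self.rpls_full is not None:
            out["rPLS_full"] = self.rpls_full
        if self.residual_kmult is not None:
            out["nani_kmult"] = self.residual_kmult.observed
            out["nani_kmult_p"] = self.residual_kmult.p
        if self.diet_fit is not None:
            out["nani_diet_R2"] = float(self.diet_fit.R2[0])
            out["nani_diet_p"] = (
                None if self.diet_fit.p_perm is None else float(self.diet_fit.p_perm[0])
            )
        return out


def allometric_stage(
    aligned: AlignedShapes,
    phy: Phylogeny | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    C: np.ndarray | None = None,
) -> tuple[GLSModelFit, np.ndarray]:
    """PGLS of shape on log centroid size; returns the fit and the
    non-allometric residual matrix (original scale, GLS coefficients)."""
    Y = aligned.flattened
    data = pd.DataFrame({"logCS": aligned.log_centroid_size})
    fit = procrustes_pgls(Y, data, ["logCS"], phy=phy, n_perm=n_perm, seed=seed, C=C)
    return fit, fit.residuals


def integration_stage(
    non_allometric: np.ndarray,
    blocks: tuple[np.ndarray, np.ndarray],
    phy: Phylogeny | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    C: np.ndarray | None = None,
    total_SS: float | None = None,
) -> tuple[PLSResult, GLSModelFit, np.ndarray]:
    """Integration stage of the cascade.

    ``blocks`` are disjoint column-index arrays (beak, braincase) into the
    flattened shape matrix.  ``total_SS``, when given, rescales the
    integration R² onto the original-shape variance basis (stored on the
    returned fit as ``R2``; the fit's own SS_total basis is kept in
    ``integration_fraction_of_nonallometric`` by the caller).
    """
    b1, b2 = (np.asarray(b, dtype=int) for b in blocks)
    if np.intersect1d(b1, b2).size:
        raise ValueError("beak and braincase blocks overlap")
    Y = np.asarray(non_allometric, dtype=float)
    pls = phylo_pls(Y[:, b1], Y[:, b2], phy=phy, n_perm=n_perm, seed=seed, C=C)
    pred = pls.prediction_scores()
    data = pd.DataFrame({"prediction_score": pred})
    fit = procrustes_pgls(
        Y, data, ["prediction_score"], phy=phy, n_perm=n_perm, seed=seed, C=C
    )
    nani = fit.residuals
    return pls, fit, nani


def decompose(
    aligned: AlignedShapes,
    phy: Phylogeny | None = None,
    blocks: tuple[np.ndarray, np.ndarray] | None = None,
    diet: pd.Series | np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    C: np.ndarray | None = None,
    fraction_basis: str = "total",
    residual_signal: bool = True,
) -> DecompositionResult:
    """Run the full allometry → integration → NANI cascade.

    ``fraction_basis`` controls the denominator of the reported
    integration fraction: ``"total"`` (default) uses the total variance of
    the original shape matrix so allometric and integration fractions are
    additive; ``"nonallometric"`` uses the non-allometric variance.
    """
    if blocks is None:
        raise ValueError("blocks (beak, braincase column indices) must be provided explicitly")
    if C is None and phy is not None:
        C = phy.C
    seed = 0 if seed is None else int(seed)
    allo_fit, non_allometric = allometric_stage(
        aligned, n_perm=n_perm, seed=seed, C=C
    )
    pls, integ_fit, nani = integration_stage(
        non_allometric, blocks, n_perm=n_perm, seed=seed + 1, C=C
    )
    allo_frac = float(allo_fit.R2[0])
    integ_of_nonallo = float(integ_fit.R2[0])
    # rescale the integration SS onto the original total-variance basis
    integ_of_total = float(integ_fit.SS[0] / allo_fit.SS_total)
    integ_frac = integ_of_total if fraction_basis == "total" else integ_of_nonallo
    b1, b2 = blocks
    rpls_full = phylo_pls(
        aligned.flattened[:, b1], aligned.flattened[:, b2], n_perm=0, C=C
    ).rPLS
    res_k = None
    if residual_signal and C is not None and n_perm > 0:
        res_k = kmult(nani, n_perm=n_perm, seed=seed + 2, C=C)
    diet_fit = None
    if diet is not None:
        diet_fit = procrustes_pgls(
            nani,
            pd.DataFrame({"diet": np.asarray(diet, dtype=object)}),
            ["diet"],
            n_perm=n_perm,
            seed=seed + 3,
            C=C,
        )
    return DecompositionResult(
        allometric_fraction=allo_frac,
        integration_fraction=integ_frac,
        combined_fraction=allo_frac + integ_of_total
        if fraction_basis == "total"
        else allo_frac + integ_frac,
        integration_fraction_of_nonallometric=integ_of_nonallo,
        nani_shapes=nani,
        residual_kmult=res_k,
        allometric_fit=allo_fit,
        pls=pls,
        integration_fit=integ_fit,
        diet_fit=diet_fit,
        rpls_full=rpls_full,
    )
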