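# Methods

This note documents the statistical models, numerical choices and known
limitations of `phylogm`. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Superimposition

**GPA.** Configurations are centred, scaled to unit centroid size
(CS = √Σ‖xᵢ − x̄‖²), and rotated to the iteratively re-estimated mean by the
orthogonal Procrustes solution restricted to det(+1) rotations (full
Procrustes, reflections disallowed). Iteration stops when the consensus
moves by less than 1e−10 (default; the change norm is reported if the
100-iteration cap is hit). Aligned shapes are orthogonally projected onto
the tangent plane to the unit pre-shape sphere at the consensus, so
Euclidean distances among flattened rows are Procrustes tangent distances —
the property that makes PERMANOVA on full PC scores identical to PERMANOVA
on shapes.

**Bending energy.** For a 3D reference the thin-plate-spline kernel is
U(r) = −r, the sign convention under which the landmark block of the
inverse bordered system L⁻¹ is positive semi-definite; the energy of any
affine displacement field is 0 (both properties are asserted in tests at
1e−9). The quadratic form is symmetrised after inversion to suppress
round-off asymmetry.

**Sliding.** Each semilandmark moves only along the unit chord between its
*before*/*after* neighbours (chord tangents, recomputed every pass from the
current positions, not TPS derivatives — simpler and standard). Per
specimen the tangent displacements solve the m×m linear system that
minimises TPS bending energy against the current consensus; a ridge of
1e−10 is added, which is inert for well-conditioned curve geometry and
stabilises nearly collinear ones. The schedule is slide → re-superimpose →
update consensus, iterated until the consensus moves < 1e−6 or five passes,
whichever comes first. The slid coordinates are returned in the aligned
orientation rescaled to each specimen's original centroid size, so sizes
remain available for allometry. Total bending energy across specimens is
non-increasing between passes (asserted, not assumed).

**Symmetric component.** Each specimen is mirrored by negating one
coordinate axis and swapping paired left/right labels; originals and
mirrors are superimposed jointly and averaged pairwise. The reflection axis
defaults to the axis of smallest variance of the midline landmarks in the
mean configuration (override available). Centroid sizes are taken from the
originals. Sliding is applied before the symmetry duplication by default
(flag to swap); the two orders differ only through second-order
interactions between sliding and asymmetry, both of which are small under
the intended use.

## Phylogenetic statistics

**Covariance.** C[i,j] is the root-to-MRCA path length under the rooted
tree — the tip covariance of unit-rate Brownian motion. The GLS transform
is the symmetric inverse square root of C via eigendecomposition; a
non-positive eigenvalue is a hard error (it indicates duplicate tips or a
corrupted tree, not something to ridge over).

**K_mult.** The multivariate signal ratio follows the standard
generalisation of Blomberg's K: the ratio of the summed squared deviations
of tips from the phylogenetic GLS mean, in the raw versus the C⁻¹ metric,
divided by its Brownian expectation (tr C − n/(1ᵀC⁻¹1))/(n−1). It is
invariant to global branch-length rescaling. The null permutes tip
identities. Calibration (mean ≈ 1 under Brownian motion) is checked over
200 simulations.

**Procrustes regression.** Sequential (Type I) sums of squares in trace
form over the flattened shape matrix, logCS entered before diet (matching
the model shape ~ logCS + diet); F statistics use the full-model residual
mean square; R² is term SS over the intercept-only residual SS. Categorical
terms use treatment contrasts with the alphabetically first level as
reference — term-level SS/F/R² are coding-invariant (tested). Significance
is by RRPP: for each term, residuals of the reduced model containing all
earlier terms are permuted across specimens, and the term's F recomputed;
default 999 permutations plus the observed, so the attainable floor is
p = 0.001. PGLS is literally the same engine after pre-multiplying response
and design (intercept included) by C^(−1/2); on a star tree it reproduces
OLS to 1e−8 (asserted). Reported coefficients and residuals are on the
original scale with GLS coefficients, so residuals are orthogonal to the
design in the transformed metric.

**Phylogenetic PLS.** The evolutionary cross-covariance of the two blocks —
each centred on its phylogenetic GLS mean and whitened by C^(−1/2) — is
decomposed by SVD. Scores are the centred (untransformed) block data
projected on the singular vectors; rPLS is the Pearson correlation of the
paired first scores; the null permutes tip rows of block 2 (the GLS means
are recomputed each permutation). The beak/braincase split is always an
explicit input (a point-index table), never inferred from geometry.

## The decomposition cascade

Stage 1 regresses shape on logCS by PGLS; its R² is the allometric
fraction and its (original-scale, GLS-coefficient) residuals are the
non-allometric shapes. Stage 2 runs phylogenetic PLS on the two blocks of
the non-allometric matrix, then an *ordinary* least-squares regression of
block-1 PLS1 scores on block-2 PLS1 scores — the phylogeny is already
accounted for in the PLS axes, and the score regression is a 1-D
bookkeeping step; its fitted values are the prediction scores. Stage 3
regresses the non-allometric shapes on the prediction scores by PGLS; the
residuals are the NANI shapes.

**Fraction basis.** The integration R² of stage 3 is natively relative to
the *non-allometric* variance. By default the reported integration fraction
rescales that SS onto the total variance of the original shape matrix (in
the transformed metric), so allometric and integration fractions share one
denominator and add exactly; the non-allometric-basis value is also carried
for audit, and a flag switches the reporting convention. NANI residuals are
orthogonal, in the transformed metric, to both the logCS direction and the
prediction-score direction (asserted at 1e−7), and the whole cascade is
invariant to a global rescaling of the landmark coordinates.

## Group tests

One-way PERMANOVA on Euclidean distances among PC-score rows, computed via
group means (pseudo-F = (SSB/(a−1))/(SSW/(n−a))), label-permutation null.
Pairwise tables run every unordered pair and correct with Bonferroni
(Holm by flag); at 999 permutations the adjusted floors are 0.003 for 3
pairs and 0.006 for 6 pairs. Groups represented by fewer than two
specimens are excluded from pairwise testing by the pipeline (driven by
the metadata, not hard-coded), mirroring the practice of dropping
two-specimen relict clades from such comparisons.

## Synthetic data: what it emulates and what it does not

A tip's flattened shape is

template + BM + β·(logCS − μ) + λ·ℓ + diet effect + ε,

where BM is isotropic multivariate Brownian motion on a unit-depth
pure-birth tree; logCS is univariate Brownian motion (σ = 0.35) plus
i.i.d. jitter (σ = 0.05), giving size the strong phylogenetic structure
seen in real comparative data; the latent integration factor λ is itself
Brownian on the tree, so integration survives phylogenetic correction; β
and the block loadings ℓ are random directions (bilaterally symmetrised so
they survive the symmetric-component step); diet classes are drawn i.i.d.
in proportions 72:40:58 (MMR:mixed:LMR) with orthogonal mean-shift
effects; ε is i.i.d. noise.

**Variance accounting.** Shares are defined in the transformed metric
(SS about the GLS mean after whitening), where every ingredient has an
exact expectation: a Brownian component of rate s² contributes q·s²·(n−1)
over q coordinates, an i.i.d. component contributes q·s²·tr(A) with
A = C⁻¹ − C⁻¹11ᵀC⁻¹/(1ᵀC⁻¹1). Effect magnitudes are solved from the
requested fractions; agreement of analytic and mean realised shares is
asserted to ±0.03 over 200 replicates.

Two honest gaps between the generator and real data:

* **Single-history fluctuation.** One dataset contains one realised logCS
  history and one latent-factor history; their quadratic forms fluctuate
  strongly (the effective degrees of freedom of a Brownian draw on a
  phylogeny are far below n−1). Realised shares therefore scatter around
  the injected values with a standard deviation near 0.07–0.09 at n = 150;
  recovery claims are about means over replicates, and the per-dataset
  manifest records the realised shares.
* **Symmetric-component re-weighting.** The injected effect vectors are
  bilaterally symmetric while the Brownian background and noise are
  isotropic; the symmetric-component step removes the asymmetric half of
  the isotropic variance, so shares measured on symmetric shapes exceed the
  tangent-space shares by roughly 1/(1 − (f_bm + f_noise)/2). Parameter
  recovery is therefore asserted on the direct (tangent-space) decomposition;
  the file-round-trip pipeline is checked for qualitative behaviour, not
  tight recovery.

The template is a schematic skull (midline dorsal beak and braincase
curves, bilateral tomial-edge curves, paired lateral landmarks), chosen so
that bending energy and sliding are well-conditioned; it makes no claim to
real psittaciform geometry — only the statistical structure is emulated.
Passing tests demonstrate correctness of the estimators under this
generative model, not the adequacy of that model for any particular
empirical dataset.

## Problem sizes and defaults

Defaults mirror the intended study design: 170 specimens × 60 landmarks,
999 permutations (+ observed) for every test, seed-derived reproducibility
everywhere. The calibration and recovery checks use 50-tip trees (signal
calibration, 200 replicates), 100–150-tip trees (recovery, 40–50
replicates) and the 12-point template, sizes at which the estimators'
behaviour is already asymptotic enough for the stated tolerances.

## Known limitations

* Brownian motion only: no Ornstein–Uhlenbeck or λ-transformed GLS.
* Sliding is along 1-D chord tangents; surface (2-D tangent-plane)
  semilandmarks are out of scope.
* The asymmetric component of shape is discarded, not analysed (no
  directional/fluctuating asymmetry ANOVA).
* Ancestral states assume the rooted tree with no fossil calibration of
  node values.
* The landmark reader accepts plain matrix and TPS-dialect text with a
  configurable block layout; proprietary digitiser formats are not parsed.
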