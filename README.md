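# phylogm

Phylogenetic geometric morphometrics of 3D landmark data, built around one
question: **how much of a clade's skull-shape variation is explained by
evolutionary allometry, by integration between the beak and the braincase,
and by phylogeny — and how much is left for ecology (diet)?**

The package implements the complete analysis chain used in comparative
studies of avian (here, parrot-like) skull evolution:

1. **Superimposition** — generalized Procrustes analysis (GPA) with
   semilandmarks slid along their curve tangents to minimise thin-plate-spline
   bending energy, and extraction of the *symmetric component* of shape for
   bilaterally symmetric configurations.
2. **Ordination** — PCA of the Procrustes shapes, maximum-likelihood Brownian
   ancestral states, phylomorphospace coordinates, and end-member warps along
   PC axes.
3. **Phylogenetic statistics** — the Brownian covariance matrix **C** from a
   time tree; multivariate phylogenetic signal
   *K*<sub>mult</sub>; Procrustes regression *shape ~ log CS + diet* by OLS and
   PGLS (GLS after whitening by **C**<sup>−1/2</sup>) with sequential sums of
   squares and RRPP permutation tests; two-block *phylogenetic* partial least
   squares (rPLS) of the beak and braincase blocks.
4. **Variance decomposition** — the allometry → integration → residual
   cascade: PGLS on log centroid size gives the allometric fraction and the
   non-allometric residuals; PLS1 block-1 scores regressed on block-2 scores
   give *prediction scores*, whose PGLS against the non-allometric shapes
   gives the integration fraction; the remaining residuals are the
   **non-allometric, non-integrated (NANI)** shapes, tested for phylogenetic
   signal and diet effects.
5. **Group tests** — Euclidean pairwise PERMANOVA of PC scores across clades
   and diet classes with Bonferroni (or Holm) correction.
6. **Synthetic data** — a first-class generator (pure-birth trees, a
   skull-like template with sliding curves and bilateral symmetry, Brownian
   shape evolution, injected allometric/integration/diet components with
   *analytically known* variance shares) so that every stage is verifiable by
   parameter recovery without any external data.

All permutation tests are seeded and bit-reproducible, and report
p = (b + 1)/(n<sub>perm</sub> + 1).

## Worked example

Simulate the default study design — 170 species on a unit-depth pure-birth
tree, 60 landmarks (20 fixed + 4 curves of 10 semilandmarks), ground-truth
variance shares of 0.30 (allometry), 0.25 (integration), 0.02 (diet) — then
run the whole pipeline from the on-disk files:

```bash
phylogm simulate full --out study --seed 1
phylogm run study/config.yaml
```

`study/run/summary.json` from that exact command contains (abridged):

```
PC1/PC2/PC3 percent variance   29.9 / 20.4 / 13.1
Kmult (symmetric shapes)       0.427   (p = 0.001, 999 permutations)
OLS   shape ~ logCS   R^2      0.196
PGLS  shape ~ logCS   R^2      0.482
rPLS  beak vs braincase        0.918   (0.922 after removing allometry)
allometric fraction            0.482
integration fraction           0.242
combined fraction              0.723
Kmult of NANI residuals        0.875   (p = 0.001)
```

Reading the output: the first three PCs concentrate the shared
latent-factor and allometric variation; *K*<sub>mult</sub> < 1 says close
relatives resemble each other less than pure Brownian motion predicts (the
non-phylogenetic noise dilutes signal); allometry and integration jointly
account for ~72 % of symmetric shape variance in this realisation.  The
generator's manifest records that this dataset's *realised* tangent-space
shares were 0.374 (allometry) and 0.217 (integration) — a single simulated
evolutionary history fluctuates around the injected 0.30/0.25, and the
symmetric-component step removes the asymmetric half of the isotropic
background, raising the symmetric-shape shares above the tangent-space ones
(see `docs/methods.md`).  Averaged over many replicates the decomposition
recovers the injected shares closely (0.290/0.263 over 50 replicates below).

Every stage is also available piecewise (`phylogm gpa|pca|kmult|pgls|pls|
permanova|simulate|run`) and as plain library calls
(`phylogm.gpa`, `phylogm.kmult`, `phylogm.decompose`, ...).

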