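# Methods

`ecomorph` implements a phylogenetic ecomorphology workflow: given a set
of candidate phylogenies, a species × morphometrics table and a species ×
ecology table (diet and locomotion categories, with unknowns), it asks
whether morphology tracks ecology once body size and shared ancestry are
accounted for, and predicts the ecology of uncharacterised species from
their morphology.

## Phylogenetic covariance and its transforms

All comparative machinery works through the Brownian-motion covariance
matrix `C` of a rooted tree with branch lengths: `C[i,j]` is the shared
root-to-MRCA path length of tips *i* and *j*. Two transforms appear
throughout:

* **Pagel's lambda**: off-diagonal entries multiplied by `λ ∈ [0, 1]`.
  `λ = 0` removes phylogenetic dependence entirely, `λ = 1` keeps the
  full Brownian structure.
* **Whitening** `P = C^{-1/2}` (symmetric inverse square root), so that
  `P C Pᵀ = I`. Pre-multiplying data by `P` converts GLS problems into
  OLS problems.

Degenerate inputs: zero-length terminal branches are permitted; if `C`
becomes numerically singular a ridge of `1e-8 · mean(diag C)` is added
with a warning. Multifurcations are allowed (the covariance is well
defined); non-ultrametric trees are accepted and branch lengths are used
as-is — no unit-height rescaling is performed, since none of the
statistics require it and rescaling would silently change rate
estimates.

Tip-order convention: every matrix is ordered by the sorted tip-name
list; data tables are re-indexed to that order before analysis, and
species-set mismatches are errors (with an explicit `drop_missing`
opt-in in the pipeline).

## Size correction

Each of the 11 linear measurements carried downstream
(LR, ZB, BIT, LMT, HMC, T, E, Vib, HF, FF, UM) is log-transformed
(natural log) and regressed on log body mass by PGLS with the
Pagel-lambda error structure: for a candidate `λ`,
`β̂ = (Xᵀ C_λ⁻¹ X)⁻¹ Xᵀ C_λ⁻¹ y`, `σ̂² = rᵀ C_λ⁻¹ r / n`, and the profile
log-likelihood `-½ [n log(2π σ̂²) + log|C_λ| + n]` is maximised over
`λ ∈ [0, 1]` by bounded scalar optimisation (tolerance 1e-6), with the
interior optimum compared explicitly against both boundary values. The
**ordinary** (response-scale) residuals `y − X β̂` are kept as
"non-allometric shape" variables — deliberately not GLS-whitened, since
they are data for downstream analyses, not diagnostics. Body mass is the
size proxy; condylobasal length and head-body length are dropped
downstream as redundant size measures.

Residuals are computed per tree and averaged across the ensemble so the
shape matrix does not depend on any single phylogenetic hypothesis.
Averaging weights trees equally. The condylar angle ACP does not scale
with size; it bypasses the regression and is centred on its
cross-species mean so that all 12 shape columns are comparable in
location (centring affects no downstream statistic).

The Mosimann log-shape-ratio transform (`log(v / geometric mean)`) is
provided as the allometry-preserving alternative for the case where body
size itself differs among ecological groups; the body-size phylogenetic
ANOVAs in the pipeline are exactly the check that decides whether plain
residuals are appropriate.

A caveat inherent to the residual approach: when trait deviations are
themselves phylogenetically correlated, the residuals retain chance
tree-level correlation with mass that does not vanish with n
(phylogenetic pseudo-replication). The generator's `lambda_signal = 0`
setting gives the clean test of size removal.

## Phylogenetic signal

* **Blomberg's K** with the GLS (phylogenetic) mean `â`:
  `K = [(y−â)ᵀ(y−â) / (y−â)ᵀC⁻¹(y−â)] / [(tr C − n/(1ᵀC⁻¹1)) / (n−1)]`.
  `K = 1` under Brownian motion (exactly 1 on a star tree).
  Significance by tip-label permutation.
* **K_mult** sums the numerator and denominator inner products over
  trait columns with a common phylogenetic mean vector; it reduces
  exactly to K for one column. Permutations shuffle whole species rows.
* **EM-Mantel** for categorical traits: the statistic is the Pearson
  correlation between the lower triangles of the 0/1
  different-category distance and the patristic distance. The null is
  *model-based*: an equal-rates Mk process simulated on the same tree
  with its rate fitted to the observed labels by maximum likelihood
  (Felsenstein pruning; bounded search on the log-rate). The test is
  one-sided (signal = positive association). The Mk model is
  parameterised so that `P(same state | t) = 1/k + (k−1)/k e^{−rate·t}`.

All permutation/simulation p-values use the `(1 + count)/(1 + n)`
convention and therefore are never exactly zero. A star phylogeny has no
variation in patristic distance; the Mantel correlation is reported as 0
there.

Because the synthetic generator evolves ecologies under exactly this Mk
model, the EM-Mantel test is *correctly specified* on synthetic data and
its rejection rate stays near the nominal level no matter how slow the
Mk rate is; the Mantel correlation itself still grows as the rate
drops. Significance on real data arises from clumping beyond what a
fitted equal-rates Mk explains — a misfit the generator intentionally
does not emulate.

## Group tests

* **Phylogenetic ANOVA** (single variable): ordinary one-way F, with a
  null distribution from Brownian simulations on the tree (rate from
  the GLS estimate; the F statistic is scale-free, so the rate only
  matters for interpretability). The group factor is never permuted.
* **Phylogenetic MANOVA**: response matrix and design (intercept +
  group dummies) are whitened by `P = C^{-1/2}`; sums of squares are
  traces of residual cross-product matrices of the full vs reduced
  model; `F = (SS_effect/df_e)/(SS_resid/df_r)`; significance by
  randomisation of the reduced-model residual rows (RRPP, 999
  permutations by default). With `C = I` this reproduces the ordinary
  MANOVA trace statistic exactly.

Both tests were calibrated under their own nulls: empirical type-I error
at α = 0.05 over 200 datasets (199 null replicates each, 50 tips) falls
in [0.02, 0.09] (see `tests/test_acceptance.py`).

## Flexible discriminant analysis and pFDA

FDA is implemented by **optimal scoring**: regress the n × g class
indicator matrix `Y` on `[1, X]`, then solve the g × g generalised
eigenproblem `(Yᵀ Ŷ) θ = α² (Yᵀ Y) θ` restricted to the complement of
the trivial constant score (deflated via the null space of `YᵀY·1`).
The discriminant variates are the fitted values projected on the score
vectors, rescaled to unit pooled within-class variance, so the
discriminant space is spherical and classification is nearest-centroid
Euclidean distance (all dimensions weighted equally; ties broken by
lexicographic class code). Eigenvalues are reported as
`λ_k = α_k²/(1−α_k²)` and the between-group variance share as
`100·λ_k/Σλ` — the canonical-correlation convention; shares always sum
to 100.

**pFDA** applies the same optimal scoring to `(P_λ [1, X_c], P_λ Y)`
with `P_λ` the whitening of the λ-transformed covariance, so the
discriminant projections are evolutionarily orthogonal. The correction
strength λ is chosen by minimising the residual sum of squares of the
whitened indicator-on-morphology regression over a 0.01-step grid with
bounded refinement around the best grid point (the profile is
occasionally multimodal, hence the pre-scan); a flat profile (star
phylogeny) returns 0 by convention. At `λ = 0` on an ultrametric tree
`P_0 ∝ I` and pFDA reproduces FDA scores exactly.

Coefficients are always reported on the untransformed scale and applied
to centred data directly; in particular, unknown species are predicted
without re-whitening their phylogenetic positions. This is a deliberate
simplification: at the small optimal λ values characteristic of weakly
conserved ecological classes, the difference is negligible (the
pipeline verifies this directly via the FDA/pFDA score correlation,
reported per tree).

A property worth knowing when interpreting λ̂: class labels produced by
*thresholding* a Brownian liability yield λ̂ well below the liability's
λ (typically 0.2–0.3 for a median-thresholded λ = 1 liability at
n = 200), because the 0/1 indicators attenuate the liability's
phylogenetic correlation. Labels that partition clades cleanly drive
λ̂ to 1, and random labels on a star tree give 0.

**Cross-validation** is stratified k-fold (default 10 "random
partitions"); the fold count degrades to the smallest class size with a
warning, and classes with fewer than 3 members (impossible to both train
on and hold out) are dropped with a warning. The partition is
seed-reproducible.

**Wilks' lambda** per variable is the one-way `SSW/SST` ratio with
`F = ((1−Λ)/Λ)·((n−g)/(g−1))` referred to `F(g−1, n−g)`; a constant
variable reports Λ = 1, F = 0, p = 1 with a warning. **Structure
correlations** are Pearson correlations between each variable and each
discriminant score over the training species, with a Holm correction
applied across the entire variable × DF table (the most conservative
reasonable family).

## Sammon morphospace

The 12-column shape matrix is embedded in 2-D by minimising Sammon's
stress `E = (Σδ)⁻¹ Σ (δ−d)²/δ` over pairs, using the original
diagonal-Newton iteration: step factor 0.3, halved whenever a step would
increase the stress, tolerance 1e-9 on the relative stress change,
at most 500 iterations. Initialisation is the first two principal
coordinates — deterministic, so results are reproducible without a
seed. Input distances are Euclidean on the 12 shape columns with no
re-weighting. Exact duplicates (zero distance) are jittered with a
warning. The stress is invariant to rescaling all input distances and
to rigid motions of the configuration; the accepted-iteration stress
path is non-increasing by construction. Because one column is an angle,
the morphospace is affine rather than strictly Euclidean — the
ordination output records this caveat in its metadata.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
at the scale of a multi-family rodent dataset:

* **Tree**: pure-birth, 200 tips by default, ultrametric.
  Alternative hypotheses in an ensemble are lognormal branch-length
  jitters (sd 0.10) plus 2 random tip swaps of the generating tree —
  local placement uncertainty, as in posterior tree sets.
* **Body mass**: Brownian log-mass around 150 g with tip sd 1.5 log
  units (≈ 10 g – 10 kg across species).
* **Linear traits**: `log v = a + b·log mass + BM(λ) deviation +
  class shift + N(0, 0.05)` with isometric slopes `b = 1/3` and
  anchors giving realistic millimetre magnitudes. The deviation sd is
  0.15 log units with `λ = 0.2` by default — the weak-but-nonzero
  signal regime (K_mult ≈ 0.15–0.2).
* **ACP**: 120° baseline, 8° Brownian(λ) deviation, 2° noise, diet
  shifts in degrees.
* **Ecology**: diet (C/I/GH/SH) by fast equal-rates Mk (rate 2.0 per
  unit branch length → Mantel r ≈ 0), locomotion (T/Sa/A/Sf/F/R/G) by
  slow Mk (rate 0.25 → moderate positive Mantel r with all classes
  represented). Class membership then shifts morphology (diet shifts
  craniodental variables, locomotion shifts external ones) with
  per-class offset vectors of RMS `class_shift` (default 3) deviation
  SDs — the strongly separable regime. Generating ecology by Mk and
  then shifting morphology decouples phylogenetic signal in ecology
  from the ecology-morphology association.
* **Unknowns**: 20% of diet and 17% of locomotion labels replaced by
  "U", to be predicted.

What the generator does **not** emulate: measurement error structure,
unequal Mk transition rates, morphology-ecology feedback (labels driven
by morphology), and the non-Mk clumping that makes real categorical
traits significant under the EM-Mantel null. Passing tests therefore
demonstrate the machinery's correctness and calibration, not the
empirical conclusions one would draw from real data.

## Pipeline aggregation and problem sizes

`run_full_analysis` repeats every per-tree statistic across the
ensemble and reports median/min/max plus the count of trees significant
at α = 0.05. Every stochastic stage draws a child seed from the master
seed, recorded in the report; a report is reproducible from
(inputs, config, seed).

Default problem sizes used by the reproduction script
(`scripts/acceptance.py`): 200 species, 100 trees, 999 permutations for
K/K_mult/ANOVA/MANOVA and 199 Mk simulations per tree for the EM-Mantel
null — chosen as a full-scale run that completes in a few minutes on a
single core. The test suite uses 40–200-tip datasets with 99–999
replicates per test.

## Known limitations

* pFDA predictions for unknown species ignore the unknowns'
  phylogenetic positions (see above); at λ ≈ 0 this is exact.
* The EM-Mantel variant is pinned to equal-rates Mk with an ML rate and
  a one-sided alternative; other rate models are out of scope.
* `optimal_lambda` is a profile over a single scalar; no uncertainty is
  attached to λ̂.
* The Sammon embedding is 2-D only, and convergence is to a local
  optimum of a non-convex stress (the deterministic PCoA start makes it
  reproducible, not global).
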