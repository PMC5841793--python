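# Methods

`carapace` re-implements, as a tested pipeline, a landmark-based analysis of
shape variation in box-turtle (*Terrapene carolina*) carapaces: it
characterizes the modern sources of variation — maturity, sexual
dimorphism, geographic clines, allometry — and then asks how much of the
fossil record those sources can account for. This note records the models,
the numerical choices, and what the synthetic data do and do not show.

## Shape model and superposition

Each specimen is digitized in three views (dorsal 49 points, lateral 44,
posterior 63). Point semantics live in a versioned scheme registry
(`schemes.yaml`): which points are sliding semilandmarks (with their tangent
chords), which lie on the midline, and how bilateral points pair. The
published landmark table fixes counts, chains, and midline membership; the
exact left/right pairing of non-chain bilateral landmarks is not recoverable
from it, so the registry defines a canonical pairing consistent with the
chain structure.

Generalized Procrustes analysis iterates center / scale-to-unit-centroid-
size / rotate-to-mean (SVD, det +1 enforced — specimens are digitized in a
consistent anatomical orientation, so reflections are excluded) until the
mean changes by < 1e-10, up to 300 iterations; the mean's rotational drift
is removed each iteration so the stopping rule is well defined.
Initialization is the first specimen; order-permutation invariance is
verified by test rather than assumed.

Semilandmarks slide along the chord through their two scheme neighbors, by
the projection of their deviation from the current mean onto that chord —
i.e., minimization of Procrustes distance, not bending energy. Sliding
passes are interleaved with re-superposition after GPA convergence and stop
when the objective improves by < 1e-8 (10 passes max); a pass that fails to
improve is reverted, so descent is monotone by construction. One
consequence worth knowing: sliding absorbs the chord-tangential component
of any systematic shape field at semilandmarks, so e.g. an allometric
vector is only partially recoverable from a slid alignment (the
parameter-recovery tests therefore use the non-slid fit).

Missing bilateral points are estimated by reflecting the present partner
across the total-least-squares midline axis (TLS because digitization error
is symmetric in x and y). For the two object-symmetric views, analyses use
the symmetric component: each aligned specimen is averaged with its
mirrored, pair-relabeled copy after joint superposition, and one half (plus
midline) is retained — using both sides' information while avoiding the
inflated degrees of freedom of analyzing a symmetric object whole. Shape
variation is treated as Procrustes residuals in the linear tangent space at
the mean (standard small-variation approximation; no separate projection
step).

Per view, only the leading "repeatable" principal components (dorsal 5,
lateral 9, posterior 13) feed the discriminant, clustering, and disparity
analyses, limiting the impact of digitization error.

## Statistics

**Procrustes ANOVA.** Sequential (Type I) sums of squares over all shape
coordinates jointly, with terms in caller order (covariates before factors,
matching how the original tables are laid out). Significance is by residual
randomization (RRPP): each term's reduced-model residuals are permuted
across specimens (the same permutation for every term within an iteration),
the term's F is recomputed with the permuted data's own full-model
denominator, and p is the proportion of permuted F at least the observed
one, observed included — so a fixed seed fixes p exactly. Default 999
permutations; the seed is a required argument.

**Pairwise tests** (subspecies, fossil sites) run the same ANOVA on each
pair's subset with any stated covariates entered first and adjust across
pairs within a view by Benjamini–Hochberg FDR.

**Repeatability.** One-way Procrustes ANOVA on specimen identity across
replicate digitizations; variance components in the standard random-effects
layout (`s2_among = (MS_among − MS_within)/n0`, floored at zero, Sokal–Rohlf
`n0` when unbalanced). ICC = s2_among/(s2_among + s2_within) and
ME% = 100·(1 − ICC), so the two always sum to one by construction.

**CVA assignment.** Canonical axes from the generalized eigenproblem of
between- vs pooled within-group covariance (axes normalized so within-group
covariance is the identity, making nearest-centroid distance Mahalanobis);
equal priors. Jackknife validation recomputes the axes with each specimen
left out, in the PC subspace computed once from the full sample (the
subspace is a fixed measurement basis, not part of the classifier). Ties go
to the first group in stable sort order.

**Clustering.** Gaussian mixtures for k = 1..4 across spherical, diagonal,
and full covariance families (scikit-learn EM, 10 k-means++ restarts,
covariance ridge 1e-6). BIC is reported as 2·loglik − n_params·ln n, higher
better; models containing a single-member cluster are flagged uninformative
and passed over.

**Sexual dimorphism.** Size dimorphism uses untransformed carapace lengths:
compressed SDI = F̄/M̄ − 1 when females are at least as large, else
−(M̄/F̄ − 1) — antisymmetric around zero and scale-invariant, negative
meaning males larger. CIs are percentile bootstrap, resampling within each
sex (stratified, preserving the two-sample design), default 10,000
replicates. Shape dimorphism is the Procrustes ANOVA with log centroid
size and subspecies entered before sex.

**Spatial structure.** Moran's I with row-standardized k = 5
nearest-neighbor weights screens variables for autocorrelation (one-tailed
permutation p; the neighbor count affects only this screen). Spatial
eigenvectors come from principal coordinates of the great-circle distance
matrix (Gower centering of −D²/2; untruncated by default, the minimal
reading of an SVD of the distance matrix; a distance-truncation option
exists for dbMEM-style analyses). Positive-eigenvalue vectors are kept,
unit-normalized, ordered by eigenvalue, and sign-fixed by positive
correlation with longitude (tie: latitude) so maps and regression signs are
reproducible. Forward selection adds, greedily, the SE with the largest
additional multivariate redundancy R² on the repeatable PCs if its
permutation p < 0.05, keeping at most two (limiting model complexity).

**Fossil chain.** Bimodality is a largest-gap rule: a site splits if the
largest gap between consecutive sorted lengths is ≥ 60 mm (the observed
separation at the bimodal sites; transparent, unlike a formal dip test).
A bimodal site is then modelled as two sexes — large morph as the larger
modern sex — and that SDI is compared with the closed modern bootstrap
interval; falling outside rejects dimorphism as the explanation. Slope
homogeneity is the log CS × era interaction in a pooled Procrustes ANOVA.
When slopes differ, all specimens are regressed against the modern
allometric model (fit on moderns only) and residual-plus-grand-mean shapes
are the corrected samples; sizes outside the modern range trigger an
extrapolation warning. Fossil scores are always projections onto the
modern (corrected) PC basis — never a joint re-PCA — so modern-only
statistics are unchanged by adding fossils.

**Disparity** is Σdᵢ²/(N−1) in repeatable-PC space, identically the trace
of the unbiased score covariance (Procrustes-variance convention; the
literal "distance to the mean" reading is available as `method=
"mean_distance"`). Rarefaction resamples the modern sample with replacement
1000 times at N = 10..200 (step 10); the one-tailed 95% bound is the 95th
percentile, upper side only, because the question is whether fossils *add*
disparity. A fossil set's augmented disparity (pooled with the full modern
sample) is compared with the bound linearly interpolated at the pooled
size. This comparison is conservative under the null: the modern sample is
part of the pooled set, so same-distribution fossils move pooled disparity
to the center of the bootstrap distribution, and the realized
false-positive rate is below the nominal 5%.

## Synthetic data

The generator is the testbed for the whole pipeline: schematic but
topologically exact carapace templates per view (correct counts, symmetry
pairing, semilandmark chains; no attempt at true shell geometry), specimen
shapes built as template + logCS·allometry + sex·dimorphism/2 + spatial
clines + landmark noise, all effects expressed as unit tangent vectors
(orthogonal to similarity transforms, symmetrized in symmetric views) times
magnitudes in Procrustes units.

Default conditions and why:

- sample sizes: 200 modern (50 per subspecies), 52 sexed (26/26), a
  215-specimen growth series, and four fossil sites (28 carapaces) — the
  study's dataset sizes;
- subspecies mean lengths 151/133/127/126 mm and within-subspecies
  log-length sd 0.13, from the reported means and ranges; male/female mean
  ratio 1.086, reproducing the modern compressed SDI of ≈ −0.086;
- growth: log length linear in ring count up to 8 rings (slope 0.105,
  noise sd 0.10, putting the juvenile-segment R² near the observed ~0.85)
  and flat beyond; fontanelles close at the threshold with a sub-percent
  discordance rate;
- effect magnitudes (allometry 0.08 per log-mm, dimorphism 0.016, clines
  0.011/0.009, landmark noise 0.004 per coordinate, digitization noise
  0.001) set by variance arithmetic so the generated shares land where the
  study reports them: allometry a few percent of shape variance, sex 4–9%,
  the two clines together ~10%, measurement error in the single-digit
  percents with ICC ≥ 0.9;
- localities from four regional Gaussians (one per subspecies range), which
  produces genuine spatial autocorrelation for the SEVM analyses;
- fossil sites: a Holocene pool matching moderns, a bimodal site pair with
  modes 130/255 mm (morph ratio ≈ 1.96, hence SDI ≈ −0.96 when modelled as
  sexes, far outside the modern CI), and two large-bodied sites with mean-
  shape offsets of 0.04–0.05 Procrustes units drawn as mixtures of the
  modern effect directions plus a fresh component — in-span offsets load on
  the leading modern PCs the way real fossil differences do.

What the synthetic data do *not* show: real shell geometry (so predicted
deformation plots are not anatomically meaningful); museum-data pathologies
(georeferencing error, missing metadata, damaged specimens beyond the
missing-landmark path); and the study's exact per-site disparity flag
pattern — the synthetic offset sites are strong enough that individual
sites can exceed the rarefaction bound, whereas in the study only the
pooled fossil set did, in one view. Passing tests certify the estimators
and the inference chain, not any empirical claim about real carapaces.

## Degenerate inputs and tie rules

Fewer than 3 points is a degenerate configuration; missing points are
masks, never sentinel coordinates, and must be estimated before
superposition. A missing point whose bilateral partner is also missing is
unrecoverable. Constant columns give Moran's I = NaN; zero size variance
makes allometry unidentifiable; disparity needs n ≥ 2; groups below minimum
size are excluded from pairwise tests with a warning; singular pooled
covariance in CVA is an error after automatic PC reduction. CVA ties break
to the first group in sorted order; mixture models that empty or
singleton a cluster are flagged. GPA non-convergence warns and returns the
last iterate.

## Problem sizes used in checks

The verification suite runs the calibration checks at the sizes that make
them meaningful while staying quick: 200 null datasets × 199 permutations
for ANOVA type-I error, 200 bootstrap-coverage repeats, 100 sliding
datasets, 100 SEVM recovery simulations, 1000-replicate rarefaction curves.
The acceptance script runs the full pipeline at the study sizes (200 modern
specimens, 999/499 permutations, 10,000-replicate SDI bootstrap).
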