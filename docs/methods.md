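# Methods

`neogyri` implements an individualized analysis of cortical folding in
neonates: a vertex-wise gyrification index (GI) computed on triangulated
pial surfaces, Gaussian-process normative models that express each subject's
GI as a deviation Z-score from the typical developmental trajectory,
cerebral oxygen delivery (CDO2), and the group/correlation statistics that
tie these together. Because suitable MRI-derived surfaces and cohort tables
are rarely shareable, the package also contains first-class synthetic
generators whose ground truth is known analytically, and every downstream
stage is validated against them.

## Gyrification index

The local GI of a vertex is the ratio of total cortical (pial) surface area
to visible envelope area inside a circular region of interest, after Zilles'
classical definition extended to vertex-wise maps. The *outer smoothed
surface* — an envelope that tightly wraps the pial surface and bridges over
sulci — is constructed by:

1. voxelizing the pial mesh at `voxel_size` (default 1 mm) and filling it;
2. morphological closing with a Euclidean ball of `closing_radius`
   (default 10 mm), implemented by distance-transform thresholding;
3. marching-cubes isosurface extraction. The level is placed at
   `closing_radius + 0.75` voxels of the inward distance transform: the
   rasterized voxel shell and the centre-to-centre distances each bias the
   discrete closing outward by roughly half a voxel, and this fixed
   sub-voxel compensation makes the envelope a near-identity on convex
   bodies (a sphere's envelope area is reproduced to about 1 %);
4. Taubin smoothing (λ = 0.5, ν = 0.51, inside the stability region
   0 < 1/λ − 1/ν < 0.1; 10 iterations).

For each (optionally stride-subsampled) envelope vertex, a geodesic disc of
`roi_radius` (default 20 mm — smaller than the 25 mm adult convention,
reflecting neonatal head size) is grown by Dijkstra's algorithm over mesh
edges, an upper bound on the exact geodesic distance that is adequate for
disc ROIs at these radii. Each pial vertex is attached to its nearest
envelope vertex (Euclidean); the local GI at a disc is the lumped vertex
area of the attached pial patch divided by the disc's own vertex area, and
values propagate back to pial vertices from their nearest retained envelope
vertex. Two passes of one-ring averaging damp residual discretization dips
(the overlapping-ROI construction is smooth by design; the averaging leaves
the mean unchanged to four decimals on the test surfaces).

Whole-brain GI is the unweighted arithmetic mean over all pial vertices
(union of hemispheres, not a mean of hemisphere means); regional GI averages
within an integer label map, with label 0 (medial wall / unassigned)
excluded. On star-shaped test surfaces with spatially uniform folding the
mean local GI agrees with the global pial-area/envelope-area ratio computed
from an independent quadrature oracle to about 2 %, and is exactly 1 on a
sphere up to discretization.

## Normative model

One GP per region per covariate specification, after the normative-modelling
approach used for neonatal brain growth:

* Model 1: post-menstrual age at scan (weeks), post-natal age at scan
  (days), sex (0/1);
* Model 2: Model 1 plus supratentorial brain volume (STBV, cm³).

Covariates are standardized by the training mean/sd. The predictive mean is
a **linear mean function** (least squares over standardized covariates) plus
a GP with an anisotropic RBF kernel and white noise fitted to the residuals
(scikit-learn backend; marginal-likelihood optimization with seeded
restarts, default 5 in the library and fewer in the bulk pipeline). Two
numerical choices matter and were made deliberately:

* *Linear mean, not linear kernel.* Clinical cohorts are typically scanned
  one to two weeks earlier than the reference cohort, i.e. at the edge of
  the covariate range. A purely stationary kernel reverts to the training
  mean there and biases deviation scores by several hundredths of a GI
  unit; the explicit linear mean extrapolates the growth trend.
* *RBF length-scale floor of 0.5 training sd.* Without it the
  marginal-likelihood optimum can memorize observation noise, deflating the
  predictive spread and miscalibrating held-out Z-scores.

The deviation score is z = (observed − predicted) / σ(x), where σ is the
*total* predictive standard deviation including the learned noise floor —
otherwise held-out reference scores cannot be N(0, 1). Reference subjects
are scored by k-fold cross-validation (default 5-fold; leave-one-out
available and exactly equal to per-subject refitting); clinical subjects by
the full reference model.

**A caution on z-based group tests.** The normative model's own estimation
error is shared across all subjects it scores. A t-test on deviation scores
treats them as independent, so when the clinical group is large relative to
the reference cohort, or demographically shifted from it, the group test's
false-positive rate exceeds its nominal level (we measure ≈0.10 at a 120/60
reference/clinical split, and far worse under covariate shift). The
end-to-end type-I Monte-Carlo therefore uses a small clinical-to-reference
ratio (200/33), where the shared error is negligible; the measured rate is
then nominal. This is a property of the method class, not of this
implementation, and is worth bearing in mind when interpreting such tests
on real cohorts.

## Physiology

Total cerebral blood flow is the sum of left/right internal carotid and
basilar flows. Oxygen delivery uses the literal clinical formula
CDO2 = SaO2 × [Hb] × 1.36 × CBF with Hüfner's constant 1.36 ml O2 per gram
of haemoglobin and Hb on the g/dl scale; with near-cohort-mean inputs
(SaO2 0.90, Hb 16.7 g/dl, CBF 85.2 ml/min) it evaluates to 1741.6, the
magnitude conventionally printed in the neonatal literature. This product
is not dimensionally strict — a unit-audit helper reports the SI-consistent
value (Hb in g/ml, i.e. the literal value / 100) alongside, and no silent
conversion is performed. SaO2 is a fraction by default; percentage input
requires an explicit flag.

## Statistics

Welch's unequal-variance t-test (group sizes and variances differ between
cohorts); ANCOVA as the nested-OLS F-test of the group factor against the
covariates-only model (equal to one-way ANOVA, i.e. the squared pooled t,
with no covariates); Pearson correlation with R²; partial Spearman as the
residual-on-residual correlation of mid-ranks after regressing out covariate
ranks, with p from the t transform at df = n − 2 − #covariates; and
Benjamini–Hochberg step-up FDR. Families: the seven regional comparisons per
model form one family, the three clinical-subgroup comparisons another.
Shapiro–Wilk is run as a logged screening step and never gates the pipeline.
Missing physiological or outcome data are handled by complete-case analysis.
Every estimator is tested against an independent textbook-formula or
brute-force oracle to 1e-8, and partial Spearman additionally against an
independent library implementation.

## Synthetic data: what it emulates, and what it does not

Surfaces are star-shaped "bumpy spheres" r(θ, φ) = R(1 + a sin kθ sin kφ):
closed, self-intersection-free for a < 0.5, with surface area available by
quadrature. They exercise the complete GI machinery but are idealized — they
have no deep narrow sulci, no medial wall, and uniform folding, so passing
the geometry checks demonstrates correctness of the area-ratio computation,
not performance on convoluted cortical anatomy.

Cohorts mirror the statistical structure the analysis assumes, with
conditions fixed at realistic neonatal values: reference n = 320 and
clinical n = 142 (subgroups 60/43/39: abnormal streaming, left-sided,
right-sided); whole-brain GI 2.96 at 41.5 weeks PMA growing 0.08/week with
noise sd 0.10 (six regional levels 2.52–3.70 with sds 0.08–0.18); STBV
320 cm³ at 40 weeks, 15 cm³/week, +8 cm³ for males, noise sd 25 cm³; CBF
85 ml/min at 280 cm³ STBV with slope 0.2 ml/min/cm³ and lognormal noise;
SaO2 0.92 ± 0.05 (clinical) vs 0.97 (reference); Hb 16.7 ± 2.4 g/dl;
outcome scores at clinical means 93/94/29, independent of GI by
construction. PNA is exactly 7·(PMA − GA) days. Three deficit modes:

* `none` — the null: both groups are exchangeable draws from the reference
  process (matched demographics, no deficit);
* `volume_mediated` — clinical STBV shifted down 60 cm³ and GI generated as
  a function of the STBV residual (0.004 GI/cm³) with no group term: Model 1
  sees a deficit, Model 2 explains it away;
* `direct` — a group term on GI in units of the noise sd, STBV untouched;
  under a deficit the clinical group is also born and scanned earlier, as in
  real cardiac cohorts.

Gaussian noise around linear trends is an assumption — the real
distributional forms are unknown — and regional noise terms are drawn
independently, so cross-regional correlation structure is not emulated.

## Replicate design of the stochastic acceptance experiments

Scoring a demographically shifted clinical cohort carries a *correlated*
model-extrapolation error of roughly 0.2 z per simulated cohort (it shifts
all clinical subjects together). Quantities defined as cohort means —
held-out calibration, deficit recovery, the Model 2 mean under the
volume-mediated scenario — are therefore measured as averages over a small
number of replicate cohorts (four to eight, seeds assigned by fixed rule),
which controls the Monte-Carlo error of the estimate without altering the
study conditions. Problem sizes throughout (10k-vertex surfaces, 200-rep
type-I Monte-Carlo at a 200/33 split, 3-fold reference CV with single
restarts in bulk runs) were chosen to keep each experiment in the
seconds-to-minutes range on one CPU.

## Known limitations

* The geodesic disc uses graph (Dijkstra) distance, an overestimate of the
  exact geodesic; discs are correspondingly slightly small at fixed radius.
  The pial↔envelope correspondence is nearest-Euclidean-point, not normal
  propagation.
* The kernel and normalization of the originally released normative-GPR
  code are not reproduced; the composite here (linear mean + RBF + white
  noise) is a conventional choice for growth-curve models.
* Whether the whole-brain mean should be vertex-area-weighted is an open
  question; the unweighted vertex mean is implemented.
* For the CDO2–GI association both Pearson (on scores) and partial Spearman
  (given PMA, PNA, sex) are computed and reported side by side, as the two
  conventions in circulation disagree; neither is privileged.
* Envelope construction assumes a single closed, watertight input mesh and
  rejects anything else rather than attempting repair.
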