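# Methods

This note documents the models, estimators, numerical choices and known
limitations of `hippoaxis`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Relaxometry

Each voxel of a multi-echo series is fitted with the two-parameter
monoexponential decay `S(TE) = S0 · exp(−TE/T)` by nonlinear least squares
on magnitude signals with Gaussian-residual assumptions (no Rician floor
term; adequate at the high SNR the generator simulates). The solver is a
Levenberg–Marquardt iteration vectorized over voxels, initialized from the
log-linear regression of the positive echoes; steps are accepted only if
they reduce the residual, so the NLLS result is never worse than its
log-linear start. `T` is constrained to `(0, T_max]` with
`T_max = 2 × TE_last`: slower decay is not identifiable from the sampled
echo window, and such voxels are clipped and flagged rather than left to
drift. Voxels with no positive echo are undefined (NaN, the package-wide
undefined marker) and flagged. Default echo grids mirror the simulated
acquisition: six spin echoes 14.6–87.6 ms (T2) and twelve gradient echoes
4–59 ms (T2\*).

## Diffusion tensor scalars

Tensors are estimated by ordinary least squares on log-signals against the
six quadratic design columns plus log S0 (plain OLS; no reweighting).
Nonpositive signals are excluded per voxel; a voxel needs ≥ 7 usable
volumes. Negative eigenvalues are clamped to zero and flagged, which keeps
profiles defined in noisy voxels. Scalars: MD = tr/3, RD = (λ2+λ3)/2,
FA = √(3/2)·‖λ−MD‖/‖λ‖, and the **trace-normalized** Westin measures
c_l = (λ1−λ2)/tr, c_p = 2(λ2−λ3)/tr, c_s = 3λ3/tr. The trace-normalized
convention (rather than the λ1-normalized original) was chosen because its
exact invariant c_l + c_p + c_s = 1 makes every downstream test sharp; the
choice rescales c values but changes no pipeline logic. The default
simulated protocol is 60 quasi-uniform directions (Fibonacci sphere) at
b = 2000 s/mm² plus four b = 0 volumes.

## Axis skeleton and profiles

The septotemporal midline of a mask is extracted with a geodesic level-set
method. Geodesic distances (26-connected voxel graph, physical edge
lengths) from the two tube end faces define an axial coordinate
h = (d_temporal − d_septal)/2 whose level sets are cross-sections; each
0.5-mm axial bin is collapsed to its medialness-weighted centroid (weights
= Euclidean distance-to-surface⁴, so boundary voxels barely contribute).
End zones, where level sets have not yet flattened into cross-sections, are
trimmed over a depth of twice the local end radius and replaced by a
quadratic continuation marched inside the mask to its boundary. The
polyline is resampled at 1-mm control points and interpolated with a
shape-preserving piecewise cubic (pchip), oriented so that position 0 mm is
the temporal (most ventral, smallest-z) end — an explicit hint point can
override the convention. This construction was preferred over lattice
thinning because it operates in physical coordinates and is therefore exact
on the strongly anisotropic grids used here (0.15–0.3 mm in-plane, 0.5-mm
slices), where thinning algorithms are lattice-bound. Against the analytic
centerline of a synthetic straight tube, control points lie within 0.05 mm
of the true axis and the length errs by < 1%; on a curved, tapering C-tube
the worst control-point deviation (~0.7 mm, at the extreme ends) stays well
below the local tube radius. Masks that are disconnected, shorter than
3 mm, or ring-shaped (cross-sections splitting into arms farther apart than
three tube radii) are rejected.

Voxels are projected to the curve by dense arc-length sampling at 0.01-mm
steps (agreement with an exhaustive 0.001-mm search is ≤ 0.005 mm; exact
ties resolve to the smaller position). Profiles use Gaussian weights
w = exp(−(s−p)²/2σ²), σ = FWHM/√(8 ln 2) with FWHM 1.5 mm, truncated beyond
4σ (peak contribution < 3·10⁻⁴); the weighted SD is the population formula
with normalized weights (no small-sample correction). Positions run every
0.5 mm from the temporal end by default. Surface voxels are removed by one
6-connected erosion before profiling (partial-volume guard); a configurable
drop of the last k slices (default 0) emulates the exclusion of low-SNR
caudal slices in real acquisitions. Positions with total weight < 10⁻⁶ are
undefined and flagged.

## Position-wise statistics

Each (parameter, day, statistic ∈ {mean, SD}, side, position) cell is
compared between groups with the two-sided Mann–Whitney U test: the exact
null distribution when the pooled sample has ≤ 20 observations without
ties, otherwise the normal approximation with tie and continuity
corrections. Benjamini–Hochberg step-up control at q = 0.05 is applied
within one family per (contrast, side, day, statistic) spanning positions ×
parameters — matching how significance is usually displayed per panel — with
a single global family available behind a flag. Single-parameter
discrimination is the rank-based empirical AUC (ties count one half) with a
bias-corrected and accelerated (BCa) bootstrap interval: resampling is
stratified by class, the bias correction comes from the bootstrap
distribution's position relative to the point estimate (ties half-weighted),
the acceleration from jackknife skewness; a degenerate bootstrap
distribution falls back to the percentile interval and is flagged.

## Prognostic models

At each axis position the feature matrix holds 48 predictors: (T2, T2\* at
days 2/7/21; FA, MD, RD, λ1–λ3, c_l, c_p, c_s at days 7/21 — no diffusion
scan at day 2) × (weighted mean, weighted SD), in a fixed canonical order.
The classifier is logistic regression with an elastic-net penalty at equal
LASSO/ridge mixing, observation-weighted by inverse class frequency
(weights normalized so rescaling them is a no-op), intercept unpenalized.

Evaluation is a nested (externally validated) leave-one-out CV. Inside each
outer training set: class weights and standardization statistics
(population SD; zero-variance columns dropped for that fold) are
recomputed — per-fold standardization was chosen for validity, with a
global-standardization flag retained only for leakage-differential testing;
a descending λ path is fitted (default 100 values log-spaced from λ_max,
the smallest strength zeroing all coefficients, down by 10⁻⁴) and the inner
CV (leave-one-out by default; seeded stratified k-fold as a faster option)
selects the λ minimizing held-out weighted binomial deviance, ties
resolving to the strongest regularization (parsimony). Class weights enter
both the fit and the inner deviance. The held-out animal's probability is
pooled across outer folds into one cross-validated AUC; its 95% BCa CI
resamples (label, probability) pairs; a position is flagged as
discriminating when the CI lower bound exceeds 0.5. Predictor importance is
the fold-averaged standardized coefficient; the top-k are those with the
largest absolute average at any position. Hippocampal volumes (2 sides × 3
days) feed the identical machinery as a 6-predictor variant.

The path solver is a coordinate-descent/IRLS implementation (JIT-compiled)
because nested LOOCV needs thousands of warm-started path fits per cohort;
it matches an independent solver on identical penalties to < 10⁻³ in the
tests. Pooled probabilities are reported to 6 decimals: under strong
regularization with class weights every fold's probability is exactly 1/2,
and rounding prevents optimizer round-off from ordering mathematically tied
predictions (which would bias the pooled AUC away from the tie value 0.5).
Randomness enters only the bootstrap and the optional inner fold
assignment; the LOO loops are deterministic.

## Synthetic cohorts

The generator emulates the study conditions rather than any specific
animal: 16 sham + 68 TBI by default, with 81% cognitive impairment and 22%
epilepsy among the injured (counts deterministically rounded; which animals
are positive is randomized per seed, making the ~80% overlap of epileptic
and impaired animals emerge naturally). Each hippocampus is a C-shaped
circular arc (length 12 mm — the septotemporal extent is a documented
assumption in the 11–12 mm range plausible for rat — spanning 150°, tube
radius tapering 0.8→1.4 mm, 2-mm ventral-to-dorsal rise so the temporal end
is the most ventral) voxelized on an anisotropic grid (0.15 mm in-plane,
0.5-mm slices by default) with flat end caps; the analytic centerline is
returned for oracle use. Per-animal size jitter (3% lognormal) and
TBI-ipsilateral radius shrinkage (5/12/20% volume at days 2/7/21) provide
volumetric pathology.

Parameter maps are baseline + windowed group effects + Gaussian voxel
noise. Baselines (T2 55 ms, T2\* 40 ms, MD 0.7·10⁻³ mm²/s, FA 0.25, ...)
are generator knobs in rodent-plausible ranges, **not** measured reference
values, as are the effect amplitudes. Effect windows live on true arc
length with a 0.5-mm half-cosine ramp extending outward (full amplitude
everywhere inside the window; no knife edges). The default injury pattern
raises T2/T2\* everywhere ipsilaterally at day 2 (edema), lowers them
septally later, raises day-7 MD, lowers septal FA/c_l while raising c_p at
day 21, adds milder septal-end contralateral changes, and places a focal
contralateral cognition effect 2.5–4.5 mm from the temporal end. **No
epilepsy effect is injected**, so the epilepsy contrast is a true null and
the pipeline's negative finding for epileptogenesis is reproduced
qualitatively. Raw-signal synthesis (monoexponential echoes, single-tensor
DWI) uses Gaussian noise by default with a Rician switch documenting the
high-SNR approximation; k-space effects, motion, eddy currents and coil
profiles are not simulated. Because masks, effects and noise are the only
sources of structure, passing tests demonstrate internal consistency and
statistical calibration of the pipeline — not segmentation or registration
accuracy on real images, which are out of scope.

## Calibration studies and problem sizes

The heavy studies (in `hippoaxis.studies`, shared by the acceptance tests
and `scripts/acceptance.py`) run at sizes chosen to complete in minutes on
one CPU while keeping the cohort design at full scale (16+68): a 0.3-mm
in-plane calibration grid, the analytic axis (the skeleton estimator has
its own oracle tests), 1-mm profile spacing, one mid-axis model position
per contrast, 5-fold inner CV over a 30-value λ grid spanning a factor 10⁻²
(the library defaults remain inner LOO / 100 values / 10⁻⁴), 1,000
bootstrap resamples, 36 null replicates and 20 effect replicates, and 500
cohorts for BCa coverage. Under the null, the pooled LOO AUC averages
slightly below 0.5 (the familiar pessimism of leave-one-out pooling) and
the BH false-rejection fraction stays far under 0.05 because profile cells
are strongly positively correlated along the axis.

One calibration property deserves emphasis: the null distribution of the
**pooled** LOOCV AUC is heavy-tailed when the minority class is small. With
48 predictors and ~68 animals, the largest chance correlation between a
noise predictor and the labels is around 0.3; when the inner CV admits that
predictor (it genuinely reduces the realized deviance), every outer fold
scores animals with the same spuriously ordered feature and the pooled AUC
can reach ~0.7. A bootstrap CI computed from the pooled probabilities
conditions on that ordering and cannot recognize it as dataset noise, so
the CI-lower-bound > 0.5 discriminability rule fires in roughly 6–10% of
null replicates for the 15-versus-53 and 13-versus-55 contrasts (it is
calibrated, ~2.5%, for the 16-versus-68 contrast). This anti-conservatism
is a property of the pooled-CV evaluation design itself — switching the
inner CV to leave-one-out makes it slightly worse, not better — and single
discriminability flags at small minority counts should therefore be read
with caution.

## Known limitations

- Skeleton ends on strongly curved, tapering tubes can deviate up to
  ~0.7 mm from the true axis (interior: < 0.1 mm); profile positions within
  ~1 mm of the poles inherit that uncertainty.
- Digitized tube volumes at 0.5-mm slices depend on slice alignment by a
  few percent; `mask_volume` is exact voxel arithmetic, the discretization
  itself carries the bias.
- The Mann–Whitney exact path is used only for pooled samples ≤ 20 without
  ties; all cohort-scale tests use the corrected normal approximation.
- BCa intervals resample pooled out-of-fold probabilities; they do not
  account for refitting variability, matching the evaluation design rather
  than improving on it.
- The generator produces co-registered, artifact-free data: registration,
  segmentation and motion/eddy preprocessing are explicitly out of scope.
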