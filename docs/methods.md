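# Methods

## The sparing model

The package models the achievable mean rectum dose of a prostate VMAT plan
as a function of a single anatomical predictor, the fraction of the rectum
volume lying inside the highest-dose PTV (here PTV1, by local convention
the 59.2 Gy volume that contains the other targets):

    D_mean / D_Px = A + B (1 − exp(C v)),    v = V_ovr / V_rec

with A in (0, 1), B > 0, C < 0 and the sanity bound A + B ≤ 1.5. At v = 0
the prediction is the offset A; as overlap grows the curve rises
monotonically and saturates below A + B. The model deliberately ignores
everything else about the plan (beam arrangement, optimiser settings,
planner): its premise is that for a well-optimised plan the rectum mean
dose is largely determined by this one geometric feature, and deviations
from the curve measure plan quality, not anatomy.

Plan quality is quantified by the relative model excess

    δ = (D_mean − D_pred) / D_pred

which is invariant under common rescaling of both doses, so plans with
different prescriptions are comparable. Unless requested otherwise, δ is
referenced to the lower-bound (OARD) curve; a table-level toggle recomputes
it against the median (MARD) curve for analyses of cohort central tendency.

### Fitting the curve pair

Historically such curve pairs have been adjusted by eye. To make that step
reproducible the package fits them as quantile regressions: the coefficient
triple minimises the pinball loss of the residuals at a chosen quantile q.
Defaults are q = 0.50 for the MARD curve ("through the middle of the
cohort") and q = 0.10 for the OARD curve ("along the lower bound"); the
lower-bound quantile is a declared modelling choice, not an empirical
constant. The MARD curve is fitted first with all three coefficients free;
the OARD curve then inherits B and C and refits only the offset A, so the
pair differs only in its offset — matching how such pairs are quoted — and
the MARD curve dominates the OARD curve everywhere by construction.

Numerics: the three-parameter fit is a bounded Nelder–Mead search
(bounds A ∈ (0, 1), B ∈ (0, 1.5], C ∈ [−10, 0), penalty on A + B > 1.5,
xatol 1e-6, at most 4000 iterations) from a fixed default init
(A = 0.3, B = 0.5, C = −2.0); it is deterministic given the init and raises
a fit error carrying the best iterate on non-convergence. With B and C
frozen, the pinball-optimal offset is the q-quantile of the partial
residuals and is computed in closed form. A cross-check against an exact
linear-programming quantile regression (profiling over C) reproduces the
Nelder–Mead optimum to ~1e-5 on synthetic cohorts, so the non-smooth loss
is not trapping the simplex search in practice.

Identifiability: B and C are strongly correlated when the cohort only spans
small overlaps (the curve is near-linear there). On 200-point cohorts over
overlap range [0, 0.6] with noise σ = 0.03 the asymptotic standard errors
are roughly 0.009 (A), 0.034 (B) and 0.34 (C); recovery claims in the test
suite are therefore made on seed-averaged estimates (bias), while per-fit
quantile coverage is checked seed-by-seed against binomial bands.

### Verdicts

A plan is classified against the pair at its own overlap fraction and
prescription: OPTIMAL iff D_mean ≤ OARD prediction, NOT_ACCEPTABLE iff
D_mean > MARD prediction, ACCEPTABLE between (equality with the MARD
prediction is still acceptable, closing both boundaries downward).
Boundary comparisons carry a 1e-9 relative tolerance: a mean dose that is
physically equal to a prediction can re-measure one ulp away after passing
through the dose pipeline, and ~5e-8 Gy is far below dosimetric meaning.

## Voxel dosimetry

All metrics are computed on an axis-aligned voxel lattice in patient
millimetres (x right–left, y anterior–posterior with posterior = −y,
z inferior–superior; arrays indexed [ix, iy, iz]; the grid origin is the
centre of voxel (0,0,0)). Masks from another lattice are resampled nearest
neighbour, dose trilinearly; metrics are evaluated on the dose grid's
lattice, which is the native lattice of the quantity being integrated.

* Rasterization: a voxel belongs to an ROI iff its centre lies inside the
  even-odd union of the slice polygons (each planar contour is assigned to
  the nearest grid slice; nested contours cut holes). The rule is
  deterministic and converges to the analytic cross-section area as spacing
  shrinks (verified on circles at 2, 1 and 0.5 mm).
* DVHs are cumulative with half-open bins of 0.1 Gy by default (fine
  enough that Dx/Vx metrics reproduce to well under clinical rounding);
  Dx and Vx are linearly interpolated between edges, with the hotter edge
  returned on flat segments so that D50 of a half-20/half-60 Gy volume is
  60 Gy. Dose-vs-edge comparisons use a 1e-9 relative slack so a voxel at
  exactly 74 Gy counts as receiving ≥ the 74.0 edge.
* The conformity index at an isodose level is |target ∩ isodose| /
  |isodose|.
* Metrics on empty masks raise errors rather than returning zeros: silent
  zeros would corrupt cohort statistics unnoticed.

## Cohort mining and statistics

`extract_record` reduces one plan to the mined metric row: PTV D99/D1
values, OAR mean doses, femoral-head D50s, rectum V30–V70 (fractions of
rectum volume, non-increasing in dose level by construction), conformity
indices at 56.2 and 40.0 Gy against PTV1, total MU, the overlap fraction,
δ, and the mean dose in the 1 cm shell around the rectum (Euclidean
distance transform at grid resolution, measured from occupied-voxel
centres, organ excluded) used to check that rectal sparing does not push
dose into the immediately surrounding tissue. Rectum, bladder and the three
PTVs are mandatory; bowel and femoral heads are optional and recorded as
absent, with cohort comparisons dropping absent values pairwise.

Validation-study selection takes the k patients with the largest δ and,
from the remainder, the k with |δ| closest to zero ("δ ≈ 0" is
operationalised as smallest magnitude; ties break by patient id, so the
selection is permutation-invariant). The replan-vs-clinical comparison is a
one-tailed paired t-test (alternative: replanned δ lower); identical
vectors have zero-variance differences and raise a degenerate-test error
rather than fabricating a p-value. Cohort-vs-cohort comparisons use
Welch's unequal-variance two-tailed t-test per metric.

## Synthetic phantoms

The generator exists to give every pipeline stage a ground truth, not to
imitate VMAT physics.

* Anatomy: prostate sphere (default radius 20 mm, ≈34 cm³), seminal
  vesicles superior-posterior, tubular rectum (radius 12 mm, length 80 mm)
  posterior to the prostate, bladder anterior-superior, femoral heads
  lateral, a small-bowel sphere superior. Sizes jitter ±5 % per seed.
  PTVs follow the trial-protocol margin recipe — PTV3 = prostate + 5 mm
  (0 mm posteriorly); PTV2 = prostate (+ SV for high-risk patients) +
  10 mm (5 mm posteriorly); PTV1 = prostate + SV + 10 mm — implemented as
  morphological dilation with a half-ellipsoid structuring element whose
  posterior half-space uses the posterior margin. The rectum's posterior
  offset is solved by bisection (≤50 iterations) so the measured
  rectum–PTV1 overlap hits the requested target within ±0.02; unreachable
  targets raise rather than silently approximating. Default lattice: 2 mm
  isotropic, 220×240×160 mm (the test-suite uses a 3 mm variant of the same
  anatomy for speed).
* Dose: prescription plateaus inside PTV3/PTV2/PTV1 (74/71/59.2 Gy in 37
  fractions) with exponential falloff (length 8 mm) outside, Gaussian noise
  (default SD 0.3 Gy), then the rectum voxels are rescaled so the mean
  rectum dose equals exactly (1 + δ_true) × the reference-curve prediction
  at the achieved overlap. This makes extraction round-trips sharp: a plan
  generated at δ_true must mine back to δ_true up to the overlap
  measurement itself.
* Cohort scatters: overlap fractions uniform over [0, 0.6] by default (the
  span over which such cohorts are typically plotted), normalised doses on
  the curve plus Gaussian noise floored at 0.05, risk labels alternating.

What passing tests on these phantoms do **not** show: real contour
irregularity, inter-observer delineation variation, deliverability of the
dose fields, or realistic correlations between MU, conformity and rectal
sparing — total MU for a phantom is an input. Conclusions about the
package's bookkeeping, fitting and classification transfer to real data;
conclusions about clinical dose trade-offs do not.

## Problem sizes in the test-suite

The acceptance-style tests use 100 random ≤32³ grids for the voxel-oracle
comparisons, 20 seeds × 200 points for fit recovery, and two phantom
anatomies × four δ values on the 3 mm lattice for the end-to-end round
trip; these sizes give stable statistics while keeping the whole suite in
the ten-second range.

## Known limitations

* One predictor: the model ignores overlap shape (no overlap-volume
  histogram), bladder geometry and prescription differences beyond the
  normalisation.
* The fitted C is weakly identified on narrow-overlap cohorts; quote the
  pair, not C alone.
* The DICOM writers emit minimal, synthetic-labelled objects sufficient for
  round-trip testing, not full clinical metadata.
* No registration: structure sets and dose grids are assumed co-registered;
  off-lattice inputs are resampled, not aligned.
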