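# Methods

This note documents the models, numerical choices and study conditions
behind `kneegap`, and what the synthetic-data tests do and do not show.

## Coordinate conventions

All geometry lives in a canonical film frame in millimetres: *y*
increases proximally, *x* increases medially, and the canonical
laterality is a right knee. Left-knee annotations are mirrored about the
y axis on load, so "medial", "lateral" and "lower" are unambiguous
everywhere downstream. "Lower" (for the condylar contact rule) means
smaller *y* in this frame. Rigid motions of the input coordinates leave
every measured length unchanged (tested to 1e-6 mm); uniform scaling
scales every *measured* length proportionally, which is what marker
calibration relies on.

## Axis fitting by maximum inscribed circles

The anatomic axis of each bone is the line through the centres of two
maximum inscribed circles of the shaft, which mimics seating an
intramedullary rod. A window is an interval along the bone axis
restricting the circle *centre*; the circle itself may extend past it.
The centre is found by maximising the distance to the contour boundary:
a regular grid (spacing ≈ span/60, at least 0.01 mm) seeds the best six
candidates, each polished by Nelder–Mead to 0.001 mm; the radius
tolerance of the construction is 0.01 mm. Several seeds are polished
because the boundary-distance landscape of irregular contours has
multiple local maxima. Agreement with an independent 0.05 mm brute-force
grid search is within 0.1 mm radius on random simple polygons.

Window placement is a free design choice (no published rule exists):
femoral diaphysis 65–85 % and metaphysis 35–50 % of the visible femoral
extent from the distal end; tibial windows at 25–40 % and 60–75 % from
the distal end. These fractions keep both windows on the shaft for
ordinary AP outlines; they are parameters, not constants.

## Cut construction

The femoral reference line makes the aLDFA (default 85°) with the
proximal axis direction, opening laterally — for a vertical axis it
rises 5° above horizontal toward the lateral side. It is swept from
distal to proximal until first contact with the condylar margin; the
contact vertex and its condyle (medial/lateral) are reported. When both
condyles touch within 0.1 mm the medial contact is chosen (the tolerance
and tie-break are this package's choices; only the "lower point" rule
itself is given). The initial cuts sit at fixed offsets: femoral cut
parallel to the reference, 9 mm proximal; tibial cut perpendicular to
the tibial axis, 10 mm distal to `T_L`. Consequently a freshly built
plan always reports exactly the configured resection thicknesses — the
cut thickness becomes informative after the post-operative overlay
adjustment replaces a cut line.

`T_L` sits at 3/8 of the total plateau width from the lateral edge,
measured perpendicular to the tibial axis on the plateau's upper
envelope; `T_M` is the most distal upper-envelope vertex of the medial
half. Identifying the plateau with the contour's upper envelope assumes
the plateau is the widest part of the annotated tibia, which holds for
proximal-tibia outlines.

## Osteophyte trapezoid and release gap

Borders of the F1–F2–T2–T1 quadrilateral are named w = |F1T1| (inner rim
along the cortex), y = |F2T2| (outer rim between the osteophyte tips),
x = |F1F2|, z = |T1T2|. The naming is inferred: the cohort magnitudes
(w largest, y second) and the tip-to-tip role of y in the prediction
equation identify the inner and outer rims. The gap gained by osteophyte
removal defaults to the three-segment outer path minus the chord,
`(x + y + z) − w`, which the triangle inequality keeps non-negative; the
alternative reading `y − w` is exposed as `mode="tip"` but not default,
since it is negative at typical border magnitudes. Areas use the
shoelace formula on the F1→F2→T2→T1 cycle; a self-intersecting cycle is
re-ordered around its centroid with a warning.

## Calibration and overlay adjustment

Marker calibration multiplies every coordinate by
`true_mm / measured_units`; a view calibrates once (a second application
raises, because silent compounding is the classic error here). The
pre/post overlay assumes both films are calibrated to the same
magnification and therefore share a frame: the post-operative cut line is
adopted directly (its orientation and along-axis position), and the
resection thicknesses are recomputed from the original checkpoints.
Lines more than 15° from parallel are rejected as annotation blunders.
Full 2-D image registration is out of scope; rotational mismatch between
films is not modelled.

## Prediction

The gap equation is linear with coefficients
(1.82, 0.15, 0.552, 0.953, 0.197) for the intercept, outer-rim border y,
tibial cut, femoral cut and posterior condylar thickness, all in mm.
The posterior condylar thickness is a planning-time preset (the implant's
posterior condyle), because it is only measurable post-operatively.
Negative predictors are rejected rather than extrapolated — the model is
fitted on physical lengths. The plan report prints the release gap and
the predicted gap side by side without combining them; the equation uses
the border y directly, not the released path length.

## Statistical pipeline

Fitting is ordinary least squares (statsmodels) with t-based 95 % CIs.
Group comparison uses the equal-variance Student t-test; variables
constant in both groups get an undefined p with a `zero-variance` flag.
Backward-stepwise selection first screens the four borders for
collinearity: if any border's VIF within the border block exceeds 10,
only the border most correlated (|r|) with the response is kept; the
survivors then undergo backward elimination at α = 0.05. The VIF
threshold and the keep-rule are this package's design (only "considering
the correlation between independent variables" is given).

Ten-fold cross-validation shuffles with a mandatory seed, splits into
near-equal folds (sizes differ by ≤ 1), fits on nine folds and scores the
held-out fold with R² = 1 − SS_res/SS_tot, RMSE and MAE. Held-out R² may
be negative and is stored as computed. The best fold maximises held-out
R² with ties (compared at 1e-12 resolution, so numerically identical
folds tie) broken by lowest RMSE, then earliest fold.

Residual diagnostics: OLS residuals are orthogonal to fitted values by
construction, so the residual-vs-fitted trend check tests the quadratic
component of residuals on fitted values; normality is Shapiro–Wilk
(`insufficient-n` below 8 residuals); the influence flag warns when any
Cook's distance exceeds 1, and the count of hat values above 2(p+1)/n is
reported as context. A raw high-leverage count is almost never zero in
Gaussian designs, so the pass/warn decision rests on influence, matching
the diagnostic's purpose of finding outliers that affect the model.

## Synthetic data: what it emulates and what it does not

**Tabular generator.** Each of the seven predictors is a zero-truncated
normal whose *underlying* parameters are moment-matched (via the
truncated-normal moment equations) so the truncated marginal has exactly
the configured mean and SD — naive truncation would inflate the means by
up to ~0.5 mm at these coefficients of variation. The borders x, y, z, w
share a latent equicorrelation (default 0.6; the borders are known to be
mutually correlated but no numeric value is published, so this is a
plausibility choice) imposed through a Gaussian copula, which preserves
the matched marginals and lands the realised Pearson correlation within
±0.05 of the target. The joint gap is the equation evaluated on the
realised predictors plus N(0, 2.9 mm) noise; because the response is
generated conditionally on the realised predictors, OLS recovery of the
coefficients is unbiased regardless of the truncation. The generator
does not emulate measurement error in the predictors, inter-rater
annotation variability, or any nonlinearity — so passing recovery tests
demonstrates the pipeline's correctness, not clinical validity.

**Knee generator.** A parametric right-knee AP annotation: rectangular
shafts (so incircle centres sit on the exact midline), circular condyle
arcs with a configurable medial drop, a plateau with a medial dip, and
osteophyte checkpoints at a configurable protrusion, with optional varus
tilt, magnification (with a consistent marker block) and laterality.
Ground truth (axis directions, checkpoints, border lengths, contact
side) is known by construction and round-trips through the geometry
module within 0.2° / 0.2 mm. The contours are idealised polygons; no
cortical irregularity, osteophyte-deformed outlines or projection
effects are modelled.

**Split rule.** The train/test split draws the test set as
round(n/10) records (halves rounded up) after a seeded shuffle, so 110
records split 99/11.

## Study conditions used by the tests and the acceptance script

* Coefficient recovery averages **50 replicate simulations of n = 10,000**
  records. A single n = 10,000 fit leaves the intercept with an analytic
  Monte-Carlo SE of ≈ 0.13 mm (σ = 2.9 with predictor mean/SD ratios of
  ≈ 1.8–2.4), too coarse for a 0.05 mm statement; averaging brings it to
  ≈ 0.018 mm. Slope SEs are ~25-fold smaller and never limiting.
* The CI-coverage check runs 100 replicates and asserts the exact
  binomial band around 95 % coverage (per term ≥ 88/100, mean ≥ 93/100).
* The collinear-border selection experiment generates x, z, w as linear
  functions of y with correlation ≈ 0.96 at n = 10,000 over 50 seeds.
  The margin by which y beats a proxy border scales as
  (1 − r)·corr(y, gap) while the VIF screen only engages for r ≳ 0.95,
  so this is the regime where the selection event has real power; a
  power analysis at these conditions gives ≈ 97 % per-seed success.
* Geometry properties use the default synthetic knee and 20 random
  star-shaped polygons against a 0.05 mm grid oracle.

These sizes keep the full test suite under half a minute on one CPU.

## Known limitations

* Inputs are coordinates; there is no pixel processing, automatic
  landmark placement or DICOM handling.
* The plateau/upper-envelope heuristics assume roughly upright bones
  (canonical frame within a few tens of degrees); extreme annotation
  rotations should be normalised first.
* The overlay adjustment is 1-D by design; films with rotational
  mismatch need external registration.
* Simulated joint gaps can (rarely) be negative in the far noise tail;
  they are left as generated since truncating the response would bias
  coefficient recovery.
* The default border correlation (0.6) and the knee-generator anatomy
  are plausibility choices, not fitted to any cohort.
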