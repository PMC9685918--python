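# Methods

This note documents the measurement conventions, the synthetic-data
geometry, the statistical procedure and the numerical choices made in
`scapmorph`, in the package's own terms.

## Scapular reference frame

The frame is anchored on three blade landmarks: the glenoid centre **C**
(centre of the sphere of best fit to the glenoid rim), the junction of the
scapular spine with the medial border **M**, and the inferior angle **I**.

- x̂ = unit(M − C) (mediolateral, medial positive);
- ŷ = unit normal of plane(C, M, I), oriented **anteriorly**. With I
  inferior, (M−C)×(I−C) points anteriorly for a right scapula and
  posteriorly for a left one, so the sign flips with side (an explicit
  `anterior_hint` can override);
- ẑ = ±(x̂ × ŷ), the sign fixed so (I − C)·ẑ < 0, i.e. ẑ points
  **superiorly**.

Left frames are mirror images (left-handed triads); all measurements are
computed in frame coordinates, which makes every quantity mirror-consistent
by construction. The three viewing planes are the scapular plane (normal
ŷ — the baseline, coronal-like view), the axial plane (normal ẑ) and the
sagittal plane (normal x̂). "Views" are orthographic projections; no
interactive re-orientation is involved.

## Angle conventions

Angles are measured between undirected lines after orthographic projection
and folded into (−90°, 90°]. The signs that carry anatomical meaning:

- **GI** (glenoid inclination): angle of the superior→inferior glenoid rim
  line vs ẑ in the scapular view. Positive = the glenoid face tips
  superiorly, its superior rim moving **medially**. This orientation makes
  the CSA open with growing GI, matching the reported positive
  GI–CSA association; the opposite convention would reverse that
  correlation.
- **GV** (glenoid version): the signed rotation about ẑ that brings the
  anterior and posterior rim points into optimal overlap in the projected
  view (the A1 condition), found by bounded 1-D minimization of the
  projected rim separation. Negative = retroversion.
- **CPAA**: transverse lateral acromial axis vs x̂ in the scapular view.
  Positive = the lateral acromion rotated superiorly about the acromion's
  longitudinal axis, which makes the CSA fall as CPAA grows — matching the
  reported negative CPAA–CSA association.
- **SPAA / APAA** and **CPSSA / SPSSA / APSSA** are recorded as raw
  projected angles (longitudinal acromial axis vs ẑ in the sagittal view
  and vs ŷ in the axial view; spinal axis vs x̂ / ẑ / ŷ in the scapular /
  sagittal / axial views). Under this convention a "neutral" acromial
  plate (long axis along ŷ) has SPAA = 90°, and a neutral spine (axis
  along −x̂) has APSSA = −90°: zero is *not* the neutral value for these
  two, and the descriptive values printed elsewhere for them may sit on a
  complementary convention. Recovery and invariance guarantees are
  unaffected because ground truth and measurement share one convention.

## Measurements

- **CSA**: the viewing direction is the baseline view rotated about ẑ by
  the measured GV (the A1 view). The CSA is the 2D angle at the inferior
  glenoid rim point between the line to the superior rim point and the
  line to the acromial vertex that **maximizes** the angle (tangent-point
  rule, mirroring radiographic practice; ties break toward the most
  inferior vertex). Acromial candidates are mesh vertices within 1.5 mm of
  the acromial undersurface plane inside the box footprint.
- **Acromial box**: the undersurface viewing plane is the total-least-
  squares plane of the undersurface patch. The lateral border plane
  contains the best-fit lateral-border line and the undersurface normal;
  the mid plane is its parallel translate through the acromiospinal (AS)
  point; anterior/posterior planes bound the acromial extremes along the
  box's longitudinal direction, and the AS plane (through AS, parallel to
  them) splits anterior and posterior sub-boxes. Width and the two lengths
  are plane-to-plane distances divided by s = CM + MI + CI.
- **Box areas**: the printed dimensionless area values come with no stated
  normalization; they are implemented as the **fill fraction** of each
  sub-box covered by the projected bone silhouette in the undersurface
  view (shapely polygon union ∩ sub-box rectangle), which is dimensionless
  and lies in [0, 1]. This is an interpretation, flagged as such.
- **Acromial axes**: the LLAP/TLAP planes bisect the box longitudinally /
  transversely; each is intersected with the mesh, only the inferior
  border of the section (points within 0.75 mm of the lowest point above
  the undersurface) is kept, and the pivot points (anterior-most,
  posterior-most, mutual, lateral-most) are projected onto the
  undersurface plane before forming the axes — suppressing the spurious
  out-of-plane offset of end-wall section points.
- **Spinal axis**: M→AS. The text defines the axis only through its
  endpoints' construction figures; M→SG and SG→AS are defensible
  alternatives that the printed summary statistics cannot disambiguate.
- **Spinoglenoid distances**: absolute components of SG − C along
  (x̂, ŷ, ẑ), each divided by s. Read as axis components (three
  independent numbers) rather than in-plane projected distances.
- **AS / SG detection** is provided for generator-style meshes: AS as the
  terminus of the v-shaped junction-ridge crease on the acromial
  undersurface (crease = mesh edges with face-normal dihedral in 25–65°
  that are oblique to the undersurface plane, restricted to the
  undersurface patch footprint); SG as the deepest point of the notch pit
  in the detection corridor, lifted along ẑ to the mid-height of the spine
  cross-section at that mediolateral station. Clinical meshes are expected
  to come with annotations, which are validated (AS must lie within 2 mm
  of a detected ridge) and passed through.

## Synthetic scapula generator

The generator builds, in the canonical frame: a thin triangular blade
through C, M, I (M = (1,0,0)·b, I = (0.6,0,−1.2)·b for body scale b, so
s = 3.6066·b); a spherical-cap glenoid of radius R (cap half-angle 50°)
centred on C whose superoinferior and anteroposterior rim axes realize GI
and GV **exactly**; a prismatic spine body from M through the SG point; a
notch pit below the spine whose unique lowest vertex marks the notch apex;
an acromial plate (extruded, optionally corner-trimmed box) whose
undersurface contains AS at its medial-edge station; and a junction ridge
terminating exactly at AS. A seeded random rigid transform (and, for left
sides, a mirror) is applied before the mesh is emitted, so frame
construction is genuinely exercised downstream; Gaussian vertex jitter of
amplitude `noise_mm` models surface noise.

Because three projected angles of one axis carry only two degrees of
freedom, the acromial-plate and spine orientations are parametrized by
intrinsic Z-X-Y rotation recipes (axial, then sagittal, then coronal
rotation, with the neutral offsets above), and the stored ground truth is
always the **realized** projected angle — equal to the parameter whenever
the other two rotations of its triple are neutral (CPAA, GI and GV are
realized exactly always). Parameter combinations whose geometry cannot
support the measurement procedures (plate touching the glenoid, foreign
structure encroaching on the box undersurface, notch outside its
detection corridor) raise an explicit infeasibility error;
`sample_scapula_params` rejects and redraws them.

Generator defaults follow the study cohort's descriptive statistics where
the conventions allow (GI 7.14°, GV −4.75°, CPAA 7.16°, box width wt 0.14,
anterior/posterior lengths wt 0.30/0.12, spinal length wt 0.29,
spinoglenoid distances wt 0.17/0.07/0.07); the printed dispersion of GV is
typographically impossible (negative), so a plausible 4.0° substitutes.
Randomized draws sample uniformly within mean ± 2 SD. Length parameters
are absolute millimetres: wt values are invariant under uniform scaling of
*all* length parameters (tested exactly), while scaling the blade alone
rescales them — the generator's documented semantics.

What the generator does **not** emulate: cortical/trabecular structure,
smooth anatomical curvature, segmentation artefacts, and the clinical
distribution of the CSA itself — the plate geometry consistent with the
printed wt means produces synthetic CSA values around 55–75°, higher than
clinical shoulders. Passing tests therefore demonstrate that the
measurement chain recovers known geometry under the stated conventions and
noise, not that it replicates clinical measurement variability.

## Cohort simulation and screening

`generate_cohort_table` draws the 17 predictors from a multivariate normal
with the descriptive means/SDs as marginals and optional equicorrelated
collinear groups (pairwise ρ), and builds
CSA = intercept + Σ coefficients·(active predictors) + N(0, noise_sd);
the default intercept centres the cohort CSA on 32.8°.
`generate_screening_log` emits scans violating each exclusion criterion
(slice thickness > 1 mm — strict inequality, 1.0 mm is included; gross
deformity; artefact; incomplete scapula) a prescribed number of times, one
criterion per excluded record; `screen_cohort` tallies each record under
the first criterion it violates.

## Model building

Predictors are screened by Pearson correlation with the CSA; collinearity
is assessed by VIF = 1/(1−R²) from regressing each predictor (with
intercept) on the others, default threshold 10 (configurable; none is
prescribed by the protocol). Variables above threshold are removed **one
at a time in separate model-building runs**, and the run whose optimal
model attains the smallest LOOCV MSE wins; the full trace is reported.

Selection is exhaustive best-subset under leave-one-out cross-validation.
Honest CV (the default) re-selects the best subset of every size inside
each fold; this is computed *exactly* through the deleted-residual
identities RSS₋ᵢ = RSS − eᵢ²/(1−hᵢ) and e_loo,i = eᵢ/(1−hᵢ), which
reproduce the literal refit-per-fold loop while enumerating each subset
once (verified against a brute-force oracle). A `cv="fixed"` mode
cross-validates the full-data best subset of each size instead. The
optimal size is the argmin of the per-size mean LOO squared error, with
ties — including numerically indistinguishable minima, via a 1e-12
relative tolerance — broken toward the smaller size (parsimony). The
final model is the best subset of that size refit to the full data by OLS
(statsmodels), reported with normal-theory 95% CIs and p-values;
**p-values are never a selection criterion**.

Minimizing LOOCV error is known not to be selection-consistent: at any
finite noise it overselects with non-vanishing probability (the
comparison between sizes is invariant to rescaling the noise). In
simulations at n = 200 with 4 strong true predictors of 17, exact
active-set recovery under the plain argmin was ≈ 40%, independent of the
signal-to-noise scale; in the noiseless limit the parsimony tie-break
makes recovery exact. The recovery guarantees quoted for this package are
therefore stated in that limit, and the finite-noise behaviour (the
active set is contained in the selection; overselection occurs) is tested
separately.

Drop-one importance refits the optimal model leaving each selected
variable out and reports AIC and adjusted R². AIC uses the Gaussian
profile-likelihood form n·log(RSS/n) + 2(k+2) for k slopes (intercept and
variance counted; additive constants dropped) — rankings are unaffected by
the constant. Diagnostics summarize residual normality (skewness, excess
kurtosis, probability-plot correlation) and heteroscedasticity
(correlation of |residual| with fitted values, flagged above 0.3), with
optional plots.

## Problem sizes and determinism

The test-suite and acceptance computations use 50 randomized scapulae for
parameter recovery, 100 noisy replicates (σ = 0.2 mm) for landmark
detection, 25 simulated cohorts of n = 200 (subset search capped at size
6 of 17) for selection recovery, and 30 meshes for the direction checks —
sizes chosen so the full run completes in well under a minute each while
keeping the Monte-Carlo margins comfortable. Every random quantity is
driven by explicit seeds; regenerating with the same seed is bit-identical.

## Known limitations

- Automatic AS/SG detection targets the generator's constructed features;
  it is not a general anatomical landmark detector.
- The acromial "area" variables are an interpretation (fill fraction) of
  an undocumented normalization.
- The spinal axis endpoint choice (M→AS) is one of several readings.
- Synthetic CSA magnitudes exceed clinical values (see above); sign and
  recovery properties, not absolute levels, are the validated claims.
- Best-subset search is exhaustive and limited to 20 candidate predictors.
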