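# Methods

## The measurement model

`whiskkin` analyses head-centric whisker angle time series from filmed
object-exploration clips. Angles are in degrees, 0° pointing caudally along
the head midline and increasing rostrally, so a larger angle means a more
protracted (forward-held) whisker. Each clip is split at the first
whisker–object contact frame into a pre-contact (PC) segment, frames
`[0, contact_frame)`, and a during-contact (DC) segment,
`[contact_frame, n_frames)`; the half-open split assigns the contact frame
itself to DC (time zero of contact marks the start of the DC section), and
every frame belongs to exactly one segment.

Whisker trackers report a variable number of whiskers per frame (2–12 in
typical footage, usually 5–6 per side) with no reliable identity across
frames. The pipeline therefore aggregates within frames first — per side
and frame, the mean angle and the across-whisker sample SD — and computes
all segment statistics on those per-frame aggregates. This order makes the
metrics insensitive to whiskers appearing and disappearing between frames,
at the cost of weighting every frame equally regardless of whisker count.

Six metrics summarise each segment:

| metric | definition | units |
|---|---|---|
| mean angular position | time mean of per-side mean angle, averaged over sides | deg |
| amplitude | 2√2 × SD of the per-side mean-angle series, averaged over sides | deg |
| asymmetry | \|time mean of (left − right mean angle)\| | deg |
| spread | mean across-whisker SD over frames and sides | deg |
| protraction speed | mean of positive smoothed angular velocity | deg/s |
| retraction speed | mean of \|negative smoothed angular velocity\| | deg/s |

The 2√2 factor makes the amplitude read out as peak-to-peak excursion for a
sinusoidal whisk (the SD of a sinusoid is peak-to-peak/(2√2)). Asymmetry is
unsigned by default because the side of object contact is not part of the
data model; the signed left−right mean is kept as an auxiliary output.
Sample (n−1) SDs are used throughout — immaterial at the ≥100-frame segment
lengths enforced by QC, but fixed so that brute-force oracles are exact.

Contact-related change is `delta = PC − DC` per metric, so a *positive*
delta means the quantity *decreased* on contact. Typical rodent contact
behaviour (larger, more asymmetric, slower, more bunched whisks on contact)
therefore appears as delta amplitude/asymmetry < 0 and delta spread/speeds
> 0.

### Smoothing and speeds

Speeds are computed on a smoothed version of the per-side mean-angle series
— a local least-squares polynomial (Savitzky–Golay) fit of order 2 over a
15-sample window, the convention used for published whisker trace figures —
then differentiated with central differences (one-sided at the ends) and
scaled by the frame rate. Near the series ends the smoothing window shrinks
symmetrically, with the polynomial degree capped by the shrunk window, so
output length equals input length and the end samples pass through
unchanged. Positional metrics are computed on the raw series; smoothing
them too is a config switch (`smooth_positions`). Frames whose velocity is
at numerical round-off scale count as "not moving"; a segment with no frame
moving in a direction reports that speed as missing rather than zero.

Whether the original analyses computed amplitude and spread per side then
averaged, or pooled bilaterally, is not fixed by their one-line
definitions; this implementation averages per-side values and documents the
choice here. Where the fuller metric definitions in the earlier mouse
literature differ from the one-line definitions used here, the one-line
definitions win.

## Quality control

Machine-checkable clip-inclusion criteria, all thresholds configurable:
PC and DC each ≥ 100 frames (observed ranges in comparable footage are
100–291 and 100–459), per-frame total whisker count within [2, 12], both
sides present in ≥ 90% of frames, and at most 4 clips retained per animal
(surplus passing clips are dropped deterministically by clip id). QC is
monotone in its thresholds — tightening a threshold can only fail more
clips — and downstream stages refuse clips that did not pass unless an
explicit override is set. Criteria that require watching the video (level
head, travel direction toward the object) are upstream manual selection and
are not re-checked from angle traces.

## Inference plan

Clips are nested in animals (1–4 per animal), so each metric is modelled as
a linear mixed model with a random intercept per animal, fitted by REML:

    y_ij = x_ij' beta + u_i + e_ij,  u_i ~ N(0, sigma_a^2), e_ij ~ N(0, sigma_e^2)

The variance ratio lambda = sigma_a²/sigma_e² is profiled out and the REML
criterion minimised by bounded scalar search on log lambda (tolerance 1e-8,
deterministic start), with the lambda = 0 boundary always checked; boundary
fits are allowed and flagged. Factors are coded sum-to-zero and tested with
type-III F-tests, matching the factorial F-table presentation. The staged
plan:

1. **Combined**: treatment × sex per response (6 PC metrics + 6 deltas).
2. **Sex-stratified**: treatment × object texture per response, within each
   sex. Texture is perfectly confounded with presentation order (the smooth
   object is always presented first); the model treats them as one factor.
3. **Post-hoc**: where a stage-2 interaction has p < α (default 0.05),
   all pairwise Tukey comparisons of the four treatment × texture estimated
   marginal means.

No correction is applied across the 12 response metrics (a deliberate,
documented caveat), and litter/dam is not modelled as an additional random
level.

### Kenward–Roger adjustment

Denominator degrees of freedom come from the Kenward–Roger first-order
adjustment. Because V = sigma_a² ZZ' + sigma_e² I is linear in its two
parameters, the second-derivative terms vanish and the adjusted covariance
is Phi_A = Phi + 2 Phi {Σ_ij W_ij (Q_ij − P_i Phi P_j)} Phi, with W the
inverse expected REML information (pseudo-inverse at boundary fits) and
P_i, Q_ij the standard first- and second-order X'V⁻¹·V_i·V⁻¹X sandwiches.
The scaled F statistic and its df follow the published formulas; the
implementation reproduces lme4+pbkrtest to printed precision on a frozen
unbalanced fixture (see `tests/test_mixed_stats.py::KR_REFERENCE`). For the
degenerate design with one clip per animal the variance split is not
identified (V ∝ I); the fit is then exact OLS and classical F-tests with
df2 = n − rank are reported. KR denominator df always lie between
(animals − rank) and (clips − rank). If the adjusted covariance ever fails
to be positive definite the test falls back to the unadjusted REML
covariance and flags the term "KR-unadjusted" — chosen over a Satterthwaite
fallback because the branch is practically unreachable for this covariance
structure and the unadjusted covariance is the better-understood object.

Tukey post-hocs are computed on estimated marginal means of the factor
cells; each contrast uses its own 1-df KR denominator df and the
studentized-range distribution with family size k = number of cells, so a
family of two reduces exactly to the raw t-test. Output ordering is by
sorted cell label, deterministic.

## Synthetic cohorts

The generator exists so the full pipeline — including its statistical
operating characteristics — is testable without animal data. Whisking is a
single-frequency sinusoid, *not* a biomechanical model; the choice makes
the ground truth analytic. Per whisker w on side s:

    angle(t) = mu + u_animal + shift(t) + o_w·s(t) + (A(t)/2)·sin(2π f(t) t + phi_s) + eps(t)

Defaults (conventions, configurable; the source study reports no kinematic
parameters of its own, so these must not be read as estimates of it):
whisk frequency 8 Hz (typical rat exploratory whisking), frame rate
500 fps, baseline mean angle 100°, peak-to-peak 40°, per-whisker offset SD
5° (the spread driver), white measurement noise SD 2°, animal intercept SD
3°. Cohort structure mirrors a realistic study: four treatment × sex cells
of 11/13/14/12 animals, 1–4 clips each split smooth-first/textured-second,
PC lengths uniform on [100, 291] frames and DC on [100, 459], 5–6 whiskers
per side drawn per clip (optional per-frame dropout exercises missing-data
paths).

During contact the envelope scales ×1.25, whisker offsets scale ×0.6
(bunching), frequency scales ×0.6 (slowing; implemented as a frequency
scale so amplitude ground truth stays clean — note mean speed ∝ amplitude ×
frequency, so the realised speed ratio is 1.25 × 0.6 = 0.75), the sides are
pushed apart by 6° (half up, half down, leaving the mean unchanged), and
the mean angle gains a +5° protraction shift. The contact shift varies per
animal (SD 3°) and per clip (SD 2°): the animal-level component gives the
PC−DC metrics a genuine animal random-intercept variance comparable to
their residual SD (≈3.4° for delta mean angle, which also absorbs
partial-whisk-cycle sampling noise), so the mixed model's random structure
is exercised for real. Phase is continuous across the contact frame.
Randomness is one root seed with per-animal/per-clip spawned substreams;
identical (config, seed) gives byte-identical cohorts.

Cell-specific effect injection overrides any subset of the contact
modulation for one treatment × sex × texture cell — e.g. setting the
MIA-female-smooth mean shift from +5° to −2° mimics a group that fails to
protract on contact, the phenotype the stratified analysis plan must
detect.

What the generator does *not* emulate: autocorrelated tracking error,
amplitude/frequency drift within a whisk bout, whisker identity, contact
mechanics, or head motion. Passing calibration and power tests therefore
demonstrates correctness of the pipeline under its own assumptions, not
robustness to every artefact of real tracking data.

## Operating characteristics

Two Monte-Carlo studies (module `calibration`) run the full simulate →
metrics → model chain:

- **Type-I error**: 500 null cohorts (defaults, no injection), female-
  stratified treatment × texture model on delta mean angular position. The
  treatment F-test's rejection fraction at α = 0.05 is compared with the
  95% binomial band around 0.05 (± 1.96·√(0.05·0.95/500) ≈ ± 0.019).
- **Power / recovery**: 200 cohorts with the MIA-female-smooth suppression
  above (7° effect ≈ 2× residual SD, 12 animals per cell). Success = the
  female interaction is significant at 0.05 *and* the Tukey comparison of
  MIA-smooth vs control-smooth is significant; required in ≥ 80% of
  cohorts.

Problem sizes (500 and 200 cohorts at the default ~50-animal scale) were
chosen as the smallest giving useful binomial resolution on these rates;
both studies are reproducible from a single seed.

## Numerical choices and degenerate inputs

- REML optimisation: bounded search on log lambda in [−25, 25], xatol
  1e-10, explicit boundary comparison at lambda = 0.
- A near-constant response (zero residual variance) yields F = 0, not NaN:
  contrasts at round-off scale relative to the response are treated as
  zero evidence, and the residual variance is floored at 1e-10 × var(y)
  to keep V invertible.
- Rank-deficient designs and single-level factors raise errors naming the
  aliased columns/factor; QC failures are reported, never raised.
- Segments shorter than the smoothing window shrink the window (speeds);
  segments with no frames, no bilateral frames, or no multi-whisker frames
  raise segment-specific errors carrying the clip id.
- Missing sides: excluded pairwise for asymmetry, used one-sided (and
  flagged) for mean position and amplitude.

## Known limitations

- Only a random intercept per animal; no random slopes, no litter level,
  no GLMMs.
- Two fixed factors with optional interaction cover the analysis plan;
  arbitrary formulas are out of scope.
- The angle convention (0° caudal, larger = more protracted) is declared,
  not detected; mixed-convention inputs are the caller's error.
- Contact frames are inputs; no automatic contact detection.
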