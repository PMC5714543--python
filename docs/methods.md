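# Methods

This note documents the models, conventions and numerical choices behind
`dose4d`, and what the synthetic phantom does and does not emulate.

## Coordinate and raster conventions

Axes are patient-like: x = left–right, y = anterior–posterior,
z = superior–inferior (craniocaudal); world coordinates in mm. Voxel
centers are the sample points; arrays are indexed `[ix, iy, iz]`,
0-based, with the origin at the center of voxel (0, 0, 0). Mask
membership is a whole-voxel, center-in-region test — there are no
partial volumes. Small structures are the most sensitive to this: a
0.6 cc GTV on the default 2.5 mm grid holds ~38 voxels, so its DVH
statistics are quantized at the few-percent level. Geometry equality is
tested to 1e-6 mm.

Mask expansion uses the ellipsoidal (per-axis scaled) metric
Σ(Δx_i/m_i)² ≤ 1, so anisotropic van Herk margins apply directly;
uniform margins reduce to Euclidean dilation. Resampling and dose
warping are trilinear with zero-padding semantics (`grid-constant`):
points outside the source extent contribute 0, since dose outside a
calculated grid is unknown and zero is the conservative reading.
Trilinear interpolation reproduces affine fields exactly, which the
tests exploit as an oracle.

## Breathing model

Per-axis centroid offsets, relative to phase 0:

    off_k = A · sin^(2n)(π k / N),   k = 0 … N−1

with A the peak-to-peak amplitude, N = 10 phases and n = 2 by default.
Phase 0 is the end-exhale extreme, where a cos^(2n)-type breather dwells
longest; the time-average offset is 0.375·A for n = 2, which puts the
mid-ventilation phase off the cycle midpoint toward exhale (phase 3 of
10 for the default waveform). All axes share one respiratory signal, so
the 3D motion is the Euclidean norm of the per-axis amplitudes. The
period (default 4 s) is bookkeeping only; accumulation uses equal time
weights 1/N exactly.

Mid-ventilation selection minimizes |z_k − mean(z)| over the SI
centroid sequence, ties to the lower phase index.

## Displacement fields

Fields are analytic, not registered: u_k(p) = (phase-k centroid offset)
× envelope(p), in the pull-back convention (a reference point p
corresponds to phase-k point p + u_k(p)). The envelope is exactly 1 on
the GTV and out to 15 mm beyond its surface — the tumor and nearby
parenchyma translate rigidly together — then tapers as cos² to exactly
zero at 40 mm, where the chest wall and mediastinum no longer follow
respiration. Consequences that the tests rely on: the GTV moves rigidly
(tracking is perfect on the GTV); the field vanishes at the body edge of
the default phantom; and field magnitude never exceeds the trajectory
amplitude. For the largest cohort tumors the 40 mm taper reaches the
lateral body wall, so a small residual SI motion exists there; no
invariant depends on it.

The pull-back convention was chosen because the direction is otherwise
ambiguous in practice; externally supplied fields in the push-forward
convention must be inverted before use. Warping is plain trilinear dose
interpolation without congruent energy/mass transfer — adequate for the
geometric mechanism studied here, but it is a known simplification: mass
is not conserved, and steep dose gradients acquire an interpolation blur
of order the voxel size (the tracking-invariance test budgets 2% of the
maximum dose for it).

## Dose model

Doses are isodose-shaped clouds, not transport calculations:

    dose(p) = D_max · Φ((d₀ − s(p)) / σ),   d₀ = σ · Φ⁻¹(isodose)

where s(p) is the signed distance to the target surface (negative
inside), σ the penumbra SD (3 mm tracking, 5 mm fixed-geometry), Φ the
standard normal CDF, and D_max = prescription / isodose. The profile is
pinned so the prescription isodose surface coincides with the PTV
boundary: the static plan covers its PTV with prescription dose by
construction (the ≥95% coverage planning objective is met), and interior
dose saturates to D_max, giving the characteristic SBRT hot core
(GTV mean ≈ 120–155% of prescription depending on the prescription
isodose, sampled per patient: 62–83% for tracking, 78–85% for fixed).

*Tracking*: in each phase the cloud is the reference PTV_CK
(GTV + uniform 5 mm) cloud rigidly translated by the phase centroid
offset — the beam follows the target.

*Fixed-geometry*: one static room-coordinate cloud shaped to PTV_VMAT
(MidV GTV + per-axis van Herk margin), identical in every phase; the 4D
accumulation then resolves the tissue moving through it. This is the
mechanism under study: accumulated coverage and conformity of the fixed
plan degrade with amplitude, while the tracking plan's do not.

With a 3 mm penumbra on a 2.5 mm grid the high-dose shells outside the
tracking PTV are thinner than one voxel and can rasterize to zero; this
quantization is deliberate desk-scale behavior, and shell comparisons
between techniques are directional, not absolute. Real delivery
penumbras, scatter and beam-entrance dose make clinical shell volumes
far larger than the phantom's.

## Margins

The van Herk-style nonlinear recipe per axis:

    M = α·Σ + β·(√(σ² + (c·A)² + σ_p²) − σ_p)

with α = 2.5, β = 1.64, penumbra SD σ_p = 3.2 mm, and the breathing
position SD modeled as c·A with c = 0.36 — the SD of cos⁴ motion
relative to its peak-to-peak range. The systematic (Σ) and random (σ)
error SDs are not knowable for the reference cohort; the package
defaults to 2.0 mm each per axis, which yields SI margins of ≈6.0 mm at
1 mm amplitude rising sublinearly to ≈14.4 mm at 22.5 mm. The margins
are therefore validated structurally (zero at zero error, strictly
monotone, secant slope < 0.5 over the study amplitude span), not
against any published per-patient values.

## DVH and plan metrics

DVHs are exact empirical curves over member-voxel dose samples, no
binning. Dx% uses the largest-dose-covering convention: with doses
sorted descending, rank r = x·n/100, interpolating linearly between
adjacent order statistics at fractional ranks (planning systems differ
here; this convention is fixed and oracle-tested). VxGy is the fraction
(or absolute cc) of structure volume at or above the threshold.

The conformity index is nCI = (PI·PTV)/TVIP², with PI the
prescription-isodose volume restricted to BODY (to avoid counting dose
in air), and TVIP the PTV volume covered; TVIP = 0 raises rather than
returning a value. Lung V20 is evaluated on the NTD2-converted dose
(linear-quadratic equivalence, α/β = 3 Gy); the lung volume excludes
the technique-specific PTV by default (configurable to GTV or none).
"Normal tissue" for the V80/50/30/10% shells is BODY minus the
technique-specific PTV.

Beam-on time is (MU/Gy × total prescription dose) / dose rate, the
relation consistent with the packaged delivery table across both
fractionation schedules; a literal per-fraction variant
(MU-per-fraction / dose rate) is available behind a flag.

## Statistics

The Wilcoxon matched-pairs signed-rank test is exact for n ≤ 20 after
zero handling: the null distribution of W⁺ is built by a dynamic
program over doubled signed ranks (integers even under average-rank
ties), equivalent to enumerating all 2ⁿ sign assignments; the two-sided
p is 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)) capped at 1. Zero differences are
dropped by default (count reported) or kept with Pratt's adjustment.
Above n = 20 a tie- and continuity-corrected normal approximation takes
over. Spearman rho uses average ranks with the t-approximation on n−2
df; an exact permutation p is available for n ≤ 8.

Cohort summaries are mean, sample SD (n−1), min, max per group;
rounding happens only at the presentation layer (MU as integers,
minutes and cc to one decimal). A single-value group reports SD = 0
with a degenerate flag.

## Synthetic cohort

The default cohort emulates the reference study population: 14
patients; GTV volumes log-uniform on 0.6–78 cc; peak-to-peak amplitudes
uniform per axis (SI 2–22.5 mm, AP 0.1–3.5 mm, LR 0.2–3.8 mm) with
rejection until the 3D motion lies in 2–23 mm; two central lesions in
fourteen treated at 48 Gy/6 fx instead of 60 Gy/3 fx; half the lesions
posterior (placement shifts the tumor off the midline; a delivery
geometry effect on low-dose shells is *not* modeled — see limitations).
MU efficiencies are sampled around the reference table's group
statistics (tracking ≈ 223 ± 55 MU/Gy at 600 MU/min; fixed ≈ 57 ± 8
MU/Gy, 85 for central lesions, at 400 MU/min). Anatomy is an elliptic
body cylinder with an auto-sized lung ellipsoid that contains the tumor
at every phase, plus cylindrical cord/esophagus/trachea and an
ellipsoidal heart. The grid is 48×48×72 at 2.5 mm isotropic, matching
the reference slice thickness; one 14-patient evaluation runs in ~12 s
on one CPU, which sets the problem size used throughout the tests and
the acceptance script.

Randomness: one master seed; per-patient substreams are spawned by
patient index, so growing the cohort never reshuffles earlier patients.
Reruns with the same config are byte-identical.

## Acceptance measurements

The motion-vs-shell-difference Spearman correlation is an inherently
noisy statistic at n = 14 (the three-decade tumor-volume range dominates
the variance of the shell differences), so the acceptance script reports
the mean rho over five replicate cohorts drawn under identical
conditions — variance reduction of the estimator, not a change of study
conditions. All other phantom-mechanism quantities (coverage and nCI
degradation for every >5 mm SI mover, the tracking GTV D99% floor) hold
per patient in every replicate.

## Known limitations

- The dose model has no transport physics: no heterogeneity effects,
  no beam geometry, no MU-to-dose coupling; MU and beam-on time are an
  independent efficiency model.
- Deformation is translation-times-envelope: no rotation, no
  deformation of the lung or OARs themselves, no hysteresis; OAR doses
  therefore vary far less than clinically.
- The anterior/posterior V10% asymmetry seen with real robotic delivery
  (no under-couch beams) is a delivery-geometry effect outside the
  model; low-dose (V10%) comparisons carry no geometric signal here.
- No interplay effect between dynamic collimation and organ motion is
  simulated; equal-weight accumulation assumes it negligible.
- Passing tests demonstrate the geometric mechanism (static cloud +
  motion ⇒ coverage/conformity loss; tracked cloud ⇒ invariant target
  dose) at phantom scale, not clinical dose accuracy.
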