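# Methods

## The phantom

The left-ventricular cavity is a truncated semi-ellipsoid of revolution
in cylindrical coordinates (θ, z) about the long axis, z = 0 at the
apex, θ = 0 anterior. The baseline endocardial radius at phase p is

    r(θ, z, p) = R(p) · sqrt(1 − ((L(p) − z) / L(p))²),   0 ≤ z ≤ L(p),

so the cavity volume of the undeformed shape is (2/3)·π·R²·L. R(p) and
L(p) interpolate their end-diastolic values by the radial-contraction
fraction s and longitudinal-shortening fraction ℓ on a raised cosine
c(p) = (1 − cos 2πp/n)/2 over the cycle; the cycle therefore starts at
end-diastole (ED, maximum volume) and reaches end-systole (ES, minimum
volume) mid-cycle. ED and ES are *defined* as the volume extremes, and
each emulated modality likewise picks its own ED/ES frames from its own
trace, as an operator does. Intracycle kinetics beyond the ED/ES
endpoints are not used by any estimator; the raised cosine only
guarantees smoothness and a well-defined extremum.

Defaults are a post-infarction mouse LV: R = 2.3 mm, L = 6.2 mm, wall
thickness 1.0 mm, s = 0.30, ℓ = 0.12, n = 20 phases (matching a cine
CMR acquisition). These give EDV ≈ 69 µL and EF ≈ 57% without infarct,
consistent with the magnitudes such studies report.

**Infarcts.** A dysfunctional sector covers `apex_extent_fraction` of
the long axis from the apex and `angular_width` degrees around
`angular_center`, with cosine tapers (default 15°) at the edges so
emulated contours stay smooth and estimators are not dominated by
discretization kinks. The sector weight w ∈ [0, 1] blends the local
contraction: akinetic s_local = 0, dyskinetic s_local = −0.5·s (outward
motion at ES), aneurysmal s_local = 0 plus a static +15% outward bulge
at every phase. The sector is defined in the material coordinate
ζ = z/L(p), so scar moves with the wall. A `base_hyperkinesis_gain` ≥ 1
multiplies s over the basal third (smooth ramp), emulating the
compensatory hyperdynamic base of infarcted ventricles.

**Epicardium.** The squared-radius annulus epi² − endo² is held at its
end-diastolic value per material point (incompressible wall per cross
section), so the wall thickens as the cavity contracts and radial
(thickening) strain is well-posed. Total wall volume is conserved
exactly only when ℓ = 0; the residual is irrelevant to the endpoints,
which compare thickness between two phases of the same rule.

**Ground truth.** Cavity volume is V = ∫∫ r²/2 dθ dz, evaluated by
96-node Gauss-Legendre quadrature in ζ × 720-point trapezoid in θ. On
axisymmetric phantoms (polynomial integrand) this matches the closed
form to machine precision; the tests assert < 1e−6 relative. Scar
fraction is the w-weighted share of the ED wall-volume integral
(epi² − endo²)/2. The histology it stands in for measures stained
*area* on sections; the phantom exposes the volume-based quantity and
treats the two as equivalent.

## The cohort

The default cohort has 32 subjects. Scar-fraction targets are drawn
from a truncated normal, mean 21.5%, SD 16.3%, clipped to [4%, 57%] —
the published cohort's mean ± SEM (21.54 ± 4.07% at n = 16, hence
SD ≈ 16.3%) and range. For each subject the infarct angular width is
then solved by bisection on the wall-volume oracle so that the
phantom's true scar fraction equals its target (the apex extent widens
at width 360° if a full-circumference sector is still too small).

Morphology jitter is normal around the defaults (R 2.3 ± 0.12 mm,
L 6.2 ± 0.25 mm, wall 1.0 ± 0.05 mm, s 0.30 ± 0.02, ℓ 0.12 ± 0.01);
infarcts are anterolateral (centre 30° ± 20°); the basal gain is 1.15.
Two anatomically motivated couplings matter for what the cohort can
show:

- **Longitudinal extent** grows with scar: extent = 0.55 + 0.45·t
  (clipped to [0.50, 0.98]). Proximal coronary-artery ligation produces
  scars running from the apex past the mid-papillary level — which is
  exactly why a mid-papillary M-mode line misreads such hearts. Were
  infarcts confined below the mid-level, the M-mode beam would see
  normal wall at ES and the Teichholz failure the study design probes
  would largely vanish.
- **Motion class** escalates with scar: akinetic below t = 0.30,
  dyskinetic to 0.45, aneurysmal above. Wall-motion severity tracks
  transmural extent in chronic infarcts (infarct expansion and aneurysm
  formation occur in large scars); assigning classes at random would
  decouple the 1–5 grading scale from scar size by construction.

Cohort generation is bit-reproducible under its seed.

## Acquisition emulation

Sampling is deterministic and noise-free (perfect gating, no speckle):

- **M-mode**: internal diameter = sum of the two opposed endocardial
  radii along one beam azimuth at a fixed level (default 0.5·L_ED, the
  mid-papillary level; default azimuth 0°, i.e. anterior–inferior).
  The beam is fixed in space, so under longitudinal shortening it
  samples more-basal material at ES — part of why diameter-based EF is
  not exact even for uniformly contracting ventricles.
- **Long-axis plane**: boundary points on a uniform grid of ζ through
  the two half-planes, joined at the apex. Because the grid is a fixed
  fraction of the instantaneous length, vertices are material points —
  the surrogate for a speckle-tracked boundary.
- **Short-axis stacks**: slice centres at start + k·step while the slab
  (centre − thickness/2) remains below the basal limit, taken as the
  *maximum* cavity extent over the cycle (or an explicit basal
  truncation emulating a poorly visualized base, which reproduces the
  systematic volume underestimation such acquisitions show). A slice
  the base has descended past at some phase contributes an empty
  polygon there, as its contoured frame would. Fine 4D slices
  (0.2 mm) use centre-point radii; the 1 mm CMR slices use through-slab
  RMS radii, so the polygon area equals the slab-average
  cross-sectional area — the partial-volume appearance of thick-slice
  imaging. Without this, the half-filled basal slab at ES inflates CMR
  ESV by ~12% at default ℓ; with it the CMR emulation tracks truth to
  ≲0.1% and serves as the reference standard the study design assumes.

## Estimators and scores

Volumes: Teichholz 7.0/(2.4 + D)·D³ (mm in, µL out — the magnitudes
come out at the rodent scale this package targets); monoplane method of
disks with the axis from the apex vertex to the basal-edge midpoint
(default 20 disks clinically, 200 in convergence tests); slice
summation Σ Aᵢhᵢ with shoelace areas and shapely validity checks.
EF = 100·(EDV − ESV)/EDV for every modality (a published slice-form
"EF" equation that actually computes ESV/EDV is treated as a
typographical slip).

WMSI: slices nearest 1/3/5 mm from the apex (ties toward the apex);
fractional excursion FE = mean over the segment of (r_ED − r_ES)/r_ED;
relative excursion q = FE/reference with the reference the mean of the
best-contracting quartile of segments (the remote zone). Grades:
q ≥ 0.55 normal, ≥ 0.20 hypokinetic, |q| < 0.20 akinetic, q ≤ −0.20
dyskinetic; a segment whose ED radius exceeds the slice median by >10%
is flagged aneurysmal (grade 5). The thresholds are surrogates for
visual grading, chosen so a fully normal phantom scores all-1 and the
phantom motion classes map to their nominal grades; they live in
`WmsiConfig`, not in code.

Strain: "peak" = signed extremum of largest magnitude over the cycle.
Longitudinal strain uses open-boundary arc length (the basal closing
chord is not myocardium); six material segments of equal ED arc length
give the segmental peaks whose sample SD (ddof = 1) is the
dyssynchrony index. The SD-of-peaks convention is used; a
time-to-peak SD is a plausible alternative reading and is not
implemented.

Statistics: Bland-Altman on percent differences, test minus reference
over the pair mean, LOA multiplier fixed at 1.96; ICC(2,1) from ANOVA
mean squares, (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)), negative
estimates reported as computed (pingouin is the independent cross-check
in the tests); Spearman via tie-averaged ranks with the t-approximation
p for n ≥ 10 and an exhaustive-permutation p below; grade-band
boundaries (0.5/0.7/0.9) belong to the higher band. D'Agostino-Pearson
K² defers to scipy's implementation and refuses n < 20, where the
standardizing transformations are unreliable.

## The in-silico study

Each subject is measured by all modalities; echo modalities are
compared to the *CMR emulation* (not truth) by Bland-Altman so the
comparison is structurally parallel to an imaging study; the quadrature
truth is also tabulated. Rater noise — reading = value·(1 + b_r +
cv·ε), defaults cv = 4%, biases (0, +2%) — feeds only the ICC analysis.
Scar associations (WMSI, GLS, dyssynchrony vs true scar fraction) use
Spearman. The whole run is deterministic under the master seed; 32
subjects take ~15 s on one CPU, which is also the problem size the
acceptance script uses throughout.

## What the phantom does and does not show

Passing tests demonstrate the *estimator properties* — geometry-
assuming estimators are biased after regional infarction while
slice-based estimators are not, WMSI ranks scar burden, the agreement
statistics are correctly implemented — under idealized acquisition:
no speckle, no tracing error, no gating artifact, no heart-rate
difference between modalities (a real CMR-vs-echo confounder), perfect
ECG alignment. In-vivo bias magnitudes are therefore not reproduced,
only their directions and orderings. Known modeling limitations:
longitudinal shortening is global rather than regionally reduced in
the scar, so longitudinal strain responds to infarction mainly through
boundary-shape change rather than local shortening loss; the epicardium
is rule-derived, not tracked; histologic scar is equated with
wall-volume fraction; and the aneurysm bulge detector (ED radius vs
slice median) degrades for sectors wider than half the circumference.
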