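# Methods

`vqlobes` simulates and compares three ways of estimating the relative
distribution of an inhaled (ventilation, V) or injected (perfusion, Q)
⁹⁹ᵐTc tracer across the five lung lobes, on digital thorax phantoms whose
true lobar fractions are known by construction.  This note records the
models, the defaults and why they were chosen, and what the simulations can
and cannot say about real patients.

## The scientific question

Clinical lobar V/Q quantification is usually done on planar scintigraphy:
each lung is divided into three equally sized rectangular regions of
interest along the cranio-caudal axis, and each third is read as a lobe.
Lobes are not axial thirds — the right middle lobe is a small anterior
wedge bounded by the horizontal fissure — so the template systematically
misassigns counts.  3D SPECT/CT quantification sums counts inside true lobe
volumes and avoids that geometric error, at the cost of delineating the
lobes, manually (slow, reader-dependent) or with an automated segmentation.
The package reproduces this three-way comparison under controlled
conditions: known truth, known noise, simulated readers.

## Phantom model

The phantom is analytic and rasterised at any requested voxel grid by a
voxel-centre inside/outside test (no label resampling).  Components:

* **Thorax**: an ellipsoid of soft tissue (HU +40) in air (HU −1000);
  default half-axes 155 × 105 × 185 mm.
* **Lungs**: two ellipsoids of parenchyma (HU −800) inside the thorax;
  default right half-axes 48 × 72 × 118 mm, left 44 × 68 × 116 mm, centres
  at x = ∓60 mm.  Axes follow the patient frame: x left(+), y anterior(+),
  z superior(+).
* **Fissures**: planes parameterised by a fractional apex-base height and a
  sagittal tilt.  The oblique fissures (right and left) rise posteriorly
  (default tilt 28°), giving the lower lobes their posterior-basal
  character; the right horizontal fissure is axial and carves the middle
  lobe out of the anterior region above the oblique plane.  Planes are the
  simplest surfaces that make lobar extents differ from equal axial thirds,
  which is the property under study; curvature would refine, not change,
  the effect.
* **Activity**: a specific activity per lobe (arbitrary units/voxel) for
  each tracer.  Only relative distributions matter, so there is no absolute
  (MBq) calibration.
* **Options**: lobectomy (labels→background, HU→soft tissue, activity→0,
  truth renormalised), emphysema (per-lobe activity scaling, HU −950), and
  spherical ventilation hotspots (activity multiplier; hotspot counts are
  *not* subtracted anywhere, so they bias all methods identically, as in
  clinical practice).

Default fissure heights (0.46 oblique, 0.58 horizontal) were chosen so the
right-lobe volume shares are ≈38/17/44 % of the right lung and the left
split ≈56/44 — the regime reported by 3D SPECT lobar quantification in
adults, where the middle lobe is roughly half an axial third.  The random
cohort (`sample_spec`) jitters lung half-axes by ±8 %, fissure heights by
±0.04, tilts by ±5°, and draws per-lobe specific activities log-normally
with CV 0.15: enough inter-phantom variability for the ANOVA stages to see
realistic spread, narrow enough that every draw keeps normal lobar
topology (verified by a 100-draw property test).

## Imaging surrogate

The quantification methods consume *reconstructed* images, so the
acquisition chain (projections, collimator response, scatter, OSEM) is not
simulated.  A reconstructed SPECT is modelled as the activity volume scaled
to a total count, blurred with an isotropic Gaussian of 5 mm FWHM (the
clinical post-filter; kernel truncated at 4σ, image renormalised so counts
are conserved to better than 1e−6), then optionally Poisson-sampled
voxel-wise.  Applying Poisson noise after the blur is not physically exact
— real reconstructed noise is correlated — but it preserves the count
statistics at the scale the region sums see.  Default grid 128³ at 3.3 mm;
default total counts 5·10⁶ (a plausible clinical count level; the true
value is scanner- and protocol-dependent and is exposed in config).

HU→µ conversion uses the standard bilinear mapping anchored at air and
water: µ = µ_w(1 + HU/1000) for HU ≤ 0 and µ = µ_w(1 + 0.5·HU/1000) above,
with µ_w = 0.0151 mm⁻¹ at 140 keV and the bone slope 0.5; both constants
are configurable.

## Planar reprojection

Anterior and posterior planar images are ray sums along y through the µ-map
with exponential attenuation.  The emitting voxel contributes half its own
µ·Δy (midpoint emitter; second-order accurate), voxels strictly between
emitter and detector contribute fully.  This convention makes the classic
identities exact and testable: anterior × posterior factors multiply to
exp(−µD) through a uniform slab, so the geometric mean of the two views is
depth-independent.  Geometry is parallel-beam, views are 0° and 180° only,
and no extra PSF is applied at projection time (the volume is already
blurred).

## Quantification

**Planar template**: lung silhouettes are, by default, projections of the
true lobe labels — this isolates the template-geometry error, which is the
quantity under study, from delineation error (a threshold delineation mode
exists for realism).  The bounding box of each silhouette is split into
three cranio-caudal bands at round(H/3) and round(2H/3) (round half away
from zero, so band heights differ by ≤1 px); bands are intersected with the
silhouette.  Background is measured in an 8×8 px rectangle placed lateral
to each lung, outside the body silhouette, and subtracted per pixel;
negative corrected counts clip to 0 with a logged warning.  Views are
combined by geometric mean (clinical standard; arithmetic/single-view modes
exist and are recorded in every report).  Right thirds are read as
RUL/RML/RLL; the left middle band is halved into the left superior and
inferior counts, conserving the total exactly.

**3D lobar**: counts are summed inside each lobe label; percentages over
the five-lobe total.  A lobe missing from the label map reports 0 % and is
flagged.  With exact labels and no blur/noise this is algebraically
identical to the ground truth — the pipeline's self-consistency anchor.

## Observer model

Readers differ only in where they draw boundaries; the counts are fixed.

* planar readers: every bounding-box edge offset by round(N(0, σ_px²)),
  σ_px = 2, and the background gap jittered (σ = 1 px);
* manual 3D readers: fissure heights offset by N(0, σ²) with σ_oblique =
  3 mm and σ_horizontal = 6 mm (the horizontal fissure is the hardest to
  see on CT, especially with emphysema), tilts by N(0, 2°²); lungs' outer
  boundaries never move;
* automated 3D: deterministic (zero jitter) by default.

The jitter SDs are tuning constants, not estimates from data: they are set
so default runs land in clinically reported interobserver regimes (planar
RSD ≈ 20 %, manual middle-lobe RSD ≈ 19 %, automated ≈ 0).  A structural
consequence of fissure-only perturbation: the manual method's *whole-lung*
counts are identical across readers, so its whole-lung RSD is exactly zero
(up to ~1e−14 float rounding) — real manual readers also redraw lung
outlines, which this model deliberately excludes.  Variability is
summarised as the relative standard deviation (100·SD/mean, n−1
denominator) per region across readers, averaged over phantoms.

## Statistics

Methods are compared per region (5 lobes + 2 lungs) and per tracer with
Welch's heteroscedastic one-way ANOVA (weights n_i/s_i²; F* with
df1 = k−1, df2 = (k²−1)/(3Λ)), α = 0.05, implemented directly and
cross-checked in tests against an independent reference implementation and,
for k = 2, against the Welch t-test.  Summaries are mean, 95 % t-interval
and min–max range.  No multiple-testing correction is applied across the
7 regions × 2 tracers; raw per-region p-values are reported, as is usual in
this literature, and noted in the report.

Calibration is verified by simulation: 3 groups × n = 43 with common mean
25 and SDs 3/5/8, 10,000 replicates; the empirical type-I error must sit in
the binomial 3σ band [4.1 %, 5.9 %] around 5 %.

## Numerical choices

* Rasterisation is deterministic given (spec, grid); identical inputs give
  bit-identical volumes.
* Gaussian kernel truncation at 4σ with post-blur renormalisation bounds
  the conservation error below 1e−6 even near volume edges.
* Band-boundary rounding (half away from zero) and the half-voxel
  self-attenuation convention are declared so the unit tests can assert
  exact values.
* Ties in majority-vote label downsampling break to the smallest label
  code.
* All randomness flows through `numpy` `SeedSequence` substreams spawned
  from one master seed: observer k of phantom j uses substream (seed, j, k),
  so enlarging a study never reshuffles earlier draws, and report files are
  byte-reproducible (no timestamps).

## Problem sizes

Default study: 43 phantoms at 128³ × 3.3 mm, both tracers, three methods;
observer studies use 10 phantoms × 3 readers.  These sizes match the
simulated clinical design and run in minutes on one CPU; the test suite
uses coarser 64³ grids wherever geometry rather than resolution is under
test.

## What passing tests do and do not show

The phantom reproduces the *geometric* mechanism of the planar bias —
lobes are not axial thirds, and superimposed counts along the AP axis are
misassigned by a 2D template — and the *structural* mechanism of observer
variability (boundary placement).  It does not contain airways, vessels,
bone (optional), curved fissures, respiratory motion, scatter, or
reconstruction artifacts; absolute error magnitudes on real patients will
differ.  Directional conclusions (middle-lobe inflation, whole-lung
robustness, automated < manual < planar variability ordering) are the
claims the simulations support.

## Known limitations

* Poisson-after-blur noise underestimates the spatial correlation of
  reconstructed SPECT noise.
* The automated method is idealised as perfectly deterministic; real
  semi-automated tools retain a small residual check-step variability.
* Fissure-only manual jitter forces whole-lung manual RSD to zero (see
  above).
* The left lung is modelled with a single oblique fissure and no lingular
  subdivision; cardiac notch and mediastinal asymmetry are reduced to a
  slightly smaller left ellipsoid.
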