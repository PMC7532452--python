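# Methods

This note documents the models behind `fetomri`, the parameters that
matter, and the choices made where the design was genuinely open.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Digital fetoplacental phantoms

A phantom is a stylized 2D coronal slice (row index = SPEN/phase axis,
column index = readout axis, 0-based row-major): a placental disc with
three concentric layers (decidua outermost, trophoblast middle, labyrinth
innermost), an elliptical amniotic sac containing a fetal-brain and a
fetal-liver disc, and maternal background elsewhere.  Geometry grows mildly
with gestational day; the fetal liver is drawn generously (radius 0.065 of
the grid) so the smallest organ still yields stable histogram statistics at
desk-scale matrices.  Labels partition the grid; geometry is not meant to
be anatomical — every downstream statistic depends only on the labeled
regions.

Tissue parameters come from one editable table
(`src/fetomri/data/presets.csv`).  Absolute magnitudes are
literature-plausible declarations, not measured facts: amniotic fluid ADC
near free water at 37 °C (3.0×10⁻³ mm²/s), placental layers in
0.7–1.6×10⁻³ mm²/s, 7 T-plausible T1/T2.  What the presets do commit to is
the *directional* structure of the emulated study, enforced as invariants:

* amniotic fluid diffuses fastest, trophoblast is the slowest placental
  layer, decidua ≈ labyrinth above it;
* knockout and l-NAME placental means sit ~20 % below wildtype;
* the l-NAME placental distribution is the broadest (within-layer
  coefficient of variation 0.40 vs 0.10 elsewhere — a single-Gaussian fit
  to the three-layer mixture under-resolves the difference, hence the large
  designed effect);
* fetal-brain ADC falls linearly with gestational day in every model, from
  a slightly higher wildtype starting point to a common endpoint, and its
  within-compartment spread narrows with age fastest in wildtype
  (CV 0.12→0.05 vs 0.12→0.095);
* wildtype labyrinth perfusion (0.030 s⁻¹) far exceeds decidua
  (0.010 s⁻¹); in diseased models the layers are similar (0.008–0.009 s⁻¹);
  fetal-liver perfusion is ~10⁻² of the placental mean in wildtype (intact
  barrier) and ~10⁻¹ in diseased models (leaky barrier).

Within-compartment heterogeneity is Gaussian jitter (default CV 10 % for
ADC, 5 % for relaxation and proton density, 10 % for perfusion).  Each
fetoplacental unit also carries per-compartment multiplicative biological
effects (CV ~5 %) that persist across gestational days, drawn from a
substream keyed by (seed, model, dam, unit) — units are therefore iid
within a cohort and there is no dam-level random effect by default (one can
be injected for the variance-decomposition analysis).  All generation is a
pure function of the cohort specification and one integer seed,
split into per-(model, dam, unit, day) substreams.

Cohort designs mirror the emulated study: 5/5/4/3 dams for
wildtype/eNOS/IL10/l-NAME with per-dam unit ranges chosen so day-E14.5
totals match the reported 22–35 / 26–38 / 17–29 / 11 fetoplacental units;
per-dam counts are monotonically non-increasing with day (units leave the
imaging field of view as pregnancy advances), and the l-NAME arm is scanned
on E14.5 and E16.5 only.

## SPEN acquisition model

Sequence defaults follow the emulated protocol: TR/TE 2000/37 ms, FOV
30×30 mm, matrix 160×160 (187.5 µm nominal), 5 interleaves; the chirp
duration is tp = 20 ms.  The chirp time–bandwidth product R is not printed
anywhere and is a declared assumption, set to 450 (encoding gradient
≈0.9 G/cm over 30 mm), in the regime of published SPEN protocols whose
chirp bandwidths are tens of kHz.

**Encoding operator.**  The chirp stamps the quadratic phase
φ(y) = −πR y²/L².  The acquisition blips rasterize the SPEN axis at the
Nyquist step 2π/L; each of the K shots acquires every K-th line and the
variable K_shot gradient adds the per-shot fine offset, which on the object
is exactly a linear phase ramp.  The assembled operator
A[ℓ,y] = exp(i(φ(y) + k_ℓ y)) is then unitary up to scale; the readout axis
is an orthonormal DFT.  Reconstruction inverts the SPEN axis by the ridge-
regularized pseudo-inverse (AᴴA + λ²I)⁻¹Aᴴ with λ = 10⁻³ of the largest
singular value — effectively exact for the full interleave set, and a
well-behaved minimum-norm solution for partial sets.  DC sits at index
matrix//2.

**Timing.**  Within a shot, line j is acquired at t = j·esp with
esp = 2·tp·K/N, i.e. the acquisition lasts 2·tp and revisits each position
at twice its chirp-inversion delay — the fully-refocused condition under
which every SPEN position is sampled at its own spin echo.

**Off-resonance.**  A frequency offset Δf is swept through by the chirp at
a shifted moment, so the spin is encoded as if displaced along the SPEN
axis by Δf·tp·L/R (the standard SPEN distortion, a fraction Δf/(R/tp) of
the FOV); this is implemented as a linear-interpolation resampling of the
object.  The additional phase evolved between each position's inversion and
its acquisition refocuses at that position's spin echo under the
fully-refocused timing and is modeled as refocused.  An earlier variant
that carried this evolution phase inside the encoding operator was
abandoned: under a regularized inverse the mismatch pumps energy into weak
singular modes and produces unphysical amplification.  The EPI comparator
(matched FOV/matrix, esp 0.5 ms, 4 interleaves) keeps the standard
phase-accrual model, displacing signal by Δf × (per-shot train duration)
voxels; its closed form is checked against simulation.

**Interleaving and resolution.**  In this k-space-subset model a single
shot leaves exact K-fold positional ambiguity (equal-height aliases at N/K
spacing) rather than a broadened main lobe, so the resolution gain of
interleaving is quantified as the K-fold increase in energy concentration
of the point response, not as an FWHM ratio.

**Relaxation.**  T2/TE and TR/T1 weighting are folded into one static
per-voxel scale, PD·e^(−TE/T2)·(1−e^(−TR/T1)); no echo-train relaxation.

## Effective b-maps

b(y) = γ²∫q(t,y)²dt with q the running gradient first moment and γ fixed
at 2.6752218744×10⁸ rad s⁻¹ T⁻¹; the moment's sign history flips at every
refocusing event, including the chirp's position-dependent inversion time
τ(y).  Waveforms are integrated on a uniform 1 µs grid; because the chirp
contributes exactly one position-dependent flip, the integral reduces to 1D
cumulative sums evaluated at τ(y), which matches the Stejskal–Tanner closed
form b = γ²G²δ²(Δ−δ/3) to ≤0.1 % for a pure gradient-echo pair and scales
exactly quadratically in amplitude.  With the encoding and raster gradients
on, b varies along the SPEN axis and its minimum stays positive even
without diffusion lobes (tens of s/mm² at the defaults) — the mechanism
that precludes very low b-values in SPEN DWI.  The printed protocol's exact
minimal b (~60 s/mm²) is not reproducible because the encoding gradient
strength is not published; only the qualitative nonzero-minimum property is
asserted.  In the default sequence the diffusion block is self-refocused
before the chirp, so its cross-terms with the imaging gradients vanish for
ideal rectangles; the integrator handles arbitrary overlapping waveforms,
where cross-terms appear automatically.

ADC fitting uses each acquisition's effective b-map voxelwise:
ADC_d = ln(S₀/S_d)/(b_d − b₀), isotropic ADC = mean of three orthogonal
directions.  The b≈0 image's own encoding-gradient weighting therefore
cancels exactly.  Voxels with S₀ below 3× the noise σ (carried by the
simulation, or estimated from image corners for external data) are masked
invalid; negative fitted ADCs are kept for histogramming and excluded only
from display, since clamping would bias region means upward.

## Region statistics

Histograms use Freedman–Diaconis binning with a floor of 8 bins.  Gaussian
fits A·exp(−(x−μ)²/2σ²) are least-squares on bin centers with
moment-based initialization and amplitude-normalized counts (making the
fit exactly invariant to count scaling); fits whose σ collapses below half
a bin width are flagged degenerate.  The three-layer placental composite is
strongly trimodal and a single-Gaussian fit to it is unstable, so composite
placental statistics are raw-voxel moments; unimodal regions use the
histogram fit.  Reconstructed-image ROIs are the ground-truth masks eroded
by one pixel to avoid boundary partial-volume — the analog of drawing
regions inside a border.

Longitudinal tables aggregate per-unit (μ, σ) per (model, day): cross-unit
mean and spread (SD), with unit/dam counts.  Model contrasts are two-sided
Welch t-tests computed from these summary statistics at the unit level.
Statistics are computed per unit and then cohort-aggregated (pooling per
animal is available but not the default).  A one-way method-of-moments
variance decomposition supports the animal-by-animal view.

## DCE and steepest-slope perfusion

FLASH defaults: TR/TE 60/2.6 ms, 75° flip, 128 phase-encode lines → 7.68 s
frame time, 180 frames; relaxivity 3.4 s⁻¹mM⁻¹.  The spoiled-GRE signal is
S = k·sinα(1−E1)/(1−cosα·E1), E1 = e^(−TR·R1), R1 = 1/T10 + r1·C; T2*
decay over the 2.6 ms TE is neglected.  DCE is simulated on the phantom's
own grid (one slice; the protocol's six slices are collapsed).

The arterial input is a gamma-variate A((t−t₀)/β)^α e^(−(t−t₀)/β) with
α = 3, β = 8 s, onset t₀ = 38.4 s (five baseline frames at the native
frame time) and a 10 % recirculation plateau — a parametric stand-in for
the image-derived kidney-hilus input of an in-vivo study (an image-derived
ROI mode exists).  The shape was fixed from bolus-physiology plausibility;
at these settings the 3-point sliding-window slope underestimates a known
uptake rate by ~8 % at 7.68 s frames, within the estimator's design
tolerance, and the bias vanishes as the frame time shrinks (the tests
verify both).

Tissue uptake is one-compartment, dC_t/dt = F·C_a − kep·C_t, solved by an
exact exponential integrator with piecewise-linear C_a (kep = 0 reduces to
the cumulative integral); per-voxel curves scale linearly in F for a shared
compartment kep (default 0.005 s⁻¹).  A non-extravasating
(albumin-bound-agent) mode returns the intravascular pool v_b·C_a, which is
identically zero in fetal compartments (v_b = 0) — the intact-barrier
behavior.

The steepest-slope estimator converts signal to concentration by inverting
the SPGR equation (per-voxel scale calibrated on the pre-onset baseline,
T10 from the phantom truth; a baseline-normalized relative-enhancement
fallback exists for unknown T10), takes the maximum 3-point sliding
linear-fit slope (larger windows underestimate fast placental uptake at
7.68 s frames), clamps negative slopes to zero, and normalizes by the AIF
peak.  F is reported in s⁻¹; normalization in the concentration domain is
the default, with the signal-domain variant available.  The estimator is
invariant to contrast dose (the scale cancels between uptake slope and AIF
peak).

## Problem sizes and what passing tests show

Tests and the acceptance script run desk-scale versions of the study:
64–96 px matrices with 4 interleaves (the default configuration retains the
full-scale 160 px / 5-interleave profile), cohorts of 2 dams × 2 units ×
3 days for the imaging-level recovery study, full design sizes
(truth-map level) for the 200-replicate statistical calibration, and 20
replicates for the off-resonance comparison.  The phantoms emulate labeled
anatomy, smooth static field offsets and Rician noise; they do not emulate
respiratory motion, susceptibility gradients at air/tissue interfaces,
chemical shift, slice-profile effects or partial-volume anatomy beyond
pixelization.  Passing tests therefore demonstrate the internal consistency
and statistical calibration of the method chain under its own assumptions,
not in-vivo performance.

## Known limitations

* 2D single-slice geometry; no Bloch-level chirp simulation (the
  stationary-phase quadratic profile is used).
* The EPI comparator is single-polarity; reversed-gradient distortion
  correction is out of scope.
* No IVIM/bi-exponential or tensor diffusion fitting.
* No deconvolution or Tofts-model perfusion; steepest slope only.
* Absolute preset magnitudes are assumptions; only orderings and ratios
  between models, layers and days are designed facts of the simulation.
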