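# fetomri

Synthetic fetoplacental MRI: multi-shot SPEN diffusion imaging, ADC
histogram statistics and steepest-slope DCE perfusion, evaluated end to end
on digital mouse-pregnancy phantoms.

## The problem

Diffusion-weighted MRI of pregnant mice can separate the layers of the
placenta — the maternal-side **decidua**, the intermediate **trophoblast**
band and the fetal-side **labyrinth** — and track fetal-brain maturation
through the apparent diffusion coefficient (ADC), while dynamic
contrast-enhanced (DCE) imaging of a gadolinium bolus measures placental
perfusion.  Echo-planar imaging (EPI) struggles in the mouse abdomen
because its low phase-encode bandwidth turns static field offsets into
large geometric distortions; spatiotemporal encoding (SPEN) replaces the
Fourier phase axis with a frequency-swept (chirp) inversion whose quadratic
phase is inverted algebraically at reconstruction, confining off-resonance
displacement to Δf/(chirp bandwidth) of the field of view.

No in-vivo data are available for this kind of study pipeline, so this
package is built as a simulation laboratory: labeled 2D fetoplacental
phantoms with ground-truth parameter maps stand in for the animals, the
full acquisition chain is simulated, and every analysis step is validated
against the truth it was generated from.  Cohorts emulate four pregnancy
models — wildtype, eNOS⁻/⁻ (growth restriction), IL10⁻/⁻ and l-NAME-treated
(preeclampsia-like) — across gestational days E14.5–E19.5.

## What is implemented

* **`fetomri.phantom`** — digital fetoplacental units: three-layer
  placental disc, amniotic sac with fetal brain and liver, per-compartment
  ADC/T1/T2/proton-density/perfusion truth maps with configurable
  heterogeneity, and cohort sampling with per-dam unit counts that decrease
  with gestational age.  Presets live in one editable table
  (`src/fetomri/data/presets.csv`).
* **`fetomri.spen`** — the physics core: Stejskal–Tanner b-values,
  effective b-maps by integration of the squared running gradient moment
  q(t, y) with position-dependent sign inversion at the chirp (so b varies
  along the SPEN axis and never reaches zero), multi-shot SPEN encoding
  with K_shot interleaving, regularized-pseudo-inverse reconstruction, an
  interleaved-EPI comparator, and Rician noise.
* **`fetomri.adc`** — voxelwise log-ratio ADC fits using each image's
  effective b-map, isotropic ADC as trace/3, region histograms
  (Freedman–Diaconis), Gaussian fits A·exp(−(x−μ)²/2σ²), longitudinal
  cohort tables, Welch model contrasts and per-animal breakdowns.
* **`fetomri.dce`** — FLASH/SPGR signal model, gamma-variate arterial input
  function, one-compartment uptake (with a non-extravasating-agent mode for
  the intact placental barrier), and the steepest-slope perfusion
  estimator F = max dC_t/dt / max C_a.
* **`fetomri.pipeline` / `fetomri` CLI** — simulate → analyze → report over
  manifest-tracked NIfTI/CSV/JSON artifacts.

The headline statistic throughout is the per-region Gaussian mean μ and
width σ of the ADC distribution, aggregated per (model, gestational day)
across fetoplacental units, and the per-region steepest-slope perfusion
coefficient F (s⁻¹).

## Worked example

```sh
python analysis/02_spen_vs_epi_robustness.py --seed 1
python analysis/03_adc_longitudinal.py --seed 1
python analysis/04_dce_perfusion.py --seed 1
```

prints (seed 1):

```
offset 300 Hz: SPEN shift 0.92 vox, EPI shift 2.79 vox (analytic EPI prediction 2.40);
SPEN less displaced in 100% of 20 replicates

worst cohort-mean ADC recovery error: 3.4%
  PASS  fluid_highest
  PASS  trophoblast_lowest_layer
  PASS  ko_placenta_below_wt
  PASS  lname_sigma_broadest
  PASS  brain_mu_decreasing
  PASS  wt_brain_sigma_narrows_fastest
  wildtype vs enos_ko: placental Δμ = 2.31e-04 mm²/s, p = 0.00019

estimator error at 7.68 s frames: 7.7%
bias vs frame time: {7.68: '-7.7%', 3.84: '-2.0%', 1.92: '-0.4%'}
  wildtype   labyrinth 0.0271 s⁻¹, decidua 0.0088 s⁻¹, liver/placenta = 0.00925
  enos_ko    labyrinth 0.0079 s⁻¹, decidua 0.0071 s⁻¹, liver/placenta = 0.0916
```

Reading it: under a 300 Hz offset SPEN's apparent displacement stays ~3×
below EPI's; the full phantom → encode → reconstruct → fit chain recovers
every compartment's mean diffusivity to within a few percent while
preserving all designed cohort effects (knockout placentas slower than
wildtype, the chemically treated model's distribution broadest, fetal-brain
diffusivity falling — and its spread narrowing fastest in wildtype — with
age); and the perfusion estimator is accurate to within its sampling bias,
separating the intact-barrier wildtype regime (fetal-liver/placenta
perfusion ratio ~10⁻²) from the leaky diseased regime (~10⁻¹).

`analysis/01_simulate_cohorts.py` writes full image-level cohorts (NIfTI +
manifest) for the pipeline CLI:

```sh
fetomri simulate --config results/run/config.json --out results/run
fetomri analyze  --config results/run/config.json --out results/run
fetomri report   --config results/run/config.json --out results/run
```

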