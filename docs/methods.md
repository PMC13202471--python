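# Methods

## Emission model

A nanoparticle containing `N` identical dye molecules sits in the focus of
a pulsed infrared beam (wavelength λ = 1030 nm, repetition period
T = 12.5 ns, sech²-shaped pulses of characteristic duration τ = 135 fs).
Each pulse is replaced by an equal-area rectangular pulse of duration
δt = 2τ = 270 fs. During a pulse, a ground-state molecule is promoted at
the two-photon rate

    Γ_exc = ½ · α²σ₂ · [κ · P_peak / (ħω · π·W₀²)]²,   P_peak = P_exc·T/δt,

where σ₂ is the per-molecule two-photon absorption cross section
(GM = 10⁻⁵⁰ cm⁴·s·photon⁻¹), α the local-field coefficient (the squared
field-enhancement a molecule experiences inside the dense dye particle;
Lorentz estimate α = ((n²+2)/3)², between 2 and 13 for dye refractive
indices 1.5–3), W₀ = 360 nm the beam waist, and κ a dimensionless geometry
factor (below). The ½ accounts for two photons consumed per excitation.

The model assumes Γ_exc ≫ Γ (excitation much faster than radiative decay
during the pulse) and 1/Γ ≪ T (full relaxation between pulses), so each
molecule emits at most one photon per pulse with probability
1 − exp(−Γ_exc·δt) and the detected rate is

    R(P_exc) = η·N·Φ·(1/T)·[1 − exp(−Γ_exc·δt)],

with quantum yield Φ and collection efficiency η = 0.80. Because
Γ_exc ∝ P_exc², defining P_sat by Γ_exc(P_sat)·δt = 1 turns this into the
saturation law F = 1 − exp(−P_exc²/P_sat²), and a fitted P_sat inverts to

    α²σ₂ = 2·δt·(ħω·π·W₀²/κ)² / (T²·P_sat²).

`pulse_train_emission` implements the closed form; the test suite checks
it against direct numerical integration of the ground-state rate equation
over the rectangular pulse (relative error < 10⁻⁶). Photobleaching is
modeled as a decay of the emitting-molecule pool proportional to the
excitation rate, τ_b = τ_b,0·(P_sat/P_exc)², i.e. a −2 log-log slope of
τ_b against power; τ_b,0 is the bleaching time at P_exc = P_sat.

### Geometry factor κ

The absolute prefactor of Γ_exc depends on beam-area and waist conventions
that the constants alone do not pin down. The package therefore uses the
effective area π·W₀² and a single dimensionless κ, calibrated once so the
first family's anchor pair (P_sat = 17.3 mW ↦ α²σ₂ = 710 GM) is
reproduced exactly; with the instrument constants above this gives
κ = 1.0014, i.e. the convention is already consistent to 0.3%. Everything
that carries scientific weight — the family ratio
α²σ₂(2)/α²σ₂(1) = (P_sat,1/P_sat,2)² — is independent of κ. κ is stored in
`InstrumentParams` and echoed in all fit outputs.

### Conventions and defaults

| parameter | value | note |
|---|---|---|
| τ | 135 fs | sech² model parameter; `tau_is_fwhm=True` reinterprets it as the intensity FWHM (δt = 2τ/1.763) |
| δt | 2τ = 270 fs | equal-area rectangular pulse |
| W₀ | 360 nm | IR intensity ∝ exp(−r²/W₀²); the two-photon (fluorescence) PSF is then Gaussian with σ = W₀/√2 ≈ 255 nm, used consistently by the simulator and as the spot-fit reference width |
| Γ | 5×10⁸ s⁻¹ (1/Γ = 2 ns) | radiative rate, not printed for these dyes; typical for this dye class. Used only to check the 1/Γ ≪ T assumption — results do not depend on it in the implemented Γ_exc ≫ Γ limit |
| η | 0.80 | stated collection efficiency |
| units | powers mW, cross sections GM, lengths nm, times s | all reconciliation inside `excitation_rate` |

## Synthetic data generator

The generator emulates the statistical structure of the three experiments
with Poisson photon counting throughout (all RNG through
`numpy.random.default_rng`, bit-reproducible under a fixed seed):

* **Sizes.** Dry diameters are truncated-normal mixtures. Family 1 is
  bimodal — (15 ± 3) nm and a broad (50 ± 15) nm mode, equal weights — so
  the large mode carries over ten times the mean volume and dominates every
  signal; family 2 is unimodal (20 ± 3) nm. The histogram shapes are not
  published numerically; the spreads (3 nm narrow, 15 nm broad) are the
  package's choice of a realistic TEM width.
* **Molecule numbers.** N = ρ·(π/6)d³·N_A/M at relative density 1.0. Dye
  molar masses are not published; defaults are calibrated so the tabulated
  (diameter, N) pairs are reproduced exactly: 1025.5 g/mol (family 1,
  29 nm ↦ 7500) and 1201.3 g/mol (family 2, 20 nm ↦ 2100).
* **Scans.** Particles are uniform over the field; each contributes a 2D
  Gaussian spot (σ = W₀/√2) whose peak rate comes from the emission model
  with its own N(d); pixel counts are Poisson(dwell × (signal +
  background)). A configurable fraction (default 10%) are aggregates of
  2–4 particles jittered within the PSF (offset SD 0.5σ).
* **Sweeps and decays.** Expected counts are dwell × R(P) (optionally
  attenuated by bleaching accumulated over the acquisition order) and
  bin × [S₀·exp(−t/τ_b) + background] respectively, then Poisson-sampled.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: detector dead time and afterpulsing; focus
drift; aberrated or z-sectioned PSFs; dye-to-dye heterogeneity; any
bleaching mechanism beyond the monoexponential law. Two consequences are
worth flagging. First, absolute simulated rates are idealized (only the
80% collection term attenuates them), so simulated brightness values are
far larger than measured ones; all fitted parameters and P²-normalized
comparisons are unaffected. Second, with strictly volume-proportional
brightness the family-1 population (dominated by its 50 nm mode) is
several times brighter per particle than family 2 — the equal-brightness
result of the real measurement is a property of the measured data, not
something these generator settings enforce, and the measured medians/means
and their t-test are accordingly not reproduced here (the pipeline
computes the statistics; their measured values require the deposited raw
data). Relatedly, most simulated aggregates broaden the merged spot by
less than the flagging tolerance — sub-PSF clusters are genuinely
unresolvable — so shape-based flagging catches only the spread-out
minority, as visual inspection does in real scans.

## Analysis pipelines

* **Spot analysis.** Detection: local maxima above median + k·MAD·1.4826
  (default k = 5) with non-maximum suppression at 500 nm. Fitting:
  offset + A·exp(−r²/2σ²) by weighted least squares (Poisson weights
  1/√(counts+1); anisotropic σx, σy by default for aggregate flagging);
  spots are rejected when the fit fails, A < 3·SE(A), or σ collapses below
  the pixel scale. Brightness = A/P_exc² in kcounts·s⁻¹·mW⁻². Aggregate
  flag: width deviation from σ = W₀/√2 or anisotropy above 10% (the
  quadrature broadening of sub-PSF pairs never reaches the ~30% a lone
  width comparison would suggest). Aggregates stay in the brightness
  statistics by default (a config flag excludes them). Quartiles use
  linear interpolation (type 7). The population comparison is a two-sided
  Welch t-test (variances visibly unequal between families); a Student
  option exists.
* **Saturation.** Per-trace weighted fit of A·(1 − exp(−P²/P_sat²)) with
  Poisson weights; start values from the maximum count and the quadratic
  low-power slope; a warning (with inflated SE) marks traces whose powers
  never reach the inflection. The ensemble stage normalizes each trace by
  its fitted asymptote, interpolates onto a common 50-point grid
  (interpolation of the convex curve costs ~3×10⁻⁴ relative on P_sat),
  reports mean ± SD across particles, and refits the mean. Both the
  ensemble fit and inverse-variance pooling of per-particle fits are
  reported. P_sat errors propagate to first order: relative error of α²σ₂
  is twice, of α equal to, that of P_sat.
* **Bleaching.** Per-trace monoexponential fits (Poisson weights,
  counts+1 so deep-bleached bins keep finite weight; background optionally
  fixed to 0); bleaching times aggregated per power as mean ± SD across
  particles; then a weighted fit of τ_b,0 with P_sat supplied from the
  saturation stage — never co-fitted, since the power law identifies only
  the product τ_b,0·P_sat². The unconstrained log-log slope is fitted
  separately as a model check. Sweeps are not bleaching-corrected by
  default; the generator can include the effect for sensitivity checks.

## Problem sizes

The parameter-recovery experiments run 50 sweeps (15 powers spanning
1–40 mW, 1 s dwell, 10⁵ counts/s asymptotic rate) for the saturation stage
and 5 powers × 10 traces (0.5–2 × P_sat, 10 ms bins, 3.5 decay times per
trace, 10⁵ counts/s initial rate) for the bleaching stage — comfortable
photon budgets at which both estimators are unbiased to well under a
percent, as the test suite verifies.

## Known limitations

* The measured α exceeds any single Lorentz factor's plain reading of the
  dye refractive index; environment-dependent corrections also affect the
  ensemble σ₂ and Φ measurements. No quantitative model of that interplay
  is implemented — α is reported as defined, √(α²σ₂/σ₂).
* Only monoexponential bleaching is supported; multi-exponential or
  stretched decays are out of scope.
* Single scans only: no drift correction, tiling or multi-frame
  registration.
* σ₂ is a single scalar at the working wavelength; no spectra.
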