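# dfon2p

Single-particle **two-photon photophysics of dye-based fluorescent organic
nanoparticles (dFONs)**: a forward emission model for pulsed two-photon
excitation, a seeded synthetic microscope-data generator, and the three
analysis stages used to characterize individual nanoparticles —
brightness statistics from raster scans, saturation-curve fitting yielding
local-field-corrected two-photon absorption cross sections, and
photobleaching-law fitting.

dFONs are self-assembled aggregates of hydrophobic dye molecules used as
ultrabright bioimaging probes. Under a femtosecond pulse train
(period *T*, equal-area rectangular pulse duration δ*t* = 2τ), each of the
*N* dye molecules in a particle is excited during a pulse at the
two-photon rate

    Γ_exc = ½ · α²σ₂ · [κ · P_exc·T/δt / (ħω · π·W₀²)]²

(σ₂: per-molecule two-photon cross section, α: local-field coefficient,
W₀: beam waist, ħω: photon energy, κ: dimensionless geometry factor), and
emits at most one photon per pulse with probability 1 − exp(−Γ_exc·δt).
This gives the saturating fluorescence law and its two companion relations:

* **Saturation**  F(P_exc) = 1 − exp(−P_exc²/P_sat²), with
  Γ_exc(P_sat)·δt ≡ 1, so a fitted P_sat converts to a combined cross
  section α²σ₂ = 2·δt·(ħω·π·W₀²/κ)²/(T²·P_sat²); comparison with the
  ensemble σ₂ gives the local-field coefficient α = √(α²σ₂/σ₂)
  (Lorentz estimate: α = ((n²+2)/3)²).
* **Brightness**  B_2P = σ₂·Φ·N per particle; scan-derived peak rates are
  normalized by P_exc², the natural unit for a quadratic absorber.
* **Photobleaching**  τ_b = τ_b,0·(P_sat/P_exc)² — bleaching accelerates
  with the excitation rate, giving a −2 slope in log-log.

The package ships the two studied particle families as ready-made
parameter sets: `DFONS1` (σ₂ = 60 GM, Φ = 0.33, N = 7500, P_sat = 17.3 mW,
τ_b,0 = 1.06 s) and `DFONS2` (σ₂ = 930 GM, Φ = 0.06, N = 2100,
P_sat = 5.29 mW, τ_b,0 = 3.84 s).

## Worked example

```python
import numpy as np
from dfon2p import (DFONS1, paper_instrument, generate_saturation_sweep,
                    fit_saturation, derive_cross_section)

inst = paper_instrument()          # λ=1030 nm, 80 MHz, τ=135 fs, W₀=360 nm
powers = np.linspace(1, 40, 15)    # mW
trace = generate_saturation_sweep(DFONS1, inst, powers, dwell_s=1.0,
                                  asymptotic_rate_cps=1e5, seed=1)
fit = fit_saturation(trace)
res = derive_cross_section(fit, inst, ensemble_sigma2_GM=DFONS1.sigma2_GM)
print(f"P_sat = {fit.psat_mW:.2f} mW, alpha2*sigma2 = "
      f"{res.alpha2_sigma2_GM:.0f} GM, alpha = {res.alpha:.2f}")
```

prints

```
P_sat = 17.31 mW, alpha2*sigma2 = 709 GM, alpha = 3.44
```

i.e. the simulated particle saturates at 17.31 mW (truth 17.3 mW), which
converts to a combined in-particle cross section of ~709 GM — about
α² ≈ 12 times the per-molecule solution value of 60 GM, an α ≈ 3.4
local-field enhancement.

The full analysis over a simulated data bundle lives in `analysis/`:

```sh
python analysis/01_simulate.py        # synthetic scans + sweeps + decays
python analysis/02_scan_brightness.py # spot fits, P²-normalized stats, t-test
python analysis/03_saturation.py      # ensemble P_sat → α²σ₂ → α per family
python analysis/04_bleaching.py       # τ_b fits → τ_b,0, log-log slope
```

Stage 4, for example, reports `tau_b0 = 1.055 ± 0.001 s` and
`3.821 ± 0.001 s` for the two families (generated with 1.06 / 3.84 s),
log-log slopes of −2.00, and a photostability ratio of 2.95: at any common
excitation power the first family bleaches about three times slower.
A `dfon2p` console script exposes the same stages
(`simulate`, `analyze-scan`, `fit-saturation`, `fit-bleaching`,
`reproduce-paper`).

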