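"""End-to-end reference computations on the published study constants.

Each function re-derives one headline quantity of the two-family dFON
study from scratch — deterministic ones from the printed instrument and
Table-1 constants, stochastic ones by simulating the experiment with the
synthetic generator and running the fitting pipeline.  Used by the
``reproduce-paper`` CLI command, the reproduction script and the test
suite.
"""

from __future__ import annotations

import math

import numpy as np

from .photophysics import (
    DFONS1,
    DFONS2,
    brightness_2p,
    cross_section_from_psat,
    lorentz_local_field,
    paper_instrument,
)
from .synthetic import generate_bleach_trace, generate_saturation_sweep
from .traces import (
    derive_cross_section,
    fit_bleach_law,
    fit_decay,
    fit_saturation,
    photostability_ratio,
)
from .traces import SaturationFit

__all__ = [
    "round_sig",
    "local_field_coefficients",
    "lorentz_bounds",
    "brightness_products",
    "cross_section_consistency",
    "stability_ratio",
    "recover_psat",
    "recover_bleach_law",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def local_field_coefficients() -> dict[str, float]:
    """α = √(α²σ₂/σ₂) for both families from their fitted saturation powers
    and ensemble per-molecule cross sections, at 2 significant figures."""
    inst = paper_instrument()
    out = {}
    for sp in (DFONS1, DFONS2):
        fit = SaturationFit(sp.psat_mW, None, 1.0, None, 0.0, 0)
        res = derive_cross_section(fit, inst, sp.sigma2_GM)
        out[sp.name] = round_sig(res.alpha, 2)
    return out


def lorentz_bounds() -> tuple[float, float]:
    """Lorentz coefficient at the refractive-index extremes n = 1.5 and 3,
    rounded to the printed (integer) precision."""
    return (
        float(round(lorentz_local_field(1.5))),
        float(round(lorentz_local_field(3.0))),
    )


def brightness_products() -> dict[str, float]:
    """Per-particle 2P brightness σ₂·Φ·N (GM) at 2 significant figures."""
    return {
        sp.name: round_sig(brightness_2p(sp.sigma2_GM, sp.phi, sp.n_molecules), 2)
        for sp in (DFONS1, DFONS2)
    }


def cross_section_consistency() -> dict[str, float]:
    """α²σ₂ for both families from their saturation powers, with the
    geometry factor κ calibrated once on the dFONs(1) case."""
    inst = paper_instrument()  # κ anchored at 17.3 mW ↦ 710 GM
    return {
        sp.name: cross_section_from_psat(sp.psat_mW, inst)
        for sp in (DFONS1, DFONS2)
    }


def stability_ratio() -> float:
    """Ratio of bleaching times dFONs(1)/dFONs(2) at any common power."""
    return photostability_ratio(
        DFONS1.tau_b0_s, DFONS1.psat_mW, DFONS2.tau_b0_s, DFONS2.psat_mW
    )


def recover_psat(
    seed: int,
    n_sweeps: int = 50,
    powers_mW=None,
    dwell_s: float = 1.0,
    asymptotic_rate_cps: float = 1e5,
) -> dict:
    """Parameter-recovery experiment for the saturation stage.

    Simulates ``n_sweeps`` Poisson saturation sweeps of dFONs(1)-like
    particles (truth P_sat = 17.3 mW, 15 powers spanning 1–40 mW), fits
    each with the saturation law and reports the mean fitted P_sat.
    """
    if powers_mW is None:
        powers_mW = np.linspace(1.0, 40.0, 15)
    inst = paper_instrument()
    rng = np.random.default_rng(seed)
    fitted = []
    for i in range(n_sweeps):
        trace = generate_saturation_sweep(
            DFONS1, inst, powers_mW, dwell_s,
            asymptotic_rate_cps=asymptotic_rate_cps,
            particle_id=f"sweep{i}", seed=rng,
        )
        fitted.append(fit_saturation(trace).psat_mW)
    fitted = np.asarray(fitted)
    return {
        "mean_psat_mW": float(fitted.mean()),
        "sd_psat_mW": float(fitted.std(ddof=1)),
        "truth_mW": DFONS1.psat_mW,
        "n_sweeps": n_sweeps,
    }


def recover_bleach_law(
    seed: int,
    n_powers: int = 5,
    n_traces_per_power: int = 10,
    initial_rate_cps: float = 1e5,
    bin_s: float = 10e-3,
) -> dict:
    """Parameter-recovery experiment for the full bleaching pipeline.

    Simulates decay traces of dFONs(2)-like particles at ``n_powers``
    excitation powers between 0.5 and 2 × P_sat (truth τ_b,0 = 3.84 s),
    fits each monoexponentially, aggregates by power and fits the
    τ_b = τ_b,0·(P_sat/P)² law with P_sat supplied.
    """
    sp = DFONS2
    powers = np.linspace(0.5 * sp.psat_mW, 2.0 * sp.psat_mW, n_powers)
    rng = np.random.default_rng(seed)
    mean_tb, sd_tb = [], []
    for p in powers:
        tau_true = sp.tau_b0_s * (sp.psat_mW / p) ** 2
        taus = []
        for j in range(n_traces_per_power):
            trace = generate_bleach_trace(
                sp, paper_instrument(), p, duration_s=3.5 * tau_true, bin_s=bin_s,
                initial_rate_cps=initial_rate_cps,
                particle_id=f"p{p:.3g}-{j}", seed=rng,
            )
            taus.append(fit_decay(trace, fit_background=False)[0])
        mean_tb.append(np.mean(taus))
        sd_tb.append(np.std(taus, ddof=1))
    law = fit_bleach_law(powers, mean_tb, sd_tb, sp.psat_mW)
    return {
        "tau_b0_s": law.tau_b0_s,
        "tau_b0_stderr_s": law.tau_b0_stderr_s,
        "loglog_slope": law.loglog_slope,
        "loglog_slope_stderr": law.loglog_slope_stderr,
        "truth_s": sp.tau_b0_s,
        "n_traces": int(n_powers * n_traces_per_power),
    }
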