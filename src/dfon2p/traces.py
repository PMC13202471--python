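"""Saturation- and bleaching-trace fitting.

Stage 1 (saturation): per-particle counts-vs-power sweeps are fitted with
the two-photon saturation law ``A·(1 − exp(−P²/P_sat²))`` (Poisson
weights), normalized to the fitted asymptote, pooled into an ensemble
mean ± SD band, and the mean curve re-fitted.  The fitted P_sat converts
to a combined cross section α²σ₂ through the inverse-square relation of
the excitation model, and comparison with the ensemble per-molecule σ₂
gives the local-field coefficient α = √(α²σ₂/σ₂).

Stage 2 (bleaching): per-trace monoexponential fits S₀·exp(−t/τ_b)+bg,
per-power aggregation (mean ± SD across particles), and a weighted fit of
the power law τ_b = τ_b,0·(P_sat/P)² with P_sat supplied from stage 1 —
τ_b,0 and P_sat are degenerate in the power law, so only τ_b,0·P_sat² is
identifiable from bleaching data alone.  An unconstrained log-log linear
fit checks the expected slope of −2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from .photophysics import (
    InstrumentParams,
    LocalFieldResult,
    alpha_from_ensemble,
    cross_section_from_psat,
)
from .synthetic import DecayTrace, SweepTrace

__all__ = [
    "SaturationFit",
    "EnsembleSaturation",
    "BleachFit",
    "FitWarning",
    "fit_saturation",
    "normalize_to_asymptote",
    "ensemble_saturation",
    "derive_cross_section",
    "fit_decay",
    "fit_bleach_law",
    "photostability_ratio",
]


class FitWarning(UserWarning):
    """Data only weakly constrain a fitted parameter."""


@dataclass(frozen=True)
class SaturationFit:
    """Result of one saturation-law fit."""

    psat_mW: float
    psat_stderr_mW: float | None
    asymptote_cps: float
    asymptote_stderr_cps: float | None
    redchi: float
    n_points: int


@dataclass(frozen=True)
class EnsembleSaturation:
    """Normalized saturation curves pooled across particles."""

    powers_mW: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    fit: SaturationFit
    n_traces: int


@dataclass
class BleachFit:
    """Bleaching-pipeline result for one particle family."""

    tau_b0_s: float
    tau_b0_stderr_s: float | None
    psat_mW: float
    loglog_slope: float
    loglog_slope_stderr: float
    powers_mW: np.ndarray = field(default_factory=lambda: np.array([]))
    mean_tau_b_s: np.ndarray = field(default_factory=lambda: np.array([]))
    sd_tau_b_s: np.ndarray = field(default_factory=lambda: np.array([]))


def _sat_model(p, a, psat):
    return a * (1.0 - np.exp(-(p**2) / psat**2))


def fit_saturation(trace: SweepTrace) -> SaturationFit:
    """Weighted least-squares fit of counts = A·(1 − exp(−P²/P_sat²)).

    Weights are Poisson (1/√(counts+1)).  Initial values come from the
    maximum count (A) and the quadratic low-power slope (P_sat).  Warns
    when the powers do not bracket the inflection (data entirely in the
    quadratic regime leave P_sat poorly constrained).
    """
    p = np.asarray(trace.powers_mW, dtype=float)
    y = np.asarray(trace.counts, dtype=float)
    mask = p > 0
    if np.unique(p[mask]).size < 5:
        warnings.warn("fewer than 5 distinct non-zero powers", FitWarning)

    a0 = max(y.max(), 1.0)
    # low-power quadratic: F ≈ A·P²/P_sat² → slope of y vs P² gives A/P_sat²
    order = np.argsort(p)
    lo = order[: max(3, p.size // 3)]
    slope = max(np.polyfit(p[lo] ** 2, y[lo], 1)[0], 1e-12) if np.ptp(p[lo]) > 0 else 1e-12
    psat0 = math.sqrt(a0 / slope) if slope > 0 else p.max()
    psat0 = min(max(psat0, 0.1 * p[mask].min()), 10.0 * p.max())

    model = Model(_sat_model, independent_vars=["p"])
    params = model.make_params(a=dict(value=a0, min=0), psat=dict(value=psat0, min=1e-6))
    result = model.fit(y, params, p=p, weights=1.0 / np.sqrt(y + 1.0))
    if not result.success:
        raise RuntimeError(f"saturation fit failed: {result.message}")

    psat = float(result.params["psat"].value)
    psat_err = result.params["psat"].stderr
    if p.max() < psat:
        warnings.warn(
            "p_sat poorly constrained: all powers in the quadratic regime",
            FitWarning,
        )
        if psat_err is not None:
            psat_err *= 1.0 + psat / p.max()  # inflate: extrapolated parameter
    return SaturationFit(
        psat_mW=psat,
        psat_stderr_mW=None if psat_err is None else float(psat_err),
        asymptote_cps=float(result.params["a"].value) / trace.dwell_s,
        asymptote_stderr_cps=(
            None
            if result.params["a"].stderr is None
            else float(result.params["a"].stderr) / trace.dwell_s
        ),
        redchi=float(result.redchi),
        n_points=int(p.size),
    )


def normalize_to_asymptote(trace: SweepTrace, fit: SaturationFit) -> np.ndarray:
    """Counts divided by the fitted asymptote (per-point, dimensionless)."""
    if fit.asymptote_cps <= 0:
        raise ValueError("fitted asymptote must be positive")
    return np.asarray(trace.counts, float) / (fit.asymptote_cps * trace.dwell_s)


def ensemble_saturation(
    traces: list[SweepTrace], power_grid=None
) -> EnsembleSaturation:
    """Pool normalized sweeps: per-grid-point mean ± SD, then fit the mean.

    Each trace is normalized by its own fitted asymptote, interpolated onto
    the common power grid (default: union range on a 50-point grid), and
    the Eq.-style saturation law is fitted to the mean curve.
    """
    if len(traces) < 2:
        raise ValueError("ensemble needs at least 2 traces")
    fits = [fit_saturation(t) for t in traces]
    los = [t.powers_mW.min() for t in traces]
    his = [t.powers_mW.max() for t in traces]
    if max(los) >= min(his):
        raise ValueError("traces have disjoint power ranges")
    if power_grid is None:
        power_grid = np.linspace(max(los), min(his), 50)
    grid = np.asarray(power_grid, dtype=float)

    norm = np.empty((len(traces), grid.size))
    for i, (t, f) in enumerate(zip(traces, fits)):
        order = np.argsort(t.powers_mW)
        norm[i] = np.interp(
            grid, t.powers_mW[order], normalize_to_asymptote(t, f)[order]
        )
    mean = norm.mean(axis=0)
    sd = norm.std(axis=0, ddof=1)

    # fit of the mean normalized curve (asymptote ≈ 1 refitted)
    mean_trace = SweepTrace("ensemble-mean", grid, 1.0, np.maximum(mean, 0.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FitWarning)
        fit = fit_saturation(mean_trace)
    return EnsembleSaturation(grid, mean, sd, fit, len(traces))


def derive_cross_section(
    fit: SaturationFit, instrument: InstrumentParams, ensemble_sigma2_GM: float
) -> LocalFieldResult:
    """α²σ₂ and α from a saturation fit.

    Composes the P_sat → α²σ₂ inversion with the ensemble comparison
    α = √(α²σ₂/σ₂); the P_sat standard error propagates to first order
    (relative error of α²σ₂ is twice that of P_sat, of α equal to it).
    """
    a2s2 = cross_section_from_psat(fit.psat_mW, instrument)
    alpha = alpha_from_ensemble(a2s2, ensemble_sigma2_GM)
    rel = (
        None
        if fit.psat_stderr_mW is None
        else fit.psat_stderr_mW / fit.psat_mW
    )
    return LocalFieldResult(
        alpha=alpha,
        alpha2_sigma2_GM=a2s2,
        alpha_stderr=None if rel is None else alpha * rel,
        alpha2_sigma2_stderr_GM=None if rel is None else a2s2 * 2.0 * rel,
    )


def _decay_model(t, s0, tau_b, bg):
    return s0 * np.exp(-t / tau_b) + bg


def fit_decay(trace: DecayTrace, *, fit_background: bool = True):
    """Monoexponential fit of a bleaching trace.

    Fits counts/bin = (S₀·exp(−t/τ_b) + bg)·bin with Poisson weights
    1/√(counts+1); the background can be fixed to 0.  Returns
    (τ_b, S₀, bg, stderr dict).  A trace that does not decay (τ_b at the
    upper bound) raises.
    """
    t = np.asarray(trace.t_s, dtype=float)
    y = np.asarray(trace.counts, dtype=float)
    if t.size < 10:
        raise ValueError("need at least 10 bins")
    span = t.max() - t.min()

    # crude initial tau: time to fall to 1/e of the smoothed start
    k = max(t.size // 20, 3)
    head = y[:k].mean()
    tail = y[-k:].mean()
    below = np.nonzero(y <= tail + (head - tail) / math.e)[0]
    tau0 = t[below[0]] if below.size else span
    tau0 = min(max(tau0, t[1] - t[0]), 10.0 * span)
    if span < tau0:
        warnings.warn("duration shorter than the decay time", FitWarning)

    model = Model(_decay_model, independent_vars=["t"])
    params = model.make_params(
        s0=dict(value=max(head / trace.bin_s, 1.0), min=0),
        tau_b=dict(value=tau0, min=(t[1] - t[0]) / 10.0, max=100.0 * span),
        bg=dict(
            value=max(tail / trace.bin_s, 0.0) if fit_background else 0.0,
            min=0,
            vary=fit_background,
        ),
    )
    result = model.fit(
        y / trace.bin_s, params, t=t, weights=trace.bin_s / np.sqrt(y + 1.0)
    )
    if not result.success:
        raise RuntimeError(f"decay fit failed: {result.message}")
    tau = result.params["tau_b"]
    if tau.value >= 99.0 * span:
        raise RuntimeError("tau_b unbounded: trace does not decay over its duration")
    errs = {
        name: (None if par.stderr is None else float(par.stderr))
        for name, par in result.params.items()
    }
    return (
        float(tau.value),
        float(result.params["s0"].value),
        float(result.params["bg"].value),
        errs,
    )


def fit_bleach_law(powers_mW, mean_tau_b_s, sd_tau_b_s, psat_mW: float) -> BleachFit:
    """Weighted fit of τ_b = τ_b,0·(P_sat/P)² plus an unconstrained log-log
    slope check.

    P_sat comes from the saturation stage (never co-fitted: the power law
    only identifies the product τ_b,0·P_sat²).  Weights are inverse
    variances from the per-power SDs; the log-log fit is ordinary least
    squares of log τ_b on log P and should give a slope of −2.
    """
    p = np.asarray(powers_mW, dtype=float)
    tau = np.asarray(mean_tau_b_s, dtype=float)
    sd = np.asarray(sd_tau_b_s, dtype=float)
    if p.size < 3:
        raise ValueError("need at least 3 powers")
    if np.any(p <= 0) or np.any(tau <= 0):
        raise ValueError("powers and bleaching times must be positive")

    # linear in tau_b0: weighted LS has the closed form below
    x = (psat_mW / p) ** 2
    w = 1.0 / np.where(sd > 0, sd, tau * 0.1) ** 2
    tau_b0 = float(np.sum(w * x * tau) / np.sum(w * x * x))
    resid = tau - tau_b0 * x
    dof = max(p.size - 1, 1)
    tau_b0_err = float(
        math.sqrt(np.sum(w * resid**2) / dof / np.sum(w * x * x))
    )

    slope, intercept = np.polyfit(np.log(p), np.log(tau), 1)
    pred = slope * np.log(p) + intercept
    s2 = np.sum((np.log(tau) - pred) ** 2) / max(p.size - 2, 1)
    slope_err = math.sqrt(s2 / np.sum((np.log(p) - np.log(p).mean()) ** 2))

    return BleachFit(
        tau_b0_s=tau_b0,
        tau_b0_stderr_s=tau_b0_err,
        psat_mW=psat_mW,
        loglog_slope=float(slope),
        loglog_slope_stderr=float(slope_err),
        powers_mW=p,
        mean_tau_b_s=tau,
        sd_tau_b_s=sd,
    )


def photostability_ratio(
    tau_b0_1: float, psat_1: float, tau_b0_2: float, psat_2: float
) -> float:
    """Ratio of bleaching times of two families at any common excitation
    power: (τ_b,0,1·P_sat,1²)/(τ_b,0,2·P_sat,2²)."""
    if min(tau_b0_1, psat_1, tau_b0_2, psat_2) <= 0:
        raise ValueError("all inputs must be positive")
    return (tau_b0_1 * psat_1**2) / (tau_b0_2 * psat_2**2)
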