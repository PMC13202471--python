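"""Seeded synthetic microscope data with the statistical structure the
analysis pipeline assumes.

Generates the three raw-data products of a single-particle 2P experiment:

* **scan images** — sparse nanoparticles rendered as 2D Gaussian spots
  (σ = W₀/√2) on a constant background, per-pixel Poisson photon counts,
  with a ground-truth sidecar;
* **saturation sweeps** — photon counts vs excitation power for one
  particle, following the pulse-train emission model, optionally with
  bleaching accumulated during the sweep;
* **bleaching traces** — binned photon counts vs time under constant
  excitation, decaying monoexponentially with τ_b = τ_b,0·(P_sat/P)².

Particle sizes are drawn from truncated-normal mixtures emulating the TEM
size histograms of the two studied dFON families: dFONs(1) is bimodal
(narrow mode near 15 nm plus a broad mode near 50 nm whose particles carry
essentially all the signal), dFONs(2) unimodal near 20 nm.  Molecule
numbers scale with particle volume at unit relative density.

All generators take an integer seed and are reproducible bit-for-bit.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .photophysics import (
    _AVOGADRO,
    InstrumentParams,
    SpeciesParams,
    bleaching_time,
    pulse_train_emission,
)

__all__ = [
    "SizePopulationSpec",
    "ScanGroundTruth",
    "SweepTrace",
    "DecayTrace",
    "DFONS1_SIZES",
    "DFONS2_SIZES",
    "sample_diameters",
    "molecules_per_particle",
    "hwp_angle_to_power",
    "generate_scan",
    "generate_saturation_sweep",
    "generate_bleach_trace",
    "write_scan",
    "write_trace",
    "read_trace",
]


@dataclass(frozen=True)
class SizePopulationSpec:
    """Truncated-normal mixture of dry-diameter modes: (mean nm, sd nm, weight)."""

    modes: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError("size spec needs at least one mode")
        w = sum(m[2] for m in self.modes)
        if any(m[0] <= 0 or m[1] < 0 or m[2] < 0 for m in self.modes):
            raise ValueError("means must be > 0, spreads and weights >= 0")
        if not math.isclose(w, 1.0, rel_tol=1e-9):
            raise ValueError("mode weights must sum to 1")


#: dFONs(1) TEM-like bimodal size distribution; the broad 50 nm mode carries
#: >10× the mean volume of the 15 nm mode, hence essentially all the signal.
DFONS1_SIZES = SizePopulationSpec(((15.0, 3.0, 0.5), (50.0, 15.0, 0.5)))
#: dFONs(2) unimodal distribution near 20 nm.
DFONS2_SIZES = SizePopulationSpec(((20.0, 3.0, 1.0),))


@dataclass
class ScanGroundTruth:
    """Per-particle truth emitted alongside every generated scan."""

    x_nm: list[float] = field(default_factory=list)
    y_nm: list[float] = field(default_factory=list)
    diameter_nm: list[float] = field(default_factory=list)
    n_molecules: list[int] = field(default_factory=list)
    peak_rate_cps: list[float] = field(default_factory=list)
    aggregate: list[bool] = field(default_factory=list)
    seed: int | None = None
    p_exc_mW: float | None = None
    background_cps: float | None = None


@dataclass
class SweepTrace:
    """Detected counts vs excitation power for one particle."""

    particle_id: str
    powers_mW: np.ndarray
    dwell_s: float
    counts: np.ndarray
    hwp_deg: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.powers_mW = np.asarray(self.powers_mW, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(self.powers_mW < 0):
            raise ValueError("powers must be non-negative")
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class DecayTrace:
    """Binned detected counts vs time under constant excitation."""

    particle_id: str
    p_exc_mW: float
    bin_s: float
    t_s: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("counts must be non-negative")


# --------------------------------------------------------------------------


def sample_diameters(spec: SizePopulationSpec, n: int, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. dry diameters (nm) from the mixture.

    Each mode is a normal truncated at zero (re-drawn); zero spread gives a
    point mass.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    means, sds, weights = (np.array(c, dtype=float) for c in zip(*spec.modes))
    which = rng.choice(len(spec.modes), size=n, p=weights / weights.sum())
    d = means[which] + sds[which] * rng.standard_normal(n)
    bad = d <= 0
    while np.any(bad):  # truncate at zero by redrawing
        d[bad] = means[which[bad]] + sds[which[bad]] * rng.standard_normal(bad.sum())
        bad = d <= 0
    return d


def molecules_per_particle(
    diameter_nm, molar_mass_g_mol: float, relative_density: float = 1.0
):
    """Dye molecules per particle: N = ρ·(π/6)·d³·N_A/M, nearest integer.

    ``relative_density`` is relative to water (1.0 g/cm³), per the TEM-based
    estimate convention.
    """
    if molar_mass_g_mol <= 0 or relative_density <= 0:
        raise ValueError("molar mass and density must be positive")
    d_cm = np.asarray(diameter_nm, dtype=float) * 1e-7
    if np.any(d_cm < 0):
        raise ValueError("diameter must be non-negative")
    mass_g = relative_density * 1.0 * (math.pi / 6.0) * d_cm**3
    n = np.rint(mass_g * _AVOGADRO / molar_mass_g_mol).astype(int)
    return int(n) if n.ndim == 0 else n


def default_molar_mass(species: SpeciesParams) -> float:
    """Molar mass consistent with the species' tabulated (diameter, N) pair."""
    if species.molar_mass_g_mol is not None:
        return species.molar_mass_g_mol
    d_cm = species.diameter_nm * 1e-7
    mass_g = (math.pi / 6.0) * d_cm**3
    return mass_g * _AVOGADRO / species.n_molecules


def hwp_angle_to_power(theta_deg, p_max_mW: float, theta0_deg: float = 0.0):
    """Malus-law power modulation of a half-wave plate before a polarizer:
    P = P_max·sin²(2(θ − θ₀))."""
    if p_max_mW <= 0:
        raise ValueError("p_max must be positive")
    th = np.deg2rad(np.asarray(theta_deg, dtype=float) - theta0_deg)
    out = p_max_mW * np.sin(2.0 * th) ** 2
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# scan images


def _render_spots(shape, centers_px, sigmas_px, amplitudes):
    """Sum of 2D Gaussians evaluated on the pixel grid (rates, not counts)."""
    yy, xx = np.indices(shape)
    img = np.zeros(shape, dtype=float)
    for (cy, cx), s, a in zip(centers_px, sigmas_px, amplitudes):
        img += a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * s**2))
    return img


def generate_scan(
    field_um: float,
    instrument: InstrumentParams,
    species: SpeciesParams,
    sizes: SizePopulationSpec,
    *,
    n_particles: int = 20,
    p_exc_mW: float = 1.7,
    background_cps: float = 100.0,
    aggregate_fraction: float = 0.10,
    alpha2_sigma2_GM: float | None = None,
    seed=0,
) -> tuple[np.ndarray, ScanGroundTruth]:
    """Simulate one raster scan of nanoparticles dried on a coverslip.

    Particles are placed uniformly over a ``field_um`` × ``field_um`` field
    scanned at the instrument's pixel size and dwell time.  Each particle of
    diameter d carries N(d) dye molecules and contributes a 2D Gaussian spot
    of width σ = W₀/√2 whose peak rate comes from the pulse-train emission
    model; a fraction are aggregates of 2–4 co-located particles.  Pixel
    counts are Poisson(dwell × (signal + background)).

    Returns the count image (uint32) and the ground truth.
    """
    if field_um <= 0 or background_cps < 0 or n_particles < 0:
        raise ValueError("field must be positive, background and count non-negative")
    rng = np.random.default_rng(seed)
    npx = int(round(field_um * 1000.0 / instrument.pixel_nm))
    sigma_px = instrument.psf_sigma_nm / instrument.pixel_nm
    if alpha2_sigma2_GM is None:
        if species.psat_mW is None:
            raise ValueError("species needs psat_mW or pass alpha2_sigma2_GM")
        from .photophysics import cross_section_from_psat

        alpha2_sigma2_GM = cross_section_from_psat(species.psat_mW, instrument)
    if n_particles * (6 * sigma_px) ** 2 > npx**2:
        warnings.warn("particle density so high that spots always overlap", UserWarning)

    molar = default_molar_mass(species)
    truth = ScanGroundTruth(
        seed=None if not np.isscalar(seed) else int(seed),
        p_exc_mW=p_exc_mW,
        background_cps=background_cps,
    )
    centers, sigmas, amps = [], [], []
    for _ in range(n_particles):
        x = rng.uniform(0, npx * instrument.pixel_nm)
        y = rng.uniform(0, npx * instrument.pixel_nm)
        is_agg = rng.uniform() < aggregate_fraction
        k = int(rng.integers(2, 5)) if is_agg else 1
        d_sub = sample_diameters(sizes, k, rng)
        n_sub = np.atleast_1d(molecules_per_particle(d_sub, molar))
        # aggregate members sit within one PSF of the nominal position,
        # which broadens/elongates the merged spot (the flagging signature)
        jitter = (
            rng.normal(0.0, 0.5 * instrument.psf_sigma_nm, size=(k, 2))
            if is_agg
            else np.zeros((k, 2))
        )
        rate_total = 0.0
        for m, (jx, jy) in zip(n_sub, jitter):
            rate = pulse_train_emission(
                p_exc_mW, instrument, species, alpha2_sigma2_GM, n_molecules=int(m)
            )
            centers.append(((y + jy) / instrument.pixel_nm, (x + jx) / instrument.pixel_nm))
            sigmas.append(sigma_px)
            amps.append(rate)
            rate_total += rate
        truth.x_nm.append(x)
        truth.y_nm.append(y)
        truth.diameter_nm.append(float((d_sub**3).sum() ** (1 / 3)))
        truth.n_molecules.append(int(n_sub.sum()))
        truth.peak_rate_cps.append(rate_total)
        truth.aggregate.append(bool(is_agg))

    rate_img = _render_spots((npx, npx), centers, sigmas, amps) + background_cps
    counts = rng.poisson(rate_img * instrument.dwell_s)
    return counts.astype(np.uint32), truth


# --------------------------------------------------------------------------
# traces


def generate_saturation_sweep(
    species: SpeciesParams,
    instrument: InstrumentParams,
    powers_mW,
    dwell_s: float = 1.0,
    *,
    alpha2_sigma2_GM: float | None = None,
    asymptotic_rate_cps: float | None = None,
    include_bleaching: bool = False,
    particle_id: str = "p0",
    seed=0,
) -> SweepTrace:
    """Photon counts vs excitation power for one particle.

    Expected counts are dwell × R(P) with R the pulse-train emission rate;
    ``asymptotic_rate_cps`` rescales R so its high-power plateau matches a
    target detected rate.  With ``include_bleaching`` the signal is
    attenuated by exp(−Σ dwell/τ_b(Pᵢ)) accumulated over the acquisition
    order.  Counts are Poisson.
    """
    rng = np.random.default_rng(seed)
    powers = np.asarray(powers_mW, dtype=float)
    if alpha2_sigma2_GM is None:
        if species.psat_mW is None:
            raise ValueError("species needs psat_mW or pass alpha2_sigma2_GM")
        from .photophysics import cross_section_from_psat

        alpha2_sigma2_GM = cross_section_from_psat(species.psat_mW, instrument)
    rate = np.asarray(
        pulse_train_emission(powers, instrument, species, alpha2_sigma2_GM)
    )
    if asymptotic_rate_cps is not None:
        plateau = (
            instrument.collection_efficiency
            * species.n_molecules
            * species.phi
            / instrument.rep_period_s
        )
        rate = rate * (asymptotic_rate_cps / plateau)
    if include_bleaching:
        from .photophysics import psat_from_cross_section

        psat = psat_from_cross_section(alpha2_sigma2_GM, instrument)
        tb0 = species.tau_b0_s if species.tau_b0_s is not None else 1.0
        dose = np.cumsum(dwell_s / bleaching_time(powers, psat, tb0))
        # attenuation accrued before each point (first point unbleached)
        rate = rate * np.exp(-(dose - dose[0]))
    counts = rng.poisson(rate * dwell_s)
    return SweepTrace(particle_id, powers, dwell_s, counts)


def generate_bleach_trace(
    species: SpeciesParams,
    instrument: InstrumentParams,
    p_exc_mW: float,
    duration_s: float,
    bin_s: float = 10e-3,
    *,
    initial_rate_cps: float = 1e5,
    background_cps: float = 0.0,
    particle_id: str = "p0",
    seed=0,
) -> DecayTrace:
    """Binned photon counts under constant excitation, decaying with
    τ_b = τ_b,0·(P_sat/P_exc)².

    Expected rate S(t) = S₀·exp(−t/τ_b) + background, integrated over each
    bin as rate × bin width; counts are Poisson.  Warns if the duration does
    not cover 3 decay times.
    """
    if species.psat_mW is None or species.tau_b0_s is None:
        raise ValueError("species needs psat_mW and tau_b0_s")
    rng = np.random.default_rng(seed)
    tau_b = bleaching_time(p_exc_mW, species.psat_mW, species.tau_b0_s)
    if duration_s < 3.0 * tau_b:
        warnings.warn(
            f"duration {duration_s:.3g}s covers less than 3 bleaching times "
            f"({tau_b:.3g}s); tau_b will be poorly constrained",
            UserWarning,
        )
    t = np.arange(0.0, duration_s, bin_s)
    rate = initial_rate_cps * np.exp(-t / tau_b) + background_cps
    counts = rng.poisson(rate * bin_s)
    return DecayTrace(particle_id, p_exc_mW, bin_s, t + bin_s / 2.0, counts)


# --------------------------------------------------------------------------
# file I/O: TIFF + JSON sidecar for scans, CSV for traces


def write_scan(path, image: np.ndarray, truth: ScanGroundTruth, config: dict | None = None):
    """Write a count image as single-channel TIFF plus a JSON ground-truth sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.uint32))
    sidecar = {"ground_truth": asdict(truth), "config": config or {}}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def write_trace(path, trace: SweepTrace | DecayTrace):
    """Write a trace as CSV: (power_mW, counts) or (time_s, counts)."""
    if isinstance(trace, SweepTrace):
        df = pd.DataFrame({"power_mW": trace.powers_mW, "counts": trace.counts})
        meta = {"particle_id": trace.particle_id, "dwell_s": trace.dwell_s}
    else:
        df = pd.DataFrame({"time_s": trace.t_s, "counts": trace.counts})
        meta = {
            "particle_id": trace.particle_id,
            "p_exc_mW": trace.p_exc_mW,
            "bin_s": trace.bin_s,
        }
    path = Path(path)
    df.to_csv(path, index=False)
    path.with_suffix(".meta.json").write_text(json.dumps(meta))


def read_trace(path) -> SweepTrace | DecayTrace:
    """Read a trace CSV written by :func:`write_trace`."""
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    if "power_mW" in df.columns:
        return SweepTrace(
            meta["particle_id"], df["power_mW"].to_numpy(), meta["dwell_s"],
            df["counts"].to_numpy(),
        )
    return DecayTrace(
        meta["particle_id"], meta["p_exc_mW"], meta["bin_s"],
        df["time_s"].to_numpy(), df["counts"].to_numpy(),
    )
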