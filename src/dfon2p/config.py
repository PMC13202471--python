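"""Run configuration: a single validated YAML/JSON schema holding the
instrument, the two particle families, generator settings and analysis
options.  Defaults are the published study values; unknown keys are
rejected so typos fail loudly before any stage runs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .photophysics import (
    InstrumentParams,
    SpeciesParams,
    calibrate_geometry_factor,
)
from .synthetic import DFONS1_SIZES, DFONS2_SIZES, SizePopulationSpec


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InstrumentConfig(_Strict):
    wavelength_nm: float = 1030.0
    repetition_rate_MHz: float = 80.0
    pulse_tau_fs: float = 135.0
    tau_is_fwhm: bool = False
    waist_nm: float = 360.0
    collection_efficiency: float = 0.80
    pixel_nm: float = 100.0
    dwell_ms: float = 10.0
    # κ calibration anchor: P_sat (mW) ↦ α²σ₂ (GM); null disables (κ = 1)
    calibration_psat_mW: float | None = 17.3
    calibration_alpha2_sigma2_GM: float | None = 710.0

    def build(self) -> InstrumentParams:
        inst = InstrumentParams(
            wavelength_nm=self.wavelength_nm,
            rep_period_s=1.0 / (self.repetition_rate_MHz * 1e6),
            pulse_tau_s=self.pulse_tau_fs * 1e-15,
            waist_nm=self.waist_nm,
            collection_efficiency=self.collection_efficiency,
            pixel_nm=self.pixel_nm,
            dwell_s=self.dwell_ms * 1e-3,
            tau_is_fwhm=self.tau_is_fwhm,
        )
        if self.calibration_psat_mW is not None:
            inst = calibrate_geometry_factor(
                self.calibration_psat_mW, self.calibration_alpha2_sigma2_GM, inst
            )
        return inst


class SizeModeConfig(_Strict):
    mean_nm: float
    sd_nm: float
    weight: float


class SpeciesConfig(_Strict):
    name: str
    sigma2_GM: float
    phi: float
    diameter_nm: float
    n_molecules: int
    tau_b0_s: float | None = None
    psat_mW: float | None = None
    gamma_rad_per_s: float = 5e8
    molar_mass_g_mol: float | None = None
    size_modes: list[SizeModeConfig] = Field(default_factory=list)

    def build(self) -> SpeciesParams:
        return SpeciesParams(
            name=self.name,
            sigma2_GM=self.sigma2_GM,
            phi=self.phi,
            diameter_nm=self.diameter_nm,
            n_molecules=self.n_molecules,
            tau_b0_s=self.tau_b0_s,
            psat_mW=self.psat_mW,
            gamma_rad_per_s=self.gamma_rad_per_s,
            molar_mass_g_mol=self.molar_mass_g_mol,
        )

    def build_sizes(self, fallback: SizePopulationSpec) -> SizePopulationSpec:
        if not self.size_modes:
            return fallback
        return SizePopulationSpec(
            tuple((m.mean_nm, m.sd_nm, m.weight) for m in self.size_modes)
        )


class GeneratorConfig(_Strict):
    field_um: float = 10.0
    n_particles_per_scan: int = 20
    scan_power_mW: dict[str, float] = Field(
        default_factory=lambda: {"dFONs(1)": 1.7, "dFONs(2)": 1.6}
    )
    background_cps: float = 100.0
    aggregate_fraction: float = 0.10
    sweep_powers_mW: list[float] = Field(
        default_factory=lambda: list(range(1, 41, 3))
    )
    sweep_dwell_s: float = 1.0
    n_sweeps: int = 20
    bleach_bin_ms: float = 10.0
    bleach_initial_rate_cps: float = 1e5
    n_bleach_traces_per_power: int = 10


class AnalysisConfig(_Strict):
    detect_threshold_sigma: float = 5.0
    min_separation_nm: float = 500.0
    fit_window_px: int = 9
    aggregate_tolerance: float = 0.10
    ttest_equal_var: bool = False
    exclude_aggregates_from_stats: bool = False


def _default_species() -> list[SpeciesConfig]:
    return [
        SpeciesConfig(
            name="dFONs(1)", sigma2_GM=60.0, phi=0.33, diameter_nm=29.0,
            n_molecules=7500, tau_b0_s=1.06, psat_mW=17.3,
            size_modes=[
                SizeModeConfig(mean_nm=15.0, sd_nm=3.0, weight=0.5),
                SizeModeConfig(mean_nm=50.0, sd_nm=15.0, weight=0.5),
            ],
        ),
        SpeciesConfig(
            name="dFONs(2)", sigma2_GM=930.0, phi=0.06, diameter_nm=20.0,
            n_molecules=2100, tau_b0_s=3.84, psat_mW=5.29,
            size_modes=[SizeModeConfig(mean_nm=20.0, sd_nm=3.0, weight=1.0)],
        ),
    ]


class RunConfig(_Strict):
    instrument: InstrumentConfig = Field(default_factory=InstrumentConfig)
    species: list[SpeciesConfig] = Field(default_factory=_default_species)
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    seed: int = 0
    output_dir: str = "dfon2p_output"

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def sizes_for(self, name: str) -> SizePopulationSpec:
        fallback = DFONS1_SIZES if "1" in name else DFONS2_SIZES
        for sp in self.species:
            if sp.name == name:
                return sp.build_sizes(fallback)
        return fallback


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration; ``None`` gives
    the study defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    return RunConfig.model_validate(raw or {})
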