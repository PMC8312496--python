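"""Synthetic plate, CFU and metadata generator with known ground truth.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage can be exercised against known parameters:

* Thermal performance curves (TPCs) mu(T) come in two archetypes observed
  in *Bacillus* lineages: ``sharp_drop`` (a gentle sub-optimal rise and a
  linear collapse within a few °C above the optimum, the *B. cereus*-like
  shape) and ``plateau`` (a broad trapezoid holding the maximum over an
  interval, the *B. subtilis*-like shape). Both are piecewise linear, so
  their 75%-of-maximum crossings have closed forms
  (:func:`analytic_niche`) and make exact oracles possible.
* OD curves are logistic trajectories with lag at rate mu(T), observed
  through multiplicative lognormal noise at 30-min sampling over 20 h with
  three replicates per condition.
* CFU viability declines exponentially with incubation temperature at a
  per-strain rate k (ln CFU per °C); spore counts follow a binomial plating
  subsample at a per-strain sporulation fraction.

The default strain panel mirrors a two-lineage (Bc/Bs), two-environment
(temperate T / hot-spring H) design of 13 strains: the Bc presets grow
faster but collapse sharply above their optimum, the Bs presets are slower
with a broad plateau; H presets are shifted 3 °C up in optimum and upper
limit relative to their T counterparts, and the Bc lineage is markedly more
heat-sensitive in viability (lineage mean ln-survival drop of about -30
across the 37-50 °C assay, versus about -19 for Bs). Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .growth_fitting import GrowthCurve
from .plate_io import CfuDataset, PlateDataset, validate_cfu, validate_plate

ARCHETYPES = ("sharp_drop", "plateau")

#: assay grid of the plate experiment (°C)
DEFAULT_TEMPERATURE_GRID = (17.0, 27.0, 37.0, 41.0, 43.0, 46.0, 49.0, 55.0)
#: incubation temperatures of the viability assay (°C)
DEFAULT_ASSAY_TEMPERATURES = (37.0, 44.0, 50.0)


@dataclass(frozen=True)
class TPCModel:
    """Piecewise-linear thermal performance curve.

    ``t_opt_lo == t_opt_hi`` for the ``sharp_drop`` archetype (a single
    optimum); the ``plateau`` archetype holds mu_max over
    [t_opt_lo, t_opt_hi]. mu is 0 outside [t_min, t_max].
    """

    archetype: str
    t_min: float
    t_opt_lo: float
    t_opt_hi: float
    t_max: float
    mu_max: float

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValidationError(f"archetype must be one of {ARCHETYPES}")
        if not (self.t_min < self.t_opt_lo <= self.t_opt_hi < self.t_max):
            raise ValidationError("require t_min < t_opt_lo <= t_opt_hi < t_max")
        if self.archetype == "sharp_drop" and self.t_opt_lo != self.t_opt_hi:
            raise ValidationError("sharp_drop has a single optimum (t_opt_lo == t_opt_hi)")
        if self.mu_max <= 0:
            raise ValidationError("mu_max must be > 0")


def tpc_rate(model: TPCModel, temperature_c) -> np.ndarray | float:
    """Deterministic growth rate mu(T), continuous in T, 0 outside the range."""
    xp = [model.t_min, model.t_opt_lo]
    fp = [0.0, model.mu_max]
    if model.t_opt_hi > model.t_opt_lo:
        xp.append(model.t_opt_hi)
        fp.append(model.mu_max)
    xp.append(model.t_max)
    fp.append(0.0)
    out = np.interp(temperature_c, xp, fp)
    return float(out) if np.isscalar(temperature_c) else out


def analytic_niche(model: TPCModel, f: float = 0.75) -> tuple[float, float]:
    """Closed-form f-of-maximum crossings of the piecewise-linear TPC."""
    t_lo = model.t_min + f * (model.t_opt_lo - model.t_min)
    t_hi = model.t_max - f * (model.t_max - model.t_opt_hi)
    return t_lo, t_hi


@dataclass(frozen=True)
class StrainSpec:
    """Ground-truth parameters of one simulated strain."""

    strain_id: str
    lineage: str  # Bc | Bs
    environment: str  # T | H | LAB
    tpc: TPCModel
    decay_k_per_c: float  # viability semilog slope, ln CFU per °C
    sporulation_fraction: float


def _panel(
    ids: Sequence[str], lineage: str, environment: str, base: TPCModel,
    k: float, spor: float,
) -> list[StrainSpec]:
    """Three strains around a preset with small fixed offsets, so replicate
    strains are distinct but deterministic."""
    temp_jitter = (-0.4, 0.0, 0.4)
    mu_jitter = (0.97, 1.0, 1.03)
    out = []
    for sid, dt, fm in zip(ids, temp_jitter, mu_jitter):
        tpc = replace(
            base,
            t_min=base.t_min + dt,
            t_opt_lo=base.t_opt_lo + dt,
            t_opt_hi=base.t_opt_hi + dt,
            t_max=base.t_max + dt,
            mu_max=base.mu_max * fm,
        )
        out.append(StrainSpec(sid, lineage, environment, tpc, k, spor))
    return out


def default_strain_set() -> tuple[StrainSpec, ...]:
    """The 13-strain default panel: 3 strains per lineage x environment plus
    one laboratory strain. Bc presets: fast, sharp post-optimum collapse;
    Bs presets: slower, broad plateau, higher upper limit; H presets sit
    3 °C above their T counterparts in optimum and upper limit."""
    bc_t = TPCModel("sharp_drop", t_min=8.0, t_opt_lo=37.0, t_opt_hi=37.0, t_max=41.0, mu_max=1.40)
    bc_h = TPCModel("sharp_drop", t_min=10.0, t_opt_lo=40.0, t_opt_hi=40.0, t_max=44.0, mu_max=1.45)
    bs_t = TPCModel("plateau", t_min=6.0, t_opt_lo=32.0, t_opt_hi=40.0, t_max=48.0, mu_max=0.90)
    bs_h = TPCModel("plateau", t_min=9.0, t_opt_lo=35.0, t_opt_hi=43.0, t_max=51.0, mu_max=0.88)
    lab = TPCModel("plateau", t_min=6.0, t_opt_lo=33.0, t_opt_hi=41.0, t_max=49.0, mu_max=0.85)
    strains: list[StrainSpec] = []
    strains += _panel(("Bc-T-370a", "Bc-T-102", "Bc-T-111b"), "Bc", "T", bc_t, -2.42, 0.10)
    strains += _panel(("Bc-H-28", "Bc-H-11", "Bc-H-51"), "Bc", "H", bc_h, -2.19, 0.25)
    strains += _panel(("Bs-T-21", "Bs-T-90", "Bs-T-427"), "Bs", "T", bs_t, -1.54, 0.30)
    strains += _panel(("Bs-H-2", "Bs-H-30", "Bs-H-45"), "Bs", "H", bs_h, -1.38, 0.35)
    strains.append(StrainSpec("PY79", "Bs", "LAB", lab, -1.46, 0.30))
    return tuple(strains)


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic experiment.

    Defaults mirror the plate protocol the analysis targets: 30-min
    sampling over 20 h, three replicates per strain x temperature, the
    eight-temperature grid, 2% multiplicative log-OD noise, and a viability
    assay at 37/44/50 °C with lognormal count noise and a binomial plating
    subsample for spores. The seed fixes the entire output stream.
    """

    strains: tuple[StrainSpec, ...] = field(default_factory=default_strain_set)
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURE_GRID
    replicates: int = 3
    sampling_interval_h: float = 0.5
    duration_h: float = 20.0
    initial_od: float = 0.005
    capacity_od: float = 1.5
    lag_h: float = 1.0
    od_noise_sd: float = 0.02  # sd of log-OD, multiplicative
    blank_od: float = 0.04  # medium background absorbance
    cfu_baseline: float = 1e8  # CFU/ml at the reference temperature
    cfu_reference_temperature_c: float = 37.0
    cfu_noise_sd: float = 0.15  # sd of log-count, multiplicative
    plating_depth: int = 1000  # colonies countable per spore plating
    assay_temperatures: tuple[float, ...] = DEFAULT_ASSAY_TEMPERATURES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1 or not self.strains:
            raise ValidationError("need >= 1 replicate and >= 1 strain")
        if self.od_noise_sd < 0 or self.cfu_noise_sd < 0:
            raise ValidationError("noise SDs must be >= 0")
        if self.sampling_interval_h <= 0 or self.duration_h <= 0:
            raise ValidationError("sampling interval and duration must be > 0")
        if self.initial_od <= 0 or self.capacity_od <= self.initial_od:
            raise ValidationError("require 0 < initial_od < capacity_od")


def _logistic_biomass(t: np.ndarray, mu: float, x0: float, k_cap: float, lag: float) -> np.ndarray:
    """Logistic biomass with a lag phase; reduces to x0 when mu = 0."""
    if mu == 0:
        return np.full_like(t, x0)
    e = np.exp(mu * np.maximum(t - lag, 0.0))
    return k_cap * x0 * e / (k_cap + x0 * (e - 1.0))


def simulate_od_curve(
    model: TPCModel,
    temperature_c: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    strain_id: str = "sim",
    replicate: int = 1,
) -> GrowthCurve:
    """One OD time series at ``temperature_c``: blank + logistic biomass at
    rate tpc_rate(model, T), under multiplicative lognormal noise.

    Above ``t_max`` (or below ``t_min``) the biomass stays at the inoculum
    level, so the curve is a flat baseline plus noise.
    """
    n = int(round(config.duration_h / config.sampling_interval_h)) + 1
    t = np.arange(n) * config.sampling_interval_h
    mu = tpc_rate(model, temperature_c)
    od = config.blank_od + _logistic_biomass(
        t, mu, config.initial_od, config.capacity_od, config.lag_h
    )
    if config.od_noise_sd > 0:
        od = od * np.exp(rng.normal(0.0, config.od_noise_sd, size=n))
    return GrowthCurve(
        strain_id=strain_id,
        replicate=replicate,
        temperature_c=float(temperature_c),
        times=t,
        od=od,
        blank=config.blank_od,
    )


def simulate_plate_experiment(config: SimulationConfig) -> PlateDataset:
    """Full factorial strains x temperature grid x replicates plate dataset,
    validated, with the strain metadata (and the plate blank) attached."""
    rng = np.random.default_rng(config.seed)
    frames = []
    for spec in config.strains:
        for temp in config.temperatures:
            for rep in range(1, config.replicates + 1):
                curve = simulate_od_curve(
                    spec.tpc, temp, config, rng, strain_id=spec.strain_id, replicate=rep
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "strain_id": spec.strain_id,
                            "replicate": rep,
                            "temperature_c": float(temp),
                            "time_h": curve.times,
                            "od": curve.od,
                        }
                    )
                )
    data = pd.concat(frames, ignore_index=True)
    meta = pd.DataFrame(
        {
            "strain_id": [s.strain_id for s in config.strains],
            "lineage": [s.lineage for s in config.strains],
            "environment": [s.environment for s in config.strains],
            "blank_od": config.blank_od,
        }
    )
    return validate_plate(data, meta)


def simulate_viability_assay(
    config: SimulationConfig, temperatures: Sequence[float] | None = None
) -> CfuDataset:
    """CFU viability assay: totals decline exponentially with temperature at
    each strain's k; spores are a binomial plating subsample at the strain's
    sporulation fraction. An expected count below one cell is recorded as 0
    (complete kill). Noise-free when ``cfu_noise_sd`` is 0."""
    temps = tuple(temperatures) if temperatures is not None else config.assay_temperatures
    rng = np.random.default_rng((config.seed, 0xCF))
    rows = []
    for spec in config.strains:
        for temp in temps:
            expected = config.cfu_baseline * np.exp(
                spec.decay_k_per_c * (temp - config.cfu_reference_temperature_c)
            )
            for rep in range(1, config.replicates + 1):
                if expected < 1.0:
                    total, spore = 0.0, 0.0
                elif config.cfu_noise_sd > 0:
                    total = expected * np.exp(rng.normal(0.0, config.cfu_noise_sd))
                    depth = min(int(round(total)), config.plating_depth)
                    frac_hat = (
                        rng.binomial(depth, spec.sporulation_fraction) / depth
                        if depth > 0 and spec.sporulation_fraction > 0
                        else (spec.sporulation_fraction if depth > 0 else 0.0)
                    )
                    spore = total * frac_hat
                else:
                    total = expected
                    spore = spec.sporulation_fraction * total
                rows.append(
                    {
                        "strain_id": spec.strain_id,
                        "temperature_c": float(temp),
                        "replicate": rep,
                        "total_cfu_ml": total,
                        "spore_cfu_ml": spore,
                    }
                )
    return validate_cfu(pd.DataFrame(rows))


def strain_grouping(config: SimulationConfig, by: str = "lineage") -> dict[str, str]:
    """strain_id -> lineage or environment mapping for the config's panel."""
    if by not in ("lineage", "environment"):
        raise ValidationError("by must be 'lineage' or 'environment'")
    return {s.strain_id: getattr(s, by) for s in config.strains}
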