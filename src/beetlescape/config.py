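"""Configuration for the forest-beetle-climate simulator.

All tunable parameters live in nested dataclasses, one section per process
(landscape, climate, vegetation, wind, beetle, indicators, experiment,
feedback).  A structured YAML file with the same section/key names overrides
any default; unknown keys are rejected with an error naming the key.  Two
presets are provided: ``desk`` (50x50 cells, 300 years, 5 replicates) for
interactive work and testing, and ``paper`` (120x120 cells, 600 years,
20 replicates) approximating the full study design.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

SPECIES = ("spruce", "beech", "fir", "other")

#: Climate scenario names: baseline, moderate, hot, hot-and-wet.
SCENARIOS = ("BC", "MC", "HC", "HWC")


def _species_dict(spruce: float, beech: float, fir: float, other: float) -> dict:
    return {"spruce": spruce, "beech": beech, "fir": fir, "other": other}


@dataclass
class LandscapeConfig:
    """Initial-landscape generator settings (100-m cell grid)."""

    rows: int = 50
    cols: int = 50
    cohort_slots: int = 8            # max cohorts tracked per cell
    cell_size_m: float = 100.0
    target_spruce_share: float = 60.5   # % of total basal area
    ba_mean: float = 38.0            # m2/ha mean initial basal area per cell
    ba_sd: float = 8.0               # m2/ha between-cell spread
    spruce_field_sigma: float = 3.0  # cells; smoothing of the spruce pattern
    spruce_field_spread: float = 0.35  # amplitude of spatial spruce variation
    fertility_range: float = 0.2     # fertility gradient half-width around 1.0
    mature_dbh_mean: float = 35.0    # cm
    mature_dbh_sd: float = 8.0       # cm
    pole_dbh_mean: float = 14.0      # cm
    pole_dbh_sd: float = 4.0         # cm
    pole_fraction: float = 0.25      # share of each species' BA in the pole cohort


@dataclass
class ClimateConfig:
    """Synthetic climate: a stationary reference block plus scenario ramps.

    The reference block emulates a montane Central-European climate
    (landscape-mean annual temperature ~6 C, precipitation ~1,400 mm/yr).
    Scenario deltas are linear ramps over ``ramp_years`` then stationary;
    they are placeholders standing in for downscaled RCP projections and
    fully overridable here.
    """

    reference_years: int = 30
    reference_seed: int = 20110101   # fixes the shared reference block
    t_mean_c: float = 6.0            # C, landscape-mean annual temperature
    t_sd_c: float = 0.7              # C, interannual s.d.
    precip_mean_mm: float = 1400.0   # mm/yr
    precip_sd_mm: float = 150.0      # mm/yr
    winter_offset_c: float = 14.0    # t_min_winter = t_mean - offset + anomaly
    winter_anomaly_sd_c: float = 2.5
    seasonal_amplitude_c: float = 9.0  # annual temperature cycle half-range
    dd_threshold_c: float = 8.3      # degree-day development threshold
    demand_base_mm: float = 800.0    # water demand at 0 C
    demand_per_deg_mm: float = 80.0  # demand increase per C
    ramp_years: int = 90
    # scenario endpoint deltas: (temperature C, precipitation factor)
    delta_t_c: dict = field(
        default_factory=lambda: {"BC": 0.0, "MC": 2.0, "HC": 4.5, "HWC": 4.5}
    )
    precip_factor: dict = field(
        default_factory=lambda: {"BC": 1.0, "MC": 1.0, "HC": 1.0, "HWC": 1.1}
    )


@dataclass
class VegetationConfig:
    """Cohort growth, mortality, self-thinning and regeneration."""

    growth_rate_cm: dict = field(       # max annual dbh increment, cm/yr
        default_factory=lambda: _species_dict(0.45, 0.40, 0.42, 0.50)
    )
    temp_opt_c: dict = field(           # species temperature optimum, C
        default_factory=lambda: _species_dict(5.5, 8.5, 7.5, 8.0)
    )
    temp_width_c: float = 4.0           # Gaussian response width, C
    drought_sens: dict = field(         # exponent on the drought index
        default_factory=lambda: _species_dict(1.5, 0.8, 1.0, 0.8)
    )
    hmax_m: dict = field(               # asymptotic height, m
        default_factory=lambda: _species_dict(38.0, 32.0, 36.0, 28.0)
    )
    h_shape: float = 0.045              # height-dbh allometry shape, 1/cm
    size_decay_cm: float = 60.0         # dbh increment declines as exp(-dbh/this)
    mortality_rate: dict = field(       # background annual mortality fraction
        default_factory=lambda: _species_dict(0.012, 0.010, 0.010, 0.014)
    )
    senescence_age_yr: float = 200.0    # age scale for extra mortality
    ba_cap_m2: float = 60.0             # self-thinning basal-area cap, m2/ha
    regen_ba_threshold_m2: float = 30.0  # canopy-closure cutoff for regeneration
    regen_prob: float = 0.35            # annual seedling-cohort probability
    seedling_stems: float = 2000.0      # stems/ha of a new cohort
    seedling_dbh_cm: float = 2.0
    immigration: float = 0.02           # background seed supply, BA-equivalent
    form_factor: float = 0.5            # stem volume = ff * BA * height
    min_stems: float = 1.0              # cohorts below this are removed


@dataclass
class WindConfig:
    """Storm regime: stationary in time (no wind-climate trend)."""

    event_prob: float = 0.5       # annual probability of a storm event
    size_mean_cells: float = 3.0  # mean number of cells hit per event
    severity_alpha: float = 4.0   # Beta(a,b) fraction of spruce stems downed
    severity_beta: float = 4.0


@dataclass
class BeetleConfig:
    """Bark beetle phenology, survival, dispersal and colonization.

    Functional forms are PHENIPS-style: floor-of-degree-days voltinism,
    logistic winter survival, exponential dispersal kernel, defence linear
    in host basal area and drought relief, kill linear in pressure excess.
    """

    dd_per_generation: float = 557.0   # degree-days per filial generation
    max_generations: int = 3
    winter_t50_c: float = -11.0         # logistic midpoint of winter survival
    winter_slope: float = 0.3         # logistic slope, 1/C
    stay_prob: float = 0.5             # dispersal: probability of staying put
    dispersal_decay_m: float = 150.0   # exponential kernel decay length
    dispersal_radius_cells: int = 3    # kernel truncation radius
    host_dbh_cm: float = 15.0          # spruce above this dbh are hosts
    defence_coeff: float = 0.6         # pressure units per m2/ha host BA
    kill_coeff: float = 2.0            # m3/ha killed per unit pressure excess
    growth_rate: float = 1.6           # brood multiplication per generation
    windfall_coeff: float = 2.0        # pressure units per m3/ha downed spruce
    background_pressure: float = 0.3   # immigrant pressure, units/ha/yr
    kill_to_pressure: float = 1.25     # next-year pressure per m3/ha killed
    attack_margin: float = 1.0         # |A - D| band with stochastic success


@dataclass
class IndicatorConfig:
    """Structural/compositional diversity indicator settings."""

    height_class_m: float = 4.0
    dbh_class_cm: float = 4.0
    host_dbh_cm: float = 15.0
    k_cov: float = 0.07              # canopy-cover saturation, per m2/ha
    count_singleton_hosts: bool = False  # AggInd: include 1-cell host patches


@dataclass
class ExperimentConfig:
    """Factorial design: climates x disturbed/undisturbed x replicates."""

    climates: tuple = SCENARIOS
    horizon_yr: int = 300
    indicator_step_yr: int = 50
    replicates: int = 5
    base_seed: int = 1


@dataclass
class FeedbackConfig:
    """Surrogate random forest and counterfactual analysis."""

    window_yr: int = 50
    n_trees: int = 500
    max_features: float = 1 / 3
    bootstrap_reps: int = 1000
    benchmark_rows: int = 300
    benchmark_trees: int = 200


@dataclass
class RunConfig:
    """Top-level configuration bundle."""

    preset: str = "desk"
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    vegetation: VegetationConfig = field(default_factory=VegetationConfig)
    wind: WindConfig = field(default_factory=WindConfig)
    beetle: BeetleConfig = field(default_factory=BeetleConfig)
    indicators: IndicatorConfig = field(default_factory=IndicatorConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    feedback: FeedbackConfig = field(default_factory=FeedbackConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the full parameterization (stored in outputs)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_PRESETS = {
    "desk": {},
    "paper": {
        "landscape": {"rows": 120, "cols": 120},
        "experiment": {"horizon_yr": 600, "replicates": 20},
    },
}


def _apply_overrides(obj, overrides: dict, path: str) -> None:
    valid = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else key
        if key not in valid:
            raise ConfigError(f"unknown configuration key: {here!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current):
            if not isinstance(value, dict):
                raise ConfigError(f"section {here!r} must be a mapping")
            _apply_overrides(current, value, here)
        elif isinstance(current, dict):
            if not isinstance(value, dict):
                raise ConfigError(f"key {here!r} must be a mapping")
            for k, v in value.items():
                if k not in current:
                    raise ConfigError(f"unknown configuration key: {here}.{k!r}")
                if not isinstance(v, (int, float)):
                    raise ConfigError(f"key {here}.{k!r} must be numeric")
                current[k] = v
        elif isinstance(current, bool):
            if not isinstance(value, bool):
                raise ConfigError(f"key {here!r} must be boolean")
            setattr(obj, key, value)
        elif isinstance(current, (int, float)):
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigError(f"key {here!r} must be numeric")
            setattr(obj, key, type(current)(value))
        elif isinstance(current, tuple):
            if not isinstance(value, (list, tuple)):
                raise ConfigError(f"key {here!r} must be a list")
            setattr(obj, key, tuple(value))
        else:
            if not isinstance(value, str):
                raise ConfigError(f"key {here!r} must be a string")
            setattr(obj, key, value)


def make_config(preset: str = "desk", overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from a named preset plus optional overrides."""
    if preset not in _PRESETS:
        raise ConfigError(f"unknown preset: {preset!r} (expected desk or paper)")
    cfg = RunConfig(preset=preset)
    _apply_overrides(cfg, _PRESETS[preset], "")
    if overrides:
        _apply_overrides(cfg, overrides, "")
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config file; defaults are merged, unknown keys rejected.

    An empty file yields the full ``desk``-preset defaults.
    """
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping at top level")
    preset = data.pop("preset", "desk")
    return make_config(preset=preset, overrides=data)
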