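"""Synthetic climate scenarios.

A stationary "historical" reference block of annual climate years is
resampled with replacement to build a baseline scenario (BC); climate-change
scenarios (MC, HC, HWC) add a linear warming ramp (and for HWC a
precipitation increase) reaching the configured endpoint after
``ramp_years``, then stay stationary.  Degree-day sums are derived from the
annual mean temperature via a sinusoidal within-year cycle, and a drought
index couples warming to water stress: index = min(1, precip / demand(T))
with demand linear in temperature, so warmer years are drier (1 = no
stress).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import SCENARIOS, ClimateConfig
from .errors import ConfigError, InvalidArgumentError


@dataclass(frozen=True)
class ClimateYear:
    """One year of landscape-level climate drivers."""

    t_mean_c: float          # mean annual temperature, C
    t_min_winter_c: float    # winter minimum temperature, C
    precip_mm: float         # annual precipitation, mm
    dd_sum: float            # degree-days above the development threshold
    drought_index: float     # in [0, 1]; 1 = no drought stress

    def validate(self) -> None:
        vals = (self.t_mean_c, self.t_min_winter_c, self.precip_mm,
                self.dd_sum, self.drought_index)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidArgumentError(f"non-finite climate year: {self}")
        assert self.dd_sum >= 0 and 0 <= self.drought_index <= 1
        assert self.t_min_winter_c <= self.t_mean_c


@dataclass
class ClimateScenario:
    """An annual climate series for one named scenario."""

    name: str
    years: list  # list[ClimateYear], length = horizon


def degree_days(t_mean_c: float, amplitude_c: float, threshold_c: float) -> float:
    """Degree-day sum above ``threshold_c`` for a sinusoidal annual cycle.

    Daily temperature is modelled as t_mean + A*cos(2*pi*(d - peak)/365)
    with the peak in mid-July; the sum of positive exceedances over 365
    days approximates the thermal energy available for beetle development.
    """
    d = np.arange(365.0)
    daily = t_mean_c + amplitude_c * np.cos(2.0 * np.pi * (d - 196.0) / 365.0)
    return float(np.maximum(daily - threshold_c, 0.0).sum())


def drought_index(t_mean_c: float, precip_mm: float, cfg: ClimateConfig) -> float:
    demand = cfg.demand_base_mm + cfg.demand_per_deg_mm * t_mean_c
    return float(min(1.0, max(0.0, precip_mm / max(demand, 1e-9))))


def _reference_block(cfg: ClimateConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The shared synthetic historical block (t_mean, precip, winter anomaly)."""
    rng = np.random.default_rng(cfg.reference_seed)
    t = rng.normal(cfg.t_mean_c, cfg.t_sd_c, cfg.reference_years)
    p = np.clip(rng.normal(cfg.precip_mean_mm, cfg.precip_sd_mm,
                           cfg.reference_years), 100.0, None)
    w = rng.normal(0.0, cfg.winter_anomaly_sd_c, cfg.reference_years)
    return t, p, w


def _build_year(t: float, precip: float, w_anom: float,
                cfg: ClimateConfig) -> ClimateYear:
    t_min = t - cfg.winter_offset_c + min(w_anom, cfg.winter_offset_c - 0.1)
    return ClimateYear(
        t_mean_c=t,
        t_min_winter_c=t_min,
        precip_mm=precip,
        dd_sum=degree_days(t, cfg.seasonal_amplitude_c, cfg.dd_threshold_c),
        drought_index=drought_index(t, precip, cfg),
    )


def make_climate_scenario(name: str, horizon: int, seed: int,
                          cfg: ClimateConfig | None = None) -> ClimateScenario:
    """Build an annual climate series for one scenario.

    BC is a pure with-replacement resample of the reference block.  MC, HC
    and HWC resample the same block (identical draws for identical seeds)
    and add the scenario's warming ramp; HWC additionally scales
    precipitation.  Because all scenarios share both the reference block
    and the resampling stream, scenario contrasts at equal seeds isolate
    the forced trend.
    """
    cfg = cfg or ClimateConfig()
    if name not in SCENARIOS:
        raise ConfigError(f"unknown climate scenario: {name!r}")
    if horizon < 1:
        raise InvalidArgumentError("horizon must be >= 1")
    t_ref, p_ref, w_ref = _reference_block(cfg)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(t_ref), size=horizon)
    ramp = np.minimum(np.arange(1, horizon + 1) / cfg.ramp_years, 1.0)
    dt = cfg.delta_t_c[name] * ramp
    pf = 1.0 + (cfg.precip_factor[name] - 1.0) * ramp
    years = [
        _build_year(float(t_ref[i] + dt[k]), float(p_ref[i] * pf[k]),
                    float(w_ref[i]), cfg)
        for k, i in enumerate(idx)
    ]
    return ClimateScenario(name=name, years=years)


def extend_climate_series(years: list, horizon: int,
                          resample_window: tuple[int, int],
                          seed: int) -> list:
    """Extend an annual series to ``horizon`` by resampling a window.

    ``resample_window`` is a 0-based half-open index range ``(start, stop)``
    into the input series; appended years are drawn from it with
    replacement.  The input prefix is returned unchanged.
    """
    n = len(years)
    if horizon < n:
        raise InvalidArgumentError("horizon shorter than the input series")
    start, stop = resample_window
    if not (0 <= start < stop <= n):
        raise InvalidArgumentError(
            f"resample window {resample_window} not inside series of length {n}")
    if horizon == n:
        return list(years)
    rng = np.random.default_rng(seed)
    idx = rng.integers(start, stop, size=horizon - n)
    return list(years) + [years[i] for i in idx]
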