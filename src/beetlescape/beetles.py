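"""Annual bark beetle (Ips typographus) outbreak dynamics on the grid.

The beetle population is tracked as a per-cell "pressure" index (an
arbitrary brood-unit scale; only its ratio to tree defence matters).  The
annual cycle, executed in this fixed order, is:

1. winter survival — logistic in the winter minimum temperature;
2. brood amplification — surviving pressure plus windthrown breeding
   material and background immigration, multiplied by r per completed
   generation, with voltinism a floor of the degree-day sum;
3. dispersal — a truncated exponential kernel over cell-centre distances
   (most beetles stay within a few hundred metres of the natal tree);
4. colonization and kill — arriving pressure is pitted against a tree
   defence proportional to host basal area and drought relief; successful
   attacks kill volume linearly in the pressure excess, capped by the
   standing host volume;
5. next-year pressure is seeded by the volume killed this year, so
   outbreaks are self-propagating until hosts are depleted.

Hosts are Norway spruce above a diameter threshold.  Stochasticity enters
only through attack success in a narrow band around the attack/defence
balance point; everything else is deterministic given climate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .climate import ClimateYear
from .config import BeetleConfig
from .errors import ConfigError, InvalidInputError
from .landscape import SPRUCE, LandscapeState


@dataclass
class BeetleState:
    """Per-cell beetle pressure plus the scalar background immigration."""

    pressure: np.ndarray   # (rows, cols), brood-unit index/ha, >= 0
    background: float = 0.3

    @staticmethod
    def zeros(rows: int, cols: int, background: float = 0.3) -> "BeetleState":
        return BeetleState(pressure=np.zeros((rows, cols)),
                           background=background)


@dataclass
class KillRecord:
    """Volume disturbed in one cell in one year, by agent."""

    year: int
    cell_index: tuple
    volume_m3_ha: float
    agent: str = "beetle"   # "beetle" | "wind"


def thermal_generations(dd_sum: float, params: BeetleConfig) -> int:
    """Completed beetle generations this year (voltinism).

    floor(dd_sum / degree-days-per-generation), clamped to
    [0, max_generations]; non-decreasing in the degree-day sum.
    """
    if not math.isfinite(dd_sum) or dd_sum < 0:
        raise InvalidInputError(f"invalid degree-day sum: {dd_sum}")
    g = int(dd_sum // params.dd_per_generation)
    return max(0, min(g, params.max_generations))


def winter_survival(t_min_winter_c: float, params: BeetleConfig) -> float:
    """Overwinter survival fraction, logistic in the winter minimum."""
    if not math.isfinite(t_min_winter_c):
        raise InvalidInputError(f"invalid winter temperature: {t_min_winter_c}")
    return 1.0 / (1.0 + math.exp(
        -params.winter_slope * (t_min_winter_c - params.winter_t50_c)))


_KERNEL_CACHE: dict = {}


def dispersal_kernel(params: BeetleConfig, cell_size_m: float) -> np.ndarray:
    """Truncated exponential dispersal kernel.

    Centre weight is the stay probability p0; the remaining mass 1 - p0 is
    spread over cells within the truncation radius proportional to
    exp(-d / L) of the cell-centre distance d, so the kernel sums to 1 and
    dispersal conserves total pressure away from grid edges.
    """
    if params.stay_prob < 0 or params.dispersal_decay_m <= 0 \
            or params.dispersal_radius_cells < 1:
        raise ConfigError("dispersal kernel parameters must be positive")
    key = (params.stay_prob, params.dispersal_decay_m,
           params.dispersal_radius_cells, cell_size_m)
    if key in _KERNEL_CACHE:
        return _KERNEL_CACHE[key]
    R = params.dispersal_radius_cells
    ax = np.arange(-R, R + 1)
    dist = np.hypot(ax[:, None], ax[None, :]) * cell_size_m
    w = np.exp(-dist / params.dispersal_decay_m)
    w[R, R] = 0.0
    w *= (1.0 - params.stay_prob) / w.sum()
    w[R, R] = params.stay_prob
    _KERNEL_CACHE[key] = w
    return w


def disperse_pressure(pressure: np.ndarray, params: BeetleConfig,
                      cell_size_m: float = 100.0) -> np.ndarray:
    """Redistribute pressure with the dispersal kernel.

    Mass leaving the grid at the edges is lost (beetles dispersing off the
    landscape); interior mass is conserved up to the kernel truncation.
    """
    kernel = dispersal_kernel(params, cell_size_m)
    return ndimage.convolve(pressure, kernel, mode="constant", cval=0.0)


def colonize_and_kill(state: LandscapeState, pressure: np.ndarray,
                      climate: ClimateYear, params: BeetleConfig,
                      rng: np.random.Generator) -> tuple:
    """Attack hosts against defence; return (new state, kill records).

    Defence D = d0 * host basal area * drought index (well-watered trees
    defend better); attack succeeds where arriving pressure A exceeds D,
    with a stochastic coin flip inside the narrow band |A - D| <
    attack_margin.  Killed volume = min(host volume, c_kill * (A - D)),
    removed proportionally from the host cohorts.  Cells without hosts are
    never killed.
    """
    st = state.copy()
    host_slots = st.host_mask_slots(params.host_dbh_cm)
    slot_ba = st.slot_basal_area()
    slot_vol = st.slot_volume()
    host_ba = np.where(host_slots, slot_ba, 0.0).sum(axis=2)
    host_vol = np.where(host_slots, slot_vol, 0.0).sum(axis=2)

    defence = params.defence_coeff * host_ba * climate.drought_index
    diff = pressure - defence
    p_succ = np.clip(0.5 + diff / (2.0 * params.attack_margin), 0.0, 1.0)
    marginal = np.abs(diff) < params.attack_margin
    success = np.where(marginal, rng.random(st.shape) < p_succ, diff > 0)

    kill = np.where(success & (host_vol > 0),
                    np.minimum(host_vol, params.kill_coeff
                               * np.maximum(diff, 0.0)), 0.0)
    frac = np.where(host_vol > 0, kill / np.maximum(host_vol, 1e-12), 0.0)
    st.stems = np.where(host_slots, st.stems * (1.0 - frac[:, :, None]),
                        st.stems)

    records = [
        KillRecord(year=st.year, cell_index=(r, c),
                   volume_m3_ha=float(kill[r, c]), agent="beetle")
        for r, c in zip(*np.nonzero(kill > 0))
    ]
    return st, records


def annual_beetle_step(state: LandscapeState, climate: ClimateYear,
                       wind_events: list, beetles: BeetleState,
                       params: BeetleConfig,
                       rng: np.random.Generator) -> tuple:
    """One full beetle year; returns (new state, new BeetleState, kills).

    Order: winter survival -> brood amplification (windthrown spruce and
    background immigration feed in) -> dispersal -> colonization/kill ->
    next-year pressure seeded by kill_to_pressure * killed volume.  With
    no hosts the kill is zero everywhere and pressure collapses back to
    the background level.
    """
    survival = winter_survival(climate.t_min_winter_c, params)
    gens = thermal_generations(climate.dd_sum, params)

    wind_grid = np.zeros(state.shape)
    for ev in wind_events:
        wind_grid[ev.cell_index] += ev.downed_spruce_volume_m3_ha

    pressure = survival * (
        beetles.pressure + params.windfall_coeff * wind_grid
        + beetles.background
    ) * params.growth_rate ** gens
    pressure = disperse_pressure(pressure, params, state.cell_size_m)

    new_state, kills = colonize_and_kill(state, pressure, climate, params, rng)
    kill_grid = np.zeros(state.shape)
    for rec in kills:
        kill_grid[rec.cell_index] = rec.volume_m3_ha
    next_beetles = BeetleState(
        pressure=params.kill_to_pressure * kill_grid,
        background=beetles.background,
    )
    return new_state, next_beetles, kills
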