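"""Landscape state and stand-in vegetation dynamics.

The landscape is a grid of 1-ha (100 m) cells.  Each cell carries up to K
tree cohorts, a cohort being (species, stems/ha, mean dbh, mean height,
age).  Internally the whole grid is stored as dense (rows, cols, K) numpy
arrays so annual steps vectorise; ``Cohort``/``Cell`` views are provided
for inspection and per-cell computation.

The vegetation core is a deliberately minimal cohort model: diameter growth
follows a species-specific Gaussian temperature response times a drought
modifier, heights follow an asymptotic height-diameter allometry, mortality
is a background rate increasing with age, a basal-area cap enforces
self-thinning, and regeneration fills open cells with seedling cohorts
whose species are drawn in proportion to neighbourhood seed supply times
climate suitability.  It reproduces the qualitative couplings the
disturbance analysis needs (host availability, succession away from spruce
under warming, canopy recovery after disturbance), not the physiology of a
process-based model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .climate import ClimateYear
from .config import SPECIES, LandscapeConfig, VegetationConfig, WindConfig
from .errors import ConfigError, InvalidInputError

SPECIES_CODE = {name: i for i, name in enumerate(SPECIES)}
SPRUCE = SPECIES_CODE["spruce"]

#: Stem volume (m3/ha) = FORM_FACTOR * basal area (m2/ha) * height (m).
FORM_FACTOR = 0.5


# ---------------------------------------------------------------------------
# State containers
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A cohort of like trees within one cell."""

    species: str
    stems_per_ha: float
    mean_dbh_cm: float
    mean_height_m: float
    age_yr: float

    @property
    def basal_area(self) -> float:
        """Basal area, m2/ha."""
        return self.stems_per_ha * math.pi * (self.mean_dbh_cm / 200.0) ** 2

    @property
    def volume(self) -> float:
        """Stem volume, m3/ha."""
        return FORM_FACTOR * self.basal_area * self.mean_height_m


@dataclass
class Cell:
    """One 1-ha stand: a list of cohorts plus a site fertility scalar."""

    cohorts: list = field(default_factory=list)
    fertility: float = 1.0

    @property
    def basal_area(self) -> float:
        return sum(c.basal_area for c in self.cohorts)

    def host_volume(self, host_dbh_cm: float = 15.0) -> float:
        """Volume of beetle-susceptible spruce (above the dbh threshold)."""
        return sum(c.volume for c in self.cohorts
                   if c.species == "spruce" and c.mean_dbh_cm > host_dbh_cm)


@dataclass
class WindEvent:
    """A storm felling spruce in one cell."""

    year: int
    cell_index: tuple
    downed_spruce_volume_m3_ha: float


@dataclass
class LandscapeState:
    """Array-backed grid of cells.

    Slot arrays have shape (rows, cols, K); ``species`` is -1 where a slot
    is empty.  All derived quantities (basal area, volume, host volume,
    top height) are computed on demand.
    """

    species: np.ndarray   # int16, -1 = empty slot
    stems: np.ndarray     # stems/ha
    dbh: np.ndarray       # cm
    height: np.ndarray    # m
    age: np.ndarray       # yr
    fertility: np.ndarray  # (rows, cols), dimensionless in [0.5, 1.5]
    cell_size_m: float = 100.0
    year: int = 0

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.species.shape[:2]

    @property
    def n_cells(self) -> int:
        r, c = self.shape
        return r * c

    def copy(self) -> "LandscapeState":
        return LandscapeState(
            species=self.species.copy(), stems=self.stems.copy(),
            dbh=self.dbh.copy(), height=self.height.copy(),
            age=self.age.copy(), fertility=self.fertility.copy(),
            cell_size_m=self.cell_size_m, year=self.year,
        )

    # -- derived per-slot / per-cell quantities ----------------------------
    @property
    def occupied(self) -> np.ndarray:
        return self.species >= 0

    def slot_basal_area(self) -> np.ndarray:
        """Basal area per cohort slot, m2/ha (0 in empty slots)."""
        ba = self.stems * np.pi * (self.dbh / 200.0) ** 2
        return np.where(self.occupied, ba, 0.0)

    def basal_area(self) -> np.ndarray:
        """Total basal area per cell, m2/ha."""
        return self.slot_basal_area().sum(axis=2)

    def slot_volume(self) -> np.ndarray:
        """Stem volume per cohort slot, m3/ha."""
        return FORM_FACTOR * self.slot_basal_area() * self.height

    def species_basal_area(self, species: str) -> np.ndarray:
        mask = self.species == SPECIES_CODE[species]
        return np.where(mask, self.slot_basal_area(), 0.0).sum(axis=2)

    def host_mask_slots(self, host_dbh_cm: float = 15.0) -> np.ndarray:
        return (self.species == SPRUCE) & (self.dbh > host_dbh_cm)

    def host_volume(self, host_dbh_cm: float = 15.0) -> np.ndarray:
        """Beetle-susceptible spruce volume per cell, m3/ha."""
        mask = self.host_mask_slots(host_dbh_cm)
        return np.where(mask, self.slot_volume(), 0.0).sum(axis=2)

    def spruce_volume(self) -> np.ndarray:
        mask = self.species == SPRUCE
        return np.where(mask, self.slot_volume(), 0.0).sum(axis=2)

    def total_volume(self) -> np.ndarray:
        return self.slot_volume().sum(axis=2)

    def top_height(self) -> np.ndarray:
        """Tallest cohort height per cell, m (0 where empty)."""
        h = np.where(self.occupied, self.height, 0.0)
        return h.max(axis=2)

    # -- object views ------------------------------------------------------
    def cell(self, row: int, col: int) -> Cell:
        cohorts = [
            Cohort(
                species=SPECIES[int(self.species[row, col, k])],
                stems_per_ha=float(self.stems[row, col, k]),
                mean_dbh_cm=float(self.dbh[row, col, k]),
                mean_height_m=float(self.height[row, col, k]),
                age_yr=float(self.age[row, col, k]),
            )
            for k in range(self.species.shape[2])
            if self.species[row, col, k] >= 0
        ]
        return Cell(cohorts=cohorts, fertility=float(self.fertility[row, col]))

    def validate(self) -> None:
        """Assert structural invariants (finite, non-negative, capped)."""
        occ = self.occupied
        for arr, name in ((self.stems, "stems"), (self.dbh, "dbh"),
                          (self.height, "height"), (self.age, "age")):
            vals = arr[occ]
            if not np.all(np.isfinite(vals)):
                raise InvalidInputError(f"non-finite {name} in landscape")
            if np.any(vals < 0):
                raise InvalidInputError(f"negative {name} in landscape")
        if np.any(self.height[occ] > 60.0):
            raise InvalidInputError("cohort height exceeds 60 m")
        if np.any(self.basal_area() > 80.0 + 1e-9):
            raise InvalidInputError("cell basal area exceeds 80 m2/ha")

    @staticmethod
    def empty(rows: int, cols: int, slots: int = 8,
              cell_size_m: float = 100.0) -> "LandscapeState":
        return LandscapeState(
            species=np.full((rows, cols, slots), -1, dtype=np.int16),
            stems=np.zeros((rows, cols, slots)),
            dbh=np.zeros((rows, cols, slots)),
            height=np.zeros((rows, cols, slots)),
            age=np.zeros((rows, cols, slots)),
            fertility=np.ones((rows, cols)),
            cell_size_m=cell_size_m,
        )


def landscape_from_cells(cells: list, cell_size_m: float = 100.0,
                         slots: int | None = None) -> LandscapeState:
    """Build a LandscapeState from a nested list of :class:`Cell` objects.

    ``cells[r][c]`` is the Cell at grid position (r, c); mainly useful for
    constructing small explicit landscapes in analyses and tests.
    """
    rows = len(cells)
    cols = len(cells[0])
    K = slots or max(1, max(len(cell.cohorts) for row in cells for cell in row))
    st = LandscapeState.empty(rows, cols, K, cell_size_m)
    for r, row in enumerate(cells):
        if len(row) != cols:
            raise InvalidInputError("ragged cell grid")
        for c, cell in enumerate(row):
            st.fertility[r, c] = cell.fertility
            for k, coh in enumerate(cell.cohorts):
                st.species[r, c, k] = SPECIES_CODE[coh.species]
                st.stems[r, c, k] = coh.stems_per_ha
                st.dbh[r, c, k] = coh.mean_dbh_cm
                st.height[r, c, k] = coh.mean_height_m
                st.age[r, c, k] = coh.age_yr
    return st


def allometric_height(dbh_cm: np.ndarray, hmax_m: np.ndarray,
                      shape: float) -> np.ndarray:
    """Asymptotic height-diameter allometry, h = 1.3 + hmax*(1 - e^(-s*d))."""
    return 1.3 + hmax_m * (1.0 - np.exp(-shape * dbh_cm))


def spatial_autocorrelation(field2d: np.ndarray) -> float:
    """Moran's I with a rook (4-neighbour) weight matrix.

    Positive values indicate that neighbouring cells are more similar than
    expected under a random spatial arrangement.
    """
    z = field2d - field2d.mean()
    num = (z[:-1, :] * z[1:, :]).sum() + (z[:, :-1] * z[:, 1:]).sum()
    w_sum = z[:-1, :].size + z[:, :-1].size
    den = (z ** 2).sum()
    if den == 0:
        return 0.0
    return float(field2d.size / w_sum * num / den)


# ---------------------------------------------------------------------------
# Initial landscape generation
# ---------------------------------------------------------------------------

def generate_initial_landscape(config: LandscapeConfig,
                               seed: int) -> LandscapeState:
    """Generate a spatially structured mixed mountain-forest landscape.

    The spruce share of basal area follows a smoothed Gaussian random field
    centred on the target share (so neighbouring cells are correlated), a
    weak row-wise fertility/elevation gradient modulates site quality, and
    each cell receives mature and pole cohorts for the species present.
    The landscape-mean spruce basal-area share is calibrated to the target.
    """
    if config.rows < 2 or config.cols < 2:
        raise ConfigError("landscape grid must be at least 2x2")
    if not (0.0 <= config.target_spruce_share <= 100.0):
        raise ConfigError("target spruce share must be in [0, 100] %")
    rng = np.random.default_rng(seed)
    rows, cols, K = config.rows, config.cols, config.cohort_slots
    state = LandscapeState.empty(rows, cols, K, config.cell_size_m)

    # fertility: elevation-like row gradient plus smooth local variation
    grad = np.linspace(1.0 + config.fertility_range,
                       1.0 - config.fertility_range, rows)[:, None]
    noise = ndimage.gaussian_filter(rng.normal(0, 1, (rows, cols)), 2.0)
    sd = noise.std() or 1.0
    state.fertility = np.clip(grad + 0.05 * noise / sd, 0.5, 1.5)

    # spatially autocorrelated spruce-share field, calibrated to the target
    target = config.target_spruce_share / 100.0
    if target == 0.0:
        p_spruce = np.zeros((rows, cols))
    else:
        f = ndimage.gaussian_filter(rng.normal(0, 1, (rows, cols)),
                                    config.spruce_field_sigma)
        f = (f - f.mean()) / (f.std() or 1.0)
        p_spruce = np.clip(target + config.spruce_field_spread * f, 0.0, 1.0)
        for _ in range(8):  # clipping shifts the mean; re-centre iteratively
            err = p_spruce.mean() - target
            if abs(err) < 1e-4:
                break
            p_spruce = np.clip(p_spruce - err, 0.0, 1.0)

    ba_total = np.clip(
        rng.normal(config.ba_mean, config.ba_sd, (rows, cols)), 5.0, 65.0
    ) * (0.7 + 0.3 * state.fertility)

    # split the non-spruce share among beech, fir and "other"
    mix = rng.dirichlet([4.0, 3.0, 1.5], size=(rows, cols))  # beech, fir, other
    shares = np.zeros((rows, cols, 4))
    shares[:, :, SPRUCE] = p_spruce
    for j, sp in enumerate(("beech", "fir", "other")):
        shares[:, :, SPECIES_CODE[sp]] = (1.0 - p_spruce) * mix[:, :, j]

    hmax = np.array([38.0, 32.0, 36.0, 28.0])  # consistent with VegetationConfig
    slot = 0
    for sp_code in range(4):
        sp_ba = ba_total * shares[:, :, sp_code]
        for cohort_kind, frac, d_mean, d_sd in (
            ("mature", 1.0 - config.pole_fraction,
             config.mature_dbh_mean, config.mature_dbh_sd),
            ("pole", config.pole_fraction,
             config.pole_dbh_mean, config.pole_dbh_sd),
        ):
            ba_c = sp_ba * frac
            present = ba_c > 0.05  # m2/ha; skip negligible cohorts
            if not present.any():
                continue
            d = np.clip(rng.normal(d_mean, d_sd, (rows, cols)), 6.0, 80.0)
            h = allometric_height(d, hmax[sp_code], 0.045) \
                * (0.85 + 0.15 * state.fertility)
            stems = ba_c / (np.pi * (d / 200.0) ** 2)
            state.species[:, :, slot] = np.where(present, sp_code, -1)
            state.stems[:, :, slot] = np.where(present, stems, 0.0)
            state.dbh[:, :, slot] = np.where(present, d, 0.0)
            state.height[:, :, slot] = np.where(present, np.minimum(h, 45.0), 0.0)
            state.age[:, :, slot] = np.where(
                present, np.clip(d * 2.0 + rng.normal(0, 10, (rows, cols)),
                                 10.0, 400.0), 0.0)
            slot += 1
    state.validate()
    return state


# ---------------------------------------------------------------------------
# Annual vegetation dynamics
# ---------------------------------------------------------------------------

def _species_array(d: dict) -> np.ndarray:
    return np.array([d[sp] for sp in SPECIES])


def annual_vegetation_step(state: LandscapeState, climate: ClimateYear,
                           params: VegetationConfig,
                           rng: np.random.Generator) -> LandscapeState:
    """Advance growth, mortality, self-thinning and regeneration one year.

    Diameter increments are the species' maximum rate scaled by a Gaussian
    temperature response (spruce optimum cooler than its competitors), a
    drought modifier (monotone in the drought index), site fertility and a
    crowding term; heights follow the height-diameter allometry.  The rng
    is consumed only by regeneration (cell-level recruitment and species
    choice), keeping growth deterministic given climate.
    """
    for v in (climate.t_mean_c, climate.precip_mm, climate.dd_sum,
              climate.drought_index, climate.t_min_winter_c):
        if not math.isfinite(v):
            raise InvalidInputError(f"non-finite climate input: {climate}")
    st = state.copy()
    occ = st.occupied
    sp = np.clip(st.species, 0, 3)  # safe index; masked by occ below

    g_max = _species_array(params.growth_rate_cm)[sp]
    t_opt = _species_array(params.temp_opt_c)[sp]
    sens = _species_array(params.drought_sens)[sp]
    hmax = _species_array(params.hmax_m)[sp]
    m0 = _species_array(params.mortality_rate)[sp]

    temp_f = np.exp(-0.5 * ((climate.t_mean_c - t_opt) / params.temp_width_c) ** 2)
    drought_f = climate.drought_index ** sens
    ba_cell = st.basal_area()
    crowd = np.clip(1.0 - ba_cell / params.ba_cap_m2, 0.0, 1.0)[:, :, None]
    size_f = np.exp(-st.dbh / params.size_decay_cm)
    fert = state.fertility[:, :, None]

    d_dbh = g_max * temp_f * drought_f * size_f * (0.25 + 0.75 * crowd) * fert
    d_dbh = np.where(occ, d_dbh, 0.0)
    new_dbh = st.dbh + d_dbh
    # height tracks the allometric curve; increments are non-negative
    h_target = allometric_height(new_dbh, hmax, params.h_shape)
    new_height = np.minimum(np.maximum(st.height, h_target), 45.0)
    st.dbh = np.where(occ, new_dbh, 0.0)
    st.height = np.where(occ, new_height, 0.0)
    st.age = np.where(occ, st.age + 1.0, 0.0)

    # background + senescence mortality
    mort = m0 * (1.0 + (st.age / params.senescence_age_yr) ** 2)
    st.stems = np.where(occ, st.stems * np.clip(1.0 - mort, 0.0, 1.0), 0.0)

    # self-thinning at the basal-area cap
    ba_cell = st.basal_area()
    over = ba_cell > params.ba_cap_m2
    if over.any():
        scale = np.where(over, params.ba_cap_m2 / np.maximum(ba_cell, 1e-12), 1.0)
        st.stems *= scale[:, :, None]

    # drop cohorts that have thinned out
    dead = occ & (st.stems < params.min_stems)
    if dead.any():
        st.species[dead] = -1
        for arr in (st.stems, st.dbh, st.height, st.age):
            arr[dead] = 0.0

    _regenerate(st, climate, params, rng)
    st.year = state.year + 1
    return st


def _regenerate(st: LandscapeState, climate: ClimateYear,
                params: VegetationConfig, rng: np.random.Generator) -> None:
    """Add seedling cohorts to open cells (in place).

    Species are drawn proportional to 8-neighbour seed supply (basal area
    of conspecifics, plus a small background immigration term) times the
    species' climatic suitability at the current temperature.
    """
    ba_cell = st.basal_area()
    free_slot = (~st.occupied).argmax(axis=2)
    has_free = (~st.occupied).any(axis=2)
    open_cell = (ba_cell < params.regen_ba_threshold_m2) & has_free
    recruit = open_cell & (rng.random(st.shape) < params.regen_prob)
    if not recruit.any():
        return

    kernel = np.ones((3, 3))
    t_opt = _species_array(params.temp_opt_c)
    suit = np.exp(-0.5 * ((climate.t_mean_c - t_opt) / params.temp_width_c) ** 2)
    weights = np.zeros(st.shape + (4,))
    for code, sp_name in enumerate(SPECIES):
        supply = ndimage.convolve(st.species_basal_area(sp_name), kernel,
                                  mode="constant")
        weights[:, :, code] = (supply + params.immigration) * suit[code]
    totals = weights.sum(axis=2, keepdims=True)
    probs = np.where(totals > 0, weights / np.maximum(totals, 1e-12), 0.25)
    cum = probs.cumsum(axis=2)
    u = rng.random(st.shape)[:, :, None]
    choice = (u > cum).sum(axis=2).clip(0, 3)

    rr, cc = np.nonzero(recruit)
    kk = free_slot[rr, cc]
    hmax = _species_array(params.hmax_m)
    st.species[rr, cc, kk] = choice[rr, cc]
    st.stems[rr, cc, kk] = params.seedling_stems
    st.dbh[rr, cc, kk] = params.seedling_dbh_cm
    st.height[rr, cc, kk] = allometric_height(
        np.full(rr.shape, params.seedling_dbh_cm), hmax[choice[rr, cc]],
        params.h_shape)
    st.age[rr, cc, kk] = 0.0


# ---------------------------------------------------------------------------
# Wind disturbance
# ---------------------------------------------------------------------------

def apply_wind(state: LandscapeState, climate: ClimateYear, params: WindConfig,
               rng: np.random.Generator) -> tuple:
    """Apply at most one storm event this year; return (state, events).

    Event occurrence is Bernoulli with a fixed annual probability (the
    storm regime is stationary: no wind-climate trend).  An event fells a
    Beta-distributed fraction of the spruce stems on a contiguous patch of
    cells around a random centre; the downed spruce volume is recorded per
    cell and removed from the live cohorts.
    """
    if params.event_prob < 0 or params.event_prob > 1:
        raise ConfigError("wind event probability must be in [0, 1]")
    if rng.random() >= params.event_prob:
        return state, []
    st = state.copy()
    rows, cols = st.shape
    n_cells = min(1 + rng.geometric(1.0 / params.size_mean_cells),
                  rows * cols)
    r0, c0 = rng.integers(0, rows), rng.integers(0, cols)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    dist = (rr - r0) ** 2 + (cc - c0) ** 2 + rng.random((rows, cols))
    order = np.argsort(dist.ravel())[:n_cells]
    severity = rng.beta(params.severity_alpha, params.severity_beta)
    cells = [divmod(int(flat), cols) for flat in order]
    events = fell_spruce(st, cells, severity)
    return st, events


def fell_spruce(st: LandscapeState, cells: list, severity: float) -> list:
    """Down a fraction ``severity`` of the spruce stems on ``cells`` (in
    place) and return the resulting :class:`WindEvent` records."""
    events = []
    spruce_slots = st.species == SPRUCE
    slot_vol = st.slot_volume()
    for r, c in cells:
        mask = spruce_slots[r, c]
        if not mask.any():
            continue
        downed = float(slot_vol[r, c][mask].sum() * severity)
        if downed <= 0:
            continue
        st.stems[r, c, mask] *= (1.0 - severity)
        events.append(WindEvent(year=st.year, cell_index=(r, c),
                                downed_spruce_volume_m3_ha=downed))
    return events
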