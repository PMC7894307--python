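"""Structural and compositional diversity indicators.

Eight landscape indicators computed from a snapshot of the landscape:

========  =====================================================================
AlpHei    within-stand Shannon entropy of 4-m height classes (nats), averaged
          over stands
AlpDbh    within-stand Shannon entropy of 4-cm dbh classes (nats)
CanCov    canopy cover fraction, Beer-Lambert saturation of basal area
RumInd    rumple index: canopy surface area / ground surface area (>= 1)
BetHei    multiplicative beta diversity of height classes, gamma/alpha on the
          effective-number (exp-entropy) scale (>= 1)
BetDbh    same for dbh classes
ProSpr    spruce share of total basal area, %
AggInd    % of the landscape in contiguous (8-neighbour) patches of cells
          hosting spruce above the host dbh threshold
========  =====================================================================

Class weights are basal-area shares; classes are half-open [k*w, (k+1)*w).
Beta diversity uses effective numbers with equal cell weights, which
guarantees gamma >= alpha and hence beta >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import IndicatorConfig
from .errors import (InvalidInputError, UndefinedDistributionError,
                     UndefinedLandscapeError)
from .landscape import Cell, LandscapeState


@dataclass
class IndicatorVector:
    """The eight indicators at one timestep."""

    AlpHei: float   # nats
    AlpDbh: float   # nats
    CanCov: float   # fraction [0, 1]
    RumInd: float   # ratio >= 1
    BetHei: float   # dimensionless >= 1
    BetDbh: float   # dimensionless >= 1
    ProSpr: float   # % [0, 100]
    AggInd: float   # % [0, 100]
    year: int = 0

    FIELDS = ("AlpHei", "AlpDbh", "CanCov", "RumInd",
              "BetHei", "BetDbh", "ProSpr", "AggInd")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS])

    def validate(self) -> None:
        assert self.AlpHei >= 0 and self.AlpDbh >= 0
        assert 0.0 <= self.CanCov <= 1.0
        assert self.RumInd >= 1.0 - 1e-9
        assert self.BetHei >= 1.0 - 1e-9 and self.BetDbh >= 1.0 - 1e-9
        assert 0.0 <= self.ProSpr <= 100.0
        assert 0.0 <= self.AggInd <= 100.0


def shannon_index(weights) -> float:
    """Shannon-Wiener entropy H = -sum p_k ln p_k (nats) of a weight vector."""
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise UndefinedDistributionError("all-zero weight vector")
    p = w[w > 0] / total
    return float(-(p * np.log(p)).sum())


def class_distribution(cell: Cell, attribute: str,
                       class_width: float | None = None) -> np.ndarray:
    """Basal-area weights of a cell's cohorts binned into attribute classes.

    ``attribute`` is "height" (default width 4 m) or "dbh" (default width
    4 cm); classes are half-open [k*w, (k+1)*w), index = floor(value / w).
    An empty cell yields an empty weight vector (entropy 0 downstream).
    """
    if attribute not in ("height", "dbh"):
        raise InvalidInputError(f"unknown attribute: {attribute!r}")
    if class_width is None:
        class_width = 4.0
    if not cell.cohorts:
        return np.zeros(0)
    values = np.array([c.mean_height_m if attribute == "height"
                       else c.mean_dbh_cm for c in cell.cohorts])
    ba = np.array([c.basal_area for c in cell.cohorts])
    idx = np.floor(values / class_width).astype(int)
    out = np.zeros(idx.max() + 1)
    np.add.at(out, idx, ba)
    return out


def _landscape_class_weights(state: LandscapeState, attribute: str,
                             class_width: float) -> np.ndarray:
    """(n_cells, n_classes) basal-area weights, vectorised over the grid."""
    occ = state.occupied
    values = state.height if attribute == "height" else state.dbh
    ba = state.slot_basal_area()
    idx = np.floor(np.where(occ, values, 0.0) / class_width).astype(int)
    n_classes = int(idx.max()) + 1
    rows, cols, K = idx.shape
    cell_id = np.repeat(np.arange(rows * cols), K)
    flat_idx = cell_id * n_classes + idx.reshape(-1)
    out = np.bincount(flat_idx, weights=np.where(occ, ba, 0.0).reshape(-1),
                      minlength=rows * cols * n_classes)
    return out.reshape(rows * cols, n_classes)


def _cell_entropies(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell entropies and the mask of non-empty cells."""
    totals = weights.sum(axis=1)
    nonempty = totals > 0
    p = weights[nonempty] / totals[nonempty, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0).sum(axis=1)
    return h, nonempty


def alpha_diversity(state: LandscapeState, attribute: str,
                    class_width: float = 4.0) -> float:
    """Mean within-stand Shannon entropy over non-empty cells (nats)."""
    weights = _landscape_class_weights(state, attribute, class_width)
    h, nonempty = _cell_entropies(weights)
    if not nonempty.any():
        raise UndefinedLandscapeError("no trees on the landscape")
    return float(h.mean())


def beta_diversity(state: LandscapeState, attribute: str,
                   class_width: float = 4.0) -> float:
    """Multiplicative beta diversity gamma/alpha on the effective-number scale.

    gamma = exp(entropy of the equal-cell-weight pooled distribution),
    alpha-bar = exp(mean per-cell entropy); beta = gamma / alpha-bar >= 1,
    equal to 1 exactly when all (non-empty) cells share one distribution.
    """
    weights = _landscape_class_weights(state, attribute, class_width)
    h, nonempty = _cell_entropies(weights)
    if not nonempty.any():
        raise UndefinedLandscapeError("no trees on the landscape")
    totals = weights.sum(axis=1)
    pooled = (weights[nonempty] / totals[nonempty, None]).mean(axis=0)
    gamma = np.exp(shannon_index(pooled))
    alpha_bar = np.exp(h.mean())
    return float(gamma / alpha_bar)


def canopy_cover(state: LandscapeState, k_cov: float = 0.07) -> float:
    """Landscape-mean canopy cover fraction.

    Per-cell cover saturates with basal area (Beer-Lambert):
    cover = 1 - exp(-k_cov * BA); the landscape value averages over all
    cells, empty cells contributing 0.
    """
    ba = state.basal_area()
    return float(np.mean(1.0 - np.exp(-k_cov * ba)))


def rumple_index(state: LandscapeState) -> float:
    """Canopy surface area divided by ground surface area (>= 1).

    The canopy surface is a triangulated mesh over cell-corner heights
    (each corner the mean of its adjacent cells' top heights, each cell
    split into two 3-D triangles).  A flat canopy gives exactly 1.
    """
    rows, cols = state.shape
    if rows < 2 or cols < 2:
        raise InvalidInputError("rumple index needs a grid of at least 2x2")
    h = state.top_height()
    cs = state.cell_size_m
    # corner heights: mean of the 1-4 adjacent cell top heights
    padded = np.pad(h, 1, mode="edge")
    corners = (padded[:-1, :-1] + padded[:-1, 1:]
               + padded[1:, :-1] + padded[1:, 1:]) / 4.0
    # interior corners average 4 distinct cells; edge/corner positions
    # replicate the nearest cells via the edge padding above
    za = corners[:-1, :-1]   # (0, 0) corner of each cell
    zb = corners[:-1, 1:]    # (0, cs)
    zc = corners[1:, :-1]    # (cs, 0)
    zd = corners[1:, 1:]     # (cs, cs)
    # split each cell into two 3-D triangles along a diagonal; averaging the
    # two possible splits keeps the index invariant under grid reflections
    split_ad = (0.5 * cs * np.sqrt((zb - za) ** 2 + (zb - zd) ** 2 + cs * cs)
                + 0.5 * cs * np.sqrt((zc - zd) ** 2 + (zc - za) ** 2 + cs * cs))
    split_bc = (0.5 * cs * np.sqrt((zb - za) ** 2 + (zc - za) ** 2 + cs * cs)
                + 0.5 * cs * np.sqrt((zc - zd) ** 2 + (zd - zb) ** 2 + cs * cs))
    area = 0.5 * (split_ad + split_bc)
    return float(area.sum() / (rows * cols * cs * cs))


def spruce_proportion(state: LandscapeState) -> float:
    """Spruce share of total basal area, %."""
    total = float(state.basal_area().sum())
    if total <= 0:
        raise UndefinedLandscapeError("no basal area on the landscape")
    spruce = float(state.species_basal_area("spruce").sum())
    return 100.0 * spruce / total


def aggregation_index(state: LandscapeState, host_dbh_threshold: float = 15.0,
                      count_singletons: bool = False) -> float:
    """Host-patch aggregation, % of the landscape.

    Host cells contain spruce above the dbh threshold; patches are
    8-connected components.  By default only cells in contiguous patches
    (size >= 2) count; singleton host cells can be included via the flag.
    """
    host = state.host_mask_slots(host_dbh_threshold).any(axis=2)
    labels, n = ndimage.label(host, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return 0.0
    sizes = np.bincount(labels.ravel())[1:]  # skip background label 0
    min_size = 1 if count_singletons else 2
    counted = sizes[sizes >= min_size].sum()
    return 100.0 * float(counted) / state.n_cells


def indicator_vector(state: LandscapeState,
                     cfg: IndicatorConfig | None = None) -> IndicatorVector:
    """All eight indicators from one landscape snapshot, year-stamped."""
    cfg = cfg or IndicatorConfig()
    vec = IndicatorVector(
        AlpHei=alpha_diversity(state, "height", cfg.height_class_m),
        AlpDbh=alpha_diversity(state, "dbh", cfg.dbh_class_cm),
        CanCov=canopy_cover(state, cfg.k_cov),
        RumInd=rumple_index(state),
        BetHei=beta_diversity(state, "height", cfg.height_class_m),
        BetDbh=beta_diversity(state, "dbh", cfg.dbh_class_cm),
        ProSpr=spruce_proportion(state),
        AggInd=aggregation_index(state, cfg.host_dbh_cm,
                                 cfg.count_singleton_hosts),
        year=state.year,
    )
    vec.validate()
    return vec
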