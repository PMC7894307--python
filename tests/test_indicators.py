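"""Diversity indicators against independent brute-force oracles.

The oracles re-derive each indicator by direct summation / enumeration on
the Cell/Cohort object views, independent of the vectorised implementation.
"""

import math

import numpy as np
import pytest

import beetlescape as bl
from beetlescape.errors import (InvalidInputError, UndefinedDistributionError,
                                UndefinedLandscapeError)
from conftest import random_landscape


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def oracle_shannon(weights):
    total = sum(weights)
    return -sum((w / total) * math.log(w / total) for w in weights if w > 0)


def oracle_cell_weights(cell, attribute, width=4.0):
    out = {}
    for coh in cell.cohorts:
        v = coh.mean_height_m if attribute == "height" else coh.mean_dbh_cm
        k = int(v // width)
        out[k] = out.get(k, 0.0) + coh.basal_area
    return out


def oracle_alpha(state, attribute):
    hs = []
    rows, cols = state.shape
    for r in range(rows):
        for c in range(cols):
            w = oracle_cell_weights(state.cell(r, c), attribute)
            if w:
                hs.append(oracle_shannon(list(w.values())))
    return sum(hs) / len(hs)


def oracle_beta(state, attribute):
    rows, cols = state.shape
    pooled = {}
    hs = []
    n = 0
    for r in range(rows):
        for c in range(cols):
            w = oracle_cell_weights(state.cell(r, c), attribute)
            if not w:
                continue
            total = sum(w.values())
            n += 1
            hs.append(oracle_shannon(list(w.values())))
            for k, v in w.items():
                pooled[k] = pooled.get(k, 0.0) + v / total
    gamma = math.exp(oracle_shannon([v / n for v in pooled.values()]))
    alpha_bar = math.exp(sum(hs) / len(hs))
    return gamma / alpha_bar


def oracle_rumple(state):
    rows, cols = state.shape
    h = state.top_height()
    cs = state.cell_size_m

    def corner(i, j):
        # edge corners replicate the nearest cells (clamped indices)
        vals = [h[min(max(r, 0), rows - 1), min(max(c, 0), cols - 1)]
                for r in (i - 1, i) for c in (j - 1, j)]
        return sum(vals) / 4.0

    def tri(p1, p2, p3):
        u = np.subtract(p2, p1)
        v = np.subtract(p3, p1)
        return 0.5 * np.linalg.norm(np.cross(u, v))

    area = 0.0
    for r in range(rows):
        for c in range(cols):
            za = (0, 0, corner(r, c))
            zb = (0, cs, corner(r, c + 1))
            zc = (cs, 0, corner(r + 1, c))
            zd = (cs, cs, corner(r + 1, c + 1))
            s1 = tri(za, zb, zd) + tri(za, zd, zc)
            s2 = tri(zb, za, zc) + tri(zb, zc, zd)
            area += 0.5 * (s1 + s2)
    return area / (rows * cols * cs * cs)


def oracle_aggregation(state, threshold=15.0, count_singletons=False):
    rows, cols = state.shape
    host = [[any(c.species == "spruce" and c.mean_dbh_cm > threshold
                 for c in state.cell(r, cc).cohorts)
             for cc in range(cols)] for r in range(rows)]
    seen = [[False] * cols for _ in range(rows)]
    counted = 0
    for r in range(rows):
        for c in range(cols):
            if not host[r][c] or seen[r][c]:
                continue
            stack, comp = [(r, c)], []
            seen[r][c] = True
            while stack:
                rr, cc = stack.pop()
                comp.append((rr, cc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < rows and 0 <= nc < cols
                                and host[nr][nc] and not seen[nr][nc]):
                            seen[nr][nc] = True
                            stack.append((nr, nc))
            if len(comp) >= (1 if count_singletons else 2):
                counted += len(comp)
    return 100.0 * counted / (rows * cols)


def oracle_spruce_proportion(state):
    rows, cols = state.shape
    spruce = total = 0.0
    for r in range(rows):
        for c in range(cols):
            for coh in state.cell(r, c).cohorts:
                total += coh.basal_area
                if coh.species == "spruce":
                    spruce += coh.basal_area
    return 100.0 * spruce / total


# ---------------------------------------------------------------------------
# unit behaviour
# ---------------------------------------------------------------------------

class TestShannon:
    def test_single_class_is_zero(self):
        assert bl.shannon_index([5.0]) == 0.0

    def test_two_equal_classes_is_ln2(self):
        assert bl.shannon_index([1.0, 1.0]) == pytest.approx(math.log(2))

    def test_direct_formula_oracle(self):
        w = [1.0, 2.0, 3.0, 4.0]
        assert bl.shannon_index(w) == pytest.approx(oracle_shannon(w),
                                                    abs=1e-12)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(UndefinedDistributionError):
            bl.shannon_index([0.0, 0.0])


class TestClassDistribution:
    def test_bin_placement(self):
        cell = bl.Cell(cohorts=[bl.Cohort("beech", 100, 10.0, 3.0, 10),
                                bl.Cohort("fir", 100, 10.0, 5.0, 10)])
        w = bl.class_distribution(cell, "height")
        assert w[0] == pytest.approx(cell.cohorts[0].basal_area)
        assert w[1] == pytest.approx(cell.cohorts[1].basal_area)

    def test_boundary_value_goes_to_upper_class(self):
        cell = bl.Cell(cohorts=[bl.Cohort("beech", 50, 12.0, 4.0, 10)])
        w = bl.class_distribution(cell, "height")
        assert w[0] == 0.0 and w[1] > 0.0

    def test_empty_cell_yields_empty_distribution(self):
        assert bl.class_distribution(bl.Cell(), "dbh").size == 0


class TestIndicatorEdgeCases:
    def test_alpha_uniform_single_cohort_landscape_is_zero(self):
        cell = bl.Cell(cohorts=[bl.Cohort("spruce", 200, 30.0, 25.0, 80)])
        st = bl.landscape_from_cells([[cell] * 3] * 3)
        assert bl.alpha_diversity(st, "height") == 0.0

    def test_alpha_is_arithmetic_mean_of_cell_entropies(self):
        low = bl.Cell(cohorts=[bl.Cohort("spruce", 200, 30.0, 25.0, 80)])
        hi = bl.Cell(cohorts=[bl.Cohort("spruce", 100, 30.0, 25.0, 80),
                              bl.Cohort("beech", 100, 30.0, 10.0, 80)])
        st = bl.landscape_from_cells([[low, hi]] * 2)
        assert bl.alpha_diversity(st, "height") \
            == pytest.approx(math.log(2) / 2)

    def test_beta_identical_cells_is_one(self):
        cell = bl.Cell(cohorts=[bl.Cohort("fir", 100, 22.0, 18.0, 60),
                                bl.Cohort("beech", 150, 40.0, 30.0, 120)])
        st = bl.landscape_from_cells([[cell] * 4] * 4)
        assert bl.beta_diversity(st, "dbh") == pytest.approx(1.0)

    def test_beta_disjoint_single_classes_is_two(self):
        a = bl.Cell(cohorts=[bl.Cohort("spruce", 100, 30.0, 25.0, 80)])
        b = bl.Cell(cohorts=[bl.Cohort("beech", 100, 30.0, 10.0, 80)])
        st = bl.landscape_from_cells([[a, b]])
        # two cells, disjoint height classes: gamma=2, alpha-bar=1
        assert bl.beta_diversity(st, "height") == pytest.approx(2.0)

    def test_all_empty_landscape_is_undefined(self):
        st = bl.landscape_from_cells([[bl.Cell(), bl.Cell()]] * 2)
        with pytest.raises(UndefinedLandscapeError):
            bl.alpha_diversity(st, "height")
        with pytest.raises(UndefinedLandscapeError):
            bl.spruce_proportion(st)

    def test_canopy_cover_empty_zero_and_halfway_closed_form(self):
        empty = bl.landscape_from_cells([[bl.Cell()] * 2] * 2)
        assert bl.canopy_cover(empty) == 0.0
        k = 0.07
        ba_half = math.log(2) / k
        dbh = 30.0
        stems = ba_half / (math.pi * (dbh / 200.0) ** 2)
        cell = bl.Cell(cohorts=[bl.Cohort("spruce", stems, dbh, 25.0, 80)])
        st = bl.landscape_from_cells([[cell] * 2] * 2)
        assert bl.canopy_cover(st, k) == pytest.approx(0.5)

    def test_rumple_flat_landscape_is_exactly_one(self):
        cell = bl.Cell(cohorts=[bl.Cohort("spruce", 200, 30.0, 25.0, 80)])
        st = bl.landscape_from_cells([[cell] * 4] * 3)
        assert bl.rumple_index(st) == 1.0

    def test_rumple_degenerate_grid_rejected(self):
        cell = bl.Cell(cohorts=[bl.Cohort("spruce", 200, 30.0, 25.0, 80)])
        with pytest.raises(InvalidInputError):
            bl.rumple_index(bl.landscape_from_cells([[cell, cell]]))

    def test_aggregation_examples_on_3x3(self):
        host = bl.Cell(cohorts=[bl.Cohort("spruce", 100, 30.0, 25.0, 80)])
        non = bl.Cell(cohorts=[bl.Cohort("beech", 100, 30.0, 25.0, 80)])
        # diagonal-opposite singletons: no contiguous patch
        grid = [[host, non, non], [non, non, non], [non, non, host]]
        assert bl.aggregation_index(bl.landscape_from_cells(grid)) == 0.0
        # 8-neighbour diagonal pair forms one patch of 2
        grid = [[host, non, non], [non, host, non], [non, non, non]]
        st = bl.landscape_from_cells(grid)
        assert bl.aggregation_index(st) == pytest.approx(100.0 * 2 / 9)

    def test_aggregation_all_or_none(self):
        host = bl.Cell(cohorts=[bl.Cohort("spruce", 100, 30.0, 25.0, 80)])
        non = bl.Cell(cohorts=[bl.Cohort("beech", 100, 30.0, 25.0, 80)])
        assert bl.aggregation_index(
            bl.landscape_from_cells([[host] * 3] * 3)) == 100.0
        assert bl.aggregation_index(
            bl.landscape_from_cells([[non] * 3] * 3)) == 0.0

    def test_uniform_pure_spruce_landscape_degenerate_vector(self):
        cell = bl.Cell(cohorts=[bl.Cohort("spruce", 200, 30.0, 25.0, 80)])
        st = bl.landscape_from_cells([[cell] * 4] * 4)
        iv = bl.indicator_vector(st)
        assert iv.AlpHei == 0.0 and iv.AlpDbh == 0.0
        assert iv.RumInd == 1.0
        assert iv.BetHei == pytest.approx(1.0)
        assert iv.BetDbh == pytest.approx(1.0)
        assert iv.ProSpr == 100.0 and iv.AggInd == 100.0
        ba = cell.basal_area
        assert iv.CanCov == pytest.approx(1.0 - math.exp(-0.07 * ba))

    def test_empty_landscape_vector_errors(self):
        st = bl.landscape_from_cells([[bl.Cell()] * 2] * 2)
        with pytest.raises(UndefinedLandscapeError):
            bl.indicator_vector(st)


# ---------------------------------------------------------------------------
# randomized oracle suite
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(100))
def test_randomized_landscapes_match_all_oracles(seed):
    """Vectorised indicators equal brute-force oracles to 1e-10."""
    rng = np.random.default_rng(1234 + seed)
    st = random_landscape(rng, rows=int(rng.integers(2, 7)),
                          cols=int(rng.integers(2, 7)))
    if not st.occupied.any():
        return
    for attr in ("height", "dbh"):
        assert bl.alpha_diversity(st, attr) \
            == pytest.approx(oracle_alpha(st, attr), abs=1e-10)
        assert bl.beta_diversity(st, attr) \
            == pytest.approx(oracle_beta(st, attr), abs=1e-10)
    assert bl.rumple_index(st) == pytest.approx(oracle_rumple(st), abs=1e-10)
    assert bl.aggregation_index(st) \
        == pytest.approx(oracle_aggregation(st), abs=1e-10)
    assert bl.spruce_proportion(st) \
        == pytest.approx(oracle_spruce_proportion(st), abs=1e-10)


@pytest.mark.parametrize("seed", range(20))
def test_indicator_bounds_and_symmetries(seed):
    """Bounds hold and all indicators are rotation/reflection invariant."""
    rng = np.random.default_rng(999 + seed)
    st = random_landscape(rng, rows=4, cols=4, p_empty=0.2)
    if not st.occupied.any() or st.basal_area().sum() == 0:
        return
    iv = bl.indicator_vector(st)
    iv.validate()  # all range bounds incl. beta >= 1

    def transform(state, fn):
        out = state.copy()
        for f in ("species", "stems", "dbh", "height", "age"):
            setattr(out, f, fn(getattr(out, f)).copy())
        out.fertility = fn(out.fertility).copy()
        return out

    for fn in (lambda a: np.rot90(a, axes=(0, 1)),
               lambda a: np.flip(a, axis=0),
               lambda a: np.flip(a, axis=1)):
        iv2 = bl.indicator_vector(transform(st, fn))
        np.testing.assert_allclose(iv2.as_array(), iv.as_array(), atol=1e-10)


def test_removing_all_spruce_zeroes_composition_and_cover_not_increased():
    rng = np.random.default_rng(77)
    st = random_landscape(rng, rows=5, cols=5, p_empty=0.0, p_spruce=0.6)
    cov_before = bl.canopy_cover(st)
    spruce = st.species == 0
    st2 = st.copy()
    st2.species[spruce] = -1
    st2.stems[spruce] = 0.0
    if not st2.occupied.any():
        return
    assert bl.spruce_proportion(st2) == 0.0
    assert bl.aggregation_index(st2) == 0.0
    assert bl.canopy_cover(st2) <= cov_before + 1e-12
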