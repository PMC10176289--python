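import dataclasses

import numpy as np
import pytest

from farmabm import (
    AdaptationParams,
    AdaptationState,
    DecisionMatrix,
    RentalMarket,
    action_probabilities,
    choose_action,
    default_decision_matrix,
    execute_action,
    market_step,
    possible_actions,
    preset,
)
from farmabm.constants import (
    ADAPTIVE_ACTIONS,
    FOREST,
    HOLDER_FOREST,
    HOLDER_RENTAL,
    ORGANIC,
    QUADRANTS,
)
from farmabm.decisions import DecisionError
from farmabm.economy import EconomyTables

from conftest import build_region

BOTH_OK = QUADRANTS.index("both_ok")
NEITHER = QUADRANTS.index("neither")


def small_region():
    """Three-patch mixed farm plus a second farm for peer context."""
    return build_region(
        [
            {"farm_type": "cash_crop", "style": "innovative"},
            {"farm_type": "livestock_meat", "style": "traditionalist"},
        ],
        [
            {"area": 2.0, "holder": 0, "land_use": "cropland", "crop_cycle": "cr1",
             "intensity": 3},
            {"area": 1.0, "holder": 0, "land_use": "cropland", "crop_cycle": "cr2",
             "intensity": 3},
            {"area": 1.5, "holder": 0, "land_use": "meadow", "crop_cycle": "none",
             "intensity": 3},
            {"area": 3.0, "holder": 1, "land_use": "pasture", "crop_cycle": "none",
             "intensity": 2},
        ],
    )


def _probs(region, farm=0, quadrant=NEITHER, config=None, plist=None, **kw):
    config = config or preset("BAU")
    plist = plist if plist is not None else [0, 1, 2]
    return action_probabilities(
        default_decision_matrix(), farm, region, quadrant, plist, config, **kw
    )


class TestMatrix:
    def test_default_matrix_is_complete_and_normalized(self):
        m = default_decision_matrix()
        assert m.weights.shape == (4, 5, 5, 10)
        np.testing.assert_allclose(m.weights.sum(axis=-1), 1.0)
        # satisfied farms always do nothing
        np.testing.assert_allclose(m.weights[BOTH_OK, :, :, 0], 1.0)

    def test_style_tilts_shape_behaviour(self):
        m = default_decision_matrix()
        # traditionalists favour inaction more than innovative farmers
        trad = m.weights[NEITHER, 0, 4, 0]
        innov = m.weights[NEITHER, 0, 0, 0]
        assert trad > innov

    def test_csv_roundtrip(self, tmp_path):
        m = default_decision_matrix()
        m.save(tmp_path / "matrix.csv")
        back = DecisionMatrix.load(tmp_path / "matrix.csv")
        np.testing.assert_allclose(back.weights, m.weights)

    def test_incomplete_table_rejected(self):
        df = default_decision_matrix().to_frame().iloc[:-1]
        with pytest.raises(DecisionError, match="incomplete"):
            DecisionMatrix.from_frame(df)


class TestMasking:
    def test_satisfied_farm_concentrates_on_nothing(self):
        p = _probs(small_region(), quadrant=BOTH_OK)
        assert p[0] == 1.0 and p[1:].sum() == 0.0

    def test_intensity_ceiling_masks_intensification(self):
        r = small_region()
        r.patches.intensity[[0, 1, 2]] = 5
        p = _probs(r)
        assert p[2] == 0.0
        assert p.sum() == pytest.approx(1.0)

    def test_intensity_floor_masks_extensification(self):
        r = small_region()
        r.patches.intensity[[0, 1, 2]] = 1
        assert _probs(r)[3] == 0.0

    def test_used_organic_switch_masks_act5(self):
        r = small_region()
        r.farms.org_switch_used[0] = True
        assert _probs(r)[4] == 0.0

    def test_organic_farm_needs_free_market_to_revert(self):
        r = small_region()
        r.farms.production[0] = ORGANIC
        assert _probs(r, config=preset("BAU"))[4] == 0.0
        assert _probs(r, config=preset("FM"))[4] > 0.0

    def test_no_grassland_masks_afforestation(self):
        r = small_region()
        assert _probs(r, plist=[0, 1])[6] == 0.0

    def test_single_patch_masks_reduction(self):
        r = small_region()
        assert _probs(r, plist=[0])[8] == 0.0

    def test_suffering_farm_restricted_to_exit_actions(self):
        r = small_region()
        r.farms.suffer_counter[0] = 5
        p = _probs(r)
        assert p[8] + p[9] == pytest.approx(1.0)
        assert _probs(r, plist=[0])[9] == 1.0  # one patch: termination only

    def test_mask_vector_shape(self):
        r = small_region()
        mask = possible_actions(0, r, [0, 1, 2], preset("BAU"))
        assert mask.dtype == bool and mask.shape == (10,)
        assert mask[0] and mask[1] and mask[7] and mask[9]


class TestAdaptationCoupling:
    def test_full_willingness_doubles_adaptive_odds(self):
        r = small_region()
        cfg = preset("BAUA")
        state = AdaptationState(x=37)
        base = _probs(r, config=preset("BAU"))
        boosted = _probs(r, config=cfg, adaptation=state, params=AdaptationParams())
        # odds of adaptive vs non-adaptive actions exactly double
        k_a, k_n = ADAPTIVE_ACTIONS[0], 0
        assert (boosted[k_a] / boosted[k_n]) == pytest.approx(
            2 * base[k_a] / base[k_n]
        )

    def test_zero_events_leaves_probabilities_untouched(self):
        r = small_region()
        base = _probs(r, config=preset("BAU"))
        adapt = _probs(
            r, config=preset("BAUA"), adaptation=AdaptationState(x=0),
            params=AdaptationParams(),
        )
        np.testing.assert_array_equal(base, adapt)


class TestSampling:
    def test_concentrated_vector_is_deterministic(self):
        p = np.zeros(10)
        p[9] = 1.0
        rng = np.random.default_rng(0)
        assert choose_action(p, rng) == 9

    def test_seeded_draws_reproducible(self):
        p = np.full(10, 0.1)
        draws1 = [choose_action(p, np.random.default_rng(5)) for _ in range(1)]
        a = np.random.default_rng(5)
        b = np.random.default_rng(5)
        assert [choose_action(p, a) for _ in range(50)] == [
            choose_action(p, b) for _ in range(50)
        ]

    def test_uniform_frequencies(self):
        p = np.full(10, 0.1)
        rng = np.random.default_rng(123)
        n = 20000
        counts = np.bincount([choose_action(p, rng) for _ in range(n)], minlength=10)
        se = np.sqrt(0.1 * 0.9 / n)
        assert np.all(np.abs(counts / n - 0.1) < 3.5 * se)


class TestExecution:
    def _setup(self, config=None):
        r = small_region()
        config = config or preset("BAU")
        market = RentalMarket.from_region(r, config.afforestation_wait)
        rng = np.random.default_rng(0)
        tables = EconomyTables()
        return r, market, rng, tables, config

    def test_hire_adds_180_hours(self):
        r, market, rng, t, c = self._setup()
        execute_action(0, 1, r, market, rng, [0, 1, 2], t, c)
        assert r.farms.hired_hours[0] == 180.0

    def test_intensify_whole_farm_with_cap(self):
        r, market, rng, t, c = self._setup()
        r.patches.intensity[[0, 1, 2]] = 4
        execute_action(0, 2, r, market, rng, [0, 1, 2], t, c)
        assert np.all(r.patches.intensity[[0, 1, 2]] == 5)

    def test_extensify_with_floor(self):
        r, market, rng, t, c = self._setup()
        r.patches.intensity[0] = 1
        execute_action(0, 3, r, market, rng, [0, 1, 2], t, c)
        assert r.patches.intensity[0] == 1  # stays at floor
        assert np.all(r.patches.intensity[[1, 2]] == 2)

    def test_organic_switch_is_single_use(self):
        r, market, rng, t, c = self._setup()
        execute_action(0, 4, r, market, rng, [0, 1, 2], t, c)
        assert r.farms.production[0] == ORGANIC
        assert r.farms.org_switch_used[0]
        with pytest.raises(DecisionError):
            execute_action(0, 4, r, market, rng, [0, 1, 2], t, c)

    def test_reverse_organic_switch_in_free_market(self):
        r, market, rng, t, c = self._setup(preset("FM"))
        r.farms.production[0] = ORGANIC
        execute_action(0, 4, r, market, rng, [0, 1, 2], t, c)
        assert r.farms.production[0] == 0

    def test_landuse_change_targets_income_or_time(self):
        r, market, rng, t, c = self._setup()
        execute_action(0, 5, r, market, rng, [0, 1, 2], t, c, income_ok=False)
        assert np.all(r.patches.crop_cycle[[0, 1]] == t.cycle_margin_mult.argmax() + 1)
        execute_action(0, 5, r, market, rng, [0, 1, 2], t, c, income_ok=True)
        assert np.all(r.patches.crop_cycle[[0, 1]] == t.cycle_labor_mult.argmin() + 1)

    def test_afforestation_converts_grassland_and_relieves_suffering(self):
        r, market, rng, t, c = self._setup()
        r.farms.suffer_counter[0] = 2
        plist = [0, 1, 2]
        execute_action(0, 6, r, market, rng, plist, t, c)
        assert r.patches.land_use[2] == FOREST
        assert r.patches.holder[2] == HOLDER_FOREST
        assert r.patches.intensity[2] == 0
        assert r.farms.suffer_counter[0] == 1
        assert plist == [0, 1]

    def test_expansion_with_empty_pool_is_noop(self):
        r, market, rng, t, c = self._setup()
        rec = execute_action(0, 7, r, market, rng, [0, 1, 2], t, c)
        assert rec["claimed"] is None

    def test_expansion_adopts_modal_intensity(self):
        r, market, rng, t, c = self._setup()
        market.release(3)  # second farm's pasture enters the pool
        plist = [0, 1, 2]
        rec = execute_action(0, 7, r, market, rng, plist, t, c)
        assert rec["claimed"] == 3
        assert r.patches.holder[3] == 0
        assert r.patches.intensity[3] == 3  # buyer's modal intensity
        assert market.pool == []

    def test_reduction_resets_hired_labor_and_sheds_patch(self):
        r, market, rng, t, c = self._setup()
        r.farms.hired_hours[0] = 360.0
        plist = [0, 1, 2]
        execute_action(0, 8, r, market, rng, plist, t, c)
        assert r.farms.hired_hours[0] == 0.0
        assert len(plist) == 2
        assert len(market.pool) == 1
        shed = market.pool[0]
        assert r.patches.holder[shed] == HOLDER_RENTAL
        assert r.patches.intensity[shed] == 0

    def test_termination_releases_everything(self):
        r, market, rng, t, c = self._setup()
        plist = [0, 1, 2]
        execute_action(0, 9, r, market, rng, plist, t, c, year=2030)
        assert not r.farms.active[0]
        assert r.farms.death_year[0] == 2030
        assert r.farms.death_reason[0] == 1
        assert plist == []
        assert sorted(market.pool) == [0, 1, 2]
        assert np.all(r.patches.intensity[[0, 1, 2]] == 0)
        r.validate()  # inactive farm holds zero patches


class TestMarketStep:
    def test_pool_ages_and_converts_past_wait(self):
        r = small_region()
        cfg = dataclasses.replace(preset("BAU"), afforestation_wait=2)
        market = RentalMarket.from_region(r, cfg.afforestation_wait)
        market.release(3)
        for _ in range(2):
            market_step(market, r, 2016)
            assert r.patches.holder[3] == HOLDER_RENTAL
        rec = market_step(market, r, 2018)
        assert r.patches.holder[3] == HOLDER_FOREST
        assert r.patches.land_use[3] == FOREST
        assert rec["afforested"] == [3]
        assert market.pool == []

    def test_claimed_patch_resets_market_clock(self):
        r = small_region()
        market = RentalMarket.from_region(r, 5)
        market.release(3)
        market_step(market, r, 2016)
        assert r.patches.years_on_market[3] == 1
        rng = np.random.default_rng(0)
        execute_action(0, 7, r, market, rng, [0, 1, 2], EconomyTables(), preset("BAU"))
        assert r.patches.years_on_market[3] == 0
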