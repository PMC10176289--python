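import dataclasses

import numpy as np
import pandas as pd
import pytest

from farmabm import (
    EventLog,
    preset,
    run_monte_carlo,
    run_simulation,
    summarize,
    synthesize_region,
)
from farmabm.config import SatisfactionThresholds
from farmabm.constants import AGRI_LAND_USES, FARM_TYPES
from farmabm.simulate import RunResult, metrics_long

from conftest import TOY_INIT, build_region


def all_false_log(config):
    years = config.start_year + 1 + np.arange(config.horizon)
    return EventLog(
        "r0", config.name, years, np.zeros(config.horizon, bool),
        np.zeros(config.horizon),
    )


AREA_COLS = ["area_cropland", "area_grassland", "area_rental", "area_forest"]


def test_zero_event_runs_make_learning_invisible(toy_region):
    """With no events alpha stays 0, so the adaptive variant is bit-identical."""
    base = preset("BAU")
    log = all_false_log(base)
    plain = run_simulation(toy_region, base, events=log, seed=9)
    adaptive = run_simulation(toy_region, preset("BAUA"), events=log, seed=9)
    assert plain.metrics.to_csv() == adaptive.metrics.to_csv()


def test_replay_reproduces_drawn_run(toy_region):
    cfg = preset("FM")
    drawn = run_simulation(toy_region, cfg, seed=21)
    replayed = run_simulation(toy_region, cfg, events=drawn.event_log, seed=21)
    assert drawn.metrics.to_csv() == replayed.metrics.to_csv()


def test_runs_are_bit_reproducible(toy_region):
    a = run_simulation(toy_region, preset("BAU"), seed=4)
    b = run_simulation(toy_region, preset("BAU"), seed=4)
    assert a.metrics.to_csv() == b.metrics.to_csv()
    c = run_simulation(toy_region, preset("BAU"), seed=5)
    assert a.metrics.to_csv() != c.metrics.to_csv()


def test_input_region_is_not_mutated(toy_region):
    before = toy_region.patches.holder.copy()
    run_simulation(toy_region, preset("FM"), seed=1)
    np.testing.assert_array_equal(toy_region.patches.holder, before)


def test_series_shape_and_conservation(toy_region):
    cfg = preset("FM")
    res = run_simulation(toy_region, cfg, seed=2)
    m = res.metrics
    assert len(m) == cfg.horizon + 1
    assert m.year.iloc[0] == 2015 and m.year.iloc[-1] == 2052
    totals = m[AREA_COLS].sum(axis=1)
    np.testing.assert_allclose(totals, totals.iloc[0], rtol=1e-9)
    assert (np.diff(m.active_farms_total) <= 0).all()
    type_sum = m[[f"active_{t}" for t in FARM_TYPES]].sum(axis=1)
    np.testing.assert_array_equal(type_sum, m.active_farms_total)


def test_fully_satisfied_region_is_static():
    """Identical farms, permissive thresholds, no events: nothing changes."""
    farms = [{"farm_type": "cash_crop", "fte": 2.0} for _ in range(5)]
    patches = [
        {"area": 4.0, "holder": i, "land_use": "cropland", "crop_cycle": "cr2",
         "intensity": 3}
        for i in range(5)
    ]
    region = build_region(farms, patches)
    cfg = dataclasses.replace(
        preset("BAU"),
        yield_trend_endpoints={lu: 0.0 for lu in AGRI_LAND_USES},
        workload_trend=0.0,
        thresholds=SatisfactionThresholds(
            min_income_per_fte={t: 1.0 for t in FARM_TYPES},
            max_workload_per_fte=1e9,
        ),
    )
    res = run_simulation(region, cfg, events=all_false_log(cfg), seed=0)
    m = res.metrics
    for col in ("active_farms_total", *AREA_COLS, "organic_farm_share",
                "extensive_area_share"):
        assert m[col].nunique() == 1, col
    assert (res.action_counts.drop(columns=["year", "act1"]).to_numpy() == 0).all()


def test_replayed_horizon_mismatch_rejected(toy_region):
    cfg = preset("BAU")
    short = dataclasses.replace(cfg, horizon=5)
    log = all_false_log(short)
    with pytest.raises(ValueError, match="horizon"):
        run_simulation(toy_region, cfg, events=log, seed=0)


class TestMonteCarlo:
    def test_single_run_equals_direct_call(self, toy_region):
        res = run_monte_carlo(preset("BAU"), toy_region, n_runs=1, base_seed=77)
        direct = run_simulation(toy_region, preset("BAU"), seed=77, run_id="run000")
        assert len(res) == 1
        assert res[0].metrics.to_csv() == direct.metrics.to_csv()

    def test_paired_runs_share_event_years(self, toy_region):
        res = run_monte_carlo(
            preset("FM"), toy_region, n_runs=3, base_seed=8, paired=True
        )
        by = {(r.scenario, r.run_id): r for r in res}
        assert len(by) == 6
        for rid in ("run000", "run001", "run002"):
            np.testing.assert_array_equal(
                by[("FM", rid)].event_log.event, by[("FMA", rid)].event_log.event
            )
            assert by[("FMA", rid)].adaptive

    def test_summary_of_single_run_has_zero_sd(self, toy_region):
        res = run_monte_carlo(preset("BAU"), toy_region, n_runs=1, base_seed=3)
        s = summarize(res)["final"]
        assert s.loc["BAU", "active_farms_total_sd"] == 0.0
        assert (
            s.loc["BAU", "active_farms_total_mean"]
            == res[0].final["active_farms_total"]
        )


def _fake_result(scenario, run_id, farms):
    m = pd.DataFrame(
        {"year": [2015, 2052], "event": [False, False],
         "active_farms_total": [100, farms]}
    )
    years = np.arange(2016, 2053)
    log = EventLog(run_id, scenario, years, np.zeros(37, bool), np.zeros(37))
    return RunResult(run_id, scenario, scenario.endswith("A"), m, log, pd.DataFrame())


def test_summarize_against_hand_computed_statistics():
    res = [
        _fake_result("X", "run000", 80),
        _fake_result("X", "run001", 60),
        _fake_result("XA", "run000", 90),
        _fake_result("XA", "run001", 62),
    ]
    s = summarize(res)
    final = s["final"]
    assert final.loc["X", "active_farms_total_mean"] == pytest.approx(70.0)
    assert final.loc["X", "active_farms_total_sd"] == pytest.approx(10.0)
    assert final.loc["X", "active_farms_total_median"] == pytest.approx(70.0)
    deltas = s["paired_deltas"]
    assert deltas.loc["X", "active_farms_total"] == pytest.approx((10 + 2) / 2)


def test_metrics_long_format(toy_region):
    res = run_monte_carlo(preset("BAU"), toy_region, n_runs=1, base_seed=0)
    long = metrics_long(res)
    assert set(long.columns) == {"run_id", "scenario", "year", "metric", "value"}
    assert (long.scenario == "BAU").all()


@pytest.fixture(scope="module")
def paired_results(toy_region):
    out = {}
    for name in ("BAU", "HS", "FM"):
        out[name] = run_monte_carlo(
            preset(name), toy_region, n_runs=30, base_seed=100, paired=True
        )
    return out


class TestScenarioAndAdaptationTendencies:
    """Direction checks on the default calibration (MC means, documented
    tolerances; these are tendency checks, not point targets)."""

    @staticmethod
    def _mean_final(results, scenario, column):
        vals = [r.final[column] for r in results if r.scenario == scenario]
        return float(np.mean(vals))

    def test_scenario_ordering_of_surviving_farms(self, paired_results):
        """Farm survival orders HS >= BAU >= FM in the MC mean."""
        hs = self._mean_final(paired_results["HS"], "HS", "active_farms_total")
        bau = self._mean_final(paired_results["BAU"], "BAU", "active_farms_total")
        fm = self._mean_final(paired_results["FM"], "FM", "active_farms_total")
        # tolerance: 2 farms (~1 % of the population) on the near tie
        assert hs >= bau - 2
        assert bau >= fm + 2

    def _paired_deltas(self, results, scenario, columns):
        by = {(r.scenario, r.run_id): r for r in results}
        deltas = []
        for (sc, rid), r in by.items():
            if sc != scenario:
                continue
            partner = by[(sc + "A", rid)]
            deltas.append(
                sum(partner.final[c] for c in columns)
                - sum(r.final[c] for c in columns)
            )
        return np.asarray(deltas)

    def test_adaptation_preserves_farms(self, paired_results):
        """Learning keeps more farms active (pooled over BAU and FM, where
        events are frequent enough for alpha to move)."""
        pooled = np.concatenate(
            [
                self._paired_deltas(paired_results[s], s, ["active_farms_total"])
                for s in ("BAU", "FM")
            ]
        )
        assert pooled.mean() > 0

    def test_adaptation_preserves_agricultural_area(self, paired_results):
        """Pooled mean adaptive-minus-plain agricultural area is not negative
        beyond noise (tolerance 0.5 % of the initial area)."""
        cols = ["area_cropland", "area_grassland"]
        pooled = np.concatenate(
            [
                self._paired_deltas(paired_results[s], s, cols)
                for s in ("BAU", "FM")
            ]
        )
        assert pooled.mean() >= -0.005 * TOY_INIT["total_area_ha"]

    def test_adaptation_raises_extensive_share_under_frequent_events(
        self, paired_results
    ):
        """Extensification shows where events are frequent (free market)."""
        deltas = self._paired_deltas(
            paired_results["FM"], "FM", ["extensive_area_share"]
        )
        assert deltas.mean() > 0
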