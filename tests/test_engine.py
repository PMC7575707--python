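"""Scenario engine: stepping, determinism, presets, configuration."""

import numpy as np
import pytest

import granulesim as gs
from granulesim import engine
from granulesim.engine import (
    FeedSchedule, PRESET_NAMES, ScenarioSpec, preset, run, scenario_from_config,
    state_hash, step,
)
from granulesim.parameters import GUILDS, SOLUTES, ConfigurationError


def mini_spec(seed=1, duration=10.0, guilds=None, cells=12):
    p = gs.default_parameters()
    p.geometry = gs.DomainGeometry(side=96.0, spacing=4.0,
                                   max_granule_diameter=80.0)
    return ScenarioSpec(
        name="mini", parameters=p, duration=duration, seed=seed,
        initial_guilds=guilds or ("clostridium1", "clostridium2",
                                  "desulfovibrio", "methanogen1",
                                  "methanogen2"),
        inoculum_cells=cells, inoculum_radius=16.0, snapshot_interval=5.0)


def test_empty_domain_step_advances_clock_only():
    spec = mini_spec(cells=0)
    state = engine.initial_state(spec)
    step(state, spec)
    assert state.time == spec.parameters.dt
    assert len(state.pop) == 0
    assert all(v == 0.0 for v in state.produced.values())
    assert all(v == 0.0 for v in state.washout.values())


def test_single_fermenter_step_produces_lactate_and_ethanol_not_methane():
    """One cellobiose fermenter in abundant substrate feeds the lactate and
    ethanol pools in its very first step; methane needs methanogens."""
    spec = mini_spec(guilds=("clostridium1",), cells=1)
    state = engine.initial_state(spec)
    step(state, spec)
    assert state.produced["lactate"] > 0
    assert state.produced["ethanol"] > 0
    assert state.produced["lactate"] == pytest.approx(state.produced["ethanol"])
    assert state.produced["methane"] == 0.0
    assert state.produced["hydrogen"] == 0.0
    # and the increment matches the exact step integral of mu*B/alpha
    gp = spec.parameters.guild("clostridium1")
    grown = state.grown["clostridium1"]
    assert state.produced["lactate"] == pytest.approx(grown / gp.alpha_b, rel=1e-9)


def test_identical_seed_and_spec_reproduce_the_state_hash():
    hashes = []
    for _ in range(2):
        spec = mini_spec(seed=77)
        state = engine.initial_state(spec)
        for _ in range(30):
            step(state, spec)
        hashes.append(state_hash(state))
    assert hashes[0] == hashes[1]


def test_different_seeds_differ():
    states = []
    for seed in (1, 2):
        spec = mini_spec(seed=seed)
        state = engine.initial_state(spec)
        for _ in range(5):
            step(state, spec)
        states.append(state_hash(state))
    assert states[0] != states[1]


def test_agent_order_does_not_matter_materially():
    """Shuffling the agent storage order under the same seed leaves the
    end-state total biomass essentially unchanged (< 0.1%)."""
    totals = []
    for shuffle in (False, True):
        spec = mini_spec(seed=5)
        state = engine.initial_state(spec)
        if shuffle:
            perm = np.random.default_rng(99).permutation(len(state.pop))
            for f in ("guild_idx", "x", "y", "radius", "biomass", "clock",
                      "ids", "density"):
                setattr(state.pop, f, getattr(state.pop, f)[perm])
        for _ in range(20):
            step(state, spec)
        totals.append(state.pop.biomass.sum() + state.dead.biomass.sum())
    assert abs(totals[0] - totals[1]) / totals[0] < 1e-3


def test_zero_duration_returns_initial_state():
    spec = mini_spec(duration=0.0)
    result = run(spec)
    assert result.state.time == 0.0
    assert len(result.timeseries) == 1
    assert result.state.pop.census()["clostridium1"] > 0


def test_ledgers_are_monotone_over_a_run():
    spec = mini_spec(duration=10.0)
    result = run(spec)
    for s in SOLUTES:
        col = result.timeseries[f"produced_g[{s}]"].to_numpy()
        assert np.all(np.diff(col) >= 0)


# --- feed schedule ---------------------------------------------------------

def test_feed_schedule_step_function():
    sched = FeedSchedule({"cellobiose": [(96.0, 0.0)],
                          "oleate": [(96.0, 1.5)]})
    base = {"cellobiose": 1.5, "oleate": 0.0}
    assert sched.bulk_at(0.0, base)["cellobiose"] == 1.5
    assert sched.bulk_at(95.9, base)["oleate"] == 0.0
    at = sched.bulk_at(96.0, base)
    assert at["cellobiose"] == 0.0 and at["oleate"] == 1.5


def test_unordered_feed_schedule_rejected():
    with pytest.raises(ConfigurationError):
        FeedSchedule({"cellobiose": [(96.0, 0.0), (48.0, 1.0)]})


# --- presets ---------------------------------------------------------------

def test_preset_names_complete():
    assert len(PRESET_NAMES) == 10
    with pytest.raises(ConfigurationError, match="cellobiose-1.5"):
        preset("bogus")


def test_preset_dual_feed_low():
    spec = preset("oleate-cellobiose-0.5")
    assert spec.parameters.solutes.bulk["cellobiose"] == 0.5
    assert spec.feed.bulk_at(408.0, spec.parameters.solutes.bulk)["oleate"] == 0.5
    assert spec.feed.bulk_at(0.0, spec.parameters.solutes.bulk)["oleate"] == 0.0
    assert any(e.guild == "oleate_degrader" and e.time == 408.0
               for e in spec.events)


def test_preset_oleate_only_halts_cellobiose():
    spec = preset("oleate-only-1.5")
    bulk0 = spec.feed.bulk_at(0.0, spec.parameters.solutes.bulk)
    bulk_late = spec.feed.bulk_at(408.0, spec.parameters.solutes.bulk)
    assert bulk0["cellobiose"] == 1.5 and bulk0["oleate"] == 0.0
    assert bulk_late["cellobiose"] == 0.0 and bulk_late["oleate"] == 1.5


def test_preset_baseline_has_no_events_and_default_diameter():
    spec = preset("cellobiose-1.5")
    assert spec.events == []
    assert spec.parameters.geometry.max_granule_diameter == 500.0
    assert spec.duration == 1008.0


def test_preset_relaxed_sloughing_diameter():
    spec = preset("oleate-cellobiose-1.5-dmax1000")
    assert spec.parameters.geometry.max_granule_diameter == 1000.0


def test_preset_reintroduction_scenarios_start_without_desulfovibrio():
    for name in ("no-desulfovibrio", "reintroduce-d-day16",
                 "reintroduce-d-m2-day16"):
        spec = preset(name)
        assert "desulfovibrio" not in spec.initial_guilds
    assert preset("reintroduce-d-day16").events[0].time == 408.0
    both = {e.guild for e in preset("reintroduce-d-m2-day16").events}
    assert both == {"desulfovibrio", "methanogen2"}


def test_reduced_presets_scale_consistently():
    spec = preset("oleate-cellobiose-1.5", reduced=True)
    assert spec.parameters.geometry.side == 256.0
    assert spec.parameters.geometry.n == 64
    assert spec.duration == 240.0
    assert spec.events[0].time == 96.0


# --- XML scenario configuration --------------------------------------------

EXAMPLE_XML = """
<granulesim name="example">
  <domain side="256.0" spacing="4.0" maxGranuleDiameter="200.0"/>
  <solutes gamma="0.5">
    <solute name="cellobiose" diffusivity="400000.0" bulk="1.5"/>
  </solutes>
  <simulation dt="0.5" duration="48.0" randomSeed="9" snapshotEvery="12"/>
  <event time="24.0" species="oleate_degrader" cellsPerSite="2" biomass="15.0">
    <site x="40.0" y="40.0" z="0"/>
    <site x="216.0" y="216.0"/>
  </event>
  <feed solute="oleate" time="24.0" bulk="1.0"/>
  <inoculum guilds="clostridium1,methanogen1" cells="10" radius="20.0"/>
</granulesim>
"""


def test_scenario_from_config_parses_everything():
    spec = scenario_from_config(EXAMPLE_XML)
    assert spec.name == "example"
    assert spec.duration == 48.0 and spec.seed == 9
    assert spec.parameters.geometry.side == 256.0
    assert spec.initial_guilds == ("clostridium1", "methanogen1")
    assert spec.inoculum_cells == 10
    ev = spec.events[0]
    assert ev.guild == "oleate_degrader" and ev.cells_per_site == 2
    assert ev.sites == [(40.0, 40.0), (216.0, 216.0)]  # z ignored
    assert spec.feed.bulk_at(24.0, spec.parameters.solutes.bulk)["oleate"] == 1.0


def test_event_beyond_duration_rejected():
    bad = EXAMPLE_XML.replace('time="24.0" species', 'time="99.0" species')
    with pytest.raises(ConfigurationError):
        scenario_from_config(bad)
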