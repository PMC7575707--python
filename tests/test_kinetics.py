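"""Growth laws, reaction assembly, biomass update and the death switch."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import granulesim as gs
from granulesim.agents import Cell, DeadCell
from granulesim.kinetics import (
    LocalEnvironment, growth_rate, haldane, integrate_batch, monod,
    product_inhibition, reaction_terms, update_biomass,
    update_starvation_and_death,
)
from granulesim.parameters import GROWTH_SUBSTRATE, GUILDS


# --- closed-form anchor points --------------------------------------------

def test_monod_half_saturation(params):
    gp = params.guild("clostridium1")
    env = LocalEnvironment(cellobiose=gp.k_s)
    assert growth_rate("clostridium1", env, gp) == pytest.approx(gp.mu_max / 2)


def test_haldane_equal_constants_gives_third(params):
    gp = params.guild("methanogen1")
    gp.k_s = gp.k_i_substrate = 0.5
    env = LocalEnvironment(acetate=0.5)
    assert growth_rate("methanogen1", env, gp) == pytest.approx(gp.mu_max / 3)


def test_saturated_monod_times_half_product_inhibition(params):
    gp = params.guild("oleate_degrader")
    env = LocalEnvironment(oleate=1e9, acetate=gp.k_i_product)
    assert growth_rate("oleate_degrader", env, gp) == pytest.approx(
        gp.mu_max / 2, rel=1e-6)


def test_haldane_degenerates_to_monod_without_self_inhibition(params):
    gp = params.guild("desulfovibrio")
    gp.k_i_substrate = 1e12  # effectively no self-inhibition
    env = LocalEnvironment(ethanol=gp.k_s, acetate=0.0)
    assert growth_rate("desulfovibrio", env, gp) == pytest.approx(
        gp.mu_max / 2, rel=1e-9)


def test_zero_substrate_means_zero_growth(params):
    env = LocalEnvironment()  # everything at 0
    for g in GUILDS:
        assert growth_rate(g, env, params.guild(g)) == 0.0


def test_guild_params_mismatch_raises(params):
    with pytest.raises(ValueError):
        growth_rate("clostridium1", LocalEnvironment(), params.guild("methanogen1"))


# --- rate-law properties ---------------------------------------------------

@given(s=st.floats(0, 1e3), ks=st.floats(1e-6, 1e2))
def test_monod_bounded_unit_interval(s, ks):
    assert 0 <= monod(s, ks) < 1


@given(s=st.floats(0, 1e3), p=st.floats(0, 1e3), ki=st.floats(1e-6, 1e3))
def test_product_inhibition_in_unit_interval(s, p, ki):
    f = product_inhibition(p, ki)
    assert 0 < f <= 1
    assert product_inhibition(0.0, ki) == 1.0


@settings(max_examples=50)
@given(ks=st.floats(1e-3, 10), ki=st.floats(1e-3, 100))
def test_haldane_peaks_at_geometric_mean(ks, ki):
    """The Haldane law is unimodal with its maximum at S* = sqrt(Ks*Ki)."""
    s_star = math.sqrt(ks * ki)
    grid = np.geomspace(s_star / 100, s_star * 100, 801)
    values = haldane(grid, ks, ki)
    peak = grid[np.argmax(values)]
    assert peak == pytest.approx(s_star, rel=0.05)
    assert haldane(s_star, ks, ki) >= values.max() * (1 - 1e-12)


@settings(max_examples=100, deadline=None)
@given(
    sc=st.floats(0, 100), so=st.floats(0, 100), sl=st.floats(0, 100),
    sa=st.floats(0, 100), se=st.floats(0, 100), sh=st.floats(0, 100),
)
def test_growth_rates_saturate_below_mu_max(sc, so, sl, sa, se, sh):
    p = gs.default_parameters()
    env = LocalEnvironment(cellobiose=sc, oleate=so, lactate=sl,
                           acetate=sa, ethanol=se, hydrogen=sh)
    for g in GUILDS:
        mu = float(growth_rate(g, env, p.guild(g)))
        assert 0.0 <= mu <= p.guild(g).mu_max + 1e-15


def test_monod_rates_monotone_in_substrate(params):
    grid = np.linspace(0, 10, 200)
    for g in ("clostridium1", "clostridium2", "methanogen2"):
        gp = params.guild(g)
        env = LocalEnvironment(**{gp.substrate: grid})
        mu = growth_rate(g, env, gp)
        assert np.all(np.diff(mu) >= 0)


# --- reaction-term assembly ------------------------------------------------

def test_no_biomass_no_reactions(params):
    rates = reaction_terms(LocalEnvironment(cellobiose=1.5), {}, params)
    for s, r in rates.net.items():
        assert r == 0


def test_lactate_sink_equals_acetate_source_for_c2_alone(params):
    """Clostridium2 moves mass from the lactate pool to the acetate pool at
    the single rate mu_c2 * B_c2 / alpha_c2."""
    env = LocalEnvironment(lactate=0.3)
    rates = reaction_terms(env, {"clostridium2": 5.0}, params)
    gp = params.guild("clostridium2")
    expected = float(growth_rate("clostridium2", env, gp)) * 5.0 / gp.alpha_b
    assert rates.sink["lactate"] == pytest.approx(expected)
    assert rates.source["acetate"] == pytest.approx(expected)


def test_hydrogen_has_no_source_without_desulfovibrio(params):
    """Ethanol oxidation is the only hydrogen-producing step, so a
    consortium lacking desulfovibrio can never make hydrogen."""
    env = LocalEnvironment(cellobiose=1.5, lactate=1.0, acetate=1.0,
                           ethanol=1.0, oleate=1.0, hydrogen=1.0)
    biomass = {g: 10.0 for g in GUILDS if g != "desulfovibrio"}
    rates = reaction_terms(env, biomass, params)
    assert rates.source["hydrogen"] == 0.0


def test_oleate_feeds_acetate_only_when_enabled(params):
    env = LocalEnvironment(oleate=1.0)
    biomass = {"oleate_degrader": 10.0}
    on = reaction_terms(env, biomass, params)
    assert on.source["acetate"] > 0
    assert on.source["hydrogen"] == 0  # oleate degradation makes no hydrogen
    params.oleate_to_acetate = False
    off = reaction_terms(env, biomass, params)
    assert off.source["acetate"] == 0


# --- biomass update --------------------------------------------------------

def make_cell(biomass=1.0, guild="clostridium1", density=1.5e-13):
    return Cell(guild=guild, x=10.0, y=10.0,
                radius=gs.parameters.radius_from_biomass(biomass, density),
                biomass=biomass, density=density)


@pytest.mark.parametrize("mu,dt,factor", [
    (0.0, 1.0, 1.0),
    (math.log(2.0), 1.0, 2.0),           # doubling time
    (0.05, 1.0, math.exp(0.05)),          # 1 pg -> 1.05127 pg
])
def test_exponential_biomass_update(mu, dt, factor):
    cell = make_cell(1.0)
    grown = update_biomass(cell, mu, dt)
    assert grown.biomass == pytest.approx(factor)
    assert grown.radius == pytest.approx(
        gs.parameters.radius_from_biomass(grown.biomass, cell.density))


# --- death switch ----------------------------------------------------------

def starve(cell, gp, hours, dt=1.0, env=None):
    env = env or LocalEnvironment()  # substrate absent
    t = 0.0
    for _ in range(int(hours / dt)):
        cell = update_starvation_and_death(cell, env, gp, dt, time=t)
        t += dt
        if isinstance(cell, DeadCell):
            return cell, t
    return cell, t


def test_c1_survives_95h_dies_at_96h(params):
    gp = params.guild("clostridium1")
    cell, _ = starve(make_cell(), gp, 95)
    assert isinstance(cell, Cell)
    dead, t = starve(make_cell(), gp, 200)
    assert isinstance(dead, DeadCell)
    assert t == 96.0
    assert dead.biomass == pytest.approx(1.0)  # mass conserved on conversion


def test_m1_dies_at_exactly_144h(params):
    gp = params.guild("methanogen1")
    cell = make_cell(guild="methanogen1")
    dead, t = starve(cell, gp, 200)
    assert isinstance(dead, DeadCell)
    assert t == 144.0


def test_recovery_resets_the_starvation_clock(params):
    """The exposure rule is consecutive: one step above threshold rearms."""
    gp = params.guild("methanogen1")
    cell = make_cell(guild="methanogen1")
    cell, _ = starve(cell, gp, 143)
    assert cell.clock == pytest.approx(143.0)
    fed = LocalEnvironment(acetate=10 * gp.death_threshold)
    cell = update_starvation_and_death(cell, fed, gp, 1.0)
    assert isinstance(cell, Cell)
    assert cell.clock == 0.0


# --- well-mixed oracle -----------------------------------------------------

def euler_oracle(env0, bio0, p, dt, t_end):
    """Independent fine-step explicit integration of the full network."""
    from granulesim.kinetics import product_edges
    from granulesim.parameters import SOLUTES
    env = {s: float(env0.get(s, 0.0)) for s in SOLUTES}
    bio = {g: float(bio0.get(g, 0.0)) for g in GUILDS}
    for _ in range(int(round(t_end / dt))):
        le = LocalEnvironment(**env)
        mu = {g: float(growth_rate(g, le, p.guild(g))) for g in GUILDS}
        d_env = {s: 0.0 for s in SOLUTES}
        for g in GUILDS:
            gp = p.guild(g)
            d_env[gp.substrate] -= mu[g] * bio[g] / gp.alpha_b
        for g, sol in product_edges(p):
            d_env[sol] += mu[g] * bio[g] / p.guild(g).alpha_b
        for s in SOLUTES:
            env[s] = max(env[s] + d_env[s] * dt, 0.0)
        for g in GUILDS:
            bio[g] *= 1.0 + mu[g] * dt
    return env, bio


def test_well_mixed_batch_matches_fine_euler_oracle(params):
    """Diffusion-free closed-system trajectories of the full 6-guild /
    7-solute network agree with an independent fine-step explicit
    integration to better than 0.1% over 100 h."""
    env0 = {"cellobiose": 1.5}
    bio0 = {g: 0.01 for g in GUILDS}
    env_a, bio_a = integrate_batch(env0, bio0, params, dt=0.02, t_end=100.0)
    env_b, bio_b = euler_oracle(env0, bio0, params, dt=0.002, t_end=100.0)
    scale_env = max(env_b.values())
    for s in env_a:
        assert abs(env_a[s] - env_b[s]) / scale_env < 1e-3, s
    for g in bio_a:
        assert abs(bio_a[g] - bio_b[g]) / max(bio_b[g], 1e-12) < 1e-3, g


def test_batch_mass_audit_is_exact(params):
    """Per guild, substrate consumed x alpha equals biomass formed."""
    env0 = {"cellobiose": 2.0}
    bio0 = {g: 0.05 for g in GUILDS}
    env, bio, series = integrate_batch(env0, bio0, params, dt=0.5,
                                       t_end=50.0, record=True)
    gp = params.guild("clostridium1")
    consumed = env0["cellobiose"] - env["cellobiose"]
    formed = bio["clostridium1"] - bio0["clostridium1"]
    assert consumed * gp.alpha_b == pytest.approx(formed, rel=1e-12)
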