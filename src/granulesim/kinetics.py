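"""Growth laws, reaction terms and the discrete death switch.

The metabolic network: clostridium1 ferments cellobiose to lactate and
ethanol; clostridium2 ferments lactate to acetate; desulfovibrio oxidizes
ethanol to acetate and hydrogen (inhibited by its own substrate at high
levels and by accumulating acetate); the oleate degrader converts oleate to
acetate (acetate-product-inhibited); methanogen1 makes methane from acetate
(Haldane self-inhibition); methanogen2 makes methane from hydrogen.  Methane
and hydrogen feed back on nothing -- they are pure products.

Every volumetric reaction term has the form ``mu_g(S) * B_g / alpha_g``
(g/L/h) with the guild's single yield ``alpha_g`` scaling substrate uptake
and every product release alike.  All rate functions accept scalars or numpy
arrays (broadcasting), so the same code serves single cells and whole
lattices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .parameters import (
    GUILDS, SOLUTES, GuildParams, ParameterSet, radius_from_biomass,
)

if TYPE_CHECKING:
    from .agents import Cell, DeadCell


@dataclass
class LocalEnvironment:
    """The seven solute concentrations (g/L) at one node (scalars or lattices)."""

    cellobiose: float | np.ndarray = 0.0
    oleate: float | np.ndarray = 0.0
    lactate: float | np.ndarray = 0.0
    acetate: float | np.ndarray = 0.0
    ethanol: float | np.ndarray = 0.0
    hydrogen: float | np.ndarray = 0.0
    methane: float | np.ndarray = 0.0

    def __getitem__(self, solute: str):
        return getattr(self, solute)

    @classmethod
    def from_mapping(cls, m: Mapping[str, float | np.ndarray]) -> "LocalEnvironment":
        return cls(**{s: m[s] for s in SOLUTES if s in m})


def monod(s, k_s):
    """Saturating uptake factor S / (Ks + S), in [0, 1)."""
    s = np.asarray(s, dtype=float)
    return s / (k_s + s)


def haldane(s, k_s, k_i):
    """Substrate-inhibited factor S / (Ks + S + S^2/Ki), unimodal in S.

    The maximum sits at S* = sqrt(Ks * Ki).
    """
    s = np.asarray(s, dtype=float)
    return s / (k_s + s + s * s / k_i)


def product_inhibition(p, k_i):
    """Multiplicative inhibition factor Ki / (Ki + P), in (0, 1], = 1 at P = 0."""
    p = np.asarray(p, dtype=float)
    return k_i / (k_i + p)


def specific_affinity(guild: str, env: LocalEnvironment, gp: GuildParams):
    """mu(S)/S in closed form (finite at S = 0); used to linearize sinks."""
    if gp.k_i_substrate is None:
        core = gp.mu_max / (gp.k_s + np.asarray(env[gp.substrate], dtype=float))
    else:
        s = np.asarray(env[gp.substrate], dtype=float)
        core = gp.mu_max / (gp.k_s + s + s * s / gp.k_i_substrate)
    if gp.k_i_product is not None:
        core = core * product_inhibition(env.acetate, gp.k_i_product)
    return core


def growth_rate(guild: str, env: LocalEnvironment, gp: GuildParams):
    """Specific growth rate mu (1/h) of ``guild`` in environment ``env``.

    Monod kinetics for clostridium1 (cellobiose), clostridium2 (lactate) and
    methanogen2 (hydrogen); Monod x acetate product inhibition for the oleate
    degrader; Haldane x acetate product inhibition for desulfovibrio
    (ethanol); plain Haldane for methanogen1 (acetate).  Always in
    [0, mu_max]; exactly 0 when the growth substrate is 0.
    """
    if guild != gp.name:
        raise ValueError(f"guild {guild!r} does not match parameters for {gp.name!r}")
    return specific_affinity(guild, env, gp) * np.asarray(env[gp.substrate], dtype=float)


# (producer guild -> solute) edges of the network; every term is dB/alpha
_PRODUCT_EDGES: tuple[tuple[str, str], ...] = (
    ("clostridium1", "lactate"),
    ("clostridium1", "ethanol"),
    ("clostridium2", "acetate"),
    ("desulfovibrio", "acetate"),
    ("desulfovibrio", "hydrogen"),
    ("methanogen1", "methane"),
    ("methanogen2", "methane"),
)


def product_edges(p: ParameterSet) -> tuple[tuple[str, str], ...]:
    """Producer->solute edges, including oleate-derived acetate when enabled."""
    edges = _PRODUCT_EDGES
    if p.oleate_to_acetate:
        edges = edges + (("oleate_degrader", "acetate"),)
    return edges


@dataclass
class ReactionRates:
    """Volumetric reaction terms at one node (or lattice of nodes).

    ``mu`` maps guild -> specific growth rate (1/h); ``source``/``sink`` map
    solute -> non-negative volumetric rate (g/L/h); ``net`` is their signed
    sum, i.e. the reaction part of each solute balance.
    """

    mu: dict[str, np.ndarray] = field(default_factory=dict)
    source: dict[str, np.ndarray] = field(default_factory=dict)
    sink: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def net(self) -> dict[str, np.ndarray]:
        return {s: self.source[s] - self.sink[s] for s in SOLUTES}


def reaction_terms(env: LocalEnvironment,
                   biomass: Mapping[str, float | np.ndarray],
                   p: ParameterSet) -> ReactionRates:
    """Assemble all reaction terms from local solutes and guild biomasses.

    ``biomass`` maps guild -> local biomass concentration (g/L); missing
    guilds count as absent.  Each guild consumes its growth substrate at
    mu*B/alpha and feeds its product(s) at the same specific rate.
    """
    zero = np.zeros(np.broadcast(*(np.asarray(env[s]) for s in SOLUTES)).shape)
    rates = ReactionRates(
        source={s: zero.copy() for s in SOLUTES},
        sink={s: zero.copy() for s in SOLUTES},
    )
    flux: dict[str, np.ndarray] = {}
    for guild in GUILDS:
        gp = p.guild(guild)
        b = np.asarray(biomass.get(guild, 0.0), dtype=float)
        mu = growth_rate(guild, env, gp)
        rates.mu[guild] = mu
        flux[guild] = mu * b / gp.alpha_b
        rates.sink[gp.substrate] = rates.sink[gp.substrate] + flux[guild]
    for guild, solute in product_edges(p):
        rates.source[solute] = rates.source[solute] + flux[guild]
    return rates


def update_biomass(cell: "Cell", mu: float, dt: float) -> "Cell":
    """Grow a cell for one step: B -> B * exp(mu * dt), radius recomputed.

    The exponential form is exact for a constant specific rate over the step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    from .agents import Cell  # local import to avoid a cycle
    new_b = cell.biomass * float(np.exp(mu * dt))
    return Cell(guild=cell.guild, x=cell.x, y=cell.y,
                radius=radius_from_biomass(new_b, cell.density),
                biomass=new_b, clock=cell.clock, id=cell.id,
                birth_time=cell.birth_time, density=cell.density)


def update_starvation_and_death(cell: "Cell", env: LocalEnvironment,
                                gp: GuildParams, dt: float, time: float = 0.0):
    """Advance the starvation clock; convert to a DeadCell when it expires.

    The clock counts *consecutive* exposure: it advances by dt while the
    guild's growth substrate sits below the death threshold and resets to
    zero the moment the substrate recovers.  At ``clock >= death_duration``
    the cell converts, mass intact, into the inert dead pool.
    """
    from .agents import Cell, DeadCell
    s_local = float(np.asarray(env[gp.substrate]))
    clock = cell.clock + dt if s_local < gp.death_threshold else 0.0
    if clock >= gp.death_duration:
        return DeadCell(x=cell.x, y=cell.y, radius=cell.radius,
                        biomass=cell.biomass, time_of_death=time + dt)
    return Cell(guild=cell.guild, x=cell.x, y=cell.y, radius=cell.radius,
                biomass=cell.biomass, clock=clock, id=cell.id,
                birth_time=cell.birth_time, density=cell.density)


def integrate_batch(env0: Mapping[str, float], biomass0: Mapping[str, float],
                    p: ParameterSet, dt: float, t_end: float,
                    record: bool = False):
    """Well-mixed (zero-dimensional) closed-system integration of the network.

    Used as a diffusion-free reference mode: one lattice node, no transport.
    Biomass grows exponentially within each step at the frozen local rates
    and solutes are updated with the exact step integral of each term,
    ``dS = +/- B * expm1(mu*dt) / alpha`` -- the same bookkeeping the spatial
    engine uses, so mass audits close to machine precision.

    Returns ``(env, biomass)`` dicts at ``t_end``; with ``record=True`` also
    a dict of time series arrays (key ``time`` plus one per solute/guild).
    """
    env = {s: float(env0.get(s, 0.0)) for s in SOLUTES}
    bio = {g: float(biomass0.get(g, 0.0)) for g in GUILDS}
    n = int(round(t_end / dt))
    edges = product_edges(p)
    series = {k: [v] for k, v in {**env, **bio}.items()}
    times = [0.0]
    for i in range(n):
        le = LocalEnvironment(**env)
        growth = {}
        for g in GUILDS:
            gp = p.guild(g)
            mu = float(growth_rate(g, le, gp))
            growth[g] = bio[g] * float(np.expm1(mu * dt))
        for g in GUILDS:
            gp = p.guild(g)
            env[gp.substrate] = max(env[gp.substrate] - growth[g] / gp.alpha_b, 0.0)
        for g, solute in edges:
            env[solute] += growth[g] / p.guild(g).alpha_b
        for g in GUILDS:
            bio[g] += growth[g]
        if record:
            times.append((i + 1) * dt)
            for k, v in {**env, **bio}.items():
                series[k].append(v)
    if record:
        out = {k: np.asarray(v) for k, v in series.items()}
        out["time"] = np.asarray(times)
        return env, bio, out
    return env, bio


__all__ = [
    "LocalEnvironment", "ReactionRates", "monod", "haldane",
    "product_inhibition", "specific_affinity", "growth_rate",
    "reaction_terms", "product_edges", "update_biomass",
    "update_starvation_and_death", "integrate_batch",
]
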