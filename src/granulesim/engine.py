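"""Scenario engine: the global simulation loop, feed schedules, events, presets.

Each global step advances the coupled system in a fixed order:

1. rasterize agent biomass onto the lattice and refresh the presence
   indicator;
2. relax all solutes to their pseudo-steady state (diffusion + reaction)
   under the current bulk-feed boundary values;
3. grow every cell at its local specific rate, advance starvation clocks and
   convert expired cells to dead biomass;
4. divide cells that reached the division radius;
5. relax overlaps (shoving);
6. slough all biomass beyond the maximum granule radius;
7. apply due introduction events and feed changes;
8. increment the production/consumption ledgers and the clock.

A single seeded random generator drives every stochastic draw (inoculum
placement, division direction and split, shoving tie-breaks), so a run is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .agents import (
    Cell, DeadPool, IntroductionEvent, Population, divide, introduce_species,
    shove_relax, slough, granule_radius,
)
from .kinetics import product_edges
from .parameters import (
    GROWTH_SUBSTRATE, GUILDS, LITRE_PER_UM3, SOLUTES,
    ConfigurationError, ParameterSet, default_parameters, load_parameters,
    radius_from_biomass,
)
from .solver import SoluteFields, production_ledger_increment, solve_steady_state

log = logging.getLogger(__name__)


@dataclass
class FeedSchedule:
    """Per-solute bulk feed concentration as a right-continuous step function.

    ``changes`` maps solute -> ordered list of (time_h, bulk g/L); before the
    first change the catalog's base bulk value applies.
    """

    changes: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for solute, steps in self.changes.items():
            if any(t1 >= t2 for (t1, _), (t2, _) in zip(steps, steps[1:])):
                raise ConfigurationError(
                    f"feed schedule for {solute} is not time-ordered")

    def bulk_at(self, t: float, base: dict[str, float]) -> dict[str, float]:
        out = dict(base)
        for solute, steps in self.changes.items():
            for t_change, value in steps:
                if t >= t_change:
                    out[solute] = value
        return out


@dataclass
class ScenarioSpec:
    """Declarative description of one simulated experiment."""

    name: str
    parameters: ParameterSet
    duration: float  # h
    seed: int = 1
    feed: FeedSchedule = field(default_factory=FeedSchedule)
    events: list[IntroductionEvent] = field(default_factory=list)
    snapshot_interval: float = 24.0  # h
    initial_guilds: tuple[str, ...] = (
        "clostridium1", "clostridium2", "desulfovibrio",
        "methanogen1", "methanogen2")
    inoculum_cells: int = 40
    inoculum_radius: float = 40.0  # um
    initial_biomass: float = 20.0  # pg per inoculated cell

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ConfigurationError("duration must be >= 0")
        for ev in self.events:
            if ev.time > self.duration:
                raise ConfigurationError(
                    f"event at t={ev.time} h is beyond the duration {self.duration} h")


@dataclass
class SimulationState:
    """Agents + fields + clock + cumulative ledgers + RNG state."""

    time: float
    pop: Population
    dead: DeadPool
    fields: SoluteFields
    rng: np.random.Generator
    produced: dict[str, float] = field(default_factory=lambda: {s: 0.0 for s in SOLUTES})
    consumed: dict[str, float] = field(default_factory=lambda: {s: 0.0 for s in SOLUTES})
    grown: dict[str, float] = field(default_factory=lambda: {g: 0.0 for g in GUILDS})
    washout: dict[str, float] = field(default_factory=lambda: {g: 0.0 for g in GUILDS})
    washout_dead: float = 0.0
    events_applied: int = 0
    solver_iterations: int = 0


def initial_state(spec: ScenarioSpec) -> SimulationState:
    """Seed the inoculum at the domain centre and initialize fields to bulk."""
    p = spec.parameters
    rng = np.random.default_rng(spec.seed)
    pop = Population()
    cells = []
    cx, cy = p.geometry.center
    for i in range(spec.inoculum_cells):
        guild = spec.initial_guilds[i % len(spec.initial_guilds)]
        rr = spec.inoculum_radius * math.sqrt(rng.uniform())
        th = rng.uniform(0.0, 2.0 * math.pi)
        gp = p.guild(guild)
        cells.append(Cell(
            guild=guild, x=cx + rr * math.cos(th), y=cy + rr * math.sin(th),
            radius=radius_from_biomass(spec.initial_biomass, gp.density),
            biomass=spec.initial_biomass, density=gp.density))
    pop.add(cells)
    dead = DeadPool()
    shove_relax(pop, dead, p.geometry, rng)
    bulk0 = spec.feed.bulk_at(0.0, p.solutes.bulk)
    fields = SoluteFields.uniform(p.geometry.n, bulk0)
    return SimulationState(time=0.0, pop=pop, dead=dead, fields=fields, rng=rng)


def _deposit_weights(x: np.ndarray, y: np.ndarray, radius: np.ndarray,
                     h: float, n: int):
    """Deposition stencil spreading each agent over its physical footprint.

    Node centres sit at (i + 0.5) h.  Each agent's mass is shared among the
    nodes inside a compact quadratic kernel of support radius
    ``R = max(1.5 r_cell, h)`` -- a *physical* width, so the rasterized
    biomass field converges under grid refinement (point or cell-in-cloud
    deposition leaves h-dependent spikes).  Weights are normalized to sum
    to 1 per agent, conserving mass exactly.

    Returns ``(ix, iy, w)`` index/weight arrays of shape (N, K).
    """
    if x.size == 0:
        empty = np.zeros((0, 1))
        return empty.astype(np.int64), empty.astype(np.int64), empty
    big_r = np.maximum(1.5 * radius, h)
    m = max(int(np.ceil(float(big_r.max()) / h)), 1)
    gx = x / h - 0.5
    gy = y / h - 0.5
    ix0 = np.rint(gx).astype(np.int64)
    iy0 = np.rint(gy).astype(np.int64)
    offs = np.arange(-m, m + 1)
    ox, oy = (a.ravel() for a in np.meshgrid(offs, offs, indexing="ij"))
    ix = ix0[:, None] + ox[None, :]
    iy = iy0[:, None] + oy[None, :]
    rr2 = (((ix + 0.5) * h - x[:, None]) ** 2
           + ((iy + 0.5) * h - y[:, None]) ** 2)
    w = np.maximum(0.0, 1.0 - rr2 / big_r[:, None] ** 2) ** 2
    wsum = w.sum(axis=1)
    center = (ox == 0) & (oy == 0)
    empty = wsum <= 0  # degenerate (cannot happen with R >= h, kept for safety)
    if np.any(empty):
        w[np.ix_(empty, center)] = 1.0
        wsum[empty] = 1.0
    w /= wsum[:, None]
    np.clip(ix, 0, n - 1, out=ix)
    np.clip(iy, 0, n - 1, out=iy)
    return ix, iy, w


def _deposit_biomass(state: SimulationState, p: ParameterSet):
    """Rasterize agent biomass to per-guild concentration lattices (g/L)."""
    n = p.geometry.n
    h = p.geometry.spacing
    vol = p.geometry.node_volume
    conc = {g: np.zeros((n, n)) for g in GUILDS}
    ix, iy, w = _deposit_weights(state.pop.x, state.pop.y,
                                 state.pop.radius, h, n)
    for gi, g in enumerate(GUILDS):
        m = state.pop.guild_idx == gi
        if np.any(m):
            np.add.at(conc[g], (ix[m].ravel(), iy[m].ravel()),
                      (state.pop.biomass[m, None] * w[m]).ravel())
        conc[g] *= 1e3 / vol  # pg per node -> g/L
    dead_conc = np.zeros((n, n))
    if len(state.dead):
        dx, dy, dw = _deposit_weights(state.dead.x, state.dead.y,
                                      state.dead.radius, h, n)
        np.add.at(dead_conc, (dx.ravel(), dy.ravel()),
                  (state.dead.biomass[:, None] * dw).ravel())
        dead_conc *= 1e3 / vol
    indicator = (sum(conc.values()) + dead_conc) > 0
    return conc, indicator, (ix, iy, w)


def step(state: SimulationState, spec: ScenarioSpec,
         p: ParameterSet | None = None) -> SimulationState:
    """Advance the state by one global timestep ``p.dt`` (mutates in place)."""
    if p is None:
        p = spec.parameters
    dt = p.dt
    n = p.geometry.n
    t0 = state.time

    # (1) biomass indicator
    conc, indicator, (ix, iy, w) = _deposit_biomass(state, p)
    state.fields.indicator = indicator

    # (2) pseudo-steady solute fields under the current feed
    bulk = spec.feed.bulk_at(t0, p.solutes.bulk)
    fields, rates, info = solve_steady_state(state.fields, conc, p, bulk)
    state.fields = fields
    state.solver_iterations += info.iterations
    for w in info.warnings:
        log.warning("t=%.1f h: %s", t0, w)

    # (8a) ledger increments: exact step integral of each mu*B/alpha term,
    # expressed as time-averaged source lattices for the quadrature helper
    growth_conc = {}  # guild -> lattice of biomass formed this step (g/L)
    for g in GUILDS:
        growth_conc[g] = conc[g] * np.expm1(rates.mu[g] * dt)
    src_eff = {s: np.zeros((n, n)) for s in SOLUTES}
    sink_eff = {s: np.zeros((n, n)) for s in SOLUTES}
    for g, solute in product_edges(p):
        src_eff[solute] += growth_conc[g] / (p.guild(g).alpha_b * dt)
    for g in GUILDS:
        sink_eff[GROWTH_SUBSTRATE[g]] += growth_conc[g] / (p.guild(g).alpha_b * dt)
    vol = p.geometry.node_volume
    for s_name, inc in production_ledger_increment(src_eff, vol, dt).items():
        state.produced[s_name] += inc
    for s_name, inc in production_ledger_increment(sink_eff, vol, dt).items():
        state.consumed[s_name] += inc
    for g in GUILDS:
        state.grown[g] += float(growth_conc[g].sum()) * vol * LITRE_PER_UM3

    # (3) per-cell growth and starvation; the growth increment uses the same
    # bilinear weights as the deposition so that the per-cell biomass change
    # sums exactly to the node-level ledger increments
    if len(state.pop):
        expm1_cells = np.zeros(len(state.pop))
        s_local = np.zeros(len(state.pop))
        theta = np.zeros(len(state.pop))
        tau = np.zeros(len(state.pop))
        for gi, g in enumerate(GUILDS):
            m = state.pop.guild_idx == gi
            if not np.any(m):
                continue
            gp = p.guild(g)
            em_lat = np.expm1(rates.mu[g] * dt)
            expm1_cells[m] = np.sum(w[m] * em_lat[ix[m], iy[m]], axis=1)
            s_local[m] = np.sum(
                w[m] * fields.concentrations[gp.substrate][ix[m], iy[m]], axis=1)
            theta[m] = gp.death_threshold
            tau[m] = gp.death_duration
        state.pop.biomass = state.pop.biomass * (1.0 + expm1_cells)
        state.pop.radius = radius_from_biomass(state.pop.biomass, state.pop.density)
        starving = s_local < theta
        state.pop.clock = np.where(starving, state.pop.clock + dt, 0.0)
        dying = state.pop.clock >= tau
        if np.any(dying):
            removed = state.pop.remove(dying)
            state.dead.x = np.concatenate([state.dead.x, removed.x])
            state.dead.y = np.concatenate([state.dead.y, removed.y])
            state.dead.radius = np.concatenate([state.dead.radius, removed.radius])
            state.dead.biomass = np.concatenate([state.dead.biomass, removed.biomass])
            state.dead.time_of_death = np.concatenate(
                [state.dead.time_of_death, np.full(len(removed), t0 + dt)])
            state.dead.guild_idx = np.concatenate(
                [state.dead.guild_idx, removed.guild_idx])

    # (4) division
    if len(state.pop):
        div_radius = np.array(
            [p.guild(GUILDS[gi]).division_radius for gi in state.pop.guild_idx])
        due = np.flatnonzero(state.pop.radius >= div_radius)
        if due.size:
            daughters = []
            for i in due:
                d1, d2 = divide(state.pop.cell(int(i)), state.rng)
                daughters.extend([d1, d2])
            mask = np.zeros(len(state.pop), dtype=bool)
            mask[due] = True
            state.pop.remove(mask)
            state.pop.add(daughters)

    # (5) shoving; pressure equilibration through a dense pack is diffusive,
    # so a sub-radius standing residual is normal and does not accumulate
    residual = shove_relax(state.pop, state.dead, p.geometry, state.rng)
    if residual > 1.0:
        log.debug("t=%.1f h: shoving cap hit, residual overlap %.3f um",
                  t0, residual)

    # (6) sloughing
    washout, washout_dead = slough(state.pop, state.dead, p.geometry)
    for g, pg in washout.items():
        state.washout[g] += pg * 1e-12  # pg -> g
    state.washout_dead += washout_dead * 1e-12

    # (7) due introduction events (feed changes take effect next solve)
    for ev in spec.events:
        if t0 < ev.time <= t0 + dt:
            added = introduce_species(
                state.pop, state.dead, ev, p.geometry,
                p.guild(ev.guild).density, state.rng)
            state.events_applied += 1
            log.info("t=%.1f h: introduced %d %s cells", t0 + dt, added, ev.guild)

    # (8b) clock
    state.time = t0 + dt
    return state


@dataclass
class RunResult:
    """Final state plus the recorded time series of one scenario run."""

    spec: ScenarioSpec
    state: SimulationState
    timeseries: pd.DataFrame


def _record(state: SimulationState, p: ParameterSet) -> dict[str, float]:
    row: dict[str, float] = {"time_h": state.time}
    bio = state.pop.biomass_by_guild()
    census = state.pop.census()
    for g in GUILDS:
        row[f"biomass_pg[{g}]"] = bio[g]
        row[f"census[{g}]"] = census[g]
    row["dead_pg"] = state.dead.total_biomass()
    row["granule_diameter_um"] = 2.0 * granule_radius(state.pop, state.dead, p.geometry)
    for s in SOLUTES:
        row[f"produced_g[{s}]"] = state.produced[s]
    row["washout_g"] = sum(state.washout.values()) + state.washout_dead
    return row


def run(spec: ScenarioSpec,
        on_snapshot: Callable[[SimulationState], None] | None = None,
        ) -> RunResult:
    """Execute a scenario to its duration, recording the time series.

    ``on_snapshot`` (optional) is called at every snapshot interval and at
    the end, e.g. to write agent/field files to disk.
    """
    p = spec.parameters
    state = initial_state(spec)
    rows = [_record(state, p)]
    n_steps = int(round(spec.duration / p.dt))
    next_snap = spec.snapshot_interval
    if on_snapshot is not None:
        on_snapshot(state)
    try:
        for _ in range(n_steps):
            step(state, spec, p)
            if state.time + 1e-9 >= next_snap:
                rows.append(_record(state, p))
                if on_snapshot is not None:
                    on_snapshot(state)
                next_snap += spec.snapshot_interval
    except Exception as err:
        # flush what exists so a failed run is still inspectable
        rows.append(_record(state, p))
        err.partial_result = RunResult(  # type: ignore[attr-defined]
            spec=spec, state=state, timeseries=pd.DataFrame(rows))
        raise
    if rows[-1]["time_h"] != state.time:
        rows.append(_record(state, p))
        if on_snapshot is not None:
            on_snapshot(state)
    return RunResult(spec=spec, state=state, timeseries=pd.DataFrame(rows))


def state_hash(state: SimulationState) -> str:
    """Deterministic digest of the full agent + field + ledger state."""
    h = hashlib.sha256()
    h.update(np.float64(state.time).tobytes())
    for arr in (state.pop.guild_idx, state.pop.x, state.pop.y, state.pop.radius,
                state.pop.biomass, state.pop.clock, state.pop.ids,
                state.dead.x, state.dead.y, state.dead.biomass):
        h.update(np.ascontiguousarray(arr).tobytes())
    for s in SOLUTES:
        h.update(np.ascontiguousarray(state.fields.concentrations[s]).tobytes())
        h.update(np.float64(state.produced[s]).tobytes())
    return h.hexdigest()


# --- preset library --------------------------------------------------------

PRESET_NAMES = (
    "cellobiose-1.5",
    "cellobiose-1.0",
    "no-desulfovibrio",
    "reintroduce-d-day16",
    "reintroduce-d-m2-day16",
    "oleate-cellobiose-1.5",
    "oleate-cellobiose-1.5-dmax1000",
    "oleate-cellobiose-1.0",
    "oleate-cellobiose-0.5",
    "oleate-only-1.5",
)

_FIVE = ("clostridium1", "clostridium2", "desulfovibrio",
         "methanogen1", "methanogen2")
_NO_D = ("clostridium1", "clostridium2", "methanogen1", "methanogen2")


def preset(name: str, seed: int = 1, reduced: bool = False) -> ScenarioSpec:
    """Return one of the ten shipped experiment presets.

    Full-scale presets use the 508 um domain (127 x 127 lattice), a 500 um
    sloughing diameter and a 42-day horizon with augmentation /
    re-introduction at t = 408 h (day 17).  With ``reduced=True`` the same
    experiments are mapped onto the documented half-scale study conditions
    (256 um domain, 64 x 64 lattice, 200 um sloughing diameter, 10-day
    horizon, events on day 4), which preserve the qualitative regimes while
    keeping runs desk-scale; see docs/methods.md.
    """
    if name not in PRESET_NAMES:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {', '.join(PRESET_NAMES)}")
    p = default_parameters()
    if reduced:
        p.geometry.side = 256.0
        p.geometry.max_granule_diameter = 200.0
        duration, t_event = 240.0, 96.0
        inoc_radius, snap = 30.0, 12.0
    else:
        duration, t_event = 1008.0, 408.0
        inoc_radius, snap = 40.0, 24.0

    def base(cellobiose: float, guilds=_FIVE, **kw) -> ScenarioSpec:
        p.solutes.bulk["cellobiose"] = cellobiose
        return ScenarioSpec(
            name=name, parameters=p, duration=duration, seed=seed,
            snapshot_interval=snap, initial_guilds=guilds,
            inoculum_radius=inoc_radius, **kw)

    def oleate_feed(level: float, halt_cellobiose: bool = False) -> FeedSchedule:
        changes = {"oleate": [(t_event, level)]}
        if halt_cellobiose:
            changes["cellobiose"] = [(t_event, 0.0)]
        return FeedSchedule(changes)

    o_event = IntroductionEvent(guild="oleate_degrader", time=t_event)
    if name == "cellobiose-1.5":
        return base(1.5)
    if name == "cellobiose-1.0":
        return base(1.0)
    if name == "no-desulfovibrio":
        return base(1.5, guilds=_NO_D)
    if name == "reintroduce-d-day16":
        return base(1.5, guilds=_NO_D,
                    events=[IntroductionEvent(guild="desulfovibrio", time=t_event)])
    if name == "reintroduce-d-m2-day16":
        return base(1.5, guilds=_NO_D,
                    events=[IntroductionEvent(guild="desulfovibrio", time=t_event),
                            IntroductionEvent(guild="methanogen2", time=t_event)])
    if name == "oleate-cellobiose-1.5":
        return base(1.5, events=[o_event], feed=oleate_feed(1.5))
    if name == "oleate-cellobiose-1.5-dmax1000":
        p.geometry.max_granule_diameter = 1000.0 if not reduced else 400.0
        return base(1.5, events=[o_event], feed=oleate_feed(1.5))
    if name == "oleate-cellobiose-1.0":
        return base(1.0, events=[o_event], feed=oleate_feed(1.0))
    if name == "oleate-cellobiose-0.5":
        return base(0.5, events=[o_event], feed=oleate_feed(0.5))
    if name == "oleate-only-1.5":
        return base(1.5, events=[o_event],
                    feed=oleate_feed(1.5, halt_cellobiose=True))
    raise AssertionError("unreachable")


# --- scenario from XML configuration --------------------------------------

def scenario_from_config(source) -> ScenarioSpec:
    """Build a full ScenarioSpec (parameters + schedule + events) from XML.

    Uses the same document as :func:`granulesim.parameters.load_parameters`,
    plus ``<simulation duration randomSeed snapshotEvery>``, ``<event>``,
    ``<feed>`` and ``<inoculum>`` elements (see docs/config_schema.md).
    """
    from lxml import etree

    p = load_parameters(source)
    if isinstance(source, str) and source.lstrip().startswith("<"):
        root = etree.fromstring(source.encode())
    else:
        root = etree.parse(source).getroot()
    sim = root.find("simulation")
    duration = float(sim.get("duration")) if sim is not None and sim.get("duration") \
        else 1008.0
    seed = int(float(sim.get("randomSeed"))) if sim is not None and sim.get("randomSeed") \
        else 1
    snap = float(sim.get("snapshotEvery")) if sim is not None and sim.get("snapshotEvery") \
        else 24.0

    events = []
    for el in root.findall("event"):
        guild = el.get("species")
        if guild is None:
            raise ConfigurationError("event: missing mandatory @species")
        if el.get("time") is None:
            raise ConfigurationError("event: missing mandatory @time")
        sites = None
        site_els = el.findall("site")
        if site_els:
            sites = []
            for s_el in site_els:  # @z accepted but ignored (2-D model)
                if s_el.get("x") is None or s_el.get("y") is None:
                    raise ConfigurationError("event/site: missing @x or @y")
                sites.append((float(s_el.get("x")), float(s_el.get("y"))))
        events.append(IntroductionEvent(
            guild=guild, time=float(el.get("time")), sites=sites,
            cells_per_site=int(el.get("cellsPerSite", "1")),
            biomass=float(el.get("biomass", "20.0"))))

    changes: dict[str, list[tuple[float, float]]] = {}
    for el in root.findall("feed"):
        solute = el.get("solute")
        if solute is None or el.get("time") is None or el.get("bulk") is None:
            raise ConfigurationError("feed: requires @solute, @time and @bulk")
        changes.setdefault(solute, []).append(
            (float(el.get("time")), float(el.get("bulk"))))
    for steps in changes.values():
        steps.sort()

    kw: dict = {}
    inoc = root.find("inoculum")
    if inoc is not None:
        if inoc.get("guilds"):
            kw["initial_guilds"] = tuple(
                g.strip() for g in inoc.get("guilds").split(","))
        if inoc.get("cells"):
            kw["inoculum_cells"] = int(inoc.get("cells"))
        if inoc.get("radius"):
            kw["inoculum_radius"] = float(inoc.get("radius"))
        if inoc.get("biomass"):
            kw["initial_biomass"] = float(inoc.get("biomass"))

    return ScenarioSpec(
        name=root.get("name", "custom"), parameters=p, duration=duration,
        seed=seed, snapshot_interval=snap, feed=FeedSchedule(changes),
        events=events, **kw)


__all__ = [
    "FeedSchedule", "ScenarioSpec", "SimulationState", "RunResult",
    "initial_state", "step", "run", "state_hash", "preset", "PRESET_NAMES",
    "scenario_from_config",
]
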