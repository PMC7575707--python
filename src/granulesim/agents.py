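"""Individual-based layer: spherical cells, division, shoving, sloughing.

Agents are spheres characterized by guild, centre, radius and biomass.  The
population is stored as structure-of-arrays (:class:`Population`) so that
growth, neighbour search and relaxation vectorize; :class:`Cell` and
:class:`DeadCell` are the per-agent views used at module boundaries.

Mechanical interaction is shoving only: overlapping neighbours are pushed
apart along their centre line until residual overlap is negligible.  Dead
cells are inert (no uptake, no lysis) but keep occupying space, so cavities
of dead biomass persist inside the granule and keep reducing local
diffusivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .parameters import GUILDS, DomainGeometry, radius_from_biomass

GUILD_INDEX = {g: i for i, g in enumerate(GUILDS)}


@dataclass
class Cell:
    """One live spherical agent."""

    guild: str
    x: float
    y: float
    radius: float
    biomass: float  # pg
    clock: float = 0.0  # consecutive hours below the death threshold
    id: int = -1
    birth_time: float = 0.0
    density: float = 1.5e-13  # g/um^3


@dataclass
class DeadCell:
    """An inert dead agent; immutable except for removal by sloughing."""

    x: float
    y: float
    radius: float
    biomass: float  # pg
    time_of_death: float = 0.0
    guild: str | None = None  # guild of origin, for washout bookkeeping


@dataclass
class IntroductionEvent:
    """Timed seeding of a guild around the granule (bioaugmentation).

    ``sites`` may list explicit (x, y) coordinates; when None, four seed
    sites are auto-placed at the corners of the square just enclosing the
    current granule, i.e. "in close vicinity" of its outer surface.
    """

    guild: str
    time: float  # h
    sites: list[tuple[float, float]] | None = None
    cells_per_site: int = 1
    biomass: float = 20.0  # pg per seeded cell


class Population:
    """Structure-of-arrays container for the live agents."""

    _FIELDS = ("x", "y", "radius", "biomass", "clock", "birth_time")

    def __init__(self) -> None:
        self.guild_idx = np.zeros(0, dtype=np.int64)
        for f in self._FIELDS:
            setattr(self, f, np.zeros(0, dtype=float))
        self.ids = np.zeros(0, dtype=np.int64)
        self._next_id = 0
        self.density = np.zeros(0, dtype=float)

    def __len__(self) -> int:
        return self.guild_idx.size

    def add(self, cells: Iterable[Cell]) -> None:
        cells = list(cells)
        if not cells:
            return
        self.guild_idx = np.concatenate(
            [self.guild_idx, [GUILD_INDEX[c.guild] for c in cells]])
        for f in self._FIELDS:
            setattr(self, f, np.concatenate(
                [getattr(self, f), [getattr(c, f) for c in cells]]))
        new_ids = []
        for c in cells:
            if c.id < 0:
                new_ids.append(self._next_id)
                self._next_id += 1
            else:
                new_ids.append(c.id)
                self._next_id = max(self._next_id, c.id + 1)
        self.ids = np.concatenate([self.ids, new_ids]).astype(np.int64)
        self.density = np.concatenate([self.density, [c.density for c in cells]])

    def cell(self, i: int) -> Cell:
        return Cell(guild=GUILDS[self.guild_idx[i]], x=float(self.x[i]),
                    y=float(self.y[i]), radius=float(self.radius[i]),
                    biomass=float(self.biomass[i]), clock=float(self.clock[i]),
                    id=int(self.ids[i]), birth_time=float(self.birth_time[i]),
                    density=float(self.density[i]))

    def cells(self) -> list[Cell]:
        return [self.cell(i) for i in range(len(self))]

    def remove(self, mask: np.ndarray) -> "Population":
        """Remove agents where ``mask`` is True; returns the removed subset."""
        removed = Population()
        keep = ~mask
        removed.guild_idx = self.guild_idx[mask]
        removed.ids = self.ids[mask]
        removed.density = self.density[mask]
        for f in self._FIELDS:
            setattr(removed, f, getattr(self, f)[mask])
        self.guild_idx = self.guild_idx[keep]
        self.ids = self.ids[keep]
        self.density = self.density[keep]
        for f in self._FIELDS:
            setattr(self, f, getattr(self, f)[keep])
        return removed

    def census(self) -> dict[str, int]:
        return {g: int(np.sum(self.guild_idx == i)) for i, g in enumerate(GUILDS)}

    def biomass_by_guild(self) -> dict[str, float]:
        return {g: float(self.biomass[self.guild_idx == i].sum())
                for i, g in enumerate(GUILDS)}


class DeadPool:
    """Structure-of-arrays container for the inert dead agents."""

    def __init__(self) -> None:
        self.x = np.zeros(0, dtype=float)
        self.y = np.zeros(0, dtype=float)
        self.radius = np.zeros(0, dtype=float)
        self.biomass = np.zeros(0, dtype=float)
        self.time_of_death = np.zeros(0, dtype=float)
        self.guild_idx = np.zeros(0, dtype=np.int64)

    def __len__(self) -> int:
        return self.x.size

    def add(self, dead: Iterable[DeadCell]) -> None:
        dead = list(dead)
        if not dead:
            return
        self.x = np.concatenate([self.x, [d.x for d in dead]])
        self.y = np.concatenate([self.y, [d.y for d in dead]])
        self.radius = np.concatenate([self.radius, [d.radius for d in dead]])
        self.biomass = np.concatenate([self.biomass, [d.biomass for d in dead]])
        self.time_of_death = np.concatenate(
            [self.time_of_death, [d.time_of_death for d in dead]])
        self.guild_idx = np.concatenate(
            [self.guild_idx,
             [GUILD_INDEX.get(d.guild, -1) for d in dead]]).astype(np.int64)

    def remove(self, mask: np.ndarray) -> "DeadPool":
        removed = DeadPool()
        keep = ~mask
        for f in ("x", "y", "radius", "biomass", "time_of_death", "guild_idx"):
            setattr(removed, f, getattr(self, f)[mask])
            setattr(self, f, getattr(self, f)[keep])
        return removed

    def total_biomass(self) -> float:
        return float(self.biomass.sum())


def divide(cell: Cell, rng: np.random.Generator,
           epsilon: float = 0.05) -> tuple[Cell, Cell]:
    """Split a cell into two daughters; total biomass conserved exactly.

    The biomass fraction of the first daughter is drawn uniformly from
    0.5 +/- epsilon; the daughters are placed tangentially along a uniformly
    random direction, centred on the parent position.
    """
    frac = 0.5 + rng.uniform(-epsilon, epsilon)
    b1 = cell.biomass * frac
    b2 = cell.biomass - b1
    r1 = radius_from_biomass(b1, cell.density)
    r2 = radius_from_biomass(b2, cell.density)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    ux, uy = math.cos(theta), math.sin(theta)
    sep = (r1 + r2) / 2.0
    d1 = Cell(guild=cell.guild, x=cell.x + ux * sep, y=cell.y + uy * sep,
              radius=r1, biomass=b1, clock=cell.clock, id=cell.id,
              birth_time=cell.birth_time, density=cell.density)
    d2 = Cell(guild=cell.guild, x=cell.x - ux * sep, y=cell.y - uy * sep,
              radius=r2, biomass=b2, clock=cell.clock, id=-1,
              birth_time=cell.birth_time, density=cell.density)
    return d1, d2


def relax_overlaps(x: np.ndarray, y: np.ndarray, r: np.ndarray,
                   side: float, rng: np.random.Generator,
                   tol: float = 0.1, max_iter: int = 60,
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Jacobi-style shoving on raw coordinate arrays.

    Each overlapping pair is displaced along its centre line by half the
    overlap (each member by a quarter, summed over a node's pairs), until the
    maximum residual overlap falls below ``tol`` um or the iteration cap is
    hit.  Centres are kept inside the domain.  Returns the new coordinates
    and the final residual overlap.
    """
    if x.size < 2:
        return x, y, 0.0
    x = x.copy()
    y = y.copy()
    residual = 0.0
    for _ in range(max_iter):
        tree = cKDTree(np.column_stack([x, y]))
        pairs = tree.query_pairs(2.0 * float(r.max()), output_type="ndarray")
        if pairs.size == 0:
            return x, y, 0.0
        i, j = pairs[:, 0], pairs[:, 1]
        dx = x[i] - x[j]
        dy = y[i] - y[j]
        dist = np.hypot(dx, dy)
        overlap = r[i] + r[j] - dist
        hit = overlap > 0
        residual = float(overlap.max(initial=0.0))
        if residual <= tol:
            return x, y, residual
        i, j, dx, dy, dist, overlap = (a[hit] for a in (i, j, dx, dy, dist, overlap))
        coincident = dist < 1e-9
        if np.any(coincident):
            ang = rng.uniform(0.0, 2.0 * math.pi, size=int(coincident.sum()))
            dx[coincident] = np.cos(ang) * 1e-6
            dy[coincident] = np.sin(ang) * 1e-6
            dist[coincident] = 1e-6
        # each member of a pair moves by half the overlap along the centre line
        push = overlap / dist
        mx = np.zeros_like(x)
        my = np.zeros_like(y)
        np.add.at(mx, i, dx * push * 0.5)
        np.add.at(my, i, dy * push * 0.5)
        np.add.at(mx, j, -dx * push * 0.5)
        np.add.at(my, j, -dy * push * 0.5)
        x += mx
        y += my
        np.clip(x, 0.0, side, out=x)
        np.clip(y, 0.0, side, out=y)
    return x, y, residual


def shove_relax(pop: Population, dead: DeadPool, geometry: DomainGeometry,
                rng: np.random.Generator, tol: float = 0.1,
                max_iter: int = 100) -> float:
    """Relax overlaps among all agents in place (live and dead together).

    Dead biomass occupies space, so it participates in the mechanics and can
    be displaced outward by growth pressure.  Returns the residual overlap;
    a positive value above ``tol`` means the iteration cap was hit (logged
    by the caller as a warning).
    """
    n_live = len(pop)
    x = np.concatenate([pop.x, dead.x])
    y = np.concatenate([pop.y, dead.y])
    r = np.concatenate([pop.radius, dead.radius])
    if x.size < 2:
        return 0.0
    x, y, residual = relax_overlaps(x, y, r, geometry.side, rng,
                                    tol=tol, max_iter=max_iter)
    pop.x, pop.y = x[:n_live], y[:n_live]
    dead.x, dead.y = x[n_live:], y[n_live:]
    return residual


def slough(pop: Population, dead: DeadPool, geometry: DomainGeometry,
           ) -> tuple[dict[str, float], float]:
    """Destroy all biomass whose centre lies beyond the sloughing radius.

    Models shear-driven detachment in an upflow reactor: any live or dead
    agent farther than ``max_granule_diameter / 2`` from the granule centre
    (boundary inclusive: a centre exactly at the radius is retained) is
    removed.  Returns (washout per guild in pg, dead washout in pg).
    """
    cx, cy = geometry.center
    rmax = geometry.max_radius
    live_out = np.hypot(pop.x - cx, pop.y - cy) > rmax
    removed = pop.remove(live_out)
    washout = {g: float(removed.biomass[removed.guild_idx == i].sum())
               for i, g in enumerate(GUILDS)}
    dead_out = np.hypot(dead.x - cx, dead.y - cy) > rmax
    removed_dead = dead.remove(dead_out)
    return washout, float(removed_dead.biomass.sum())


def granule_radius(pop: Population, dead: DeadPool,
                   geometry: DomainGeometry) -> float:
    """Outer radius of the granule: max centre distance + agent radius."""
    cx, cy = geometry.center
    x = np.concatenate([pop.x, dead.x])
    y = np.concatenate([pop.y, dead.y])
    r = np.concatenate([pop.radius, dead.radius])
    if x.size == 0:
        return 0.0
    return float(np.max(np.hypot(x - cx, y - cy) + r))


def corner_sites(pop: Population, dead: DeadPool, geometry: DomainGeometry,
                 margin: float) -> list[tuple[float, float]]:
    """Four corner seed sites just outside the current granule surface."""
    cx, cy = geometry.center
    rg = granule_radius(pop, dead, geometry) + margin
    c = rg / math.sqrt(2.0)
    return [(cx + sx * c, cy + sy * c) for sx in (-1, 1) for sy in (-1, 1)]


def introduce_species(pop: Population, dead: DeadPool, event: IntroductionEvent,
                      geometry: DomainGeometry, density: float,
                      rng: np.random.Generator) -> int:
    """Seed the event's cells around the granule; returns the number added.

    A seed site overlapping existing biomass is displaced outward along the
    ray from the granule centre until clear.  Coordinates outside the domain
    raise a configuration error.
    """
    from .parameters import ConfigurationError

    sites = event.sites
    seed_radius = radius_from_biomass(event.biomass, density)
    if sites is None:
        sites = corner_sites(pop, dead, geometry, margin=seed_radius + 1.0)
    cx, cy = geometry.center
    x_all = np.concatenate([pop.x, dead.x])
    y_all = np.concatenate([pop.y, dead.y])
    r_all = np.concatenate([pop.radius, dead.radius])
    new_cells: list[Cell] = []
    for (sx, sy) in sites:
        if not (0 <= sx <= geometry.side and 0 <= sy <= geometry.side):
            raise ConfigurationError(
                f"introduction site ({sx}, {sy}) outside the domain")
        px, py = float(sx), float(sy)
        if x_all.size:
            vx, vy = px - cx, py - cy
            norm = math.hypot(vx, vy)
            ux, uy = (vx / norm, vy / norm) if norm > 1e-9 else (1.0, 0.0)
            for _ in range(1000):
                clear = np.all(np.hypot(x_all - px, y_all - py)
                               >= r_all + seed_radius - 1e-9)
                if clear:
                    break
                px += ux * 1.0
                py += uy * 1.0
        px = min(max(px, 0.0), geometry.side)
        py = min(max(py, 0.0), geometry.side)
        for k in range(event.cells_per_site):
            jx = rng.uniform(-0.1, 0.1) if k else 0.0
            jy = rng.uniform(-0.1, 0.1) if k else 0.0
            new_cells.append(Cell(
                guild=event.guild, x=px + jx, y=py + jy, radius=seed_radius,
                biomass=event.biomass, clock=0.0, birth_time=event.time,
                density=density))
    pop.add(new_cells)
    return len(new_cells)


__all__ = [
    "Cell", "DeadCell", "IntroductionEvent", "Population", "DeadPool",
    "divide", "relax_overlaps", "shove_relax", "slough", "granule_radius",
    "corner_sites", "introduce_species", "GUILD_INDEX",
]
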