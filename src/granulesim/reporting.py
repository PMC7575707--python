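"""Turn run outputs into reportable quantities and figures.

Gas totals are emitted in three unit systems -- cumulative mass (g), gas
volume at standard conditions (L, via the molar volume 22.414 L/mol) and
concentration over the domain volume (mg/L, using the slab-thickness volume
convention) -- so results can be compared against either reporting style
used in the granular-sludge literature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .agents import granule_radius
from .engine import SimulationState
from .parameters import (
    GUILDS, MOLAR_MASS, MOLAR_VOLUME_L, SOLUTES, DomainGeometry,
)

#: rendering palette: one colour per guild plus black for dead biomass
PALETTE = {
    "clostridium1": "#2ca02c",    # green
    "clostridium2": "#9467bd",    # purple
    "oleate_degrader": "#d62728", # red
    "desulfovibrio": "#ffd700",   # yellow
    "methanogen1": "#1f77b4",     # blue
    "methanogen2": "#1f77b4",     # blue (both methanogen guilds)
    "dead": "#000000",
}


@dataclass
class GasReport:
    """Cumulative production of one gaseous product in three unit systems."""

    solute: str
    mass_g: float
    volume_L: float
    concentration_mg_per_L: float


def gas_report(state: SimulationState, geometry: DomainGeometry,
               ) -> dict[str, GasReport]:
    """Convert the production ledgers of methane and hydrogen to all units."""
    out = {}
    for solute, molar_mass in MOLAR_MASS.items():
        mass = state.produced[solute]
        out[solute] = GasReport(
            solute=solute,
            mass_g=mass,
            volume_L=mass / molar_mass * MOLAR_VOLUME_L,
            concentration_mg_per_L=mass * 1e3 / geometry.domain_volume_litres,
        )
    return out


def composition_fractions(state: SimulationState, weight: str = "biomass",
                          ) -> dict[str, float]:
    """Granule composition: per-guild fractions plus a separate "dead" class.

    ``weight`` selects biomass-weighted (default) or cell-count-weighted
    fractions.  Fractions sum to 1; an empty granule returns all zeros.
    """
    if weight == "biomass":
        values = state.pop.biomass_by_guild()
        values["dead"] = state.dead.total_biomass()
    elif weight == "count":
        values = {g: float(c) for g, c in state.pop.census().items()}
        values["dead"] = float(len(state.dead))
    else:
        raise ValueError(f"weight must be 'biomass' or 'count', got {weight!r}")
    total = sum(values.values())
    if total == 0:
        return {k: 0.0 for k in values}
    return {k: v / total for k, v in values.items()}


def radial_profile(state: SimulationState, geometry: DomainGeometry,
                   n_bins: int = 10):
    """Per-guild biomass density versus radius, plus a mixing index.

    Equal-width annuli span the granule centre out to the sloughing radius;
    densities are biomass per annulus area (pg/um^2).  The mixing index of a
    guild is the population variance of its annulus biomass shares relative
    to the annulus area shares: 0 for a perfectly area-proportional (well
    mixed) layout, larger for stratified or pocketed layouts.

    Returns ``(edges, density, mixing)`` where ``density`` maps guild (and
    "dead") to an array of length ``n_bins``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    cx, cy = geometry.center
    edges = np.linspace(0.0, geometry.max_radius, n_bins + 1)
    area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    area_share = area / area.sum()
    density: dict[str, np.ndarray] = {}
    mixing: dict[str, float] = {}

    def profile(x, y, biomass):
        rr = np.hypot(x - cx, y - cy)
        mass, _ = np.histogram(rr, bins=edges, weights=biomass)
        return mass

    groups = {}
    for gi, g in enumerate(GUILDS):
        m = state.pop.guild_idx == gi
        groups[g] = (state.pop.x[m], state.pop.y[m], state.pop.biomass[m])
    groups["dead"] = (state.dead.x, state.dead.y, state.dead.biomass)
    for g, (x, y, b) in groups.items():
        mass = profile(x, y, b)
        density[g] = mass / area
        total = mass.sum()
        if total > 0:
            share = mass / total
            mixing[g] = float(np.mean((share - area_share) ** 2))
        else:
            mixing[g] = 0.0
    return edges, density, mixing


# --- text snapshots --------------------------------------------------------

def write_agent_snapshot(state: SimulationState, path) -> None:
    """One row per agent: id, guild, x, y, radius, biomass, alive, birth time."""
    lines = ["id\tguild\tx_um\ty_um\tradius_um\tbiomass_pg\talive\tbirth_h"]
    for i in range(len(state.pop)):
        c = state.pop.cell(i)
        lines.append(f"{c.id}\t{c.guild}\t{c.x:.4f}\t{c.y:.4f}"
                     f"\t{c.radius:.4f}\t{c.biomass:.6g}\t1\t{c.birth_time:.2f}")
    d = state.dead
    for i in range(len(d)):
        g = GUILDS[d.guild_idx[i]] if d.guild_idx[i] >= 0 else "unknown"
        lines.append(f"-1\t{g}\t{d.x[i]:.4f}\t{d.y[i]:.4f}"
                     f"\t{d.radius[i]:.4f}\t{d.biomass[i]:.6g}\t0"
                     f"\t{d.time_of_death[i]:.2f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_field_snapshots(state: SimulationState, outdir, prefix: str = "") -> None:
    """One delimited-text grid per solute."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in SOLUTES:
        np.savetxt(outdir / f"{prefix}{s}.tsv",
                   state.fields.concentrations[s], delimiter="\t", fmt="%.6e")


def summary(state: SimulationState, geometry: DomainGeometry) -> dict:
    """JSON-ready run summary: ledgers, composition, geometry, gas units."""
    gases = gas_report(state, geometry)
    return {
        "time_h": state.time,
        "census": state.pop.census(),
        "biomass_pg": state.pop.biomass_by_guild(),
        "dead_biomass_pg": state.dead.total_biomass(),
        "granule_diameter_um": 2.0 * granule_radius(state.pop, state.dead, geometry),
        "composition": composition_fractions(state),
        "produced_g": dict(state.produced),
        "consumed_g": dict(state.consumed),
        "washout_g": dict(state.washout),
        "gas": {s: vars(r) for s, r in gases.items()},
    }


def write_summary(state: SimulationState, geometry: DomainGeometry, path) -> None:
    Path(path).write_text(json.dumps(summary(state, geometry), indent=2) + "\n")


# --- rendering -------------------------------------------------------------

def render_composition(state: SimulationState, geometry: DomainGeometry,
                       path=None):
    """Composition map: agents drawn as coloured discs on the domain."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PatchCollection
    from matplotlib.patches import Circle

    fig, ax = plt.subplots(figsize=(5, 5))
    patches, colors = [], []
    for i in range(len(state.dead)):
        patches.append(Circle((state.dead.x[i], state.dead.y[i]),
                              state.dead.radius[i]))
        colors.append(PALETTE["dead"])
    for i in range(len(state.pop)):
        patches.append(Circle((state.pop.x[i], state.pop.y[i]),
                              state.pop.radius[i]))
        colors.append(PALETTE[GUILDS[state.pop.guild_idx[i]]])
    ax.add_collection(PatchCollection(patches, facecolor=colors, edgecolor="none"))
    ax.set_xlim(0, geometry.side)
    ax.set_ylim(0, geometry.side)
    ax.set_aspect("equal")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_title(f"t = {state.time:.0f} h")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def render_field(state: SimulationState, solute: str, geometry: DomainGeometry,
                 path=None):
    """Heat map of one solute concentration field."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(state.fields.concentrations[solute].T, origin="lower",
                   extent=(0, geometry.side, 0, geometry.side), cmap="viridis")
    fig.colorbar(im, ax=ax, label=f"{solute} (g/L)")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_title(f"{solute}, t = {state.time:.0f} h")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


__all__ = [
    "GasReport", "PALETTE", "gas_report", "composition_fractions",
    "radial_profile", "write_agent_snapshot", "write_field_snapshots",
    "summary", "write_summary", "render_composition", "render_field",
]
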