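"""Parameter registry and configuration handling.

The simulator tracks an anaerobic granule built from six microbial guilds --
two cellobiose-chain fermenters ("clostridium1" on cellobiose,
"clostridium2" on lactate), an oleate degrader, an ethanol-oxidizing
syntroph ("desulfovibrio"), an acetoclastic methanogen ("methanogen1") and a
hydrogenotrophic methanogen ("methanogen2") -- coupled to seven diffusible
solutes (cellobiose, oleate, lactate, acetate, ethanol, hydrogen, methane).

Every constant used by the kinetics, transport and agent layers is owned by
one of the dataclasses below and collected into a :class:`ParameterSet`.

Units used throughout the package:

========================  =========================
length                    micrometre (um)
time                      hour (h)
solute concentration      g per litre (g/L)
per-cell biomass          picogram (pg)
cell density              g per cubic micrometre
diffusivity               um^2 per hour
========================  =========================

The shipped numeric defaults are literature-typical values for mesophilic
anaerobic digestion communities, chosen once and documented in
``docs/methods.md``; they are not fitted to any particular dataset and every
one of them can be overridden from an XML configuration document
(see :func:`load_parameters` and ``docs/config_schema.md``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from lxml import etree

log = logging.getLogger(__name__)

# --- canonical names -------------------------------------------------------

SOLUTES: tuple[str, ...] = (
    "cellobiose",
    "oleate",
    "lactate",
    "acetate",
    "ethanol",
    "hydrogen",
    "methane",
)

GUILDS: tuple[str, ...] = (
    "clostridium1",
    "clostridium2",
    "oleate_degrader",
    "desulfovibrio",
    "methanogen1",
    "methanogen2",
)

#: growth substrate of each guild (the solute entering its uptake kinetics)
GROWTH_SUBSTRATE: dict[str, str] = {
    "clostridium1": "cellobiose",
    "clostridium2": "lactate",
    "oleate_degrader": "oleate",
    "desulfovibrio": "ethanol",
    "methanogen1": "acetate",
    "methanogen2": "hydrogen",
}

#: the single consumer guild of each solute (methane has none)
CONSUMER_OF: dict[str, str] = {s: g for g, s in GROWTH_SUBSTRATE.items()}

# unit conversion constants
LITRE_PER_UM3 = 1e-15  #: 1 um^3 = 1e-15 L
PG_PER_G = 1e12
MOLAR_MASS = {"methane": 16.04, "hydrogen": 2.016}  # g/mol
MOLAR_VOLUME_L = 22.414  # L/mol at standard conditions


class ConfigurationError(ValueError):
    """A configuration document is structurally unusable (missing field etc.)."""


class ValidationError(ValueError):
    """A parameter value violates a hard physical constraint."""


def _require_positive(name: str, value: float) -> None:
    if not (value > 0) or not math.isfinite(value):
        raise ValidationError(f"{name} must be positive and finite, got {value!r}")


# --- dataclasses -----------------------------------------------------------


@dataclass
class SoluteCatalog:
    """Diffusivities and bulk feed concentrations for the seven solutes.

    ``gamma`` is the single relative-diffusivity factor applied wherever the
    lattice node is occupied by biomass (live or dead): transport through the
    granule matrix is slower than through free liquid.
    """

    diffusivity: dict[str, float]  # um^2/h
    bulk: dict[str, float]  # g/L at the domain boundary
    gamma: float = 0.5

    def __post_init__(self) -> None:
        for s in SOLUTES:
            if s not in self.diffusivity:
                raise ConfigurationError(f"solutes/{s}: missing diffusivity")
            _require_positive(f"diffusivity[{s}]", self.diffusivity[s])
            b = self.bulk.setdefault(s, 0.0)
            if b < 0:
                raise ValidationError(f"bulk[{s}] must be >= 0, got {b}")
        if not (0 < self.gamma <= 1):
            raise ValidationError(f"gamma must lie in (0, 1], got {self.gamma}")


@dataclass
class GuildParams:
    """Kinetic, yield, death and geometric constants of one guild.

    The uptake law is Monod when ``k_i_substrate`` is None and Haldane
    (substrate self-inhibition) otherwise; ``k_i_product`` adds a
    multiplicative acetate product-inhibition factor Ki/(Ki + S_acetate).

    ``alpha_b`` is the biomass conversion rate: grams of biomass formed per
    gram of growth substrate consumed; the same alpha scales every product
    term the guild feeds.

    Death is a discrete switch: when the guild's growth substrate stays below
    ``death_threshold`` for ``death_duration`` consecutive hours, the cell is
    converted, mass intact, into the inert dead-biomass pool.
    """

    name: str
    mu_max: float  # 1/h
    k_s: float  # g/L, half-saturation on the growth substrate
    alpha_b: float  # dimensionless yield
    k_i_substrate: float | None = None  # g/L, Haldane self-inhibition
    k_i_product: float | None = None  # g/L, acetate product inhibition
    death_threshold: float = 1e-4  # g/L
    death_duration: float = 120.0  # h
    division_radius: float = 4.0  # um
    birth_radius_fraction: float = 0.5 ** (1.0 / 3.0)
    density: float = 1.5e-13  # g/um^3 (150 g/L wet biomass)

    def __post_init__(self) -> None:
        if self.name not in GUILDS:
            raise ConfigurationError(f"unknown guild {self.name!r}")
        for attr in ("mu_max", "k_s", "alpha_b", "death_duration",
                     "division_radius", "density"):
            _require_positive(f"{self.name}.{attr}", getattr(self, attr))
        for attr in ("k_i_substrate", "k_i_product"):
            v = getattr(self, attr)
            if v is not None:
                _require_positive(f"{self.name}.{attr}", v)
        if self.death_threshold < 0:
            raise ValidationError(f"{self.name}.death_threshold must be >= 0")
        if not (0 < self.birth_radius_fraction < 1):
            raise ValidationError(
                f"{self.name}.birth_radius_fraction must lie in (0, 1)")

    @property
    def substrate(self) -> str:
        return GROWTH_SUBSTRATE[self.name]

    @property
    def division_biomass(self) -> float:
        """Biomass (pg) at which the cell radius reaches the division radius."""
        return biomass_from_radius(self.division_radius, self.density)


def radius_from_biomass(biomass_pg: float, density: float):
    """Spherical radius (um) of a cell of ``biomass_pg`` pg at ``density`` g/um^3."""
    grams = biomass_pg / PG_PER_G
    return (3.0 * grams / (4.0 * math.pi * density)) ** (1.0 / 3.0)


def biomass_from_radius(radius_um: float, density: float):
    """Inverse of :func:`radius_from_biomass` (returns pg)."""
    return (4.0 / 3.0) * math.pi * radius_um**3 * density * PG_PER_G


@dataclass
class DomainGeometry:
    """Square 2-D computational domain holding one granule.

    The granule centre is pinned to the domain centre (the inoculum is seeded
    there) and sloughing removes any agent whose centre lies beyond
    ``max_granule_diameter / 2`` from it.  A slab thickness equal to the grid
    spacing converts 2-D lattice areas into volumes for mass bookkeeping.
    """

    side: float = 508.0  # um
    spacing: float = 4.0  # um
    max_granule_diameter: float = 500.0  # um
    slab: float | None = None  # um; defaults to spacing

    def __post_init__(self) -> None:
        _require_positive("side", self.side)
        _require_positive("spacing", self.spacing)
        _require_positive("max_granule_diameter", self.max_granule_diameter)
        if self.slab is None:
            self.slab = self.spacing
        _require_positive("slab", self.slab)
        n = self.side / self.spacing
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"domain side {self.side} is not a multiple of spacing {self.spacing}")

    @property
    def n(self) -> int:
        """Number of lattice nodes along each axis."""
        return int(round(self.side / self.spacing))

    @property
    def center(self) -> tuple[float, float]:
        return (self.side / 2.0, self.side / 2.0)

    @property
    def max_radius(self) -> float:
        return self.max_granule_diameter / 2.0

    @property
    def node_volume(self) -> float:
        """Volume of one lattice node (um^3), using the slab convention."""
        return self.spacing * self.spacing * self.slab

    @property
    def domain_volume_litres(self) -> float:
        return self.side * self.side * self.slab * LITRE_PER_UM3


@dataclass
class SolverSettings:
    """Numerical controls of the pseudo-steady-state reaction-diffusion solve."""

    tol: float = 1e-6  # relative L-inf convergence of Picard iterates
    max_outer: int = 200
    relax: float = 0.7  # Picard under-relaxation
    cap_factor: float = 10.0  # warn if a substrate exceeds cap_factor * bulk

    def __post_init__(self) -> None:
        _require_positive("solver.tol", self.tol)
        _require_positive("solver.max_outer", self.max_outer)
        if not (0 < self.relax <= 1):
            raise ValidationError(f"solver.relax must lie in (0, 1], got {self.relax}")


@dataclass
class ParameterSet:
    """Complete, validated parameter state of one simulation."""

    solutes: SoluteCatalog
    guilds: dict[str, GuildParams]
    geometry: DomainGeometry = field(default_factory=DomainGeometry)
    solver: SolverSettings = field(default_factory=SolverSettings)
    dt: float = 0.5  # h, global timestep
    oleate_to_acetate: bool = True  # oleate degraders feed the acetate pool
    #: names of fields filled from the default registry by load_parameters()
    substituted_defaults: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _require_positive("dt", self.dt)
        missing = [g for g in GUILDS if g not in self.guilds]
        if missing:
            raise ConfigurationError(f"missing guild parameter sets: {missing}")

    def guild(self, name: str) -> GuildParams:
        try:
            return self.guilds[name]
        except KeyError:
            raise ConfigurationError(f"unknown guild {name!r}") from None


# --- default registry ------------------------------------------------------

#: Effective diffusivities (um^2/h) of the solutes in dense granular sludge,
#: literature-typical biofilm values (well below infinite-dilution aqueous
#: numbers: the granule matrix hinders transport even before the gamma
#: factor applies); see docs/methods.md.
_DEFAULT_DIFFUSIVITY = {
    "cellobiose": 4.0e5,
    "oleate": 1.0e5,
    "lactate": 2.0e6,
    "acetate": 1.5e6,
    "ethanol": 1.6e6,
    "hydrogen": 6.0e6,
    "methane": 2.0e6,
}

_DEFAULT_BULK = {
    "cellobiose": 1.5,
    "oleate": 0.0,
    "lactate": 0.0,
    "acetate": 0.0,
    "ethanol": 0.0,
    "hydrogen": 0.0,
    "methane": 0.0,
}

# Literature-typical kinetic defaults for mesophilic anaerobic digestion
# (maximum rates on the per-day scale usual in digestion models);
# rationale per guild in docs/methods.md.
_DEFAULT_GUILDS: dict[str, dict] = {
    "clostridium1": dict(mu_max=0.10, k_s=4.5, alpha_b=0.15,
                         death_threshold=1e-4, death_duration=96.0),
    "clostridium2": dict(mu_max=0.05, k_s=0.05, alpha_b=0.15,
                         death_threshold=7e-3, death_duration=120.0),
    "oleate_degrader": dict(mu_max=0.05, k_s=0.3, alpha_b=0.12,
                            k_i_product=0.5,
                            death_threshold=1e-4, death_duration=120.0),
    "desulfovibrio": dict(mu_max=0.06, k_s=0.03, alpha_b=0.10,
                          k_i_substrate=5.0, k_i_product=1.5,
                          death_threshold=1e-4, death_duration=120.0),
    "methanogen1": dict(mu_max=0.05, k_s=0.05, alpha_b=0.05,
                        k_i_substrate=4.0,
                        death_threshold=1e-4, death_duration=144.0),
    "methanogen2": dict(mu_max=0.07, k_s=0.01, alpha_b=0.06,
                        death_threshold=1e-6, death_duration=120.0),
}


def default_parameters() -> ParameterSet:
    """Return a fresh :class:`ParameterSet` populated from the default registry."""
    return ParameterSet(
        solutes=SoluteCatalog(diffusivity=dict(_DEFAULT_DIFFUSIVITY),
                              bulk=dict(_DEFAULT_BULK)),
        guilds={g: GuildParams(name=g, **kw) for g, kw in _DEFAULT_GUILDS.items()},
    )


# --- XML configuration -----------------------------------------------------

_SPECIES_ATTRS = {
    "muMax": "mu_max",
    "Ks": "k_s",
    "alphaB": "alpha_b",
    "KiSubstrate": "k_i_substrate",
    "KiProduct": "k_i_product",
    "deathThreshold": "death_threshold",
    "deathDuration": "death_duration",
    "divisionRadius": "division_radius",
    "birthFraction": "birth_radius_fraction",
    "density": "density",
}

_DOMAIN_ATTRS = {
    "side": "side",
    "spacing": "spacing",
    "maxGranuleDiameter": "max_granule_diameter",
    "slab": "slab",
}

_SOLVER_ATTRS = {
    "tol": "tol",
    "maxOuter": "max_outer",
    "relax": "relax",
    "capFactor": "cap_factor",
}


def _parse_number(text: str, path: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ConfigurationError(f"{path}: not a number: {text!r}") from None


def load_parameters(source) -> ParameterSet:
    """Parse an XML configuration document into a validated ParameterSet.

    ``source`` may be a path, a file object, or an XML string.  Any optional
    field absent from the document is filled from the default registry; each
    substitution is logged and recorded in ``ParameterSet.substituted_defaults``
    so a run's provenance is explicit.

    Raises :class:`ConfigurationError` for structural problems (naming the
    offending element path) and :class:`ValidationError` for values violating
    hard constraints (e.g. a non-positive maximum growth rate).
    """
    if isinstance(source, str) and source.lstrip().startswith("<"):
        root = etree.fromstring(source.encode())
    else:
        root = etree.parse(source).getroot()
    if root.tag != "granulesim":
        raise ConfigurationError(f"root element must be <granulesim>, got <{root.tag}>")

    subs: list[str] = []

    def note(path: str, value) -> None:
        subs.append(path)
        log.info("config: %s not specified, using default %r", path, value)

    # domain
    dom_kw = {}
    dom_el = root.find("domain")
    dom_defaults = DomainGeometry()
    for xml_name, attr in _DOMAIN_ATTRS.items():
        if dom_el is not None and dom_el.get(xml_name) is not None:
            dom_kw[attr] = _parse_number(dom_el.get(xml_name), f"domain/@{xml_name}")
        else:
            note(f"domain/@{xml_name}", getattr(dom_defaults, attr))
    geometry = DomainGeometry(**dom_kw)

    # solutes
    sol_el = root.find("solutes")
    diffusivity = dict(_DEFAULT_DIFFUSIVITY)
    bulk = dict(_DEFAULT_BULK)
    gamma = None
    declared = set()
    if sol_el is not None:
        if sol_el.get("gamma") is not None:
            gamma = _parse_number(sol_el.get("gamma"), "solutes/@gamma")
        for el in sol_el.findall("solute"):
            name = el.get("name")
            if name is None:
                raise ConfigurationError("solutes/solute: missing mandatory @name")
            if name not in SOLUTES:
                raise ConfigurationError(f"solutes/solute/@name: unknown solute {name!r}")
            declared.add(name)
            if el.get("diffusivity") is not None:
                diffusivity[name] = _parse_number(
                    el.get("diffusivity"), f"solute[{name}]/@diffusivity")
            else:
                note(f"solute[{name}]/@diffusivity", diffusivity[name])
            if el.get("bulk") is not None:
                bulk[name] = _parse_number(el.get("bulk"), f"solute[{name}]/@bulk")
            else:
                note(f"solute[{name}]/@bulk", bulk[name])
    for name in SOLUTES:
        if name not in declared:
            note(f"solute[{name}]", "(registry entry)")
    if gamma is None:
        gamma = SoluteCatalog(dict(_DEFAULT_DIFFUSIVITY), dict(_DEFAULT_BULK)).gamma
        note("solutes/@gamma", gamma)
    catalog = SoluteCatalog(diffusivity=diffusivity, bulk=bulk, gamma=gamma)

    # species
    guilds: dict[str, GuildParams] = {}
    declared_guilds = set()
    for el in root.findall("species"):
        name = el.get("name")
        if name is None:
            raise ConfigurationError("species: missing mandatory @name")
        if name not in GUILDS:
            raise ConfigurationError(f"species/@name: unknown guild {name!r}")
        declared_guilds.add(name)
        kw = dict(_DEFAULT_GUILDS[name])
        for xml_name, attr in _SPECIES_ATTRS.items():
            if el.get(xml_name) is not None:
                kw[attr] = _parse_number(el.get(xml_name), f"species[{name}]/@{xml_name}")
            elif attr in kw or attr in ("division_radius", "birth_radius_fraction",
                                        "density"):
                default = kw.get(attr, getattr(GuildParams, attr, None))
                note(f"species[{name}]/@{xml_name}", default)
        guilds[name] = GuildParams(name=name, **kw)
    for name in GUILDS:
        if name not in declared_guilds:
            guilds[name] = GuildParams(name=name, **_DEFAULT_GUILDS[name])
            note(f"species[{name}]", "(registry entry)")

    # solver
    solver_kw = {}
    solver_el = root.find("solver")
    solver_defaults = SolverSettings()
    for xml_name, attr in _SOLVER_ATTRS.items():
        if solver_el is not None and solver_el.get(xml_name) is not None:
            v = _parse_number(solver_el.get(xml_name), f"solver/@{xml_name}")
            solver_kw[attr] = int(v) if attr == "max_outer" else v
        else:
            note(f"solver/@{xml_name}", getattr(solver_defaults, attr))
    solver = SolverSettings(**solver_kw)

    # simulation / options
    dt = 0.5
    sim_el = root.find("simulation")
    if sim_el is not None and sim_el.get("dt") is not None:
        dt = _parse_number(sim_el.get("dt"), "simulation/@dt")
    else:
        note("simulation/@dt", dt)
    oleate_to_acetate = True
    opt_el = root.find("options")
    if opt_el is not None and opt_el.get("oleateToAcetate") is not None:
        oleate_to_acetate = opt_el.get("oleateToAcetate").lower() in ("1", "true", "yes")
    else:
        note("options/@oleateToAcetate", oleate_to_acetate)

    return ParameterSet(
        solutes=catalog, guilds=guilds, geometry=geometry, solver=solver,
        dt=dt, oleate_to_acetate=oleate_to_acetate, substituted_defaults=subs,
    )


def to_xml(p: ParameterSet) -> str:
    """Serialize a ParameterSet to the XML configuration dialect.

    Numbers are written with ``repr`` so that ``load_parameters(to_xml(p))``
    reproduces every numeric field bit-exactly.
    """
    root = etree.Element("granulesim")
    g = p.geometry
    etree.SubElement(root, "domain", side=repr(g.side), spacing=repr(g.spacing),
                     maxGranuleDiameter=repr(g.max_granule_diameter),
                     slab=repr(g.slab))
    sol = etree.SubElement(root, "solutes", gamma=repr(p.solutes.gamma))
    for name in SOLUTES:
        etree.SubElement(sol, "solute", name=name,
                         diffusivity=repr(p.solutes.diffusivity[name]),
                         bulk=repr(p.solutes.bulk[name]))
    for name in GUILDS:
        gp = p.guilds[name]
        attrs = {"name": name}
        for xml_name, attr in _SPECIES_ATTRS.items():
            v = getattr(gp, attr)
            if v is not None:
                attrs[xml_name] = repr(v)
        etree.SubElement(root, "species", **attrs)
    etree.SubElement(root, "solver", tol=repr(p.solver.tol),
                     maxOuter=repr(float(p.solver.max_outer)),
                     relax=repr(p.solver.relax), capFactor=repr(p.solver.cap_factor))
    etree.SubElement(root, "simulation", dt=repr(p.dt))
    etree.SubElement(root, "options",
                     oleateToAcetate="true" if p.oleate_to_acetate else "false")
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def validate_consistency(p: ParameterSet) -> list[str]:
    """Return warnings for suspicious but legal settings; never mutates ``p``.

    Checks: growth per timestep (mu_max * dt), lattice resolution versus the
    smallest cell diameter, and a sloughing diameter exceeding the domain
    (legal: it disables sloughing).
    """
    warnings: list[str] = []
    for name, gp in p.guilds.items():
        if p.dt * gp.mu_max > 0.1:
            warnings.append(
                f"{name}: mu_max*dt = {p.dt * gp.mu_max:.3g} > 0.1; "
                "growth per step is large, consider a smaller dt")
    min_birth_diameter = min(
        2.0 * gp.division_radius * gp.birth_radius_fraction for gp in p.guilds.values())
    if p.geometry.spacing > min_birth_diameter:
        warnings.append(
            f"grid spacing {p.geometry.spacing} um exceeds the smallest cell "
            f"diameter {min_birth_diameter:.3g} um; agents are sub-grid")
    if p.geometry.max_granule_diameter > p.geometry.side:
        warnings.append(
            "max granule diameter exceeds the domain side: sloughing is "
            "effectively disabled")
    return warnings


__all__ = [
    "SOLUTES", "GUILDS", "GROWTH_SUBSTRATE", "CONSUMER_OF",
    "LITRE_PER_UM3", "PG_PER_G", "MOLAR_MASS", "MOLAR_VOLUME_L",
    "ConfigurationError", "ValidationError",
    "SoluteCatalog", "GuildParams", "DomainGeometry", "SolverSettings",
    "ParameterSet", "default_parameters", "load_parameters", "to_xml",
    "validate_consistency", "radius_from_biomass", "biomass_from_radius",
]
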