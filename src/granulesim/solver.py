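"""Pseudo-steady-state reaction-diffusion solver on the square lattice.

Solute transport is assumed fast relative to biomass growth, so at every
biological timestep each solute field is relaxed to the steady state of

    div( D_eff grad S_i ) + r_i(S) = 0,

with Dirichlet bulk-feed values on all four domain edges.  ``D_eff`` equals
the free-liquid diffusivity outside the granule and ``gamma * D`` wherever
the node carries biomass (live or dead), modelling the extra mass-transfer
resistance of the aggregate matrix.

Discretization is a 5-point finite-volume stencil with harmonic-mean face
diffusivities (flux continuity across the biofilm/liquid jump).  The
nonlinear reaction terms are handled with damped Picard iterations: at each
outer iteration the uptake of each solute is linearized as ``k(S_prev) * S``
-- with ``k = B/alpha * mu(S)/S`` evaluated in closed form, finite at S = 0
-- and placed on the matrix diagonal, while production terms are lagged on
the right-hand side.  Each linear system is then an M-matrix and is solved
directly (sparse LU), which keeps every iterate non-negative without any
clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .kinetics import (
    LocalEnvironment, ReactionRates, product_edges, reaction_terms,
    specific_affinity,
)
from .parameters import (
    CONSUMER_OF, GUILDS, LITRE_PER_UM3, SOLUTES, ParameterSet,
)


class SolverError(RuntimeError):
    """Picard iteration failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class SoluteFields:
    """Seven concentration lattices plus the biomass-presence indicator.

    Lattices are indexed ``[ix, iy]`` with node centres at
    ``(ix + 0.5) * h, (iy + 0.5) * h``.
    """

    concentrations: dict[str, np.ndarray]
    indicator: np.ndarray  # bool, True where the node carries biomass

    @classmethod
    def uniform(cls, n: int, bulk: Mapping[str, float]) -> "SoluteFields":
        return cls(
            concentrations={s: np.full((n, n), float(bulk.get(s, 0.0))) for s in SOLUTES},
            indicator=np.zeros((n, n), dtype=bool),
        )

    def copy(self) -> "SoluteFields":
        return SoluteFields(
            concentrations={s: a.copy() for s, a in self.concentrations.items()},
            indicator=self.indicator.copy(),
        )

    def environment(self) -> LocalEnvironment:
        return LocalEnvironment(**self.concentrations)


def effective_diffusivity(fields: SoluteFields, d: float, gamma: float) -> np.ndarray:
    """Node-wise effective diffusivity: D in liquid, gamma*D under biomass."""
    return np.where(fields.indicator, gamma * d, d)


def _assemble(deff: np.ndarray, k: np.ndarray, h: float,
              source: np.ndarray, bulk):
    """Build the linear system for one solute.

    Interior nodes get the 5-point divergence of harmonic-mean face fluxes
    plus the linearized sink ``k`` on the diagonal; edge nodes are identity
    rows pinned to the boundary value (``bulk``: scalar, or a full lattice
    whose edge entries supply per-node Dirichlet values).
    """
    n = deff.shape[0]
    idx = np.arange(n * n).reshape(n, n)

    def hmean(a, b):
        return 2.0 * a * b / (a + b)

    # face diffusivities between node (i,j) and (i+1,j) / (i,j+1)
    fx = hmean(deff[:-1, :], deff[1:, :]) / h**2
    fy = hmean(deff[:, :-1], deff[:, 1:]) / h**2

    diag = k.astype(float).copy()
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r.ravel())
        cols.append(c.ravel())
        vals.append(v.ravel())

    # x-direction couplings
    diag[:-1, :] += fx
    diag[1:, :] += fx
    add(idx[:-1, :], idx[1:, :], -fx)
    add(idx[1:, :], idx[:-1, :], -fx)
    # y-direction couplings
    diag[:, :-1] += fy
    diag[:, 1:] += fy
    add(idx[:, :-1], idx[:, 1:], -fy)
    add(idx[:, 1:], idx[:, :-1], -fy)

    rhs = source.astype(float).ravel().copy()

    # Dirichlet edges: overwrite with identity rows
    edge = np.zeros((n, n), dtype=bool)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    edge_flat = edge.ravel()
    diag_flat = diag.ravel()
    diag_flat[edge_flat] = 1.0
    bulk_arr = np.asarray(bulk, dtype=float)
    rhs[edge_flat] = bulk_arr.ravel()[edge_flat] if bulk_arr.ndim == 2 else bulk_arr

    rows = np.concatenate([np.arange(n * n)] + rows)
    cols = np.concatenate([np.arange(n * n)] + cols)
    vals = np.concatenate([diag_flat] + vals)
    keep = ~(edge_flat[rows] & (rows != cols))  # strip off-diagonals of edge rows
    a = sp.csc_matrix((vals[keep], (rows[keep], cols[keep])), shape=(n * n, n * n))
    return a, rhs


def solve_linear(deff: np.ndarray, k: np.ndarray, h: float,
                 source: np.ndarray, boundary) -> np.ndarray:
    """Solve one linear diffusion-reaction problem on the lattice.

    ``div(D_eff grad S) - k S + source = 0`` with Dirichlet edges taken from
    ``boundary`` (scalar or full lattice).  This is the inner primitive of
    the Picard iteration, exposed separately so analytic solutions (linear
    profiles, cosh decay in a strip) can be checked directly against it.
    """
    n = deff.shape[0]
    a, rhs = _assemble(deff, k, h, source, boundary)
    return spla.spsolve(a, rhs).reshape(n, n)


@dataclass
class SolveInfo:
    iterations: int
    residual: float
    warnings: list[str] = field(default_factory=list)


def solve_steady_state(fields: SoluteFields,
                       biomass: Mapping[str, np.ndarray],
                       p: ParameterSet,
                       bulk: Mapping[str, float] | None = None,
                       ) -> tuple[SoluteFields, ReactionRates, SolveInfo]:
    """Relax all seven solutes to the reaction-diffusion steady state.

    ``biomass`` maps guild -> lattice of local biomass concentration (g/L);
    ``bulk`` overrides the catalog's boundary values (used by feed
    schedules).  The incoming ``fields`` provide the Picard starting point
    (warm start), which keeps the iteration count low along a simulation.

    Returns the converged fields, the reaction rates evaluated at the
    converged concentrations, and iteration diagnostics.  Raises
    :class:`SolverError` on non-convergence.
    """
    n = p.geometry.n
    h = p.geometry.spacing
    if bulk is None:
        bulk = p.solutes.bulk
    s = {name: fields.concentrations[name].astype(float).copy() for name in SOLUTES}
    info = SolveInfo(iterations=0, residual=np.inf)
    edges = product_edges(p)
    bio = {g: np.asarray(biomass.get(g, 0.0), dtype=float) for g in GUILDS}

    deff = {name: effective_diffusivity(fields, p.solutes.diffusivity[name],
                                        p.solutes.gamma) for name in SOLUTES}

    # Sweep the solutes in metabolic order so each solve sees the freshest
    # upstream fields (Gauss-Seidel across the network); the only true
    # feedback loop runs through acetate product inhibition, which the outer
    # iteration closes.
    order = ("cellobiose", "lactate", "ethanol", "acetate",
             "oleate", "hydrogen", "methane")
    producers = {name: [g for g, sol in edges if sol == name] for name in SOLUTES}

    relax = 1.0  # full Picard steps while converging; damped on stagnation
    prev_delta = np.inf
    any_bio = {g: bool(np.any(bio[g])) for g in GUILDS}
    for it in range(1, p.solver.max_outer + 1):
        delta = 0.0
        for name in order:
            env = LocalEnvironment(**s)
            consumer = CONSUMER_OF.get(name)
            k = np.zeros((n, n))
            if consumer is not None and any_bio[consumer]:
                gp = p.guild(consumer)
                # mu/S in closed form, finite at S = 0
                k = specific_affinity(consumer, env, gp) * bio[consumer] / gp.alpha_b
            source = np.zeros((n, n))
            for g in producers[name]:
                if not any_bio[g]:
                    continue
                gp = p.guild(g)
                source = source + (specific_affinity(g, env, gp)
                                   * np.asarray(env[gp.substrate], dtype=float)
                                   * bio[g] / gp.alpha_b)
            if not np.any(k) and not np.any(source):
                # pure diffusion with constant boundary: uniform bulk field
                new_uniform = np.full((n, n), float(bulk[name]))
                delta = max(delta, float(np.max(np.abs(new_uniform - s[name])))
                            / max(float(bulk[name]), 1e-12))
                s[name] = new_uniform
                continue
            a, rhs = _assemble(deff[name], k, h, source, float(bulk[name]))
            new = spla.spsolve(a, rhs).reshape(n, n)
            # the linearized system is an M-matrix, so the exact solution is
            # non-negative; only LU roundoff at the field's scale is tolerated
            scale_new = max(float(np.max(np.abs(new))), 1e-30)
            assert new.min() >= -(1e-12 + 1e-7 * scale_new), \
                "negative concentration beyond roundoff in M-matrix solve"
            np.maximum(new, 0.0, out=new)
            mixed = relax * new + (1.0 - relax) * s[name]
            scale = max(float(np.max(np.abs(mixed))), 1e-12)
            delta = max(delta, float(np.max(np.abs(mixed - s[name]))) / scale)
            s[name] = mixed
        info.iterations = it
        info.residual = delta
        if delta < p.solver.tol:
            break
        if delta > 0.9 * prev_delta:
            # Picard stagnating or oscillating: switch to damped iterations
            relax = p.solver.relax
        prev_delta = delta
    else:
        raise SolverError(
            f"steady-state solve did not converge in {p.solver.max_outer} "
            f"iterations (residual {info.residual:.3e})", info.residual)

    for name in SOLUTES:
        cap = p.solver.cap_factor * float(bulk[name])
        if cap > 0 and float(s[name].max()) > cap:
            info.warnings.append(
                f"{name}: max concentration {s[name].max():.3g} exceeds "
                f"{p.solver.cap_factor:g} x bulk")

    out = SoluteFields(concentrations=s, indicator=fields.indicator.copy())
    rates = reaction_terms(out.environment(), bio, p)
    return out, rates, info


def production_ledger_increment(sources: Mapping[str, np.ndarray],
                                node_volume_um3: float,
                                dt: float) -> dict[str, float]:
    """Mass (g) produced per solute this step from volumetric source lattices.

    Integrates the non-negative source terms (g/L/h) over node volume and the
    step: ``sum(source) * V_node * dt`` with the um^3 -> L conversion.  The
    cumulative ledger built from these increments -- not the instantaneous
    concentration field -- is what backs "total methane produced" style
    reporting, because product that diffuses out of the domain is not
    otherwise accounted for.
    """
    out = {}
    for name, lattice in sources.items():
        arr = np.asarray(lattice, dtype=float)
        if np.any(arr < 0):
            raise ValueError(f"source lattice for {name} has negative entries")
        out[name] = float(arr.sum()) * node_volume_um3 * LITRE_PER_UM3 * dt
    return out


__all__ = [
    "SoluteFields", "SolveInfo", "SolverError", "effective_diffusivity",
    "solve_linear", "solve_steady_state", "production_ledger_increment",
]
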