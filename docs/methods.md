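# Methods

## Model overview

`granulesim` simulates the formation and bioaugmentation of a single
anaerobic granule as a hybrid of two coupled layers:

* **An individual-based layer.**  Microbial cells are spheres with a guild
  identity, centre position, biomass and radius, living on a 2-D square
  domain.  Cells grow exponentially at their local specific rate, divide
  when they reach a division radius, push each other apart when they
  overlap (shoving), starve and die when their growth substrate stays
  scarce, and are destroyed (sloughed) when the granule outgrows a maximum
  diameter — the model's stand-in for shear-driven detachment in an upflow
  anaerobic sludge blanket (UASB) reactor.
* **A continuum solute layer.**  Seven solutes (cellobiose, oleate,
  lactate, acetate, ethanol, hydrogen, methane) diffuse on a lattice and
  react with the rasterized biomass field.  Because solute transport
  equilibrates in minutes while biomass turns over in days, the fields are
  relaxed to a *pseudo-steady state* at every biological timestep:

      div(D_eff grad S_i) + r_i(S, B) = 0

  with Dirichlet bulk-feed values on all four domain edges (the
  surrounding reactor liquid, assumed well mixed and constantly
  replenished).  `D_eff = gamma * D` wherever a node carries biomass (live
  or dead), modelling the extra mass-transfer resistance of the granule
  matrix; `D` elsewhere.

## Metabolic network and rate laws

Six guilds form a syntrophic chain from polysaccharide- or lipid-derived
feed to methane.  Each guild consumes one growth substrate with specific
rate mu_g(S) and a single yield alpha_g (g biomass per g substrate); every
coupled production term is mu_g B_g / alpha_g:

| guild          | substrate  | products            | rate law |
|----------------|-----------|----------------------|----------|
| clostridium1   | cellobiose | lactate + ethanol   | Monod |
| clostridium2   | lactate    | acetate             | Monod |
| oleate degrader| oleate     | acetate (optional)  | Monod x Ki/(Ki+S_ac) |
| desulfovibrio  | ethanol    | acetate + hydrogen  | Haldane x Ki/(Ki+S_ac) |
| methanogen1    | acetate    | methane             | Haldane |
| methanogen2    | hydrogen   | methane             | Monod |

Monod: mu = mu_max S/(Ks+S).  Haldane: mu = mu_max S/(Ks+S+S^2/Ki),
unimodal with its maximum at sqrt(Ks*Ki).  Methane and hydrogen exert no
feedback inhibition; they are pure products.  Oleate degradation produces
no hydrogen.  Whether oleate-derived acetate enters the acetate pool is a
flag (`oleate_to_acetate`, default on): the oleate degrader's own
acetate product inhibition, and the survival of acetoclastic methanogens
on an oleate-only feed, both presuppose the coupling.

**Death switch.**  A cell whose growth substrate stays below a threshold
theta for a *consecutive* duration tau is converted, biomass intact, into
an inert dead agent.  Exposure is consecutive by design — one step above
threshold rearms the clock — because a sustained-starvation reading is the
natural interpretation of nutritional stress over a multi-day window.
Dead agents take no further part in kinetics but keep occupying space and
keep counting toward the biomass indicator of the diffusivity reduction,
which is what lets cavities of dead biomass persist inside the granule.

## Units

Length um, time h, concentration g/L, per-cell biomass pg, cell density
g/um^3 (1 g/L = 1e-15 g/um^3).  The 2-D domain is given a slab thickness
equal to the grid spacing for all mass/volume conversions; reported
totals (grams of methane, etc.) are therefore per-slab quantities and the
"concentration over domain volume" output uses the same convention.

## Default parameter registry

No single published table pins down all constants of this six-guild
network, so the shipped registry holds literature-typical values for
mesophilic anaerobic digestion, chosen once and used by every preset; all
are overridable from the XML configuration.

* **Maximum growth rates** are on the per-day scale usual in anaerobic
  digestion models: 0.10/h for the cellobiose fermenter (paired with a
  weakly saturating Ks, see below), 0.05/h for the lactate fermenter and
  the oleate degrader and the acetoclastic methanogen, 0.06/h for the
  ethanol oxidizer, 0.07/h for the hydrogenotroph.
* **Half-saturation constants**: cellobiose 4.5 g/L — the effective
  hydrolysis-limited uptake of a polymeric feed saturates only far above
  reactor feed strengths, so realized growth is close to linear in the
  0.5-1.5 g/L feed range and the feed level propagates strongly to the
  whole cross-feeding chain; lactate 0.05, oleate 0.3, ethanol 0.03,
  acetate 0.05, hydrogen 0.01 g/L.
* **Inhibition constants**: acetate product inhibition 0.5 g/L (oleate
  degrader) and 1.5 g/L (ethanol oxidizer); Haldane self-inhibition 5 g/L
  (ethanol) and 4 g/L (acetate).
* **Yields** alpha: 0.10-0.15 for fermenters, 0.05-0.06 for methanogens.
* **Death thresholds**: 1e-4 g/L (1e-6 for hydrogen) — essentially
  "substrate absent" — except the lactate fermenter, whose threshold is
  7e-3 g/L: lactate is the most thermodynamically marginal intermediate
  of the chain, and a maintenance-level threshold there is what separates
  a lactate supply that can sustain the guild from one that cannot.  It
  sits centred in the gap between the granule-interior lactate levels
  that the high-feed (1.5 g/L) and low-feed (1.0 g/L) regimes reach
  within the guild's death window, so the regime split is robust to the
  random seed.  Death durations: 96 h (cellobiose fermenter), 144 h
  (acetoclastic methanogen), 120 h for the rest (bracketed by the two
  anchor values).
* **Transport**: effective diffusivities in granular sludge (cellobiose
  4.0e5, oleate 1.0e5, lactate 2.0e6, acetate 1.5e6, ethanol 1.6e6,
  hydrogen 6.0e6, methane 2.0e6 um^2/h), i.e. moderately below
  infinite-dilution aqueous values as biofilm diffusivity studies report
  (most strongly for the bulky feed molecules), with gamma = 0.5 applied
  on top under biomass.  These give a feed penetration depth of a few
  tens of micrometres at packed-biomass density — rim-dominated growth
  and interior starvation in mature granules — while keeping the product
  fields smooth enough that same-guild cells a few nodes apart see
  similar concentrations.
* **Geometry**: 508 um domain at 4 um spacing (127 x 127), granule capped
  at 500 um diameter; cells divide at radius 4 um (about 40 pg at density
  150 g/L), daughters at 2^-1/3 of the division radius.
* **Timestep** 0.5 h.  The biomass update is the exact exponential
  exp(mu dt) for the frozen local rate, and all ledgers integrate source
  terms as B expm1(mu dt)/alpha — the exact step integral under the same
  assumption — so no kinetics sub-stepping is needed: growth, substrate
  consumption and product formation satisfy their stoichiometric identity
  to machine precision at any dt, and dt only controls how often the
  fields and mechanics are refreshed.

## Numerics

* **Discretization**: 5-point finite volume; harmonic-mean face
  diffusivities, so flux is continuous across the biomass/liquid
  diffusivity jump.
* **Nonlinear strategy**: the solutes are swept in metabolic order
  (cellobiose, lactate, ethanol, acetate, oleate, hydrogen, methane);
  each solute's uptake is linearized as k(S_prev) S with
  k = (mu/S) B/alpha evaluated in closed form (finite at S = 0) and placed
  on the diagonal, production lagged on the right-hand side, and the
  linear system solved directly (sparse LU).  Because the linearized
  operator is an M-matrix, every iterate is non-negative without
  clipping (asserted each solve).  Sweeps repeat — Picard — until the
  relative L-inf change falls below 1e-6 (at most 200 sweeps, full steps
  while converging, damped by 0.7 on stagnation); the warm start from the
  previous step's fields keeps typical counts at 3-5 sweeps.
* **Agent rasterization** uses a compact quadratic kernel of *physical*
  support radius max(1.5 r_cell, h), normalized per agent.  A physical
  footprint (rather than nearest-node or bilinear deposition) is what
  makes the biomass field, and with it the production ledgers, converge
  under grid refinement.  Per-cell growth combines node growth factors
  with the same weights, so the per-cell biomass increase equals the
  node-level ledger increment exactly.
* **Shoving** displaces each member of an overlapping pair by half the
  overlap along the centre line, iterating (Jacobi, KD-tree neighbour
  search) to a 0.1 um residual or 100 iterations.  Pressure equilibration
  through a dense pack is diffusive, so a standing residual below about a
  quarter cell radius persists in a growing granule; it does not
  accumulate and is reported per step.
* **Production ledgers**, not instantaneous fields, back all "total
  methane/hydrogen produced" outputs: product that diffuses across the
  open boundary leaves the model silently by design.  Ledger increments
  integrate the positive source terms over node volume and step.
* **Sloughing** tests agent *centres* against the maximum granule radius
  (boundary inclusive) every step, with the granule centre fixed at the
  domain centre where the inoculum is seeded.  A maximum diameter larger
  than the domain is legal and simply disables sloughing (used by the
  relaxed-sloughing scenario).
* **Randomness**: one seeded generator drives inoculum placement,
  division splits and directions, and shoving tie-breaks; a run is
  bit-reproducible for a fixed seed.

## Scenario presets and study scales

Ten presets cover the experiment families: granule formation on 1.5 or
1.0 g/L cellobiose; formation without the ethanol oxidizer, with its
re-introduction (alone or with the hydrogenotroph) at day 17; dual
cellobiose+oleate feeds at 1.5/1.0/0.5 g/L with oleate-degrader
augmentation at day 17 (plus a relaxed-sloughing variant); and an
oleate-only feed with cellobiose halted at day 17.  Introduction events
default to four seed cells placed at the corners of the square just
enclosing the granule surface at event time.

Full-scale presets use the 508 um domain and a 42-day horizon.  The
package also defines *reduced* presets — 256 um domain (64 x 64), granule
capped at 200 um, 10-day horizon, events on day 4 — chosen as the
smallest conditions that preserve the qualitative regimes (guild
coexistence at 1.5 g/L, lactate-fermenter collapse at 1.0 g/L,
augmentation capture vs. washout at low vs. high dual feed).  The test
suite and the acceptance script run the reduced presets.

## What the simulations do and do not emulate

The model captures niche availability, cross-feeding, spatial competition
for substrate, diffusion limitation, starvation death and
detachment-driven washout.  It omits pH and temperature effects,
thermodynamic (free-energy) rate limitation, EPS production, attractive
cell-cell forces, convective transport, gas-bubble formation and granule
fission.  Passing tests therefore demonstrate internal consistency and
the qualitative mechanisms above, not quantitative agreement with any
particular reactor: absolute gas totals depend on the parameter registry,
for which only literature-typical defaults ship.

## Known limitations

* Biomass deposited near the domain edge is clipped to edge nodes; in
  practice the granule never reaches the boundary (sloughing caps it
  first) except in the relaxed-sloughing scenario, where the cap exceeds
  the domain deliberately.
* The acetate product-inhibition loop makes the steady-state problem
  non-monotone in principle; the damped Picard fallback has handled every
  scenario exercised, but a pathological parameter set could require a
  smaller relaxation factor.
* At the default spacing (cell diameter about 2 grid nodes) the ledger's
  residual grid sensitivity is a few percent; halving the spacing from an
  already-resolved state changes cumulative methane by about 1%.
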