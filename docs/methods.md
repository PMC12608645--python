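# Methods

## Scope and architecture

The simulator couples three scales. The *environmental* scale is a square
2D voxel lattice carrying oxygen, glucose, lactate and free protons as
reaction–diffusion fields. The *tissue* scale is an agent population with
overdamped mechanics, a cell-cycle state machine and necrotic death. The
*cellular* scale is a 53-variable gene–metabolism ODE system carried by
every agent. A multirate scheduler binds them: diffusion every 0.6 s,
metabolite integration every 1.2 s, mechanics every 6 s, and a phenotype
evaluation (classification, gene regulation, cycle/death checkpointing,
snapshots) every 6 min. Within a base tick the order is: scheduled
perturbations → cell exchange deposition → diffusion. Exchange is
accumulated per voxel and consumed by the diffusion step, and all per-cell
randomness comes from counter-based streams keyed by (seed, cell id,
tick), so serial runs are bit-reproducible and results do not depend on
cell iteration order.

## Environment

Concentrations are in mM; the lattice uses 20 µm voxels (a conventional
resolution for cell-scale reaction–diffusion, roughly one cell diameter).
Diffusion coefficients are fixed per species (oxygen 87,600; glucose
30,000; lactate 12,600; protons 270,000 µm²/min). Oxygen is interconverted
with partial pressure at 1.30×10⁻³ mM/mmHg. Boundary conditions are
Dirichlet (renewed medium) or zero-flux Neumann per species and scenario.

The solver is locally one-dimensional: each step applies volumetric
sources explicitly (clipping negative results to zero and logging the
clipped mass), then solves an implicit tridiagonal system along each axis
(Thomas algorithm). The scheme is unconditionally stable; the explicit
(FTCS) bound for protons at this resolution would be ≈ 0.02 s, far below
the 0.6 s step. Under zero-flux boundaries the discrete scheme conserves
mass to solver round-off; Dirichlet boundary voxels are re-imposed exactly
after every step. Fidelity is checked against two independent oracles in
the test suite: the closed-form parabolic steady state of diffusion with
uniform uptake on a clamped strip (≤ 1 % at voxel centers), and a tiny-step
explicit reference integration on a 9×9 lattice (≤ 0.5 % max-norm over 50
production steps).

pH is stored and diffused as free-proton concentration; pH values are
derived only for reporting and for the glycolysis-modulation input.
Because free protons are heavily buffered in tissue, cell proton fluxes
are divided by an *effective buffering capacity* before entering the
proton field (default 30): this lumps physiological buffering into a
single dial that sets how strongly lactic-acid export acidifies the
interstitium. Intracellular pH uses a separate, larger capacity (2000)
plus a fast exchanger-like regulation toward pH 7.1, so transient acid
loads (for instance during lactic-acid import) depress pH-i while
balanced export/production leaves it at the set point.

## The gene–metabolism network

Each cell integrates 53 variables: 33 metabolites (glycolysis chain,
glycogen store, TCA intermediates, cytosolic and mitochondrial NAD/NADH,
FAD/FADH₂, ATP/ADP/AMP, CoA, intracellular lactate and protons), ten
enzyme/transporter proteins, and ten regulated gene expressions (HIF-1α,
AMPK, p53, MYC, PDK, and the genes for GLUT, LDH, PDH, MCT and PFK). The
full rate-law parameterization ships as a single editable CSV
(`data/metabolic_params.csv`); loading fails fast on any key mismatch.

Design principles, in decreasing order of importance:

* **Redox routes the pyruvate node.** LDH (`r12`) is reversible mass
  action against a fixed equilibrium strongly favoring lactate; PDH
  (`r18`) is irreversible. Oxygen enters only the electron-transport
  reactions (cubic Hill in O₂, half-max ≈ 7 mmHg). Hypoxia therefore backs
  NADH up through the shuttle into the cytosol and flips the node into
  fermentation without any hard switch.
* **Transport is product-driven.** The MCT symport rate is proportional to
  the difference of `lactate·H⁺` products across the membrane (protons
  normalized to their pH-7.4 value), saturating in the combined product.
  It is exactly zero at product equality, exports down-gradient, and
  imports under an acidic, lactate-rich exterior.
* **Acid inhibits glycolysis at PFK.** A product of two sigmoids (one in
  extracellular pH, midpoint 6.6; one in intracellular pH, midpoint 6.9),
  each normalized to 1 at its physiological anchor (7.4 / 7.1). This is the
  mechanism that lets self-generated acidity shut down core fermentation
  and that redirects metabolism under acid shock.
* **Energy homeostasis is two-sided.** Maintenance demand saturates in ATP
  and is damped by AMPK; PFK is ATP-inhibited, AMP-activated, and
  lactate-product-inhibited; the ETC is under respiratory (ADP) control.
  The ATP set point under nutrient-replete conditions is ≈ 3 mM of a 3 mM
  adenylate pool, with the necrosis threshold at 0.3 mM.
* **Regulation closes the loops.** HIF-1α degradation requires oxygen and
  is partially suppressed by extracellular lactate (with a floor, so
  oxygen-rich cells are sensitized but not locked glycolytic). HIF drives
  LDH, PDK, GLUT, MCT, PFK and hexokinase; PDK represses PDH expression;
  AMPK→p53 support the oxidative program and repress MYC. The two stable
  programs — oxidative (LDH ≈ 1, PDH ≈ 1) and glycolytic (LDH ≈ 5,
  PDH ≈ 0.4) — are the attractors of the LDH/PDH landscape projection.
* **γ** multiplies every gene's production term. It is redrawn for both
  daughters at division (lognormal around the parent, σ = 0.05, clipped to
  [0.5, 2]), providing heritable, drift-like epimutational variability.

Metabolites integrate with the explicit trapezoid (Heun) scheme at the
1.2 s step — second order, two derivative evaluations, with every network
eigenvalue inside the stability region at this step size; a step that produces a
negative or non-finite metabolite is retried with doubled substepping (up
to 64 substeps) and aborts with the cell id if still failing. Interval
averages of all reaction rates are accumulated with the integrator's
stage weights,
which makes flux integrals consistent with pool changes to round-off (the
carbon-bookkeeping test exploits this). Genes and proteins evolve on the
6-min clock (Euler–Maruyama; additive Gaussian noise, default σ = 0.01,
per-cell counter-based streams), which is appropriate because their time
constants (0.5–2 h) are three orders of magnitude above the metabolite
step.

Parameter values were chosen once so that single cells in clamped
environments reproduce the qualitative outcome matrix (lactate import
under very high lactate or under oxygen without glucose; excretion under
hypoxia with glucose; death when both carbon sources are effectively
absent, when oxygen and glucose are both low, or under acidic hypoxia)
and the two-basin landscape, and were not revisited afterwards.

## Cells

Cycle: G1 5 h, S 8 h, G2 4 h, M 1 h (18 h total, inside the 18–24 h
glioblastoma band). In G1 the cell checks ATP (≥ 0.8 mM) and local
crowding (neighborhood occupancy ≤ 0.55 within a 25 µm disc) every 6 min;
failing either parks it in G0 with its G1 progress preserved. G1 duration
is stretched by the factor (38 mmHg)/max(O₂, 15 mmHg) between the hypoxia
floor and the reference tension. Volume doubles linearly across S; at M
completion the cell splits into equal-volume daughters, one cell radius
apart, each with a copy of the metabolic state and an independently
redrawn γ.

Necrosis: ATP < 0.3 mM accumulates a deficit clock (reset on recovery);
after 3 h the per-evaluation death probability is
`clamp(1 − ATP/0.3, 0, 1) × p_max` (p_max = 0.2 per 6-min evaluation).
Necrotic cells swell to 1.5× over 6 h, lyse — releasing intracellular
glucose (including the store), lactate and protons into their voxel,
plus a nominal dissolved-oxygen content — shrink to 10 % of basal volume
over 24 h, and are cleared 24 h after becoming debris.

Mechanics is a means to plausible packing, not a calibration target:
polynomial repulsion inside contact distance and weaker polynomial
adhesion to 1.25× contact, overdamped position updates, repelling domain
walls. The defaults give a rest separation ≈ 5 % below contact.

## Scenarios and scales

All five stress protocols are pure configuration (perturbation entries of
kind `boundary_set`, `field_clamp`, `square_wave`): the reference culture
(38 mmHg / 6 mM glucose / 0.1 mM lactate / pH 7.4, all Dirichlet), cyclic
hypoxia (70/15 mmHg square wave, periods 18/36/72 h), acid shock (uniform
pH clamp, 7.4 until 50 h then 7.4/6.7/6.0/5.3), glucose depletion (uniform
clamp 6 mM until 60 h then 0.01 mM), and the glycolytic challenge
(160 mmHg oxygen, 1 mM glucose, zero-flux lactate/proton boundaries,
pH 6.7 start).

Full-scale runs (3,000 µm domain, 440 cells, 300–443 h) are hours of CPU;
the shipped desk scale (800 µm, 200 cells seeded in a 240 µm disc, 120 h)
runs the whole layered-spheroid development on one core and is what the
test suite exercises. The initial disc radius sets the seeding density
(about half the quiescence threshold), so crowding arrest emerges after
roughly one division round rather than instantly; it is a geometry choice
exposed in the config, and desk overrides never touch kinetic parameters.
Some tests reduce further (600 µm, 100–120 cells, 40–60 h) where only the
direction of an effect is asserted. The qualitative outcome matrix maps
the qualitative levels to low = 2 mmHg O₂ / 0.1 mM glucose / 0.1 mM
lactate, high = 38 mmHg / 6 mM / 3 mM, very-high lactate = 10 mM, and
calls a row "death" when ≥ 90 % of replicates necrose within 48 h.

## What the synthetic scenarios do and do not show

The generator-free design means every input is a configuration: there is
no external data. The spheroid emulates an in-vitro culture in renewed
medium; it does not represent vascularized tissue (no convection or
perfusion heterogeneity), includes no carbonate buffering chemistry
(buffering is a lumped capacity), no apoptosis (the modeled population
evades it; only necrosis is implemented), and no fatty-acid/glutamine
metabolism — so "carbon-starved" here means glucose+lactate-starved.
2D geometry exaggerates radial growth rates relative to a real 3D
spheroid; conclusions are about emergent structure and flux directions,
not absolute sizes or times. Passing tests demonstrate internal
consistency of the model and reproduction of the qualitative biology
described above at reduced scale, not quantitative agreement with any
particular cell line.

## Numerical choices and degenerate inputs

* Diffusion: implicit LOD; Dirichlet re-imposition exact; negative
  concentrations after the source half-step are clipped and the mass
  logged; divergence (non-finite values) aborts.
* Metabolites: Heun with automatic substep halving; all rate laws evaluate
  on values clamped at zero so transient tiny negatives cannot propagate.
* Empty populations are legal (pure diffusion); an empty living population
  flags its census rather than emitting fractions.
* Classification ties (`r12 == r18`) fall to the respiratory hybrid — a
  measure-zero event; negative `r12` counts as zero fermentation when
  labeling (the reverse flux is reported as reverse-Warburg status
  instead). The Warburg neutral band is 1 % of the population median
  |net MCT| with a 10⁻⁶ mM/min floor.
* Landscape attractors: local maxima of the Gaussian-smoothed integrated
  histogram above a prominence threshold (default 5 % of the peak),
  separated by ≥ 3 bins.
* Warburg/phenotype fractions are computed over living cells only.

## Known limitations

* The hypoxic transition transiently dips ATP; cells that would be viable
  at the hypoxic steady state can die if the dip outlasts the 3 h
  persistence bar. The regulation time constants were chosen fast enough
  that this does not happen under the standard protocols, but extreme
  step perturbations (e.g. instant anoxia plus acid) remain lethal by
  construction.
* The proton model tracks free concentration with lumped buffering;
  absolute interstitial pH values depend directly on the effective
  buffering capacity.
* Mechanics has no active migration, ECM, or 3D mode (the lattice and
  agent code are 2D throughout, although nothing in the architecture
  precludes a third axis).
* Parallel execution is not implemented; the determinism contract is
  stated for serial runs.
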