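"""Cell agents: cycle with checkpoints, quiescence, division, two-stage
necrosis with lysis, and overdamped adhesion/repulsion mechanics.

The population is stored structure-of-arrays for the hot loops (metabolism,
mechanics); :class:`CellAgent` is a lightweight per-cell view used by the
cycle/death logic and by callers.  Cell-cycle phases follow a fixed
G1 -> S -> G2 -> M structure (defaults 5/8/4/1 h, an 18 h cycle inside the
18-24 h glioblastoma band), with:

* checkpoint 1 (in G1): ATP and local-density conditions; failing either
  sends the cell to quiescence (G0) until both clear,
* checkpoint 3: the G1 target duration is stretched in proportion to the
  oxygen deficit between the hypoxia floor and the reference tension,
* checkpoint 4: volume doubles linearly across S phase,
* division at M completion: equal-volume daughters with copied metabolic
  state and independently redrawn gamma (lognormal around the parent).

Necrosis triggers when ATP stays below the death threshold (0.3 mM) for at
least 3 h, with per-evaluation probability increasing with the depth of the
deficit.  Necrotic cells swell, lyse (releasing glucose, lactate and
protons into their voxel), shrink to debris and are finally cleared.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from ._kernels import _counter_uniform, counter_normal, mechanics_step_kernel
from .config import CellConfig
from .metabolism import BASAL_VALUES, init_state
from .state import GLC_I, GLY, H_I, LAC_I, N_FLUXES, N_VARS, MetabolicState


class Phase(IntEnum):
    G1 = 0
    S = 1
    G2 = 2
    M = 3
    G0 = 4
    NECROTIC_SWELLING = 5
    NECROTIC_SHRINKING = 6
    DEBRIS = 7
    REMOVED = 8


LIVING_PHASES = (Phase.G1, Phase.S, Phase.G2, Phase.M, Phase.G0)
PROLIFERATIVE_PHASES = (Phase.G1, Phase.S, Phase.G2, Phase.M)


def radius_from_volume(volume_um3: float) -> float:
    return (3.0 * volume_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class LysisDeposit:
    """Amounts released into the cell's voxel at lysis (cell-volume mM)."""

    glucose: float
    lactate: float
    proton: float
    oxygen: float
    volume_um3: float

    def voxel_concentrations(self, voxel_volume_um3: float) -> dict[str, float]:
        f = self.volume_um3 / voxel_volume_um3
        return {
            "glucose": self.glucose * f,
            "lactate": self.lactate * f,
            "proton": self.proton * f,
            "oxygen": self.oxygen * f,
        }


class Population:
    """Structure-of-arrays container for all agents (including dead ones)."""

    def __init__(self, config: CellConfig, capacity: int = 64):
        self.config = config
        cap = max(capacity, 1)
        self.n = 0
        self._next_id = 0
        self.cell_id = np.zeros(cap, dtype=np.int64)
        self.pos = np.zeros((cap, 2))
        self.volume = np.zeros(cap)
        self.phase = np.full(cap, int(Phase.REMOVED), dtype=np.int64)
        self.phase_clock = np.zeros(cap)
        self.g1_progress = np.zeros(cap)
        self.atp_deficit_clock = np.zeros(cap)
        self.necrosis_volume0 = np.zeros(cap)
        self.gamma = np.ones(cap)
        self.states = np.zeros((cap, N_VARS))
        self.flux_window = np.zeros((cap, N_FLUXES))

    # -- slot management ---------------------------------------------------

    def _grow(self, need: int) -> None:
        cap = self.cell_id.shape[0]
        if need <= cap:
            return
        new = max(need, 2 * cap)
        for name in ("cell_id", "pos", "volume", "phase", "phase_clock",
                     "g1_progress", "atp_deficit_clock", "necrosis_volume0",
                     "gamma", "states", "flux_window"):
            arr = getattr(self, name)
            shape = (new,) + arr.shape[1:]
            bigger = np.zeros(shape, dtype=arr.dtype)
            bigger[: arr.shape[0]] = arr
            setattr(self, name, bigger)
        self.phase[self.n:] = int(Phase.REMOVED)

    def add_cell(self, position, volume: float, phase: Phase, phase_clock: float,
                 gamma: float, state_vector: np.ndarray | None = None) -> int:
        self._grow(self.n + 1)
        i = self.n
        self.n += 1
        self.cell_id[i] = self._next_id
        self._next_id += 1
        self.pos[i] = position
        self.volume[i] = volume
        self.phase[i] = int(phase)
        self.phase_clock[i] = phase_clock
        self.g1_progress[i] = phase_clock if phase == Phase.G1 else 0.0
        self.atp_deficit_clock[i] = 0.0
        self.gamma[i] = gamma
        self.states[i] = BASAL_VALUES if state_vector is None else state_vector
        self.flux_window[i] = 0.0
        return i

    def remove(self, i: int) -> None:
        """Swap-with-last removal; cell ids stay stable."""
        last = self.n - 1
        if i != last:
            for name in ("cell_id", "pos", "volume", "phase", "phase_clock",
                         "g1_progress", "atp_deficit_clock", "necrosis_volume0",
                         "gamma", "states", "flux_window"):
                arr = getattr(self, name)
                arr[i] = arr[last]
        self.phase[last] = int(Phase.REMOVED)
        self.n = last

    # -- views and masks ---------------------------------------------------

    def agent(self, i: int) -> "CellAgent":
        return CellAgent(self, i)

    def agents(self) -> list["CellAgent"]:
        return [CellAgent(self, i) for i in range(self.n)]

    def living_mask(self) -> np.ndarray:
        ph = self.phase[: self.n]
        return ph <= int(Phase.G0)

    def radii(self) -> np.ndarray:
        return (3.0 * self.volume[: self.n] / (4.0 * math.pi)) ** (1.0 / 3.0)

    def counts(self) -> dict[str, int]:
        """Exact partition of all agents into the four reported states."""
        ph = self.phase[: self.n]
        proliferative = int(np.sum(ph <= int(Phase.M)))
        quiescent = int(np.sum(ph == int(Phase.G0)))
        necrotic = int(np.sum((ph == int(Phase.NECROTIC_SWELLING))
                              | (ph == int(Phase.NECROTIC_SHRINKING))))
        debris = int(np.sum(ph == int(Phase.DEBRIS)))
        assert proliferative + quiescent + necrotic + debris == self.n
        return {
            "proliferative": proliferative,
            "quiescent": quiescent,
            "necrotic": necrotic,
            "debris": debris,
            "total": self.n,
        }


class CellAgent:
    """Per-cell view over the population arrays."""

    __slots__ = ("_pop", "_i")

    def __init__(self, pop: Population, i: int):
        self._pop = pop
        self._i = i

    @classmethod
    def single(cls, config: CellConfig | None = None, *, gamma: float = 1.0,
               position=(0.0, 0.0), phase: Phase = Phase.G1) -> "CellAgent":
        """A free-standing agent backed by a one-cell population."""
        cfg = config or CellConfig()
        pop = Population(cfg, capacity=4)
        i = pop.add_cell(np.asarray(position, dtype=float), cfg.volume_um3,
                         phase, 0.0, gamma, init_state(gamma).variables)
        return pop.agent(i)

    # attribute plumbing
    @property
    def id(self) -> int:
        return int(self._pop.cell_id[self._i])

    @property
    def position(self) -> np.ndarray:
        return self._pop.pos[self._i]

    @position.setter
    def position(self, value) -> None:
        self._pop.pos[self._i] = value

    @property
    def volume(self) -> float:
        return float(self._pop.volume[self._i])

    @volume.setter
    def volume(self, v: float) -> None:
        self._pop.volume[self._i] = v

    @property
    def radius(self) -> float:
        return radius_from_volume(self.volume)

    @property
    def phase(self) -> Phase:
        return Phase(self._pop.phase[self._i])

    @phase.setter
    def phase(self, ph: Phase) -> None:
        self._pop.phase[self._i] = int(ph)

    @property
    def phase_clock(self) -> float:
        return float(self._pop.phase_clock[self._i])

    @phase_clock.setter
    def phase_clock(self, v: float) -> None:
        self._pop.phase_clock[self._i] = v

    @property
    def atp_deficit_clock(self) -> float:
        return float(self._pop.atp_deficit_clock[self._i])

    @atp_deficit_clock.setter
    def atp_deficit_clock(self, v: float) -> None:
        self._pop.atp_deficit_clock[self._i] = v

    @property
    def gamma(self) -> float:
        return float(self._pop.gamma[self._i])

    @gamma.setter
    def gamma(self, g: float) -> None:
        self._pop.gamma[self._i] = g

    @property
    def metabolic_state(self) -> MetabolicState:
        return MetabolicState(self._pop.states[self._i], self.gamma)

    @property
    def alive(self) -> bool:
        return self.phase in LIVING_PHASES

    @property
    def config(self) -> CellConfig:
        return self._pop.config


# ---------------------------------------------------------------------------
# population construction
# ---------------------------------------------------------------------------


def create_initial_population(n: int, disc_radius_um: float, seed: int,
                              config: CellConfig | None = None,
                              center=(0.0, 0.0)) -> Population:
    """Pack ``n`` cells in a jittered hex lattice inside a disc.

    Initial phases are sampled with probability proportional to phase
    duration and clocks uniform within the phase, so the population starts
    asynchronous.  Deterministic for a given seed.
    """
    if n < 0:
        raise ValueError("cell count must be non-negative")
    cfg = config or CellConfig()
    if n == 0:
        return Population(cfg, capacity=16)
    cell_r = radius_from_volume(cfg.volume_um3)
    # hex lattice spacing that fits n sites in the disc
    area_per_cell = math.pi * disc_radius_um ** 2 / n
    spacing = math.sqrt(2.0 * area_per_cell / math.sqrt(3.0))
    if spacing < 1.8 * cell_r:
        raise ValueError(
            f"disc of radius {disc_radius_um} um too small to pack {n} cells "
            f"(spacing {spacing:.1f} um < {1.8 * cell_r:.1f} um)"
        )
    rng = np.random.default_rng(seed)
    sites = []
    k = int(disc_radius_um / spacing) + 2
    for row in range(-k * 2, k * 2 + 1):
        y = row * spacing * math.sqrt(3.0) / 2.0
        off = (row % 2) * spacing / 2.0
        for col in range(-k * 2, k * 2 + 1):
            x = col * spacing + off
            sites.append((x * x + y * y, x, y))
    sites.sort()
    sites = sites[:n]
    if len(sites) < n:
        raise ValueError("lattice generation failed to produce enough sites")

    durations = np.array([cfg.g1_h, cfg.s_h, cfg.g2_h, cfg.m_h])
    probs = durations / durations.sum()
    phases = rng.choice(4, size=n, p=probs)
    clocks = rng.uniform(0.0, durations[phases])
    jitter = rng.uniform(-0.18 * spacing, 0.18 * spacing, size=(n, 2))

    pop = Population(cfg, capacity=max(4 * n, 64))
    for i, (_, x, y) in enumerate(sites):
        ph = Phase(int(phases[i]))
        vol = cfg.volume_um3
        if ph == Phase.S:
            vol *= 1.0 + clocks[i] / cfg.s_h
        elif ph in (Phase.G2, Phase.M):
            vol *= 2.0
        pos = (center[0] + x + jitter[i, 0], center[1] + y + jitter[i, 1])
        pop.add_cell(np.asarray(pos), vol, ph, float(clocks[i]),
                     cfg.gamma_init, init_state(cfg.gamma_init).variables)
    return pop


# ---------------------------------------------------------------------------
# cycle, death, necrosis
# ---------------------------------------------------------------------------


def g1_target_duration(cfg: CellConfig, o2_mmHg: float) -> float:
    """G1 stretched in proportion to oxygen scarcity between the hypoxia
    floor and the reference tension (checkpoint 3)."""
    o2 = min(max(o2_mmHg, cfg.hypoxia_floor_mmHg), cfg.o2_reference_mmHg)
    return cfg.g1_h * cfg.o2_reference_mmHg / o2


def advance_cycle(cell: CellAgent, dt_h: float, local_density: float,
                  o2_mmHg: float, atp_mM: float) -> bool:
    """Advance one cycle evaluation; returns True when the cell completes M
    (division signal)."""
    if not cell.alive:
        raise ValueError("cannot advance the cycle of a dead cell")
    cfg = cell.config
    ph = cell.phase
    conditions_ok = (atp_mM >= cfg.atp_checkpoint_mM
                     and local_density <= cfg.density_threshold)
    if ph == Phase.G0:
        cell.phase_clock += dt_h
        if conditions_ok:
            cell.phase = Phase.G1
            cell.phase_clock = cell._pop.g1_progress[cell._i]
        return False
    if ph == Phase.G1:
        if not conditions_ok:  # checkpoints 1 -> 2
            cell._pop.g1_progress[cell._i] = cell.phase_clock
            cell.phase = Phase.G0
            cell.phase_clock = 0.0
            return False
        cell.phase_clock += dt_h
        if cell.phase_clock >= g1_target_duration(cfg, o2_mmHg):
            cell.phase = Phase.S
            cell.phase_clock = 0.0
            cell._pop.g1_progress[cell._i] = 0.0
        return False
    if ph == Phase.S:
        cell.phase_clock += dt_h
        frac = min(cell.phase_clock / cfg.s_h, 1.0)
        cell.volume = cfg.volume_um3 * (1.0 + frac)  # checkpoint 4
        if cell.phase_clock >= cfg.s_h:
            cell.phase = Phase.G2
            cell.phase_clock = 0.0
        return False
    if ph == Phase.G2:
        cell.phase_clock += dt_h
        if cell.phase_clock >= cfg.g2_h:
            cell.phase = Phase.M
            cell.phase_clock = 0.0
        return False
    # M phase
    cell.phase_clock += dt_h
    if cell.phase_clock >= cfg.m_h:
        return True
    return False


def draw_gamma(parent_gamma: float, cfg: CellConfig, u_normal: float) -> float:
    """Lognormal multiplicative perturbation, clipped to the allowed range."""
    g = parent_gamma * math.exp(cfg.gamma_sigma * u_normal)
    return min(max(g, cfg.gamma_min), cfg.gamma_max)


def divide(cell: CellAgent, rng_key: tuple[int, int]) -> CellAgent:
    """Split at mitosis completion: the parent slot becomes daughter 1, a
    new slot holds daughter 2.  Equal volumes, copied metabolic state,
    positions offset by one radius along a random direction, gammas
    independently redrawn around the parent value."""
    pop = cell._pop
    cfg = cell.config
    seed, tick = rng_key
    cid = cell.id
    parent_volume = cell.volume
    parent_gamma = cell.gamma
    state_copy = pop.states[cell._i].copy()

    theta = 2.0 * math.pi * _counter_uniform(seed, cid, tick, 101)
    direction = np.array([math.cos(theta), math.sin(theta)])
    r = radius_from_volume(parent_volume / 2.0)
    p0 = cell.position.copy()

    cell.volume = parent_volume / 2.0
    cell.phase = Phase.G1
    cell.phase_clock = 0.0
    pop.g1_progress[cell._i] = 0.0
    cell.position = p0 - 0.5 * r * direction
    cell.gamma = draw_gamma(parent_gamma, cfg, counter_normal(seed, cid, tick, 102))

    j = pop.add_cell(p0 + 0.5 * r * direction, parent_volume / 2.0, Phase.G1,
                     0.0, parent_gamma, state_copy)
    d2 = pop.agent(j)
    d2.gamma = draw_gamma(parent_gamma, cfg, counter_normal(seed, cid, tick, 103))
    return d2


def update_death(cell: CellAgent, dt_h: float, rng_key: tuple[int, int]) -> None:
    """Necrosis trigger: the ATP deficit must persist for 3 h, after which
    the per-evaluation death probability grows with the depth of depletion:
    p = clamp(1 - ATP/0.3, 0, 1) * p_max."""
    if not cell.alive:
        return
    cfg = cell.config
    atp = cell.metabolic_state.atp
    if atp < cfg.atp_death_mM:
        cell.atp_deficit_clock += dt_h
    else:
        cell.atp_deficit_clock = 0.0
        return
    if cell.atp_deficit_clock < cfg.death_persistence_h:
        return
    p = min(max(1.0 - atp / cfg.atp_death_mM, 0.0), 1.0) * cfg.death_p_max
    seed, tick = rng_key
    if _counter_uniform(seed, cell.id, tick, 104) < p:
        cell.phase = Phase.NECROTIC_SWELLING
        cell.phase_clock = 0.0
        cell._pop.necrosis_volume0[cell._i] = cell.volume


def progress_necrosis(cell: CellAgent, dt_h: float) -> LysisDeposit | None:
    """Two-stage necrosis: swelling, lysis (released contents returned),
    shrinkage to debris, then clearance."""
    cfg = cell.config
    pop = cell._pop
    ph = cell.phase
    if ph == Phase.NECROTIC_SWELLING:
        cell.phase_clock += dt_h
        v0 = pop.necrosis_volume0[cell._i]
        frac = min(cell.phase_clock / cfg.swell_h, 1.0)
        cell.volume = v0 * (1.0 + (cfg.swell_factor - 1.0) * frac)
        if cell.phase_clock >= cfg.swell_h:
            state = pop.states[cell._i]
            deposit = LysisDeposit(
                glucose=float(state[GLC_I]) + float(state[GLY]),  # incl. stores
                lactate=float(state[LAC_I]),
                proton=float(state[H_I]),
                oxygen=cfg.lysis_nominal_o2_mM,
                volume_um3=cell.volume,
            )
            state[:] = 0.0
            cell.phase = Phase.NECROTIC_SHRINKING
            cell.phase_clock = 0.0
            pop.necrosis_volume0[cell._i] = cell.volume
            return deposit
        return None
    if ph == Phase.NECROTIC_SHRINKING:
        cell.phase_clock += dt_h
        v0 = pop.necrosis_volume0[cell._i]
        vmin = cfg.debris_volume_frac * cfg.volume_um3
        frac = min(cell.phase_clock / cfg.shrink_h, 1.0)
        cell.volume = v0 + (vmin - v0) * frac
        if cell.phase_clock >= cfg.shrink_h:
            cell.phase = Phase.DEBRIS
            cell.phase_clock = 0.0
        return None
    if ph == Phase.DEBRIS:
        cell.phase_clock += dt_h
        return None
    raise ValueError(f"cell in phase {ph.name} is not necrotic")


# ---------------------------------------------------------------------------
# mechanics and density
# ---------------------------------------------------------------------------


def mechanics_step(pop: Population, dt_s: float, extent_um: float) -> None:
    """Overdamped position update from pairwise adhesion/repulsion forces."""
    cfg = pop.config
    n = pop.n
    if n == 0:
        return
    pos = pop.pos[:n]
    radii = pop.radii()
    vel = np.zeros_like(pos)
    mechanics_step_kernel(pos, radii, dt_s / 60.0, cfg.repulsion,
                          cfg.adhesion, cfg.adhesion_scale, extent_um, vel)


def rest_separation(cfg: CellConfig, r_i: float, r_j: float) -> float:
    """Pair distance at which repulsion balances adhesion."""
    s = r_i + r_j
    ra = cfg.adhesion_scale * s
    sq_rep = math.sqrt(cfg.repulsion)
    sq_adh = math.sqrt(cfg.adhesion)
    if sq_adh == 0.0:
        return s
    return (sq_rep - sq_adh) / (sq_rep / s - sq_adh / ra)


def local_density(cell: CellAgent, neighbors) -> float:
    """Fraction of the reference neighborhood disc covered by neighbor
    cross-sections (centers within the neighborhood radius).  Can exceed 1
    under transient overlap."""
    cfg = cell.config
    rn = cfg.neighborhood_radius_um
    area = 0.0
    cx, cy = cell.position
    for nb in neighbors:
        dx = nb.position[0] - cx
        dy = nb.position[1] - cy
        if dx * dx + dy * dy <= rn * rn:
            area += math.pi * nb.radius ** 2
    return area / (math.pi * rn * rn)


def local_densities(pop: Population, extent_um: float) -> np.ndarray:
    """Vectorized neighborhood occupancy for every agent (same rule as
    :func:`local_density`)."""
    from scipy.spatial import cKDTree

    n = pop.n
    if n == 0:
        return np.zeros(0)
    rn = pop.config.neighborhood_radius_um
    pos = pop.pos[:n]
    radii = pop.radii()
    areas = math.pi * radii ** 2
    tree = cKDTree(pos)
    out = np.zeros(n)
    pairs = tree.query_ball_point(pos, rn)
    for i, idx in enumerate(pairs):
        s = 0.0
        for j in idx:
            if j != i:
                s += areas[j]
        out[i] = s / (math.pi * rn * rn)
    return out
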