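"""Voxelized extracellular medium: reaction-diffusion of oxygen, glucose,
lactate and protons on a 2D lattice.

The diffusion solver is a locally-one-dimensional (operator-split) implicit
scheme with tridiagonal solves per axis.  It is unconditionally stable, which
matters because the standard 0.6 s diffusion step is far beyond the explicit
stability bound for protons on a 20 um lattice (~0.02 s).

Unit conventions: concentrations in mM, lengths in um, diffusion
coefficients in um^2/min.  Oxygen is converted between partial pressure
(mmHg) and mM with the Valabregue solubility coefficient 1.30e-3 mM/mmHg.
Protons are stored and diffused as free concentration; pH is derived for
reporting and for the glycolysis-modulation input.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import lod_diffusion_step
from .config import DIFFUSION_UM2_MIN, VALABREGUE_MM_PER_MMHG, ScenarioConfig
from .state import SPECIES_NAMES


class DivergenceError(RuntimeError):
    """Raised when a diffusion step produces non-finite values."""


def o2_mmHg_to_mM(p_mmHg: float) -> float:
    """Oxygen partial pressure to dissolved concentration."""
    if np.any(np.asarray(p_mmHg) < 0):
        raise ValueError("oxygen pressure must be non-negative")
    return p_mmHg * VALABREGUE_MM_PER_MMHG


def o2_mM_to_mmHg(c_mM: float) -> float:
    if np.any(np.asarray(c_mM) < 0):
        raise ValueError("oxygen concentration must be non-negative")
    return c_mM / VALABREGUE_MM_PER_MMHG


def ph_from_proton(c_mM: float) -> float:
    """pH from free-proton concentration in mM."""
    c = np.asarray(c_mM, dtype=float)
    if np.any(c <= 0):
        raise ValueError("proton concentration must be positive")
    out = -np.log10(c * 1e-3)
    return float(out) if out.ndim == 0 else out


def proton_from_ph(ph: float) -> float:
    ph = np.asarray(ph, dtype=float)
    if not np.all(np.isfinite(ph)):
        raise ValueError("pH must be finite")
    out = 10.0 ** (-ph) * 1e3
    return float(out) if out.ndim == 0 else out


@dataclass
class BoundaryCondition:
    kind: str                      # dirichlet | neumann_zero_flux
    value: float | None = None     # mM, dirichlet only


@dataclass
class SpeciesField:
    """One diffusible species on the shared lattice."""

    name: str
    concentrations: np.ndarray     # (nx, ny), mM
    diffusion_coefficient: float   # um^2/min
    boundary: BoundaryCondition
    voxel_size: float              # um

    def __post_init__(self) -> None:
        if self.name not in SPECIES_NAMES:
            raise ValueError(f"unknown species {self.name!r}")
        self.concentrations = np.ascontiguousarray(self.concentrations, dtype=np.float64)
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")

    def total_mass(self) -> float:
        """Total amount in mM * voxel units (uniform voxel volume)."""
        return float(self.concentrations.sum())


@dataclass
class RadialProfile:
    bin_centers: np.ndarray        # um from the profiling center
    means: np.ndarray              # mM (NaN where a bin holds no voxel)
    counts: np.ndarray             # voxels per bin

    @property
    def empty_bins(self) -> np.ndarray:
        return self.counts == 0


@dataclass
class Grid:
    """The four species fields plus the per-voxel cell exchange accumulator."""

    extent: float
    voxel_size: float
    fields: dict[str, SpeciesField]
    exchange: dict[str, np.ndarray] = field(default_factory=dict)
    clipped_mass: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {f.concentrations.shape for f in self.fields.values()}
        if len(shapes) != 1:
            raise ValueError("all species fields must share the lattice geometry")
        self._shape = shapes.pop()
        if not self.exchange:
            self.exchange = {n: np.zeros(self._shape) for n in SPECIES_NAMES}
        if not self.clipped_mass:
            self.clipped_mass = {n: 0.0 for n in SPECIES_NAMES}

    @property
    def n(self) -> int:
        return int(round(self.extent / self.voxel_size))

    @property
    def shape(self) -> tuple[int, int]:
        return self._shape

    @property
    def voxel_volume_um3(self) -> float:
        # the 2D lattice is one voxel thick
        return self.voxel_size ** 3

    def voxel_centers(self) -> np.ndarray:
        return (np.arange(self.n) + 0.5) * self.voxel_size

    def voxel_of(self, position) -> tuple[int, int]:
        i = int(position[0] / self.voxel_size)
        j = int(position[1] / self.voxel_size)
        nx, ny = self.shape
        if not (0 <= i < nx and 0 <= j < ny):
            raise IndexError(f"position {position} outside the domain")
        return i, j

    # -- cell <-> environment exchange ------------------------------------

    def deposit_exchange(self, voxel_index, rates_mM_min: dict[str, float]) -> None:
        """Add per-voxel net source/sink rates; additive over cells."""
        i, j = voxel_index
        nx, ny = self.shape
        if not (0 <= i < nx and 0 <= j < ny):
            raise IndexError(f"voxel index {voxel_index} outside the domain")
        for name, rate in rates_mM_min.items():
            self.exchange[name][i, j] += rate

    def withdraw(self, species: str, voxel_index, amount_mM: float) -> float:
        """Mass-limited withdrawal: returns what was actually available.

        The voxel concentration floors at zero; the caller receives
        ``min(requested, available)``.
        """
        i, j = voxel_index
        c = self.fields[species].concentrations
        granted = min(amount_mM, c[i, j])
        c[i, j] -= granted
        return granted

    # -- diffusion ----------------------------------------------------------

    def step_diffusion(self, dt_s: float) -> None:
        """Advance all species one implicit diffusion step, consuming the
        exchange accumulator; Dirichlet boundaries re-imposed exactly."""
        if dt_s <= 0:
            raise ValueError("dt must be positive")
        for name, f in self.fields.items():
            dirichlet = f.boundary.kind == "dirichlet"
            bc = f.boundary.value if dirichlet else 0.0
            clipped = lod_diffusion_step(
                f.concentrations, f.diffusion_coefficient, dt_s, self.voxel_size,
                dirichlet, bc, self.exchange[name],
            )
            self.clipped_mass[name] += clipped
            if not np.all(np.isfinite(f.concentrations)):
                raise DivergenceError(
                    f"non-finite concentration in species {name!r} after diffusion step"
                )
            self.exchange[name][:] = 0.0


def make_grid(config: ScenarioConfig) -> Grid:
    """Build the lattice from a scenario config (errors on bad geometry)."""
    config.grid.validate()
    if set(config.species) != set(SPECIES_NAMES):
        raise ValueError(f"species must be exactly {SPECIES_NAMES}")
    n = config.grid.n_voxels
    fields = {}
    for name in SPECIES_NAMES:
        sp = config.species[name]
        sp.validate()
        bc = BoundaryCondition(
            kind=sp.boundary_kind,
            value=sp.boundary_value_mM if sp.boundary_kind == "dirichlet" else None,
        )
        conc = np.full((n, n), sp.initial_mM, dtype=np.float64)
        if bc.kind == "dirichlet":
            conc[0, :] = conc[-1, :] = bc.value
            conc[:, 0] = conc[:, -1] = bc.value
        fields[name] = SpeciesField(
            name=name,
            concentrations=conc,
            diffusion_coefficient=DIFFUSION_UM2_MIN[name],
            boundary=bc,
            voxel_size=config.grid.voxel_um,
        )
    return Grid(extent=config.grid.extent_um, voxel_size=config.grid.voxel_um, fields=fields)


def radial_profile(field: SpeciesField, center, bin_width: float) -> RadialProfile:
    """Mean concentration over voxels binned by distance from ``center``.

    Every voxel contributes to exactly one bin; empty bins are flagged
    (NaN mean, zero count), not zero-filled.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    nx, ny = field.concentrations.shape
    extent = nx * field.voxel_size
    if not (0 <= center[0] <= extent and 0 <= center[1] <= ny * field.voxel_size):
        raise ValueError("profiling center outside the domain")
    xs = (np.arange(nx) + 0.5) * field.voxel_size
    ys = (np.arange(ny) + 0.5) * field.voxel_size
    dx = xs[:, None] - center[0]
    dy = ys[None, :] - center[1]
    r = np.hypot(dx, dy)
    nbins = int(math.ceil(r.max() / bin_width)) + 1
    idx = np.minimum((r / bin_width).astype(np.int64), nbins - 1)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    sums = np.bincount(idx.ravel(), weights=field.concentrations.ravel(), minlength=nbins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(nbins) + 0.5) * bin_width
    return RadialProfile(bin_centers=centers, means=means, counts=counts)
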