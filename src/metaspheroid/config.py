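"""Scenario configuration: grid, species, cells, schedule, perturbations.

Configs are plain dataclasses with JSON round-tripping.  The shipped
scenario files under ``data/configs`` are produced by the builders in
:mod:`metaspheroid.scenarios`.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .state import SPECIES_NAMES

#: fixed per-species diffusion coefficients (um^2/min)
DIFFUSION_UM2_MIN = {
    "oxygen": 87_600.0,
    "glucose": 30_000.0,
    "lactate": 12_600.0,
    "proton": 270_000.0,
}

VALABREGUE_MM_PER_MMHG = 1.30e-3


@dataclass
class SpeciesConfig:
    name: str
    initial_mM: float
    boundary_kind: str = "dirichlet"          # dirichlet | neumann_zero_flux
    boundary_value_mM: float | None = None    # required for dirichlet

    def validate(self) -> None:
        if self.name not in SPECIES_NAMES:
            raise ValueError(f"unknown species name {self.name!r}")
        if self.initial_mM < 0:
            raise ValueError(f"{self.name}: initial concentration must be >= 0")
        if self.boundary_kind not in ("dirichlet", "neumann_zero_flux"):
            raise ValueError(f"{self.name}: unknown boundary kind {self.boundary_kind!r}")
        if self.boundary_kind == "dirichlet":
            if self.boundary_value_mM is None or self.boundary_value_mM < 0:
                raise ValueError(f"{self.name}: dirichlet boundary needs a value >= 0")


@dataclass
class GridConfig:
    extent_um: float = 800.0
    voxel_um: float = 20.0

    def validate(self) -> None:
        if self.voxel_um <= 0:
            raise ValueError("voxel size must be positive")
        n = self.extent_um / self.voxel_um
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError("extent must be a positive multiple of voxel size")

    @property
    def n_voxels(self) -> int:
        return int(round(self.extent_um / self.voxel_um))


@dataclass
class CellConfig:
    n_initial: int = 200
    disc_radius_um: float = 170.0
    volume_um3: float = 2494.0
    # cycle
    g1_h: float = 5.0
    s_h: float = 8.0
    g2_h: float = 4.0
    m_h: float = 1.0
    density_threshold: float = 0.55
    atp_checkpoint_mM: float = 0.8
    hypoxia_floor_mmHg: float = 15.0
    o2_reference_mmHg: float = 38.0
    neighborhood_radius_um: float = 25.0
    # death
    atp_death_mM: float = 0.3
    death_persistence_h: float = 3.0
    death_p_max: float = 0.2
    # necrosis
    swell_factor: float = 1.5
    swell_h: float = 6.0
    shrink_h: float = 24.0
    debris_volume_frac: float = 0.1
    debris_clear_h: float = 24.0
    lysis_nominal_o2_mM: float = 0.05
    # heritable gene-regulation modulation
    gamma_init: float = 1.0
    gamma_sigma: float = 0.05
    gamma_min: float = 0.5
    gamma_max: float = 2.0
    # mechanics
    repulsion: float = 10.0
    adhesion: float = 0.5
    adhesion_scale: float = 1.25

    def validate(self) -> None:
        if self.n_initial < 0:
            raise ValueError("initial cell count must be non-negative")
        for name in ("g1_h", "s_h", "g2_h", "m_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.density_threshold <= 1:
            raise ValueError("density threshold must be in (0, 1]")

    @property
    def total_cycle_h(self) -> float:
        return self.g1_h + self.s_h + self.g2_h + self.m_h


@dataclass
class ScheduleConfig:
    dt_diffusion_s: float = 0.6
    dt_metabolism_s: float = 1.2
    dt_mechanics_s: float = 6.0
    dt_phenotype_s: float = 360.0
    t_end_h: float = 120.0

    def validate(self) -> None:
        for name in ("dt_diffusion_s", "dt_metabolism_s", "dt_mechanics_s",
                     "dt_phenotype_s", "t_end_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        ratios = (self.dt_metabolism_s / self.dt_diffusion_s,
                  self.dt_mechanics_s / self.dt_diffusion_s,
                  self.dt_phenotype_s / self.dt_diffusion_s)
        if ratios != (2.0, 10.0, 600.0):
            warnings.warn(
                f"non-default time-step ratios {ratios}; the standard schedule is "
                "metabolism=2x, mechanics=10x, phenotype=600x diffusion",
                stacklevel=2,
            )
        for name in ("dt_metabolism_s", "dt_mechanics_s", "dt_phenotype_s"):
            k = getattr(self, name) / self.dt_diffusion_s
            if abs(k - round(k)) > 1e-9:
                raise ValueError(f"{name} must be an integer multiple of dt_diffusion_s")


@dataclass
class PerturbationEntry:
    """A timed environmental perturbation.

    kinds:
      * ``boundary_set``: set a species' Dirichlet boundary value.
      * ``field_clamp``: overwrite the whole field (and boundary) each
        diffusion step while active.
      * ``square_wave``: boundary alternates ``high``/``low``, the high phase
        occupying the first half of each period.
    """

    kind: str
    species: str
    t_start_h: float = 0.0
    t_end_h: float = float("inf")
    value_mM: float | None = None
    high_mM: float | None = None
    low_mM: float | None = None
    period_h: float | None = None

    def validate(self) -> None:
        if self.kind not in ("boundary_set", "field_clamp", "square_wave"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.species not in SPECIES_NAMES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.kind in ("boundary_set", "field_clamp") and self.value_mM is None:
            raise ValueError(f"{self.kind} needs value_mM")
        if self.kind == "square_wave":
            if None in (self.high_mM, self.low_mM, self.period_h):
                raise ValueError("square_wave needs high_mM, low_mM and period_h")

    def active(self, t_h: float) -> bool:
        return self.t_start_h <= t_h < self.t_end_h

    def boundary_value(self, t_h: float) -> float:
        if self.kind == "square_wave":
            phase = (t_h - self.t_start_h) % self.period_h
            return self.high_mM if phase < self.period_h / 2 else self.low_mM
        return self.value_mM


@dataclass
class OutputConfig:
    snapshot_every_h: float = 1.0
    out_dir: str | None = None
    save_fields: bool = False
    ldh_range: tuple[float, float] = (0.0, 8.0)
    pdh_range: tuple[float, float] = (0.0, 1.5)
    landscape_bins: int = 60
    radial_bin_um: float = 20.0


@dataclass
class ScenarioConfig:
    name: str = "reference"
    seed: int = 0
    grid: GridConfig = field(default_factory=GridConfig)
    species: dict[str, SpeciesConfig] = field(default_factory=dict)
    cells: CellConfig = field(default_factory=CellConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    perturbations: list[PerturbationEntry] = field(default_factory=list)
    outputs: OutputConfig = field(default_factory=OutputConfig)
    noise_sigma: float | None = None   # overrides the parameter-table value
    param_table: str | None = None     # path to an alternative parameter CSV

    def validate(self) -> None:
        self.grid.validate()
        if set(self.species) != set(SPECIES_NAMES):
            raise ValueError(f"species must be exactly {SPECIES_NAMES}")
        for name, sp in self.species.items():
            if sp.name != name:
                raise ValueError("species dict key/name mismatch")
            sp.validate()
        self.cells.validate()
        self.schedule.validate()
        for entry in self.perturbations:
            entry.validate()
        self._check_overlaps()

    def _check_overlaps(self) -> None:
        """Two field clamps on the same species must not be simultaneously active."""
        clamps = [e for e in self.perturbations if e.kind == "field_clamp"]
        for i, a in enumerate(clamps):
            for b in clamps[i + 1:]:
                if a.species != b.species:
                    continue
                lo = max(a.t_start_h, b.t_start_h)
                hi = min(a.t_end_h, b.t_end_h)
                if lo < hi and a.value_mM != b.value_mM:
                    raise ValueError(
                        f"contradictory field clamps on {a.species} overlap in [{lo}, {hi}) h"
                    )

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outputs"]["ldh_range"] = list(self.outputs.ldh_range)
        d["outputs"]["pdh_range"] = list(self.outputs.pdh_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["grid"] = GridConfig(**d.get("grid", {}))
        d["species"] = {k: SpeciesConfig(**v) for k, v in d.get("species", {}).items()}
        d["cells"] = CellConfig(**d.get("cells", {}))
        d["schedule"] = ScheduleConfig(**d.get("schedule", {}))
        d["perturbations"] = [PerturbationEntry(**e) for e in d.get("perturbations", [])]
        out = dict(d.get("outputs", {}))
        for key in ("ldh_range", "pdh_range"):
            if key in out:
                out[key] = tuple(out[key])
        d["outputs"] = OutputConfig(**out)
        return cls(**d)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioConfig":
        cfg = cls.from_dict(json.loads(Path(path).read_text()))
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
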