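"""Multirate scheduler binding environment, metabolism and cells.

One diffusion tick is the base clock (0.6 s).  Metabolism runs every 2nd
tick, mechanics every 10th, and the phenotype evaluation (classification,
gene regulation, cycle/death checkpointing, snapshots) closes every 600th
tick, i.e. every 6 simulated minutes.  Within a tick the order is:
perturbations -> cell exchange deposition (metabolism) -> diffusion.
Exchange is accumulated per voxel and applied by the diffusion solver, and
all per-cell randomness comes from counter-based streams keyed by
(seed, cell id, tick), so results do not depend on cell iteration order
and identical (config, seed) pairs reproduce byte-identical outputs.
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import params as P
from . import state as S
from ._kernels import gene_protein_step, metabolism_tick
from .cells import (
    CellAgent,
    Phase,
    Population,
    advance_cycle,
    create_initial_population,
    divide,
    local_densities,
    mechanics_step,
    progress_necrosis,
    update_death,
)
from .config import PerturbationEntry, ScenarioConfig, VALABREGUE_MM_PER_MMHG
from .environment import Grid, make_grid, radial_profile
from .metabolism import IntegrationError, get_params
from .phenotyping import (
    Landscape,
    LactateStatus,
    PhenotypeLabel,
    classify_lactate_status,
    classify_phenotype,
    neutral_band,
)

__version__ = "0.1.0"

#: canonical alias: the multirate schedule is configured via ScheduleConfig
from .config import ScheduleConfig as Schedule  # noqa: E402  (re-export)


def apply_perturbation(grid: Grid, entry: PerturbationEntry, t_h: float) -> Grid:
    """Apply one schedule entry at time ``t_h`` (no-op when inactive).

    ``boundary_set`` and ``square_wave`` change the Dirichlet boundary
    value; ``field_clamp`` overwrites the whole field (the paper-style
    "uniformly imposed" condition) in addition to the boundary.
    """
    if not entry.active(t_h):
        return grid
    f = grid.fields[entry.species]
    value = entry.boundary_value(t_h)
    f.boundary.kind = "dirichlet"
    f.boundary.value = value
    if entry.kind == "field_clamp":
        f.concentrations[:, :] = value
    return grid


@dataclass
class SimulationOutput:
    """Time series, accumulated landscape and manifest of one run."""

    times_h: np.ndarray
    counts: dict[str, np.ndarray]
    label_fractions: dict[str, np.ndarray]
    status_fractions: dict[str, np.ndarray]
    boundary_o2_mmHg: np.ndarray
    landscape: Landscape
    radial_bin_centers: np.ndarray
    radial_means: dict[str, np.ndarray]          # (n_snapshots, n_bins)
    cell_table: pd.DataFrame
    invocations: dict[str, int]
    clipped_mass: dict[str, float]
    manifest: dict
    grid: Grid = field(repr=False, default=None)
    population: Population = field(repr=False, default=None)

    def save(self, out_dir: str | Path, save_fields: bool = False) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ts = {"time_h": self.times_h, "boundary_o2_mmHg": self.boundary_o2_mmHg}
        ts.update({f"count_{k}": v for k, v in self.counts.items()})
        ts.update({f"label_{k}": v for k, v in self.label_fractions.items()})
        ts.update({f"status_{k}": v for k, v in self.status_fractions.items()})
        pd.DataFrame(ts).to_csv(out / "timeseries.csv", index=False)
        self.cell_table.to_csv(out / "cells_final.csv", index=False)
        rows = []
        for si, t in enumerate(self.times_h):
            for sp, arr in self.radial_means.items():
                for r, m in zip(self.radial_bin_centers, arr[si]):
                    if np.isfinite(m):
                        rows.append((t, r, sp, m))
        pd.DataFrame(rows, columns=["time_h", "radius_um", "species", "mean_value"]) \
            .to_csv(out / "radial_profiles.csv", index=False)
        np.savetxt(out / "landscape_integrated.csv", self.landscape.integrated,
                   delimiter=",")
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        if save_fields and self.grid is not None:
            import h5py

            with h5py.File(out / "fields_final.h5", "w") as h5:
                g = h5.create_group(f"t_{self.times_h[-1]:.2f}h")
                g.attrs["time_h"] = float(self.times_h[-1])
                for name, fld in self.grid.fields.items():
                    d = g.create_dataset(name, data=fld.concentrations)
                    d.attrs["units"] = "mM"


class SimulationAbort(RuntimeError):
    """Divergence or positivity failure; carries a state dump summary."""


def _cell_table(pop: Population, flux: np.ndarray, labels, statuses) -> pd.DataFrame:
    rows = []
    for i in range(pop.n):
        st = pop.states[i]
        rows.append({
            "id": int(pop.cell_id[i]),
            "x": pop.pos[i, 0],
            "y": pop.pos[i, 1],
            "volume": pop.volume[i],
            "phase": Phase(pop.phase[i]).name,
            "LDH": st[S.LDH_G],
            "PDH": st[S.PDH_G],
            "ATP": st[S.ATP],
            "r12": flux[i, S.R12],
            "r18": flux[i, S.R18],
            "r21": flux[i, S.R21],
            "phenotype": labels.get(i, PhenotypeLabel.DEAD).value,
            "lactate_status": statuses.get(i, LactateStatus.DEAD).value,
        })
    return pd.DataFrame(rows)


def run_simulation(config: ScenarioConfig) -> SimulationOutput:
    """Run one scenario deterministically under its seed."""
    config.validate()
    p = get_params(config.param_table)
    sigma = config.noise_sigma if config.noise_sigma is not None else p[P.P_NOISE_SIGMA]
    seed = int(config.seed)
    sched = config.schedule
    dt = sched.dt_diffusion_s
    m_every = int(round(sched.dt_metabolism_s / dt))
    mech_every = int(round(sched.dt_mechanics_s / dt))
    phe_every = int(round(sched.dt_phenotype_s / dt))
    n_ticks = int(round(sched.t_end_h * 3600.0 / dt))
    snap_every = max(1, int(round(config.outputs.snapshot_every_h * 3600.0
                                  / sched.dt_phenotype_s)))
    total_phenotype_ticks = n_ticks // phe_every
    if total_phenotype_ticks >= 1:
        # guarantee at least one snapshot even for very short runs
        snap_every = min(snap_every, total_phenotype_ticks)

    grid = make_grid(config)
    extent = config.grid.extent_um
    center = (extent / 2.0, extent / 2.0)
    pop = create_initial_population(config.cells.n_initial,
                                    config.cells.disc_radius_um, seed,
                                    config.cells, center=center)
    nvox = grid.n
    vox_vol = grid.voxel_volume_um3
    buffer_e = p[P.P_PROTON_BUFFER_E]

    def voxel_indices():
        vi = np.clip((pop.pos[: pop.n, 0] / grid.voxel_size).astype(np.int64), 0, nvox - 1)
        vj = np.clip((pop.pos[: pop.n, 1] / grid.voxel_size).astype(np.int64), 0, nvox - 1)
        return vi, vj

    vox_i, vox_j = voxel_indices()
    invocations = {"diffusion": 0, "metabolism": 0, "mechanics": 0, "phenotype": 0}
    fields = grid.fields
    o2_field = fields["oxygen"].concentrations
    glc_field = fields["glucose"].concentrations
    lac_field = fields["lactate"].concentrations
    h_field = fields["proton"].concentrations
    acc = grid.exchange

    landscape = Landscape.empty(config.outputs.ldh_range, config.outputs.pdh_range,
                                config.outputs.landscape_bins)
    times, bo2 = [], []
    count_rec: dict[str, list] = {k: [] for k in
                                  ("proliferative", "quiescent", "necrotic", "debris", "total")}
    label_rec = {lab.value: [] for lab in PhenotypeLabel if lab != PhenotypeLabel.DEAD}
    status_rec = {st.value: [] for st in LactateStatus if st != LactateStatus.DEAD}
    radial_means: dict[str, list] = {name: [] for name in fields}
    radial_centers = None
    n_window = 0
    last_labels: dict[int, PhenotypeLabel] = {}
    last_statuses: dict[int, LactateStatus] = {}
    final_table = pd.DataFrame()
    t_start = time.time()

    for k in range(n_ticks):
        t_h = k * dt / 3600.0
        for entry in config.perturbations:
            apply_perturbation(grid, entry, t_h)

        if k % m_every == 0:
            living = np.flatnonzero(pop.living_mask())
            if living.size:
                fail = metabolism_tick(
                    pop.states, living, vox_i, vox_j, pop.volume,
                    o2_field, glc_field, lac_field, h_field,
                    acc["oxygen"], acc["glucose"], acc["lactate"], acc["proton"],
                    sched.dt_metabolism_s, p, pop.flux_window, vox_vol, buffer_e,
                )
                if fail >= 0:
                    raise IntegrationError(
                        f"metabolite integration failed for cell id "
                        f"{int(pop.cell_id[fail])} at t={t_h:.2f} h"
                    )
            n_window += 1
            invocations["metabolism"] += 1

        grid.step_diffusion(dt)
        invocations["diffusion"] += 1

        if k % mech_every == 0:
            mechanics_step(pop, sched.dt_mechanics_s, extent)
            vox_i, vox_j = voxel_indices()
            invocations["mechanics"] += 1

        if (k + 1) % phe_every == 0:
            invocations["phenotype"] += 1
            pt = (k + 1) // phe_every
            dt_h = sched.dt_phenotype_s / 3600.0
            nw = max(n_window, 1)
            pop.flux_window[: pop.n] /= nw

            living = np.flatnonzero(pop.living_mask())
            labels: dict[int, PhenotypeLabel] = {}
            statuses: dict[int, LactateStatus] = {}
            if living.size:
                r12 = pop.flux_window[living, S.R12]
                r18 = pop.flux_window[living, S.R18]
                r21 = pop.flux_window[living, S.R21]
                eps = neutral_band(r21)
                for idx, a, b, c in zip(living, r12, r18, r21):
                    lab = classify_phenotype(None, r12=a, r18=b)
                    labels[int(idx)] = lab
                    statuses[int(idx)] = classify_lactate_status(c, lab, eps)
                # slow gene/protein clock (living cells only)
                states_l = pop.states[living]
                envs_l = np.empty((living.size, 4))
                envs_l[:, 0] = o2_field[vox_i[living], vox_j[living]]
                envs_l[:, 1] = glc_field[vox_i[living], vox_j[living]]
                envs_l[:, 2] = lac_field[vox_i[living], vox_j[living]]
                envs_l[:, 3] = h_field[vox_i[living], vox_j[living]]
                gene_protein_step(states_l, envs_l, pop.gamma[living],
                                  pop.cell_id[living],
                                  sched.dt_phenotype_s / 60.0, p, sigma, seed, pt)
                pop.states[living] = states_l

            dens = local_densities(pop, extent)
            to_divide: list[int] = []
            to_remove: list[int] = []
            for i in range(pop.n):
                cell = pop.agent(i)
                ph = cell.phase
                if ph in (Phase.NECROTIC_SWELLING, Phase.NECROTIC_SHRINKING, Phase.DEBRIS):
                    deposit = progress_necrosis(cell, dt_h)
                    if deposit is not None:
                        dep = deposit.voxel_concentrations(vox_vol)
                        vi, vj = vox_i[i], vox_j[i]
                        glc_field[vi, vj] += dep["glucose"]
                        lac_field[vi, vj] += dep["lactate"]
                        h_field[vi, vj] += dep["proton"] / buffer_e
                        o2_field[vi, vj] += dep["oxygen"]
                    if cell.phase == Phase.DEBRIS and cell.phase_clock >= config.cells.debris_clear_h:
                        to_remove.append(i)
                    continue
                atp = pop.states[i, S.ATP]
                o2_mmHg = o2_field[vox_i[i], vox_j[i]] / VALABREGUE_MM_PER_MMHG
                if advance_cycle(cell, dt_h, dens[i], o2_mmHg, atp):
                    to_divide.append(i)
                update_death(cell, dt_h, (seed, pt))

            for i in to_divide:
                cell = pop.agent(i)
                if cell.phase == Phase.M:  # still alive after death check
                    divide(cell, (seed, pt))
            for i in sorted(to_remove, reverse=True):
                pop.remove(i)
            vox_i, vox_j = voxel_indices()

            if pt % snap_every == 0:
                times.append(t_h + dt / 3600.0)
                bo2.append(fields["oxygen"].boundary.value / VALABREGUE_MM_PER_MMHG
                           if fields["oxygen"].boundary.value is not None else np.nan)
                cts = pop.counts()
                for name in count_rec:
                    count_rec[name].append(cts[name])
                n_living = len(labels)
                for lab in label_rec:
                    label_rec[lab].append(
                        sum(1 for v in labels.values() if v.value == lab) / n_living
                        if n_living else np.nan)
                for st in status_rec:
                    status_rec[st].append(
                        sum(1 for v in statuses.values() if v.value == st) / n_living
                        if n_living else np.nan)
                if living.size:
                    landscape.accumulate(pop.states[living, S.LDH_G],
                                         pop.states[living, S.PDH_G])
                for name, fld in fields.items():
                    prof = radial_profile(fld, center, config.outputs.radial_bin_um)
                    radial_means[name].append(prof.means)
                    radial_centers = prof.bin_centers
                last_labels, last_statuses = labels, statuses
                final_table = _cell_table(pop, pop.flux_window[: pop.n].copy(),
                                          labels, statuses)

            pop.flux_window[: pop.n] *= 0.0
            n_window = 0

    nb = max(len(radial_centers) if radial_centers is not None else 0, 0)
    rm = {}
    for name, lst in radial_means.items():
        arr = np.full((len(lst), nb), np.nan)
        for i, prof in enumerate(lst):
            arr[i, : len(prof)] = prof[:nb]
        rm[name] = arr

    out = SimulationOutput(
        times_h=np.asarray(times),
        counts={k2: np.asarray(v) for k2, v in count_rec.items()},
        label_fractions={k2: np.asarray(v) for k2, v in label_rec.items()},
        status_fractions={k2: np.asarray(v) for k2, v in status_rec.items()},
        boundary_o2_mmHg=np.asarray(bo2),
        landscape=landscape,
        radial_bin_centers=radial_centers if radial_centers is not None else np.zeros(0),
        radial_means=rm,
        cell_table=final_table,
        invocations=invocations,
        clipped_mass=dict(grid.clipped_mass),
        manifest={
            "config_hash": config.config_hash(),
            "seed": seed,
            "code_version": __version__,
            "scenario": config.name,
            "n_ticks": n_ticks,
            "wall_s": round(time.time() - t_start, 2),
        },
        grid=grid,
        population=pop,
    )
    if config.outputs.out_dir:
        out.save(config.outputs.out_dir, config.outputs.save_fields)
    return out


def _env_of(pop: Population, vox_i, vox_j, o2, glc, lac, h) -> np.ndarray:
    envs = np.empty((pop.n, 4))
    envs[:, 0] = o2[vox_i, vox_j]
    envs[:, 1] = glc[vox_i, vox_j]
    envs[:, 2] = lac[vox_i, vox_j]
    envs[:, 3] = h[vox_i, vox_j]
    return envs
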