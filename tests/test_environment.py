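"""Reaction-diffusion environment: conversions, solver fidelity, profiling."""
import numpy as np
import pytest

from metaspheroid.config import DIFFUSION_UM2_MIN
from metaspheroid.environment import (
    BoundaryCondition,
    Grid,
    SpeciesField,
    make_grid,
    o2_mM_to_mmHg,
    o2_mmHg_to_mM,
    ph_from_proton,
    proton_from_ph,
    radial_profile,
)
from metaspheroid.scenarios import build_reference


def field(conc, species="glucose", voxel=20.0, bc=("neumann_zero_flux", None)):
    return SpeciesField(
        name=species,
        concentrations=np.asarray(conc, dtype=float),
        diffusion_coefficient=DIFFUSION_UM2_MIN[species],
        boundary=BoundaryCondition(kind=bc[0], value=bc[1]),
        voxel_size=voxel,
    )


def grid_of(fields_dict, extent, voxel=20.0):
    return Grid(extent=extent, voxel_size=voxel, fields=fields_dict)


def uniform_grid(value=1.0, n=8, species="glucose", bc=("neumann_zero_flux", None)):
    f = field(np.full((n, n), value), species=species, bc=bc)
    other = {}
    for name in ("oxygen", "glucose", "lactate", "proton"):
        if name == species:
            other[name] = f
        else:
            other[name] = field(np.full((n, n), value), species=name, bc=bc)
    return grid_of(other, extent=n * 20.0)


class TestUnitConversions:
    @pytest.mark.parametrize("mmHg,mM", [(0.0, 0.0), (38.0, 0.0494), (160.0, 0.208)])
    def test_oxygen_solubility(self, mmHg, mM):
        assert o2_mmHg_to_mM(mmHg) == pytest.approx(mM, abs=1e-4)
        assert o2_mM_to_mmHg(o2_mmHg_to_mM(mmHg)) == pytest.approx(mmHg, rel=1e-12)

    def test_oxygen_negative_rejected(self):
        with pytest.raises(ValueError):
            o2_mmHg_to_mM(-1.0)

    @pytest.mark.parametrize("ph,mM", [(7.0, 1.0e-4), (6.0, 1.0e-3), (7.4, 3.981e-5)])
    def test_ph_proton(self, ph, mM):
        assert proton_from_ph(ph) == pytest.approx(mM, rel=1e-3)
        assert ph_from_proton(proton_from_ph(ph)) == pytest.approx(ph, abs=1e-12)

    def test_nonpositive_proton_rejected(self):
        with pytest.raises(ValueError):
            ph_from_proton(0.0)


class TestMakeGrid:
    def test_reference_initial_conditions(self):
        cfg = build_reference(scaled=True)
        g = make_grid(cfg)
        interior = (slice(1, -1), slice(1, -1))
        assert np.allclose(g.fields["oxygen"].concentrations[interior],
                           38.0 * 1.30e-3)
        assert np.allclose(g.fields["glucose"].concentrations[interior], 6.0)
        assert np.allclose(g.fields["lactate"].concentrations[interior], 0.1)
        ph = ph_from_proton(g.fields["proton"].concentrations[interior])
        assert np.allclose(ph, 7.4, atol=1e-9)

    def test_lattice_shape(self):
        cfg = build_reference(scaled=True)
        cfg.grid.extent_um, cfg.grid.voxel_um = 100.0, 20.0
        g = make_grid(cfg)
        assert all(f.concentrations.shape == (5, 5) for f in g.fields.values())

    def test_indivisible_extent_rejected(self):
        cfg = build_reference(scaled=True)
        cfg.grid.extent_um = 95.0
        with pytest.raises(ValueError):
            make_grid(cfg)

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            SpeciesField(name="ethanol", concentrations=np.ones((3, 3)),
                         diffusion_coefficient=1.0,
                         boundary=BoundaryCondition("dirichlet", 1.0),
                         voxel_size=20.0)


class TestDiffusion:
    def test_uniform_dirichlet_equilibrium(self):
        g = uniform_grid(2.0, bc=("dirichlet", 2.0))
        before = g.fields["glucose"].concentrations.copy()
        for _ in range(20):
            g.step_diffusion(0.6)
        assert np.allclose(g.fields["glucose"].concentrations, before,
                           rtol=0, atol=1e-13)

    def test_neumann_mass_conservation(self):
        rng = np.random.default_rng(0)
        g = uniform_grid(1.0)
        g.fields["proton"].concentrations[:] = rng.uniform(0.5, 2.0, (8, 8))
        m0 = g.fields["proton"].total_mass()
        for _ in range(2000):
            g.step_diffusion(0.6)
        m1 = g.fields["proton"].total_mass()
        assert abs(m1 - m0) / m0 < 1e-9

    def test_dirichlet_boundary_clamped_exactly(self):
        g = uniform_grid(1.0, species="oxygen", bc=("dirichlet", 3.0))
        for _ in range(5):
            g.step_diffusion(0.6)
        c = g.fields["oxygen"].concentrations
        assert np.all(c[0, :] == 3.0) and np.all(c[-1, :] == 3.0)
        assert np.all(c[:, 0] == 3.0) and np.all(c[:, -1] == 3.0)

    def test_stability_at_standard_step_for_protons(self):
        # explicit FTCS would be unstable here (bound ~0.02 s at 20 um)
        g = uniform_grid(1e-4, species="proton", bc=("dirichlet", 1e-4))
        g.fields["proton"].concentrations[4, 4] = 1e-2
        for _ in range(200):
            g.step_diffusion(0.6)
        c = g.fields["proton"].concentrations
        assert np.all(np.isfinite(c)) and c.max() <= 1e-2 + 1e-12

    def test_strip_steady_state_matches_parabola(self):
        """Stationary diffusion-uptake on a strip: D c'' = k with fixed ends."""
        n, dx, c0, k = 41, 20.0, 2.0, 0.004  # mM/min uptake
        fields = {}
        for name in ("oxygen", "glucose", "lactate", "proton"):
            fields[name] = field(np.full((n, 3), c0), species=name,
                                 bc=("dirichlet", c0))
        g = grid_of(fields, extent=n * dx)
        D = DIFFUSION_UM2_MIN["glucose"]
        for _ in range(6000):
            g.exchange["glucose"][1:-1, :] = -k
            g.step_diffusion(0.6)
        got = g.fields["glucose"].concentrations[:, 1]
        x = (np.arange(n) - 0.0) * dx  # distance between clamped voxel centers
        L = (n - 1) * dx
        expected = c0 + (k / 60.0) / (2 * D) * (x * x - L * x)
        interior = slice(1, -1)
        err = np.abs(got[interior] - expected[interior]) / np.abs(expected[interior])
        assert err.max() < 0.01

    def test_matches_fine_step_explicit_reference(self):
        """50 production steps vs brute-force explicit FTCS at tiny dt."""
        rng = np.random.default_rng(3)
        c0 = rng.uniform(1.0, 2.0, (9, 9))
        g = uniform_grid(1.0, n=9, species="glucose", bc=("dirichlet", 1.5))
        g.fields["glucose"].concentrations[:] = c0.copy()
        g.fields["glucose"].concentrations[0, :] = 1.5
        g.fields["glucose"].concentrations[-1, :] = 1.5
        g.fields["glucose"].concentrations[:, 0] = 1.5
        g.fields["glucose"].concentrations[:, -1] = 1.5
        start = g.fields["glucose"].concentrations.copy()
        for _ in range(50):
            g.step_diffusion(0.6)
        got = g.fields["glucose"].concentrations

        # independent explicit reference
        D = DIFFUSION_UM2_MIN["glucose"]
        dx = 20.0
        dt_fine = 0.002 / 60.0  # min, far below the stability bound
        alpha = D * dt_fine / dx**2
        ref = start.copy()
        nsub = int(round(50 * 0.6 / 60.0 / dt_fine))
        for _ in range(nsub):
            lap = (np.roll(ref, 1, 0) + np.roll(ref, -1, 0)
                   + np.roll(ref, 1, 1) + np.roll(ref, -1, 1) - 4 * ref)
            ref = ref + alpha * lap
            ref[0, :] = ref[-1, :] = 1.5
            ref[:, 0] = ref[:, -1] = 1.5
        assert np.max(np.abs(got - ref)) / np.max(np.abs(ref)) < 0.005

    def test_divergence_detected(self):
        g = uniform_grid(1.0)
        g.fields["glucose"].concentrations[2, 2] = np.inf
        with pytest.raises(Exception):
            g.step_diffusion(0.6)


class TestExchange:
    def test_deposit_additivity(self):
        g = uniform_grid(1.0)
        g.deposit_exchange((2, 3), {"lactate": 1.0})
        g.deposit_exchange((2, 3), {"lactate": 1.0})
        assert g.exchange["lactate"][2, 3] == pytest.approx(2.0)

    def test_zero_rate_noop(self):
        g = uniform_grid(1.0)
        g.deposit_exchange((1, 1), {"glucose": 0.0})
        assert np.all(g.exchange["glucose"] == 0.0)

    def test_out_of_domain_rejected(self):
        g = uniform_grid(1.0)
        with pytest.raises(IndexError):
            g.deposit_exchange((99, 0), {"glucose": 1.0})

    def test_uptake_is_mass_limited(self):
        g = uniform_grid(0.5)
        got = g.withdraw("glucose", (3, 3), 2.0)
        assert got == pytest.approx(0.5)
        assert g.fields["glucose"].concentrations[3, 3] == pytest.approx(0.0)

    def test_overdraw_via_accumulator_clips_and_logs(self):
        g = uniform_grid(0.01)
        g.exchange["glucose"][4, 4] = -500.0  # mM/min, far beyond content
        g.step_diffusion(0.6)
        assert g.fields["glucose"].concentrations[4, 4] >= 0.0
        assert g.clipped_mass["glucose"] > 0.0


class TestRadialProfile:
    def test_uniform_field(self):
        f = field(np.full((10, 10), 2.5))
        prof = radial_profile(f, (100.0, 100.0), 20.0)
        assert np.allclose(prof.means[prof.counts > 0], 2.5)

    def test_linear_radial_field_brute_force(self):
        n, dx = 21, 20.0
        xs = (np.arange(n) + 0.5) * dx
        cx = n * dx / 2
        r = np.hypot(xs[:, None] - cx, xs[None, :] - cx)
        f = field(r)
        prof = radial_profile(f, (cx, cx), 15.0)
        half_diag = dx * np.sqrt(2) / 2
        mask = prof.counts > 0
        assert np.all(np.abs(prof.means[mask] - prof.bin_centers[mask]) <= half_diag)

    def test_single_voxel_perturbation_is_local(self):
        n = 15
        conc = np.full((n, n), 1.0)
        conc[10, 7] = 5.0
        f = field(conc)
        cx = n * 20.0 / 2
        prof = radial_profile(f, (cx, cx), 20.0)
        r_star = np.hypot((10 + 0.5) * 20 - cx, (7 + 0.5) * 20 - cx)
        hot = int(r_star // 20.0)
        mask = prof.counts > 0
        for b in np.flatnonzero(mask):
            if b == hot:
                assert prof.means[b] > 1.0
            else:
                assert prof.means[b] == pytest.approx(1.0)

    def test_empty_bins_flagged(self):
        f = field(np.ones((4, 4)), voxel=20.0)
        prof = radial_profile(f, (40.0, 40.0), 5.0)
        assert np.any(prof.empty_bins)
        assert np.all(np.isnan(prof.means[prof.empty_bins]))
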