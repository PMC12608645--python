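"""Agent behavior: cycle checkpoints, division, necrosis, mechanics."""
import math

import numpy as np
import pytest

from metaspheroid.cells import (
    CellAgent,
    Phase,
    advance_cycle,
    create_initial_population,
    divide,
    local_density,
    mechanics_step,
    progress_necrosis,
    rest_separation,
    update_death,
)
from metaspheroid.config import CellConfig
import metaspheroid.state as S


@pytest.fixture
def cfg():
    return CellConfig()


class TestInitialPopulation:
    def test_requested_count(self, cfg):
        pop = create_initial_population(440, 250.0, seed=0, config=cfg)
        assert pop.n == 440
        assert pop.counts()["proliferative"] + pop.counts()["quiescent"] == 440

    def test_deterministic_per_seed(self, cfg):
        a = create_initial_population(100, 170.0, seed=3, config=cfg)
        b = create_initial_population(100, 170.0, seed=3, config=cfg)
        assert np.array_equal(a.pos[:100], b.pos[:100])
        assert np.array_equal(a.phase[:100], b.phase[:100])

    def test_phase_histogram_matches_duration_weights(self, cfg):
        n = 40000
        pop = create_initial_population(n, 4000.0, seed=1, config=cfg)
        ph = pop.phase[:n]
        durations = np.array([cfg.g1_h, cfg.s_h, cfg.g2_h, cfg.m_h])
        expected = durations / durations.sum()
        got = np.array([(ph == k).mean() for k in range(4)])
        assert np.all(np.abs(got - expected) < 0.01)

    def test_disc_too_small_rejected(self, cfg):
        with pytest.raises(ValueError):
            create_initial_population(500, 50.0, seed=0, config=cfg)

    def test_cells_inside_disc(self, cfg):
        pop = create_initial_population(200, 170.0, seed=0, config=cfg,
                                        center=(400.0, 400.0))
        r = np.hypot(pop.pos[:200, 0] - 400, pop.pos[:200, 1] - 400)
        assert r.max() < 170.0 + 25.0


class TestCycle:
    def run_g1(self, cell, o2=38.0, density=0.0, atp=2.5, hours=30.0):
        t = 0.0
        while cell.phase == Phase.G1 and t < hours:
            advance_cycle(cell, 0.1, density, o2, atp)
            t += 0.1
        return t

    def test_baseline_g1_duration(self, cfg):
        cell = CellAgent.single(cfg)
        t = self.run_g1(cell)
        assert cell.phase == Phase.S
        assert t == pytest.approx(cfg.g1_h, abs=0.11)

    def test_oxygen_stretching_doubles_g1_at_half_reference(self, cfg):
        cell = CellAgent.single(cfg)
        t = self.run_g1(cell, o2=19.0)
        assert t == pytest.approx(2 * cfg.g1_h, abs=0.11)

    def test_crowding_sends_to_quiescence_until_cleared(self, cfg):
        cell = CellAgent.single(cfg)
        advance_cycle(cell, 0.1, cfg.density_threshold + 0.1, 38.0, 2.5)
        assert cell.phase == Phase.G0
        for _ in range(50):
            advance_cycle(cell, 0.1, cfg.density_threshold + 0.1, 38.0, 2.5)
            assert cell.phase == Phase.G0
        advance_cycle(cell, 0.1, 0.0, 38.0, 2.5)
        assert cell.phase == Phase.G1

    def test_atp_checkpoint_triggers_quiescence(self, cfg):
        cell = CellAgent.single(cfg)
        advance_cycle(cell, 0.1, 0.0, 38.0, cfg.atp_checkpoint_mM - 0.1)
        assert cell.phase == Phase.G0

    def test_g0_resumes_g1_progress(self, cfg):
        cell = CellAgent.single(cfg)
        for _ in range(30):  # 3 h of G1
            advance_cycle(cell, 0.1, 0.0, 38.0, 2.5)
        advance_cycle(cell, 0.1, 0.9, 38.0, 2.5)
        assert cell.phase == Phase.G0
        advance_cycle(cell, 0.1, 0.0, 38.0, 2.5)
        assert cell.phase == Phase.G1
        assert cell.phase_clock == pytest.approx(3.0, abs=0.2)

    def test_volume_doubles_linearly_in_s_phase(self, cfg):
        cell = CellAgent.single(cfg)
        self.run_g1(cell)
        for _ in range(int(cfg.s_h * 10 / 2)):
            advance_cycle(cell, 0.1, 0.0, 38.0, 2.5)
        assert cell.volume == pytest.approx(1.5 * cfg.volume_um3, rel=0.02)
        while cell.phase == Phase.S:
            advance_cycle(cell, 0.1, 0.0, 38.0, 2.5)
        assert cell.volume == pytest.approx(2 * cfg.volume_um3, rel=0.01)

    def test_full_cycle_emits_division_signal_in_band(self, cfg):
        cell = CellAgent.single(cfg)
        t = 0.0
        while t < 40.0:
            if advance_cycle(cell, 0.1, 0.0, 38.0, 2.5):
                break
            t += 0.1
        assert 18.0 - 0.2 <= t + 0.1 <= 24.0

    def test_population_doubling_time_matches_cycle_length(self, cfg):
        """Abundant nutrients, no crowding: doubling every ~18 h (within 10%)."""
        pop = create_initial_population(300, 250.0, seed=5, config=cfg)
        hours = 36.0
        for _ in range(int(hours * 10)):
            signals = []
            for i in range(pop.n):
                if advance_cycle(pop.agent(i), 0.1, 0.0, 38.0, 2.5):
                    signals.append(i)
            for i in signals:
                divide(pop.agent(i), (0, 0))
        growth = pop.n / 300
        td = hours / math.log2(growth)
        assert abs(td - cfg.total_cycle_h) / cfg.total_cycle_h < 0.10

    def test_dead_cell_cycle_rejected(self, cfg):
        cell = CellAgent.single(cfg)
        cell.phase = Phase.NECROTIC_SWELLING
        with pytest.raises(ValueError):
            advance_cycle(cell, 0.1, 0.0, 38.0, 2.5)


class TestDivision:
    def ready_parent(self, cfg):
        cell = CellAgent.single(cfg)
        cell.phase = Phase.M
        cell.volume = 2 * cfg.volume_um3
        cell.metabolic_state.variables[:] = np.linspace(0.1, 5.3, 53)
        return cell

    def test_equal_volumes(self, cfg):
        parent = self.ready_parent(cfg)
        v = parent.volume
        d2 = divide(parent, (0, 1))
        assert parent.volume == pytest.approx(v / 2)
        assert d2.volume == pytest.approx(v / 2)

    def test_daughters_inherit_metabolic_state(self, cfg):
        parent = self.ready_parent(cfg)
        expected = parent.metabolic_state.variables.copy()
        d2 = divide(parent, (0, 1))
        assert np.array_equal(parent.metabolic_state.variables, expected)
        assert np.array_equal(d2.metabolic_state.variables, expected)

    def test_zero_sigma_keeps_gamma(self):
        cfg = CellConfig(gamma_sigma=0.0)
        parent = self.ready_parent(cfg)
        parent.gamma = 1.21
        d2 = divide(parent, (0, 1))
        assert parent.gamma == pytest.approx(1.21)
        assert d2.gamma == pytest.approx(1.21)

    def test_gamma_redrawn_independently(self):
        cfg = CellConfig(gamma_sigma=0.2)
        parent = self.ready_parent(cfg)
        parent.gamma = 1.0
        d2 = divide(parent, (0, 1))
        assert parent.gamma != d2.gamma

    def test_daughters_offset_by_one_radius(self, cfg):
        parent = self.ready_parent(cfg)
        p0 = parent.position.copy()
        d2 = divide(parent, (0, 1))
        sep = np.linalg.norm(parent.position - d2.position)
        r = (3 * parent.volume / (4 * math.pi)) ** (1 / 3)
        assert sep == pytest.approx(r, rel=1e-9)
        mid = 0.5 * (parent.position + d2.position)
        assert np.allclose(mid, p0)


class TestDeath:
    def clamp_atp(self, cell, atp):
        cell.metabolic_state.variables[S.ATP] = atp

    def test_short_deficit_does_not_kill(self, cfg):
        cell = CellAgent.single(cfg)
        self.clamp_atp(cell, 0.1)
        for _ in range(20):  # 2 h at 6-min evaluations
            update_death(cell, 0.1, (0, 0))
        assert cell.alive
        assert cell.atp_deficit_clock == pytest.approx(2.0)

    def test_adequate_atp_never_kills(self, cfg):
        cell = CellAgent.single(cfg)
        self.clamp_atp(cell, 0.5)
        for tick in range(2000):
            update_death(cell, 0.1, (0, tick))
        assert cell.alive
        assert cell.atp_deficit_clock == 0.0

    def test_zero_atp_kills_certainly_after_persistence(self):
        cfg = CellConfig(death_p_max=1.0)
        cell = CellAgent.single(cfg)
        self.clamp_atp(cell, 0.0)
        for _ in range(29):  # 2.9 h of deficit: below the persistence bar
            update_death(cell, 0.1, (0, 0))
        assert cell.alive
        update_death(cell, 0.1, (0, 1))  # 3.0 h reached, p = p_max = 1
        update_death(cell, 0.1, (0, 2))
        assert cell.phase == Phase.NECROTIC_SWELLING

    def test_recovery_resets_clock(self, cfg):
        cell = CellAgent.single(cfg)
        self.clamp_atp(cell, 0.1)
        update_death(cell, 0.1, (0, 0))
        self.clamp_atp(cell, 0.6)
        update_death(cell, 0.1, (0, 1))
        assert cell.atp_deficit_clock == 0.0


class TestNecrosis:
    def necrotic_cell(self, cfg):
        cell = CellAgent.single(cfg)
        cell.phase = Phase.NECROTIC_SWELLING
        cell._pop.necrosis_volume0[cell._i] = cell.volume
        return cell

    def test_swelling_monotone_up_to_factor(self, cfg):
        cell = self.necrotic_cell(cfg)
        v0 = cell.volume
        prev = v0
        for _ in range(int(cfg.swell_h * 10) - 1):
            progress_necrosis(cell, 0.1)
            assert cell.volume >= prev
            prev = cell.volume
        assert prev == pytest.approx(cfg.swell_factor * v0, rel=0.02)

    def test_lysis_deposit_and_conversion(self, cfg):
        cell = self.necrotic_cell(cfg)
        cell.metabolic_state.variables[S.LAC_I] = 4.0
        deposit = None
        while deposit is None:
            deposit = progress_necrosis(cell, 0.5)
        assert cell.phase == Phase.NECROTIC_SHRINKING
        vox = deposit.voxel_concentrations(8000.0)
        assert vox["lactate"] == pytest.approx(4.0 * deposit.volume_um3 / 8000.0)
        # metabolism is off after lysis
        assert np.all(cell.metabolic_state.variables == 0.0)

    def test_full_shrinkage_reaches_debris(self, cfg):
        cell = self.necrotic_cell(cfg)
        for _ in range(int((cfg.swell_h + cfg.shrink_h) * 10) + 2):
            progress_necrosis(cell, 0.1)
        assert cell.phase == Phase.DEBRIS
        assert cell.volume == pytest.approx(cfg.debris_volume_frac * cfg.volume_um3,
                                            rel=0.05)


class TestMechanics:
    def two_cell_pop(self, cfg, separation):
        pop = create_initial_population(1, 50.0, seed=0, config=cfg,
                                        center=(200.0, 200.0))
        pop.pos[0] = (200.0, 200.0)
        pop.volume[0] = cfg.volume_um3
        pop.phase[0] = int(Phase.G1)
        pop.add_cell(np.array([200.0 + separation, 200.0]), cfg.volume_um3,
                     Phase.G1, 0.0, 1.0)
        return pop

    def test_rest_separation_is_equilibrium(self, cfg):
        r = (3 * cfg.volume_um3 / (4 * math.pi)) ** (1 / 3)
        d_star = rest_separation(cfg, r, r)
        pop = self.two_cell_pop(cfg, d_star)
        before = pop.pos[:2].copy()
        mechanics_step(pop, 6.0, 400.0)
        assert np.allclose(pop.pos[:2], before, atol=1e-9)

    def test_overlapping_cells_separate(self, cfg):
        r = (3 * cfg.volume_um3 / (4 * math.pi)) ** (1 / 3)
        pop = self.two_cell_pop(cfg, 0.6 * 2 * r)
        seps = []
        for _ in range(40):
            mechanics_step(pop, 6.0, 400.0)
            seps.append(np.linalg.norm(pop.pos[0] - pop.pos[1]))
        assert all(b >= a - 1e-12 for a, b in zip(seps, seps[1:]))
        assert seps[-1] > seps[0]

    def test_isolated_cell_stationary(self, cfg):
        pop = create_initial_population(1, 50.0, seed=0, config=cfg,
                                        center=(200.0, 200.0))
        before = pop.pos[0].copy()
        for _ in range(10):
            mechanics_step(pop, 6.0, 400.0)
        assert np.allclose(pop.pos[0], before)

    def test_walls_repel(self, cfg):
        pop = create_initial_population(1, 50.0, seed=0, config=cfg,
                                        center=(200.0, 200.0))
        pop.pos[0] = (1.0, 200.0)
        mechanics_step(pop, 6.0, 400.0)
        assert pop.pos[0, 0] > 1.0


class TestLocalDensity:
    def test_no_neighbors(self, cfg):
        cell = CellAgent.single(cfg)
        assert local_density(cell, []) == 0.0

    def test_ring_matches_analytic_area_fraction(self, cfg):
        center = CellAgent.single(cfg, position=(100.0, 100.0))
        k = 6
        ring = []
        for j in range(k):
            ang = 2 * math.pi * j / k
            ring.append(CellAgent.single(
                cfg, position=(100 + 15 * math.cos(ang), 100 + 15 * math.sin(ang))))
        r = ring[0].radius
        expected = k * math.pi * r**2 / (math.pi * cfg.neighborhood_radius_um**2)
        assert local_density(center, ring) == pytest.approx(expected, abs=1e-6)

    def test_monotone_in_neighbors(self, cfg):
        center = CellAgent.single(cfg, position=(100.0, 100.0))
        neighbors = []
        prev = 0.0
        for j in range(5):
            neighbors.append(CellAgent.single(cfg, position=(105.0 + j, 100.0)))
            d = local_density(center, neighbors)
            assert d >= prev
            prev = d

    def test_distant_neighbors_ignored(self, cfg):
        center = CellAgent.single(cfg, position=(100.0, 100.0))
        far = CellAgent.single(cfg, position=(100.0 + cfg.neighborhood_radius_um + 1, 100.0))
        assert local_density(center, [far]) == 0.0
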