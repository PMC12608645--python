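"""Gene-metabolism network: rate laws, transport, regulation, integration."""
import numpy as np
import pytest

import metaspheroid.state as S
from metaspheroid.environment import o2_mmHg_to_mM, proton_from_ph
from metaspheroid.metabolism import (
    BASAL_VALUES,
    gene_regulation_step,
    glycolysis_ph_modulation,
    init_state,
    mct_flux,
    reaction_rates,
    relax_cell,
    step_metabolism,
)
from metaspheroid.state import LocalEnvironment, MetabolicState


class TestInitState:
    def test_deterministic(self):
        a = init_state(1.0, rng_seed=7)
        b = init_state(1.0, rng_seed=7)
        assert np.array_equal(a.variables, b.variables)

    def test_gamma_stored(self):
        assert init_state(1.3).gamma == pytest.approx(1.3)
        with pytest.raises(ValueError):
            init_state(0.0)

    def test_full_vector_nonnegative(self):
        st = init_state(1.0)
        assert st.variables.shape == (53,)
        assert np.all(st.variables >= 0)

    def test_named_accessors(self):
        st = init_state(1.0)
        assert st.glucose_i == st.variables[S.GLC_I]
        assert st.atp == st.variables[S.ATP]
        assert st.ldh == st.variables[S.LDH_G]
        assert st.pdh == st.variables[S.PDH_G]
        assert st.hif1a == st.variables[S.HIF1A]


class TestReactionRates:
    def test_anoxia_stops_mitochondrial_oxidation(self, rich_env):
        env = LocalEnvironment(0.0, rich_env.glucose_e, rich_env.lactate_e,
                               rich_env.proton_e)
        flux = reaction_rates(init_state(1.0), env)
        assert flux["r28"] == pytest.approx(0.0, abs=1e-12)
        assert flux["r29"] == pytest.approx(0.0, abs=1e-12)

    def test_ldh_reverses_when_pyruvate_absent(self, rich_env):
        st = init_state(1.0)
        st.variables[S.PYR] = 0.0
        st.variables[S.LAC_I] = 3.0
        flux = reaction_rates(st, rich_env)
        assert flux.r12 < 0.0

    def test_respiration_dominates_at_basal_rich_conditions(self, steady_states):
        _, flux = steady_states(38.0, 6.0, 0.1)
        assert flux.r18 > flux.r12 > 0.0

    def test_no_state_mutation(self, rich_env):
        st = init_state(1.0)
        before = st.variables.copy()
        reaction_rates(st, rich_env)
        assert np.array_equal(st.variables, before)

    def test_r18_never_negative(self, rich_env):
        rng = np.random.default_rng(11)
        for _ in range(50):
            st = init_state(1.0)
            st.variables[:S.N_METABOLITES] *= rng.uniform(0.0, 3.0, S.N_METABOLITES)
            flux = reaction_rates(st, rich_env)
            assert flux.r18 >= 0.0
            assert np.all(np.isfinite(flux.rates))


class TestMctFlux:
    def test_zero_at_product_equilibrium(self):
        h = proton_from_ph(7.0)
        assert mct_flux(2.0, h, 2.0, h, 1.0) == pytest.approx(0.0, abs=1e-15)
        # equal products with different partitioning
        assert mct_flux(4.0, h / 2, 2.0, h, 1.0) == pytest.approx(0.0, abs=1e-15)

    def test_export_down_gradient(self):
        h = proton_from_ph(7.2)
        assert mct_flux(5.0, h, 0.1, h, 1.0) > 0.0

    def test_import_under_acidic_exterior(self):
        assert mct_flux(0.5, proton_from_ph(7.1), 8.0, proton_from_ph(6.2), 1.0) < 0.0

    def test_odd_under_side_exchange(self):
        hi, he = proton_from_ph(7.1), proton_from_ph(6.8)
        f1 = mct_flux(4.0, hi, 1.0, he, 1.0)
        f2 = mct_flux(1.0, he, 4.0, hi, 1.0)
        assert f1 == pytest.approx(-f2, rel=1e-12)

    def test_saturates_in_substrate(self):
        h = proton_from_ph(7.0)
        f_lo = mct_flux(5.0, h, 0.0, 1e-9, 1.0)
        f_hi = mct_flux(500.0, h, 0.0, 1e-9, 1.0)
        assert f_hi < 10 * f_lo  # far from linear growth

    def test_capacity_scaling_and_validation(self):
        h = proton_from_ph(7.0)
        assert mct_flux(5.0, h, 0.1, h, 2.0) == pytest.approx(
            2 * mct_flux(5.0, h, 0.1, h, 1.0))
        with pytest.raises(ValueError):
            mct_flux(-1.0, h, 0.1, h, 1.0)


class TestPhModulation:
    def test_physiological_anchor(self):
        assert glycolysis_ph_modulation(1.0, 7.1, 7.4) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_extracellular_ph(self):
        phs = np.linspace(4.5, 8.5, 40)
        vals = [glycolysis_ph_modulation(1.0, 7.1, p) for p in phs]
        assert np.all(np.diff(vals) >= -1e-12)
        assert vals[0] < 0.05

    def test_bounded_unit_interval(self):
        for pi in (5.5, 6.5, 7.1, 8.0):
            for pe in (5.3, 6.0, 6.7, 7.4, 8.5):
                f = glycolysis_ph_modulation(1.0, pi, pe)
                assert 0.0 <= f <= 1.0 + 1e-12

    def test_acidic_interior_also_inhibits(self):
        assert (glycolysis_ph_modulation(1.0, 6.5, 7.4)
                < glycolysis_ph_modulation(1.0, 7.1, 7.4))

    def test_rejects_extreme_ph(self):
        with pytest.raises(ValueError):
            glycolysis_ph_modulation(1.0, 2.0, 7.4)


class TestGeneRegulation:
    def test_deterministic_per_seed(self, rich_env):
        st = init_state(1.0)
        a = gene_regulation_step(st, rich_env, 1.0, 360.0, seed=5, cell_id=3, tick=9)
        b = gene_regulation_step(st, rich_env, 1.0, 360.0, seed=5, cell_id=3, tick=9)
        c = gene_regulation_step(st, rich_env, 1.0, 360.0, seed=6, cell_id=3, tick=9)
        assert np.array_equal(a.variables, b.variables)
        assert not np.array_equal(a.variables, c.variables)

    def test_steady_state_is_fixed_point_without_noise(self, steady_states):
        st, _ = steady_states(38.0, 6.0, 0.1, hours=40.0)
        env = LocalEnvironment(o2_mmHg_to_mM(38.0), 6.0, 0.1, proton_from_ph(7.4))
        out = gene_regulation_step(st, env, 1.0, 360.0, sigma=0.0)
        genes_before = st.variables[S.GENE_SLICE]
        genes_after = out.variables[S.GENE_SLICE]
        assert np.allclose(genes_after, genes_before, rtol=5e-3, atol=5e-3)

    def test_lactate_raises_hif_and_ldh_under_oxygen(self, steady_states):
        lo, _ = steady_states(38.0, 6.0, 0.0)
        hi, _ = steady_states(38.0, 6.0, 8.0)
        assert hi.hif1a > lo.hif1a
        assert hi.ldh > lo.ldh

    def test_hypoxia_induces_glycolytic_program(self, steady_states):
        nx, _ = steady_states(38.0, 6.0, 0.1)
        hx, _ = steady_states(2.0, 6.0, 0.1)
        assert hx.hif1a > 3 * nx.hif1a
        assert hx.ldh > 2 * nx.ldh
        assert hx.pdh < 0.7 * nx.pdh

    def test_expressions_stay_nonnegative_under_noise(self, rich_env):
        st = init_state(1.0)
        for tick in range(200):
            st = gene_regulation_step(st, rich_env, 1.0, 360.0, sigma=0.5,
                                      seed=1, tick=tick)
            assert np.all(st.variables[S.GENE_SLICE] >= 0.0)


class TestStepMetabolism:
    def test_hypoxic_fermentation_exports_lactate(self, steady_states):
        st, flux = steady_states(2.0, 6.0, 3.0)
        assert flux.r12 > 0.0
        assert flux.r21 > 0.0

    def test_lactate_fuels_respiration_without_glucose(self, steady_states):
        st, flux = steady_states(38.0, 0.1, 3.0)
        assert flux.r21 < 0.0
        assert flux.r18 > 0.0

    def test_interval_average_flux_and_exchange_signs(self, rich_env):
        st = init_state(1.0)
        out, flux, exch = step_metabolism(st, rich_env, 1.2)
        assert np.all(np.isfinite(flux.rates))
        assert exch.oxygen < 0.0      # oxygen consumed
        assert exch.glucose < 0.0     # glucose taken up
        assert np.all(out.variables[:S.N_METABOLITES] >= 0.0)

    def test_closed_cell_carbon_bookkeeping(self, rich_env):
        """With all transport capacities zero, glucose-equivalent carbon in
        {hexoses, store, trioses} changes only through the PDH drain."""
        st = init_state(1.0)
        st.variables[S.GLUT_P] = 0.0
        st.variables[S.MCT_P] = 0.0

        hexose = [S.GLC_I, S.G6P, S.F6P, S.FBP, S.GLY]
        triose = [S.DHAP, S.GAP, S.BPG, S.PG3, S.PG2, S.PEP, S.PYR, S.LAC_I]

        def carbon(v):
            return 2.0 * sum(v[i] for i in hexose) + sum(v[i] for i in triose)

        c0 = carbon(st.variables)
        drained = 0.0
        for _ in range(600):  # 12 min
            st, flux, exch = step_metabolism(st, rich_env, 1.2)
            # protein block frozen within metabolite stepping -> GLUT/MCT stay 0
            assert flux.glucose_uptake == pytest.approx(0.0, abs=1e-12)
            assert flux.r21 == pytest.approx(0.0, abs=1e-12)
            drained += flux.r18 * (1.2 / 60.0)
        c1 = carbon(st.variables)
        assert c0 - c1 == pytest.approx(drained, rel=1e-6, abs=1e-9)

    def test_positivity_over_random_perturbed_states(self, rich_env):
        rng = np.random.default_rng(42)
        st = init_state(1.0)
        for _ in range(300):
            st.variables[:S.N_METABOLITES] *= rng.uniform(0.5, 1.5, S.N_METABOLITES)
            st, flux, _ = step_metabolism(st, rich_env, 1.2)
            assert np.all(st.variables >= 0.0)
            assert np.all(np.isfinite(st.variables))


class TestBistability:
    def test_two_basins_across_environment_scan(self):
        """Steady states split into oxidative (high PDH / low LDH) and
        glycolytic (low PDH / high LDH) basins across an oxygen/lactate
        gradient."""
        points = []
        for w in np.linspace(0.0, 1.0, 7):
            o2 = 38.0 * (1 - w) + 1.0 * w
            lac = 0.0 * (1 - w) + 8.0 * w
            env = LocalEnvironment(o2_mmHg_to_mM(o2), 6.0, lac, proton_from_ph(7.4))
            st, _ = relax_cell(init_state(1.0), env, 30.0, sigma=0.0)
            points.append((st.ldh, st.pdh))
        pts = np.array(points)
        oxidative = pts[(pts[:, 1] > 0.8) & (pts[:, 0] < 2.0)]
        glycolytic = pts[(pts[:, 1] < 0.6) & (pts[:, 0] > 3.5)]
        assert len(oxidative) >= 1
        assert len(glycolytic) >= 1
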