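import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vortexsim.biology import (
    BUILDER,
    EXPLORER,
    ModelState,
    Params,
    PhaseConfig,
    accumulate_dead,
    linear_rate,
    mean_colony_density,
    model_rhs,
    mortality_ecoli,
    mortality_pvortex,
    phase_update,
    rhs_single,
    rhs_three_species,
    rhs_two_species,
    update_phase_field,
)
from vortexsim.integrators import IntegratorConfig
from vortexsim.operators import Field


def make_state(mesh, rng=None, algae=False, phase=BUILDER):
    rng = rng or np.random.default_rng(0)
    n = mesh.n_nodes
    return ModelState(
        mesh=mesh,
        b1=rng.uniform(0, 0.5, n),
        b2=rng.uniform(0, 0.5, n),
        n=rng.uniform(0.5, 2, n),
        a=rng.uniform(0, 2, n),
        X=rng.uniform(0, 0.3, n) if algae else None,
        phase=np.full(n, phase, dtype=np.int8),
    )


# ---------------------------------------------------------------- Params


class TestParams:
    def test_table_defaults(self):
        p = Params()
        assert (p.D1_explore, p.D1_build) == (0.35, 0.0125)
        assert (p.D2, p.C2, p.Dn, p.Da) == (0.0001, 6.0, 0.25, 0.25)
        assert (p.beta1_explore, p.beta1_build, p.beta2) == (0.7, 0.9, 0.5)
        assert (p.k_explore, p.k_build) == (0, 1)
        assert (p.lambda1, p.lambda2) == (0.9, 0.9)
        assert (p.n0, p.p, p.a0) == (2.0, 0.6, 2.0)
        assert (p.bbar_max, p.bbar_min, p.r0) == (0.033, 0.007, 0.15)
        assert (p.rX, p.DX, p.CX) == (1.0, 0.25, 10.0)
        assert (p.betaX, p.muX, p.lambdaX) == (0.25, 0.1, 0.9)

    def test_three_species_overrides(self):
        p3 = Params().three_species_defaults()
        assert (p3.n0, p3.bbar_max, p3.bbar_min) == (0.5, 0.04, 0.02)

    def test_invalid(self):
        with pytest.raises(ValueError):
            Params(lambda1=-0.1)
        with pytest.raises(ValueError):
            Params(bbar_min=0.05, bbar_max=0.033)

    def test_d2_warning(self):
        with pytest.warns(UserWarning, match="D2"):
            Params(D2=0.2)

    def test_motility_swaps_jointly(self):
        p = Params()
        assert p.motility(BUILDER) == (0.0125, 0.9, 1)
        assert p.motility(EXPLORER) == (0.35, 0.7, 0)


# ---------------------------------------------------------------- rates


class TestRates:
    def test_mortality_pvortex_no_antibiotic(self):
        assert mortality_pvortex(1.23, 0.0) == 0.0
        assert mortality_pvortex(1.23, 0.0, nutrient_shielded=True) == 0.0

    def test_mortality_pvortex_values(self):
        # both forms agree at n = 0
        assert mortality_pvortex(0.0, 2.0) == pytest.approx(0.6)
        assert mortality_pvortex(0.0, 2.0, nutrient_shielded=True) == pytest.approx(0.6)
        # nutrient-shielded variant: 0.3 a / (1 + 4 n)
        assert mortality_pvortex(1.0, 1.0, nutrient_shielded=True) == pytest.approx(0.06)
        # growth-coupled default: 0.3 a (1 + 4 n)
        assert mortality_pvortex(1.0, 1.0) == pytest.approx(1.5)

    def test_mortality_forms_select_cooperation(self):
        # the growth-coupled form makes a nutrient-rich antibiotic front
        # lethal (death > growth), so the swarmer needs its partner there;
        # the shielded form lets it outgrow the antibiotic alone
        p = Params()
        growth = p.beta1_explore * p.n0
        assert mortality_pvortex(p.n0, p.a0) > growth
        assert mortality_pvortex(p.n0, p.a0, nutrient_shielded=True) < growth

    def test_mortality_ecoli(self):
        assert mortality_ecoli(0.0) == pytest.approx(1.0)
        assert mortality_ecoli(1e9) == pytest.approx(0.0, abs=1e-9)
        n = np.linspace(0, 2, 50)
        assert np.all(np.diff(mortality_ecoli(n)) < 0)

    def test_linear_rates(self):
        assert linear_rate(0.0, 0.7) == 0.0
        assert linear_rate(2.0, 0.9) == pytest.approx(1.8)
        # degradation sink p(a) b2 >= 0, so a cannot grow absent diffusion
        assert linear_rate(1.5, 0.6) * 0.3 >= 0


# ---------------------------------------------------------------- RHS


class TestRHS:
    def test_zero_bacteria_inert(self, mesh_6x6):
        state = make_state(mesh_6x6)
        state.b1[:] = 0.0
        out = rhs_single(state, Params())
        np.testing.assert_array_equal(out["b1"], 0.0)
        # nutrient only diffuses; with uniform n nothing changes
        state.n[:] = 1.5
        out = rhs_single(state, Params())
        np.testing.assert_allclose(out["n"], 0.0, atol=1e-12)

    def test_uniform_fields_reaction_only(self, mesh_6x6):
        state = make_state(mesh_6x6)
        state.b1[:] = 0.2
        state.n[:] = 1.0
        state.a[:] = 0.5
        p = Params()
        out = rhs_single(state, p)
        expected = (p.beta1_build * 1.0 - mortality_pvortex(1.0, 0.5)) * 0.2
        np.testing.assert_allclose(out["b1"], expected, atol=1e-12)

    def test_nutrient_decay_matches_quadrature(self, mesh_6x6, rng):
        state = make_state(mesh_6x6, rng)
        state.b2[:] = 0.0
        p = Params()
        out = rhs_single(state, p)
        # total nutrient mass decay = -sum A_i lambda1 n_i b1_i (diffusion conserves)
        got = float(np.dot(mesh_6x6.A, out["n"]))
        expected = -float(np.dot(mesh_6x6.A, p.lambda1 * state.n * state.b1))
        assert got == pytest.approx(expected, rel=1e-10)

    def test_two_species_nesting(self, mesh_6x6, rng):
        state = make_state(mesh_6x6, rng)
        state.b2[:] = 0.0
        state.a[:] = 0.0
        two = rhs_two_species(state, Params())
        one = rhs_single(state, Params())
        np.testing.assert_array_equal(two["b1"], one["b1"])
        np.testing.assert_array_equal(two["n"], one["n"])
        np.testing.assert_array_equal(two["b2"], 0.0)
        np.testing.assert_array_equal(two["a"], 0.0)

    def test_no_b2_antibiotic_diffuses_only(self, mesh_6x6, rng):
        state = make_state(mesh_6x6, rng)
        state.b2[:] = 0.0
        out = rhs_two_species(state, Params())
        # with uniform a the antibiotic is inert
        state.a[:] = 2.0
        out = rhs_two_species(state, Params())
        np.testing.assert_allclose(out["a"], 0.0, atol=1e-12)

    def test_uniform_b1_no_advection(self, mesh_6x6, rng):
        state = make_state(mesh_6x6, rng, phase=EXPLORER)
        state.b1[:] = 0.3
        p = Params(D2=0.0)  # isolate the advection term
        out = rhs_two_species(state, p)
        growth = (linear_rate(state.n, p.beta2) - mortality_ecoli(state.n)) * state.b2
        np.testing.assert_allclose(out["b2"], growth, atol=1e-10)

    def test_three_species_nesting(self, mesh_6x6, rng):
        state = make_state(mesh_6x6, rng, algae=True)
        state.X[:] = 0.0
        three = rhs_three_species(state, Params())
        two = rhs_two_species(state, Params())
        for key in ("b1", "b2", "n", "a"):
            np.testing.assert_array_equal(three[key], two[key])
        np.testing.assert_array_equal(three["X"], 0.0)

    def test_three_species_rx_zero(self, mesh_6x6, rng):
        state = make_state(mesh_6x6, rng, algae=True)
        p = dataclasses.replace(Params(), rX=0.0)
        three = rhs_three_species(state, p)
        two = rhs_two_species(state, p)
        np.testing.assert_array_equal(three["b1"], two["b1"])
        np.testing.assert_array_equal(three["b2"], two["b2"])

    def test_algae_decay_ode(self, mesh_6x6):
        # beta_X(n) = 0 (n = 0): X decays at rate muX; compare vs exact ODE
        state = make_state(mesh_6x6, algae=True)
        state.n[:] = 0.0
        state.b1[:] = 0.0
        state.b2[:] = 0.0
        state.X[:] = 0.8
        p = Params()
        out = rhs_three_species(state, p)
        np.testing.assert_allclose(out["X"], -p.muX * 0.8, atol=1e-12)

    def test_literal_algae_diffusion_switch(self, mesh_6x6, rng):
        state = make_state(mesh_6x6, rng, algae=True)
        default = rhs_three_species(state, Params())
        literal = rhs_three_species(
            state, dataclasses.replace(Params(), literal_algae_diffusion=True)
        )
        assert not np.allclose(default["X"], literal["X"])


# ------------------------------------------------------------- mean density


class TestMeanColonyDensity:
    def test_constant_above_threshold(self, mesh_6x6):
        b1 = Field.full(mesh_6x6, 0.02)
        assert mean_colony_density(b1) == pytest.approx(0.02, rel=1e-12)

    def test_below_threshold_everywhere(self, mesh_6x6):
        b1 = Field.full(mesh_6x6, 1e-8)
        assert mean_colony_density(b1) == 0.0

    def test_half_domain_support(self, mesh_6x6):
        vals = np.where(mesh_6x6.nodes[:, 0] < 0.5, 0.04, 0.0)
        got = mean_colony_density(Field(vals, mesh_6x6))
        assert got == pytest.approx(0.04, rel=1e-12)

    def test_quadrature_oracle(self, mesh_6x6, rng):
        vals = rng.uniform(0, 0.05, mesh_6x6.n_nodes)
        vals[rng.uniform(size=mesh_6x6.n_nodes) < 0.3] = 0.0
        sup = vals > 1e-6
        expected = np.dot(mesh_6x6.A[sup], vals[sup]) / mesh_6x6.A[sup].sum()
        assert mean_colony_density(Field(vals, mesh_6x6)) == pytest.approx(expected)

    def test_b1_plus_b2_rule(self, mesh_6x6):
        cfg = PhaseConfig(rule="b1_plus_b2", bbar_min=0.029, bbar_max=0.066)
        b1 = Field.full(mesh_6x6, 0.01)
        got = mean_colony_density(b1, Field.full(mesh_6x6, 0.02), cfg)
        assert got == pytest.approx(0.03, rel=1e-12)


# ---------------------------------------------------------------- phase


class TestPhaseUpdate:
    def test_hysteresis_band_inert(self):
        cfg = PhaseConfig()
        assert phase_update(0.02, BUILDER, cfg) == BUILDER
        assert phase_update(0.02, EXPLORER, cfg) == EXPLORER

    def test_builder_to_explorer(self):
        assert phase_update(0.034, BUILDER, PhaseConfig()) == EXPLORER

    def test_explorer_to_builder(self):
        assert phase_update(0.006, EXPLORER, PhaseConfig()) == BUILDER

    @given(bbar=st.floats(0, 0.1), phase=st.sampled_from([BUILDER, EXPLORER]))
    @settings(max_examples=200, deadline=None)
    def test_hysteresis_property(self, bbar, phase):
        cfg = PhaseConfig()
        new = phase_update(bbar, phase, cfg)
        if bbar > cfg.bbar_max:
            assert new == EXPLORER
        elif bbar < cfg.bbar_min:
            assert new == BUILDER
        else:
            assert new == phase

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            PhaseConfig(bbar_min=0.05, bbar_max=0.01)

    def test_per_component_phases(self, mesh_20x20):
        # two disjoint blobs: one dense (-> explorer), one dilute (stays builder)
        mesh = mesh_20x20
        x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
        b1 = np.zeros(mesh.n_nodes)
        b1[np.hypot(x - 0.25, y - 0.5) < 0.15] = 0.05
        b1[np.hypot(x - 0.75, y - 0.5) < 0.15] = 0.01
        state = ModelState(
            mesh=mesh, b1=b1, b2=np.zeros_like(b1), n=np.ones_like(b1), a=np.zeros_like(b1)
        )
        cfg = PhaseConfig(track_components=True)
        records = update_phase_field(state, cfg)
        assert len(records) == 2
        phases = {round(b, 3): ph for _, b, ph in records}
        assert phases[0.05] == EXPLORER
        assert phases[0.01] == BUILDER


# ---------------------------------------------------------------- dead mass


class TestAccumulateDead:
    def test_zero_mu(self, rng):
        s = rng.uniform(size=10)
        out = accumulate_dead(s, np.ones(10), np.zeros(10), 0.1)
        np.testing.assert_array_equal(out, s)

    def test_constant_increment(self):
        s = np.zeros(5)
        out = accumulate_dead(s, np.full(5, 0.4), np.full(5, 0.3), 0.5)
        np.testing.assert_allclose(out, 0.06)

    def test_live_plus_dead_bookkeeping(self, mesh_6x6):
        # death-only dynamics: d(b)/dt = -mu b, ds/dt = mu b; total conserved
        from vortexsim.operators import total_mass

        n = mesh_6x6.n_nodes
        b = np.full(n, 0.5)
        s = np.zeros(n)
        mu = np.full(n, 0.3)
        dt = 1e-3
        total0 = float(np.dot(mesh_6x6.A, b + s))
        for _ in range(500):
            s = accumulate_dead(s, b, mu, dt)
            b = b - dt * mu * b
        assert float(np.dot(mesh_6x6.A, b + s)) == pytest.approx(total0, rel=1e-12)


# ---------------------------------------------------------------- stepping


class TestAdvance:
    def test_growth_matches_scalar_ode(self, mesh_6x6):
        # uniform fields, no antibiotic: nodewise dynamics equal the scalar
        # explicit-Euler recursion for db/dt = beta1 n b, dn/dt = -lambda1 n b
        from vortexsim.biology import advance

        n_nodes = mesh_6x6.n_nodes
        state = ModelState(
            mesh=mesh_6x6,
            b1=np.full(n_nodes, 0.01),
            b2=np.zeros(n_nodes),
            n=np.full(n_nodes, 2.0),
            a=np.zeros(n_nodes),
        )
        p = Params()
        cfg = IntegratorConfig(dt=1e-3)
        phase_cfg = PhaseConfig()
        b_ref, n_ref = 0.01, 2.0
        for _ in range(200):
            ph = int(state.phase[0])
            _, beta1, _ = p.motility(ph)
            b_new = b_ref + cfg.dt * (beta1 * n_ref * b_ref)
            n_ref = n_ref + cfg.dt * (-p.lambda1 * n_ref * b_ref)
            b_ref = b_new
            state = advance(state, p, cfg, phase_cfg)
        np.testing.assert_allclose(state.b1, b_ref, rtol=1e-9)
        np.testing.assert_allclose(state.n, n_ref, rtol=1e-9)

    def test_nesting_two_vs_single(self, mesh_6x6, rng):
        from vortexsim.biology import advance

        state = make_state(mesh_6x6, rng)
        state.b2[:] = 0.0
        state.a[:] = 0.0
        cfg = IntegratorConfig(dt=1e-3)
        out = advance(state, Params(), cfg)
        single = rhs_single(state, Params())
        np.testing.assert_allclose(
            out.b1, np.maximum(state.b1 + cfg.dt * single["b1"], 0.0), rtol=1e-12
        )

    def test_antibiotic_mass_nonincreasing(self, mesh_6x6, rng):
        from vortexsim.biology import advance

        state = make_state(mesh_6x6, rng)
        cfg = IntegratorConfig(dt=1e-3)
        masses = [float(np.dot(mesh_6x6.A, state.a))]
        for _ in range(50):
            state = advance(state, Params(), cfg)
            masses.append(float(np.dot(mesh_6x6.A, state.a)))
        assert all(m1 <= m0 + 1e-12 for m0, m1 in zip(masses, masses[1:]))

    def test_clipping_logged(self, mesh_6x6):
        from vortexsim.biology import advance

        n = mesh_6x6.n_nodes
        # large dt + strong death drives b2 negative -> clipped and logged
        state = ModelState(
            mesh=mesh_6x6,
            b1=np.zeros(n),
            b2=np.full(n, 0.1),
            n=np.zeros(n),
            a=np.zeros(n),
        )
        cfg = IntegratorConfig(dt=1.5)  # mu2(0) = 1 -> b2 goes negative
        out = advance(state, Params(), cfg)
        assert np.all(out.b2 == 0.0)
        assert out.clipped_mass > 0

    def test_negative_initial_rejected(self, mesh_6x6):
        n = mesh_6x6.n_nodes
        with pytest.raises(ValueError):
            ModelState(
                mesh=mesh_6x6, b1=np.zeros(3), b2=np.zeros(n), n=np.zeros(n), a=np.zeros(n)
            )
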