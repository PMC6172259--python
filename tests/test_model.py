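import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import qalife as q
from qalife.model import DissipationParams, mixture_correlation

from conftest import ROLES

UNIT1 = q.LivingUnit("g1", "p1")
UNIT2 = q.LivingUnit("g2", "p2", creation_step=1)


def make_individual(alpha, roles=("g1", "p1")):
    state = q.StateVector.blank(roles)
    return q.create_individual(state, q.PrecursorSpec(alpha=alpha),
                               q.LivingUnit(*roles))


class TestCreateAndReplicate:
    def test_pair_state_and_cloned_sigma_z(self):
        state = make_individual(math.pi / 3)
        c, s = math.cos(math.pi / 3), math.sin(math.pi / 3)
        np.testing.assert_allclose(state.amplitudes, [c, 0, 0, s], atol=1e-12)
        for role in ("g1", "p1"):
            assert q.expectation(state, q.SIGMA_Z.on(role)) == pytest.approx(
                -0.5)

    def test_blank_precursor_stays_blank(self):
        state = make_individual(0.0)
        assert state.overlap(
            q.StateVector.computational("00", ("g1", "p1"))) == 1

    def test_equal_weight_precursor_gives_bell_pair(self):
        state = make_individual(math.pi / 4)
        xx = q.Observable(np.kron(q.SIGMA_X.matrix, q.SIGMA_X.matrix),
                          ("g1", "p1"))
        assert q.expectation(state, xx) == pytest.approx(1.0)

    def test_occupied_phenotype_rejected(self):
        state = q.StateVector.computational("01", ("g1", "p1"))
        with pytest.raises(ValueError, match="not blank"):
            q.create_individual(state, q.PrecursorSpec(alpha=0.3), UNIT1)

    @pytest.mark.parametrize("alpha", [0.0, math.pi / 8, math.pi / 3])
    def test_replication_ghz_oracle(self, alpha):
        # independent oracle: cos(a)|0000> + sin(a)|1111>
        state = q.StateVector.blank(ROLES)
        state = q.create_individual(state, q.PrecursorSpec(alpha=alpha), UNIT1)
        state = q.self_replicate(state, UNIT1, UNIT2)
        ghz = np.zeros(16)
        ghz[0], ghz[15] = math.cos(alpha), math.sin(alpha)
        np.testing.assert_allclose(state.amplitudes, ghz, atol=1e-12)
        zs = [q.expectation(state, q.SIGMA_Z.on(r)) for r in ROLES]
        np.testing.assert_allclose(zs, math.cos(2 * alpha), atol=1e-9)

    def test_x_expectation_migrates_to_joint_correlation(self):
        state = q.StateVector.blank(ROLES)
        state = q.create_individual(state, q.PrecursorSpec(alpha=math.pi / 3),
                                    UNIT1)
        state = q.self_replicate(state, UNIT1, UNIT2)
        xxxx = q.Observable(q.model._kron4(q.SIGMA_X.matrix), ROLES)
        assert q.expectation(state, xxxx) == pytest.approx(
            math.sin(2 * math.pi / 3))


class TestDissipation:
    def test_zero_time_is_identity(self, ghz_like):
        rho = ghz_like.density()
        out = q.dissipate_continuous(rho, "p1", DissipationParams(1.0, 0.0))
        np.testing.assert_allclose(out.matrix, rho.matrix, atol=1e-12)

    def test_long_time_reaches_dark_state(self, ghz_like):
        out = q.dissipate_continuous(ghz_like.density(), "p1",
                                     DissipationParams(1.0, 60.0))
        marg = q.partial_trace(out, ["p1"])
        np.testing.assert_allclose(marg.matrix, [[1, 0], [0, 0]], atol=1e-9)

    def test_sigma_z_closed_form(self):
        # gamma t = ln 2, <sigma_z>_0 = -0.5  ->  1 - e^{-gt}(1 - z0) = 0.25
        rho = make_individual(math.pi / 3).density()
        out = q.dissipate_continuous(rho, "p1",
                                     DissipationParams(1.0, math.log(2)))
        assert q.expectation(out, q.SIGMA_Z.on("p1")) == pytest.approx(0.25)

    def test_coherence_decays_at_half_rate(self):
        plus = q.StateVector(np.ones(2) / math.sqrt(2), ("p",))
        gt = 0.8
        out = q.dissipate_continuous(plus.density(), "p",
                                     DissipationParams(1.0, gt))
        assert q.expectation(out, q.SIGMA_X.on("p")) == pytest.approx(
            math.exp(-gt / 2))

    @pytest.mark.parametrize("steps,expected", [(1, -0.5 * math.cos(math.pi / 8)),
                                                (2, -0.5 * math.cos(math.pi / 4)),
                                                (0, -0.5)])
    def test_discrete_steps_scale_sigma_z(self, steps, expected):
        state = make_individual(math.pi / 3)
        for _ in range(steps):
            state = q.dissipate_discrete(state, "p1", math.pi / 8)
        assert q.expectation(state, q.SIGMA_Z.on("p1")) == pytest.approx(
            expected, abs=1e-9)

    def test_discrete_matches_continuous_in_z_but_not_x(self):
        # matching the z-relaxation with a rotation angle necessarily breaks
        # the x-decay: the no-consistent-solution obstruction as a property
        a, gamma, t = 0.2, 1.0, 0.35
        z0 = 2 * a - 1
        z_target = 1 - 2 * math.exp(-gamma * t) * (1 - a)
        theta = math.acos(z_target / z0)
        alpha = math.acos(math.sqrt(a))
        pair = make_individual(alpha)
        disc = q.dissipate_discrete(pair, "p1", theta)
        cont = q.dissipate_continuous(pair.density(), "p1",
                                      DissipationParams(gamma, t))
        z_d = q.expectation(disc, q.SIGMA_Z.on("p1"))
        z_c = q.expectation(cont, q.SIGMA_Z.on("p1"))
        assert z_d == pytest.approx(z_c, abs=1e-9)
        xx = q.Observable(np.kron(q.SIGMA_X.matrix, q.SIGMA_X.matrix),
                          ("g1", "p1"))
        x_d = q.expectation(disc, xx)
        x_c = q.expectation(q.DensityOperator(cont.matrix, cont.roles), xx)
        assert abs(x_d - x_c) > 1e-3

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            DissipationParams(-1.0, 1.0)


class TestLifetime:
    def test_closed_form(self):
        assert q.effective_lifetime(0.5, 1.0, 0.05) == pytest.approx(
            math.log(10))

    def test_already_dead_returns_zero(self):
        assert q.effective_lifetime(0.9, 1.0, 0.2) == 0.0

    @pytest.mark.parametrize("a", [0.0, 0.25, 0.5, 0.75])
    def test_agrees_with_bisection_on_channel(self, a):
        closed = q.effective_lifetime(a, 1.3, 0.02)
        assert q.effective_lifetime_bisect(a, 1.3, 0.02) == pytest.approx(
            closed, abs=1e-9)

    def test_monotonically_decreasing_in_genotype_weight(self):
        # higher ground-state weight = shorter distance to the dark state
        assert (q.effective_lifetime(0.25, 1.0, 0.05)
                > q.effective_lifetime(0.75, 1.0, 0.05))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            q.effective_lifetime(1.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            q.effective_lifetime(0.5, 0.0, 0.1)


class TestMutation:
    def test_sigma_x_flips_sign(self):
        state = make_individual(math.pi / 3)
        out = q.mutate(state, "g1")
        assert q.expectation(out, q.SIGMA_Z.on("g1")) == pytest.approx(0.5)

    def test_double_flip_is_identity(self, ghz_like):
        out = q.mutate(q.mutate(ghz_like, "g1"), "g1")
        assert out.overlap(ghz_like) == pytest.approx(1.0)

    def test_pre_replication_mutation_is_inherited(self):
        state = q.StateVector.blank(ROLES)
        state = q.create_individual(state, q.PrecursorSpec(alpha=math.pi / 3),
                                    UNIT1)
        state = q.mutate(state, "g1")
        state = q.self_replicate(state, UNIT1, UNIT2)
        for role in ("g2", "p2"):
            assert q.expectation(state, q.SIGMA_Z.on(role)) == pytest.approx(
                0.5)
        # the already-cloned phenotype keeps the unmutated value
        assert q.expectation(state, q.SIGMA_Z.on("p1")) == pytest.approx(-0.5)

    def test_partial_mutation_angle(self):
        state = make_individual(0.0)
        out = q.mutate(state, "g1", theta_mut=math.pi / 2)
        assert q.expectation(out, q.SIGMA_Z.on("g1")) == pytest.approx(0.0)


class TestInteraction:
    def test_interaction_exchanges_phenotypes(self, blank4):
        state = blank4
        state = q.create_individual(state, q.PrecursorSpec(alpha=math.pi / 8),
                                    UNIT1)
        state = q.create_individual(state,
                                    q.PrecursorSpec(alpha=3 * math.pi / 8),
                                    UNIT2)
        state = q.interact(state, UNIT1, UNIT2)
        zs = [q.expectation(state, q.SIGMA_Z.on(r)) for r in ROLES]
        c = math.cos(math.pi / 4)
        np.testing.assert_allclose(zs, [c, -c, -c, c], atol=1e-9)

    def test_identical_individuals_keep_their_expectations(self, blank4):
        # exchanging phenotypes between identical individuals leaves every
        # single-qubit <sigma_z> unchanged (the state itself acquires
        # exchange branches on the genotype-disagreement components)
        state = blank4
        for unit in (UNIT1, UNIT2):
            state = q.create_individual(state,
                                        q.PrecursorSpec(alpha=math.pi / 5),
                                        unit)
        out = q.interact(state, UNIT1, UNIT2)
        for role in ROLES:
            assert q.expectation(out, q.SIGMA_Z.on(role)) == pytest.approx(
                q.expectation(state, q.SIGMA_Z.on(role)), abs=1e-9)

    def test_vacuum_fixed(self, blank4):
        out = q.interact(blank4, UNIT1, UNIT2)
        assert out.overlap(blank4) == pytest.approx(1.0)

    def test_role_collision_rejected(self, blank4):
        with pytest.raises(ValueError, match="distinct"):
            q.interact(blank4, UNIT1, q.LivingUnit("g1", "p2"))


class TestEq2Consistency:
    def test_no_dissipation_trivially_consistent(self):
        res = q.eq2_residuals(0.7, 0.0, 0.0, 0.0, 0.0, 0.0)
        np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_pure_ground_precursor_reduction(self):
        # a = 1: z-conditions force theta = 0, the x-condition residual
        # reduces to e^{-gamma(t1+t2)/2} - 1 times <sigma_x> = 0 here,
        # but the cos terms must equal one exactly
        r1, r2, r3 = q.eq2_residuals(1.0, 1.0, 0.2, 0.2, 0.0, 0.0)
        assert r2 == pytest.approx(0.0)
        assert r3 == pytest.approx(0.0)

    def test_solution_depends_on_genotype(self):
        # the solved angles (and hence the x-residual) vary with a:
        # no genotype-independent rotation surrogate exists.  The
        # z-conditions are only solvable for ground weight a < 1/2 with
        # gamma*t below ln(2(1-a)); scan inside that domain.
        sols = [q.solve_eq2(a, 1.0, 0.2, 0.2)
                for a in (0.05, 0.1, 0.2, 0.3)]
        thetas = np.array([(s[0], s[1]) for s in sols])
        assert np.ptp(thetas[:, 0]) > 1e-3
        assert np.ptp(thetas[:, 1]) > 1e-3
        residuals = [s[2] for s in sols]
        assert max(abs(r) for r in residuals) > 1e-4

    def test_unsolvable_domain_reported(self):
        with pytest.raises(ValueError, match="no real rotation"):
            q.solve_eq2(0.55, 5.0, 2.0, 2.0)


class TestCausalCorrelations:
    @pytest.mark.parametrize("alpha", [0.0, 0.5, math.sin(2 * math.pi / 3)])
    def test_lineage_alpha_vs_independent_alpha_squared(self, alpha):
        rep, ind = q.causal_correlation_demo(alpha)
        assert rep == pytest.approx(alpha, abs=1e-9)
        assert ind == pytest.approx(alpha**2, abs=1e-9)

    @given(st.floats(0.01, 0.99))
    def test_separation_positive_for_genuine_superposition(self, alpha):
        rep, ind = q.causal_correlation_demo(alpha)
        assert rep - ind == pytest.approx(alpha - alpha**2, abs=1e-9)
        assert rep - ind > 0

    @pytest.mark.parametrize("a", [0.0, 0.3, 0.8, 1.0])
    def test_classical_mixture_propagates_nothing(self, a):
        assert mixture_correlation(a) == pytest.approx(0.0, abs=1e-9)
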