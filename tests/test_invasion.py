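"""Invasion fitness, extinction probabilities, regimes, phase diagram."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import phagedorm as pg
from phagedorm.invasion import det_A_closed_form, det_F_closed_form

from conftest import model_params, random_params


def fd_jacobian(n, p, h=1e-6):
    n = np.asarray(n, dtype=float)
    J = np.empty((6, 6))
    for j in range(6):
        e = np.zeros(6)
        e[j] = h
        J[:, j] = (pg.rhs_full(n + e, p) - pg.rhs_full(n - e, p)) / (2 * h)
    return J


class TestJacobian:
    @given(p=model_params(), raw=st.tuples(*[st.floats(0.01, 3.0)] * 6))
    def test_matches_finite_differences(self, p, raw):
        n = np.array(raw)
        assert pg.jacobian_full(n, p) == pytest.approx(fd_jacobian(n, p),
                                                       abs=1e-5)

    def test_mutant_block_at_resident_equilibrium_is_A(self, fig2):
        n1a, n1i, n3 = pg.host1_virus_equilibrium(fig2)
        J = pg.jacobian_full([n1a, n1i, 0, 0, 0, n3], fig2)
        assert J[np.ix_([2, 3, 4], [2, 3, 4])] == pytest.approx(
            pg.matrix_A(fig2))

    def test_resident_block_at_mutant_equilibrium_is_F(self, fig2):
        tilde = pg.host2_virus_equilibrium(fig2)
        J = pg.jacobian_full([0, 0, *tilde], fig2)
        assert J[:2, :2] == pytest.approx(pg.matrix_F(fig2))


class TestMeanMatrices:
    def test_frozen_jstar(self, fig2):
        expect = np.array([[-2.12, 1.824, 1.216], [2, -2.1, 0], [1, 0, -2]])
        assert pg.matrix_Jstar(fig2) == pytest.approx(expect)

    def test_transpose_identities(self, fig2):
        assert np.array_equal(pg.matrix_Jstar(fig2), pg.matrix_A(fig2).T)
        assert np.array_equal(pg.matrix_Jtilde(fig2), pg.matrix_F(fig2).T)

    @given(p=model_params())
    def test_spectra_and_determinant_cross_checks(self, p):
        if pg.host1_virus_equilibrium(p) is not None:
            A = pg.matrix_A(p)
            assert np.linalg.det(A) == pytest.approx(
                det_A_closed_form(p), rel=1e-9, abs=1e-9)
            eigA = np.sort_complex(np.linalg.eigvals(A))
            eigJ = np.sort_complex(np.linalg.eigvals(pg.matrix_Jstar(p)))
            assert eigA == pytest.approx(eigJ, abs=1e-10)
            # Perron-Frobenius: the leading eigenvalue is real
            lead = eigA[np.argmax(eigA.real)]
            assert abs(lead.imag) < 1e-9
        if pg.host2_virus_equilibrium(p) is not None:
            F = pg.matrix_F(p)
            assert np.linalg.det(F) == pytest.approx(
                det_F_closed_form(p), rel=1e-9, abs=1e-9)
            eigF = np.sort_complex(np.linalg.eigvals(F))
            eigJt = np.sort_complex(np.linalg.eigvals(pg.matrix_Jtilde(p)))
            assert eigF == pytest.approx(eigJt, abs=1e-10)

    def test_absent_equilibrium_propagates(self, fig5):
        with pytest.raises(ValueError):
            pg.matrix_F(fig5)
        with pytest.raises(ValueError):
            pg.matrix_Jtilde(fig5)


class TestInvasionConditions:
    def test_mutual_invasion_in_darkgreen(self, fig2):
        c = pg.invasion_conditions(fig2)
        assert c.inv2_yes and c.inv1_yes and not c.critical

    def test_purple_blocks_the_dormancy_trait(self, fig4):
        c = pg.invasion_conditions(fig4)
        assert c.inv2_no and c.inv1_yes
        # margin: cost 1.15 exceeds the dormancy pivot ~ 0.550
        assert c.margin2 == pytest.approx(0.550 - 1.15, abs=2e-3)

    def test_blue_blocks_the_resident(self, fig3):
        c = pg.invasion_conditions(fig3)
        assert c.inv2_yes and c.inv1_no

    def test_limit_without_recovery_and_dormant_death(self, fig2):
        # with kappa = 0 and r -> 0 the pivot tends to q D n3*: the basic
        # dormancy emergence condition
        p = fig2.replace(kappa=0.0, r=1e-9)
        c = pg.invasion_conditions(p)
        n3_star = pg.host1_virus_equilibrium(p)[2]
        pivot = c.margin2 + (p.lambda1 - p.lambda2)
        assert pivot == pytest.approx(p.q * p.D * n3_star, rel=1e-6)

    def test_not_applicable_without_reference_equilibrium(self, fig5):
        c = pg.invasion_conditions(fig5)
        assert c.inv1_yes is None and c.margin1 is None
        assert c.inv2_yes is True

    @given(p=model_params())
    def test_sign_equivalences(self, p):
        # leading eig of J* > 0  <=>  det A > 0  <=>  invasion of type 2;
        # leading eig of J~ > 0  <=>  det F < 0  <=>  invasion of type 1
        c = pg.invasion_conditions(p)
        tol = 1e-9
        if c.margin2 is not None and abs(c.margin2) > 1e-6:
            lam = pg.leading_eigenvalue(pg.matrix_Jstar(p))
            if abs(lam) > tol:
                assert (lam > 0) == c.inv2_yes
                assert (det_A_closed_form(p) > 0) == c.inv2_yes
        if c.margin1 is not None and abs(c.margin1) > 1e-6:
            lam = pg.leading_eigenvalue(pg.matrix_Jtilde(p))
            if abs(lam) > tol:
                assert (lam > 0) == c.inv1_yes
                assert (det_F_closed_form(p) < 0) == c.inv1_yes


class TestExtinctionProbabilities:
    def test_subcritical_invader_dies_out_surely(self, fig4):
        assert pg.extinction_probability_type2(fig4) == (1.0, 1.0, 1.0)

    def test_darkgreen_frozen_values(self, fig2):
        s2a, s2d, s2i = pg.extinction_probability_type2(fig2)
        assert 0 < s2a < 1
        assert s2a == pytest.approx(0.911709, abs=1e-6)
        s1a, s1i = pg.extinction_probability_type1(fig2)
        assert 0 < s1a < 1
        assert s1a == pytest.approx(0.959305, abs=1e-6)

    def test_blue_blocks_reverse_invasion(self, fig3):
        assert pg.extinction_probability_type1(fig3) == (1.0, 1.0)

    def test_all_ones_is_exact_fixed_point(self, fig2):
        # substituting s = 1 into the first-step system zeroes every term
        n1a, n1i, n3 = pg.host1_virus_equilibrium(fig2)
        death = fig2.mu1 + fig2.C * (n1a + n1i)
        res = (fig2.lambda2 * (1 - 1) + death * 0
               + (1 - fig2.q) * fig2.D * n3 * 0 + fig2.q * fig2.D * n3 * 0)
        assert res == 0.0

    def test_printed_variant_flag_changes_pressure_term(self, fig2):
        s_rate_list = pg.extinction_probability_type1(fig2)
        s_printed = pg.extinction_probability_type1(
            fig2, literal_printed_system=True)
        # dropping the dormant pressure makes the invader strictly fitter
        assert s_printed[0] < s_rate_list[0]

    @given(p=model_params())
    def test_consistency_with_supercriticality(self, p):
        if pg.host1_virus_equilibrium(p) is None:
            return
        lam = pg.leading_eigenvalue(pg.matrix_Jstar(p))
        if abs(lam) < 1e-6:
            return
        s2a, s2d, s2i = pg.extinction_probability_type2(p)
        assert 0 < min(s2a, s2d, s2i) and max(s2a, s2d, s2i) <= 1
        assert (s2a < 1 - 1e-9) == (lam > 0)


class TestTimescales:
    def test_darkgreen_prediction(self, fig2):
        ts = pg.timescales(fig2, K=1000)
        assert ts.lambda_star == pytest.approx(0.108507, abs=1e-6)
        assert ts.t_beta_type2 == pytest.approx(np.log(1000) / 0.108507,
                                                rel=1e-4)
        # fixation (conjecture-backed) always exceeds the macroscopic
        # threshold time (theorem-backed)
        assert ts.t_fixation > ts.t_beta_type2

    def test_subcritical_not_applicable(self, fig4):
        ts = pg.timescales(fig4, K=1000)
        assert ts.t_beta_type2 is None


class TestRegimeClassification:
    @pytest.mark.parametrize("name, regime, case, color", [
        ("fig2_darkgreen", "coexistence_sixtype", "C", "darkgreen"),
        ("fig3_blue", "fixation_type2_with_virus", "C", "blue"),
        ("fig4_purple", "fixation_type1_with_virus", "C", "purple"),
        ("fig5_lightgreen", "coexistence_sixtype", "D", "lightgreen"),
        ("fig6_red", "fixation_type1_with_virus", "D", "red"),
    ])
    def test_study_scenarios(self, name, regime, case, color):
        label = pg.classify_regime(pg.scenario(name))
        assert (label.regime, label.case, label.color) == (regime, case,
                                                           color)

    def test_orange_virus_free_fixation(self, fig2):
        # above lambda1 but below the mutant-epidemic existence curve:
        # mutants win outright and the epidemic collapses
        p = pg.scenario("fig1_base", lambda2=3.3, q=0.9)
        label = pg.classify_regime(p)
        assert label.regime == "fixation_type2a_virus_free"
        assert label.color == "orange"

    def test_degenerate_virion_balance_labelled(self, fig2):
        p = fig2.replace(r=2.0, kappa=1.0, v=1.0, sigma=2.0)
        assert pg.classify_regime(p).regime == "degenerate"

    def test_founder_control_reachable_for_reversed_cost(self):
        # lambda2 > lambda1 with r*kappa*mu1 > v*sigma admits mutual
        # non-invasion
        p = pg.ModelParams(lambda1=2.0, lambda2=2.2, mu1=1.0, C=1.0, D=0.5,
                           q=0.5, r=2.0, v=0.5, m=20, sigma=0.2, kappa=1.0,
                           mu3=0.5)
        assert p.r * p.kappa * p.mu1 > p.v * p.sigma
        c = pg.invasion_conditions(p)
        if c.inv2_no and c.inv1_no:
            assert pg.classify_regime(p).regime == "founder_control"

    @given(p=model_params(require_cost=True))
    def test_costly_trait_never_founder_control(self, p):
        # for lambda2 < lambda1 the two branching processes are never
        # simultaneously subcritical
        label = pg.classify_regime(p)
        assert label.regime != "founder_control"


class TestPhaseDiagram:
    def test_single_cell_equals_classifier(self, fig4):
        df = pg.scan_phase_diagram(fig4, ("lambda2", 2.0, 2.0),
                                   ("q", 0.4, 0.4), n1=1)
        assert len(df) == 1
        assert df.iloc[0]["regime"] == "fixation_type1_with_virus"
        assert df.iloc[0]["color"] == "purple"

    def test_case_boundary_curve(self, fig2):
        # the analytic curve nbar_2a = ñ2a separates case C from case D
        for q in (0.2, 0.5, 0.8):
            l2_crit = pg.boundary_coex23_lambda2(fig2, q)
            above = fig2.replace(lambda2=l2_crit + 1e-6, q=q)
            below = fig2.replace(lambda2=l2_crit - 1e-6, q=q)
            assert pg.host2_virus_equilibrium(above) is not None
            assert pg.host2_virus_equilibrium(below) is None

    def test_small_grid_reproduces_regime_geography(self, fig2):
        base = pg.scenario("fig1_base", lambda2=2.0, q=0.5)
        df = pg.scan_phase_diagram(base, ("lambda2", 1.3, 3.9),
                                   ("q", 0.05, 0.95), n1=12)
        assert len(df) == 144
        regimes = set(df["regime"])
        assert {"coexistence_sixtype", "fixation_type1_with_virus",
                "fixation_type2_with_virus",
                "fixation_type2a_virus_free"} <= regimes
        # virus-free mutant fixation only beyond lambda2 = lambda1 = 3.15
        orange = df[df["regime"] == "fixation_type2a_virus_free"]
        assert (orange["lambda2"] > 3.15).all()
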