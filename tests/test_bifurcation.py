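import numpy as np
import pytest

import mlautapse as m


class TestEquilibria:
    def test_stability_by_class_and_current(self, type2, type3):
        assert m.find_equilibrium(0.0, type2).stable
        assert not m.find_equilibrium(100.0, type2).stable
        assert m.find_equilibrium(100.0, type3).stable

    def test_focus_node_label_follows_discriminant(self, type2, hopf_ii):
        # near the Hopf point the eigenvalues are necessarily complex;
        # far from it (rest, strong drive) they are real, so those points
        # are labelled nodes from the discriminant even where oscillatory
        # behaviour nearby might suggest a spiral
        assert m.find_equilibrium(hopf_ii, type2).is_focus
        assert not m.find_equilibrium(0.0, type2).is_focus
        assert not m.find_equilibrium(100.0, type2).is_focus

    def test_residual_below_tolerance(self, type2, type3):
        for params, I in [(type2, 0.0), (type2, 100.0), (type3, 150.0)]:
            eq = m.find_equilibrium(I, params)
            dV, dw = m.ml_vector_field(m.State(eq.V, eq.w), I, params)
            assert abs(dV) < 1e-10 and abs(dw) < 1e-10

    def test_w_consistent_with_steady_state(self, type3):
        eq = m.find_equilibrium(60.0, type3)
        assert eq.w == pytest.approx(float(m.w_inf(eq.V, type3)), abs=1e-12)


class TestBranch:
    def test_class_iii_branch_fully_stable(self, type3):
        branch = m.equilibrium_branch((0.0, 200.0), 41, type3)
        assert all(p.stable for p in branch)

    def test_class_ii_branch_flips_once(self, type2):
        branch = m.equilibrium_branch((0.0, 100.0), 51, type2)
        flags = [p.stable for p in branch]
        flips = sum(1 for a, b in zip(flags[:-1], flags[1:]) if a != b)
        assert flips == 1
        assert flags[0] and not flags[-1]

    def test_potential_increases_with_current(self, type2):
        branch = m.equilibrium_branch((0.0, 100.0), 21, type2)
        V = [p.V for p in branch]
        assert all(b >= a for a, b in zip(V[:-1], V[1:]))

    def test_single_point_range_matches_find(self, type2):
        (only,) = m.equilibrium_branch((30.0, 30.0), 1, type2)
        assert only.V == pytest.approx(m.find_equilibrium(30.0, type2).V, abs=1e-10)


class TestHopf:
    def test_class_ii_location(self, hopf_ii):
        assert hopf_ii == pytest.approx(42.797, rel=0.005)

    def test_planar_hopf_conditions_at_crossing(self, type2, hopf_ii):
        eq = m.find_equilibrium(hopf_ii, type2)
        J = m.jacobian(eq.V, eq.w, type2)
        assert abs(np.trace(J)) < 1e-3
        assert np.linalg.det(J) > 0
        assert abs(eq.eigenvalues[0].imag) > 0

    def test_absent_for_class_iii(self, type3):
        assert m.find_hopf(0.0, 200.0, type3).I_H is None

    def test_absent_below_the_crossing(self, type2):
        assert m.find_hopf(0.0, 10.0, type2).I_H is None


class TestLimitCycle:
    def test_class_ii_cycle_at_high_current(self, type2):
        info = m.limit_cycle_from_simulation(100.0, type2, T=300.0, settle=100.0)
        assert info.exists
        assert info.period == pytest.approx(5.32, rel=0.02)
        assert info.V_max > 0 > info.V_min

    def test_no_cycle_for_class_iii(self, type3):
        assert not m.limit_cycle_from_simulation(100.0, type3, T=300.0, settle=100.0).exists

    def test_no_cycle_below_the_fold_from_rest(self, type2):
        assert not m.limit_cycle_from_simulation(40.0, type2, T=500.0, settle=200.0).exists


class TestFoldOfCycles:
    def test_bracket_sanity_with_cycle_seeding(self, type2):
        # seed both probes from the established cycle at I = 100
        tr = m.integrate(type2, None, m.StimulusProtocol(kind="constant", baseline=100.0),
                         T=300.0, initial=m.resting_state(type2, 0.0))
        seed = m.State(float(tr.V[-1]), float(tr.w[-1]))
        above = m.limit_cycle_from_simulation(42.5, type2, init=seed, T=500.0, settle=200.0)
        below = m.limit_cycle_from_simulation(42.0, type2, init=seed, T=500.0, settle=200.0)
        assert above.exists and not below.exists

    def test_bistability_between_fold_and_hopf(self, type2, hopf_ii):
        # at 42.5 the resting equilibrium is still stable while the cycle exists
        assert 42.5 < hopf_ii
        assert m.find_equilibrium(42.5, type2).stable

    def test_misuse_without_cycle_rejected(self, type3):
        with pytest.raises(ValueError):
            m.find_fold_of_cycles(type3, I_start=100.0)
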