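import numpy as np
import pytest

import mlautapse as m
from conftest import make_trajectory


def synthetic_spiking(period=10.0, t_end=1000.0, h=0.1, width=1.0, peak=20.0, rest=-60.0):
    """Square spikes of the given period: crossings of 0 mV at known times."""
    t = np.arange(0.0, t_end + h / 2, h)
    phase = t % period
    V = np.where(phase < width, peak, rest)
    return make_trajectory(t, V)


class TestDetectSpikes:
    def test_known_crossings(self):
        traj = synthetic_spiking(period=10.0)
        spikes = m.detect_spikes(traj)
        assert len(spikes) == 100
        assert np.allclose(np.diff(spikes), 10.0)

    def test_invariant_to_subthreshold_wiggle(self):
        traj = synthetic_spiking()
        wiggled = make_trajectory(traj.t, traj.V + np.where(traj.V < 0, 5.0 * np.sin(traj.t), 0.0))
        assert np.array_equal(m.detect_spikes(traj), m.detect_spikes(wiggled))

    def test_refractory_merges_double_crossings(self):
        t = np.arange(0, 5, 0.1)
        V = np.full_like(t, -60.0)
        V[10] = 10.0  # crossing at 1.0
        V[13] = 10.0  # re-crossing 0.3 ms later: discarded
        V[40] = 10.0  # crossing at 4.0: kept
        spikes = m.detect_spikes(make_trajectory(t, V), refractory=1.0)
        assert len(spikes) == 2

    def test_subthreshold_constant_drive_class_iii(self, type3):
        # 60 uA/cm^2 sustained: a subthreshold oscillation, never a spike
        traj = m.integrate(type3, None, m.standard_protocols()["constant_60"], T=1100.0)
        assert len(m.detect_spikes(traj)) == 0

    def test_brief_pulse_one_spike_both_classes(self, type2, type3):
        proto = m.standard_protocols()["brief_pulse_100"]
        for params in (type2, type3):
            traj = m.integrate(params, None, proto, T=400.0)
            assert len(m.detect_spikes(traj)) == 1


class TestClassifyResponse:
    def test_no_spikes_is_resting(self):
        traj = make_trajectory(np.arange(0, 1000, 0.1), np.full(10000, -60.0))
        assert m.classify_response(np.array([]), traj) == "resting"

    def test_early_spikes_only_is_transient(self):
        traj = synthetic_spiking()
        assert m.classify_response(np.array([100.0, 110.0]), traj) == "transient_then_rest"

    def test_persistent_spikes_are_repetitive(self):
        traj = synthetic_spiking()
        spikes = m.detect_spikes(traj)
        assert m.classify_response(spikes, traj) == "repetitive"

    def test_short_run_rejected(self):
        traj = make_trajectory(np.arange(0, 100, 0.1), np.full(1000, -60.0))
        with pytest.raises(ValueError):
            m.classify_response(np.array([]), traj, settle_window=200.0)

    def test_long_pulse_class_iii_single_transient_spike(self, type3):
        # 100 uA/cm^2 for 60 ms then 200+ ms of observation
        traj = m.integrate(type3, None, m.standard_protocols()["long_pulse_100"], T=400.0)
        spikes = m.detect_spikes(traj)
        assert len(spikes) == 1
        assert m.classify_response(spikes, traj) == "transient_then_rest"


class TestClassifyCase:
    def test_reference_runs_match_known_labels(self, autapse_runs, hopf_ii):
        expected = {
            ("typeII", 0.1): "case2",
            ("typeIII", 0.1): "case1",
            ("typeII", 0.01): "case2",
        }
        for key, label in expected.items():
            traj = autapse_runs[key]
            summ = m.summarize(traj, tau=15.0, I_H=hopf_ii)
            assert summ.firing_case == label, key

    def test_case1_interval_tracks_delay(self, autapse_runs, hopf_ii):
        traj = autapse_runs[("typeIII", 0.1)]
        summ = m.summarize(traj, tau=15.0, I_H=hopf_ii)
        assert abs(summ.steady_isi - 15.0) / 15.0 < 0.15

    def test_fast_decay_entrains_both_classes_at_either_delay(self, type2, type3, hopf_ii):
        # the fast autapse (beta = 1) acts as a periodic brief pulse: the
        # interval locks to the delay for both 7 ms and 15 ms
        for tau in (7.0, 15.0):
            for params in (type2, type3):
                traj = m.run_triggered(params, m.SynapseParams(g_syn=3.0, tau=tau, beta=1.0), T=1000.0)
                summ = m.summarize(traj, tau=tau, I_H=hopf_ii)
                assert summ.firing_case == "case1"
                assert abs(summ.steady_isi - tau) / tau < 0.15

    def test_misuse_on_non_repetitive_run_rejected(self, autapse_runs, hopf_ii):
        traj = autapse_runs[("typeIII", 0.01)]
        summ = m.summarize(traj)
        with pytest.raises(ValueError):
            m.classify_case(summ, traj, tau=15.0, I_H=hopf_ii)


class TestAverages:
    def test_zero_and_constant_current(self):
        t = np.arange(0, 100, 0.1)
        traj = make_trajectory(t, np.full_like(t, -60.0))
        assert m.average_autaptic_current(traj, (10, 90)) == 0.0
        traj2 = make_trajectory(t, np.full_like(t, -60.0), I_syn=np.full_like(t, 3.7))
        assert m.average_autaptic_current(traj2, (10, 90)) == pytest.approx(3.7)

    def test_linear_in_conductance(self):
        t = np.arange(0, 100, 0.1)
        base = np.sin(t) + 2.0
        a = make_trajectory(t, np.zeros_like(t), I_syn=base)
        b = make_trajectory(t, np.zeros_like(t), I_syn=2.0 * base)
        assert m.average_autaptic_current(b, (5, 95)) == pytest.approx(
            2.0 * m.average_autaptic_current(a, (5, 95))
        )

    def test_invalid_window_rejected(self):
        traj = synthetic_spiking(t_end=100.0)
        with pytest.raises(ValueError):
            m.average_autaptic_current(traj, (90.0, 90.0))
        with pytest.raises(ValueError):
            m.average_autaptic_current(traj, (50.0, 200.0))


class TestFrequency:
    def test_zero_without_spikes(self):
        assert m.firing_frequency(np.array([]), (0.0, 100.0)) == 0.0

    def test_reciprocal_of_steady_interval(self):
        spikes = np.arange(0.0, 1000.0, 10.0)
        assert m.firing_frequency(spikes, (0.0, 1000.0)) == pytest.approx(100.0)

    def test_class_ii_limit_cycle_rate(self, type2):
        info = m.limit_cycle_from_simulation(100.0, type2, T=300.0, settle=100.0)
        assert 1000.0 / info.period == pytest.approx(188.0, rel=0.02)


def test_steady_isi_requires_two_late_spikes():
    assert m.steady_isi(np.array([10.0]), t_end=1000.0) is None
    assert m.steady_isi(np.array([800.0, 810.0, 820.0]), t_end=1000.0) == pytest.approx(10.0)
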