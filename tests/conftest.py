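import numpy as np
import pytest

import mlautapse as m

# Reference autapse settings shared across the suite: g_syn = 3 mS/cm^2,
# delay 15 ms, standard single-pulse trigger, 1000 ms runs.
AUTAPSE_CASES = {
    ("typeII", 0.1): dict(tau=15.0),
    ("typeIII", 0.1): dict(tau=15.0),
    ("typeII", 0.01): dict(tau=15.0),
    ("typeIII", 0.01): dict(tau=15.0),
}


@pytest.fixture(scope="session")
def type2():
    return m.preset("typeII")


@pytest.fixture(scope="session")
def type3():
    return m.preset("typeIII")


@pytest.fixture(scope="session")
def hopf_ii(type2):
    """Hopf current of the class II preset, located once per session."""
    res = m.find_hopf(0.0, 100.0, type2, tol=1e-4)
    assert res.I_H is not None
    return res.I_H


@pytest.fixture(scope="session")
def autapse_runs(type2, type3):
    """The reference triggered autapse trajectories, integrated once."""
    runs = {}
    for (name, beta), extra in AUTAPSE_CASES.items():
        params = type2 if name == "typeII" else type3
        syn = m.SynapseParams(g_syn=3.0, tau=extra["tau"], beta=beta)
        runs[(name, beta)] = m.run_triggered(params, syn, T=1000.0)
    return runs


def make_trajectory(t, V, **cols):
    """Hand-built Trajectory for metric tests (zero-filled synapse columns)."""
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    z = np.zeros_like(t)
    return m.Trajectory(
        t=t,
        V=V,
        w=cols.get("w", z.copy()),
        s=cols.get("s", z.copy()),
        I_syn=cols.get("I_syn", z.copy()),
        I_stim=cols.get("I_stim", z.copy()),
        h=float(t[1] - t[0]),
    )
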