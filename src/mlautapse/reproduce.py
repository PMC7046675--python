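"""End-to-end recomputation of the study's headline quantities.

Each function runs the full pipeline (build parameters, integrate or
continue, measure) and returns a plain number; ``run_all`` collects them in a
dict keyed by descriptive names.  Everything is deterministic — the model is
a deterministic (delay) ODE and the protocols are fixed.
"""

from __future__ import annotations

from .bifurcation import find_fold_of_cycles, find_hopf, limit_cycle_from_simulation
from .integrate import integrate
from .model import ModelParams, preset
from .scans import firing_border_in_beta, run_triggered
from .spikes import detect_spikes, steady_isi
from .stimulus import StimulusProtocol
from .synapse import SynapseParams

__all__ = [
    "hopf_current",
    "fold_current",
    "limit_cycle_period",
    "long_pulse_spike_count",
    "autapse_steady_isi",
    "beta_firing_border",
    "run_all",
]


def hopf_current(params: ModelParams | None = None, tol: float = 1e-4) -> float:
    """Hopf bifurcation current I_H of the class II equilibrium (uA/cm^2)."""
    params = params or preset("typeII")
    res = find_hopf(0.0, 100.0, params, tol=tol)
    if res.I_H is None:
        raise RuntimeError("no Hopf point found on [0, 100]")
    return res.I_H


def fold_current(params: ModelParams | None = None, tol: float = 0.01) -> float:
    """Fold-of-limit-cycles current of the class II model (uA/cm^2)."""
    params = params or preset("typeII")
    return find_fold_of_cycles(params, I_start=100.0, I_lo=30.0, tol=tol)


def limit_cycle_period(I_app: float = 100.0, params: ModelParams | None = None) -> float:
    """Stable limit-cycle period at constant I_app for class II (ms).

    300 ms run from the I_app = 0 resting state, first 100 ms discarded.
    """
    params = params or preset("typeII")
    info = limit_cycle_from_simulation(I_app, params, T=300.0, settle=100.0)
    if not info.exists:
        raise RuntimeError(f"no stable cycle at I_app={I_app}")
    return float(info.period)


def long_pulse_spike_count(preset_name: str = "typeII") -> int:
    """Spikes emitted during a 100 uA/cm^2, 60 ms depolarising pulse."""
    params = preset(preset_name)
    proto = StimulusProtocol(kind="pulse", amplitude=100.0, onset=50.0, duration=60.0)
    traj = integrate(params, None, proto, T=400.0)
    st = detect_spikes(traj)
    return int(((st >= proto.onset) & (st < proto.onset + proto.duration)).sum())


def autapse_steady_isi(
    preset_name: str,
    beta: float,
    tau: float = 15.0,
    g_syn: float = 3.0,
    T: float = 1000.0,
) -> float:
    """Steady ISI of autapse-driven firing after the standard trigger (ms).

    Mean interspike interval over the final 300 ms of the run.
    """
    params = preset(preset_name)
    syn = SynapseParams(g_syn=g_syn, tau=tau, beta=beta)
    traj = run_triggered(params, syn, T=T)
    st = detect_spikes(traj)
    isi = steady_isi(st, traj.t_end, window=300.0)
    if isi is None:
        raise RuntimeError(
            f"{preset_name} autapse run (beta={beta}, tau={tau}) is not repetitive"
        )
    return isi


def beta_firing_border(
    preset_name: str = "typeIII",
    g_syn: float = 3.0,
    tau: float = 4.0,
    tol: float = 0.01,
) -> float:
    """Decay rate separating firing from quiescence (1/ms)."""
    params = preset(preset_name)
    res = firing_border_in_beta(g_syn, tau, params, beta_lo=0.01, beta_hi=1.0, tol=tol)
    if res.beta is None:
        raise RuntimeError("no firing border in beta on [0.01, 1]")
    return res.beta


def run_all() -> dict[str, float]:
    """Recompute every headline quantity; keys are descriptive names."""
    return {
        "hopf_current_typeII": hopf_current(),
        "fold_of_cycles_typeII": fold_current(),
        "limit_cycle_period_typeII_I100": limit_cycle_period(),
        "long_pulse_spike_count_typeII": float(long_pulse_spike_count("typeII")),
        "autapse_isi_typeII_beta0p1_tau15": autapse_steady_isi("typeII", beta=0.1),
        "autapse_isi_typeIII_beta0p1_tau15": autapse_steady_isi("typeIII", beta=0.1),
        "autapse_isi_typeII_beta0p01_tau15": autapse_steady_isi("typeII", beta=0.01),
        "beta_firing_border_typeIII_tau4": beta_firing_border(),
    }
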