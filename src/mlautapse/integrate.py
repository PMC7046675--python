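"""Trajectory integration of the neuron with (or without) the delayed autapse.

The model with autapse is a delay differential equation: the autaptic current
at time t depends on the synaptic activation at t - tau.  It is advanced with
the classical fourth-order Runge-Kutta scheme on a fixed grid (default step
h = 0.01 ms) while the delayed activation is read from the stored solution
history with linear interpolation; the pre-history is s = 0 (no spikes before
the run starts), so the first spike must be evoked by the stimulus.

The autapse-free model is the special case g_syn = 0, run through the
identical code path, which makes the reduction exact to the bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import _core
from .model import ModelParams, State, w_inf
from .stimulus import StimulusProtocol, current_at
from .synapse import SynapseParams

__all__ = ["Trajectory", "integrate", "resting_state", "BlowupError"]

_KIND_CODE = {"constant": _core.KIND_CONSTANT, "pulse": _core.KIND_PULSE, "pulse_train": _core.KIND_TRAIN}


class BlowupError(RuntimeError):
    """The integration produced a non-finite state."""

    def __init__(self, t_fail: float):
        super().__init__(f"integration diverged at t = {t_fail:.4f} ms")
        self.t_fail = t_fail


@dataclass
class Trajectory:
    """Sampled solution on a uniform grid.

    Columns: time t (ms), membrane potential V (mV), recovery w, synaptic
    activation s, autaptic current I_syn (uA/cm^2, reconstructed as
    ``-g_syn s(t - tau) (V(t) - E_syn)``), and applied current I_stim.
    """

    t: np.ndarray
    V: np.ndarray
    w: np.ndarray
    s: np.ndarray
    I_syn: np.ndarray
    I_stim: np.ndarray
    h: float
    params: ModelParams | None = None
    syn: SynapseParams | None = None
    protocol: StimulusProtocol | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("V", "w", "s", "I_syn", "I_stim"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} has wrong length")

    @property
    def t_end(self) -> float:
        return float(self.t[-1])

    def to_frame(self):
        """Trajectory as a pandas DataFrame (column names carry units)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "t_ms": self.t,
                "V_mV": self.V,
                "w": self.w,
                "s": self.s,
                "I_syn_uA_cm2": self.I_syn,
                "I_stim_uA_cm2": self.I_stim,
            }
        )


def resting_state(params: ModelParams, I_app: float = 0.0, v_range: tuple[float, float] = (-100.0, 40.0)) -> State:
    """Equilibrium of the autapse-free model at constant current I_app.

    Solves the reduced scalar equation (membrane current balance with
    w = w_inf(V)) by bracketed root finding; with the class II / III
    parameter sets the equilibrium is unique over the physiological range.
    """
    p = params

    def F(V: float) -> float:
        return (
            I_app
            - p.g_Na * (0.5 * (1 + np.tanh((V - p.beta_m) / p.gamma_m))) * (V - p.E_Na)
            - p.g_K * (0.5 * (1 + np.tanh((V - p.beta_w) / p.gamma_w))) * (V - p.E_K)
            - p.g_L * (V - p.E_L)
        )

    lo, hi = v_range
    if F(lo) * F(hi) > 0:
        raise ValueError(f"no equilibrium bracketed in V range {v_range} at I_app={I_app}")
    V_star = brentq(F, lo, hi, xtol=1e-12)
    return State(V=float(V_star), w=float(w_inf(V_star, params)))


def integrate(
    params: ModelParams,
    syn: SynapseParams | None,
    protocol: StimulusProtocol,
    T: float,
    h: float = 0.01,
    initial: State | str = "equilibrium",
) -> Trajectory:
    """Integrate for T ms with step h and return the sampled Trajectory.

    ``initial="equilibrium"`` starts from the autapse-free resting state at
    the protocol baseline (with s = 0).  ``syn=None`` disables the autapse
    (equivalent to g_syn = 0).
    """
    if h <= 0:
        raise ValueError("step h must be positive")
    if T < h:
        raise ValueError("run length T must be at least one step")
    if syn is None:
        syn = SynapseParams(g_syn=0.0)

    if isinstance(initial, str):
        if initial != "equilibrium":
            raise ValueError(f"unknown initial condition {initial!r}")
        init = resting_state(params, I_app=protocol.baseline)
    else:
        init = State(*initial)

    n = int(round(T / h))
    V = np.empty(n + 1)
    w = np.empty(n + 1)
    s = np.empty(n + 1)
    V[0], w[0], s[0] = init.V, init.w, 0.0

    p = params
    fail = _core.rk4_dde(
        V, w, s, float(h),
        p.C, p.g_Na, p.g_K, p.g_L, p.E_Na, p.E_K, p.E_L,
        p.beta_m, p.gamma_m, p.beta_w, p.gamma_w, p.phi_w, p.w_cosh_denom,
        syn.g_syn, syn.E_syn, syn.tau, syn.alpha, syn.beta, syn.theta_syn, syn.k_sig,
        _KIND_CODE[protocol.kind], protocol.baseline, protocol.amplitude,
        protocol.onset, protocol.duration,
        protocol.period if protocol.period > 0 else 1.0,
        protocol.n_pulses,
    )
    if fail >= 0:
        raise BlowupError(fail * h)

    t = np.arange(n + 1) * h
    # delayed activation at the sample times, same convention as the core
    s_del = np.interp(t - syn.tau, t, s, left=0.0)
    s_del[t - syn.tau <= 0.0] = 0.0
    I_syn = -syn.g_syn * s_del * (V - syn.E_syn)
    I_stim = np.asarray(current_at(protocol, t), dtype=float)

    return Trajectory(t=t, V=V, w=w, s=s, I_syn=I_syn, I_stim=I_stim, h=float(h),
                      params=params, syn=syn, protocol=protocol)
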