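"""Conductance-based autaptic synapse: release sigmoid and gating kinetics.

The neuron feeds its own delayed output back through an excitatory synapse.
Transmitter release is gated by a steep sigmoid of the presynaptic potential
around the release threshold, and the synaptic activation s follows first-order
rise/decay kinetics

    ds/dt = alpha * Gamma(V_pre) * (1 - s) - beta * s .

The autaptic current is  I_syn = -g_syn * s(t - tau) * (V - E_syn)  with the
activation read ``tau`` milliseconds in the past (axonal plus synaptic
latency).  For an excitatory autapse E_syn sits well above rest, so I_syn is
depolarizing whenever s is active.  The decay rate beta is the key control:
small beta mimics slowly deactivating (NMDA-like) receptors and yields a
sustained autaptic current, large beta a brief pulse-like one.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import expit

__all__ = ["SynapseParams", "release_sigmoid", "synapse_rate"]


@dataclass(frozen=True)
class SynapseParams:
    """Autapse constants.

    g_syn  mS/cm^2   autaptic conductance (0 disables the feedback)
    E_syn  mV        reversal potential (30 mV -> excitatory)
    tau    ms        feedback delay
    alpha  1/ms      activation rise rate
    beta   1/ms      activation decay rate
    theta_syn mV     release threshold (release only during a spike)
    k_sig  1/mV      steepness of the release sigmoid
    """

    g_syn: float = 0.0
    E_syn: float = 30.0
    tau: float = 0.0
    alpha: float = 12.0
    beta: float = 1.0
    theta_syn: float = 10.0
    k_sig: float = 10.0

    def __post_init__(self) -> None:
        if self.g_syn < 0:
            raise ValueError("g_syn must be non-negative")
        if self.tau < 0:
            raise ValueError("delay tau must be non-negative")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("rates alpha and beta must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynapseParams":
        return cls(**d)


def release_sigmoid(V_pre, syn: SynapseParams):
    """Release gate ``Gamma(V_pre) = 1 / (1 + exp(-k_sig (V_pre - theta_syn)))``.

    Essentially 0 below threshold and essentially 1 during a spike; vectorized.
    """
    return expit(syn.k_sig * (np.asarray(V_pre, dtype=float) - syn.theta_syn))


def synapse_rate(s, V_pre, syn: SynapseParams):
    """ds/dt of the synaptic activation (1/ms).

    Positive at s = 0 whenever the gate is open, negative at s = 1; hence
    [0, 1] is invariant.  With the gate pinned open the fixed point is
    ``alpha / (alpha + beta)``.
    """
    g = release_sigmoid(V_pre, syn)
    return syn.alpha * g * (1.0 - np.asarray(s, dtype=float)) - syn.beta * np.asarray(s, dtype=float)
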