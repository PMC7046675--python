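"""Morris-Lecar membrane model: gating functions, vector field, nullclines.

The model is the planar conductance-based neuron

    C dV/dt = I_app - g_Na m_inf(V) (V - E_Na) - g_K w (V - E_K) - g_L (V - E_L)
      dw/dt = phi_w (w_inf(V) - w) / tau_w(V)

with instantaneous sodium activation m_inf and a single recovery variable w
(delayed-rectifier potassium activation).  The gating steady states are
Boltzmann sigmoids and the recovery time constant is a reciprocal cosh.

Two excitability classes are obtained from the same parameter set by moving
the half-activation voltage of w: ``beta_w = -13 mV`` yields class II
(repetitive firing appears through a subcritical Hopf bifurcation as the
applied current grows) and ``beta_w = -25 mV`` yields class III (the resting
state stays stable for every constant current in the physiological range, so
sustained current elicits at most a single onset spike).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, NamedTuple

import numpy as np

__all__ = [
    "ModelParams",
    "State",
    "boltzmann_activation",
    "recovery_time_constant",
    "m_inf",
    "w_inf",
    "ml_vector_field",
    "v_nullcline",
    "w_nullcline",
    "jacobian",
    "preset",
    "PRESETS",
]

TauWVariant = Literal["factor_2", "no_factor_2"]


@dataclass(frozen=True)
class ModelParams:
    """Constants of the membrane equations.

    Units: capacitance uF/cm^2, conductances mS/cm^2, potentials mV,
    ``phi_w`` a dimensionless rate scale (the combination
    ``phi_w / tau_w(V)`` is a rate in 1/ms).

    ``tau_w_variant`` selects the denominator of the cosh argument in the
    recovery time constant: ``"factor_2"`` uses ``2 * gamma_w`` (the standard
    Morris-Lecar form, the default) and ``"no_factor_2"`` uses ``gamma_w``.
    """

    C: float = 2.0
    g_Na: float = 20.0
    g_K: float = 20.0
    g_L: float = 2.0
    E_Na: float = 50.0
    E_K: float = -100.0
    E_L: float = -70.0
    beta_m: float = -1.2
    gamma_m: float = 18.0
    beta_w: float = -13.0
    gamma_w: float = 10.0
    phi_w: float = 0.15
    tau_w_variant: TauWVariant = "factor_2"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("capacitance C must be positive")
        if min(self.g_Na, self.g_K, self.g_L) < 0:
            raise ValueError("conductances must be non-negative")
        if self.gamma_m <= 0 or self.gamma_w <= 0:
            raise ValueError("slope parameters gamma_m, gamma_w must be positive")
        if self.phi_w <= 0:
            raise ValueError("phi_w must be positive")
        if self.tau_w_variant not in ("factor_2", "no_factor_2"):
            raise ValueError(f"unknown tau_w_variant {self.tau_w_variant!r}")

    @property
    def w_cosh_denom(self) -> float:
        """Denominator of the cosh argument in tau_w."""
        return 2.0 * self.gamma_w if self.tau_w_variant == "factor_2" else self.gamma_w

    def with_variant(self, variant: TauWVariant) -> "ModelParams":
        return replace(self, tau_w_variant=variant)


class State(NamedTuple):
    """Instantaneous membrane state: potential V (mV) and K+ activation w."""

    V: float
    w: float


def preset(name: str, variant: TauWVariant = "factor_2") -> ModelParams:
    """Return the class II or class III parameter set.

    ``"typeII"`` sets ``beta_w = -13 mV``; ``"typeIII"`` sets
    ``beta_w = -25 mV``.  All other constants are shared.
    """
    if name == "typeII":
        return ModelParams(beta_w=-13.0, tau_w_variant=variant)
    if name == "typeIII":
        return ModelParams(beta_w=-25.0, tau_w_variant=variant)
    raise ValueError(f"unknown preset {name!r}; expected 'typeII' or 'typeIII'")


PRESETS = ("typeII", "typeIII")


def boltzmann_activation(V, beta_x: float, gamma_x: float):
    """Steady-state activation ``0.5 * (1 + tanh((V - beta_x) / gamma_x))``.

    Strictly increasing in V for ``gamma_x > 0``, with value 0.5 at the
    half-activation voltage ``beta_x``.  Accepts scalars or arrays.
    """
    if gamma_x == 0:
        raise ValueError("gamma_x must be nonzero")
    return 0.5 * (1.0 + np.tanh((np.asarray(V, dtype=float) - beta_x) / gamma_x))


def m_inf(V, params: ModelParams):
    """Instantaneous sodium activation."""
    return boltzmann_activation(V, params.beta_m, params.gamma_m)


def w_inf(V, params: ModelParams):
    """Steady-state potassium activation."""
    return boltzmann_activation(V, params.beta_w, params.gamma_w)


def recovery_time_constant(V, params: ModelParams, variant: TauWVariant | None = None):
    """Voltage-dependent recovery time constant ``1 / cosh(...)`` (ms).

    Symmetric about ``V = beta_w`` where it attains its maximum of 1; always
    in (0, 1].  ``variant`` overrides the parameter set's cosh-argument
    convention (``"factor_2"`` divides by ``2 * gamma_w``).
    """
    if variant is None:
        variant = params.tau_w_variant
    denom = 2.0 * params.gamma_w if variant == "factor_2" else params.gamma_w
    return 1.0 / np.cosh((np.asarray(V, dtype=float) - params.beta_w) / denom)


def ml_vector_field(state: State, I_app: float, params: ModelParams) -> tuple[float, float]:
    """Time derivatives (dV/dt in mV/ms, dw/dt in 1/ms) of the planar model."""
    V, w = float(state[0]), float(state[1])
    if not (np.isfinite(V) and np.isfinite(w)):
        raise ValueError(f"non-finite state ({V}, {w})")
    dV = (
        I_app
        - params.g_Na * m_inf(V, params) * (V - params.E_Na)
        - params.g_K * w * (V - params.E_K)
        - params.g_L * (V - params.E_L)
    ) / params.C
    dw = params.phi_w * (w_inf(V, params) - w) * np.cosh((V - params.beta_w) / params.w_cosh_denom)
    return float(dV), float(dw)


def v_nullcline(V, I_app: float, params: ModelParams):
    """w on the dV/dt = 0 curve at membrane potential V.

    Moves up with I_app for fixed V above the potassium reversal.  Singular
    at ``V = E_K`` where the potassium driving force vanishes.
    """
    Varr = np.asarray(V, dtype=float)
    if np.any(Varr == params.E_K):
        raise ValueError("v_nullcline is singular at V = E_K")
    num = I_app - params.g_Na * m_inf(Varr, params) * (Varr - params.E_Na) - params.g_L * (Varr - params.E_L)
    return num / (params.g_K * (Varr - params.E_K))


def w_nullcline(V, params: ModelParams):
    """w on the dw/dt = 0 curve (identical to ``w_inf``; I_app-independent)."""
    return w_inf(V, params)


def jacobian(V: float, w: float, params: ModelParams) -> np.ndarray:
    """Analytic 2x2 Jacobian of the vector field at (V, w)."""
    p = params
    dm = 0.5 / (p.gamma_m * np.cosh((V - p.beta_m) / p.gamma_m) ** 2)
    dwi = 0.5 / (p.gamma_w * np.cosh((V - p.beta_w) / p.gamma_w) ** 2)
    ch = np.cosh((V - p.beta_w) / p.w_cosh_denom)
    sh = np.sinh((V - p.beta_w) / p.w_cosh_denom) / p.w_cosh_denom
    a11 = (-p.g_Na * (dm * (V - p.E_Na) + m_inf(V, p)) - p.g_K * w - p.g_L) / p.C
    a12 = -p.g_K * (V - p.E_K) / p.C
    a21 = p.phi_w * (dwi * ch + (w_inf(V, p) - w) * sh)
    a22 = -p.phi_w * ch
    return np.array([[a11, a12], [a21, a22]], dtype=float)
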