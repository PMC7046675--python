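"""Parameter scans over the autapse: (tau, g_syn) planes, the decay-rate
firing border, and decay-rate sweeps of the average autaptic current.

Every cell runs the same deterministic experiment: start at rest, elicit one
spike with the standard trigger (a 1.5 ms, 100 uA/cm^2 pulse), then let the
delayed autaptic feedback evolve freely and classify whether firing persists.
The paradoxical regime of class III excitability appears here: decreasing the
synaptic decay rate beta makes the autaptic current larger and longer-lasting
yet *destroys* sustained firing, because class III neurons spike only on
current onsets, not on sustained depolarisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .integrate import Trajectory, integrate
from .model import ModelParams
from .spikes import (
    average_autaptic_current,
    classify_response,
    detect_spikes,
    summarize,
)
from .stimulus import standard_trigger
from .synapse import SynapseParams

__all__ = [
    "ScanResult",
    "BorderResult",
    "run_triggered",
    "scan_tau_gsyn",
    "firing_border_in_beta",
    "beta_sweep_avg_current",
]

TRIGGER_ONSET = 50.0


def run_triggered(
    params: ModelParams,
    syn: SynapseParams,
    T: float = 1000.0,
    h: float = 0.01,
) -> Trajectory:
    """Standard autapse experiment: rest -> single trigger pulse -> free run."""
    return integrate(params, syn, standard_trigger(TRIGGER_ONSET), T=T, h=h,
                     initial="equilibrium")


@dataclass
class ScanResult:
    """Gridded firing outcomes on the (tau, g_syn) plane at fixed beta."""

    tau: np.ndarray            # (n_tau,) ms
    g_syn: np.ndarray          # (n_g,) mS/cm^2
    beta: float                # 1/ms
    frequency: np.ndarray      # (n_tau, n_g) spikes/s; 0 unless repetitive
    response_class: np.ndarray  # (n_tau, n_g) str
    firing_case: np.ndarray    # (n_tau, n_g) str
    errors: list[tuple[int, int, str]] = field(default_factory=list)

    def to_frame(self):
        """Long-format DataFrame (one row per grid cell)."""
        import pandas as pd

        ti, gi = np.meshgrid(np.arange(len(self.tau)), np.arange(len(self.g_syn)), indexing="ij")
        return pd.DataFrame(
            {
                "tau_ms": self.tau[ti.ravel()],
                "g_syn_mS_cm2": self.g_syn[gi.ravel()],
                "beta_per_ms": self.beta,
                "frequency_Hz": self.frequency.ravel(),
                "response_class": self.response_class.ravel(),
                "firing_case": self.firing_case.ravel(),
            }
        )


def scan_tau_gsyn(
    beta: float,
    tau_range: tuple[float, float],
    g_range: tuple[float, float],
    n_tau: int,
    n_g: int,
    params: ModelParams,
    T: float = 600.0,
    h: float = 0.01,
    settle_window: float = 200.0,
    I_H: float | None = None,
    syn_defaults: SynapseParams | None = None,
) -> ScanResult:
    """Classify the triggered run on an (tau, g_syn) grid at fixed beta.

    Cells are independent and deterministic; a failed integration is recorded
    in ``errors`` and the scan continues.
    """
    taus = np.linspace(tau_range[0], tau_range[1], n_tau)
    gs = np.linspace(g_range[0], g_range[1], n_g)
    base = syn_defaults or SynapseParams()
    freq = np.zeros((n_tau, n_g))
    cls = np.full((n_tau, n_g), "resting", dtype="<U20")
    case = np.full((n_tau, n_g), "not_applicable", dtype="<U20")
    errors: list[tuple[int, int, str]] = []
    for i, tau in enumerate(taus):
        for j, g in enumerate(gs):
            syn = SynapseParams(
                g_syn=float(g), E_syn=base.E_syn, tau=float(tau), alpha=base.alpha,
                beta=float(beta), theta_syn=base.theta_syn, k_sig=base.k_sig,
            )
            try:
                traj = run_triggered(params, syn, T=T, h=h)
            except Exception as exc:  # record and move on
                errors.append((i, j, str(exc)))
                cls[i, j] = "error"
                continue
            summ = summarize(traj, settle_window=settle_window,
                             isi_window=settle_window, tau=float(tau), I_H=I_H)
            cls[i, j] = summ.response_class
            case[i, j] = summ.firing_case
            if summ.response_class == "repetitive":
                freq[i, j] = summ.frequency
    return ScanResult(tau=taus, g_syn=gs, beta=float(beta), frequency=freq,
                      response_class=cls, firing_case=case, errors=errors)


@dataclass(frozen=True)
class BorderResult:
    """Decay-rate border between non-firing and firing regimes."""

    beta: float | None          # border value, or None when absent
    bracket: float              # final bracket width
    pre_scan: tuple[tuple[float, bool], ...]  # (beta, fires) coarse scan
    monotone: bool              # single transition across the pre-scan


def _fires(params: ModelParams, syn: SynapseParams, T: float, h: float, settle: float) -> bool:
    traj = run_triggered(params, syn, T=T, h=h)
    st = detect_spikes(traj)
    return classify_response(st, traj, settle_window=settle) == "repetitive"


def firing_border_in_beta(
    g_syn: float,
    tau: float,
    params: ModelParams,
    beta_lo: float = 0.01,
    beta_hi: float = 1.0,
    tol: float = 0.01,
    n_prescan: int = 9,
    T: float = 1000.0,
    h: float = 0.01,
    settle_window: float = 200.0,
) -> BorderResult:
    """Bisect the beta value separating repetitive firing from quiescence.

    A coarse pre-scan over [beta_lo, beta_hi] guards against non-monotone
    classification: bisection is only run when the pre-scan shows a single
    transition, otherwise the pre-scan itself is returned for inspection.
    When both endpoints classify the same (fires everywhere, as for class II
    at these settings, or nowhere, as for g_syn = 0), the border is absent.
    """
    if not beta_lo < beta_hi:
        raise ValueError("need beta_lo < beta_hi")

    def syn_at(beta: float) -> SynapseParams:
        return SynapseParams(g_syn=float(g_syn), tau=float(tau), beta=float(beta))

    grid = np.linspace(beta_lo, beta_hi, n_prescan)
    fires = [_fires(params, syn_at(b), T, h, settle_window) for b in grid]
    pre = tuple((float(b), bool(f)) for b, f in zip(grid, fires))
    transitions = sum(1 for a, b in zip(fires[:-1], fires[1:]) if a != b)
    monotone = transitions <= 1
    if fires[0] == fires[-1] or not monotone:
        return BorderResult(beta=None, bracket=0.0, pre_scan=pre, monotone=monotone)

    # locate the transition interval in the pre-scan, then bisect inside it
    k = next(i for i in range(len(grid) - 1) if fires[i] != fires[i + 1])
    lo, hi = float(grid[k]), float(grid[k + 1])
    f_lo = fires[k]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _fires(params, syn_at(mid), T, h, settle_window) == f_lo:
            lo = mid
        else:
            hi = mid
    return BorderResult(beta=0.5 * (lo + hi), bracket=hi - lo, pre_scan=pre, monotone=True)


def beta_sweep_avg_current(
    g_syn: float,
    tau: float,
    beta_values,
    params: ModelParams,
    T: float = 1000.0,
    h: float = 0.01,
    settle_window: float = 200.0,
    window: tuple[float, float] | None = None,
):
    """Average autaptic current and response class for each decay rate.

    The measurement window defaults to two interspike intervals of the
    beta = 1 reference run (same g_syn and tau): from that run's third spike
    to its fifth, i.e. shortly after firing is established, where the slow
    and fast autapses differ most.  The same fixed window is used for every
    beta, so the averages are directly comparable.  Returns a list of dicts
    with the window echoed.
    """
    if window is None:
        ref = run_triggered(params, SynapseParams(g_syn=float(g_syn), tau=float(tau), beta=1.0),
                            T=T, h=h)
        ref_spikes = detect_spikes(ref)
        if len(ref_spikes) < 5:
            raise ValueError("beta = 1 reference run has too few spikes; pass window explicitly")
        window = (float(ref_spikes[2]), float(ref_spikes[4]))

    rows = []
    for beta in np.atleast_1d(np.asarray(beta_values, dtype=float)):
        syn = SynapseParams(g_syn=float(g_syn), tau=float(tau), beta=float(beta))
        traj = run_triggered(params, syn, T=T, h=h)
        st = detect_spikes(traj)
        cls = classify_response(st, traj, settle_window=settle_window)
        avg = average_autaptic_current(traj, window)
        rows.append(
            {
                "beta": float(beta),
                "avg_I_syn": avg,
                "response_class": cls,
                "window_t0": window[0],
                "window_t1": window[1],
            }
        )
    return rows
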