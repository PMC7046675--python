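"""Spike detection, interspike intervals and firing-regime classification.

Spikes are upward threshold crossings of the membrane potential (default
0 mV — action potentials in this model overshoot 0 mV, while the synaptic
release threshold of 10 mV plays no role in detection).  A run is classified

* ``resting``             — no spikes at all;
* ``transient_then_rest`` — spikes occurred but none in the final settle
  window, i.e. firing died out;
* ``repetitive``          — spikes persist into the final settle window.

Repetitive autapse-driven firing is further split into the two mechanisms:

* ``case1`` — the delayed autaptic current arrives as a brief pulse and each
  pulse evokes the next spike, so the interspike interval tracks the feedback
  delay tau;
* ``case2`` — the autaptic current stays above the Hopf current I_H most of
  the time, so the neuron rides its limit cycle and the interval is set by
  the cycle period instead (only possible for class II excitability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrate import Trajectory

__all__ = [
    "FiringSummary",
    "detect_spikes",
    "interspike_intervals",
    "steady_isi",
    "classify_response",
    "classify_case",
    "average_autaptic_current",
    "firing_frequency",
    "summarize",
]


@dataclass
class FiringSummary:
    """Per-run firing statistics and regime labels."""

    spike_times: np.ndarray
    isis: np.ndarray
    steady_isi: float | None
    frequency: float
    response_class: str  # resting | transient_then_rest | repetitive
    firing_case: str = "not_applicable"  # case1 | case2 | not_applicable
    v_threshold: float = 0.0
    refractory: float = 1.0
    settle_window: float = 200.0


def detect_spikes(traj: Trajectory, v_threshold: float = 0.0, refractory: float = 1.0) -> np.ndarray:
    """Times of upward crossings of ``v_threshold`` at grid resolution.

    Crossings closer than ``refractory`` ms to the previous accepted spike
    are discarded.  Adding samples strictly below threshold cannot create or
    destroy spikes.
    """
    V = traj.V
    idx = np.nonzero((V[:-1] < v_threshold) & (V[1:] >= v_threshold))[0]
    times = traj.t[idx + 1]
    if refractory <= 0 or len(times) < 2:
        return times
    kept = [times[0]]
    for x in times[1:]:
        if x - kept[-1] >= refractory:
            kept.append(x)
    return np.asarray(kept)


def interspike_intervals(spike_times: np.ndarray) -> np.ndarray:
    return np.diff(np.asarray(spike_times, dtype=float))


def steady_isi(spike_times: np.ndarray, t_end: float, window: float = 300.0) -> float | None:
    """Mean interspike interval among spikes in the final ``window`` ms.

    Returns None when fewer than two spikes fall in the window (no steady
    interval is defined).
    """
    st = np.asarray(spike_times, dtype=float)
    late = st[st >= t_end - window]
    if len(late) < 2:
        return None
    return float(np.mean(np.diff(late)))


def classify_response(spike_times: np.ndarray, traj: Trajectory, settle_window: float = 200.0) -> str:
    """Label the run resting / transient_then_rest / repetitive.

    ``repetitive`` requires at least one spike inside the final settle
    window, i.e. firing that persists to the end of the run.
    """
    if traj.t_end < 2 * settle_window:
        raise ValueError(
            f"run of {traj.t_end} ms too short to classify with settle_window={settle_window} ms"
        )
    st = np.asarray(spike_times, dtype=float)
    if len(st) == 0:
        return "resting"
    if np.any(st >= traj.t_end - settle_window):
        return "repetitive"
    return "transient_then_rest"


def classify_case(
    summary: FiringSummary,
    traj: Trajectory,
    tau: float,
    I_H: float,
    isi_rtol: float = 0.15,
    supra_fraction: float = 0.5,
    settle_window: float = 200.0,
) -> str:
    """Discriminate case-1 (delay-entrained) from case-2 (supra-Hopf) firing.

    Delay entrainment is the defining signature of case-1 firing, so it takes
    precedence: the run is case-1 when the steady interspike interval is
    within ``isi_rtol`` of the delay tau.  Otherwise the firing is case-2 —
    the supra-Hopf mechanism, corroborated when the autaptic current exceeds
    I_H for more than ``supra_fraction`` of the final settle window.  (The
    fraction alone cannot discriminate: slowly decaying feedback keeps I_syn
    above I_H most of the time even in delay-entrained class III firing,
    where sustained supra-Hopf current cannot drive spiking at all.)
    """
    if summary.response_class != "repetitive":
        raise ValueError("firing case is defined only for repetitive runs")
    if tau <= 0:
        raise ValueError("tau must be positive")
    if summary.steady_isi is not None and abs(summary.steady_isi - tau) / tau < isi_rtol:
        return "case1"
    return "case2"


def average_autaptic_current(traj: Trajectory, window: tuple[float, float]) -> float:
    """Time average of I_syn over ``window = (t0, t1)`` ms (trapezoidal)."""
    t0, t1 = window
    if not (traj.t[0] <= t0 < t1 <= traj.t_end):
        raise ValueError(f"window {window} not inside trajectory span [0, {traj.t_end}]")
    mask = (traj.t >= t0) & (traj.t <= t1)
    tt = traj.t[mask]
    return float(np.trapezoid(traj.I_syn[mask], tt) / (tt[-1] - tt[0]))


def firing_frequency(spike_times: np.ndarray, window: tuple[float, float]) -> float:
    """Spike count in ``window`` divided by its length, in spikes/s."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window length must be positive")
    st = np.asarray(spike_times, dtype=float)
    count = int(np.sum((st >= t0) & (st < t1)))
    return 1000.0 * count / (t1 - t0)


def summarize(
    traj: Trajectory,
    v_threshold: float = 0.0,
    refractory: float = 1.0,
    settle_window: float = 200.0,
    isi_window: float = 300.0,
    tau: float | None = None,
    I_H: float | None = None,
) -> FiringSummary:
    """Full per-run summary: spikes, ISIs, response class, firing case.

    The firing case is computed only for repetitive runs when both the
    feedback delay and the Hopf current are supplied.
    """
    st = detect_spikes(traj, v_threshold, refractory)
    cls = classify_response(st, traj, settle_window)
    s_isi = steady_isi(st, traj.t_end, isi_window) if cls == "repetitive" else None
    freq = firing_frequency(st, (traj.t_end - settle_window, traj.t_end)) if cls == "repetitive" else 0.0
    out = FiringSummary(
        spike_times=st,
        isis=interspike_intervals(st),
        steady_isi=s_isi,
        frequency=freq,
        response_class=cls,
        v_threshold=v_threshold,
        refractory=refractory,
        settle_window=settle_window,
    )
    if cls == "repetitive" and tau is not None and tau > 0 and I_H is not None:
        out.firing_case = classify_case(out, traj, tau, I_H, settle_window=settle_window)
    return out
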