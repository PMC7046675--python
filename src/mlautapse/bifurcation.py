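"""Equilibrium continuation, Hopf detection and the fold of limit cycles.

The autapse-free model is planar, so its bifurcation structure in the applied
current I_app can be resolved with elementary tools:

* equilibria are roots of a scalar current-balance equation (w eliminated via
  w = w_inf(V)), with stability from the analytic 2x2 Jacobian;
* the Hopf point I_H is located by bisection on the sign of the largest
  eigenvalue real part along the equilibrium branch, checking that the
  eigenvalues are complex at the crossing;
* the stable limit cycle is characterised by direct simulation, and the fold
  (saddle-node) of limit cycles is found by hysteresis continuation: sweep
  I_app downward re-seeding each probe run from the end state of the previous
  cycle, then bisect the smallest current at which repetitive firing
  persists.

For the class II parameter set this yields the subcritical scenario: the
stable cycle is born at the fold (~42.18 uA/cm^2) below the Hopf point
(~42.80 uA/cm^2), with bistability in between.  For class III the equilibrium
stays stable over the whole physiological range and no Hopf point exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrate import State, integrate, resting_state
from .model import ModelParams, jacobian, m_inf, w_inf
from .spikes import classify_response, detect_spikes, steady_isi
from .stimulus import StimulusProtocol

__all__ = [
    "EquilibriumPoint",
    "LimitCycleInfo",
    "HopfResult",
    "find_equilibria",
    "find_equilibrium",
    "equilibrium_branch",
    "find_hopf",
    "limit_cycle_from_simulation",
    "find_fold_of_cycles",
]


@dataclass(frozen=True)
class EquilibriumPoint:
    I_app: float
    V: float
    w: float
    eigenvalues: tuple[complex, complex]
    stable: bool

    @property
    def is_focus(self) -> bool:
        """Complex eigenvalues (spiral) rather than a node."""
        return abs(self.eigenvalues[0].imag) > 0


@dataclass(frozen=True)
class LimitCycleInfo:
    I_app: float
    exists: bool
    period: float | None = None
    V_max: float | None = None
    V_min: float | None = None


@dataclass(frozen=True)
class HopfResult:
    I_H: float | None
    bracket: float  # final bracket width (uA/cm^2); 0 when absent


def _current_balance(V: float, I_app: float, p: ModelParams) -> float:
    return float(
        I_app
        - p.g_Na * m_inf(V, p) * (V - p.E_Na)
        - p.g_K * w_inf(V, p) * (V - p.E_K)
        - p.g_L * (V - p.E_L)
    )


def _point(V: float, I_app: float, params: ModelParams) -> EquilibriumPoint:
    w = float(w_inf(V, params))
    eig = np.linalg.eigvals(jacobian(V, w, params))
    eig = tuple(sorted((complex(e) for e in eig), key=lambda z: z.real))
    stable = all(e.real < 0 for e in eig)
    return EquilibriumPoint(I_app=float(I_app), V=float(V), w=w, eigenvalues=eig, stable=stable)


def find_equilibria(
    I_app: float,
    params: ModelParams,
    v_range: tuple[float, float] = (-100.0, 40.0),
    n_scan: int = 400,
) -> list[EquilibriumPoint]:
    """All equilibria in ``v_range``, found by sign-change scan + Brent refine."""
    from scipy.optimize import brentq

    Vs = np.linspace(v_range[0], v_range[1], n_scan)
    F = np.array([_current_balance(v, I_app, params) for v in Vs])
    roots: list[float] = []
    for i in range(len(Vs) - 1):
        if F[i] == 0.0:
            roots.append(float(Vs[i]))
        elif F[i] * F[i + 1] < 0:
            roots.append(float(brentq(_current_balance, Vs[i], Vs[i + 1],
                                      args=(I_app, params), xtol=1e-12)))
    return [_point(v, I_app, params) for v in roots]


def find_equilibrium(
    I_app: float,
    params: ModelParams,
    v_range: tuple[float, float] = (-100.0, 40.0),
) -> EquilibriumPoint:
    """The unique equilibrium at I_app; raises when none or several exist."""
    pts = find_equilibria(I_app, params, v_range)
    if not pts:
        raise ValueError(f"no equilibrium found in V range {v_range} at I_app={I_app}")
    if len(pts) > 1:
        raise ValueError(
            f"{len(pts)} equilibria at I_app={I_app}; use find_equilibria and select"
        )
    return pts[0]


def equilibrium_branch(
    I_range: tuple[float, float],
    n_points: int,
    params: ModelParams,
) -> list[EquilibriumPoint]:
    """Equilibria on a uniform I_app grid, following the branch by V-continuity."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    branch: list[EquilibriumPoint] = []
    prev_V: float | None = None
    for I in np.linspace(I_range[0], I_range[1], n_points):
        pts = find_equilibria(float(I), params)
        if not pts:
            raise ValueError(f"no equilibrium at I_app={I}")
        if prev_V is None or len(pts) == 1:
            pt = pts[0]
        else:
            pt = min(pts, key=lambda q: abs(q.V - prev_V))
        branch.append(pt)
        prev_V = pt.V
    return branch


def _max_real(I_app: float, params: ModelParams) -> float:
    return max(e.real for e in find_equilibrium(I_app, params).eigenvalues)


def find_hopf(
    I_lo: float,
    I_hi: float,
    params: ModelParams,
    tol: float = 1e-4,
) -> HopfResult:
    """Bisect the stability change of the equilibrium branch in [I_lo, I_hi].

    Returns the crossing current with bracket width <= tol, verifying the
    eigenvalues are complex there (a genuine Hopf rather than a real
    eigenvalue passing through zero).  Absence of a sign change reports
    ``I_H = None`` — the expected outcome for class III.
    """
    if not I_lo < I_hi:
        raise ValueError("need I_lo < I_hi")
    f_lo, f_hi = _max_real(I_lo, params), _max_real(I_hi, params)
    if f_lo * f_hi > 0:
        return HopfResult(I_H=None, bracket=0.0)
    lo, hi = float(I_lo), float(I_hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _max_real(mid, params) * f_lo <= 0:
            hi = mid
        else:
            lo = mid
    I_H = 0.5 * (lo + hi)
    eig = find_equilibrium(I_H, params).eigenvalues
    if abs(eig[0].imag) == 0:
        raise ValueError(
            f"eigenvalues real at the stability change near I_app={I_H:.4f}; "
            "not a Hopf bifurcation"
        )
    return HopfResult(I_H=float(I_H), bracket=float(hi - lo))


def limit_cycle_from_simulation(
    I_app: float,
    params: ModelParams,
    init: State | None = None,
    T: float = 500.0,
    h: float = 0.01,
    settle: float = 200.0,
) -> LimitCycleInfo:
    """Characterise the stable limit cycle at constant I_app by simulation.

    Integrates the autapse-free model from ``init`` (default: the resting
    state at I_app = 0, i.e. a current step) and measures the steady
    interspike interval after discarding the first ``settle`` ms.  Reports
    ``exists=False`` when firing does not persist to the end of the run.
    """
    if init is None:
        init = resting_state(params, 0.0)
    proto = StimulusProtocol(kind="constant", baseline=float(I_app))
    traj = integrate(params, None, proto, T=T, h=h, initial=init)
    st = detect_spikes(traj)
    if classify_response(st, traj, settle_window=min(settle, traj.t_end / 2)) != "repetitive":
        return LimitCycleInfo(I_app=float(I_app), exists=False)
    period = steady_isi(st, traj.t_end, window=traj.t_end - settle)
    if period is None:
        return LimitCycleInfo(I_app=float(I_app), exists=False)
    tail = traj.V[traj.t >= traj.t_end - 3 * period]
    return LimitCycleInfo(
        I_app=float(I_app),
        exists=True,
        period=float(period),
        V_max=float(tail.max()),
        V_min=float(tail.min()),
    )


def find_fold_of_cycles(
    params: ModelParams,
    I_start: float = 100.0,
    I_lo: float = 30.0,
    tol: float = 0.01,
    step: float = 2.0,
    probe_T: float = 500.0,
    h: float = 0.01,
    settle: float = 200.0,
) -> float:
    """Smallest I_app at which the stable cycle persists (fold of cycles).

    Hysteresis continuation: establish the cycle at ``I_start``, sweep I_app
    downward in ``step`` decrements re-seeding each probe run from the final
    state of the previous one (so the trajectory stays on the cycle branch,
    not the coexisting resting state), then bisect the disappearance current
    to a bracket <= ``tol``.
    """
    proto0 = StimulusProtocol(kind="constant", baseline=float(I_start))
    traj = integrate(params, None, proto0, T=probe_T, h=h,
                     initial=resting_state(params, 0.0))
    st = detect_spikes(traj)
    if classify_response(st, traj, settle_window=settle) != "repetitive":
        raise ValueError(f"no stable cycle at I_start={I_start}")
    state = State(float(traj.V[-1]), float(traj.w[-1]))

    def probe(I: float, seed: State) -> tuple[bool, State]:
        tr = integrate(params, None, StimulusProtocol(kind="constant", baseline=float(I)),
                       T=probe_T, h=h, initial=seed)
        stt = detect_spikes(tr)
        ok = classify_response(stt, tr, settle_window=settle) == "repetitive"
        return ok, State(float(tr.V[-1]), float(tr.w[-1]))

    hi = float(I_start)
    lo = None
    I = hi - step
    while I >= I_lo:
        ok, end_state = probe(I, state)
        if ok:
            hi, state = I, end_state
        else:
            lo = I
            break
        I -= step
    if lo is None:
        raise ValueError(f"cycle persists down to I_lo={I_lo}; no fold bracketed")

    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        ok, end_state = probe(mid, state)
        if ok:
            hi, state = mid, end_state
        else:
            lo = mid
    return 0.5 * (lo + hi)
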