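"""Numba-compiled fixed-step RK4 core with a delay history buffer.

One flat loop advances (V, w, s).  The delayed synaptic activation s(t - tau)
is read from the filled portion of the solution array with linear
interpolation, so the delay need not be a grid multiple and the RK4 stage
times (t + h/2) are handled exactly the same way as grid times.  Pre-history
is s = 0 for t <= 0 (no spikes before the run).

Stimulus kinds are encoded as integers: 0 constant, 1 single pulse,
2 periodic pulse train.  The window logic must match stimulus.current_at
(half-open [start, start + duration) windows).
"""

import numpy as np
from numba import njit

KIND_CONSTANT = 0
KIND_PULSE = 1
KIND_TRAIN = 2


@njit(cache=True)
def _stim(tq, kind, base, amp, onset, dur, period, n_pulses):
    if kind == 0:
        return base
    if kind == 1:
        if onset <= tq < onset + dur:
            return base + amp
        return base
    rel = tq - onset
    if rel < 0.0:
        return base
    k = int(rel // period)
    if n_pulses > 0 and k >= n_pulses:
        return base
    if rel - k * period < dur:
        return base + amp
    return base


@njit(cache=True)
def _sigmoid(x):
    # overflow-safe logistic
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    z = np.exp(x)
    return z / (1.0 + z)


@njit(cache=True)
def _s_delayed(s, i, tq, tau, h):
    tp = tq - tau
    if tp <= 0.0:
        return 0.0
    x = tp / h
    j = int(x)
    if j >= i:
        # only reachable when tau < h (stage time past the filled history)
        return s[i]
    f = x - j
    return s[j] * (1.0 - f) + s[j + 1] * f


@njit(cache=True)
def rk4_dde(
    V, w, s, h,
    C, gNa, gK, gL, ENa, EK, EL, bm, gm, bw, gw, phi, wden,
    gsyn, Esyn, tau, alpha, beta, theta, ksig,
    kind, base, amp, onset, dur, period, n_pulses,
):
    """Fill V, w, s in place from index 1; index 0 holds the initial state.

    Returns -1 on success, or the step index at which the state became
    non-finite.
    """
    n = V.shape[0] - 1
    for i in range(n):
        ti = i * h
        Vi = V[i]
        wi = w[i]
        si = s[i]

        # stage 1
        sd = _s_delayed(s, i, ti, tau, h)
        Iv = _stim(ti, kind, base, amp, onset, dur, period, n_pulses)
        minf = 0.5 * (1.0 + np.tanh((Vi - bm) / gm))
        winf = 0.5 * (1.0 + np.tanh((Vi - bw) / gw))
        dV1 = (Iv - gNa * minf * (Vi - ENa) - gK * wi * (Vi - EK) - gL * (Vi - EL)
               - gsyn * sd * (Vi - Esyn)) / C
        dw1 = phi * (winf - wi) * np.cosh((Vi - bw) / wden)
        ds1 = alpha * _sigmoid(ksig * (Vi - theta)) * (1.0 - si) - beta * si

        # stage 2
        th2 = ti + 0.5 * h
        sd = _s_delayed(s, i, th2, tau, h)
        Iv = _stim(th2, kind, base, amp, onset, dur, period, n_pulses)
        Vx = Vi + 0.5 * h * dV1
        wx = wi + 0.5 * h * dw1
        sx = si + 0.5 * h * ds1
        minf = 0.5 * (1.0 + np.tanh((Vx - bm) / gm))
        winf = 0.5 * (1.0 + np.tanh((Vx - bw) / gw))
        dV2 = (Iv - gNa * minf * (Vx - ENa) - gK * wx * (Vx - EK) - gL * (Vx - EL)
               - gsyn * sd * (Vx - Esyn)) / C
        dw2 = phi * (winf - wx) * np.cosh((Vx - bw) / wden)
        ds2 = alpha * _sigmoid(ksig * (Vx - theta)) * (1.0 - sx) - beta * sx

        # stage 3 (same stage time as stage 2)
        Vx = Vi + 0.5 * h * dV2
        wx = wi + 0.5 * h * dw2
        sx = si + 0.5 * h * ds2
        minf = 0.5 * (1.0 + np.tanh((Vx - bm) / gm))
        winf = 0.5 * (1.0 + np.tanh((Vx - bw) / gw))
        dV3 = (Iv - gNa * minf * (Vx - ENa) - gK * wx * (Vx - EK) - gL * (Vx - EL)
               - gsyn * sd * (Vx - Esyn)) / C
        dw3 = phi * (winf - wx) * np.cosh((Vx - bw) / wden)
        ds3 = alpha * _sigmoid(ksig * (Vx - theta)) * (1.0 - sx) - beta * sx

        # stage 4
        th4 = ti + h
        sd = _s_delayed(s, i, th4, tau, h)
        Iv = _stim(th4, kind, base, amp, onset, dur, period, n_pulses)
        Vx = Vi + h * dV3
        wx = wi + h * dw3
        sx = si + h * ds3
        minf = 0.5 * (1.0 + np.tanh((Vx - bm) / gm))
        winf = 0.5 * (1.0 + np.tanh((Vx - bw) / gw))
        dV4 = (Iv - gNa * minf * (Vx - ENa) - gK * wx * (Vx - EK) - gL * (Vx - EL)
               - gsyn * sd * (Vx - Esyn)) / C
        dw4 = phi * (winf - wx) * np.cosh((Vx - bw) / wden)
        ds4 = alpha * _sigmoid(ksig * (Vx - theta)) * (1.0 - sx) - beta * sx

        V[i + 1] = Vi + (h / 6.0) * (dV1 + 2.0 * dV2 + 2.0 * dV3 + dV4)
        w[i + 1] = wi + (h / 6.0) * (dw1 + 2.0 * dw2 + 2.0 * dw3 + dw4)
        s[i + 1] = si + (h / 6.0) * (ds1 + 2.0 * ds2 + 2.0 * ds3 + ds4)

        if not (np.isfinite(V[i + 1]) and np.isfinite(w[i + 1]) and np.isfinite(s[i + 1])):
            return i + 1
    return -1
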