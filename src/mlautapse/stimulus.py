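"""Piecewise-constant applied-current protocols.

Three stimulus kinds cover all the input waveforms used in the study of
autapse-driven firing: a constant holding current, a single rectangular pulse,
and a periodic train of brief rectangular pulses.  Pulse windows are half-open
``[start, start + duration)`` so a sample exactly at a pulse's end already
takes the baseline value.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

__all__ = ["StimulusProtocol", "current_at", "standard_protocols", "standard_trigger"]

Kind = Literal["constant", "pulse", "pulse_train"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Applied current I_app(t) in uA/cm^2.

    ``amplitude`` is added to ``baseline`` inside active pulse windows.  For
    ``pulse_train``, windows start at ``onset + k * period`` for
    ``k = 0 .. n_pulses - 1`` (``n_pulses = 0`` means the train continues to
    the end of the run).
    """

    kind: Kind = "constant"
    baseline: float = 0.0
    amplitude: float = 0.0
    onset: float = 50.0
    duration: float = 0.0
    period: float = 0.0
    n_pulses: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "pulse", "pulse_train"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")
        if self.kind in ("pulse", "pulse_train") and self.duration <= 0:
            raise ValueError("pulse kinds require duration > 0")
        if self.kind == "pulse_train":
            if self.period <= self.duration:
                raise ValueError("pulse_train requires period > duration")
            if self.n_pulses < 0:
                raise ValueError("n_pulses must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(**d)


def current_at(protocol: StimulusProtocol, t):
    """Evaluate I_app at time(s) ``t`` (ms).  Right-continuous in t.

    Vectorized over ``t``; raises for negative query times.
    """
    tarr = np.asarray(t, dtype=float)
    if np.any(tarr < 0):
        raise ValueError("stimulus query time must be non-negative")
    p = protocol
    if p.kind == "constant":
        out = np.full_like(tarr, p.baseline)
        return float(out) if np.isscalar(t) else out

    if p.kind == "pulse":
        active = (tarr >= p.onset) & (tarr < p.onset + p.duration)
    else:  # pulse_train
        rel = tarr - p.onset
        k = np.floor_divide(rel, p.period).astype(np.int64)
        in_window = (rel >= 0) & (rel - k * p.period < p.duration)
        if p.n_pulses > 0:
            in_window &= k < p.n_pulses
        active = in_window
    out = np.where(active, p.baseline + p.amplitude, p.baseline)
    return float(out) if np.isscalar(t) else out


def standard_protocols() -> dict[str, StimulusProtocol]:
    """Named bundle of the stimuli used throughout the firing-regime study.

    * ``constant_40/50/60/80/100`` — 1000 ms steps of the named amplitude,
      probing sub- and supra-threshold constant drive for the two
      excitability classes.
    * ``long_pulse_100`` — 100 uA/cm^2 for 60 ms (many limit-cycle periods
      long: repetitive firing for class II, a single onset spike for
      class III).
    * ``brief_pulse_100`` — 100 uA/cm^2 for 1.5 ms (one spike for both
      classes; also the standard trigger for the autapse runs).
    * ``pulse_train_100`` — 1.5 ms pulses of 100 uA/cm^2 every 11.5 ms
      (entrains one spike per pulse in both classes).
    """
    protos: dict[str, StimulusProtocol] = {}
    for amp in (40, 50, 60, 80, 100):
        protos[f"constant_{amp}"] = StimulusProtocol(
            kind="pulse", amplitude=float(amp), onset=50.0, duration=1000.0
        )
    protos["long_pulse_100"] = StimulusProtocol(
        kind="pulse", amplitude=100.0, onset=50.0, duration=60.0
    )
    protos["brief_pulse_100"] = StimulusProtocol(
        kind="pulse", amplitude=100.0, onset=50.0, duration=1.5
    )
    protos["pulse_train_100"] = StimulusProtocol(
        kind="pulse_train", amplitude=100.0, onset=50.0, duration=1.5, period=11.5
    )
    return protos


def standard_trigger(onset: float = 50.0) -> StimulusProtocol:
    """The single 1.5 ms / 100 uA/cm^2 pulse that elicits the first spike
    in every autapse study."""
    return StimulusProtocol(kind="pulse", amplitude=100.0, onset=onset, duration=1.5)
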