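"""Plain-text serialisation: YAML run configs and delimited data exports."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .bifurcation import EquilibriumPoint
from .integrate import Trajectory
from .model import ModelParams, preset
from .scans import ScanResult
from .stimulus import StimulusProtocol
from .synapse import SynapseParams

__all__ = [
    "save_trajectory",
    "load_trajectory",
    "save_branch",
    "save_scan",
    "load_config",
    "resolve_config",
]

_TRAJ_HEADER = "t_ms\tV_mV\tw\ts\tI_syn_uA_cm2\tI_stim_uA_cm2"


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as tab-separated text with a unit-bearing header."""
    data = np.column_stack([traj.t, traj.V, traj.w, traj.s, traj.I_syn, traj.I_stim])
    np.savetxt(path, data, delimiter="\t", header=_TRAJ_HEADER, comments="")


def load_trajectory(path: str | Path, h: float | None = None) -> Trajectory:
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    t = data[:, 0]
    if h is None:
        h = float(t[1] - t[0])
    return Trajectory(t=t, V=data[:, 1], w=data[:, 2], s=data[:, 3],
                      I_syn=data[:, 4], I_stim=data[:, 5], h=h)


def save_branch(points: list[EquilibriumPoint], path: str | Path) -> None:
    """Equilibrium branch as delimited text (current, state, eigenvalues, stability)."""
    rows = [
        (p.I_app, p.V, p.w, p.eigenvalues[0].real, p.eigenvalues[1].real,
         abs(p.eigenvalues[0].imag), int(p.stable))
        for p in points
    ]
    header = "I_app_uA_cm2\tV_mV\tw\tre_lambda1\tre_lambda2\tabs_im_lambda\tstable"
    np.savetxt(path, np.asarray(rows), delimiter="\t", header=header, comments="")


def save_scan(result: ScanResult, path: str | Path) -> None:
    """Scan grid in long format (one line per cell) as tab-separated text."""
    result.to_frame().to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def resolve_config(cfg: dict) -> dict:
    """Build model/synapse/protocol/integration objects from a config mapping.

    Recognised sections::

        model:      {preset: typeII|typeIII} or explicit ModelParams fields
        synapse:    SynapseParams fields (omit or null -> no autapse)
        protocol:   StimulusProtocol fields
        integration: {T: ms, h: ms}
    """
    out: dict = {}
    model_cfg = dict(cfg.get("model", {"preset": "typeII"}))
    if "preset" in model_cfg:
        name = model_cfg.pop("preset")
        base = preset(name)
        out["params"] = ModelParams(**{**asdict(base), **model_cfg}) if model_cfg else base
    else:
        out["params"] = ModelParams(**model_cfg)

    syn_cfg = cfg.get("synapse")
    out["syn"] = SynapseParams(**syn_cfg) if syn_cfg else None

    proto_cfg = cfg.get("protocol", {"kind": "constant"})
    out["protocol"] = StimulusProtocol(**proto_cfg)

    integ = cfg.get("integration", {})
    out["T"] = float(integ.get("T", 1000.0))
    out["h"] = float(integ.get("h", 0.01))
    return out
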