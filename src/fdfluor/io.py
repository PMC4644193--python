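"""CSV and JSON interchange.

Waveforms travel as two-column CSV time series (``t_s,value``);
harmonic tables as ``k,freq_rad_s,phase_deg,phase_sd,mod,mod_sd``;
model/drive/acquisition specifications as JSON.  User-facing
frequencies are in Hz (``freq_hz``) and are converted to angular
frequency internally; stored curve frequencies are rad/s with explicit
column names.
"""

from __future__ import annotations

import json
import math
from typing import Any

import numpy as np
import pandas as pd

from .closed_form import DriveSpec
from .harmonics import HarmonicEstimate
from .models import LinearFilter, MultiExpModel, ThreeLevelModel
from .synth import AcquisitionSpec
from .waveforms import SampledSignal

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "write_harmonics_csv",
    "read_harmonics_csv",
    "model_from_dict",
    "drive_from_dict",
    "acquisition_from_dict",
    "load_json",
]


def write_signal_csv(sig: SampledSignal, path) -> None:
    pd.DataFrame({"t_s": sig.times(), "value": sig.values}).to_csv(path, index=False)


def read_signal_csv(path) -> SampledSignal:
    df = pd.read_csv(path)
    for col in ("t_s", "value"):
        if col not in df.columns:
            raise ValueError(f"signal CSV missing column {col!r}")
    t = df["t_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("signal CSV must contain at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
        raise ValueError("signal CSV is not uniformly sampled")
    return SampledSignal(float(t[0]), float(dt.mean()), df["value"].to_numpy(dtype=float))


def write_harmonics_csv(estimates: list[HarmonicEstimate], path) -> None:
    pd.DataFrame(
        {
            "k": [e.order for e in estimates],
            "freq_rad_s": [e.frequency for e in estimates],
            "phase_deg": [e.phase_deg for e in estimates],
            "phase_sd": [e.phase_sd for e in estimates],
            "mod": [e.mod for e in estimates],
            "mod_sd": [e.mod_sd for e in estimates],
        }
    ).to_csv(path, index=False)


def read_harmonics_csv(path, fundamental: float | None = None) -> list[HarmonicEstimate]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            HarmonicEstimate(
                order=int(row["k"]),
                frequency=float(row["freq_rad_s"]),
                phase_deg=float(row["phase_deg"]),
                phase_sd=float(row["phase_sd"]),
                mod=float(row["mod"]),
                mod_sd=float(row["mod_sd"]),
                n_blocks=int(row.get("n_blocks", 1)),
            )
        )
    return out


def model_from_dict(cfg: dict[str, Any]) -> MultiExpModel | ThreeLevelModel:
    """Build an emitter model from its JSON form.

    Multi-exponential: {"components": [{"fraction": f, "lifetime_s": tau}, ...]}
    Three-level:       {"three_level": {"g13": ., "g21": ., "g31": ., "g32": .}}
    """
    if "components" in cfg:
        return MultiExpModel(
            [(c["fraction"], c["lifetime_s"]) for c in cfg["components"]]
        )
    if "three_level" in cfg:
        tl = cfg["three_level"]
        return ThreeLevelModel(
            gamma_13=tl["g13"], gamma_21=tl["g21"], gamma_31=tl["g31"], gamma_32=tl["g32"]
        )
    raise ValueError("model config needs either 'components' or 'three_level'")


def drive_from_dict(cfg: dict[str, Any]) -> DriveSpec:
    """Build a DriveSpec from {"kind": ., "freq_hz": ., "amplitude": ., "bias": ., "duty": .}."""
    kind = cfg["kind"]
    omega = 2.0 * math.pi * float(cfg.get("freq_hz", 0.0))
    return DriveSpec(
        kind=kind,
        omega=omega,
        amplitude=float(cfg.get("amplitude", 1.0)),
        bias=float(cfg.get("bias", 0.0)),
        duty=cfg.get("duty"),
    )


def _detector_from_dict(cfg: dict[str, Any]) -> LinearFilter:
    """Single-pole detector from {"pole_hz": f} (unit DC gain), or explicit poles/zeros/gain."""
    if "pole_hz" in cfg:
        wc = 2.0 * math.pi * float(cfg["pole_hz"])
        return LinearFilter(gain=wc, poles=(-wc,))
    return LinearFilter(
        gain=float(cfg.get("gain", 1.0)),
        poles=[complex(p) for p in cfg.get("poles", [])],
        zeros=[complex(z) for z in cfg.get("zeros", [])],
    )


def acquisition_from_dict(cfg: dict[str, Any], seed: int | None = None) -> AcquisitionSpec:
    """Build an AcquisitionSpec from its JSON form.

    Keys: model (or null), drive, fs_hz, duration_s, and optionally
    detector, noise_sd, seed, flat_fraction.  A ``seed`` argument
    overrides the config value.
    """
    model = model_from_dict(cfg["model"]) if cfg.get("model") else None
    return AcquisitionSpec(
        model=model,
        drive=drive_from_dict(cfg["drive"]),
        fs=float(cfg["fs_hz"]),
        duration=float(cfg["duration_s"]),
        detector=_detector_from_dict(cfg["detector"]) if cfg.get("detector") else None,
        noise_sd=float(cfg.get("noise_sd", 0.0)),
        seed=int(seed if seed is not None else cfg.get("seed", 0)),
        flat_fraction=float(cfg.get("flat_fraction", 0.0)),
    )


def load_json(path_or_str: str) -> dict[str, Any]:
    """Parse JSON from a file path or an inline JSON string."""
    s = str(path_or_str)
    if s.lstrip().startswith("{"):
        return json.loads(s)
    with open(s) as fh:
        return json.load(fh)
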