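"""Sampled excitation waveforms and their exact harmonic content.

A square wave or a rectangular pulse train ("frequency comb") excites a
fluorophore at many frequencies simultaneously: the harmonic content of
the drive determines which orders carry power and with what phase.  For
a pulse train of duty cycle ``D`` the k-th harmonic has modulation

    Mod_k = D |sin(πkD) / (πkD)|

(zero whenever ``kD`` is an integer) and phase delay ``Φ_k = πkD``,
linear in the order.  A square wave is the ``D = 1/2`` special case:
odd orders only, amplitudes falling as ``1/k``, and a fundamental 4/π
(~27 %) more intense than a sine of the same swing.

Sampling a rectangle aligns pulse edges to sample boundaries, so FFT
cross-checks against these laws use the exact discrete-time spectrum
(provided here via ``n_samples``); the continuous sinc law is its limit,
offset by half a sample of phase.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .closed_form import DriveSpec

__all__ = [
    "SampledSignal",
    "generate",
    "pulse_train_harmonic_mod",
    "pulse_train_harmonic_phase",
    "square_fundamental_gain",
    "square_harmonic_amplitude",
]


@dataclass(frozen=True)
class SampledSignal:
    """Uniformly sampled real-valued time series."""

    t0: float
    dt: float
    values: np.ndarray

    def __init__(self, t0: float, dt: float, values):
        values = np.asarray(values, dtype=float)
        if not dt > 0:
            raise ValueError("dt must be positive")
        if values.ndim != 1 or len(values) < 2:
            raise ValueError("values must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "t0", float(t0))
        object.__setattr__(self, "dt", float(dt))
        object.__setattr__(self, "values", values)

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.values))

    def __len__(self) -> int:
        return len(self.values)


def generate(drive: DriveSpec, fs: float, duration: float) -> SampledSignal:
    """Sample a drive waveform at rate ``fs`` (Hz) for ``duration`` seconds.

    Periodic drives realized for FFT analysis should cover an integer
    number of fundamental periods; a warning is issued otherwise.
    Rectangular pulse edges are aligned to sample boundaries (the pulse
    width is rounded to the nearest whole sample).
    """
    if not fs > 0:
        raise ValueError("fs must be positive")
    n = int(round(fs * duration))
    if n < 2:
        raise ValueError("duration too short for the requested sampling rate")
    dt = 1.0 / fs
    t = dt * np.arange(n)

    if drive.kind == "delta":
        v = np.zeros(n)
        v[0] = drive.amplitude / dt  # unit-area impulse scaled by amplitude
        return SampledSignal(0.0, dt, v)

    cycles = duration * drive.omega / (2.0 * math.pi)
    if abs(cycles - round(cycles)) > 1e-9 * max(1.0, abs(cycles)):
        warnings.warn(
            f"duration covers {cycles:.6g} fundamental periods (non-integer); "
            "FFT analysis of this record will suffer spectral leakage",
            stacklevel=2,
        )

    if drive.kind == "sine":
        v = drive.bias + drive.amplitude * np.sin(drive.omega * t)
    elif drive.kind == "biased_cosine":
        v = drive.bias + drive.amplitude * (1.0 - np.cos(drive.omega * t)) / 2.0
    elif drive.kind in ("square_biased", "pulse_train"):
        duty = 0.5 if drive.kind == "square_biased" else float(drive.duty)
        spc = fs * 2.0 * math.pi / drive.omega  # samples per cycle
        width = int(round(duty * spc))
        # integer sample arithmetic whenever the cycle length is a whole
        # number of samples, so edges stay sample-aligned in every cycle
        if abs(spc - round(spc)) < 1e-6 * spc:
            phase_samples = np.arange(n) % int(round(spc))
        else:
            phase_samples = np.arange(n, dtype=float) % spc
        v = np.where(phase_samples < width - 0.5 + 1e-9, drive.amplitude, 0.0)
        v = v + drive.bias
    else:  # pragma: no cover - DriveSpec already validates kinds
        raise ValueError(f"unknown drive kind {drive.kind!r}")

    if np.any(v < -1e-12 * max(1.0, drive.amplitude)):
        raise ValueError("realized drive goes negative; populations cannot be driven negative")
    return SampledSignal(0.0, dt, np.maximum(v, 0.0))


def pulse_train_harmonic_mod(duty: float, k: int, n_samples: int | None = None) -> float:
    """Modulation of harmonic ``k`` of a rectangular pulse train.

    Continuous-time law: D |sin(πkD)/(πkD)|, exactly zero whenever kD is
    an integer.  With ``n_samples`` (samples per period, pulse width
    rounded to a whole sample) the exact discrete-time magnitude
    |sin(πkM/N) / (N sin(πk/N))| is returned instead, which is what the
    FFT of a synthesized train measures.
    """
    if not 0.0 < duty < 1.0:
        raise ValueError("duty must lie in (0, 1)")
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError("harmonic order k must be an integer >= 1")
    if n_samples is None:
        x = math.pi * k * duty
        # sin(x)/x with the exact zero at integer kD
        kd = k * duty
        if abs(kd - round(kd)) < 1e-12:
            return 0.0
        return duty * abs(math.sin(x) / x)
    width = int(round(duty * n_samples))
    if k % n_samples == 0:
        return float(width) / n_samples  # degenerate alias of DC
    num = math.sin(math.pi * k * width / n_samples)
    den = n_samples * math.sin(math.pi * k / n_samples)
    return abs(num / den)


def pulse_train_harmonic_phase(
    duty: float, k: int, wrapped: bool = False, n_samples: int | None = None
) -> float:
    """Phase delay (degrees) of harmonic ``k`` of a rectangular pulse train.

    Continuous law Φ_k = πkD, i.e. 180·k·D degrees: linear in the order
    with slope 180 D degrees per harmonic.  Undefined at nulled orders
    (kD integer).  ``wrapped=True`` maps into [-90, 90), producing the
    sawtooth of the arctangent convention.  With ``n_samples`` the exact
    discrete-time phase πk(M-1)/N is returned (the sampled pulse's
    centroid sits half a sample earlier than the continuous pulse's).
    """
    if not 0.0 < duty < 1.0:
        raise ValueError("duty must lie in (0, 1)")
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError("harmonic order k must be an integer >= 1")
    if n_samples is None:
        kd = k * duty
        if abs(kd - round(kd)) < 1e-12:
            raise ValueError(f"harmonic {k} is nulled at duty {duty}: phase undefined")
        phase = 180.0 * k * duty
    else:
        width = int(round(duty * n_samples))
        if (k * width) % n_samples == 0:
            raise ValueError(f"harmonic {k} is nulled for this sampled train: phase undefined")
        phase = 180.0 * k * (width - 1) / n_samples
    if wrapped:
        from .models import wrap_phase_deg

        return float(wrap_phase_deg(phase, "arctan"))
    return phase


class SquareFundamentalGain(NamedTuple):
    ratio: float
    excess_percent: float


def square_fundamental_gain() -> SquareFundamentalGain:
    """Fundamental Fourier amplitude of a unit square wave relative to a unit sine.

    The ±1 square wave's fundamental coefficient is 4/π ≈ 1.273: driving
    with a square wave from the same supply delivers ~27 % more power at
    the fundamental than a sine.
    """
    ratio = 4.0 / math.pi
    return SquareFundamentalGain(ratio=ratio, excess_percent=100.0 * (ratio - 1.0))


def square_harmonic_amplitude(k: int) -> float:
    """Relative drive-harmonic amplitude of a square wave: 1/k for odd k, 0 for even."""
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError("harmonic order k must be an integer >= 1")
    return 0.0 if k % 2 == 0 else 1.0 / k
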