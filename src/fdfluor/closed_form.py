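"""Analytic time-domain fluorescence responses for standard drives.

Each function is the inverse Laplace transform (Bromwich integral,
evaluated by residues) of the single-pole decay transfer function
``1/(s+Γ)`` multiplied by the transform of a particular drive: an
impulse, a sine, a positively biased cosine, or a biased square wave.
The expressions include the turn-on transients, so they are valid from
``t = 0`` and settle into the periodic steady state after a few decay
times.  An excited-state population cannot be negative, so all the
periodic drives here are biased to be nonnegative.

Every expression in this module is cross-validated against the
brute-force convolution in :mod:`fdfluor.oracle`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "DriveSpec",
    "delta_response",
    "sine_response",
    "biased_cosine_response",
    "square_response",
]

DRIVE_KINDS = ("delta", "sine", "biased_cosine", "square_biased", "pulse_train")


@dataclass(frozen=True)
class DriveSpec:
    """Parametric periodic excitation.

    kind:
        "delta"         unit-area impulse at t=0 (amplitude scales area)
        "sine"          bias + A sin(ωt)   (requires bias >= A >= 0)
        "biased_cosine" A (1 - cos ωt)/2   (swings 0 -> A)
        "square_biased" A for the first half of each period, else 0
        "pulse_train"   A for t mod T < D*T, else 0 (duty D in (0,1))

    omega is the angular fundamental in rad/s; the realized waveform
    must be nonnegative everywhere (excited-state populations cannot be
    driven negative).
    """

    kind: str
    omega: float = 0.0
    amplitude: float = 1.0
    bias: float = 0.0
    duty: float | None = None

    def __post_init__(self):
        if self.kind not in DRIVE_KINDS:
            raise ValueError(f"unknown drive kind {self.kind!r}; expected one of {DRIVE_KINDS}")
        if self.kind != "delta" and not self.omega > 0:
            raise ValueError("omega must be positive for periodic drives")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.bias < 0:
            raise ValueError("bias must be nonnegative (drive must stay nonnegative)")
        if self.kind == "pulse_train":
            if self.duty is None or not (0.0 < self.duty < 1.0):
                raise ValueError("pulse_train requires duty in (0, 1)")
        elif self.duty is not None:
            raise ValueError("duty is only meaningful for pulse_train drives")
        if self.kind == "sine" and self.bias < self.amplitude:
            raise ValueError(
                "sine drive would go negative: bias must be >= amplitude "
                "(populations cannot be driven negative)"
            )

    @property
    def period(self) -> float:
        if self.kind == "delta":
            raise ValueError("delta drive has no period")
        return 2.0 * math.pi / self.omega


def _check_t(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    return t


def delta_response(gamma: float, n0: float, t):
    """Free decay n(t) = n0 e^{-Γt} after impulsive excitation."""
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    t = _check_t(t)
    out = n0 * np.exp(-gamma * t)
    return float(out) if out.ndim == 0 else out


def sine_response(gamma: float, amplitude: float, omega: float, n0: float, t):
    """Response to g(t) = A sin(ωt), initial population n0.

    Real form of the residue inversion: a decaying transient plus the
    phase-shifted steady state

        n(t) = n0 e^{-Γt} + A [ω e^{-Γt} + Γ sin ωt - ω cos ωt] / (Γ²+ω²)

    so n(0) = n0 exactly.  For ω ≪ Γ this tends to (A/Γ) sin ωt and for
    ω ≫ Γ to -(A/ω) cos ωt: scanning the drive frequency accumulates a
    phase shift from zero up to π/2.
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    if not omega > 0:
        raise ValueError("omega must be positive")
    t = _check_t(t)
    denom = gamma * gamma + omega * omega
    out = n0 * np.exp(-gamma * t) + amplitude * (
        omega * np.exp(-gamma * t) + gamma * np.sin(omega * t) - omega * np.cos(omega * t)
    ) / denom
    return float(out) if out.ndim == 0 else out


def biased_cosine_response(
    gamma: float, amplitude: float, omega: float, t, literal_printed: bool = False
):
    """Response to the biased drive g(t) = A (1 - cos ωt)/2, n(0) = 0.

    Residue inversion with the cosine sign fixed so that the t = 0
    boundary condition holds:

        n(t) = (A/2Γ) [1 - ((ω/Γ)² e^{-Γt} + cos ωt + (ω/Γ) sin ωt)
                           / (1 + (ω/Γ)²)]

    The long-time mean is the DC gain times the drive mean, A/(2Γ).
    ``literal_printed=True`` evaluates instead a historical variant with
    the cosine sign flipped; it violates n(0)=0 and is retained only for
    comparison.
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    if not omega > 0:
        raise ValueError("omega must be positive")
    t = _check_t(t)
    r = omega / gamma
    cos_sign = -1.0 if literal_printed else 1.0
    out = (amplitude / (2.0 * gamma)) * (
        1.0
        - (r * r * np.exp(-gamma * t) + cos_sign * np.cos(omega * t) + r * np.sin(omega * t))
        / (1.0 + r * r)
    )
    return float(out) if out.ndim == 0 else out


def square_response(gamma: float, omega: float, t, n_terms: int = 200):
    """Response to a biased unit square drive (0 -> 2 swing), n(0) = 0.

    The drive is 1 + sq(t) where sq is the ±1 square wave of angular
    frequency ω.  Residue inversion of its transform against 1/(s+Γ)
    gives a DC term with a decaying turn-on transient plus a series over
    the odd drive harmonics:

        r(t) = (1/Γ) [1 - 2 e^{-Γt} / (1 + e^{πΓ/ω})]
             + (4/π) Σ_{k odd} [(Γ/k) sin kωt - ω cos kωt] / (k²ω² + Γ²)

    truncated at order 2*n_terms - 1.  The coefficients are fixed by the
    r(0) = 0 boundary condition (the transient factor and the pairing of
    ±k poles each contribute a factor of two relative to a one-sided odd
    sum with 2/π).  At ω ≪ Γ the steady state is a rounded square wave
    with plateau 2/Γ; near ω ≈ Γ it takes the "shark's fin" shape; at
    ω ≫ Γ it shrinks toward a triangle ripple about the DC offset 1/Γ.
    Truncation leaves a Gibbs wiggle near the drive edges.
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    if not omega > 0:
        raise ValueError("omega must be positive")
    if not n_terms >= 1:
        raise ValueError("n_terms must be >= 1")
    t = _check_t(t)
    # 2/(1+e^x) computed stably as 2*expit(-x) for large Γ/ω
    transient = 2.0 * expit(-math.pi * gamma / omega) * np.exp(-gamma * t)
    out = (1.0 - transient) / gamma
    k = np.arange(1, 2 * n_terms, 2, dtype=float)  # odd orders
    denom = k * k * omega * omega + gamma * gamma
    sin_c = (4.0 / math.pi) * (gamma / k) / denom
    cos_c = (4.0 / math.pi) * omega / denom

    def _series(tc: np.ndarray) -> np.ndarray:
        kwt = np.multiply.outer(tc, k) * omega
        return np.sin(kwt) @ sin_c - np.cos(kwt) @ cos_c

    if t.ndim == 0:
        return float(out + _series(t[None])[0])
    # chunk the (len(t) x n_terms) outer product to bound memory
    chunk = max(1, int(2e7) // max(n_terms, 1))
    parts = [_series(t[i : i + chunk]) for i in range(0, len(t), chunk)]
    return out + np.concatenate(parts)
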