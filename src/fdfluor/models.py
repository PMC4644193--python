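"""Transfer-function models of fluorescence decay.

A fluorophore driven by a modulated excitation behaves as an analog
low-pass filter: each decay pathway with rate ``Γ = 1/τ`` contributes a
simple pole at ``s = -Γ`` in the Laplace domain, and multi-exponential
emission is a weighted parallel sum of such poles.  Restricting ``s`` to
the imaginary axis yields the frequency response, from which the two
quantities measured in frequency-domain fluorometry follow directly:

* the **phase shift** ``Φ`` of the emission behind the drive, with
  ``tan Φ = ωτ`` for a single lifetime, and
* the **modulation index** ``Mod``, the AC amplitude of the emission
  relative to the drive, normalized here so that ``Mod -> 1`` as
  ``ω -> 0``.

Phases are lags.  Internally a lag is a negative complex argument; all
reported values follow the fluorometry plotting convention of a positive
phase shift.

The same algebra describes the drive electronics and the detector, so an
entire instrument chain is the cascade (product) of its members'
transfer functions: phases add, modulation indices multiply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MultiExpModel",
    "ThreeLevelModel",
    "LinearFilter",
    "FrequencyResponse",
    "eval_multiexp",
    "phase_mod",
    "three_level_transfer",
    "cascade",
    "lifetime_from_rc",
    "wrap_phase_deg",
    "CIRCUIT_STAGE2_PARAMS",
]


def wrap_phase_deg(phase: np.ndarray | float, mode: str = "principal"):
    """Map phase angles (degrees) into a reporting interval.

    mode="principal" maps into (-180, 180]; mode="arctan" maps into
    [-90, 90), the convention used when phases of periodic signals are
    obtained from an arc tangent; mode="none" returns the input.
    """
    phase = np.asarray(phase, dtype=float)
    if mode == "none":
        out = phase
    elif mode == "principal":
        out = -(np.mod(-phase + 180.0, 360.0) - 180.0)
    elif mode == "arctan":
        out = np.mod(phase + 90.0, 180.0) - 90.0
    else:
        raise ValueError(f"unknown phase wrap mode: {mode!r}")
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MultiExpModel:
    """Parallel sum of weighted single-pole decays.

    ``components`` is a sequence of ``(fraction, lifetime_s)`` pairs.
    Fractions are nonnegative weights (not forced to sum to one);
    lifetimes are in seconds, strictly positive, and pairwise distinct
    within ``distinct_rtol`` so that a fit against the model is
    identifiable.
    """

    components: tuple[tuple[float, float], ...]
    distinct_rtol: float = 1e-9

    def __init__(self, components: Iterable[Sequence[float]], distinct_rtol: float = 1e-9):
        comps = tuple((float(f), float(tau)) for f, tau in components)
        if not comps:
            raise ValueError("MultiExpModel needs at least one component")
        for f, tau in comps:
            if not (tau > 0.0 and math.isfinite(tau)):
                raise ValueError(f"lifetime must be positive and finite, got {tau}")
            if not (f >= 0.0 and math.isfinite(f)):
                raise ValueError(f"fraction must be nonnegative and finite, got {f}")
        if not any(f > 0.0 for f, _ in comps):
            raise ValueError("at least one fraction must be positive")
        taus = sorted(tau for _, tau in comps)
        for a, b in zip(taus, taus[1:]):
            if abs(b - a) <= distinct_rtol * max(a, b):
                raise ValueError(
                    f"lifetimes {a} and {b} coincide within rtol={distinct_rtol}; "
                    "degenerate components are not identifiable"
                )
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "distinct_rtol", float(distinct_rtol))

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for f, _ in self.components])

    @property
    def lifetimes(self) -> np.ndarray:
        return np.array([tau for _, tau in self.components])

    @property
    def rates(self) -> np.ndarray:
        """Decay rates Γ_k = 1/τ_k in 1/s."""
        return 1.0 / self.lifetimes

    def transfer(self, omega):
        """F(iω) = Σ f_k / (1 + iωτ_k); see :func:`eval_multiexp`."""
        return eval_multiexp(self, omega)

    def impulse_response(self, t):
        """Σ f_k e^{-t/τ_k}: weights act directly on each decaying pole."""
        t = np.asarray(t, dtype=float)
        f = self.fractions
        g = self.rates
        return np.einsum("k,k...->...", f, np.exp(-np.multiply.outer(g, t)))


@dataclass(frozen=True)
class ThreeLevelModel:
    """Rates of a pump/relax/emit three-level scheme.

    ``gamma_13`` couples the drive into the pump transition (ground ->
    pumped level), ``gamma_32`` is the fast relaxation into the emitting
    level, ``gamma_21`` the radiative return to ground, and ``gamma_31``
    a weak direct leak back to ground.  The fluorescence signal is
    proportional to the emitting-level population n2.
    """

    gamma_13: float
    gamma_21: float
    gamma_31: float
    gamma_32: float
    n1_0: float = 1.0
    n2_0: float = 0.0
    n3_0: float = 0.0

    def __post_init__(self):
        for name in ("gamma_13", "gamma_21", "gamma_31", "gamma_32"):
            v = getattr(self, name)
            if not (v >= 0.0 and math.isfinite(v)):
                raise ValueError(f"{name} must be nonnegative and finite, got {v}")
        if not self.gamma_21 > 0.0:
            raise ValueError("gamma_21 must be positive (emission path must exist)")
        if not self.gamma_32 > 0.0:
            raise ValueError("gamma_32 must be positive (feeding path must exist)")
        for name in ("n1_0", "n2_0", "n3_0"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class LinearFilter:
    """Rational transfer function gain * Π(s - z) / Π(s - p).

    Poles must have nonpositive real part (stability).  Real-rate
    fluorescence and RC stages contribute real poles; the class accepts
    complex ones for generality.
    """

    gain: float
    poles: tuple[complex, ...] = ()
    zeros: tuple[complex, ...] = ()

    def __init__(self, gain: float, poles: Iterable[complex] = (), zeros: Iterable[complex] = ()):
        poles = tuple(complex(p) for p in poles)
        zeros = tuple(complex(z) for z in zeros)
        for p in poles:
            if p.real > 0.0:
                raise ValueError(f"unstable pole {p}: positive real part")
        object.__setattr__(self, "gain", float(gain))
        object.__setattr__(self, "poles", poles)
        object.__setattr__(self, "zeros", zeros)

    def eval(self, s):
        """Evaluate H(s) at complex s (scalar or array)."""
        s = np.asarray(s, dtype=complex)
        num = np.ones_like(s) * self.gain
        for z in self.zeros:
            num = num * (s - z)
        den = np.ones_like(s)
        for p in self.poles:
            den = den * (s - p)
        return num / den

    def freq_response(self, omega):
        """H(iω) for real angular frequency ω (rad/s)."""
        omega = np.asarray(omega, dtype=float)
        return self.eval(1j * omega)

    def dc_gain(self) -> complex:
        if any(p == 0 for p in self.poles):
            raise ValueError("filter has a pole at the origin: DC gain undefined")
        return complex(self.eval(0j))


@dataclass
class FrequencyResponse:
    """Phase/modulation curve sampled on a strictly increasing ω grid.

    Frequencies are angular (rad/s); phase is the lag in degrees,
    reported positive; mod is the DC-normalized modulation index in
    [0, 1] (a small tolerance absorbs estimation noise).  Optional
    per-point standard deviations accompany measured curves.
    """

    frequencies: np.ndarray
    phase_deg: np.ndarray
    mod: np.ndarray
    phase_sd: np.ndarray | None = None
    mod_sd: np.ndarray | None = None
    mod_tol: float = 0.05

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.phase_deg = np.asarray(self.phase_deg, dtype=float)
        self.mod = np.asarray(self.mod, dtype=float)
        n = len(self.frequencies)
        if self.phase_deg.shape != (n,) or self.mod.shape != (n,):
            raise ValueError("frequencies, phase_deg and mod must have equal length")
        if n and not np.all(np.diff(self.frequencies) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(self.phase_deg)):
            raise ValueError("phase must be finite")
        if np.any(self.mod < 0) or np.any(self.mod > 1.0 + self.mod_tol):
            raise ValueError(f"mod must lie in [0, 1+{self.mod_tol}]")
        for name in ("phase_sd", "mod_sd"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (n,):
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)

    def __len__(self) -> int:
        return len(self.frequencies)

    def to_csv(self, path) -> None:
        import pandas as pd

        nan = np.full(len(self), np.nan)
        pd.DataFrame(
            {
                "freq_rad_s": self.frequencies,
                "phase_deg": self.phase_deg,
                "mod": self.mod,
                "phase_sd": self.phase_sd if self.phase_sd is not None else nan,
                "mod_sd": self.mod_sd if self.mod_sd is not None else nan,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FrequencyResponse":
        import pandas as pd

        df = pd.read_csv(path)
        for col in ("freq_rad_s", "phase_deg", "mod"):
            if col not in df.columns:
                raise ValueError(f"frequency-response CSV missing column {col!r}")
        phase_sd = df["phase_sd"].to_numpy() if "phase_sd" in df else None
        mod_sd = df["mod_sd"].to_numpy() if "mod_sd" in df else None
        if phase_sd is not None and np.all(np.isnan(phase_sd)):
            phase_sd = None
        if mod_sd is not None and np.all(np.isnan(mod_sd)):
            mod_sd = None
        return cls(
            frequencies=df["freq_rad_s"].to_numpy(),
            phase_deg=df["phase_deg"].to_numpy(),
            mod=df["mod"].to_numpy(),
            phase_sd=phase_sd,
            mod_sd=mod_sd,
        )


def eval_multiexp(model: MultiExpModel, omega):
    """Evaluate the multi-exponential transfer function F(iω).

    F(iω) = Σ_k f_k / (1 + iωτ_k), the parallel weighted sum of
    single-pole low-pass responses; at ω = 0 this is exactly Σ f_k.
    """
    omega = np.asarray(omega, dtype=float)
    if not np.all(np.isfinite(omega)):
        raise ValueError("omega must be finite")
    f = model.fractions
    tau = model.lifetimes
    denom = 1.0 + 1j * np.multiply.outer(omega, tau)
    out = (f / denom).sum(axis=-1)
    return complex(out) if out.ndim == 0 else out


def phase_mod(model: MultiExpModel | LinearFilter, omega):
    """Phase shift (degrees, positive lag) and DC-normalized modulation.

    phase = -arg F(iω); mod = |F(iω)| / |F(0)|, so mod(0) = 1.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be nonnegative")
    if isinstance(model, LinearFilter):
        h = model.freq_response(omega)
        h0 = model.dc_gain()
    else:
        h = eval_multiexp(model, omega)
        h0 = eval_multiexp(model, 0.0)
    if abs(h0) == 0.0:
        raise ValueError("model has zero DC response; phase/mod undefined")
    phase = -np.degrees(np.angle(np.asarray(h, dtype=complex)))
    mod = np.abs(h) / abs(h0)
    if phase.ndim == 0:
        return float(phase), float(mod)
    return phase, mod


def three_level_transfer(m: ThreeLevelModel) -> LinearFilter:
    """Transfer function n2/drive of the three-level scheme, weak pumping.

    Assuming the ground level is not depleted, the emitting-level
    response to the pump drive is second order: gain Γ32 with poles at
    -Γ21 and -(Γ31+Γ32).  Transient (initial-population) terms are not
    part of the transfer function.  When Γ32 ≫ Γ21 the second pole lies
    far above the probed band and the wing of that pole cancels the Γ32
    in the numerator, collapsing onto a single low-pass.
    """
    if m.gamma_21 <= 0 or m.gamma_32 <= 0:
        raise ValueError("three-level transfer requires gamma_21 > 0 and gamma_32 > 0")
    return LinearFilter(
        gain=m.gamma_32,
        poles=(-m.gamma_21, -(m.gamma_31 + m.gamma_32)),
    )


def cascade(filters: Sequence[LinearFilter]) -> LinearFilter:
    """Product of transfer functions: gains multiply, poles/zeros concatenate.

    The phase of the cascade is the sum of the member phases (mod 360°),
    which is how drive electronics, fluorophore, and detector combine
    into one instrument response.
    """
    filters = list(filters)
    if not filters:
        raise ValueError("cascade of an empty filter list")
    gain = 1.0
    poles: list[complex] = []
    zeros: list[complex] = []
    for f in filters:
        gain *= f.gain
        poles.extend(f.poles)
        zeros.extend(f.zeros)
    return LinearFilter(gain=gain, poles=poles, zeros=zeros)


def lifetime_from_rc(resistance: float, capacitance: float) -> float:
    """Circuit-equivalent lifetime 2πRC of a single RC low-pass stage.

    Maps a resistor-capacitor product (ohm, farad) onto the fluorescence
    lifetime whose pole produces the same phase/modulation curve when
    frequency is read in Hz.
    """
    if not resistance > 0:
        raise ValueError("resistance must be positive")
    if not capacitance > 0:
        raise ValueError("capacitance must be positive")
    return 2.0 * math.pi * resistance * capacitance


# Second-stage RC values quoted for the two curves of the cascaded-low-pass
# demonstration.  The source text and its figure caption disagree about which
# parameter set belongs to which curve label, so both sets are exposed without
# asserting a label.
CIRCUIT_STAGE2_PARAMS = {
    "fast_stage2": {"R_ohm": 1.6e3, "C_farad": 100e-9},
    "very_fast_stage2": {"R_ohm": 0.159, "C_farad": 10e-12},
}
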