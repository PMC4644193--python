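"""Brute-force forward simulators used to verify every closed form.

Two independent numerical routes to the fluorescence response:

* :func:`convolve_response` — the superposition integral
  ``n(t) = Σ_k f_k ∫ e^{-t'/τ_k} g(t-t') dt'`` for a multi-exponential
  emitter under weak pumping, evaluated by an exponential-integrator
  recursion that is *exact* when the drive is piecewise linear between
  samples.  There is no stability constraint, so decay rates separated
  by many decades pose no stiffness problem.

* :func:`three_level_integrate` — the full linear rate equations of the
  pump/relax/emit three-level scheme, including ground-state depletion,
  advanced by matrix-exponential steps with the drive held constant
  within each sample.  Total population is conserved to machine
  precision by construction.

Transients are never discarded here; callers comparing steady states
should skip an initial settle window of order ``10·max(τ)``.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.linalg import expm
from scipy.signal import lfilter

from .models import MultiExpModel, ThreeLevelModel
from .waveforms import SampledSignal

__all__ = ["convolve_response", "single_pole_response", "three_level_integrate"]


def _phi_coeffs(x: float) -> tuple[float, float]:
    """e1 = (1-e^{-x})/x and e2 = (x-1+e^{-x})/x², series-protected for small x."""
    if x < 1e-4:
        e1 = 1.0 - x / 2.0 + x * x / 6.0 - x ** 3 / 24.0
        e2 = 0.5 - x / 6.0 + x * x / 24.0 - x ** 3 / 120.0
    else:
        e1 = -math.expm1(-x) / x
        e2 = (1.0 - e1) / x
    return e1, e2


def single_pole_response(gamma: float, drive: SampledSignal) -> np.ndarray:
    """Exact response y' = -Γy + g(t), y(0)=0, for piecewise-linear g.

    One step of the exponential integrator:
        y[n] = e^{-Γdt} y[n-1] + dt [(e1-e2) g[n-1] + e2 g[n]]
    which is the exact convolution of e^{-Γt} with the linear
    interpolant of the samples.
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    dt = drive.dt
    x = gamma * dt
    a = math.exp(-x)
    e1, e2 = _phi_coeffs(x)
    b = np.array([dt * e2, dt * (e1 - e2)])
    a_coef = np.array([1.0, -a])
    u = drive.values
    # initial filter state chosen so y[0] = 0
    zi = np.array([-b[0] * u[0]])
    y, _ = lfilter(b, a_coef, u, zi=zi)
    return y


def convolve_response(model: MultiExpModel, drive: SampledSignal) -> SampledSignal:
    """Superposition response of a multi-exponential emitter to a sampled drive.

    The weights act directly on each decaying pole (impulse response
    ``Σ f_k e^{-Γ_k t}``): a discrete impulse of area ``a`` yields
    ``a Σ f_k e^{-Γ_k t}`` and a constant drive ``c`` settles to
    ``c Σ f_k/Γ_k``.  (The DC *amplitude fraction* of component k is
    therefore f_k τ_k, not f_k; scale weights by 1/τ_k to prescribe DC
    fractions.)  Initial populations are zero.
    """
    if len(drive) == 0:
        raise ValueError("empty drive")
    tau_min = float(model.lifetimes.min())
    if drive.dt > tau_min / 20.0:
        warnings.warn(
            f"drive.dt={drive.dt:.3g} s under-resolves the fastest lifetime "
            f"{tau_min:.3g} s (want dt <= tau/20); result may be inaccurate",
            stacklevel=2,
        )
    out = np.zeros(len(drive))
    for f, tau in model.components:
        if f == 0.0:
            continue
        out += f * single_pole_response(1.0 / tau, drive)
    return SampledSignal(drive.t0, drive.dt, out)


def three_level_integrate(
    m: ThreeLevelModel, drive_gamma13: SampledSignal
) -> tuple[SampledSignal, SampledSignal, SampledSignal]:
    """Integrate the full three-level rate equations under a sampled drive.

    The drive waveform multiplies the pump coupling ``gamma_13`` to give
    the instantaneous pump rate.  No weak-pumping assumption is made:
    ground-state depletion is included, and n1+n2+n3 is conserved.  The
    drive is held constant within each sampling interval, so each step
    is a 3x3 matrix exponential (cached per distinct drive level, which
    makes square and pulse drives cheap).

    Returns the three population time series (n1, n2, n3); the
    fluorescence signal is proportional to n2.
    """
    u = drive_gamma13.values
    if np.any(u < 0):
        raise ValueError("drive must be nonnegative")
    dt = drive_gamma13.dt
    g21, g31, g32 = m.gamma_21, m.gamma_31, m.gamma_32
    rates = np.array([g21, g31, g32, m.gamma_13 * float(u.max())])
    stiffest = float(rates.max())
    if stiffest * dt > 50.0:
        name = ["gamma_21", "gamma_31", "gamma_32", "pump rate"][int(rates.argmax())]
        raise ValueError(
            f"step size dt={dt:.3g} s is too coarse for the stiff rate {name}="
            f"{stiffest:.3g} 1/s (rate*dt={stiffest * dt:.3g} > 50); reduce dt"
        )

    base = np.array(
        [
            [0.0, g21, g31],
            [0.0, -g21, g32],
            [0.0, 0.0, -(g31 + g32)],
        ]
    )
    pump = np.array(
        [
            [-1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
        ]
    )

    cache: dict[float, np.ndarray] = {}

    def step_matrix(level: float) -> np.ndarray:
        mat = cache.get(level)
        if mat is None:
            mat = expm((base + m.gamma_13 * level * pump) * dt)
            cache[level] = mat
        return mat

    n = len(u)
    out = np.empty((n, 3))
    x = np.array([m.n1_0, m.n2_0, m.n3_0], dtype=float)
    out[0] = x
    for j in range(n - 1):
        x = step_matrix(float(u[j])) @ x
        out[j + 1] = x
    t0, dtv = drive_gamma13.t0, drive_gamma13.dt
    return (
        SampledSignal(t0, dtv, out[:, 0]),
        SampledSignal(t0, dtv, out[:, 1]),
        SampledSignal(t0, dtv, out[:, 2]),
    )
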