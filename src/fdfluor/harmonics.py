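"""FFT harmonic demodulation of driver/response waveform pairs.

This is a digital lock-in: digitized driver and response records are
cut into blocks, each block is averaged over a fixed number of
fundamental cycles (typically 100), the averaged cycles are Fourier
transformed, and for every harmonic order carried by the driver the
phase delay and modulation ratio of the response are computed.  Means
and uncertainties come from the scatter across blocks.  Because a
square-wave or pulse-train driver carries many harmonics at once, a
handful of fundamentals (e.g. 10 Hz, 250 Hz, 2.5 kHz with 50 orders
each) samples the phase/modulation curve across four decades in one
short acquisition; :func:`build_frequency_response` merges such sweeps
into a single curve.

Rectangular windows on exact integer cycles only — records that do not
contain a whole number of cycles are linearly resampled onto the
nearest integer-cycle grid rather than windowed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .models import FrequencyResponse, wrap_phase_deg
from .waveforms import SampledSignal

__all__ = [
    "HarmonicEstimate",
    "cycle_average",
    "harmonic_phases",
    "build_frequency_response",
]

logger = logging.getLogger(__name__)

#: an order is reported only if the driver bin power exceeds this
#: fraction of the driver fundamental bin power (phase is undefined at
#: nulled orders)
DRIVER_POWER_FLOOR = 1e-6


@dataclass(frozen=True)
class HarmonicEstimate:
    """Per-harmonic phase delay and modulation ratio with uncertainties.

    ``phase_sd``/``mod_sd`` are standard errors of the across-block mean
    (block scatter / sqrt(n_blocks)); they are the inverse-variance
    weights used when sweeps are merged.
    """

    order: int
    frequency: float  # rad/s, = order * fundamental
    phase_deg: float
    phase_sd: float
    mod: float
    mod_sd: float
    n_blocks: int

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.mod < 0:
            raise ValueError("mod ratio must be nonnegative")
        for name in ("phase_sd", "mod_sd"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be nonnegative")


def _integer_cycle_blocks(
    sig: SampledSignal, fundamental: float, cycles_per_block: int, n_blocks: int
) -> np.ndarray:
    """Trailing samples of ``sig`` reshaped to (n_blocks, cycles, spc).

    Uses the *last* ``n_blocks*cycles_per_block`` cycles of the record so
    that any turn-on transient at the head is excluded.  If the sampling
    rate does not give an integer number of samples per cycle, the
    record is linearly resampled onto the nearest integer-cycle grid.
    """
    if not fundamental > 0:
        raise ValueError("fundamental must be positive (rad/s)")
    if cycles_per_block < 1 or n_blocks < 1:
        raise ValueError("cycles_per_block and n_blocks must be >= 1")
    period = 2.0 * math.pi / fundamental
    spc_exact = period / sig.dt
    spc = int(round(spc_exact))
    if spc < 4:
        raise ValueError("fewer than 4 samples per fundamental cycle")
    values = sig.values
    if abs(spc_exact - spc) > 1e-9 * spc_exact:
        # resample onto an integer-cycle grid with the same span
        n_cycles_avail = int(len(values) * sig.dt / period)
        if n_cycles_avail < 1:
            raise ValueError("record shorter than one fundamental period")
        t_old = sig.dt * np.arange(len(values))
        t_new = (period / spc) * np.arange(n_cycles_avail * spc)
        values = np.interp(t_new, t_old, values)
    needed = n_blocks * cycles_per_block * spc
    if len(values) < needed:
        raise ValueError(
            f"record too short: need {needed} samples "
            f"({n_blocks} blocks x {cycles_per_block} cycles x {spc} samples/cycle), "
            f"have {len(values)}"
        )
    tail = values[len(values) - needed :]
    return tail.reshape(n_blocks, cycles_per_block, spc)


def cycle_average(
    sig: SampledSignal, fundamental: float, cycles_per_block: int, n_blocks: int
) -> list[np.ndarray]:
    """Average consecutive fundamental cycles within blocks.

    Returns ``n_blocks`` single-cycle waveforms, each the pointwise mean
    of ``cycles_per_block`` cycles.  Averaging N cycles suppresses white
    noise by 1/sqrt(N) while leaving every harmonic of the fundamental
    untouched.
    """
    blocks = _integer_cycle_blocks(sig, fundamental, cycles_per_block, n_blocks)
    return [blocks[b].mean(axis=0) for b in range(blocks.shape[0])]


def _circular_stats(phases_deg: np.ndarray) -> tuple[float, float]:
    """Circular mean and standard error (degrees) of block phases."""
    ang = np.radians(phases_deg)
    mean = math.degrees(math.atan2(np.sin(ang).mean(), np.cos(ang).mean()))
    # deviations unwrapped around the circular mean
    dev = (phases_deg - mean + 180.0) % 360.0 - 180.0
    mean = mean + dev.mean()
    n = len(phases_deg)
    if n > 1:
        sd = float(np.std(dev, ddof=1)) / math.sqrt(n)
    else:
        sd = float("nan")
    return mean, sd


def harmonic_phases(
    driver: SampledSignal,
    response: SampledSignal,
    fundamental: float,
    max_order: int,
    cycles_per_block: int = 100,
    n_blocks: int = 4,
    wrap: str = "principal",
    power_floor: float = DRIVER_POWER_FLOOR,
) -> list[HarmonicEstimate]:
    """Per-harmonic phase delays and modulation ratios, response vs driver.

    Both records are cycle-averaged per block and FFT'd; for each order
    ``k`` whose driver bin power clears ``power_floor`` (relative to the
    fundamental bin) the phase delay ``arg(D_k) - arg(R_k)`` and the
    DC-normalized modulation ratio ``(|R_k|/|D_k|) / (R_0/D_0)`` are
    estimated per block, then aggregated across blocks (circular mean
    for phase; uncertainties are standard errors of the mean).  The sign
    convention makes a causal low-pass yield a positive reported lag.

    ``wrap`` selects the reporting convention: "principal" ((-180, 180]),
    "arctan" ([-90, 90), the sawtooth convention), or "unwrapped"
    (continuous in k, unwrapped from the principal values).
    """
    if driver.dt != response.dt or len(driver) != len(response):
        raise ValueError("driver and response must share the same sampling grid")
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    nyquist_order = math.pi / (fundamental * driver.dt)
    if max_order >= nyquist_order:
        raise ValueError(
            f"max_order {max_order} is at or above the Nyquist order {nyquist_order:.1f} "
            "for this sampling rate"
        )
    if wrap not in ("principal", "arctan", "unwrapped"):
        raise ValueError(f"unknown wrap mode {wrap!r}")

    d_blocks = _integer_cycle_blocks(driver, fundamental, cycles_per_block, n_blocks)
    r_blocks = _integer_cycle_blocks(response, fundamental, cycles_per_block, n_blocks)
    d_fft = np.fft.rfft(d_blocks.mean(axis=1), axis=-1)
    r_fft = np.fft.rfft(r_blocks.mean(axis=1), axis=-1)

    dc_ratio = np.abs(r_fft[:, 0]) / np.abs(d_fft[:, 0])
    fund_power = np.abs(d_fft[:, 1]) ** 2
    if np.any(fund_power == 0):
        raise ValueError("driver has no power at the fundamental")

    estimates: list[HarmonicEstimate] = []
    phases_by_order: list[tuple[int, float, float, float, float]] = []
    for k in range(1, max_order + 1):
        dk = d_fft[:, k]
        rk = r_fft[:, k]
        power = np.abs(dk) ** 2
        if np.any(power < power_floor * fund_power):
            logger.info(
                "order %d omitted: driver bin power below floor (%.1e of fundamental)",
                k,
                float((power / fund_power).min()),
            )
            continue
        block_phase = np.degrees(np.angle(dk * np.conj(rk)))
        block_mod = (np.abs(rk) / np.abs(dk)) / dc_ratio
        ph, ph_sd = _circular_stats(block_phase)
        mod = float(block_mod.mean())
        mod_sd = float(np.std(block_mod, ddof=1) / math.sqrt(n_blocks)) if n_blocks > 1 else float("nan")
        phases_by_order.append((k, ph, ph_sd, mod, mod_sd))

    if wrap == "unwrapped" and phases_by_order:
        raw = np.array([wrap_phase_deg(p[1], "principal") for p in phases_by_order])
        unwrapped = np.degrees(np.unwrap(np.radians(raw)))
        phases_by_order = [
            (k, float(u), sd, mod, mod_sd)
            for (k, _, sd, mod, mod_sd), u in zip(phases_by_order, unwrapped)
        ]

    for k, ph, ph_sd, mod, mod_sd in phases_by_order:
        if wrap in ("principal", "arctan"):
            ph = float(wrap_phase_deg(ph, wrap))
        estimates.append(
            HarmonicEstimate(
                order=k,
                frequency=k * fundamental,
                phase_deg=ph,
                phase_sd=ph_sd,
                mod=mod,
                mod_sd=mod_sd,
                n_blocks=n_blocks,
            )
        )
    return estimates


def build_frequency_response(
    estimates: Iterable[HarmonicEstimate] | Sequence[Iterable[HarmonicEstimate]],
    freq_rtol: float = 1e-9,
    mod_tol: float = 0.05,
) -> FrequencyResponse:
    """Merge harmonic estimates (possibly from several fundamentals) into one curve.

    Accepts a flat iterable of estimates or an iterable of sweeps.
    Estimates at coinciding absolute frequencies (within ``freq_rtol``)
    are inverse-variance averaged using their standard errors; the
    merged uncertainty is then at most the smallest individual one.
    """
    flat: list[HarmonicEstimate] = []
    for item in estimates:
        if isinstance(item, HarmonicEstimate):
            flat.append(item)
        else:
            flat.extend(item)
    if not flat:
        raise ValueError("no harmonic estimates to merge")
    flat.sort(key=lambda e: e.frequency)

    groups: list[list[HarmonicEstimate]] = [[flat[0]]]
    for est in flat[1:]:
        if abs(est.frequency - groups[-1][0].frequency) <= freq_rtol * est.frequency:
            groups[-1].append(est)
        else:
            groups.append([est])

    freqs, phases, mods, phase_sds, mod_sds = [], [], [], [], []
    for grp in groups:
        freqs.append(float(np.mean([e.frequency for e in grp])))

        def _merge(values, sds):
            values = np.asarray(values, dtype=float)
            sds = np.asarray(sds, dtype=float)
            if len(grp) == 1:
                return float(values[0]), float(sds[0])
            if np.all(np.isfinite(sds)) and np.all(sds > 0):
                w = 1.0 / sds**2
                return float((w * values).sum() / w.sum()), float(math.sqrt(1.0 / w.sum()))
            return float(values.mean()), float(np.nanmean(sds))

        ph, ph_sd = _merge([e.phase_deg for e in grp], [e.phase_sd for e in grp])
        mod, mod_sd = _merge([e.mod for e in grp], [e.mod_sd for e in grp])
        phases.append(ph)
        mods.append(mod)
        phase_sds.append(ph_sd)
        mod_sds.append(mod_sd)

    return FrequencyResponse(
        frequencies=np.array(freqs),
        phase_deg=np.array(phases),
        mod=np.array(mods),
        phase_sd=np.array(phase_sds),
        mod_sd=np.array(mod_sds),
        mod_tol=mod_tol,
    )
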