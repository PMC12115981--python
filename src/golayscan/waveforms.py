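"""Sampled excitation waveforms built from ±1 codes.

Two modulation schemes are provided.  The *wide-pulse* scheme holds each
chip at a constant level (±amplitude) for one chip period T — binary
phase keying of a rectangular pulse, where "+1" means 0° and "−1" means
180°.  The *square-carrier* scheme multiplies that chip signal with a
50%-duty unit square wave so the transducer is driven at its resonant
frequency; chip boundaries are aligned to carrier zero crossings and
each chip carries an integer number of carrier cycles.

The printed piecewise time-domain formulas for the two coded wide pulses
are not self-consistent, so waveforms are always constructed directly
from the code sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .codes import _as_pm1

__all__ = [
    "Waveform",
    "ModulationSpec",
    "modulate_wide_pulse",
    "modulate_square_carrier",
    "pulse_cancelation_excitation",
    "matched_filter_reference",
]


@dataclass(frozen=True)
class Waveform:
    """A uniformly sampled real signal.

    Parameters
    ----------
    samples : ndarray
        Signal values in volts (arbitrary scale).
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError("fs must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs

    def delayed(self, delay_s: float) -> "Waveform":
        return replace(self, t0=self.t0 + delay_s)


@dataclass(frozen=True)
class ModulationSpec:
    """How a ±1 code maps onto a sampled drive waveform.

    ``chip_period`` is the per-chip duration T.  With a carrier,
    ``chip_period * carrier_freq`` must equal ``cycles_per_chip`` so
    every chip holds a whole number of carrier cycles.  The defaults
    match a 75 kHz air-coupled transducer driven one carrier cycle per
    chip, sampled at 64 samples per cycle.
    """

    carrier_freq: float = 75e3
    cycles_per_chip: int = 1
    fs: float = 4.8e6
    amplitude: float = 1.0
    chip_period: float | None = None

    def __post_init__(self):
        if self.chip_period is None:
            if self.carrier_freq <= 0:
                raise ValueError(
                    "chip_period is required when carrier_freq is 0"
                )
            object.__setattr__(
                self, "chip_period", self.cycles_per_chip / self.carrier_freq
            )
        if self.fs <= 0 or self.chip_period <= 0:
            raise ValueError("fs and chip_period must be positive")
        if self.carrier_freq < 0:
            raise ValueError("carrier_freq must be >= 0")
        if self.carrier_freq > 0:
            if self.fs < 20 * self.carrier_freq:
                raise ValueError(
                    "fs must be at least 20x the carrier frequency"
                )
            if self.cycles_per_chip < 1:
                raise ValueError("cycles_per_chip must be a positive integer")
            if not np.isclose(
                self.chip_period * self.carrier_freq, self.cycles_per_chip
            ):
                raise ValueError(
                    "chip_period * carrier_freq must equal cycles_per_chip"
                )
        spc = self.chip_period * self.fs
        if abs(spc - round(spc)) > 1e-6 or round(spc) < 1:
            raise ValueError(
                "chip_period * fs must be a positive integer "
                f"(got {spc:g} samples per chip)"
            )

    @property
    def samples_per_chip(self) -> int:
        return int(round(self.chip_period * self.fs))

    @property
    def samples_per_cycle(self) -> int:
        if self.carrier_freq <= 0:
            raise ValueError("no carrier")
        return int(round(self.fs / self.carrier_freq))


def modulate_wide_pulse(code, spec: ModulationSpec) -> Waveform:
    """BPSK a code onto a rectangular wide pulse (baseband, no carrier).

    Chip ``i`` holds ``amplitude * code[i]`` for one chip period; total
    duration is ``N * chip_period``.  An all-ones code recovers the
    plain wide pulse of length ``N·T``.
    """
    code = _as_pm1(code, "code")
    if spec.carrier_freq != 0:
        raise ValueError("wide-pulse modulation requires carrier_freq = 0")
    samples = np.repeat(
        spec.amplitude * code.astype(np.float64), spec.samples_per_chip
    )
    return Waveform(samples=samples, fs=spec.fs)


def _unit_square_cycle(spec: ModulationSpec) -> np.ndarray:
    n_cycle = spec.fs / spec.carrier_freq
    if abs(n_cycle / 2 - round(n_cycle / 2)) > 1e-9:
        raise ValueError(
            "fs must be an integer multiple of 2 * carrier_freq "
            "for exact half-period sampling"
        )
    half = int(round(n_cycle / 2))
    return np.concatenate([np.ones(half), -np.ones(half)])


def modulate_square_carrier(code, spec: ModulationSpec) -> Waveform:
    """BPSK a code onto a 50%-duty square-wave carrier.

    The output is (unit ±1 square wave at ``carrier_freq``) × (the
    wide-pulse chip waveform): each chip spans ``cycles_per_chip``
    carrier cycles starting at phase 0° (positive half first), and a
    "−1" chip inverts the sign (180°).
    """
    code = _as_pm1(code, "code")
    if spec.carrier_freq <= 0:
        raise ValueError("square-carrier modulation requires carrier_freq > 0")
    cycle = _unit_square_cycle(spec)
    chip = np.tile(cycle, spec.cycles_per_chip)
    samples = spec.amplitude * np.concatenate([c * chip for c in code])
    return Waveform(samples=samples, fs=spec.fs)


def pulse_cancelation_excitation(
    n_cycles: int,
    spec: ModulationSpec,
    cancel_delay_cycles: float | None = None,
    cancel_amplitude: float = 1.0,
) -> Waveform:
    """Burst followed by an anti-phase canceling cycle.

    The antiphase pulse-cancelation technique shortens transducer
    ringing by injecting, ``cancel_delay_cycles`` carrier cycles after
    the burst starts, one sign-inverted cycle scaled by
    ``cancel_amplitude`` that destructively interferes with the
    residual resonant motion.  Delay and scale are free parameters; the
    defaults place the canceling cycle immediately after the burst at
    full scale.
    """
    if not isinstance(n_cycles, (int, np.integer)) or n_cycles < 1:
        raise ValueError("n_cycles must be a positive integer")
    if spec.carrier_freq <= 0:
        raise ValueError("pulse cancelation requires carrier_freq > 0")
    if cancel_delay_cycles is None:
        cancel_delay_cycles = float(n_cycles)
    if cancel_delay_cycles <= 0:
        raise ValueError("cancel_delay_cycles must be positive")
    if not 0 <= cancel_amplitude <= 1:
        raise ValueError("cancel_amplitude must be in [0, 1]")
    if cancel_delay_cycles < n_cycles:
        raise ValueError(
            "canceling segment overlaps the main burst "
            f"(delay {cancel_delay_cycles} < {n_cycles} cycles)"
        )
    cycle = _unit_square_cycle(spec)
    main = spec.amplitude * np.tile(cycle, int(n_cycles))
    if cancel_amplitude == 0:
        return Waveform(samples=main, fs=spec.fs)
    start = cancel_delay_cycles * len(cycle)
    if abs(start - round(start)) > 1e-6:
        raise ValueError("cancel_delay_cycles must land on a sample boundary")
    start = int(round(start))
    out = np.zeros(start + len(cycle))
    out[: len(main)] = main
    out[start:] += -cancel_amplitude * spec.amplitude * cycle
    return Waveform(samples=out, fs=spec.fs)


def matched_filter_reference(code, spec: ModulationSpec) -> Waveform:
    """Time-reversed modulated replica of a code.

    Filtering (convolving) a received trace with this reference equals
    correlating it with the transmitted waveform — the matched filter
    that maximizes peak SNR in white noise.  Wide-pulse or
    square-carrier modulation is chosen by ``spec.carrier_freq``.
    """
    if spec.carrier_freq > 0:
        mod = modulate_square_carrier(code, spec)
    else:
        mod = modulate_wide_pulse(code, spec)
    return Waveform(samples=mod.samples[::-1].copy(), fs=mod.fs)
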