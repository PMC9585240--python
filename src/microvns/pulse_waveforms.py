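"""Stimulation waveforms and their energetics.

µM-VNS is driven with trains of exponentially decaying current pulses
(i(t) = I_peak·exp(-t/τ), truncated at a configurable multiple of τ);
electrical VNS (eVNS) uses rectangular constant-current pulses.  The
induced E-field is proportional to dI/dt, so this module also provides
the time derivative of a sampled waveform and scalar "drive factors"
(A/s) used to scale per-unit-current field maps into RMS field maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

__all__ = [
    "PulseTrain",
    "Waveform",
    "build_train",
    "time_derivative",
    "rms_drive_factor",
    "harmonic_drive_factor",
    "exponential_pulse_rms_didt",
    "delivered_energy",
]


@dataclass(frozen=True)
class PulseTrain:
    """Parameters of one stimulation pulse train.

    ``pulse_width`` is the decay constant τ for exponential pulses and the
    flat-top width for rectangular pulses.  ``sample_rate`` must resolve
    the decay (≥ 50 samples per pulse width).
    """

    shape: Literal["exponential", "rectangular"] = "exponential"
    V_peak: float = 32.4
    I_peak: float = 10.0
    pulse_width: float = 10e-6
    n_pulses_per_train: int = 5
    intra_train_rate: float = 20.0
    train_duration: float = 0.25
    sample_rate: float = 50e6

    def __post_init__(self) -> None:
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be positive")
        if self.n_pulses_per_train < 1:
            raise ValueError("n_pulses_per_train must be >= 1")
        if self.I_peak < 0:
            raise ValueError("I_peak must be non-negative")
        if self.sample_rate < 50.0 / self.pulse_width:
            raise ValueError(
                "sample_rate too low to resolve the pulse "
                f"(need >= {50.0 / self.pulse_width:.3g} Hz)"
            )


@dataclass(frozen=True)
class Waveform:
    """A uniformly sampled time series (A, or A/s for derivatives)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-D and equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
                raise ValueError("times must be uniformly spaced")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("waveform contains non-finite entries")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(
            path, index=False
        )


def build_train(train: PulseTrain, cutoff: float = 5.0) -> Waveform:
    """Sample a pulse train as a :class:`Waveform`.

    Exponential pulses are hard-truncated at ``cutoff`` decay constants;
    pulse onsets sit at multiples of ``1/intra_train_rate``.  Truncated
    pulses that still overlap are superposed, but a repetition rate so
    high that a pulse starts inside the un-decayed body of the previous
    one (period < cutoff·τ) is rejected.
    """
    period = 1.0 / train.intra_train_rate
    tau = train.pulse_width
    if train.shape == "exponential":
        support = cutoff * tau
    else:
        support = tau
    if train.n_pulses_per_train > 1 and period < support:
        raise ValueError(
            f"intra_train_rate {train.intra_train_rate} Hz too high: pulse "
            f"support {support:.3g} s exceeds the period {period:.3g} s"
        )
    t_end = (train.n_pulses_per_train - 1) * period + support
    dt = 1.0 / train.sample_rate
    n = int(math.floor(t_end / dt)) + 1
    t = np.arange(n) * dt
    v = np.zeros(n)
    eps = 0.5 * dt  # nearest-sample assignment of pulse onsets
    for k in range(train.n_pulses_per_train):
        t0 = k * period
        rel = t - t0
        if train.shape == "exponential":
            m = (rel >= -eps) & (rel < support - eps)
            v[m] += train.I_peak * np.exp(-np.maximum(rel[m], 0.0) / tau)
        else:
            m = (rel >= -eps) & (rel < tau - eps)
            v[m] += train.I_peak
    return Waveform(t, v)


def time_derivative(w: Waveform) -> Waveform:
    """dI/dt by central differences (one-sided at the ends), units A/s."""
    if w.times.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return Waveform(w.times, np.gradient(w.values, w.dt))


def rms_drive_factor(
    w: Waveform, window: Optional[tuple[float, float]] = None
) -> float:
    """Root-mean-square of dI/dt (A/s) over a time window.

    ``window=None`` uses the waveform's support (samples where the
    current is non-zero) — the union of pulse supports for a train,
    excluding inter-pulse silence.
    """
    d = time_derivative(w)
    if window is None:
        mask = w.values != 0.0
    else:
        t0, t1 = window
        if t1 <= t0:
            raise ValueError("empty window")
        if t0 < w.times[0] - 0.5 * w.dt or t1 > w.times[-1] + 0.5 * w.dt:
            raise ValueError("window outside waveform support")
        mask = (w.times >= t0) & (w.times <= t1)
    if not np.any(mask):
        raise ValueError("window selects no samples")
    return float(np.sqrt(np.mean(d.values[mask] ** 2)))


def exponential_pulse_rms_didt(
    I_peak: float, tau: float, cutoff: float = 5.0
) -> float:
    """Closed-form RMS of dI/dt over the support of one truncated pulse.

    RMS = (I/τ)·sqrt((1 − e^(−2c)) / (2c)) for truncation at c·τ.
    """
    return (I_peak / tau) * math.sqrt((1.0 - math.exp(-2.0 * cutoff)) / (2.0 * cutoff))


def harmonic_drive_factor(train: PulseTrain) -> float:
    """Harmonic-equivalent RMS drive ω·I_peak/√2 with ω = 2π/pulse_width.

    Maps a pulsed drive onto the frequency-domain quasi-static picture:
    a sinusoidal coil current of amplitude I_peak at the pulse's
    characteristic frequency 1/pulse_width has RMS dI/dt equal to this
    factor.  Used as the study-arm convention for RMS field maps.
    """
    omega = 2.0 * math.pi / train.pulse_width
    return omega * train.I_peak / math.sqrt(2.0)


def delivered_energy(
    train: PulseTrain,
    mode: Literal["magnetic_with_efficiency", "resistive"],
    *,
    load_resistance: Optional[float] = None,
    efficiency: Optional[float] = None,
    duration: float = 1.0,
    cutoff: float = 5.0,
) -> float:
    """Energy (J) delivered over ``duration`` seconds of stimulation.

    ``resistive`` (eVNS): Σ_pulses I²·R·pw for every pulse starting
    inside the window.  ``magnetic_with_efficiency`` (µM-VNS): per-pulse
    source energy ∫ v(t)·i(t) dt with matched exponential voltage/current
    decays — V_peak·I_peak·(τ/2)·(1 − e^(−2c)) — summed and divided by
    the coil efficiency.
    """
    if mode == "resistive":
        if load_resistance is None or efficiency is not None:
            raise ValueError("resistive mode takes load_resistance only")
        per_pulse = train.I_peak**2 * load_resistance * train.pulse_width
    elif mode == "magnetic_with_efficiency":
        if efficiency is None or load_resistance is not None:
            raise ValueError("magnetic mode takes efficiency only")
        if not (0.0 < efficiency <= 1.0):
            raise ValueError("efficiency must be in (0, 1]")
        per_pulse = (
            train.V_peak
            * train.I_peak
            * (train.pulse_width / 2.0)
            * (1.0 - math.exp(-2.0 * cutoff))
        ) / efficiency
    else:
        raise ValueError(f"unknown mode {mode!r}")
    period = 1.0 / train.intra_train_rate
    n_starts = int(math.floor(duration / period - 1e-12)) + 1 if duration > 0 else 0
    return per_pulse * n_starts
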