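"""Synthetic electroretinogram traces with exact amplitude/latency truth.

The waveform is built from monotone piecewise segments so that, at zero
noise, the stated a-wave and b-wave amplitudes and implicit times are
realized exactly on the sample grid: a half-cosine descent from baseline to
the a-trough, a half-cosine rise from the trough to the b-peak, then an
exponential relaxation that never exceeds the peak.  Component shapes are a
modelling choice; only the measured features (baseline-to-trough,
trough-to-peak, latencies) are treated as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..erg import ErgTrace

FLASH_INTENSITY_RANGE = (0.622, 6.955)  # log photons / um^2, stimulus protocol


@dataclass(frozen=True)
class ErgTraceSpec:
    sampling_rate_hz: float = 2000.0
    duration_ms: float = 250.0
    flash_time_ms: float = 20.0
    flash_intensity_log_photons_per_um2: float = 6.3
    a_amplitude_uV: float = 200.0
    a_implicit_ms: float = 15.0
    b_amplitude_uV: float = 400.0
    b_implicit_ms: float = 60.0
    noise_sigma_uV: float = 0.0
    decay_tau_ms: float = 80.0
    adaptation: str = "dark"
    group: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a_amplitude_uV < 0 or self.b_amplitude_uV < 0:
            raise ValueError("amplitudes must be >= 0")
        if not self.a_implicit_ms < self.b_implicit_ms:
            raise ValueError("a_implicit_ms must precede b_implicit_ms")
        lo, hi = FLASH_INTENSITY_RANGE
        if not lo <= self.flash_intensity_log_photons_per_um2 <= hi:
            raise ValueError(
                f"flash intensity outside the stimulus range [{lo}, {hi}]"
            )
        if self.duration_ms <= self.flash_time_ms + self.b_implicit_ms:
            raise ValueError("duration shorter than the b-wave implicit time")
        if self.flash_time_ms <= 0 or self.duration_ms <= 0:
            raise ValueError("flash_time_ms and duration_ms must be positive")


@dataclass
class ErgTruth:
    a_amplitude_uV: float
    a_implicit_ms: float
    b_amplitude_uV: float
    b_implicit_ms: float

    @property
    def b_a_ratio(self) -> float:
        return self.b_amplitude_uV / self.a_amplitude_uV if self.a_amplitude_uV else np.nan


def make_erg_trace(spec: ErgTraceSpec) -> tuple[ErgTrace, ErgTruth]:
    """Generate one trace plus its exact truth; pure function of the spec."""
    rng = np.random.default_rng(spec.seed)
    dt_ms = 1000.0 / spec.sampling_rate_hz
    t = np.arange(0.0, spec.duration_ms, dt_ms)
    tf = spec.flash_time_ms
    ta = tf + spec.a_implicit_ms
    tb = tf + spec.b_implicit_ms
    A, B = spec.a_amplitude_uV, spec.b_amplitude_uV

    v = np.zeros_like(t)
    seg = (t >= tf) & (t <= ta)
    v[seg] = -A / 2.0 * (1 - np.cos(np.pi * (t[seg] - tf) / (ta - tf)))
    seg = (t > ta) & (t <= tb)
    v[seg] = -A + B / 2.0 * (1 - np.cos(np.pi * (t[seg] - ta) / (tb - ta)))
    peak = -A + B
    seg = t > tb
    if peak >= 0:
        v[seg] = peak * np.exp(-(t[seg] - tb) / spec.decay_tau_ms)
    else:
        v[seg] = peak  # hold: a sub-baseline "peak" must stay the local max

    if spec.noise_sigma_uV > 0:
        v = v + rng.normal(0.0, spec.noise_sigma_uV, size=v.shape)

    trace = ErgTrace(
        time_ms=t,
        voltage_uV=v,
        flash_time_ms=tf,
        flash_intensity_log_photons_per_um2=spec.flash_intensity_log_photons_per_um2,
        adaptation=spec.adaptation,
        group=spec.group,
    )
    truth = ErgTruth(
        a_amplitude_uV=A,
        a_implicit_ms=spec.a_implicit_ms,
        b_amplitude_uV=B,
        b_implicit_ms=spec.b_implicit_ms,
    )
    return trace, truth
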