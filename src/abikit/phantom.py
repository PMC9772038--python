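"""Synthetic acoustoelectric (AE) phantom recordings with known ground truth.

Acoustoelectric brain imaging (ABI) records the voltage of an electrode pair
while a focused ultrasound burst train sweeps the sample.  Acoustic pressure
modulates conductivity at the focus (the AE effect, |Δσ/σ0| = K·ΔP with K on
the order of 1e-9 Pa⁻¹ in saline), so the recorded trace contains a carrier at
the pulse repetition frequency (PRF) whose amplitude follows the low-frequency
current sources near the focus, riding on top of untagged low-frequency
leakage and broadband noise.

This module collapses the full 3-D lead-field forward model into a scalar
focal-sensitivity picture good enough to exercise decoders:

* the MHz acoustic carrier is unobservable at kHz sampling rates and is not
  represented; the PRF burst train is the effective carrier,
* the lead-field/beam product is an isotropic Gaussian ``focal_weight`` of the
  focus-to-source distance,
* carrier modulation is pedestal AM, ``1 + μ·M(t)/M_max`` with modulation
  index μ ≤ 1, so the envelope is an affine, sign-preserving image of the
  local source mixture M(t).  ``M_max = Σ_s amplitude_s`` is the
  focus-independent worst case of |M|, which keeps the pedestal nonnegative
  while preserving linear amplitude encoding across focal spots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InvalidConfigError

__all__ = [
    "SourceSpec",
    "TransducerSpec",
    "PhantomConfig",
    "ScanGrid",
    "RawRecording",
    "make_pulse_train",
    "focal_weight",
    "simulate_recording",
    "simulate_scan",
]


@dataclass(frozen=True)
class SourceSpec:
    """A point current source with sinusoidal drive.

    Parameters
    ----------
    position : (float, float)
        Source location ``(x, y)`` in mm, in the scan plane.
    frequency : float
        Drive frequency in Hz (must be > 0).
    amplitude : float
        Drive amplitude in mV (must be >= 0).
    phase : float
        Initial phase in radians.
    """

    position: tuple[float, float]
    frequency: float
    amplitude: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise InvalidConfigError(
                f"source frequency must be > 0 Hz, got {self.frequency}"
            )
        if self.amplitude < 0:
            raise InvalidConfigError(
                f"source amplitude must be >= 0 mV, got {self.amplitude}"
            )

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Drive waveform ``amplitude·sin(2π·frequency·t + phase)``."""
        return self.amplitude * np.sin(2 * np.pi * self.frequency * t + self.phase)


@dataclass(frozen=True)
class TransducerSpec:
    """Focused-ultrasound burst train and focal sensitivity.

    ``prf`` is the pulse repetition frequency (bursts per second);
    ``pulse_width`` the burst duration in s (must satisfy
    ``0 < pulse_width < 1/prf``); ``carrier_phase`` a constant burst-timing
    phase offset in rad; ``focal_sigma`` the Gaussian focal-sensitivity width
    in mm; ``gain`` the net dimensionless pulser/amplifier gain.
    """

    prf: float = 1000.0
    pulse_width: float = 2e-4
    carrier_phase: float = 0.0
    focal_sigma: float = 0.6
    gain: float = 1000.0

    def __post_init__(self) -> None:
        if not self.prf > 0:
            raise InvalidConfigError(f"prf must be > 0 Hz, got {self.prf}")
        if not 0 < self.pulse_width < 1.0 / self.prf:
            raise InvalidConfigError(
                f"pulse_width must lie in (0, 1/prf) = (0, {1.0 / self.prf:g}) s, "
                f"got {self.pulse_width}"
            )
        if not self.focal_sigma > 0:
            raise InvalidConfigError(
                f"focal_sigma must be > 0 mm, got {self.focal_sigma}"
            )


@dataclass(frozen=True)
class PhantomConfig:
    """Complete description of one synthetic phantom experiment.

    ``ae_constant`` (Pa⁻¹) and ``pressure_peak`` (Pa) set the fractional
    conductivity modulation ``A0 = ae_constant·pressure_peak``;
    ``modulation_index`` μ ∈ (0, 1] is the pedestal-AM depth;
    ``lf_leak_gain`` scales the untagged low-frequency leakage of the source
    mixture into the recording; ``noise_sd`` is the additive white Gaussian
    noise standard deviation in recording units.
    """

    sources: tuple[SourceSpec, ...]
    transducer: TransducerSpec = field(default_factory=TransducerSpec)
    fs_record: float = 20_000.0
    duration: float = 2.0
    ae_constant: float = 1e-9
    pressure_peak: float = 1e6
    modulation_index: float = 0.8
    lf_leak_gain: float = 0.01
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        if len(self.sources) == 0:
            raise InvalidConfigError("sources must contain at least one SourceSpec")
        if not self.fs_record > 2 * self.transducer.prf:
            raise InvalidConfigError(
                f"fs_record must exceed 2·prf = {2 * self.transducer.prf:g} Hz, "
                f"got {self.fs_record}"
            )
        if not self.duration > 0:
            raise InvalidConfigError(f"duration must be > 0 s, got {self.duration}")
        if not 0 < self.modulation_index <= 1:
            raise InvalidConfigError(
                f"modulation_index must lie in (0, 1], got {self.modulation_index}"
            )
        if self.lf_leak_gain < 0:
            raise InvalidConfigError(
                f"lf_leak_gain must be >= 0, got {self.lf_leak_gain}"
            )
        if self.noise_sd < 0:
            raise InvalidConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.fs_record)

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_record


@dataclass(frozen=True)
class ScanGrid:
    """Rectangular focal-spot raster in mm, inclusive of both end points."""

    x_min: float
    x_max: float
    x_step: float
    y_min: float
    y_max: float
    y_step: float

    def __post_init__(self) -> None:
        if self.x_step <= 0 or self.y_step <= 0:
            raise InvalidConfigError("grid steps must be > 0 mm")
        if self.x_max < self.x_min or self.y_max < self.y_min:
            raise InvalidConfigError("grid extents must satisfy min <= max")

    @property
    def nx(self) -> int:
        return int(round((self.x_max - self.x_min) / self.x_step)) + 1

    @property
    def ny(self) -> int:
        return int(round((self.y_max - self.y_min) / self.y_step)) + 1

    @property
    def n_spots(self) -> int:
        return self.nx * self.ny

    @property
    def x_coords(self) -> np.ndarray:
        return self.x_min + self.x_step * np.arange(self.nx)

    @property
    def y_coords(self) -> np.ndarray:
        return self.y_min + self.y_step * np.arange(self.ny)

    def spots(self) -> list[tuple[float, float]]:
        """Focal spots in scan order: x is the outer (slow) axis, y the inner."""
        return [(float(x), float(y)) for x in self.x_coords for y in self.y_coords]


@dataclass
class RawRecording:
    """One focal-spot voltage trace with its acquisition metadata."""

    samples: np.ndarray
    fs: float
    focus: tuple[float, float]
    prf: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidConfigError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidConfigError("samples must be finite")
        if not self.fs > 0:
            raise InvalidConfigError(f"fs must be > 0 Hz, got {self.fs}")
        self.focus = (float(self.focus[0]), float(self.focus[1]))

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs


def make_pulse_train(
    transducer: TransducerSpec, fs: float, duration: float
) -> np.ndarray:
    """Unit-peak raised-cosine burst train at the transducer PRF.

    One smooth pulse of width ``pulse_width`` per PRF period, the first
    starting at t = 0 (shifted by ``carrier_phase``).  Samples are taken at
    bin centres within the pulse support so the discrete pulse has exactly
    ``pulse_width·fs`` nonzero samples; the train is renormalised to peak 1.
    """
    if not fs > 2 * transducer.prf:
        raise InvalidConfigError(
            f"fs must exceed 2·prf = {2 * transducer.prf:g} Hz, got {fs}"
        )
    n = round(duration * fs)
    period = 1.0 / transducer.prf
    w = transducer.pulse_width
    t = np.arange(n) / fs + transducer.carrier_phase / (2 * np.pi) * period
    # half-sample offset: no identically-zero samples at the pulse edges
    tau = np.mod(t + 0.5 / fs, period)
    p = np.where(tau < w, np.sin(np.pi * np.minimum(tau, w) / w) ** 2, 0.0)
    peak = p.max()
    if peak > 0:
        p /= peak
    return p


def focal_weight(
    focus: tuple[float, float], source: tuple[float, float], focal_sigma: float
) -> float:
    """Gaussian focal sensitivity ``exp(-d²/(2σ²))`` of a source at distance d.

    Scalar stand-in for the lead-field/acoustic-beam product: sensitivity 1 at
    the focus, falling off isotropically with the focus-to-source distance.
    """
    if not focal_sigma > 0:
        raise InvalidConfigError(f"focal_sigma must be > 0 mm, got {focal_sigma}")
    d2 = (focus[0] - source[0]) ** 2 + (focus[1] - source[1]) ** 2
    return float(math.exp(-d2 / (2.0 * focal_sigma**2)))


def source_mixture(
    config: PhantomConfig, focus: tuple[float, float], t: np.ndarray
) -> np.ndarray:
    """Focally weighted source mixture M(t) seen from ``focus``."""
    sigma = config.transducer.focal_sigma
    m = np.zeros_like(t)
    for s in config.sources:
        m += focal_weight(focus, s.position, sigma) * s.waveform(t)
    return m


def simulate_recording(
    config: PhantomConfig, focus: tuple[float, float], *, seed: int | None = None
) -> RawRecording:
    """Simulate one focal-spot recording.

    The trace is ``gain·p(t)·A0·[1 + μ·M(t)/M_max] + lf_leak_gain·S(t) + ε(t)``
    where ``p`` is the PRF burst train, ``A0 = ae_constant·pressure_peak`` the
    fractional conductivity modulation, ``M`` the focally weighted source
    mixture, ``M_max = Σ_s amplitude_s`` its focus-independent worst case,
    ``S`` the unweighted source sum (leakage), and ε i.i.d. Gaussian noise.
    Deterministic for a fixed seed (default ``config.seed``).
    """
    if seed is None:
        seed = config.seed
    tr = config.transducer
    t = config.times()
    p = make_pulse_train(tr, config.fs_record, config.duration)
    s_total = np.zeros_like(t)
    for s in config.sources:
        s_total += s.waveform(t)
    m = source_mixture(config, focus, t)
    m_max = sum(s.amplitude for s in config.sources)
    a0 = config.ae_constant * config.pressure_peak
    if m_max > 0:
        carrier = tr.gain * a0 * p * (1.0 + config.modulation_index * m / m_max)
    else:
        carrier = tr.gain * a0 * p
    rng = np.random.default_rng(seed)
    samples = carrier + config.lf_leak_gain * s_total
    samples = samples + rng.normal(0.0, config.noise_sd, t.size)
    return RawRecording(
        samples=samples, fs=config.fs_record, focus=focus, prf=tr.prf, seed=seed
    )


def simulate_scan(config: PhantomConfig, grid: ScanGrid) -> list[RawRecording]:
    """One recording per focal spot, in ``grid.spots()`` order.

    Per-spot seeds are ``config.seed + spot_index`` so a scan is reproducible
    and the spots' noise realisations independent.
    """
    return [
        simulate_recording(config, spot, seed=config.seed + i)
        for i, spot in enumerate(grid.spots())
    ]
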