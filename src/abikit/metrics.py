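"""Decoder-comparison statistics: correlations, ratios, improvements, spectra.

These are the quantities a decoding study reports per scenario: Pearson
correlation between the decoded timing signal and the known source waveform,
the decoded amplitude ratio between two foci, the relative improvement of one
method over another in percent (per-case |new − old|/old, averaged unweighted
over cases), and one-sided magnitude spectra normalised so an integer-period
unit sinusoid reads 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .decoders import DecodedTrace, EnvelopeTrace

__all__ = [
    "ComparisonReport",
    "pearson_corr",
    "amplitude_ratio",
    "relative_improvement",
    "mean_relative_improvement",
    "spectrum",
]


def pearson_corr(a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length sequences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D sequences of equal length")
    if a.size < 3:
        raise ValueError(f"need at least 3 samples, got {a.size}")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(np.corrcoef(a, b)[0, 1])


def amplitude_ratio(d1: DecodedTrace, d2: DecodedTrace) -> float:
    """Decoded amplitude ratio d1/d2.

    Each trace's own amplitude convention applies: the selected harmonic's
    c_k for aDAF, √2·RMS of the mean-removed envelope for DAE.
    """
    if d2.amplitude <= 0:
        raise ValueError("denominator trace has zero amplitude")
    return d1.amplitude / d2.amplitude


def relative_improvement(new: float, old: float) -> float:
    """Relative change in percent: 100·|new − old| / old (old must be > 0)."""
    if old <= 0:
        raise ValueError(f"reference value must be > 0, got {old}")
    return 100.0 * abs(new - old) / old


def mean_relative_improvement(pairs: Iterable[tuple[float, float]]) -> float:
    """Unweighted mean of per-case relative improvements, percent."""
    vals = [relative_improvement(new, old) for new, old in pairs]
    if not vals:
        raise ValueError("need at least one (new, old) pair")
    return float(np.mean(vals))


def spectrum(
    trace: DecodedTrace | EnvelopeTrace | np.ndarray, fs: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided magnitude spectrum (frequencies Hz, magnitudes).

    Magnitudes are 2|X_k|/n (1/n at DC and Nyquist) so an integer-period unit
    sinusoid reads 1.0 at its frequency.
    """
    if hasattr(trace, "samples"):
        x = np.asarray(trace.samples, dtype=float)
        fs = trace.fs
    else:
        x = np.asarray(trace, dtype=float)
        if fs is None:
            raise ValueError("fs must be given for a bare sample array")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    X = np.fft.rfft(x)
    mag = np.abs(X) * 2.0 / n
    mag[0] /= 2.0
    if n % 2 == 0:
        mag[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return freqs, mag


@dataclass
class ComparisonReport:
    """Per-scenario records of both decoders plus aggregated improvements.

    ``records`` holds one dict per (focal spot, method) with keys such as
    method, focus, frequency, correlation, amplitude, snr_db, width_mm;
    ``improvements`` holds the aggregated percentages (keys depend on the
    scenario kind).
    """

    scenario: str
    records: list[dict] = field(default_factory=list)
    improvements: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rec in self.records:
            r = rec.get("correlation")
            if r is not None and not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
                raise ValueError(f"correlation {r} outside [-1, 1]")
        for key, val in self.improvements.items():
            if not np.isfinite(val):
                raise ValueError(f"improvement {key!r} is not finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "records": self.records,
            "improvements": self.improvements,
        }
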