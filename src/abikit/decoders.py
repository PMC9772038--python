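"""The two AE-signal decoders under comparison: DAE and aDAF.

DAE (decoding algorithm with envelope) is the classical baseline: form the
analytic signal of the band-passed AE trace and take its modulus, the
instantaneous amplitude A(t).

aDAF (adaptive decoding algorithm based on Fourier fitting) refines DAE:
expand A(t) over the trigonometric basis at harmonics of the record's
fundamental f₀ = fs/n,

    A(t) ≈ a0 + Σ_i a_i·cos(i·2πt/n) + b_i·sin(i·2πt/n),   i = 1..⌊n/2⌋,

with the least-squares coefficients

    a0 = mean(A),  a_i = (2/n)·Σ_t A(t)·cos(i·2πt/n),
                   b_i = (2/n)·Σ_t A(t)·sin(i·2πt/n),      c_i² = a_i² + b_i²,

then keep the single harmonic with the largest amplitude c_i inside a
candidate band (1–50 Hz by default) as the decoded timing signal.  Confining
the decoded signal to one harmonic of the fit rejects all envelope noise that
does not fall in that single frequency bin, which is what buys aDAF its
accuracy over the raw envelope.

The time index runs t = 0..n−1.  For even n the Nyquist harmonic i = n/2 is a
cosine-only term with coefficient normalised 1/n (its sine partner vanishes at
the sample points); the least-squares fit over a whole record is then exact.
Records are used whole — no windowing or zero-padding — so sources that do not
complete an integer number of cycles leak across bins (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as _signal

__all__ = [
    "EnvelopeTrace",
    "HarmonicDecomposition",
    "DecodedTrace",
    "analytic_signal",
    "dae_decode",
    "fourier_fit",
    "select_dominant",
    "adaf_decode",
    "DEFAULT_BAND",
]

#: Candidate band for the dominant-harmonic search, Hz.  Keeps the fit off
#: the DC/drift end and off residual PRF-beat components.
DEFAULT_BAND: tuple[float, float] = (1.0, 50.0)


@dataclass
class EnvelopeTrace:
    """Instantaneous amplitude A(t) ≥ 0 of a band-passed AE trace."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("envelope samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("envelope samples must be finite")
        if np.any(self.samples < 0):
            raise ValueError("envelope samples must be non-negative")

    @property
    def n(self) -> int:
        return self.samples.size


@dataclass
class HarmonicDecomposition:
    """Least-squares trigonometric fit of an envelope over harmonics 1..⌊n/2⌋.

    ``a``/``b`` hold the cosine/sine coefficients of harmonics 1..m (index
    ``i-1`` ↔ harmonic ``i``); ``c = √(a² + b²)`` the harmonic amplitudes;
    ``fundamental = fs/n`` Hz; ``rss`` the residual sum of squares of the full
    reconstruction (zero up to round-off for a whole record); ``ss_centered``
    the total sum of squares of the mean-removed envelope.
    """

    a0: float
    a: np.ndarray
    b: np.ndarray
    n: int
    fs: float
    rss: float
    ss_centered: float

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("a and b must be 1-D arrays of equal length")
        if self.a.size != self.n // 2:
            raise ValueError(f"expected {self.n // 2} harmonics, got {self.a.size}")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))
                and np.isfinite(self.a0)):
            raise ValueError("coefficients must be finite")

    @property
    def m(self) -> int:
        return self.a.size

    @property
    def c(self) -> np.ndarray:
        return np.hypot(self.a, self.b)

    @property
    def fundamental(self) -> float:
        return self.fs / self.n

    @property
    def frequencies(self) -> np.ndarray:
        """Frequencies of harmonics 1..m, Hz."""
        return np.arange(1, self.m + 1) * self.fundamental

    def harmonic(self, k: int) -> np.ndarray:
        """Samples of harmonic k alone: a_k·cos(k·2πt/n) + b_k·sin(k·2πt/n)."""
        if not 1 <= k <= self.m:
            raise ValueError(f"harmonic index must lie in [1, {self.m}], got {k}")
        t = np.arange(self.n)
        ang = 2 * np.pi * k * t / self.n
        return self.a[k - 1] * np.cos(ang) + self.b[k - 1] * np.sin(ang)

    def single_harmonic_rss(self, k: int) -> float:
        """Residual sum of squares of the DC + single-harmonic-k model.

        By orthogonality this is ``Σ(A − mean)² − n/2·c_k²`` (``n·a_k²`` for
        the Nyquist harmonic); clipped at zero against round-off.
        """
        if not 1 <= k <= self.m:
            raise ValueError(f"harmonic index must lie in [1, {self.m}], got {k}")
        if self.n % 2 == 0 and k == self.m:
            explained = self.n * self.a[k - 1] ** 2
        else:
            explained = 0.5 * self.n * self.c[k - 1] ** 2
        return float(max(self.ss_centered - explained, 0.0))


@dataclass
class DecodedTrace:
    """Reconstructed low-frequency timing signal plus its summary parameters.

    For aDAF, ``selected_harmonic`` is the kept harmonic index k,
    ``frequency = k·fs/n``, ``amplitude = c_k`` and ``phase = atan2(a_k, b_k)``.
    For DAE the samples are the raw envelope, ``selected_harmonic`` is None and
    ``amplitude`` is the envelope oscillation amplitude, √2·RMS of the
    mean-removed envelope.
    """

    samples: np.ndarray
    fs: float
    method: str
    selected_harmonic: int | None
    frequency: float | None
    amplitude: float
    phase: float | None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.method not in ("DAE", "aDAF"):
            raise ValueError(f"method must be 'DAE' or 'aDAF', got {self.method!r}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.selected_harmonic is not None and self.frequency is not None:
            expect = self.selected_harmonic * self.fs / self.samples.size
            if abs(self.frequency - expect) > 1e-9 * max(1.0, expect):
                raise ValueError(
                    f"frequency {self.frequency} inconsistent with harmonic "
                    f"{self.selected_harmonic} (expected {expect})"
                )


def analytic_signal(x: Sequence[float] | np.ndarray) -> np.ndarray:
    """Analytic signal x̃(t) = x(t) + j·x̂(t) of a real trace.

    x̂ is the discrete Hilbert transform via the frequency-domain construction
    (negative frequencies zeroed, positive doubled).  The real part is the
    input, exactly.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("input must be a 1-D sequence of at least 2 samples")
    h = _signal.hilbert(x)
    return x + 1j * h.imag


def dae_decode(
    x: Sequence[float] | np.ndarray, fs: float
) -> tuple[EnvelopeTrace, DecodedTrace]:
    """Envelope decoder: A(t) = |x̃(t)| of the band-passed AE trace."""
    env = np.abs(analytic_signal(x))
    trace = DecodedTrace(
        samples=env.copy(),
        fs=fs,
        method="DAE",
        selected_harmonic=None,
        frequency=None,
        amplitude=float(np.sqrt(2.0) * np.std(env)),
        phase=None,
    )
    return EnvelopeTrace(samples=env, fs=fs), trace


def fourier_fit(env: EnvelopeTrace) -> HarmonicDecomposition:
    """Least-squares trigonometric fit of the envelope at harmonics of fs/n.

    The closed-form coefficients (orthogonality of the basis over a whole
    record) are evaluated through a real FFT, which computes exactly the
    direct sums a_i = (2/n)·ΣA·cos, b_i = (2/n)·ΣA·sin in O(n log n).
    """
    x = env.samples
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 samples to fit, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("envelope contains non-finite samples")
    X = np.fft.rfft(x)
    a0 = float(X[0].real / n)
    a = 2.0 * X[1:].real / n
    b = -2.0 * X[1:].imag / n
    if n % 2 == 0:
        a[-1] = X[-1].real / n  # Nyquist: cosine-only, weight 1/n
        b[-1] = 0.0
    # reconstruct from the fitted coefficients to report the fit residual
    Y = np.empty(n // 2 + 1, dtype=complex)
    Y[0] = n * a0
    Y[1:] = (a - 1j * b) * (n / 2.0)
    if n % 2 == 0:
        Y[-1] = n * a[-1]
    recon = np.fft.irfft(Y, n)
    rss = float(np.sum((x - recon) ** 2))
    ss_centered = float(np.sum((x - x.mean()) ** 2))
    return HarmonicDecomposition(
        a0=a0, a=a, b=b, n=n, fs=env.fs, rss=rss, ss_centered=ss_centered
    )


def select_dominant(
    decomp: HarmonicDecomposition, band: tuple[float, float] = DEFAULT_BAND
) -> int:
    """Index k of the largest-amplitude harmonic with frequency inside ``band``.

    DC is never eligible; ties break toward the lowest index.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError(f"band must satisfy low < high, got {band}")
    freqs = decomp.frequencies
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(
            f"no harmonic of fundamental {decomp.fundamental:g} Hz lies in "
            f"band {band}"
        )
    c = np.where(mask, decomp.c, -np.inf)
    return int(np.argmax(c)) + 1  # argmax takes the first maximum: lowest index


def adaf_decode(
    x: Sequence[float] | np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    top_m: int = 1,
) -> DecodedTrace:
    """Adaptive Fourier-fitting decoder: envelope → harmonic fit → keep the best.

    Composes :func:`dae_decode`, :func:`fourier_fit` and
    :func:`select_dominant`; the decoded timing signal is
    ``a0 + a_k·cos(k·2πt/n) + b_k·sin(k·2πt/n)`` for the selected harmonic k.
    ``top_m > 1`` retains the m largest in-band harmonics (exploration aid);
    the reported parameters always describe the single dominant one.
    """
    if top_m < 1:
        raise ValueError(f"top_m must be >= 1, got {top_m}")
    env, _ = dae_decode(x, fs)
    decomp = fourier_fit(env)
    k = select_dominant(decomp, band)
    freqs = decomp.frequencies
    mask = (freqs >= band[0]) & (freqs <= band[1])
    in_band = np.flatnonzero(mask) + 1
    order = in_band[np.argsort(decomp.c[in_band - 1])[::-1]]
    kept = order[: min(top_m, order.size)]
    samples = np.full(decomp.n, decomp.a0)
    for idx in kept:
        samples += decomp.harmonic(int(idx))
    return DecodedTrace(
        samples=samples,
        fs=fs,
        method="aDAF",
        selected_harmonic=k,
        frequency=k * fs / decomp.n,
        amplitude=float(decomp.c[k - 1]),
        phase=float(np.arctan2(decomp.a[k - 1], decomp.b[k - 1])),
    )
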