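# Methods

## Forward model of the synthetic phantom

The phantom simulator produces the recorded voltage of one electrode pair
while a focused ultrasound burst train interrogates a plane of point current
sources. The full acoustoelectric forward model is a 3-D lead-field
integral — the measured voltage is the volume integral of the lead field
dotted with the current density, and the AE component is that integral
weighted by the pressure-induced conductivity change K·ΔP. `abikit`
deliberately collapses this to a scalar picture sufficient to exercise
decoders:

- **Carrier.** The MHz acoustic oscillation is unobservable at kHz sampling
  rates, so it is not represented; the observable carrier is the burst
  train at the pulse repetition frequency (PRF). `make_pulse_train` emits
  one raised-cosine pulse of width `pulse_width` per PRF period, unit peak,
  sampled at bin centres within the pulse support so the discrete pulse has
  exactly `pulse_width·fs` nonzero samples.
- **Focal sensitivity.** The lead-field/beam product is modelled as an
  isotropic Gaussian `focal_weight = exp(−d²/2σ²)` of the focus-to-source
  distance, σ = `focal_sigma` (default 0.6 mm). Direction sensitivity of AE
  signals is out of scope.
- **Modulation.** The carrier amplitude follows the focally weighted source
  mixture M(t) = Σ wₛ·Aₛ·sin(2πfₛt + φₛ) as *pedestal* amplitude
  modulation: gain·A₀·p(t)·[1 + μ·M(t)/M_max], with A₀ =
  `ae_constant·pressure_peak` the fractional conductivity modulation and
  μ = `modulation_index` ≤ 1. A pure magnitude envelope of a sign-flipping
  modulation would rectify the source waveform; the pedestal keeps the
  envelope an affine, sign- and phase-preserving image of M(t), which is the
  regime in which envelope-family decoders recover source timing. The
  normaliser M_max = Σₛ Aₛ is the focus-independent worst case of |M|: it
  guarantees a nonnegative pedestal for μ ≤ 1 at every focus while keeping
  the modulation depth linear in the local source amplitudes, so decoded
  amplitude ratios across foci reflect true source ratios.
- **Leakage and noise.** The unweighted source sum enters directly with
  gain `lf_leak_gain` (low-frequency leakage, removed by the band-pass),
  plus i.i.d. Gaussian noise of standard deviation `noise_sd`, seeded; the
  whole simulator is bit-reproducible for a fixed seed. Scans derive
  per-spot seeds as `seed + spot_index`.

What the generator does *not* emulate: acoustic propagation and tissue
heterogeneity, transducer beamforming, electrode impedance, non-Gaussian or
correlated physiological noise, drift, and any nonlinearity of the
acquisition chain. Passing tests therefore demonstrate decoder behaviour
under an idealised, calibrated AM model, not performance on bench or in-vivo
recordings.

## Default study conditions

Recording rate 20 kHz, record length 2 s, PRF 1 kHz, pulse width 0.2 ms,
focal σ 0.6 mm, μ = 0.8, gain 1000, A₀ = 10⁻⁹ Pa⁻¹ × 10⁶ Pa = 10⁻³. Source
frequencies 7–13 Hz with amplitudes 50–150 mV, placed so the default record
length holds an integer number of cycles of every source (2 s × 7/8/10/13 Hz
are all integers), putting each source line exactly on a fit harmonic.

Three noise levels are fixed once as scenario conditions:

- **Single-source scenarios** (`1source-8/10/13`): `noise_sd = 1.4`,
  calibrated by a one-time sweep so the baseline DAE correlation with the
  source falls mid-way in the 0.6–0.85 range (median ≈ 0.76 over seeds).
  This is the stress regime in which the decoder comparison is made.
- **Multi-frequency point scenarios** (`2source-freq`, `3source`) and the
  **imaging scans** (`image-2source`, `image-3source`): `noise_sd = 0.1`.
  These scenarios run at a half to a third of the single-source modulation
  depth per source (the pedestal normaliser spans all sources), and they
  emulate experiments in which the baseline decoder still produces usable
  spectra and maps — visible source lines, mid-teens-dB map SNR with
  artifacts — rather than pure noise.
- **Amplitude-ratio scenarios** (`2source-amp2/3`): noiseless, since they
  probe the linearity of amplitude decoding.

## Conditioning

Decimation to 5 kHz uses a zero-phase FIR anti-alias filter
(`scipy.signal.decimate`). The PRF band-pass is a 3rd-order Butterworth,
PRF ± 30 Hz, applied forward-backward over reflectively padded data (three
filter time constants, padding trimmed after), so the decoded envelope is
not delayed against the source. Forward-backward application doubles the
effective magnitude order; a single-pass option (`zero_phase=False`) is
provided. Whether the original conditioning was causal or zero-phase is not
documented anywhere authoritative; zero-phase is the choice here because the
comparison metrics are phase-sensitive.

## Decoders and numerical choices

`analytic_signal` uses the frequency-domain Hilbert construction; the real
part is forced to equal the input exactly. `fourier_fit` evaluates the
closed-form least-squares trigonometric sums through a real FFT
(mathematically identical, O(n log n) instead of O(n·m)); an independent
brute-force implementation of the direct sums serves as the test oracle.
Conventions, chosen once and verified against that oracle:

- time index t = 0..n−1; harmonics i = 1..⌊n/2⌋ of the record fundamental
  fs/n; records are used whole, no windowing or zero-padding. Sources that
  do not complete an integer number of cycles leak across bins and lose
  fitted amplitude; the default scenarios avoid this by construction.
- Nyquist harmonic (even n): cosine-only, coefficient weight 1/n; with this
  weight the whole-record fit is exact and the Parseval identity
  mean(A²) = a₀² + Σc²ᵢ/2 (+ the full-weight Nyquist term) holds to
  round-off.
- the decoded aDAF trace includes a₀ (correlation metrics are
  shift-invariant; amplitude reporting uses c_k only); `top_m` optionally
  retains the m largest in-band harmonics for exploration.
- dominant-harmonic search band: 1–50 Hz by default, keeping the fit off
  DC/drift and residual PRF-beat components; ties break to the lowest
  index; DC is never eligible.
- DAE's scalar amplitude is √2·RMS of the mean-removed envelope (the
  amplitude an ideal sinusoidal oscillation of that power would have).

## Imaging metrics

Maps are per-spot decoded amplitudes on the scan grid (x the slow scan
axis), bicubically interpolated onto a 0.01 mm lattice (bilinear option);
cubic undershoot below zero is clipped. dB maps use 20·log₁₀ relative to
the peak, floored at the display dynamic range (5 dB default). Image SNR is
10·log₁₀ of mean squared ROI-peak amplitude (one peak per 1.5 mm-radius
source ROI; radius unreported in the source study, fixed here once) over
mean squared background amplitude (all pixels outside every ROI) — because
region definitions are a free choice, absolute SNR values are
implementation-specific and only orderings and ratios are meaningful. The
−3 dB source width is measured on a nearest-row line profile as the
contiguous interval around the peak above peak·10^(−3/20), with linear
sub-step boundary interpolation; it requires an interior peak that falls
below threshold on both sides.

## Comparison statistics

Improvement percentages are per-case 100·|new − old|/old, averaged
unweighted over cases — the convention that reproduces the study's printed
aggregates from its printed per-case values. Correlations are Pearson
coefficients between the mean-removed decoded trace and the mean-removed
source sinusoid at known frequency and phase. Spectra are one-sided FFT
magnitudes normalised so an integer-period unit sinusoid reads 1.0.

## Problem sizes

The test suite and the acceptance script run every scenario at its native
size: 2 s × 20 kHz records, 10-seed batteries for the stochastic claims, and
full 50- and 120-spot scans for the imaging battery.

## Known limitations

- The aDAF output is a single stationary sinusoid per record; time-varying
  or multi-component sources within one record are outside the model (the
  `top_m` option is exploratory, not validated).
- Frequencies are confined to the fs/n grid; no off-grid refinement.
- The Gaussian focal model makes map peak widths directly reflect
  `focal_sigma`; resolution comparisons between decoders here measure noise
  robustness, not beam physics.
- Absolute decoded amplitudes are arbitrary (acquisition gain is a free
  parameter); only ratios and correlations are meaningful.
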