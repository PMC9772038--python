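# abikit

Simulation, decoding and imaging metrics for **acoustoelectric brain-imaging
(ABI)** signals.

ABI maps biological current sources by sweeping a focused ultrasound beam
over the sample while recording with an electrode pair. Acoustic pressure
modulates conductivity at the focus (the acoustoelectric effect,
|Δσ/σ₀| = K·ΔP with K ~ 10⁻⁹ Pa⁻¹ in saline), so the recorded voltage
contains a carrier at the ultrasound pulse repetition frequency (PRF) whose
amplitude follows the low-frequency current sources at the focus. Decoding
that amplitude modulation per focal spot yields a functional image whose
spatial resolution is set by the ultrasound focus — and by the accuracy of
the decoder.

`abikit` implements and compares the two decoders at the heart of that
pipeline, together with everything needed to exercise them without
laboratory hardware:

- **DAE** (decoding algorithm with envelope) — the classical baseline: the
  instantaneous amplitude A(t) = |x̃(t)| of the band-passed AE signal, with
  x̃(t) = x(t) + j·x̂(t) the analytic signal.
- **aDAF** (adaptive decoding algorithm based on Fourier fitting) — expand
  A(t) over the trigonometric basis at harmonics of the record fundamental
  f₀ = fs/n,

      A(t) ≈ a₀ + Σᵢ aᵢ·cos(i·2πt/n) + bᵢ·sin(i·2πt/n),  cᵢ² = aᵢ² + bᵢ²,

  with the closed-form least-squares coefficients
  a₀ = mean(A), aᵢ = (2/n)·Σ A(t)·cos(i·2πt/n), bᵢ = (2/n)·Σ A(t)·sin(i·2πt/n),
  then keep the single in-band harmonic with the largest cᵢ as the decoded
  timing signal. Confining the output to one fitted harmonic rejects all
  envelope noise outside that frequency bin.
- a **synthetic phantom simulator** (point sources with sinusoidal drive,
  Gaussian focal sensitivity, pedestal amplitude modulation of a PRF burst
  train, low-frequency leakage, seeded Gaussian noise) with known ground
  truth for every test,
- the standard **conditioning chain** (decimation to 5 kHz, zero-phase
  3rd-order Butterworth band-pass at PRF ± 30 Hz),
- the **imaging/metric layer**: scan-grid amplitude maps, bicubic
  interpolation to a 0.01 mm lattice, dB maps with a 5 dB dynamic range,
  image SNR = 10·log₁₀(P_signal/P_noise), line profiles and the −3 dB
  source width, plus comparison statistics (Pearson correlation with the
  source, amplitude ratios, relative improvements, spectra).

It is aimed at people developing or evaluating AE/ABI decoding methods who
want a reproducible, hardware-free benchmark harness.

## Worked example

Decode a noisy single-source phantom (8 Hz source, 2 s record, 1 kHz PRF,
noise calibrated so the envelope baseline is visibly degraded):

```sh
$ python examples/single_source_decoding.py
  DAE: corr(decoded, source) = 0.7161
 aDAF: corr(decoded, source) = 1.0000   decoded frequency = 8 Hz
aDAF improves the source correlation by 39.65% over DAE
```

The envelope tracks the source only loosely at this noise level
(r ≈ 0.72), while the adaptive decoder locks onto the correct 8 Hz harmonic
bin and reproduces the source waveform almost exactly.

Image two sources with a 10 × 5 focal-spot raster scan:

```sh
$ python examples/two_source_imaging.py
  DAE: SNR = 16.74 dB, -3 dB source width = 1.13 mm
 aDAF: SNR = 30.30 dB, -3 dB source width = 1.10 mm
SNR improvement: 80.94%  width change: 2.31%
```

Both decoders localise the sources; the single-harmonic decoder suppresses
the background noise floor of the map (higher SNR) and gives a slightly
tighter source profile. `examples/amplitude_ratio.py` (decoded amplitude
ratios of unequal sources: aDAF recovers 2:1 and 3:1 within 0.1 %) and
`examples/multi_source_spectrum.py` (frequency separation of a 7/10/13 Hz
source triplet) cover the remaining capabilities.

The same pipeline is scriptable from the shell:

```sh
abikit compare --scenario 2source-amp2 --seed 0
abikit scenario --name image-3source --seed 1 --out runs/img3
abikit simulate --config phantom.json --focus 0,0 --out rec.csv
```

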