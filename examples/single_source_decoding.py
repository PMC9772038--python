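"""Decode a noisy single-source phantom with both decoders.

Simulates a 2 s recording of an 8 Hz, 100 mV source at the ultrasound focus
(1 kHz PRF, 20 kHz sampling, calibrated noise), conditions it (decimation to
5 kHz, band-pass PRF ± 30 Hz), and decodes with the envelope baseline (DAE)
and the adaptive Fourier-fitting decoder (aDAF).  The printed correlations
measure how faithfully each decoded timing signal tracks the injected source
sinusoid; aDAF should sit near 1 while the raw envelope degrades with noise.
"""

from abikit import run_scenario

report = run_scenario("1source-8", seed=1)
for rec in report.records:
    print(
        f"{rec['method']:>5}: corr(decoded, source) = {rec['correlation']:.4f}"
        + (
            f"   decoded frequency = {rec['decoded_frequency_hz']:g} Hz"
            if rec["decoded_frequency_hz"]
            else ""
        )
    )
imp = report.improvements["correlation_improvement_pct"]
print(f"aDAF improves the source correlation by {imp:.2f}% over DAE")
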