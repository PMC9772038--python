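"""Separate three sources by frequency from their focal-spot spectra.

Three sources at 7, 10 and 13 Hz sit 6-8 mm apart; focusing the simulated
ultrasound on each source in turn and decoding picks out that source's
frequency.  For each focus the script prints the dominant in-band line of the
envelope spectrum and the single harmonic aDAF keeps — both should match the
local source, demonstrating frequency-selective decoding.
"""

import numpy as np

from abikit import SCENARIOS, dae_decode, adaf_decode, simulate_recording, spectrum
from abikit.scenarios import preprocess_recording

scenario = SCENARIOS["3source"]
config = scenario.config(seed=0)
for focus, source in zip(scenario.foci, scenario.sources):
    rec = simulate_recording(config, focus, seed=0)
    cond = preprocess_recording(rec)
    env, _ = dae_decode(cond.samples, cond.fs)
    freqs, mag = spectrum(env)
    band = (freqs >= 1.0) & (freqs <= 50.0)
    peak = freqs[band][np.argmax(mag[band])]
    trace = adaf_decode(cond.samples, cond.fs)
    print(f"focus {focus} (true {source.frequency:g} Hz): "
          f"envelope spectrum peak {peak:g} Hz, "
          f"aDAF harmonic {trace.selected_harmonic} -> {trace.frequency:g} Hz")
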