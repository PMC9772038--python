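"""Image two sources with a 10x5 focal-spot raster scan and compare maps.

Simulates the 50-spot scan over two 10 Hz / 100 mV sources at (-8, 0) and
(-2, 0) mm, decodes every spot with both methods, assembles the amplitude
maps, interpolates them onto a 0.01 mm lattice and reports image SNR and the
-3 dB source width of the x profile through y = 0.  Higher SNR and a
narrower width mean a cleaner, sharper functional image.
"""

from abikit import run_scenario

report = run_scenario("image-2source", seed=1, outdir="scratch/image-2source")
for rec in report.records:
    print(f"{rec['method']:>5}: SNR = {rec['snr_db']:.2f} dB, "
          f"-3 dB source width = {rec['width_mm']:.2f} mm")
print(f"SNR improvement: {report.improvements['snr_improvement_pct']:.2f}%  "
      f"width change: {report.improvements['width_change_pct']:.2f}%")
print("maps, profiles and manifest written to scratch/image-2source/")
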