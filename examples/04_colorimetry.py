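"""Plumage reflectance processing and color metrics.

Builds replicate spectra with known brightness / UV-chroma targets,
processes them (1-nm interpolation over 300-700 nm, replicate averaging)
and recovers the metrics.
"""

import pandas as pd

import invadiv as iv
from invadiv.simulate import simulate_spectra

targets = pd.DataFrame(
    [
        dict(id="bird1", patch="dorsal", brightness=22.0, uv_chroma=0.28),
        dict(id="bird1", patch="breast", brightness=48.0, uv_chroma=0.22),
    ]
)
raw = simulate_spectra(targets, noise_sd=1.0, n_replicates=3, seed=5)
processed = iv.process_spectra(raw)
metrics = iv.color_table(processed)
print(metrics.round(4))
print(
    "\nbrightness = mean % reflectance over 300-700 nm (0 = black, 100 ="
    "\nwhite); uv_chroma = share of summed reflectance in the ultraviolet"
    "\nband 300-400 nm. With replicate noise of 1% reflectance the recovered"
    "\nvalues sit within a fraction of a unit of the targets above."
)
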