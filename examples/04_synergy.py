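"""Score a simulated drug-combination matrix with the ZIP synergy model.

Generates a Bliss-independent 8x8 dose grid with a +15-point interaction
injected at one cell, averages three replicates, and scores departures from
the zero-interaction expectation.
"""

import numpy as np

from drugscreen import validate_matrix, zip_delta
from drugscreen.simulate import SynergySimConfig, average_replicates, gen_synergy

cfg = SynergySimConfig(noise_sd=2.0, interaction={(4, 5): 15.0}, n_replicates=3)
records, truth = gen_synergy(cfg, seed=1)
matrix = validate_matrix(average_replicates(records))
surface = zip_delta(matrix)

i, j = np.unravel_index(np.argmax(surface.delta), surface.delta.shape)
print(f"max synergy score: {surface.max_score:.1f} points at "
      f"({surface.doses_a[i]:.3g}, {surface.doses_b[j]:.3g}) uM")
print(f"quantiles of the delta surface: "
      + ", ".join(f"{q}%: {v:.1f}" for q, v in surface.quantiles.items()))
print()
print("Delta is observed minus Bliss-expected inhibition (percentage points) at")
print("each nonzero dose pair; the injected +15-point interaction is recovered at")
print("its cell while the rest of the surface stays near zero.")
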