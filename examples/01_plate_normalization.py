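"""Normalize a simulated 384-well resazurin plate to percent viability.

Builds one plate with known per-well viability truths, converts the raw
fluorescence back to viability with the within-plate normalization, and
shows that the control wells define the 0 % / 100 % scale.
"""

import numpy as np
import pandas as pd

from drugscreen import normalize_plates
from drugscreen.simulate import PlateSimConfig, gen_plate

truth = pd.DataFrame({
    "cell_line": "CTRL",
    "drug": [f"drug{i:02d}" for i in range(1, 11)],
    "dose_uM": 0.534,
    "viability_pct": np.linspace(10, 100, 10),
})
plate = gen_plate(truth, PlateSimConfig(noise_sd_frac=0.02), seed=0)
viability = normalize_plates(plate)

merged = viability.merge(truth, on="drug", suffixes=("_estimated", "_true"))
print(merged[["drug", "viability_pct_true", "viability_pct_estimated"]]
      .round(2).to_string(index=False))
print()
print("Each estimate is (well - background mean) / (untreated mean - background mean)")
print("x 100; with 2 % fluorescence noise the estimates sit within a few points")
print("of the generating truths, and untreated wells average 100 % by construction.")
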