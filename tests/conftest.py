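import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")


def make_plate(treated, *, background=(100.0, 100.0), untreated=(1100.0, 1100.0),
               plate_id="P1", cell_line="CTRL"):
    """Build a minimal plate-reading frame.

    ``treated`` is a list of (drug, dose_uM, fluorescence) tuples;
    ``background``/``untreated`` are raw fluorescence readings.
    """
    rows = []
    well = iter(f"{r}{i}" for r in "ABCDEFGHIJKLMNOP" for i in range(1, 25))
    for fl in background:
        rows.append((plate_id, next(well), "background", cell_line, "", np.nan, fl))
    for fl in untreated:
        rows.append((plate_id, next(well), "untreated", cell_line, "", np.nan, fl))
    for drug, dose, fl in treated:
        rows.append((plate_id, next(well), "treated", cell_line, drug, dose, fl))
    return pd.DataFrame(rows, columns=["plate_id", "well", "role", "cell_line",
                                       "drug", "dose_uM", "fluorescence"])


@pytest.fixture
def simple_plate():
    """Background mean 100, untreated mean 1100 (span 1000)."""
    return make_plate([("drugA", 0.534, 600.0), ("drugB", 0.534, 1100.0),
                       ("drugC", 0.534, 100.0)])


@pytest.fixture
def screen_table():
    """Three-line screen table with hand-set viabilities per drug."""
    rows = []
    viab = {
        "sens_both": {"CTRL": 80.0, "KO1": 60.0, "KO2": 65.0},
        "prot_one": {"CTRL": 70.0, "KO1": 80.0, "KO2": 72.0},
        "dual": {"CTRL": 60.0, "KO1": 75.0, "KO2": 49.0},
        "boundary": {"CTRL": 50.0, "KO1": 59.0, "KO2": 41.0},  # deltas exactly +/-9
        "quiet": {"CTRL": 90.0, "KO1": 91.0, "KO2": 89.0},
    }
    for drug, lines in viab.items():
        for line, v in lines.items():
            rows.append({"cell_line": line, "drug": drug, "viability_pct": v})
    return pd.DataFrame(rows)
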