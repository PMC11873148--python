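"""Bundled reference datasets from the isogenic T24 STAG2 screening study.

Two small CSVs ship with the package:

* the 100-row differential hit table of the 312-compound single-dose
  (534 nM, 72 h) screen on T24 bladder-cancer cells — control line A6 versus
  the STAG2 knockout clones G2 and H2 — with per-line percent viabilities,
  printed KO-minus-control deltas, and the published sensitizer/protector
  categorization (one drug, PKI-402, legitimately appears in both
  categories and therefore has two rows);
* mean ± SEM EC50s (µM) from triplicate dose-response experiments for seven
  follow-up drugs on the same three lines.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

CONTROL_LINE = "A6"
KO_LINES = ("G2", "H2")


def _read(name: str) -> pd.DataFrame:
    with resources.files("drugscreen.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_t24_hit_table() -> pd.DataFrame:
    """The published 100-row hit table (one row per drug x category)."""
    return _read("t24_stag2_screen_hits.csv")


def t24_screen_viabilities() -> pd.DataFrame:
    """Unique per-drug screen viabilities in long format.

    Collapses the hit table to one row per drug x cell line with columns
    ``cell_line, drug, viability_pct`` — the input
    :func:`drugscreen.hits.compute_deltas` expects.
    """
    wide = load_t24_hit_table().drop_duplicates("drug")
    long = wide.melt(
        id_vars="drug",
        value_vars=[f"viability_{line}" for line in (CONTROL_LINE, *KO_LINES)],
        var_name="cell_line",
        value_name="viability_pct",
    )
    long["cell_line"] = long["cell_line"].str.removeprefix("viability_")
    return long[["cell_line", "drug", "viability_pct"]]


def load_t24_ec50_table() -> pd.DataFrame:
    """Mean ± SEM EC50s (µM) per drug x cell line from triplicate experiments."""
    return _read("t24_ec50_means.csv")
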