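"""384-well plate coordinate helpers.

Wells are labelled row-letter + 1-based column number ("A1" .. "P24").
Internal indices are 0-based (row, column) tuples.
"""

from __future__ import annotations

import re

N_ROWS = 16
N_COLS = 24
ROW_LETTERS = "ABCDEFGHIJKLMNOP"

_WELL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")


def well_to_indices(label: str) -> tuple[int, int]:
    """Convert a well label like ``"B07"`` or ``"B7"`` to 0-based (row, col)."""
    m = _WELL_RE.match(label.strip())
    if m is None:
        raise ValueError(f"not a valid 384-well label: {label!r}")
    row = ROW_LETTERS.index(m.group(1).upper())
    col = int(m.group(2)) - 1
    if not 0 <= col < N_COLS:
        raise ValueError(f"column out of range in well label {label!r}")
    return row, col


def indices_to_well(row: int, col: int) -> str:
    """Convert 0-based (row, col) to a serialized well label with 1-based column."""
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise ValueError(f"indices out of range for a 384-well plate: {(row, col)}")
    return f"{ROW_LETTERS[row]}{col + 1}"
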