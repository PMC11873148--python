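"""Within-plate viability normalization for resazurin plate-reader exports.

A plate carries three well roles:

* ``background`` — media-only wells defining the 0 % fluorescence level,
* ``untreated`` — cells without drug defining the 100 % level,
* ``treated`` — cells plus a drug at a known dose.

For each treated well the normalized viability is::

    viability (%) = (reading - mean(background)) / (mean(untreated) - mean(background)) * 100

Means are arithmetic means over all wells of that role on the *same* physical
plate; cross-plate pooling is not performed.  Values below 0 % or above 100 %
are reported as computed — clipping would bias downstream control-vs-knockout
deltas.

Input schema (long-format CSV, one row per well)::

    plate_id,well,role,cell_line,drug,dose_uM,fluorescence

Output schema::

    cell_line,drug,dose_uM,viability_pct,plate_id,replicate
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DegeneratePlateError, PlateConfigurationError, SchemaError

logger = logging.getLogger(__name__)

ROLES = ("background", "untreated", "treated")

READING_COLUMNS = ["plate_id", "well", "role", "cell_line", "drug", "dose_uM", "fluorescence"]
VIABILITY_COLUMNS = ["cell_line", "drug", "dose_uM", "viability_pct", "plate_id", "replicate"]


def _check_readings(readings: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in READING_COLUMNS if c not in readings.columns]
    if missing:
        raise SchemaError(f"plate readings missing columns: {missing}")
    bad_roles = set(readings["role"]) - set(ROLES)
    if bad_roles:
        raise SchemaError(f"unknown well roles: {sorted(bad_roles)}")
    fl = readings["fluorescence"].to_numpy(dtype=float)
    if not np.all(np.isfinite(fl)):
        raise SchemaError("non-finite fluorescence readings present")
    if (fl < 0).any():
        raise SchemaError("negative fluorescence readings present")
    treated = readings["role"] == "treated"
    drug = readings["drug"].fillna("").astype(str)
    if (treated & (drug == "")).any():
        raise SchemaError("treated wells must carry a drug identifier")
    if (~treated & (drug != "")).any():
        raise SchemaError("only treated wells may carry a drug identifier")
    return readings


def normalize_plate(readings: pd.DataFrame, *, replicate: int = 1) -> pd.DataFrame:
    """Normalize the treated wells of one plate to percent viability.

    Parameters
    ----------
    readings
        Long-format table of every well on a single plate
        (columns :data:`READING_COLUMNS`).
    replicate
        Replicate index recorded in the output (≥ 1).

    Returns
    -------
    DataFrame with columns :data:`VIABILITY_COLUMNS`, one row per treated well.

    Raises
    ------
    PlateConfigurationError
        If the plate lacks background or untreated wells.
    DegeneratePlateError
        If the background and untreated means coincide.
    """
    readings = _check_readings(readings)
    plate_ids = readings["plate_id"].unique()
    if len(plate_ids) != 1:
        raise PlateConfigurationError(
            f"normalize_plate expects a single plate, got {sorted(map(str, plate_ids))}"
        )
    plate_id = plate_ids[0]

    by_role = {role: readings.loc[readings["role"] == role, "fluorescence"] for role in ROLES}
    for role in ("background", "untreated"):
        if by_role[role].empty:
            raise PlateConfigurationError(f"plate {plate_id!r} has no {role} wells")

    bg = float(by_role["background"].mean())
    unt = float(by_role["untreated"].mean())
    if np.isclose(bg, unt, rtol=0.0, atol=1e-12 * max(1.0, abs(unt))):
        raise DegeneratePlateError(
            f"plate {plate_id!r}: background mean ({bg:g}) equals untreated mean ({unt:g})"
        )
    logger.info("plate %s: background mean %.4g, untreated mean %.4g", plate_id, bg, unt)

    treated = readings.loc[readings["role"] == "treated"]
    viability = (treated["fluorescence"].to_numpy(dtype=float) - bg) / (unt - bg) * 100.0
    return pd.DataFrame(
        {
            "cell_line": treated["cell_line"].to_numpy(),
            "drug": treated["drug"].to_numpy(),
            "dose_uM": treated["dose_uM"].to_numpy(dtype=float),
            "viability_pct": viability,
            "plate_id": plate_id,
            "replicate": int(replicate),
        }
    )


def normalize_plates(readings: pd.DataFrame, *, replicate_of: dict | None = None) -> pd.DataFrame:
    """Normalize a multi-plate export, plate by plate.

    ``replicate_of`` optionally maps plate_id -> replicate index; plates
    default to replicate 1.
    """
    frames = []
    for plate_id, plate in readings.groupby("plate_id", sort=False):
        rep = 1 if replicate_of is None else replicate_of.get(plate_id, 1)
        frames.append(normalize_plate(plate, replicate=rep))
    if not frames:
        raise PlateConfigurationError("no plates in input")
    return pd.concat(frames, ignore_index=True)


def aggregate_screen(records: pd.DataFrame) -> pd.DataFrame:
    """Average replicate wells of a single-dose screen per cell line x drug.

    All records must share one dose (the screen is run at a fixed
    concentration).  Returns a table with columns
    ``cell_line, drug, dose_uM, viability_pct, n_wells``.
    """
    doses = records["dose_uM"].to_numpy(dtype=float)
    if len(records) == 0:
        raise SchemaError("empty viability table")
    if not np.allclose(doses, doses[0], rtol=0.0, atol=0.0):
        raise SchemaError(f"aggregate_screen requires a single dose, got {sorted(set(doses))}")
    grouped = (
        records.groupby(["cell_line", "drug"], sort=False)
        .agg(viability_pct=("viability_pct", "mean"), n_wells=("viability_pct", "size"))
        .reset_index()
    )
    grouped.insert(2, "dose_uM", doses[0])
    return grouped


def read_plate_csv(path) -> pd.DataFrame:
    """Read a long-format plate export (UTF-8, '.' decimal separator)."""
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "role": str,
                                  "cell_line": str, "drug": str})
    if "drug" in df.columns:
        df["drug"] = df["drug"].fillna("")
    return _check_readings(df)


def write_viability_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, columns=VIABILITY_COLUMNS)
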