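"""Differential hit calling between a control line and knockout lines.

The screen compares replicate-averaged percent viability of each drug in a
control cell line against one or more isogenic knockout (KO) lines.  For each
KO line the delta is ``KO - control`` on the percent scale.  A drug is a

* **sensitizer** hit if any KO delta is below ``-threshold`` (the drug kills
  the KO line harder than the control), and a
* **protector** hit if any KO delta is above ``+threshold`` (the KO line is
  spared relative to control).

The comparison is strict, labels are not mutually exclusive (different KO
clones may disagree, and such drugs legitimately carry both labels), and
deltas are kept at full precision — rounding happens only in reports.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DesignError, SchemaError

logger = logging.getLogger(__name__)

SENSITIZER = "sensitizer"
PROTECTOR = "protector"
LABELS = (SENSITIZER, PROTECTOR)


def compute_deltas(
    screen_table: pd.DataFrame,
    control_line: str,
    ko_lines: Iterable[str],
) -> pd.DataFrame:
    """Pivot a screen table to one row per drug with control/KO viability deltas.

    Parameters
    ----------
    screen_table
        Long table with columns ``cell_line, drug, viability_pct`` (typically
        :func:`drugscreen.plates.aggregate_screen` output).
    control_line, ko_lines
        Which cell line is the control and which are compared against it.

    Returns
    -------
    Wide DataFrame indexed by drug with columns ``viability_<line>`` for the
    control and every KO line, ``delta_<ko>`` for every KO line, and an
    ``error`` column naming drugs with a missing control value (their deltas
    are NaN rather than silently dropped).
    """
    ko_lines = list(ko_lines)
    if not ko_lines:
        raise DesignError("at least one KO line is required")
    for col in ("cell_line", "drug", "viability_pct"):
        if col not in screen_table.columns:
            raise SchemaError(f"screen table missing column {col!r}")

    wide = screen_table.pivot_table(
        index="drug", columns="cell_line", values="viability_pct", aggfunc="mean"
    )
    for line in [control_line, *ko_lines]:
        if line not in wide.columns:
            wide[line] = np.nan

    out = pd.DataFrame(index=wide.index)
    out[f"viability_{control_line}"] = wide[control_line]
    for ko in ko_lines:
        out[f"viability_{ko}"] = wide[ko]
    for ko in ko_lines:
        out[f"delta_{ko}"] = wide[ko] - wide[control_line]
    missing_control = wide[control_line].isna()
    out["error"] = np.where(missing_control, "missing control viability", "")
    if missing_control.any():
        logger.warning(
            "%d drugs missing a control viability: %s",
            int(missing_control.sum()),
            list(out.index[missing_control])[:10],
        )
    out.attrs["control_line"] = control_line
    out.attrs["ko_lines"] = ko_lines
    return out


def classify_hits(records: pd.DataFrame, threshold: float = 9.0) -> pd.DataFrame:
    """Attach sensitizer/protector labels to :func:`compute_deltas` output.

    A KO line provides sensitizer evidence when its delta is strictly below
    ``-threshold`` and protector evidence when strictly above ``+threshold``.
    Adds boolean ``sensitizer``/``protector`` columns, a ``labels`` column
    (comma-joined), and per-label ``<label>_lines`` columns listing the KO
    lines providing the evidence.
    """
    if threshold <= 0:
        raise DesignError(f"threshold must be positive, got {threshold}")
    ko_lines = records.attrs.get("ko_lines")
    if ko_lines is None:
        ko_lines = [c[len("delta_"):] for c in records.columns if c.startswith("delta_")]

    out = records.copy()
    deltas = np.column_stack([records[f"delta_{ko}"].to_numpy(dtype=float) for ko in ko_lines])
    sens = deltas < -threshold
    prot = deltas > threshold
    out[SENSITIZER] = sens.any(axis=1)
    out[PROTECTOR] = prot.any(axis=1)

    def _lines(mask_row):
        return ",".join(ko for ko, m in zip(ko_lines, mask_row) if m)

    out[f"{SENSITIZER}_lines"] = [_lines(row) for row in sens]
    out[f"{PROTECTOR}_lines"] = [_lines(row) for row in prot]
    out["labels"] = [
        ",".join(lab for lab, flag in zip(LABELS, flags) if flag)
        for flags in zip(out[SENSITIZER], out[PROTECTOR])
    ]
    out.attrs.update(records.attrs)
    out.attrs["threshold"] = float(threshold)
    return out


def summarize_hits(records: pd.DataFrame) -> dict:
    """Count labelled drugs per category (a dual-labelled drug counts in both)."""
    n_sens = int(records[SENSITIZER].sum()) if SENSITIZER in records else 0
    n_prot = int(records[PROTECTOR].sum()) if PROTECTOR in records else 0
    return {
        SENSITIZER: n_sens,
        PROTECTOR: n_prot,
        "total_labels": n_sens + n_prot,
        "n_drugs": int(len(records)),
    }


def target_enrichment(
    records: pd.DataFrame,
    annotation: pd.DataFrame | Mapping[str, Iterable[str]],
    category: str,
) -> pd.DataFrame:
    """Tally, per target molecule, how many library drugs hit in a category.

    Parameters
    ----------
    records
        Classified hit table (:func:`classify_hits` output).
    annotation
        Either a DataFrame with columns ``drug, target`` (one row per pair)
        covering the *whole* screened library, or a mapping drug -> targets.
        A drug annotated to several targets counts once per target.
    category
        ``"sensitizer"`` or ``"protector"``.

    Returns
    -------
    DataFrame with columns ``target, category, n_hits, n_library, pct`` where
    ``pct = 100 * n_hits / n_library``.  Hit drugs absent from the annotation
    are excluded from numerators, logged, and listed in ``.attrs["unannotated"]``.
    """
    if category not in LABELS:
        raise DesignError(f"category must be one of {LABELS}, got {category!r}")
    if isinstance(annotation, Mapping):
        annotation = pd.DataFrame(
            [(d, t) for d, targets in annotation.items() for t in targets],
            columns=["drug", "target"],
        )
    for col in ("drug", "target"):
        if col not in annotation.columns:
            raise SchemaError(f"annotation missing column {col!r}")

    hit_drugs = set(records.index[records[category]])
    unannotated = sorted(hit_drugs - set(annotation["drug"]))
    if unannotated:
        logger.warning("hit drugs missing from annotation (excluded): %s", unannotated)

    lib = annotation.groupby("target")["drug"].nunique().rename("n_library")
    hits = (
        annotation[annotation["drug"].isin(hit_drugs)]
        .groupby("target")["drug"]
        .nunique()
        .rename("n_hits")
    )
    out = pd.concat([hits, lib], axis=1).fillna({"n_hits": 0}).reset_index()
    out["n_hits"] = out["n_hits"].astype(int)
    out["pct"] = 100.0 * out["n_hits"] / out["n_library"]
    out.insert(1, "category", category)
    out = out.sort_values(["n_hits", "target"], ascending=[False, True], ignore_index=True)
    out.attrs["unannotated"] = unannotated
    return out
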