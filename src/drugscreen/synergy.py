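"""ZIP (zero-interaction potency) scoring of dose-combination matrices.

A combination experiment measures percent viability on a rectangular grid of
doses of drug A x drug B, each axis including dose 0, so row 0 and column 0
are the two monotherapy series and cell (0, 0) is untreated.  Analysis runs
on fractional inhibition ``y = 1 - viability / 100``.

The ZIP reference surface assumes the two drugs act independently (Bliss
independence) through their own potency curves: log-logistic inhibition
curves ``y_a(d)``, ``y_b(d)`` rising from 0 are fitted to the two margins and
the zero-interaction expectation at a dose pair is
``y_zip = y_a + y_b - y_a * y_b``.  The synergy score at each nonzero dose
pair is::

    delta = (y_observed - y_zip) * 100        [percentage points]

Positive delta means the combination inhibits more than independence
predicts (synergy); negative means antagonism.  The maximum synergy score of
a matrix is the 100 % quantile of its delta surface.

Two observed-effect estimators are available.  The default, ``"raw"``,
evaluates the observed inhibition directly at each cell, so localized
interactions are preserved cell-for-cell.  ``"conditional"`` is the
classical smoothed ZIP surface: for each row/column the potency-shifted
log-logistic curve (floor fixed at the partner's fitted monotherapy effect)
is refitted and the two fitted values are averaged; monotone conditional
curves necessarily smooth single-cell interactions toward their neighbours.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DesignError, SchemaError

logger = logging.getLogger(__name__)

QUANTILES = (0, 25, 50, 75, 100)
HILL_BOUNDS = (0.1, 10.0)


@dataclass
class SynergyMatrix:
    """A complete dose-combination viability grid for one cell line."""

    drug_a: str
    drug_b: str
    doses_a: np.ndarray  # sorted ascending, first entry 0
    doses_b: np.ndarray
    viability: np.ndarray  # shape (len(doses_a), len(doses_b)), percent scale
    cell_line: str = ""
    replicate: int = 1

    @property
    def inhibition(self) -> np.ndarray:
        """Raw fractional inhibition, unclamped."""
        return 1.0 - self.viability / 100.0

    def transposed(self) -> "SynergyMatrix":
        return SynergyMatrix(
            drug_a=self.drug_b, drug_b=self.drug_a,
            doses_a=self.doses_b.copy(), doses_b=self.doses_a.copy(),
            viability=self.viability.T.copy(),
            cell_line=self.cell_line, replicate=self.replicate,
        )


@dataclass
class ZipSurface:
    """Per-cell ZIP delta scores over the nonzero dose pairs of a matrix."""

    doses_a: np.ndarray  # nonzero doses only
    doses_b: np.ndarray
    delta: np.ndarray  # percentage points, shape (len(doses_a), len(doses_b))
    expected: np.ndarray
    observed: np.ndarray
    quantiles: dict = field(default_factory=dict)

    @property
    def max_score(self) -> float:
        return float(np.max(self.delta))

    def at_dose(self, dose_a: float, dose_b: float) -> float:
        """Delta at a named dose pair (must be grid doses)."""
        ia = _dose_index(self.doses_a, dose_a, "drug A")
        ib = _dose_index(self.doses_b, dose_b, "drug B")
        return float(self.delta[ia, ib])


def _dose_index(doses: np.ndarray, dose: float, axis: str) -> int:
    idx = np.nonzero(np.isclose(doses, dose, rtol=1e-6, atol=0.0))[0]
    if len(idx) == 0:
        raise DesignError(f"dose {dose:g} not on the {axis} axis: {list(doses)}")
    return int(idx[0])


def validate_matrix(records: pd.DataFrame) -> SynergyMatrix:
    """Assemble and check a rectangular combination matrix from long records.

    Expects columns ``drug_a, dose_a_uM, drug_b, dose_b_uM, viability_pct``
    (plus optional ``cell_line``/``replicate``).  Duplicate cells are averaged
    with a warning; missing cells are an error naming every hole.
    """
    needed = ["drug_a", "dose_a_uM", "drug_b", "dose_b_uM", "viability_pct"]
    for col in needed:
        if col not in records.columns:
            raise SchemaError(f"synergy records missing column {col!r}")
    drugs_a = records["drug_a"].unique()
    drugs_b = records["drug_b"].unique()
    if len(drugs_a) != 1 or len(drugs_b) != 1:
        raise SchemaError("validate_matrix expects a single drug pair")
    lines = records["cell_line"].unique() if "cell_line" in records else [""]
    if len(lines) != 1:
        raise SchemaError("validate_matrix expects a single cell line")

    dup = records.duplicated(subset=["dose_a_uM", "dose_b_uM"], keep=False)
    if dup.any():
        warnings.warn("duplicate dose pairs averaged", stacklevel=2)
    grid = records.pivot_table(index="dose_a_uM", columns="dose_b_uM",
                               values="viability_pct", aggfunc="mean")
    grid = grid.sort_index().sort_index(axis=1)
    if grid.isna().any().any():
        holes = [(float(grid.index[i]), float(grid.columns[j]))
                 for i, j in zip(*np.nonzero(grid.isna().to_numpy()))]
        raise SchemaError(f"incomplete matrix, missing cells (dose_a, dose_b): {holes}")
    doses_a = grid.index.to_numpy(dtype=float)
    doses_b = grid.columns.to_numpy(dtype=float)
    if doses_a[0] != 0 or doses_b[0] != 0:
        raise SchemaError("both dose axes must include 0 (monotherapy margins)")
    rep = int(records["replicate"].iloc[0]) if "replicate" in records else 1
    return SynergyMatrix(
        drug_a=str(drugs_a[0]), drug_b=str(drugs_b[0]),
        doses_a=doses_a, doses_b=doses_b,
        viability=grid.to_numpy(dtype=float),
        cell_line=str(lines[0]), replicate=rep,
    )


# ---------------------------------------------------------------------------
# marginal and conditional potency curves (inhibition scale, baseline floor)


def _loglogistic_w(d: np.ndarray, log_m: float, lam: float) -> np.ndarray:
    """Rising weight (d/m)^lam / (1 + (d/m)^lam); 0 at d = 0."""
    w = np.zeros_like(d, dtype=float)
    pos = d > 0
    z = lam * (np.log(d[pos]) - log_m)
    w[pos] = 1.0 / (1.0 + np.exp(np.clip(-z, -700, 700)))
    return w


def _fit_floor_curve(doses: np.ndarray, y: np.ndarray, floor: float,
                     ceiling_max: float = 1.0) -> tuple:
    """Fit y ~ floor + (c - floor) * w(d; m, lam) with c in [floor, ceiling_max].

    The dose-0 point(s) pin the floor; c solves analytically per (m, lam)
    grid node, then the best nodes are refined.  Returns (c, log_m, lam).
    """
    d = np.asarray(doses, dtype=float)
    y = np.clip(np.asarray(y, dtype=float), 0.0, 1.0)
    pos = d > 0
    if pos.sum() == 0:
        raise DesignError("no nonzero doses on margin")
    log_ms = np.linspace(np.log(d[pos].min() / 100.0), np.log(d[pos].max() * 100.0), 50)
    lams = np.geomspace(*HILL_BOUNDS, 12)
    best = None
    for lam in lams:
        for log_m in log_ms:
            w = _loglogistic_w(d, log_m, lam)
            denom = float(w @ w)
            if denom <= 0:
                continue
            amp = float(w @ (y - floor)) / denom  # c - floor
            amp = float(np.clip(amp, 0.0, ceiling_max - floor))
            resid = y - floor - amp * w
            sse = float(resid @ resid)
            if best is None or sse < best[0]:
                best = (sse, floor + amp, log_m, lam)
    _, c0, log_m0, lam0 = best

    if pos.sum() >= 3:
        def residuals(theta):
            c, log_m, lam = theta
            return floor + (c - floor) * _loglogistic_w(d, log_m, lam) - y
        try:
            res = optimize.least_squares(
                residuals, [c0, log_m0, lam0],
                bounds=([floor, log_ms[0], HILL_BOUNDS[0]],
                        [ceiling_max, log_ms[-1], HILL_BOUNDS[1]]),
                xtol=1e-12, ftol=1e-12)
            if float(res.fun @ res.fun) <= best[0]:
                return tuple(res.x)
        except Exception:  # pragma: no cover
            pass
    return c0, log_m0, lam0


def _margin_inhibition(doses: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fitted monotherapy inhibition at each nonzero dose of a margin.

    Falls back to the raw (clamped) margin values when the margin has too few
    points to fit or the fit fails.
    """
    pos = doses > 0
    try:
        if pos.sum() < 3:
            raise DesignError("margin too short to fit")
        c, log_m, lam = _fit_floor_curve(doses, y, floor=0.0)
        return c * _loglogistic_w(doses[pos], log_m, lam)
    except Exception:
        logger.warning("monotherapy margin unfittable; using raw margin values")
        return np.clip(y[pos], 0.0, 1.0)


def zip_delta(matrix: SynergyMatrix, observed: str = "raw") -> ZipSurface:
    """Score a validated combination matrix with the ZIP model.

    Parameters
    ----------
    matrix
        Output of :func:`validate_matrix` (axes include dose 0).
    observed
        ``"raw"`` (default) scores each cell against its own measured
        inhibition; ``"conditional"`` uses the classical averaged
        conditional-curve fits (smoothed surface).
    """
    if observed not in ("raw", "conditional"):
        raise ValueError(f"observed must be 'raw' or 'conditional', got {observed!r}")
    inh = matrix.inhibition
    da, db = matrix.doses_a, matrix.doses_b
    pos_a, pos_b = da > 0, db > 0

    y_a = _margin_inhibition(da, inh[:, 0])  # drug A alone, at nonzero da
    y_b = _margin_inhibition(db, inh[0, :])
    expected = y_a[:, None] + y_b[None, :] - y_a[:, None] * y_b[None, :]

    if observed == "raw":
        obs = inh[np.ix_(pos_a, pos_b)]
    else:
        obs = _conditional_surface(matrix, y_a, y_b)

    delta = (obs - expected) * 100.0
    quants = {q: float(np.percentile(delta, q)) for q in QUANTILES}
    return ZipSurface(doses_a=da[pos_a].copy(), doses_b=db[pos_b].copy(),
                      delta=delta, expected=expected, observed=obs, quantiles=quants)


def _conditional_surface(matrix: SynergyMatrix, y_a: np.ndarray, y_b: np.ndarray) -> np.ndarray:
    """Average of the two potency-shifted conditional fits at each cell."""
    inh = matrix.inhibition
    da, db = matrix.doses_a, matrix.doses_b
    pos_a, pos_b = da > 0, db > 0
    na, nb = pos_a.sum(), pos_b.sum()

    by_col = np.empty((na, nb))
    for j, jb in enumerate(np.nonzero(pos_b)[0]):
        floor = float(y_b[j])
        try:
            c, log_m, lam = _fit_floor_curve(da, np.clip(inh[:, jb], 0, 1), floor=floor)
            by_col[:, j] = floor + (c - floor) * _loglogistic_w(da[pos_a], log_m, lam)
        except Exception:
            logger.warning("conditional fit failed for column %d; using raw values", j)
            by_col[:, j] = np.clip(inh[pos_a, jb], 0, 1)
    by_row = np.empty((na, nb))
    for i, ia in enumerate(np.nonzero(pos_a)[0]):
        floor = float(y_a[i])
        try:
            c, log_m, lam = _fit_floor_curve(db, np.clip(inh[ia, :], 0, 1), floor=floor)
            by_row[i, :] = floor + (c - floor) * _loglogistic_w(db[pos_b], log_m, lam)
        except Exception:
            logger.warning("conditional fit failed for row %d; using raw values", i)
            by_row[i, :] = np.clip(inh[ia, pos_b], 0, 1)
    return 0.5 * (by_col + by_row)


# ---------------------------------------------------------------------------
# cross-line and cross-combination summaries


def synergy_ratio(max_scores: Mapping[str, float], control_line: str) -> dict:
    """Each line's maximum synergy score divided by the control line's."""
    if control_line not in max_scores:
        raise DesignError(f"control line {control_line!r} absent")
    ctrl = float(max_scores[control_line])
    if ctrl == 0:
        raise DesignError("control maximum synergy score is zero; ratio undefined")
    return {line: float(s) / ctrl for line, s in max_scores.items()}


def at_dose_ratio(surfaces: Mapping[str, ZipSurface], dose_pair: tuple[float, float],
                  control_line: str) -> dict:
    """Per-line ratio of the delta score at a named (dose_a, dose_b) pair."""
    if control_line not in surfaces:
        raise DesignError(f"control line {control_line!r} absent")
    scores = {line: s.at_dose(*dose_pair) for line, s in surfaces.items()}
    ctrl = scores[control_line]
    if ctrl == 0:
        raise DesignError("control score at this dose pair is zero; ratio undefined")
    return {line: s / ctrl for line, s in scores.items()}


def pool_max_scores(scores: pd.DataFrame) -> dict:
    """Compare pooled per-cell-line maximum synergy scores across combinations.

    ``scores`` has columns ``combination, cell_line, max_score``; each
    combination pools its cell lines.  With >=2 observations per combination
    a one-way ANOVA plus Tukey-adjusted pairwise comparisons is run;
    otherwise only descriptive summaries are returned.
    """
    for col in ("combination", "cell_line", "max_score"):
        if col not in scores.columns:
            raise SchemaError(f"scores table missing column {col!r}")
    groups = {comb: grp["max_score"].to_numpy(dtype=float)
              for comb, grp in scores.groupby("combination", sort=False)}
    report: dict = {
        "means": {k: float(np.mean(g)) for k, g in groups.items()},
        "n": {k: int(len(g)) for k, g in groups.items()},
        "comparisons": [],
    }
    if len(groups) < 2:
        raise DesignError("need >=2 combinations to compare")
    if min(len(g) for g in groups.values()) < 2:
        logger.warning("a combination has a single observation: descriptive only")
        report["design"] = "descriptive"
        return report
    f, p = stats.f_oneway(*groups.values())
    report["design"] = "anova+tukey"
    report["anova"] = {"F": float(f), "p": float(p)}
    tuk = pairwise_tukeyhsd(scores["max_score"].to_numpy(dtype=float),
                            scores["combination"].to_numpy())
    for row, padj, diff in zip(tuk._results_table.data[1:], tuk.pvalues, tuk.meandiffs):
        report["comparisons"].append(
            {"a": str(row[0]), "b": str(row[1]),
             "mean_diff": float(diff), "p_adjusted": float(padj)}
        )
    return report
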