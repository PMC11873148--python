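"""Four-parameter log-logistic (4PL) dose-response fitting and EC50 ratios.

The model for percent viability v at dose d (µM) is::

    v(d) = lower + (upper - lower) / (1 + (d / ec50)^hill)

In canonical form ``lower <= upper``; ``hill > 0`` means viability falls with
dose (the cytotoxicity convention) and ``hill < 0`` means it rises.  ``ec50``
is the *relative* EC50: the dose at which the fitted curve sits midway between
its own asymptotes.  The absolute EC50 (dose where the curve crosses 50 %
viability) is available as a secondary output.

Fitting is least squares with a dense internal grid over (log ec50, hill) —
the two asymptotes solve analytically for any fixed pair — followed by local
refinement from the best grid candidates.  Standard errors come from the
local curvature (Gauss-Newton covariance) at the optimum.

Potencies are compared across cell lines as EC50 ratios: each line's EC50
divided by the average EC50 of the control line(s), so the control pools to
1 by construction and a ratio > 1 means *less* sensitive than control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DesignError, SchemaError

logger = logging.getLogger(__name__)

HILL_BOUNDS = (0.1, 10.0)
EC50_DOSE_MARGIN = 100.0  # ec50 searched within [min dose / 100, max dose * 100]
GRID_N_EC50 = 60
GRID_N_HILL = 15
N_REFINE = 3


@dataclass
class DoseResponseFit:
    """One fitted 4PL curve for a cell line x drug series."""

    lower: float
    upper: float
    ec50: float
    hill: float
    residual_sse: float
    se: dict = field(default_factory=dict)
    n_points: int = 0
    converged: bool = False
    ec50_reliable: bool = True
    cell_line: str = ""
    drug: str = ""

    def predict(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        return four_pl(dose, self.lower, self.upper, self.ec50, self.hill)


def four_pl(dose, lower, upper, ec50, hill):
    """Evaluate the 4PL curve; dose 0 maps to the d -> 0 limit."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(dose > 0, dose / ec50, 0.0)
        powed = np.where(dose > 0, np.exp(hill * np.log(np.maximum(ratio, 1e-300))), 0.0)
        w = 1.0 / (1.0 + powed)
    # d -> 0: hill > 0 gives w = 1 (upper); hill < 0 gives w = 0 (lower)
    w = np.where(dose > 0, w, 1.0 if hill > 0 else 0.0)
    return lower + (upper - lower) * w


def _solve_asymptotes(w: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    """Closed-form least squares for (lower, upper) given weights w in [0, 1].

    v ~ lower * (1 - w) + upper * w.  Returns (lower, upper, sse).
    """
    a = 1.0 - w
    s_aa = float(a @ a)
    s_ab = float(a @ w)
    s_bb = float(w @ w)
    s_av = float(a @ v)
    s_bv = float(w @ v)
    det = s_aa * s_bb - s_ab * s_ab
    if det <= 1e-12 * max(s_aa * s_bb, 1e-300):
        # w nearly constant: model degenerates to a flat line at mean(v)
        mu = float(np.mean(v))
        resid = v - mu
        return mu, mu, float(resid @ resid)
    lower = (s_av * s_bb - s_bv * s_ab) / det
    upper = (s_bv * s_aa - s_av * s_ab) / det
    resid = v - (lower * a + upper * w)
    return lower, upper, float(resid @ resid)


def _grid_search(log_d: np.ndarray, v: np.ndarray,
                 log_e_bounds: tuple[float, float],
                 n_ec50: int = GRID_N_EC50, n_hill: int = GRID_N_HILL) -> list[tuple]:
    """Profile SSE over a (log ec50, hill) grid with analytic asymptotes.

    Returns grid candidates sorted by SSE as tuples
    (sse, lower, upper, log_e, hill).
    """
    log_es = np.linspace(*log_e_bounds, n_ec50)
    hills = np.geomspace(*HILL_BOUNDS, n_hill)
    out = []
    for h in hills:
        # w matrix: n_ec50 x n_points, w = 1 / (1 + exp(h * (log d - log e)))
        z = h * (log_d[None, :] - log_es[:, None])
        w = 1.0 / (1.0 + np.exp(np.clip(z, -700, 700)))
        for i, log_e in enumerate(log_es):
            lower, upper, sse = _solve_asymptotes(w[i], v)
            out.append((sse, lower, upper, log_e, h))
    out.sort(key=lambda t: t[0])
    return out


def fit_4pl(
    doses: Sequence[float],
    viabilities: Sequence[float],
    *,
    cell_line: str = "",
    drug: str = "",
) -> DoseResponseFit:
    """Least-squares 4PL fit of percent viability against dose.

    Requires at least 5 distinct positive doses and finite viabilities
    (replicate wells simply appear as repeated doses).  Monotone-flat data is
    not an error: the fit is returned with ``ec50_reliable=False``.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if d.shape != v.shape:
        raise SchemaError("doses and viabilities must have equal length")
    if not np.all(np.isfinite(v)):
        raise SchemaError("non-finite viabilities")
    if np.any(d <= 0):
        raise DesignError("doses must be strictly positive (omit untreated wells)")
    if len(np.unique(d)) < 5:
        raise DesignError(f"need >=5 distinct doses, got {len(np.unique(d))}")

    log_d = np.log(d)
    log_e_bounds = (float(np.log(d.min() / EC50_DOSE_MARGIN)),
                    float(np.log(d.max() * EC50_DOSE_MARGIN)))
    candidates = _grid_search(log_d, v, log_e_bounds)

    def residuals(theta):
        lower, upper, log_e, h = theta
        w = 1.0 / (1.0 + np.exp(np.clip(h * (log_d - log_e), -700, 700)))
        return lower + (upper - lower) * w - v

    lo = [-np.inf, -np.inf, log_e_bounds[0], HILL_BOUNDS[0]]
    hi = [np.inf, np.inf, log_e_bounds[1], HILL_BOUNDS[1]]
    best = None
    best_res = None
    for sse, lower, upper, log_e, h in candidates[:N_REFINE]:
        x0 = np.array([lower, upper,
                       np.clip(log_e, lo[2] + 1e-9, hi[2] - 1e-9),
                       np.clip(h, HILL_BOUNDS[0], HILL_BOUNDS[1])])
        try:
            res = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                         xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        r_sse = float(res.fun @ res.fun)
        if best is None or r_sse < best[0]:
            best = (r_sse, *res.x)
            best_res = res
    # guard: keep whichever of refined/grid is better
    if best is None or candidates[0][0] < best[0]:
        sse, lower, upper, log_e, h = candidates[0]
        best = (sse, lower, upper, log_e, h)
        best_res = None

    sse, lower, upper, log_e, h = best
    ec50 = float(np.exp(log_e))
    n = len(v)

    # standard errors from Gauss-Newton curvature at the optimum
    se = {}
    converged = best_res is not None and bool(best_res.success)
    if best_res is not None and n > 4:
        J = best_res.jac
        try:
            cov = np.linalg.inv(J.T @ J) * (sse / max(n - 4, 1))
            sds = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
            se = {"lower": sds[0], "upper": sds[1],
                  "ec50": ec50 * sds[2], "hill": sds[3]}
        except np.linalg.LinAlgError:
            converged = False

    # canonical form: lower <= upper, hill sign encodes direction
    if lower > upper:
        lower, upper = upper, lower
        h = -h
        if se:
            se["lower"], se["upper"] = se["upper"], se["lower"]

    # reliability: a dose effect must actually be detectable
    sse_const = float(np.sum((v - v.mean()) ** 2))
    span = upper - lower
    reliable = span > 1e-8 and (sse_const - sse) > 0.01 * max(sse_const, 1e-12)
    if not reliable:
        logger.warning("flat dose-response for %s/%s: ec50 flagged unreliable",
                       cell_line or "?", drug or "?")

    return DoseResponseFit(
        lower=float(lower), upper=float(upper), ec50=ec50, hill=float(h),
        residual_sse=float(sse), se=se, n_points=n, converged=converged,
        ec50_reliable=bool(reliable), cell_line=cell_line, drug=drug,
    )


def ec50(fit: DoseResponseFit, kind: str = "relative") -> float:
    """EC50 of a fitted curve.

    ``kind="relative"`` (default) is the dose at the asymptote midpoint and
    equals the ``ec50`` parameter in this parameterization.  ``kind="absolute"``
    is the dose where the fitted curve crosses 50 % viability (NaN when 50 %
    lies outside the asymptote range).
    """
    if not fit.ec50_reliable:
        logger.warning("EC50 requested from an unreliable fit (%s/%s)", fit.cell_line, fit.drug)
    if kind == "relative":
        return fit.ec50
    if kind != "absolute":
        raise ValueError(f"kind must be 'relative' or 'absolute', got {kind!r}")
    span = fit.upper - fit.lower
    if span <= 0:
        return float("nan")
    w = (50.0 - fit.lower) / span
    if not 0.0 < w < 1.0:
        return float("nan")
    return float(fit.ec50 * (1.0 / w - 1.0) ** (1.0 / fit.hill))


def fit_many(records: pd.DataFrame, drug: str | None = None) -> list[DoseResponseFit]:
    """Fit one 4PL per cell line (x drug) from a long viability table."""
    df = records if drug is None else records[records["drug"] == drug]
    fits = []
    for (line, drg), grp in df.groupby(["cell_line", "drug"], sort=False):
        fits.append(fit_4pl(grp["dose_uM"], grp["viability_pct"], cell_line=line, drug=drg))
    return fits


def relative_ec50(
    ec50_table: pd.DataFrame,
    control_lines: str | Iterable[str],
) -> pd.DataFrame:
    """Control-normalized EC50 ratios, per replicate and pooled.

    Parameters
    ----------
    ec50_table
        Columns ``cell_line, replicate, ec50_uM`` (one fitted EC50 per line
        and independent experiment; a single row per line is fine).
    control_lines
        The control line(s) whose average EC50 is the denominator.

    Returns
    -------
    DataFrame ``cell_line, replicate, ratio`` containing the per-replicate
    ratios (line EC50 over the same-replicate control average) plus one
    ``replicate="pooled"`` row per line, defined as the ratio of
    replicate-mean EC50s.  The pooled control ratio is 1 by construction.
    """
    if isinstance(control_lines, str):
        control_lines = [control_lines]
    control_lines = list(control_lines)
    for col in ("cell_line", "replicate", "ec50_uM"):
        if col not in ec50_table.columns:
            raise SchemaError(f"ec50 table missing column {col!r}")
    present = set(ec50_table["cell_line"])
    missing = [c for c in control_lines if c not in present]
    if missing:
        raise DesignError(f"control line(s) missing from EC50 table: {missing}")
    if (ec50_table["ec50_uM"] <= 0).any():
        raise DesignError("EC50 values must be positive")

    rows = []
    for rep, grp in ec50_table.groupby("replicate", sort=False):
        ctrl = grp.loc[grp["cell_line"].isin(control_lines), "ec50_uM"].mean()
        if not np.isfinite(ctrl) or ctrl <= 0:
            raise DesignError(f"replicate {rep!r} lacks a usable control EC50")
        for _, r in grp.iterrows():
            rows.append({"cell_line": r["cell_line"], "replicate": rep,
                         "ratio": r["ec50_uM"] / ctrl})

    means = ec50_table.groupby("cell_line")["ec50_uM"].mean()
    ctrl_mean = means.loc[[c for c in control_lines]].mean()
    for line, m in means.items():
        rows.append({"cell_line": line, "replicate": "pooled", "ratio": m / ctrl_mean})
    return pd.DataFrame(rows)


def compare_ratios(ratios: pd.DataFrame, control_line: str) -> dict:
    """Test per-replicate EC50 ratios across cell lines.

    Two lines: two-tailed two-sample t-test.  Three or more: one-way ANOVA
    plus Dunnett many-to-one comparisons against ``control_line``.  With a
    single replicate per line only descriptive output is returned.
    """
    df = ratios[ratios["replicate"] != "pooled"]
    groups = {line: grp["ratio"].to_numpy(dtype=float)
              for line, grp in df.groupby("cell_line", sort=False)}
    if control_line not in groups:
        raise DesignError(f"control line {control_line!r} absent from ratios")
    report: dict = {
        "design": None,
        "means": {k: float(np.mean(g)) for k, g in groups.items()},
        "n": {k: int(len(g)) for k, g in groups.items()},
        "comparisons": [],
    }
    if min(len(g) for g in groups.values()) < 2:
        logger.warning("single replicate per line: statistical test skipped")
        report["design"] = "descriptive"
        return report

    others = [k for k in groups if k != control_line]
    if len(groups) == 2:
        report["design"] = "t-test"
        t, p = stats.ttest_ind(groups[others[0]], groups[control_line])
        report["comparisons"].append(
            {"line": others[0], "vs": control_line,
             "statistic": float(t), "p": float(p), "p_adjusted": float(p)}
        )
    else:
        report["design"] = "anova+dunnett"
        f, p = stats.f_oneway(*groups.values())
        report["anova"] = {"F": float(f), "p": float(p)}
        dun = stats.dunnett(*(groups[k] for k in others), control=groups[control_line])
        raw = [float(stats.ttest_ind(groups[k], groups[control_line]).pvalue) for k in others]
        for k, stat, padj, praw in zip(others, dun.statistic, dun.pvalue, raw):
            report["comparisons"].append(
                {"line": k, "vs": control_line, "statistic": float(stat),
                 "p": praw, "p_adjusted": float(padj)}
            )
    return report
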