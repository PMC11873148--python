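"""Biomarker-stratified drug-sensitivity comparison across a cell-line cohort.

A cohort of cell lines is split into biomarker-``high`` and ``low`` groups at
the median expression (TPM) of a marker gene.  Per-drug sensitivities are
log2 fold-changes of viability versus vehicle (more negative = more
sensitive).  Group comparisons use the two-sample Wilcoxon rank-sum test:
exact by enumeration for small tie-free samples, otherwise a normal
approximation with tie and continuity corrections.  Drugs can be pooled by
mechanism-of-action (MOA) label, and each expression group can be
sub-stratified by the mutation status of a second gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd

from .errors import DesignError, SchemaError

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12


def median_split(expression: pd.DataFrame, value_col: str = "tpm") -> pd.DataFrame:
    """Split a cohort into expression-high and -low groups at the median.

    ``expression`` has columns ``cell_line`` and ``tpm``.  Lines strictly
    below the median are ``low``, strictly above are ``high``; lines exactly
    at the median go to ``low`` (deterministic tie policy).  The median is
    reported in ``.attrs["median"]``.
    """
    for col in ("cell_line", value_col):
        if col not in expression.columns:
            raise SchemaError(f"expression table missing column {col!r}")
    vals = expression[value_col].to_numpy(dtype=float)
    if len(vals) < 2:
        raise DesignError("need >=2 cell lines to split")
    if not np.all(np.isfinite(vals)):
        raise SchemaError("non-finite expression values")
    med = float(np.median(vals))
    if np.all(vals == vals[0]):
        raise DesignError("all expression values identical; median split is degenerate")
    out = expression.copy()
    out["group"] = np.where(vals > med, "high", "low")
    out.attrs["median"] = med
    return out


@dataclass
class RankSumResult:
    statistic: float  # rank sum W of the first sample
    u: float  # Mann-Whitney U of the first sample
    pvalue: float
    method: str  # "exact" or "normal"
    n_a: int
    n_b: int


def rank_sum_test(values_a, values_b, alternative: str = "two-sided") -> RankSumResult:
    """Two-sample Wilcoxon rank-sum test.

    Exact null distribution by enumeration of all group assignments when the
    combined sample size is at most 12 and there are no ties; otherwise the
    normal approximation with tie correction and a 0.5 continuity correction.
    Only the two-sided alternative is implemented (the field's default).
    """
    if alternative != "two-sided":
        raise NotImplementedError("only the two-sided alternative is supported")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DesignError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    ranks = _midranks(pooled)
    w = float(ranks[:n_a].sum())
    u = w - n_a * (n_a + 1) / 2.0
    has_ties = len(np.unique(pooled)) < n

    if n <= EXACT_MAX_N and not has_ties:
        mu = n_a * (n + 1) / 2.0
        dev = abs(w - mu)
        count = 0
        for idx in combinations(range(n), n_a):
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
                count += 1
        p = count / comb(n, n_a)
        return RankSumResult(w, u, float(p), "exact", n_a, n_b)

    mu = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return RankSumResult(w, u, 1.0, "normal", n_a, n_b)
    z = max(abs(w - mu) - 0.5, 0.0) / sqrt(var)
    # two-sided p from the standard normal survival function
    p = min(1.0, 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0)))))
    return RankSumResult(w, u, float(p), "normal", n_a, n_b)


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def moa_compare(
    sensitivity: pd.DataFrame,
    cohort: pd.DataFrame,
    moa: pd.DataFrame,
    moa_label: str,
) -> dict:
    """Compare pooled sensitivities of a mechanism class between groups.

    Pools the log2fc values of every drug whose MOA annotation carries
    ``moa_label``, splits them by the cohort's high/low group, and runs the
    rank-sum test.  ``sensitivity`` has columns ``cell_line, drug, log2fc``;
    ``moa`` has ``drug, moa`` (one row per pair); ``cohort`` is
    :func:`median_split` output.
    """
    for col in ("cell_line", "drug", "log2fc"):
        if col not in sensitivity.columns:
            raise SchemaError(f"sensitivity table missing column {col!r}")
    labels = set(moa["moa"])
    if moa_label not in labels:
        raise DesignError(f"MOA label {moa_label!r} not found; available: {sorted(labels)}")
    drugs = set(moa.loc[moa["moa"] == moa_label, "drug"])
    sub = sensitivity[sensitivity["drug"].isin(drugs)].merge(
        cohort[["cell_line", "group"]], on="cell_line", how="inner"
    )
    vals = {g: grp["log2fc"].to_numpy(dtype=float) for g, grp in sub.groupby("group")}
    if "low" not in vals or "high" not in vals:
        raise DesignError("both cohort groups must contribute sensitivities")
    res = rank_sum_test(vals["low"], vals["high"])
    return {
        "moa": moa_label,
        "n_drugs": len(drugs),
        "median_low": float(np.median(vals["low"])),
        "median_high": float(np.median(vals["high"])),
        "statistic": res.statistic,
        "pvalue": res.pvalue,
        "method": res.method,
        "n_low": res.n_a,
        "n_high": res.n_b,
    }


def stratify_by_mutation(
    sensitivity: pd.DataFrame,
    cohort: pd.DataFrame,
    mutations: pd.DataFrame,
    gene: str,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Within each expression group, compare mutant vs wildtype per drug.

    ``mutations`` has columns ``cell_line, gene, status`` with status in
    {"mutant", "wildtype"}.  Strata with an empty arm are reported with a
    note and NaN p-value rather than raising.  ``bh_adjust=True`` adds a
    Benjamini-Hochberg adjusted column across the tested comparisons.
    Mutant counts per expression group land in ``.attrs["n_mutant"]``.
    """
    flags = mutations.loc[mutations["gene"] == gene, ["cell_line", "status"]]
    if flags.empty:
        raise DesignError(f"no mutation flags for gene {gene!r}")
    merged = sensitivity.merge(cohort[["cell_line", "group"]], on="cell_line") \
                        .merge(flags, on="cell_line")
    rows = []
    for (group, drug), grp in merged.groupby(["group", "drug"], sort=False):
        mut = grp.loc[grp["status"] == "mutant", "log2fc"].to_numpy(dtype=float)
        wt = grp.loc[grp["status"] == "wildtype", "log2fc"].to_numpy(dtype=float)
        row = {"group": group, "drug": drug, "n_mutant": len(mut), "n_wildtype": len(wt)}
        if len(mut) == 0 or len(wt) == 0:
            row.update(statistic=np.nan, pvalue=np.nan, note="stratum empty; skipped")
            logger.info("skipping %s/%s: empty stratum", group, drug)
        else:
            res = rank_sum_test(mut, wt)
            row.update(statistic=res.statistic, pvalue=res.pvalue, note="")
        rows.append(row)
    out = pd.DataFrame(rows)
    if bh_adjust and out["pvalue"].notna().any():
        from statsmodels.stats.multitest import multipletests
        mask = out["pvalue"].notna()
        adj = np.full(len(out), np.nan)
        adj[mask.to_numpy()] = multipletests(out.loc[mask, "pvalue"], method="fdr_bh")[1]
        out["pvalue_bh"] = adj
    counts = flags.merge(cohort[["cell_line", "group"]], on="cell_line")
    out.attrs["n_mutant"] = (
        counts[counts["status"] == "mutant"].groupby("group")["cell_line"].nunique().to_dict()
    )
    return out
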