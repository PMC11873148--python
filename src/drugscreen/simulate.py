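"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator draws from the same data model the pipeline assumes —
fluorescence plates with additive background, 4PL dose-response curves,
Bliss-structured combination matrices with an optionally injected
interaction, and a two-group cohort with a shifted sensitivity distribution —
and returns the generated tables *together with* a machine-readable truth
table, so recovery can be tested without the pipeline ever seeing the truth.

All randomness flows through ``numpy.random.default_rng(seed)``; a fixed seed
reproduces every output bit-for-bit.

Default conditions mirror the screening study the package is built around:
384-well plates, a 312-compound library screened at 534 nM on one control
and two knockout lines, EC50s on the order of 2 µM with 5-point viability
noise, 0.0009-50 µM combination grids with 2-point inhibition noise, and a
36-line cohort split 18/18 at the median marker expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doseresponse import four_pl
from .errors import DesignError
from .wells import indices_to_well

SCREEN_DOSE_UM = 0.534  # single-dose screen concentration


# ---------------------------------------------------------------------------
# plates


@dataclass
class PlateSimConfig:
    n_background: int = 16
    n_untreated: int = 16
    background_mean: float = 2000.0
    untreated_mean: float = 20000.0
    noise_sd_frac: float = 0.02  # additive fluorescence noise, fraction of the bg-untreated span


def gen_plate(
    truth: pd.DataFrame,
    config: PlateSimConfig | None = None,
    *,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    plate_id: str = "P1",
) -> pd.DataFrame:
    """Simulate one 384-well plate from per-drug viability truths.

    ``truth`` has columns ``cell_line, drug, dose_uM, viability_pct`` (one
    treated well per row).  Fluorescence is background + viability/100 x span
    + additive Gaussian noise.  Returns a long plate-reading table.
    """
    cfg = config or PlateSimConfig()
    rng = rng if rng is not None else np.random.default_rng(seed)
    n_treated = len(truth)
    n_total = cfg.n_background + cfg.n_untreated + n_treated
    if n_total > 384:
        raise DesignError(f"{n_total} wells exceed a 384-well plate")
    span = cfg.untreated_mean - cfg.background_mean
    sd = cfg.noise_sd_frac * span

    cell_line = truth["cell_line"].iloc[0] if n_treated else ""
    rows = []
    wells = iter(indices_to_well(i // 24, i % 24) for i in range(384))
    for _ in range(cfg.n_background):
        rows.append((plate_id, next(wells), "background", cell_line, "", np.nan,
                     cfg.background_mean + sd * rng.standard_normal()))
    for _ in range(cfg.n_untreated):
        rows.append((plate_id, next(wells), "untreated", cell_line, "", np.nan,
                     cfg.untreated_mean + sd * rng.standard_normal()))
    for _, t in truth.iterrows():
        fl = cfg.background_mean + t["viability_pct"] / 100.0 * span + sd * rng.standard_normal()
        rows.append((plate_id, next(wells), "treated", t["cell_line"], t["drug"],
                     t["dose_uM"], fl))
    df = pd.DataFrame(rows, columns=["plate_id", "well", "role", "cell_line",
                                     "drug", "dose_uM", "fluorescence"])
    df["fluorescence"] = df["fluorescence"].clip(lower=0.0)
    return df


# ---------------------------------------------------------------------------
# single-dose differential screen


@dataclass
class ScreenSimConfig:
    n_drugs: int = 312
    control_line: str = "CTRL"
    ko_lines: tuple = ("KO1", "KO2")
    n_sensitizers: int = 20
    sensitizer_effect: float = -15.0  # percentage points added to KO viability
    n_protectors: int = 10
    protector_effect: float = 15.0
    n_dual: int = 0  # drugs spiked +effect in the first KO line, -effect in the second
    dual_effect: float = 12.0
    base_mean: float = 85.0  # control viability distribution at the screen dose
    base_sd: float = 15.0
    n_replicates: int = 3
    plate: PlateSimConfig = field(default_factory=PlateSimConfig)


def gen_screen(config: ScreenSimConfig | None = None, *, seed: int = 0):
    """Simulate a full differential screen with spiked-in hits.

    Returns ``(readings, truth)``: plate readings for every cell line and
    replicate (one plate each), and a per-drug truth table with the control
    viability, the per-line effects, and the implied ground-truth labels.
    """
    cfg = config or ScreenSimConfig()
    rng = np.random.default_rng(seed)
    n_special = cfg.n_sensitizers + cfg.n_protectors + cfg.n_dual
    if n_special > cfg.n_drugs:
        raise DesignError("more spiked drugs than drugs in the library")
    if len(cfg.ko_lines) < 1 or (cfg.n_dual and len(cfg.ko_lines) < 2):
        raise DesignError("dual spikes need two KO lines")

    drugs = [f"drug{i:03d}" for i in range(1, cfg.n_drugs + 1)]
    base = cfg.base_mean + cfg.base_sd * rng.standard_normal(cfg.n_drugs)
    effects = {ko: np.zeros(cfg.n_drugs) for ko in cfg.ko_lines}
    idx = rng.permutation(cfg.n_drugs)[:n_special]
    sens_idx = idx[: cfg.n_sensitizers]
    prot_idx = idx[cfg.n_sensitizers: cfg.n_sensitizers + cfg.n_protectors]
    dual_idx = idx[cfg.n_sensitizers + cfg.n_protectors:]
    for ko in cfg.ko_lines:
        effects[ko][sens_idx] = cfg.sensitizer_effect
        effects[ko][prot_idx] = cfg.protector_effect
    if cfg.n_dual:
        effects[cfg.ko_lines[0]][dual_idx] = cfg.dual_effect
        effects[cfg.ko_lines[1]][dual_idx] = -cfg.dual_effect

    truth = pd.DataFrame({"drug": drugs, "viability_control": base})
    for ko in cfg.ko_lines:
        truth[f"effect_{ko}"] = effects[ko]
    truth["label_sensitizer"] = np.any(
        np.column_stack([effects[ko] < 0 for ko in cfg.ko_lines]), axis=1)
    truth["label_protector"] = np.any(
        np.column_stack([effects[ko] > 0 for ko in cfg.ko_lines]), axis=1)

    frames = []
    for line in [cfg.control_line, *cfg.ko_lines]:
        v = base if line == cfg.control_line else base + effects[line]
        line_truth = pd.DataFrame({
            "cell_line": line, "drug": drugs, "dose_uM": SCREEN_DOSE_UM,
            "viability_pct": v,
        })
        for rep in range(1, cfg.n_replicates + 1):
            plate = gen_plate(line_truth, cfg.plate, rng=rng,
                              plate_id=f"{line}-r{rep}")
            plate["replicate"] = rep
            frames.append(plate)
    readings = pd.concat(frames, ignore_index=True)
    return readings, truth


# ---------------------------------------------------------------------------
# dose-response


@dataclass
class DoseResponseSimConfig:
    lower: float = 0.0
    upper: float = 100.0
    ec50: float = 1.936  # µM, an ATR-inhibitor-like potency
    hill: float = 1.0
    n_doses: int = 10
    dose_spacing: float = 10.0**0.5  # half-log series
    dose_center: float | None = None  # series centre; defaults to the true ec50
    n_replicates: int = 3
    noise_sd: float = 5.0  # viability points
    cell_line: str = "CTRL"
    drug: str = "drugA"


def gen_dose_response(config: DoseResponseSimConfig | None = None, *, seed: int = 0):
    """Simulate a replicated dose-response series from a known 4PL truth.

    Doses form a geometric (default half-log) series centered on the true
    EC50.  Returns ``(records, truth)`` where records is a long viability
    table and truth a one-row DataFrame of the generating parameters.
    """
    cfg = config or DoseResponseSimConfig()
    rng = np.random.default_rng(seed)
    k = np.arange(cfg.n_doses) - (cfg.n_doses - 1) / 2.0
    center = cfg.dose_center if cfg.dose_center is not None else cfg.ec50
    doses = center * cfg.dose_spacing**k
    if doses.max() < cfg.ec50 / 1e3 or doses.min() > cfg.ec50 * 1e3:
        import warnings
        warnings.warn("dose span excludes the true EC50 by >3 decades", stacklevel=2)
    clean = four_pl(doses, cfg.lower, cfg.upper, cfg.ec50, cfg.hill)
    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        noisy = clean + cfg.noise_sd * rng.standard_normal(cfg.n_doses)
        for d, v in zip(doses, noisy):
            rows.append((cfg.cell_line, cfg.drug, d, v, rep))
    records = pd.DataFrame(rows, columns=["cell_line", "drug", "dose_uM",
                                          "viability_pct", "replicate"])
    truth = pd.DataFrame([{
        "cell_line": cfg.cell_line, "drug": cfg.drug, "lower": cfg.lower,
        "upper": cfg.upper, "ec50": cfg.ec50, "hill": cfg.hill,
    }])
    return records, truth


# ---------------------------------------------------------------------------
# synergy matrices


@dataclass
class SynergySimConfig:
    drug_a: str = "drugA"
    drug_b: str = "cisplatin"
    # marginal inhibition curves: y(d) = emax * (d/m)^lam / (1 + (d/m)^lam)
    emax_a: float = 1.0
    m_a: float = 1.0
    lam_a: float = 1.0
    emax_b: float = 1.0
    m_b: float = 2.0
    lam_b: float = 1.2
    top_dose: float = 50.0
    dilution: float = 4.0
    n_doses: int = 8  # nonzero doses per axis (dose 0 added automatically)
    noise_sd: float = 2.0  # inhibition points (percentage scale)
    interaction: dict = field(default_factory=dict)  # (i, j) 1-based nonzero-cell -> added inhibition points
    cell_line: str = "CTRL"
    n_replicates: int = 1


def _margin_curve(d, emax, m, lam):
    d = np.asarray(d, dtype=float)
    y = np.zeros_like(d)
    pos = d > 0
    y[pos] = emax / (1.0 + (m / d[pos]) ** lam)
    return y


def gen_synergy(config: SynergySimConfig | None = None, *, seed: int = 0):
    """Simulate Bliss-structured combination matrices with injected interaction.

    The noiseless surface is the Bliss product of the two exact log-logistic
    margins; ``interaction`` adds inhibition points at named nonzero cells
    (1-based indices into the nonzero dose grid).  Gaussian noise of
    ``noise_sd`` inhibition points is added per replicate.  Returns
    ``(records, truth)`` with records in the long synergy schema and truth
    holding the noiseless viability grid and the injected delta surface.
    """
    cfg = config or SynergySimConfig()
    rng = np.random.default_rng(seed)
    nz = cfg.top_dose / cfg.dilution ** np.arange(cfg.n_doses - 1, -1, -1)
    doses_a = np.concatenate([[0.0], nz])
    doses_b = np.concatenate([[0.0], nz])
    y_a = _margin_curve(doses_a, cfg.emax_a, cfg.m_a, cfg.lam_a)
    y_b = _margin_curve(doses_b, cfg.emax_b, cfg.m_b, cfg.lam_b)
    y_null = y_a[:, None] + y_b[None, :] - y_a[:, None] * y_b[None, :]
    delta_truth = np.zeros_like(y_null)
    for (i, j), pts in cfg.interaction.items():
        if not (1 <= i <= cfg.n_doses and 1 <= j <= cfg.n_doses):
            raise DesignError(f"interaction cell {(i, j)} outside the nonzero grid")
        delta_truth[i, j] += pts / 100.0
    y_clean = y_null + delta_truth

    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        y_noisy = y_clean + cfg.noise_sd / 100.0 * rng.standard_normal(y_clean.shape)
        for i, da in enumerate(doses_a):
            for j, db in enumerate(doses_b):
                rows.append((cfg.cell_line, cfg.drug_a, da, cfg.drug_b, db,
                             (1.0 - y_noisy[i, j]) * 100.0, rep))
    records = pd.DataFrame(rows, columns=["cell_line", "drug_a", "dose_a_uM",
                                          "drug_b", "dose_b_uM", "viability_pct",
                                          "replicate"])
    truth_rows = []
    for i, da in enumerate(doses_a):
        for j, db in enumerate(doses_b):
            truth_rows.append((da, db, (1.0 - y_null[i, j]) * 100.0,
                               delta_truth[i, j] * 100.0))
    truth = pd.DataFrame(truth_rows, columns=["dose_a_uM", "dose_b_uM",
                                              "viability_null_pct", "delta_truth_pts"])
    return records, truth


def average_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Average a long synergy table over replicates (standard pre-ZIP step)."""
    keys = ["cell_line", "drug_a", "dose_a_uM", "drug_b", "dose_b_uM"]
    return records.groupby(keys, as_index=False)["viability_pct"].mean()


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortSimConfig:
    n_lines: int = 36
    n_drugs: int = 12
    moa_label: str = "ATR"
    n_labeled_drugs: int = 3
    expression_median: float = 5.4  # TPM scale of the marker gene
    expression_sd_log: float = 0.6
    log2fc_mean: float = -0.8
    log2fc_sd: float = 0.6
    group_effect: float = 0.0  # added to log2fc of labeled drugs in the low group
    mutation_gene: str = "TP53"
    n_mutant_low: int = 4
    n_mutant_high: int = 1
    mutation_effect: float = 0.0  # added to log2fc of labeled drugs in mutant lines


def gen_cohort(config: CohortSimConfig | None = None, *, seed: int = 0):
    """Simulate a cohort of cell lines with expression, sensitivity and mutations.

    Returns ``(expression, sensitivity, moa, mutations, truth)``.  The low
    expression group receives ``group_effect`` added to the log2fc of the
    labeled drugs (negative = more sensitive, the direction the biomarker
    hypothesis predicts); mutants optionally receive ``mutation_effect``.
    """
    cfg = config or CohortSimConfig()
    rng = np.random.default_rng(seed)
    lines = [f"line{i:02d}" for i in range(1, cfg.n_lines + 1)]
    tpm = cfg.expression_median * np.exp(cfg.expression_sd_log * rng.standard_normal(cfg.n_lines))
    expression = pd.DataFrame({"cell_line": lines, "tpm": tpm})
    med = np.median(tpm)
    low_mask = tpm <= med  # ties-to-low, matching median_split
    group = np.where(tpm > med, "high", "low")

    drugs = [f"cpd{i:02d}" for i in range(1, cfg.n_drugs + 1)]
    labeled = drugs[: cfg.n_labeled_drugs]
    moa = pd.DataFrame(
        [(d, cfg.moa_label) for d in labeled]
        + [(d, "other") for d in drugs[cfg.n_labeled_drugs:]],
        columns=["drug", "moa"],
    )

    low_lines = [l for l, m in zip(lines, low_mask) if m]
    high_lines = [l for l, m in zip(lines, low_mask) if not m]
    if cfg.n_mutant_low > len(low_lines) or cfg.n_mutant_high > len(high_lines):
        raise DesignError("more mutants requested than lines in a group")
    mutants = set(rng.choice(low_lines, cfg.n_mutant_low, replace=False)) | \
        set(rng.choice(high_lines, cfg.n_mutant_high, replace=False))
    mutations = pd.DataFrame({
        "cell_line": lines,
        "gene": cfg.mutation_gene,
        "status": ["mutant" if l in mutants else "wildtype" for l in lines],
    })

    rows = []
    for li, line in enumerate(lines):
        for d in drugs:
            lfc = cfg.log2fc_mean + cfg.log2fc_sd * rng.standard_normal()
            if d in labeled and group[li] == "low":
                lfc += cfg.group_effect
            if d in labeled and line in mutants:
                lfc += cfg.mutation_effect
            rows.append((line, d, lfc))
    sensitivity = pd.DataFrame(rows, columns=["cell_line", "drug", "log2fc"])

    truth = {
        "median_tpm": float(med),
        "group": dict(zip(lines, group)),
        "labeled_drugs": labeled,
        "group_effect": cfg.group_effect,
        "mutants": sorted(mutants),
    }
    return expression, sensitivity, moa, mutations, truth
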