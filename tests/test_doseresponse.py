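"""4PL fitting, EC50 derivation, potency ratios, and ratio tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from drugscreen import (
    DesignError,
    compare_ratios,
    ec50,
    fit_4pl,
    relative_ec50,
)
from drugscreen.datasets import load_t24_ec50_table
from drugscreen.doseresponse import four_pl
from drugscreen.simulate import DoseResponseSimConfig, gen_dose_response


def grid_oracle_sse(doses, viab, n_ec50=200, n_hill=50):
    """Best SSE over a dense (log ec50, hill) grid, asymptotes solved exactly.

    Independent of the fitter: brute-force profile likelihood by linear
    least squares on the two asymptotes at every grid node.
    """
    d = np.asarray(doses, float)
    v = np.asarray(viab, float)
    log_es = np.linspace(np.log(d.min() / 100), np.log(d.max() * 100), n_ec50)
    hills = np.geomspace(0.1, 10.0, n_hill)
    best = np.inf
    for h in hills:
        for le in log_es:
            w = 1.0 / (1.0 + np.exp(np.clip(h * (np.log(d) - le), -700, 700)))
            X = np.column_stack([1.0 - w, w])
            coef, *_ = np.linalg.lstsq(X, v, rcond=None)
            sse = float(np.sum((v - X @ coef) ** 2))
            best = min(best, sse)
    return best


class TestFit4pl:
    def test_exact_model_identity(self):
        d = np.geomspace(1e-2, 1e2, 9)
        v = four_pl(d, 0.0, 100.0, 1.0, 1.0)
        f = fit_4pl(d, v)
        assert f.converged
        assert f.lower == pytest.approx(0.0, abs=1e-6)
        assert f.upper == pytest.approx(100.0, rel=1e-6)
        assert f.ec50 == pytest.approx(1.0, rel=1e-6)
        assert f.hill == pytest.approx(1.0, rel=1e-6)

    def test_dose_unit_covariance(self):
        d = np.geomspace(1e-2, 1e2, 9)
        v = four_pl(d, 10.0, 95.0, 0.7, 1.4)
        f_uM = fit_4pl(d, v)
        f_nM = fit_4pl(d * 1000, v)
        assert f_nM.ec50 == pytest.approx(f_uM.ec50 * 1000, rel=1e-6)
        assert f_nM.hill == pytest.approx(f_uM.hill, rel=1e-6)
        assert f_nM.upper == pytest.approx(f_uM.upper, rel=1e-6)

    def test_noisy_fit_matches_grid_oracle(self):
        rec, _ = gen_dose_response(DoseResponseSimConfig(n_doses=8, noise_sd=5.0), seed=11)
        d = rec["dose_uM"].to_numpy()
        v = rec["viability_pct"].to_numpy()
        f = fit_4pl(d, v)
        oracle = grid_oracle_sse(d, v)
        assert f.residual_sse <= oracle * (1 + 1e-6) + 1e-9
        # the oracle's best ec50 brackets ours within one grid step
        assert f.converged

    @pytest.mark.parametrize("seed", range(5))
    def test_sse_never_worse_than_oracle(self, seed):
        rec, _ = gen_dose_response(
            DoseResponseSimConfig(n_doses=8, noise_sd=5.0, ec50=0.5, hill=1.8), seed=seed)
        d, v = rec["dose_uM"].to_numpy(), rec["viability_pct"].to_numpy()
        f = fit_4pl(d, v)
        assert f.residual_sse <= grid_oracle_sse(d, v) * (1 + 1e-6) + 1e-9

    def test_recovery_median_error_under_10pct(self):
        # replicated simulation at the study's control-line potency
        errs = []
        for seed in range(40):
            rec, truth = gen_dose_response(DoseResponseSimConfig(n_doses=8), seed=seed)
            f = fit_4pl(rec["dose_uM"], rec["viability_pct"])
            errs.append(abs(f.ec50 - truth["ec50"][0]) / truth["ec50"][0])
        assert np.median(errs) <= 0.10

    def test_flat_data_flagged_not_raised(self):
        d = np.geomspace(1e-2, 1e2, 8)
        f = fit_4pl(d, np.full(8, 80.0))
        assert not f.ec50_reliable

    def test_too_few_distinct_doses(self):
        with pytest.raises(DesignError):
            fit_4pl([1, 1, 2, 2, 3, 4], [90, 91, 70, 69, 50, 30])

    def test_increasing_curve_canonicalized(self):
        d = np.geomspace(1e-2, 1e2, 9)
        v = four_pl(d, 20.0, 90.0, 1.0, -1.2)  # viability rising with dose
        f = fit_4pl(d, v)
        assert f.lower <= f.upper
        assert f.hill < 0


class TestEc50:
    def test_relative_is_the_parameter(self):
        d = np.geomspace(1e-2, 1e2, 9)
        f = fit_4pl(d, four_pl(d, 0.0, 100.0, 2.5, 1.0))
        assert ec50(f) == pytest.approx(2.5, rel=1e-6)

    def test_midpoint_crossing_numerically(self):
        d = np.geomspace(1e-3, 1e3, 11)
        f = fit_4pl(d, four_pl(d, 20.0, 80.0, 0.9, 1.7))
        mid = (f.lower + f.upper) / 2
        root = optimize.brentq(lambda x: f.predict(x) - mid, 1e-6, 1e6)
        assert root == pytest.approx(f.ec50, abs=1e-8 * f.ec50)

    def test_absolute_ec50_crosses_50pct(self):
        d = np.geomspace(1e-3, 1e3, 11)
        f = fit_4pl(d, four_pl(d, 20.0, 80.0, 0.9, 1.7))
        d50 = ec50(f, kind="absolute")
        assert f.predict(d50) == pytest.approx(50.0, abs=1e-6)

    def test_absolute_ec50_nan_when_unreachable(self):
        d = np.geomspace(1e-3, 1e3, 11)
        f = fit_4pl(d, four_pl(d, 60.0, 100.0, 1.0, 1.0))  # never reaches 50 %
        assert np.isnan(ec50(f, kind="absolute"))


class TestRelativeEc50:
    def test_published_mean_ratios(self):
        tab = load_t24_ec50_table().rename(columns={"ec50_mean_uM": "ec50_uM"})
        tab["replicate"] = 1
        berzo = relative_ec50(tab[tab.drug == "Berzosertib"], "Control A6")
        pooled = berzo[berzo.replicate == "pooled"].set_index("cell_line")["ratio"]
        assert round(pooled["STAG2 KO G2"], 2) == 0.53
        assert round(pooled["STAG2 KO H2"], 2) == 0.40
        assert pooled["Control A6"] == pytest.approx(1.0)
        pi103 = relative_ec50(tab[tab.drug == "PI-103"], "Control A6")
        pooled = pi103[pi103.replicate == "pooled"].set_index("cell_line")["ratio"]
        assert round(pooled["STAG2 KO H2"], 2) == 4.33

    def test_scale_free(self):
        tab = pd.DataFrame({"cell_line": ["C", "C", "K", "K"],
                            "replicate": [1, 2, 1, 2],
                            "ec50_uM": [1.0, 1.2, 0.5, 0.7]})
        r0 = relative_ec50(tab, "C")
        tab2 = tab.assign(ec50_uM=tab.ec50_uM * 37.5)
        r1 = relative_ec50(tab2, "C")
        np.testing.assert_allclose(r0["ratio"], r1["ratio"])

    def test_pooled_is_ratio_of_replicate_means(self):
        tab = pd.DataFrame({"cell_line": ["C", "C", "K", "K"],
                            "replicate": [1, 2, 1, 2],
                            "ec50_uM": [1.0, 3.0, 4.0, 4.0]})
        out = relative_ec50(tab, "C")
        pooled = out[out.replicate == "pooled"].set_index("cell_line")["ratio"]
        assert pooled["K"] == pytest.approx(4.0 / 2.0)

    def test_missing_control_errors(self):
        tab = pd.DataFrame({"cell_line": ["K"], "replicate": [1], "ec50_uM": [1.0]})
        with pytest.raises(DesignError):
            relative_ec50(tab, "C")


class TestCompareRatios:
    @staticmethod
    def permutation_p(a, b, n_perm=2000, seed=0):
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        obs = abs(np.mean(a) - np.mean(b))
        count = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if abs(pooled[:len(a)].mean() - pooled[len(a):].mean()) >= obs - 1e-12:
                count += 1
        return count / n_perm

    def test_identical_groups_give_p_one(self):
        ratios = pd.DataFrame({"cell_line": ["C"] * 3 + ["K"] * 3,
                               "replicate": [1, 2, 3] * 2,
                               "ratio": [1.0, 1.1, 0.9] * 2})
        rep = compare_ratios(ratios, "C")
        assert rep["design"] == "t-test"
        assert rep["comparisons"][0]["p"] == pytest.approx(1.0)

    def test_separated_groups_agree_with_permutation_oracle(self):
        rng = np.random.default_rng(5)
        a = 1.0 + 0.05 * rng.standard_normal(4)
        b = 2.0 + 0.05 * rng.standard_normal(4)
        ratios = pd.DataFrame({
            "cell_line": ["C"] * 4 + ["K"] * 4,
            "replicate": list(range(4)) * 2,
            "ratio": np.concatenate([a, b]),
        })
        rep = compare_ratios(ratios, "C")
        assert rep["comparisons"][0]["p"] < 0.05
        assert self.permutation_p(a, b) < 0.05

    def test_three_line_design_reports_per_noncontrol_line(self):
        rng = np.random.default_rng(2)
        rows = []
        for line, mu in (("C", 1.0), ("K1", 0.6), ("K2", 1.4)):
            for rep in range(3):
                rows.append({"cell_line": line, "replicate": rep,
                             "ratio": mu + 0.05 * rng.standard_normal()})
        rep = compare_ratios(pd.DataFrame(rows), "C")
        assert rep["design"] == "anova+dunnett"
        assert len(rep["comparisons"]) == 2
        assert {c["line"] for c in rep["comparisons"]} == {"K1", "K2"}

    def test_single_replicate_descriptive_only(self):
        ratios = pd.DataFrame({"cell_line": ["C", "K"], "replicate": [1, 1],
                               "ratio": [1.0, 2.0]})
        rep = compare_ratios(ratios, "C")
        assert rep["design"] == "descriptive"
        assert rep["comparisons"] == []
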