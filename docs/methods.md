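# Methods

This note records the models the package implements, the defaults and why,
the numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Plate normalization

The model is a two-point affine calibration per physical plate: media-only
background wells define 0 % and drug-free untreated wells define 100 %, and
every treated well is mapped linearly between (and beyond) those anchors.
Consequences that the tests rely on:

* the transform is invariant to any affine change of the fluorescence scale
  (gain or offset drift between plates cancels), and
* values outside [0, 100] are meaningful — a reading above the untreated
  mean is reported as > 100 % viability, never clipped, because clipping
  would bias the knockout-minus-control deltas downstream.

Background/untreated means are arithmetic means over all wells of that role
on the same plate; pooling across plates is deliberately impossible in the
API. The number of control wells is a generator/config choice (default 16
of each on a 384-well plate), since instrument layouts vary. Readings are
treated as endpoint values; incubation metadata is provenance only.
Degenerate plates (background mean = untreated mean) raise rather than
return infinities.

## Hit calling

Deltas are computed from replicate-averaged viabilities, one value per cell
line × drug, matching how screen tables are usually reported. The
classification threshold is strict (|Δ| > 9 percentage points), chosen to
match the reference screen, where the smallest qualifying delta is 9.03 and
the largest non-qualifying one 8.68. Labels are per-category, not
per-drug-exclusive: each knockout line contributes evidence independently,
so a drug can be sensitizer in one clone and protector in another (the
bundled table contains exactly one such drug). Category totals therefore
count labels, not drugs. Deltas are held at full precision internally and
rounded to 2 decimals only in reports. Single-dose screen differences get
no significance test — the threshold *is* the decision rule — which mirrors
practice for 1-point screens.

Target enrichment needs an annotation covering the whole library, because
the denominator is "all screened drugs with this target". A multi-target
drug counts once per target; hit drugs missing from the annotation are
excluded from numerators and surfaced in a warning instead of silently
shifting percentages.

## 4PL dose-response

Parameterization: v(d) = lower + (upper − lower)/(1 + (d/EC50)^hill), with
canonical form lower ≤ upper and hill > 0 meaning viability decreases with
dose. EC50 is the *relative* EC50 (asymptote midpoint), which in this
parameterization is the EC50 parameter itself; the absolute EC50 (curve
crosses 50 % viability) is a secondary output and NaN when 50 % lies
outside the fitted asymptote range.

Fitting profiles the two nonlinear parameters on a 60 × 15 (log EC50 ×
hill) grid — the asymptotes solve in closed form at each node — and refines
the top three nodes with bounded trust-region least squares (xtol/ftol
1e-12). The grid start makes the optimizer insensitive to initialization
and in practice at least as good as a much denser grid; the test suite
verifies the final SSE never exceeds a 200 × 50 brute-force oracle.
Bounds: EC50 within [min dose/100, max dose × 100], hill within [0.1, 10]
(direction is carried by asymptote order during fitting and moved into the
hill sign at canonicalization). Standard errors come from the Gauss-Newton
covariance at the optimum; the EC50 SE is delta-method-transformed from the
log scale. Flat series are not errors: the fit is returned with
`ec50_reliable=False` when the dose effect explains < 1 % of the variance
around the mean. Five distinct positive doses are the minimum for four
parameters with one residual degree of freedom.

At the default validation conditions (8 half-log doses centred on the true
EC50, σ = 5 viability points, 3 replicates) the median relative EC50 error
across simulations is ≈ 9 % — that is the statistical information limit of
the design, not an optimizer artifact, which is why the recovery bound is
stated at 10 %.

EC50 ratios divide each line's EC50 by the average EC50 of the control
line(s). Two ratio flavours are reported: per-replicate ratios
(same-replicate control average in the denominator), which feed the
statistical tests, and a pooled ratio defined as the ratio of
replicate-mean EC50s, which is the number quoted in summaries. Many-to-one
testing uses Dunnett's method (scipy's multivariate-t implementation) after
a one-way ANOVA; with two lines it is a plain two-tailed t-test.

## ZIP synergy

Scoring happens on fractional inhibition. Margins are fitted with rising
log-logistic curves anchored at 0 (untreated) with free maximum ≤ 1, by the
same grid-plus-refinement strategy as the 4PL; margins with fewer than
three nonzero doses, or failed fits, fall back to the raw margin values —
expectation only ever needs the margins *at the grid's own doses*, so the
fallback is exact there. The zero-interaction expectation is the Bliss
product of the fitted margins.

The observed effect at each cell is, by default, the measured inhibition at
that cell (`observed="raw"`). The classical smoothed alternative — refit a
potency-shifted log-logistic along each row and column with the partner's
fitted effect as the floor and average the two fitted values — is available
as `observed="conditional"`. It is not the default because a monotone
conditional curve cannot represent a localized interaction: in simulation a
+15-point interaction at a single cell is smoothed to ≈ 6 points (one cell
carries limited leverage in an 8-point column fit), whereas the raw
estimator recovers it cell-for-cell. The raw estimator also preserves
drug-order symmetry and reduces, on a 2 × 2 single-dose design, to the
plain Bliss excess. Noise control belongs to replication, not smoothing:
matrices from repeated experiments are averaged cell-wise
(`simulate.average_replicates`) before scoring, which at σ = 2 inhibition
points and 3 replicates keeps single-cell recovery within ±3 points.

Inhibition values are clamped to [0, 1] for curve fitting only; observed
values enter the delta unclamped so super-100 % viability noise is not
folded. Scores are reported in percentage points to match how synergy
surfaces are usually colour-scaled, with the maximum synergy score defined
as the 100 % quantile of the surface. Cross-line comparison uses ratios of
maximum scores (or of scores at a named dose pair) to the control line;
cross-combination comparison pools per-line maxima and runs one-way ANOVA
with Tukey-adjusted pairwise tests.

## Cohort comparison

The median split assigns lines strictly below the cohort median to "low"
and strictly above to "high"; values exactly at the median go to "low"
(deterministic, and unexercised for even cohorts with distinct values). The
split depends only on ranks, so any strictly monotone transform of
expression leaves it unchanged. An all-equal cohort is a degenerate-split
error.

The rank-sum test enumerates the exact null distribution of the rank sum
over all C(n, n_a) group assignments when the combined sample is ≤ 12 and
tie-free; otherwise it uses the normal approximation with the standard tie
correction and a 0.5 continuity correction. The continuity-corrected
approximation is mildly conservative: at n = 18 vs 18 the simulated type-I
error at α = 0.05 is ≈ 0.047. Mechanism-level comparisons pool one log2fc
value per cell line × drug for every drug carrying the label — replicates
are averaged upstream, never treated as independent observations. Raw
p-values are reported per comparison (matching common practice for
per-panel Wilcoxon tests); Benjamini-Hochberg adjustment is available
behind a flag in the mutation substratification, which otherwise skips —
with a note, not an error — any stratum with an empty mutant or wildtype
arm.

## Synthetic data

The generators emulate: a 384-well plate whose fluorescence is background +
viability × span + additive Gaussian noise (default sd 2 % of the span); a
312-drug three-line screen with spiked differential effects (defaults: 20
sensitizers at −15 points, 10 protectors at +15, replicated 3×); triplicate
10-point half-log dose series from a known 4PL truth (default EC50
1.936 µM, σ = 5 points); 8 × 8 four-fold dose-combination grids within
0.0009–50 µM built as exact Bliss products of log-logistic margins with
cell-wise injected interaction (σ = 2 inhibition points); and a 36-line
cohort with log-normal marker expression split 18/18, configurable
group effects on labelled drugs, and mutation prevalences (defaults 4
mutants in the low group, 1 in the high group). Every generator returns a
truth table alongside the data; pipeline code never reads truths.

What they do *not* emulate: spatial plate artifacts (edge effects,
dispense gradients), systematic inter-experiment batch shifts,
non-Gaussian heavy-tailed well failures, pharmacokinetics, or any
transcriptome structure beyond a single expression value per line. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated noise model, not robustness to those real-world artifacts —
plate-effect correction is explicitly out of scope.

Determinism: all draws flow through `numpy.random.default_rng(seed)`; a
fixed seed reproduces outputs byte-for-byte, which the suite asserts on
serialized CSV.

## Problem sizes

The test suite and the acceptance script size their simulations to what the
estimates need: 100 seeds for the 4PL recovery median, 2000 null
simulations for the rank-sum type-I rate, 300 for p-value uniformity
(Kolmogorov-Smirnov), 5-seed sweeps for synergy noise behaviour. These
choices keep the full suite under a minute on one core while leaving the
Monte-Carlo error of each asserted quantity well inside its test band.

## Known limitations

* The 4PL fitter assumes homoscedastic Gaussian noise; no robust loss or
  weighting is offered.
* Model selection (3PL/5PL) and Bayesian uncertainty are out of scope.
* ZIP is the only synergy framework; Loewe/HSA surfaces are not computed.
* The exact rank-sum path is O(C(n, n_a)) and intentionally capped at
  combined n = 12.
* Target-enrichment percentages are only as meaningful as the annotation's
  library coverage; the bundled reference data includes the hit table but
  not the full library annotation, so enrichment is validated on synthetic
  annotations.
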