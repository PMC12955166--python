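# Methods

This note documents the statistical procedures implemented in `ptbpanel`,
the assumptions behind the synthetic-data generator, the defaults and why
they were chosen, and the limits of what the synthetic experiments can
show about real cohort data.

## Study design being emulated

The package targets a four-site nested case–control biomarker study of
spontaneous preterm birth (sPTB): a small single-draw discovery cohort
(11 term / 14 sPTB, samples at 13–29 weeks), a longitudinal validation
cohort (19/31, up to four draws per participant at 7–36 weeks), a large
external cohort (194/114, one to two draws at 5–30 weeks) and a second
external cohort (50/23, single draws at 5–28 weeks). All serum draws are
pre-outcome: sample gestational age (GA) is strictly below delivery GA,
enforced row-wise by the generator and asserted in tests. The primary
analysis window is samples drawn at ≤ 24 weeks; later draws are kept for
descriptive use.

Because the analytic sets are case-enriched by design (case fractions
25–37%), predictive values computed on them do not reflect deployment;
the prevalence-weighted bootstrap (below) addresses this.

## Synthetic cohort generator

Log concentration of analyte *a* for participant *i*, draw at GA *t*:

    log C = f_a(t) + delta_a * 1[sPTB] + b_i + eps,
    b_i ~ N(0, sigma_b^2),  eps ~ N(0, sigma_e^2)

* `f_a` is a linear log-median trend in GA (PAPPA2 rising steeply, the
  others gently). The real physiologic trajectories are unknown to us;
  any smooth positive curve works because the MoM step removes it. The
  MoM→z chain's scale invariance is a tested property, so intercepts are
  arbitrary.
* Defaults `sigma_b = 0.6`, `sigma_e = 0.8` make the total per-draw SD
  exactly 1, so the case shift `delta` is directly a standardized effect
  and the binormal equal-variance identity `AUC = Phi(delta / sqrt(2))`
  holds marginally. `calibrate_effect_size(auc)` inverts it; the
  within-person correlation implied by the split (0.36) is a free choice —
  repeated-draw correlation is not identified by anything we emulate — and
  only affects the effective sample size of longitudinal cohorts, not the
  per-draw AUC.
* The composite score sums three z-scores; with independent equally
  shifted analytes its SD is sqrt(3), so `panel_effect_size` divides the
  calibrated composite shift by sqrt(3). Cohorts are calibrated to
  composite targets 0.74 / 0.93 / 0.80 / 0.83.
* IBP4 gets a mild positive shift (0.35 SD) everywhere; SHBG's shift is
  positive in the US-style cohorts and null/slightly negative in the
  Asian-style cohorts. This reproduces, qualitatively, a comparator ratio
  that works in its development population and degrades elsewhere.
* Delivery GA: term is truncated normal on [37, 42] (mean 39.5); sPTB is a
  two-component mixture of an early (< 34 wk) and a late (34–37 wk)
  truncated normal. Mixture weights are set per cohort so the simulated
  delivery medians approximate the printed ones (discovery cohort median
  28 — early-dominated at weight 0.8; the external cohorts median ≈ 35 —
  weight 0.3–0.35).
* Longitudinal schedules: draws per participant uniform in a per-cohort
  range ((1,4) for the longitudinal validation cohort ≈ 2.5 draws each,
  (1,2) for the large external cohort ≈ 1.5), at sorted uniform GAs in the
  cohort window truncated below delivery. The printed totals (127 samples
  from 50 participants; 448 from 308) motivated the ranges.
* Demographics (age, BMI, delivery mode) are drawn from the printed
  per-group summaries of the four cohort tables so the demographic-table
  statistics operate on realistic input; they never enter scoring.
* PPROM status is Bernoulli(0.4) among sPTB; it labels phenotype strata
  only.

What the generator does **not** emulate: batch effects, assay drift,
platform-specific error structure, missingness in analyte panels,
non-normal concentration tails, correlation between analytes beyond the
shared outcome effect, or any dependence of sampling schedule on risk.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness of the biomarker panel
on real sera.

## Meta-analysis stage

Per study, per gene, the two-group comparison uses Welch statistics on
log₂ expression: effect y (case − control mean), sampling variance v, and
a two-sided t p-value. The integration is the contribution and is computed
three ways:

* **RRA**: each study's genes are ranked by signed fold change, once
  descending (up list) and once ascending (down list), normalized to
  (0,1] with average ranks for ties. For one gene with sorted ranks
  r₍₁₎ ≤ … ≤ r₍ₖ₎, ρ = min_j P(Beta(j, k−j+1) ≤ r₍ⱼ₎); the reported
  p-value is Bonferroni-corrected over the gene universe (the standard
  correction for this score; the minimum over order statistics is not a
  p-value itself). A gene's direction, hence which list's ρ it reports,
  follows the sign of its pooled fold change. Improving any rank can only
  decrease ρ (tested property), and under i.i.d. uniform null ranks the
  corrected p is conservative (tested at 3000 null genes).
* **DerSimonian–Laird pooling**: τ² = max(0, (Q − (k−1)) / C) with
  C = Σw − Σw²/Σw, w = 1/v; random-effects weights 1/(v + τ²). k = 1
  degenerates to the single study's effect and variance.
* **Fisher's combined probability** over the per-study p-values; this is
  the "meta p" used by the candidate filter, since it is the stated
  significance method. The filter keeps genes present in all studies with
  |2^pooled-lfc| ≥ 1.2 — the fold-scale reading of "absolute fold change
  ≥ 1.2"; the log₂ reading (≥ 2^1.2) would be far stricter and was
  rejected — and combined p < 0.05.

The planted-gene fixture (6 studies, 5% planted at lfc 1.0, between-study
SD 0.2, 20 per group) yields recall ≥ 0.8 at false-positive rate ≤ 0.05.

## Proteomics screen

Missingness is handled by exclusion, not imputation: peptides missing in
strictly more than 20% of samples are dropped (20.0% exactly is kept,
reading the rule as "> 20%"), and with technical-replicate annotations a
peptide whose replicate CV is ≥ 15% is dropped — reusing the assay's
analytical-reproducibility bound as the operational meaning of "poor
reproducibility". Remaining missing cells stay missing and are excluded
pairwise. Normalization is log₂ then per-sample median centring
(idempotent, tested); protein abundance is the mean of observed peptides.
The screen is a two-sided Mann–Whitney per protein — exact enumeration
when both groups have ≤ 8 samples without ties, tie-corrected normal
approximation otherwise — with BH adjustment across the screened set
(21 targeted proteins, not the upstream candidate list: the smallest
family the screen actually tests). Validation concordance requires the
same sign and at least half the discovery effect magnitude (the 0.5
fraction is configurable; "comparable magnitude" is not quantified by any
source we reproduce).

## MoM / z normalization

Reference medians are tabulated per completed week from the term-outcome
samples of the same cohort and platform — standard prenatal-screening
practice uses unaffected pregnancies, and cohort-specific references keep
the z-scale local; both choices are configurable. Weeks with at least
`min_n = 5` reference draws anchor the curve; sparser interior weeks are
linearly interpolated and edges extend as constants; if no week reaches
`min_n` the threshold falls back to 1 so small cohorts still normalize
(at the cost of a noisier curve — visible as mild AUC attenuation in the
smallest simulated cohort). MoM = value / curve(floor(GA)); z is the
within-cohort standardization of ln MoM with the n−1 SD. Natural log is
used; the base cancels in z. Degenerate cells (zero variance, < 2
samples) raise errors naming the cell rather than emitting NaNs.

## Scoring and threshold transfer

The panel score is the unweighted sum of the three z-scores — weighted or
model-based combinations are deliberately out of scope. The comparator is
ln(IBP4 MoM / SHBG MoM); the published comparator's exact scale is not
specified anywhere we reproduce, and the log-MoM ratio was chosen because
it is symmetric, unbounded and monotone in both inputs. The Youden
cut-point scans midpoints of adjacent distinct scores plus sentinels
beyond the extremes; ties in J break toward higher specificity, then the
lower cutoff, making derivation deterministic (equivalence with an
exhaustive scan is tested). Classification is high-risk iff
score ≥ cutoff (boundary inclusive), and the threshold is never re-derived
on validation data — transfer invariance is tested by permuting validation
labels.

## Evaluation

AUC is the tie-corrected Mann–Whitney probability; CIs are percentile
bootstrap with stratified within-class resampling (B = 1000 by default),
seeded and deterministic. Strata: GA bins < 16 / 16–20⁺⁶ / > 20 weeks and
trimesters T1 ≤ 13⁺⁶, T2 14–27⁺⁶, T3 ≥ 28 — boundaries are applied in
completed weeks-and-days, so GA 13.9 (= 13 weeks 6.3 days) is still T1;
numerically T1 is GA < 14, the middle GA bin is [16, 21). Strata under 15
observations are emitted with metrics suppressed and an explicit reason.
The prevalence-weighted bootstrap draws round(π·N) cases and N − round(π·N)
controls with replacement (fixed total N, not binomial counts — the fixed-N
variant has strictly smaller Monte-Carlo variance and the same mean),
reclassifies at the fixed threshold, and summarizes PPV/NPV by mean and
percentile CI; its mean converges to the Bayes value
se·π / (se·π + (1−sp)(1−π)), tested at π = 0.104 and 0.059. Undefined
predictive values (no predicted positives) are flagged, never coerced to
zero. Demographic statistics follow the printed tables' conventions:
pooled-variance t with df = n₁+n₂−2, two-sided rank-sum, Pearson
chi-square without continuity correction, and point-probability two-sided
Fisher exact for sparse 2×2 tables — each convention verified by
reproducing printed values (8.36, 22.08, 50, 73, 0.016, t = 0.7) exactly.

## Survival

One observation per participant, classified by the earliest draw at
≤ 24 weeks; delivery is always observed (no censoring), so the
Kaplan–Meier estimator equals one minus the empirical CDF of delivery GA,
and step masses sum to one (tested). The log-rank statistic is
(O−E)²/V with hypergeometric variance per distinct event time; the
lifelines implementation is used and checked against an independently
coded accumulation. The headline summary is the low-risk minus high-risk
difference in median delivery GA, which grows monotonically with the
planted panel effect (tested at three effect levels).

## Problem sizes and reproducibility

Simulated experiments run at the study-design cohort sizes; the
acceptance script averages per-cohort metrics over 15 replicate simulated
studies to suppress the Monte-Carlo error that single small cohorts
(25–73 participants) necessarily carry, and the meta-analysis fixture
uses 1000 genes × 6 studies × 40 samples. All randomness flows from
explicit seeds; identical configs produce byte-identical tables (tested
by checksum).

## Known limitations

* The generator's independence of analytes given outcome makes the
  composite calibration exact; correlated analytes would need a smaller
  per-analyte shift for the same composite AUC.
* Reference-curve noise in very small cohorts attenuates AUC by a few
  points; real MoM systems pool larger reference populations.
* The discovery screen treats longitudinal samples as independent; a
  per-participant mode exists only for the survival stage.
* No batch correction, covariate adjustment (maternal weight, smoking),
  censoring, or multifetal pregnancies.
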