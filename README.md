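# ptbpanel

Serum biomarker panel analysis for early prediction of spontaneous preterm
birth (sPTB), implemented as a tested Python pipeline that runs end to end
on synthetic nested case–control cohorts.

## The problem

sPTB — spontaneous labor or membrane rupture leading to delivery before 37
completed weeks — is a leading cause of neonatal morbidity, and existing
mid-gestation biomarkers such as the IBP4/SHBG serum ratio identify risk too
late for the most effective preventive interventions. A candidate
alternative is a three-protein maternal-serum panel (GPX3, NID1, PAPPA2)
derived from placental transcriptomics and refined by targeted proteomics,
scored early in gestation and validated across multiple cohorts. This
package implements the full analytical chain behind such a study, for
biostatisticians and methodologists who want to exercise, test or extend
each stage without access to raw cohort data:

1. **Multi-study differential-expression integration**
   (`meta_transcriptomics`) — robust rank aggregation (RRA), in which a
   gene's score is ρ = min over j of P(Beta(j, k−j+1) ≤ r₍ⱼ₎) for its
   order-ranked normalized ranks r₍ⱼ₎ across k studies; DerSimonian–Laird
   random-effects pooling of log₂ fold changes with moment-estimated
   between-study variance τ²; Fisher's combined probability
   −2Σln pᵢ ~ χ²₂ₘ; and the candidate filter (present in all studies,
   |fold| ≥ 1.2, combined p < 0.05).
2. **Targeted-proteomics refinement** (`proteomics_processing`) — peptide
   QC (missing > 20% or replicate CV ≥ 15% excluded), log₂ global-median
   normalization, peptide→protein roll-up, Mann–Whitney screening with
   Benjamini–Hochberg FDR, and a validation-cohort concordance check.
3. **Gestational-age normalization** (`ga_normalization`) — multiples of
   the median: MoM = x / median_ref(GA week), then z = standardized ln MoM
   within cohort (mean 0, SD 1), which removes physiologic GA trends and
   harmonizes platforms.
4. **Risk scoring** (`risk_scoring`) — composite score
   z_GPX3 + z_NID1 + z_PAPPA2, the comparator ln(IBP4 MoM / SHBG MoM), a
   cut-point maximizing the Youden index J = sensitivity + specificity − 1
   on the discovery cohort, transferred unchanged to validation cohorts.
5. **Performance evaluation** (`performance_eval`) — tie-corrected
   Mann–Whitney AUC with percentile bootstrap CIs, GA-bin / trimester /
   phenotype stratification (strata under n = 15 suppressed), predictive
   values re-weighted to population prevalence (10.4% US, 5.9% Asia) by a
   class-weighted bootstrap, Bland–Altman cross-platform agreement, and the
   demographic-table statistics (pooled t, rank-sum, chi-square without
   continuity correction, point-probability Fisher exact).
6. **Survival comparison** (`survival_analysis`) — Kaplan–Meier curves of
   ongoing pregnancy versus GA at delivery for predicted risk groups, the
   log-rank test, and the difference in median delivery timing.
7. **Synthetic cohorts** (`synthetic_cohorts`) — a generator for the
   four-site study design (25 / 50 / 308 / 73 participants, longitudinal
   pre-outcome draws, PPROM labels) whose case effect sizes are calibrated
   through the binormal identity AUC = Φ(δ/√2), plus planted-gene
   expression matrices for the meta-analysis and a nested case–control
   subsampler.

## Worked example

Run the whole pipeline on the default synthetic study (the `ptbpanel`
console script wraps the same call):

```python
from ptbpanel.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=7, output_dir="runs/demo", bootstrap={"n_reps": 200})
run_dir = run_pipeline(cfg)
print((run_dir / "report.md").read_text())
```

Excerpts of the report this prints:

```
## Candidate refinement funnel
- proteins screened: 21; significant in discovery: 3; validated (concordant): 3
- validated proteins: GPX3, NID1, PAPPA2

## Cohort performance (primary window)
- stanford / three_protein: AUC 0.958 (95% CI 0.910-0.992), sens 0.70, spec 0.97
- stanford / ibp4_shbg:     AUC 0.532 (95% CI 0.408-0.673), sens 0.37, spec 0.68
- asia1 / three_protein:    AUC 0.787 (95% CI 0.744-0.838), sens 0.72, spec 0.69

## Prevalence-weighted predictive values
- asia1 / three_protein @ prevalence 0.059: PPV 0.129 (0.092-0.162), NPV 0.976

## Time to delivery
- stanford / three_protein: median gap 3.9 wk, log-rank chi2 26.88 (p=2.2e-07)
```

Reading this: of 21 screened candidate proteins, exactly the three planted
ones survive the discovery Mann–Whitney screen and validation concordance
check; the composite panel discriminates sPTB from term outcomes (AUC near
its cohort calibration target) while the IBP4/SHBG comparator degrades in
the Asian-style cohorts where SHBG carries no case signal; at a realistic
5.9% population prevalence the panel's PPV drops to ≈0.13 despite good
discrimination (predictive values are prevalence-bound); and participants
flagged high-risk before 24 weeks deliver a median ≈4 weeks earlier.

Every stage also writes tidy TSVs (`scored_samples.tsv`,
`stratified_performance.tsv`, `km_curves.tsv`, …) into the run directory,
and `manifest.json` records the config hash, seed and per-stage row counts
so identical configs reproduce identical tables.

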