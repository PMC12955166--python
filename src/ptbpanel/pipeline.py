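"""End-to-end orchestration of the synthetic biomarker study.

Stages run in dependency order: simulate -> meta -> proteomics ->
normalize -> score -> evaluate -> survive -> report.  Every stage writes
plain TSV into the run directory and appends its row counts to a manifest,
so a run is fully reproducible from its config (all randomness flows from
the config seed) and auditable stage by stage.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import (
    ga_normalization,
    meta_transcriptomics,
    performance_eval,
    proteomics_processing,
    risk_scoring,
    survival_analysis,
    synthetic_cohorts,
)

__all__ = ["RunConfig", "load_config", "run_pipeline", "render_report"]

STAGES = ("simulate", "meta", "proteomics", "normalize", "score", "evaluate",
          "survive", "report")


class CohortOverride(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_term: int | None = None
    n_sptb: int | None = None
    panel_target_auc: float | None = None


class MetaSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_studies: int = 6
    n_genes: int = 1000
    n_per_group: int = 20
    de_fraction: float = 0.05
    planted_lfc: float = 1.0
    heterogeneity_sd: float = 0.2


class Thresholds(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_fold: float = 1.2
    max_p: float = 0.05
    max_missing: float = 0.20
    max_cv: float = 0.15
    fdr: float = 0.05
    min_stratum_n: int = 15
    ga_primary_max: float = 24.0


class BootstrapSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_reps: int = 1000


class PrevalencePriors(BaseModel):
    model_config = ConfigDict(extra="forbid")
    us: float = 0.104
    asia: float = 0.059


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    output_dir: str = "runs/demo"
    discovery_cohort: str = "uab"
    panel_target_auc: dict[str, float] = Field(
        default_factory=lambda: {
            "uab": 0.74, "stanford": 0.93, "asia1": 0.80, "asia2": 0.83
        }
    )
    cohorts: dict[str, CohortOverride] = Field(default_factory=dict)
    meta: MetaSettings = Field(default_factory=MetaSettings)
    thresholds: Thresholds = Field(default_factory=Thresholds)
    bootstrap: BootstrapSettings = Field(default_factory=BootstrapSettings)
    prevalence: PrevalencePriors = Field(default_factory=PrevalencePriors)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _prior_for(cohort: str, priors: PrevalencePriors) -> float:
    return priors.asia if cohort.startswith("asia") else priors.us


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute every stage on synthetic data; returns the run directory."""
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    # -- simulate ----------------------------------------------------------
    specs = synthetic_cohorts.default_cohort_specs(seed=config.seed)
    for name, ov in config.cohorts.items():
        if name not in specs:
            raise ValueError(f"unknown cohort {name!r}")
        from dataclasses import replace as _replace

        kwargs = {k: v for k, v in ov.model_dump().items()
                  if v is not None and k != "panel_target_auc"}
        specs[name] = _replace(specs[name], **kwargs)
    participants, samples = [], []
    for name, spec in specs.items():
        target = config.panel_target_auc.get(name, 0.85)
        ov = config.cohorts.get(name)
        if ov is not None and ov.panel_target_auc is not None:
            target = ov.panel_target_auc
        models = synthetic_cohorts.default_analyte_models(panel_target_auc=target)
        part, samp = synthetic_cohorts.generate_cohort(spec, models)
        participants.append(part)
        samples.append(samp)
    participants = pd.concat(participants, ignore_index=True)
    samples = pd.concat(samples, ignore_index=True)
    participants.to_csv(out / "participants.tsv", sep="\t", index=False)
    samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    manifest["stages"]["simulate"] = {
        "participants": len(participants), "samples": len(samples)
    }

    # -- meta --------------------------------------------------------------
    ms = config.meta
    meta_spec = synthetic_cohorts.MetaStudySpec(
        n_studies=ms.n_studies, n_genes=ms.n_genes, n_per_group=ms.n_per_group,
        de_fraction=ms.de_fraction, planted_lfc=ms.planted_lfc,
        heterogeneity_sd=ms.heterogeneity_sd, seed=config.seed + 100,
    )
    studies = synthetic_cohorts.generate_meta_studies(meta_spec)
    summaries = [
        meta_transcriptomics.welch_study_summary(m, lab, study_id=f"study{i}")
        for i, (m, lab, _) in enumerate(studies)
    ]
    meta_results = meta_transcriptomics.meta_analyze(summaries)
    up, down = meta_transcriptomics.filter_candidates(
        meta_results, min_abs_fold=config.thresholds.min_fold,
        max_p=config.thresholds.max_p,
    )
    meta_results.to_csv(out / "meta_gene_results.tsv", sep="\t")
    (out / "genes_up.txt").write_text("\n".join(up) + ("\n" if up else ""))
    (out / "genes_down.txt").write_text("\n".join(down) + ("\n" if down else ""))
    planted = studies[0][2]
    planted_genes = set(meta_results.index[planted])
    called = set(up) | set(down)
    recall = len(called & planted_genes) / max(1, len(planted_genes))
    fpr = len(called - planted_genes) / max(1, (~planted).sum())
    manifest["stages"]["meta"] = {
        "genes": int(ms.n_genes), "up": len(up), "down": len(down),
        "planted_recall": recall, "false_positive_rate": fpr,
    }

    # -- proteomics (discovery screen funnel) ------------------------------
    peptides, screen_labels = synthetic_cohorts.generate_peptide_screen(
        seed=config.seed + 200
    )
    pmat = proteomics_processing.PeptideMatrix.from_long(peptides)
    filtered, report = proteomics_processing.filter_peptides(
        pmat, config.thresholds.max_missing, config.thresholds.max_cv
    )
    normalized = proteomics_processing.normalize_peptides(filtered)
    prot = proteomics_processing.rollup_proteins(normalized)
    screen = proteomics_processing.screen_candidates(
        prot, screen_labels, alpha_fdr=config.thresholds.fdr
    )
    val_peptides, val_labels = synthetic_cohorts.generate_peptide_screen(
        n_term=19, n_sptb=31, seed=config.seed + 201
    )
    val_prot = proteomics_processing.rollup_proteins(
        proteomics_processing.normalize_peptides(
            proteomics_processing.filter_peptides(
                proteomics_processing.PeptideMatrix.from_long(val_peptides),
                config.thresholds.max_missing, config.thresholds.max_cv,
            )[0]
        )
    )
    hits = [r for r in screen if r.q < config.thresholds.fdr and r.direction == "up"]
    checked = proteomics_processing.concordance_check(hits, val_prot, val_labels)
    validated = [r.protein for r in checked if r.concordant_in_validation]
    screen_frame = pd.DataFrame(
        [
            dict(protein=r.protein, u=r.u_statistic, p=r.p, q=r.q,
                 direction=r.direction, effect=r.effect)
            for r in screen
        ]
    )
    screen_frame.to_csv(out / "proteomics_screen.tsv", sep="\t", index=False)
    manifest["stages"]["proteomics"] = {
        "proteins_screened": len(screen),
        "peptides_dropped": int(report["dropped"].sum()),
        "significant_hits": len(hits),
        "validated": validated,
        "funnel": {"screened": len(screen), "significant": len(hits),
                   "validated": len(validated)},
    }

    # -- normalize ---------------------------------------------------------
    normalized_samples, curves = ga_normalization.normalize_samples(
        samples, participants, synthetic_cohorts.ANALYTES
    )
    curve_frame = pd.concat([c.to_frame() for c in curves.values()], ignore_index=True)
    curve_frame.to_csv(out / "reference_curves.tsv", sep="\t", index=False)
    manifest["stages"]["normalize"] = {"samples": len(normalized_samples)}

    # -- score -------------------------------------------------------------
    scored = risk_scoring.score_samples(normalized_samples)
    meta_cols = participants.set_index("participant_id")[
        ["cohort", "group", "pprom", "ga_delivery_wk"]
    ]
    scored = scored.join(meta_cols, on="participant_id")
    scored.to_csv(out / "scored_samples.tsv", sep="\t", index=False)

    disc = scored[
        (scored["cohort"] == config.discovery_cohort)
        & (scored["ga_sample_wk"] <= config.thresholds.ga_primary_max)
    ]
    y_disc = (disc["group"] == "sptb").astype(int).to_numpy()
    panel_model = risk_scoring.derive_youden_threshold(
        disc["panel_score"], y_disc, predictor="three_protein",
        cohort=config.discovery_cohort,
    )
    ratio_model = risk_scoring.derive_youden_threshold(
        disc["ratio_score"], y_disc, predictor="ibp4_shbg",
        cohort=config.discovery_cohort,
    )
    with open(out / "threshold_models.json", "w") as fh:
        json.dump(
            {
                m.predictor: dict(cutoff=m.cutoff, youden_j=m.youden_j,
                                  derivation_cohort=m.derivation_cohort)
                for m in (panel_model, ratio_model)
            },
            fh, indent=2,
        )
    manifest["stages"]["score"] = {
        "panel_cutoff": panel_model.cutoff, "ratio_cutoff": ratio_model.cutoff
    }

    # -- evaluate ----------------------------------------------------------
    primary = scored[scored["ga_sample_wk"] <= config.thresholds.ga_primary_max]
    perf_rows, prev_rows, demo_rows = [], [], []
    scheme_all = performance_eval.StratificationScheme(
        "none", config.thresholds.min_stratum_n
    )
    scheme_bins = performance_eval.StratificationScheme(
        "ga_bins", config.thresholds.min_stratum_n
    )
    scheme_tri = performance_eval.StratificationScheme(
        "trimester", config.thresholds.min_stratum_n
    )
    for cohort_name in specs:
        sub = primary[primary["cohort"] == cohort_name]
        if sub.empty:
            continue
        for model, col in ((panel_model, "panel_score"), (ratio_model, "ratio_score")):
            for scheme in (scheme_all, scheme_bins, scheme_tri):
                perf_rows.append(
                    performance_eval.stratified_performance(
                        sub, col, scheme, model, cohort=cohort_name,
                        bootstrap_reps=config.bootstrap.n_reps,
                        seed=config.seed + 300,
                    )
                )
            y = (sub["group"] == "sptb").astype(int).to_numpy()
            if y.sum() and (1 - y).sum():
                prev = performance_eval.prevalence_weighted_bootstrap(
                    sub[col].to_numpy(dtype=float), y, model,
                    performance_eval.PrevalenceBootstrapConfig(
                        target_prevalence=_prior_for(cohort_name, config.prevalence),
                        n_reps=config.bootstrap.n_reps,
                        seed=config.seed + 301,
                    ),
                )
                prev_rows.append(
                    dict(cohort=cohort_name, predictor=model.predictor,
                         prevalence=_prior_for(cohort_name, config.prevalence),
                         ppv=prev["ppv"]["mean"], ppv_lo=prev["ppv"]["lo"],
                         ppv_hi=prev["ppv"]["hi"], npv=prev["npv"]["mean"],
                         npv_lo=prev["npv"]["lo"], npv_hi=prev["npv"]["hi"])
                )
        demo = performance_eval.cohort_table_stats(
            participants[participants["cohort"] == cohort_name]
        )
        demo.insert(0, "cohort", cohort_name)
        demo_rows.append(demo)
    perf = pd.concat(perf_rows, ignore_index=True)
    perf.to_csv(out / "stratified_performance.tsv", sep="\t", index=False)
    prev_frame = pd.DataFrame(prev_rows)
    prev_frame.to_csv(out / "prevalence_weighted_ppv.tsv", sep="\t", index=False)
    demographics = pd.concat(demo_rows, ignore_index=True)
    demographics.to_csv(out / "demographics_stats.tsv", sep="\t", index=False)
    manifest["stages"]["evaluate"] = {
        "performance_rows": len(perf), "prevalence_rows": len(prev_frame)
    }

    # -- survive -----------------------------------------------------------
    surv_rows, curve_rows = [], []
    for cohort_name in specs:
        sub = scored[scored["cohort"] == cohort_name]
        parts = participants[participants["cohort"] == cohort_name]
        for model, col in ((panel_model, "panel_score"), (ratio_model, "ratio_score")):
            try:
                surv = survival_analysis.risk_group_survival(
                    sub, parts, model, score_column=col,
                    ga_max=config.thresholds.ga_primary_max,
                )
                hi = surv.loc[surv["risk_group"] == "high", "ga_delivery_wk"]
                lo = surv.loc[surv["risk_group"] == "low", "ga_delivery_wk"]
                if hi.empty or lo.empty:
                    continue
                chi2, p = survival_analysis.log_rank(hi, lo)
                gap = survival_analysis.median_delivery_gap(surv)
                surv_rows.append(
                    dict(cohort=cohort_name, predictor=model.predictor,
                         n_high=len(hi), n_low=len(lo), logrank_chi2=chi2,
                         logrank_p=p, median_gap_wk=gap)
                )
                for grp, times in (("high", hi), ("low", lo)):
                    km = survival_analysis.km_estimate(times, group=grp)
                    frame = km.to_frame()
                    frame.insert(0, "predictor", model.predictor)
                    frame.insert(0, "cohort", cohort_name)
                    curve_rows.append(frame)
            except ValueError:
                continue
    survival_summary = pd.DataFrame(surv_rows)
    survival_summary.to_csv(out / "survival_summary.tsv", sep="\t", index=False)
    pd.concat(curve_rows, ignore_index=True).to_csv(
        out / "km_curves.tsv", sep="\t", index=False
    )
    manifest["stages"]["survive"] = {"comparisons": len(survival_summary)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    # -- report ------------------------------------------------------------
    (out / "report.md").write_text(render_report(out))
    return out


def _fmt(x, nd=3):
    return "NA" if x is None or (isinstance(x, float) and not np.isfinite(x)) else f"{x:.{nd}f}"


def render_report(run_dir: str | Path) -> str:
    """Human-readable summary of a finished run directory."""
    run_dir = Path(run_dir)
    with open(run_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    lines = ["# Biomarker pipeline run summary", ""]
    lines.append(f"Config hash: {manifest['config_hash']}  seed: {manifest['seed']}")
    lines.append("")
    lines.append("## Candidate refinement funnel")
    prot = manifest["stages"].get("proteomics", {})
    funnel = prot.get("funnel", {})
    if funnel:
        lines.append(
            f"- proteins screened: {funnel['screened']}; significant in discovery: "
            f"{funnel['significant']}; validated (concordant): {funnel['validated']}"
        )
        lines.append(f"- validated proteins: {', '.join(prot.get('validated', [])) or 'none'}")
    meta = manifest["stages"].get("meta", {})
    if meta:
        lines.append("")
        lines.append("## Meta-analysis")
        lines.append(
            f"- {meta['up']} up / {meta['down']} down candidates from "
            f"{meta['genes']} genes; planted recall {meta['planted_recall']:.2f}, "
            f"FPR {meta['false_positive_rate']:.3f}"
        )
    perf_path = run_dir / "stratified_performance.tsv"
    if perf_path.exists():
        perf = pd.read_csv(perf_path, sep="\t")
        lines.append("")
        lines.append("## Cohort performance (primary window)")
        overall = perf[(perf["stratum"] == "all")]
        for _, row in overall.iterrows():
            if row.get("suppressed", False):
                lines.append(
                    f"- {row['cohort']} / {row['predictor']}: suppressed — {row['reason']}"
                )
            else:
                lines.append(
                    f"- {row['cohort']} / {row['predictor']}: AUC {_fmt(row['auc'])} "
                    f"(95% CI {_fmt(row['auc_lo'])}-{_fmt(row['auc_hi'])}), "
                    f"sens {_fmt(row['sensitivity'], 2)}, spec {_fmt(row['specificity'], 2)}"
                )
        suppressed = perf[perf["suppressed"] == True]  # noqa: E712
        if len(suppressed):
            lines.append(
                f"- {len(suppressed)} strata suppressed "
                f"(insufficient n (<15) or single class)"
            )
    prev_path = run_dir / "prevalence_weighted_ppv.tsv"
    if prev_path.exists():
        prev = pd.read_csv(prev_path, sep="\t")
        lines.append("")
        lines.append("## Prevalence-weighted predictive values")
        if prev.empty:
            lines.append("- (empty)")
        for _, row in prev.iterrows():
            lines.append(
                f"- {row['cohort']} / {row['predictor']} @ prevalence "
                f"{row['prevalence']:.3f}: PPV {_fmt(row['ppv'])} "
                f"({_fmt(row['ppv_lo'])}-{_fmt(row['ppv_hi'])}), NPV {_fmt(row['npv'])}"
            )
    surv_path = run_dir / "survival_summary.tsv"
    if surv_path.exists():
        surv = pd.read_csv(surv_path, sep="\t")
        lines.append("")
        lines.append("## Time to delivery")
        if surv.empty:
            lines.append("- (empty)")
        for _, row in surv.iterrows():
            lines.append(
                f"- {row['cohort']} / {row['predictor']}: median gap "
                f"{row['median_gap_wk']:.1f} wk, log-rank chi2 "
                f"{row['logrank_chi2']:.2f} (p={row['logrank_p']:.2g})"
            )
    lines.append("")
    return "\n".join(lines)
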