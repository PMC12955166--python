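"""ROC/AUC, bootstrap CIs, stratified metrics, prevalence-weighted PPV,
cross-platform agreement and demographic-table statistics.

The AUC is the tie-corrected Mann–Whitney probability
``[#(case > control) + 0.5 * #(case = control)] / (n_case * n_control)``.
Confidence intervals are percentile bootstrap with stratified resampling
within outcome class.  Because the analytic sets are case-enriched by the
nested case-control design, predictive values at a population prevalence
pi are estimated by a prevalence-weighted bootstrap: each replicate draws
``round(pi * N)`` cases and the remaining controls with replacement,
reclassifies at the fixed transferred threshold, and recomputes PPV/NPV.

Demographic-table statistics reproduce the conventions of the printed
cohort tables: pooled-variance two-sample t (df = n1 + n2 - 2) or Wilcoxon
rank-sum for continuous variables, Pearson chi-square *without* continuity
correction for categorical ones, and the two-sided point-probability
Fisher exact test for sparse 2x2 tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StratificationScheme",
    "PrevalenceBootstrapConfig",
    "auc_mann_whitney",
    "bootstrap_ci",
    "confusion_metrics",
    "stratified_performance",
    "prevalence_weighted_bootstrap",
    "cross_platform_agreement",
    "cohort_table_stats",
    "fisher_exact_2x2",
    "chi_square_2xk",
    "pooled_t_from_summary",
    "ga_bin",
    "trimester",
]


# ---------------------------------------------------------------- core ROC

def auc_mann_whitney(scores, labels) -> float:
    """Tie-corrected AUC via the rank-sum identity U / (n1 * n0)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for AUC")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def bootstrap_ci(
    scores,
    labels,
    metric=auc_mann_whitney,
    n_reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI with stratified within-class resampling."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    if case_idx.size == 0 or ctrl_idx.size == 0:
        raise ValueError("both classes required for bootstrap")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_reps)
    for b in range(n_reps):
        idx = np.concatenate(
            [
                rng.choice(case_idx, size=case_idx.size, replace=True),
                rng.choice(ctrl_idx, size=ctrl_idx.size, replace=True),
            ]
        )
        vals[b] = metric(scores[idx], y[idx])
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    ppv_defined: bool = True
    npv_defined: bool = True


def confusion_metrics(risk_classes, labels) -> ConfusionMetrics:
    """2x2 confusion summaries; undefined cells flagged, never coerced to 0."""
    pred = np.asarray(risk_classes)
    pred = pred == "high" if pred.dtype.kind in "US" else pred.astype(bool)
    y = np.asarray(labels, dtype=int).astype(bool)
    tp = int((pred & y).sum())
    fn = int((~pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    if tp + fn == 0 or fp + tn == 0:
        raise ValueError("both classes required for confusion metrics")
    sens = tp / (tp + fn)
    spec = tn / (fp + tn)
    ppv_def = (tp + fp) > 0
    npv_def = (tn + fn) > 0
    ppv = tp / (tp + fp) if ppv_def else np.nan
    npv = tn / (tn + fn) if npv_def else np.nan
    return ConfusionMetrics(sens, spec, ppv, npv, ppv_def, npv_def)


# ------------------------------------------------------------- stratification

def trimester(ga_week) -> np.ndarray:
    """Obstetric trimester from GA in weeks: T1 through 13 weeks + 6 days,
    T2 through 27 weeks + 6 days, T3 from 28 completed weeks."""
    ga = np.atleast_1d(np.asarray(ga_week, dtype=float))
    out = np.where(ga < 14.0, "T1", np.where(ga < 28.0, "T2", "T3"))
    return out if np.ndim(ga_week) else out[0]


def ga_bin(ga_week) -> np.ndarray:
    """Sampling-window bin: <16 wk, 16 through 20 weeks + 6 days, >20 wk."""
    ga = np.atleast_1d(np.asarray(ga_week, dtype=float))
    out = np.where(ga < 16.0, "<16", np.where(ga < 21.0, "16-20", ">20"))
    return out if np.ndim(ga_week) else out[0]


@dataclass(frozen=True)
class StratificationScheme:
    """How to slice a cohort before computing metrics."""

    kind: str = "none"  # none | ga_bins | trimester | pprom | severity
    min_stratum_n: int = 15

    def assign(self, table: pd.DataFrame) -> pd.Series:
        if self.kind == "none":
            return pd.Series("all", index=table.index)
        if self.kind == "ga_bins":
            return pd.Series(ga_bin(table["ga_sample_wk"].to_numpy()), index=table.index)
        if self.kind == "trimester":
            return pd.Series(trimester(table["ga_sample_wk"].to_numpy()), index=table.index)
        if self.kind == "pprom":
            return table["pprom"].map({"pos": "pprom+", "neg": "pprom-", "na": "term"})
        if self.kind == "severity":
            ga_del = table["ga_delivery_wk"].astype(float)
            return pd.Series(
                np.where(ga_del < 34.0, "<34wk", np.where(ga_del < 37.0, "34-37wk", "term")),
                index=table.index,
            )
        raise ValueError(f"unknown stratification kind {self.kind!r}")


def stratified_performance(
    table: pd.DataFrame,
    score_column: str,
    scheme: StratificationScheme,
    threshold_model,
    label_column: str = "group",
    cohort: str = "",
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One row of metrics per stratum; strata below min_stratum_n are
    emitted with metrics suppressed and an explicit reason."""
    from .risk_scoring import apply_threshold

    strata = scheme.assign(table)
    rows = []
    for name in pd.unique(strata):
        sub = table[strata == name]
        y = (sub[label_column] == "sptb").astype(int).to_numpy()
        n_case, n_ctrl = int(y.sum()), int((1 - y).sum())
        base = dict(
            cohort=cohort,
            predictor=threshold_model.predictor,
            stratum=name,
            n_case=n_case,
            n_control=n_ctrl,
            threshold_source=threshold_model.derivation_cohort,
        )
        if len(sub) < scheme.min_stratum_n or n_case == 0 or n_ctrl == 0:
            reason = (
                f"insufficient n (<{scheme.min_stratum_n})"
                if len(sub) < scheme.min_stratum_n
                else "single outcome class"
            )
            rows.append({**base, "suppressed": True, "reason": reason})
            continue
        scores = sub[score_column].to_numpy(dtype=float)
        auc = auc_mann_whitney(scores, y)
        lo, hi = bootstrap_ci(scores, y, n_reps=bootstrap_reps, seed=seed)
        cm = confusion_metrics(apply_threshold(scores, threshold_model), y)
        rows.append(
            {
                **base,
                "suppressed": False,
                "reason": "",
                "auc": auc,
                "auc_lo": lo,
                "auc_hi": hi,
                "sensitivity": cm.sensitivity,
                "specificity": cm.specificity,
                "ppv": cm.ppv,
                "npv": cm.npv,
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------- prevalence-weighted bootstrap

@dataclass(frozen=True)
class PrevalenceBootstrapConfig:
    """Target population prevalence and bootstrap settings.

    Default priors: 10.4% for the US cohorts, 5.9% for the Asian cohorts.
    """

    target_prevalence: float
    n_reps: int = 1000
    seed: int = 0
    keep_total_n: bool = True

    def __post_init__(self):
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("need at least one replicate")


def prevalence_weighted_bootstrap(
    scores, labels, threshold_model, cfg: PrevalenceBootstrapConfig
) -> dict:
    """Re-estimate PPV/NPV at a population prevalence by class-weighted
    resampling of the case-enriched analytic set.

    Each replicate draws round(pi * N) cases and N - that controls with
    replacement, classifies at the fixed transferred threshold and records
    PPV/NPV.  Returns means, percentile 95% CIs, and the replicate vectors.
    """
    from .risk_scoring import apply_threshold

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    case_scores = scores[y == 1]
    ctrl_scores = scores[y == 0]
    if case_scores.size == 0 or ctrl_scores.size == 0:
        raise ValueError("both classes required")
    n_total = scores.size
    n_case = int(round(cfg.target_prevalence * n_total))
    if n_case < 1:
        raise ValueError(
            "target prevalence times N is below one case; use a larger analytic set"
        )
    rng = np.random.default_rng(cfg.seed)
    ppv = np.full(cfg.n_reps, np.nan)
    npv = np.full(cfg.n_reps, np.nan)
    for b in range(cfg.n_reps):
        cases = rng.choice(case_scores, size=n_case, replace=True)
        ctrls = rng.choice(ctrl_scores, size=n_total - n_case, replace=True)
        s = np.concatenate([cases, ctrls])
        yy = np.concatenate([np.ones(n_case, int), np.zeros(n_total - n_case, int)])
        cm = confusion_metrics(apply_threshold(s, threshold_model), yy)
        ppv[b] = cm.ppv if cm.ppv_defined else np.nan
        npv[b] = cm.npv if cm.npv_defined else np.nan

    def _summ(v):
        v = v[np.isfinite(v)]
        if v.size == 0:
            return dict(mean=np.nan, lo=np.nan, hi=np.nan)
        lo, hi = np.percentile(v, [2.5, 97.5])
        return dict(mean=float(v.mean()), lo=float(lo), hi=float(hi))

    return dict(
        ppv=_summ(ppv),
        npv=_summ(npv),
        ppv_replicates=ppv,
        npv_replicates=npv,
        n_case_per_replicate=n_case,
    )


# -------------------------------------------------- cross-platform agreement

def cross_platform_agreement(values_a, values_b) -> dict:
    """Pearson r plus Bland–Altman bias and 95% limits of agreement."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need at least 3 complete pairs")
    r_defined = a.std() > 0 and b.std() > 0
    r = float(stats.pearsonr(a, b).statistic) if r_defined else np.nan
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1)) if a.size > 1 else 0.0
    return dict(
        pearson_r=r,
        r_defined=bool(r_defined),
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=int(a.size),
    )


# ----------------------------------------------------- demographic statistics

def pooled_t_from_summary(n1, mean1, sd1, n2, mean2, sd2) -> tuple[float, int, float]:
    """Equal-variance two-sample t from printed summary statistics.

    Returns (t, df, two-sided p) with df = n1 + n2 - 2, the convention of
    the printed cohort demographic tables.
    """
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean2 - mean1) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), int(df), float(2.0 * stats.t.sf(abs(t), df))


def chi_square_2xk(table) -> tuple[float, int, float]:
    """Pearson chi-square WITHOUT continuity correction."""
    table = np.asarray(table, dtype=float)
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p by the point-probability method.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = np.round(t).astype(int)
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


def cohort_table_stats(
    participants: pd.DataFrame,
    continuous: dict[str, str] | None = None,
    categorical: list[str] | None = None,
    group_column: str = "group",
) -> pd.DataFrame:
    """Demographic comparison table for one cohort.

    ``continuous`` maps column -> test ("ttest" for mean(SD) with the
    pooled t, "ranksum" for median(IQR) with the two-sided rank-sum test);
    ``categorical`` columns get a Pearson chi-square without continuity
    correction, or a two-sided Fisher exact test for 2x2 tables with any
    expected cell below 5.
    """
    continuous = continuous or {"age_yr": "ttest", "bmi": "ranksum"}
    categorical = categorical if categorical is not None else ["mode_delivery"]
    groups = sorted(participants[group_column].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    g1 = participants[participants[group_column] == groups[0]]
    g2 = participants[participants[group_column] == groups[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("empty group")
    rows = []
    for col, test in continuous.items():
        a = g1[col].dropna().astype(float)
        b = g2[col].dropna().astype(float)
        if test == "ttest":
            t, df, p = pooled_t_from_summary(
                len(a), a.mean(), a.std(ddof=1), len(b), b.mean(), b.std(ddof=1)
            )
            rows.append(
                dict(variable=col, test=f"t-test ({df} df)", statistic=abs(t), p=p)
            )
        elif test == "ranksum":
            stat, p = stats.ranksums(a, b)
            rows.append(dict(variable=col, test="rank-sum", statistic=abs(stat), p=p))
        else:
            raise ValueError(f"unknown continuous test {test!r}")
    for col in categorical:
        tab = pd.crosstab(participants[col], participants[group_column])
        arr = tab.to_numpy()
        expected = stats.contingency.expected_freq(arr)
        if arr.shape == (2, 2) and (expected < 5).any():
            p = fisher_exact_2x2(arr)
            rows.append(dict(variable=col, test="Fisher exact", statistic=np.nan, p=p))
        else:
            chi2, dof, p = chi_square_2xk(arr)
            rows.append(
                dict(variable=col, test=f"chi-square ({dof} df)", statistic=chi2, p=p)
            )
    return pd.DataFrame(rows)
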