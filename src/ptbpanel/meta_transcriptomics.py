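"""Multi-study placental differential-expression integration.

Combines per-study differential-expression evidence for the same gene
universe across several independent expression studies using three
complementary summaries:

* **robust rank aggregation (RRA)** — each study contributes a normalized
  rank list; a gene consistently near the top of the lists receives a small
  rho score, computed from Beta order statistics under the null that ranks
  are i.i.d. uniform;
* **random-effects fold-change pooling** — DerSimonian–Laird moment
  estimation of the between-study variance tau^2, then inverse-variance
  pooling with weights 1/(v_i + tau^2);
* **Fisher's combined probability** — -2*sum(ln p_i) against chi^2 with 2m
  degrees of freedom.

Candidate genes are retained when present in every study, with pooled
absolute fold-change >= 1.2 (fold scale) and combined p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StudySummary",
    "normalize_ranks",
    "rra_rho",
    "pool_fold_changes",
    "fisher_combined",
    "welch_study_summary",
    "meta_analyze",
    "filter_candidates",
    "read_expression_tsv",
]


@dataclass
class StudySummary:
    """Per-gene differential-expression summaries for one study.

    Attributes
    ----------
    study_id : str
    genes : index of gene labels
    lfc : per-gene log2 fold change (case minus control group mean)
    var : per-gene sampling variance of ``lfc`` (Welch)
    p : per-gene two-sided p-value
    """

    study_id: str
    genes: pd.Index
    lfc: np.ndarray
    var: np.ndarray
    p: np.ndarray


def normalize_ranks(statistic: np.ndarray, direction: str = "descending") -> np.ndarray:
    """Normalized ranks r = rank/n in (0, 1], average ranks for ties.

    ``direction="descending"`` puts the largest statistic first (rank 1,
    smallest r) — the up-regulation list; ``"ascending"`` the reverse.
    """
    statistic = np.asarray(statistic, dtype=float)
    if statistic.size == 0:
        raise ValueError("cannot rank an empty statistic vector")
    if not np.all(np.isfinite(statistic)):
        raise ValueError("statistics must be finite")
    if direction == "descending":
        ranks = stats.rankdata(-statistic, method="average")
    elif direction == "ascending":
        ranks = stats.rankdata(statistic, method="average")
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return ranks / statistic.size


def rra_rho(ranks, n_genes: int | None = None) -> tuple[float, float]:
    """Robust rank aggregation score for one gene.

    With order statistics r_(1) <= ... <= r_(k) of the normalized ranks
    across the k studies, under the null each r_(j) ~ Beta(j, k-j+1); the
    rho score is the minimum over j of the Beta CDF at r_(j).  When a
    gene-universe size is supplied the Bonferroni-corrected p-value
    min(1, rho * n_genes) is also returned, else the raw rho twice.
    """
    r = np.sort(np.asarray(ranks, dtype=float))
    k = r.size
    if k == 0:
        raise ValueError("need at least one rank")
    if np.any(r <= 0) or np.any(r > 1):
        raise ValueError("normalized ranks must lie in (0, 1]")
    j = np.arange(1, k + 1)
    rho = float(np.min(stats.beta.cdf(r, j, k - j + 1)))
    corrected = min(1.0, rho * n_genes) if n_genes is not None else rho
    return rho, corrected


def pool_fold_changes(y, v) -> tuple[float, float, float]:
    """DerSimonian–Laird random-effects pooling of study effects.

    Returns ``(meta_lfc, tau2, pooled_variance)``.  Fixed-effect weights
    w_i = 1/v_i give Cochran's Q; the moment estimator
    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) feeds the
    random-effects weights 1/(v_i + tau2).
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    k = y.size
    if k == 0:
        raise ValueError("no studies to pool")
    if np.any(v <= 0):
        raise ValueError("sampling variances must be positive")
    w = 1.0 / v
    ybar = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - ybar) ** 2))
    if k == 1:
        tau2 = 0.0
    else:
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    wstar = 1.0 / (v + tau2)
    meta = float(np.sum(wstar * y) / np.sum(wstar))
    pooled_var = float(1.0 / np.sum(wstar))
    return meta, tau2, pooled_var


def fisher_combined(p) -> tuple[float, int, float]:
    """Fisher's combined probability: (-2*sum(ln p), df=2m, chi^2 upper tail)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    statistic = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return statistic, df, float(stats.chi2.sf(statistic, df))


def welch_study_summary(
    matrix: pd.DataFrame, labels: pd.Series, study_id: str = "study"
) -> StudySummary:
    """Per-gene Welch statistics on a genes-by-samples log2 matrix.

    ``labels`` maps sample id -> group with exactly two levels; the level
    sorted last is treated as the case group (``sptb`` sorts after
    ``term``), so lfc > 0 means higher in cases.
    """
    labels = labels.reindex(matrix.columns)
    groups = sorted(labels.dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    ctrl, case = groups[0], groups[1]
    a = matrix.loc[:, labels == case].to_numpy(dtype=float)
    b = matrix.loc[:, labels == ctrl].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1) / a.shape[1]
    vb = b.var(axis=1, ddof=1) / b.shape[1]
    lfc = ma - mb
    var = va + vb
    # Welch–Satterthwaite df; guard zero-variance genes
    with np.errstate(divide="ignore", invalid="ignore"):
        df = var**2 / (va**2 / (a.shape[1] - 1) + vb**2 / (b.shape[1] - 1))
        t = lfc / np.sqrt(var)
    df = np.where(np.isfinite(df), df, 1.0)
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    var = np.maximum(var, np.finfo(float).tiny)
    return StudySummary(study_id=study_id, genes=matrix.index, lfc=lfc, var=var, p=p)


def meta_analyze(summaries: list[StudySummary]) -> pd.DataFrame:
    """Integrate per-study summaries into one table of MetaGeneResult rows.

    Up- and down-regulation are aggregated as two separate one-directional
    rank lists (each study ranked by its signed fold change, descending for
    the up list and ascending for the down list); a gene's reported rho is
    the one matching the sign of its pooled fold change.
    """
    if not summaries:
        raise ValueError("no studies supplied")
    genes = summaries[0].genes
    for s in summaries[1:]:
        if not genes.equals(s.genes):
            raise ValueError("all studies must share the same gene universe")
    n_genes = len(genes)
    k = len(summaries)

    up_ranks = np.column_stack(
        [normalize_ranks(s.lfc, "descending") for s in summaries]
    )
    down_ranks = np.column_stack(
        [normalize_ranks(s.lfc, "ascending") for s in summaries]
    )
    lfc = np.column_stack([s.lfc for s in summaries])
    var = np.column_stack([s.var for s in summaries])
    pmat = np.column_stack([s.p for s in summaries])

    rows = []
    for i, gene in enumerate(genes):
        meta_lfc, tau2, pooled_var = pool_fold_changes(lfc[i], var[i])
        fstat, fdf, fp = fisher_combined(pmat[i])
        direction = "up" if meta_lfc >= 0 else "down"
        ranks = up_ranks[i] if direction == "up" else down_ranks[i]
        rho, rho_p = rra_rho(ranks, n_genes=n_genes)
        rows.append(
            dict(
                gene=gene,
                n_studies_present=k,
                meta_lfc=meta_lfc,
                tau2=tau2,
                pooled_var=pooled_var,
                rra_rho=rho,
                rra_p=rho_p,
                fisher_stat=fstat,
                fisher_df=fdf,
                fisher_p=fp,
                direction=direction,
            )
        )
    return pd.DataFrame(rows).set_index("gene")


def filter_candidates(
    results: pd.DataFrame,
    min_abs_fold: float = 1.2,
    max_p: float = 0.05,
    require_all_studies: bool = True,
    n_studies: int | None = None,
) -> tuple[list[str], list[str]]:
    """Partition significant genes into (up, down) candidate lists.

    A gene passes iff present in all studies, |2^meta_lfc| >= ``min_abs_fold``
    (fold scale) and combined p < ``max_p``.  Empty output is allowed.
    """
    if min_abs_fold <= 0 or max_p <= 0:
        raise ValueError("thresholds must be positive")
    if results.empty:
        return [], []
    fold = 2.0 ** results["meta_lfc"].abs()
    keep = (fold >= min_abs_fold) & (results["fisher_p"] < max_p)
    if require_all_studies:
        total = n_studies if n_studies is not None else results["n_studies_present"].max()
        keep &= results["n_studies_present"] == total
    kept = results.loc[keep]
    up = kept.index[kept["meta_lfc"] >= 0].tolist()
    down = kept.index[kept["meta_lfc"] < 0].tolist()
    return up, down


def read_expression_tsv(matrix_path, labels_path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a genes-by-samples TSV and a (sample_id, group) label TSV."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t")
    return matrix, labels.set_index("sample_id")["group"]
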