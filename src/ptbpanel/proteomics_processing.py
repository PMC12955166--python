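"""Peptide-level QC, normalization, protein roll-up and candidate screening.

Mirrors a targeted mass-spectrometry workflow downstream of peak-area
extraction: peptides with more than 20% missing values or technical
replicate CV of 15% or worse are excluded; retained peak areas are
log2-transformed and global-median normalized per sample; protein
abundances are the mean of their observed peptides; and the discovery
screen is a two-sided Mann–Whitney U test per protein with
Benjamini–Hochberg FDR control, followed by a direction/magnitude
concordance check in the validation cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PeptideMatrix",
    "ScreenResult",
    "filter_peptides",
    "normalize_peptides",
    "rollup_proteins",
    "screen_candidates",
    "concordance_check",
]


@dataclass
class PeptideMatrix:
    """Raw peptide peak areas with a peptide -> protein assignment.

    ``values`` is peptides x samples (missing allowed as NaN);
    ``protein`` maps each peptide row to exactly one protein label;
    ``replicate_groups`` optionally maps sample id -> technical-replicate
    group for CV-based reproducibility filtering.
    """

    values: pd.DataFrame
    protein: pd.Series
    replicate_groups: pd.Series | None = None

    def __post_init__(self):
        if not self.values.index.equals(self.protein.index):
            self.protein = self.protein.reindex(self.values.index)
        if self.protein.isna().any():
            missing = self.protein.index[self.protein.isna()].tolist()
            raise ValueError(f"peptides without protein assignment: {missing}")
        if not self.values.attrs.get("log2", False):
            vals = self.values.to_numpy(dtype=float)
            if np.isfinite(vals).any() and np.nanmin(vals) < 0:
                raise ValueError("raw intensities must be >= 0 or missing")

    @classmethod
    def from_long(cls, frame: pd.DataFrame) -> "PeptideMatrix":
        """Build from long-format records (peptide_id, protein, sample_id,
        intensity[, replicate])."""
        wide = frame.pivot_table(
            index="peptide_id", columns="sample_id", values="intensity", aggfunc="mean"
        )
        protein = frame.drop_duplicates("peptide_id").set_index("peptide_id")["protein"]
        protein = protein.reindex(wide.index)
        reps = None
        if "replicate" in frame.columns:
            reps = frame.drop_duplicates("sample_id").set_index("sample_id")["replicate"]
            reps = reps.reindex(wide.columns)
        return cls(wide, protein, reps)


def filter_peptides(
    matrix: PeptideMatrix,
    max_missing_fraction: float = 0.20,
    max_replicate_cv: float = 0.15,
) -> tuple[PeptideMatrix, pd.DataFrame]:
    """Drop peptides with missing fraction strictly above the cap or, when
    technical-replicate annotations exist, replicate CV >= the cap.

    Returns the retained matrix and a per-peptide report; proteins whose
    peptides were all dropped are flagged in the report's attrs under
    ``"fully_dropped_proteins"`` rather than silently vanishing.
    """
    if not 0 < max_missing_fraction < 1 or not 0 < max_replicate_cv < 1:
        raise ValueError("fractions must lie in (0, 1)")
    vals = matrix.values
    if vals.empty:
        raise ValueError("empty peptide matrix")
    missing_frac = vals.isna().mean(axis=1)
    drop_missing = missing_frac > max_missing_fraction

    cv = pd.Series(np.nan, index=vals.index)
    if matrix.replicate_groups is not None:
        groups = matrix.replicate_groups.dropna()
        multi = groups.value_counts()
        multi = multi.index[multi >= 2]
        cvs = []
        for g in multi:
            cols = groups.index[groups == g]
            sub = vals[cols]
            m = sub.mean(axis=1)
            s = sub.std(axis=1, ddof=1)
            cvs.append(s / m.where(m != 0))
        if cvs:
            cv = pd.concat(cvs, axis=1).mean(axis=1)
    drop_cv = cv.ge(max_replicate_cv).fillna(False)

    keep = ~(drop_missing | drop_cv)
    report = pd.DataFrame(
        dict(
            protein=matrix.protein,
            missing_fraction=missing_frac,
            replicate_cv=cv,
            dropped=~keep,
            reason=np.where(
                drop_missing, "missing>20%", np.where(drop_cv, "cv>=15%", "")
            ),
        )
    )
    kept_proteins = set(matrix.protein[keep])
    lost = sorted(set(matrix.protein) - kept_proteins)
    report.attrs["fully_dropped_proteins"] = lost
    filtered = PeptideMatrix(
        vals.loc[keep], matrix.protein.loc[keep], matrix.replicate_groups
    )
    return filtered, report


def normalize_peptides(matrix: PeptideMatrix) -> PeptideMatrix:
    """log2 transform then per-sample global median centring.

    After normalization every sample column has median 0 over its observed
    cells; missing cells stay missing.  Idempotent up to the log: applying
    the median centring twice equals applying it once.
    """
    already_log = matrix.values.attrs.get("log2", False)
    vals = matrix.values.astype(float)
    if already_log:
        logged = vals
    else:
        bad = vals.le(0).fillna(False)
        if bad.any().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"nonpositive intensity at peptide {vals.index[r]!r}, "
                f"sample {vals.columns[c]!r}"
            )
        logged = np.log2(vals)
    centred = logged - logged.median(axis=0, skipna=True)
    centred.attrs["log2"] = True
    return PeptideMatrix(centred, matrix.protein, matrix.replicate_groups)


def rollup_proteins(matrix: PeptideMatrix) -> pd.DataFrame:
    """Protein abundance = mean over that protein's observed peptides;
    missing only when every peptide is missing in the sample."""
    return matrix.values.groupby(matrix.protein).mean()


@dataclass
class ScreenResult:
    protein: str
    u_statistic: float
    p: float
    q: float
    direction: str
    effect: float  # case median minus control median
    concordant_in_validation: bool | None = None


def _mann_whitney(case, ctrl) -> tuple[float, float]:
    """Two-sided Mann–Whitney; exact enumeration when both groups <= 8 with
    no ties, tie-corrected normal approximation otherwise."""
    no_ties = len(np.unique(np.concatenate([case, ctrl]))) == len(case) + len(ctrl)
    method = "exact" if (len(case) <= 8 and len(ctrl) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(case, ctrl, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def screen_candidates(
    proteins: pd.DataFrame,
    labels: pd.Series,
    alpha_fdr: float = 0.05,
    case_label: str = "sptb",
) -> list[ScreenResult]:
    """Per-protein two-sided Mann–Whitney with BH adjustment across the
    screened protein set; significant iff q < ``alpha_fdr``."""
    labels = labels.reindex(proteins.columns)
    levels = sorted(labels.dropna().unique())
    if len(levels) < 2:
        raise ValueError("need both outcome groups to screen")
    case_cols = labels.index[labels == case_label]
    ctrl_cols = labels.index[(labels != case_label) & labels.notna()]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    results = []
    for prot, row in proteins.iterrows():
        case = row[case_cols].dropna().to_numpy(dtype=float)
        ctrl = row[ctrl_cols].dropna().to_numpy(dtype=float)
        u, p = _mann_whitney(case, ctrl)
        effect = float(np.median(case) - np.median(ctrl))
        results.append(
            ScreenResult(
                protein=str(prot),
                u_statistic=u,
                p=p,
                q=np.nan,
                direction="up" if effect >= 0 else "down",
                effect=effect,
            )
        )
    qs = multipletests([r.p for r in results], method="fdr_bh")[1]
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def concordance_check(
    discovery: list[ScreenResult],
    validation_proteins: pd.DataFrame,
    validation_labels: pd.Series,
    min_effect_fraction: float = 0.5,
    case_label: str = "sptb",
) -> list[ScreenResult]:
    """Mark each discovery hit concordant iff the validation group-median
    difference has the same sign and at least ``min_effect_fraction`` of the
    discovery magnitude.  Proteins absent from validation are flagged
    non-evaluable (concordant = None is replaced by False with direction
    'absent' noted via effect = NaN)."""
    labels = validation_labels.reindex(validation_proteins.columns)
    case_cols = labels.index[labels == case_label]
    ctrl_cols = labels.index[(labels != case_label) & labels.notna()]
    out = []
    for r in discovery:
        if r.protein not in validation_proteins.index:
            out.append(
                ScreenResult(r.protein, r.u_statistic, r.p, r.q, r.direction,
                             np.nan, concordant_in_validation=False)
            )
            continue
        row = validation_proteins.loc[r.protein]
        v_effect = float(
            np.nanmedian(row[case_cols].to_numpy(dtype=float))
            - np.nanmedian(row[ctrl_cols].to_numpy(dtype=float))
        )
        same_sign = np.sign(v_effect) == np.sign(r.effect) and v_effect != 0
        big_enough = abs(v_effect) >= min_effect_fraction * abs(r.effect)
        out.append(
            ScreenResult(r.protein, r.u_statistic, r.p, r.q, r.direction,
                         r.effect, concordant_in_validation=bool(same_sign and big_enough))
        )
    return out
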