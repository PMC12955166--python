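"""Composite risk score, comparator ratio, and Youden threshold transfer.

The three-protein panel score is the unweighted sum of the cohort z-scores
of GPX3, NID1 and PAPPA2.  The comparator is the IBP4/SHBG ratio, computed
here as a log-ratio of MoM values so it is symmetric and unbounded like the
panel score.  A binary cut-point is derived once, on the discovery cohort,
at the maximum of the Youden index J = sensitivity + specificity - 1, and
then transferred unchanged to every validation cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdModel",
    "panel_score",
    "ratio_score",
    "derive_youden_threshold",
    "apply_threshold",
]


@dataclass(frozen=True)
class ThresholdModel:
    """A transferred binary cut-point: high risk iff score >= cutoff."""

    predictor: str
    cutoff: float
    derivation_cohort: str
    youden_j: float

    def __post_init__(self):
        if not -1.0 <= self.youden_j <= 1.0:
            raise ValueError("Youden J must lie in [-1, 1]")
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")


def panel_score(z_gpx3, z_nid1, z_pappa2):
    """Composite three-protein score: z_GPX3 + z_NID1 + z_PAPPA2."""
    arrs = [np.asarray(a, dtype=float) for a in (z_gpx3, z_nid1, z_pappa2)]
    for a in arrs:
        if np.any(~np.isfinite(a)):
            raise ValueError("panel score requires all three z-scores finite")
    return arrs[0] + arrs[1] + arrs[2]


def ratio_score(ibp4_mom, shbg_mom):
    """Comparator score: ln(IBP4 MoM / SHBG MoM)."""
    a = np.asarray(ibp4_mom, dtype=float)
    b = np.asarray(shbg_mom, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("ratio score requires positive MoM inputs")
    return np.log(a / b)


def _sens_spec(scores, y, cutoff):
    pred = scores >= cutoff
    sens = np.mean(pred[y == 1]) if np.any(y == 1) else np.nan
    spec = np.mean(~pred[y == 0]) if np.any(y == 0) else np.nan
    return sens, spec


def derive_youden_threshold(
    scores, labels, predictor: str = "three_protein", cohort: str = "discovery"
) -> ThresholdModel:
    """Cut-point maximizing J over midpoints of adjacent distinct scores.

    Candidates are the midpoints between adjacent distinct sorted scores
    plus sentinels below/above every score.  Ties in J are broken toward
    higher specificity, then toward the lower cutoff, so the derivation is
    deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if scores.size != y.size or scores.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes required to derive a threshold")
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))
    best = None
    for c in candidates:
        sens, spec = _sens_spec(scores, y, c)
        j = sens + spec - 1.0
        key = (j, spec, -c)  # maximize J, then specificity, then prefer lower cutoff
        if best is None or key > best[0]:
            best = (key, c, j)
    return ThresholdModel(predictor, float(best[1]), cohort, float(best[2]))


def apply_threshold(scores, model: ThresholdModel) -> np.ndarray:
    """Classify scores with a transferred model: 'high' iff score >= cutoff."""
    scores = np.asarray(scores, dtype=float)
    return np.where(scores >= model.cutoff, "high", "low")


def score_samples(normalized: pd.DataFrame) -> pd.DataFrame:
    """Attach panel and ratio scores to a normalized sample table.

    Expects the ``{analyte}_z`` and ``{analyte}_mom`` columns produced by
    the normalization stage.
    """
    out = normalized.copy()
    out["panel_score"] = panel_score(
        out["GPX3_z"], out["NID1_z"], out["PAPPA2_z"]
    )
    out["ratio_score"] = ratio_score(out["IBP4_mom"], out["SHBG_mom"])
    return out
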