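"""Gestational-age-specific multiples-of-median (MoM) normalization.

Serum analyte concentrations change physiologically across pregnancy, so a
raw abundance is not comparable between a 10-week and a 25-week draw.  The
standard prenatal-screening remedy is the multiple of the median: each
measurement is divided by the GA-specific median of a reference population
(here, by default, the term-outcome samples of the same cohort).  MoM
values are then natural-log-transformed and z-standardized within cohort
(mean 0, SD 1, n-1 denominator) to harmonize scale across cohorts and
measurement platforms.

The reference median curve is tabulated per completed week of gestation;
weeks with fewer than ``min_n`` reference samples are filled by linear
interpolation between neighbouring well-populated weeks and by nearest-week
extrapolation at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceMedianCurve",
    "fit_reference_curve",
    "to_mom",
    "log_z_standardize",
    "normalize_samples",
]


@dataclass(frozen=True)
class ReferenceMedianCurve:
    """Per-analyte GA-week reference medians with the fill rule applied."""

    analyte: str
    cohort: str
    week_grid: np.ndarray  # sorted integer completed weeks
    median_by_week: np.ndarray  # positive medians, same length

    def __post_init__(self):
        if len(self.week_grid) == 0:
            raise ValueError("empty week grid")
        if np.any(self.median_by_week <= 0):
            raise ValueError("reference medians must be positive")

    def __call__(self, ga_week) -> np.ndarray:
        """Evaluate at completed week floor(ga); nearest-week outside the grid."""
        week = np.floor(np.atleast_1d(np.asarray(ga_week, dtype=float)))
        idx = np.searchsorted(self.week_grid, week).clip(0, len(self.week_grid) - 1)
        # searchsorted gives the right neighbour; pick the nearer grid week
        left = np.maximum(idx - 1, 0)
        pick = np.where(
            np.abs(self.week_grid[idx] - week) <= np.abs(self.week_grid[left] - week),
            idx,
            left,
        )
        out = self.median_by_week[pick]
        return out if np.ndim(ga_week) else float(out[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                analyte=self.analyte,
                cohort=self.cohort,
                week=self.week_grid.astype(int),
                median=self.median_by_week,
            )
        )


def fit_reference_curve(
    reference: pd.DataFrame,
    analyte: str,
    cohort: str = "",
    ga_column: str = "ga_sample_wk",
    min_n: int = 5,
) -> ReferenceMedianCurve:
    """Fit the per-completed-week median curve from reference samples.

    Weeks with at least ``min_n`` reference draws anchor the curve; sparser
    weeks inside the anchored span are linearly interpolated and the edges
    extend as constants.  If no week reaches ``min_n`` the threshold falls
    back to 1 so a curve always exists for a non-empty reference set.
    """
    values = reference[analyte].astype(float)
    ok = values.notna() & (values > 0)
    if not ok.any():
        raise ValueError(f"empty reference set for analyte {analyte!r}")
    week = np.floor(reference.loc[ok, ga_column].astype(float)).astype(int)
    grouped = values[ok].groupby(week)
    counts = grouped.count()
    anchors = counts.index[counts >= min_n]
    if len(anchors) == 0:
        anchors = counts.index  # fall back: every populated week anchors
    medians = grouped.median()
    lo = int(min(counts.index)), int(max(counts.index))
    grid = np.arange(lo[0], lo[1] + 1)
    anchor_weeks = np.asarray(anchors, dtype=float)
    anchor_meds = medians.loc[anchors].to_numpy(dtype=float)
    filled = np.interp(grid.astype(float), anchor_weeks, anchor_meds)
    return ReferenceMedianCurve(analyte, cohort, grid, filled)


def to_mom(value, ga, curve: ReferenceMedianCurve):
    """MoM = value / reference median at floor(ga) completed weeks."""
    value = np.asarray(value, dtype=float)
    if np.any(value <= 0):
        raise ValueError("concentration values must be positive for MoM")
    return value / curve(ga)


def log_z_standardize(
    mom: pd.Series, cohort: pd.Series
) -> pd.Series:
    """z = (ln MoM - cohort mean ln MoM) / cohort SD ln MoM (ddof=1)."""
    if (mom <= 0).any():
        raise ValueError("MoM values must be positive")
    logm = np.log(mom.astype(float))
    out = pd.Series(np.nan, index=mom.index, dtype=float)
    for coh, idx in logm.groupby(cohort).groups.items():
        vals = logm.loc[idx]
        if len(vals) < 2:
            raise ValueError(f"need >= 2 samples per cohort cell, cohort {coh!r}")
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero variance in cohort {coh!r}; cannot z-score")
        out.loc[idx] = (vals - vals.mean()) / sd
    return out


def normalize_samples(
    samples: pd.DataFrame,
    participants: pd.DataFrame,
    analytes,
    reference_group: str = "term",
    min_n: int = 5,
    group_by_platform: bool = True,
) -> tuple[pd.DataFrame, dict[tuple[str, str], ReferenceMedianCurve]]:
    """Full MoM -> log -> z chain over a sample table, cohort by cohort.

    The reference set for each (cohort, analyte) cell is the samples of
    participants with the ``reference_group`` outcome in that cohort
    (configurable to ``"all"``).  Returns the sample table with added
    ``{analyte}_mom`` and ``{analyte}_z`` columns plus the fitted curves.
    """
    meta = participants.set_index("participant_id")[["cohort", "group"]]
    merged = samples.join(meta, on="participant_id")
    out = samples.copy()
    curves: dict[tuple[str, str], ReferenceMedianCurve] = {}
    cell = merged["cohort"].astype(str)
    if group_by_platform and "platform" in merged.columns:
        cell = cell + "/" + merged["platform"].astype(str)
    for analyte in analytes:
        mom = pd.Series(np.nan, index=merged.index, dtype=float)
        for coh in cell.unique():
            in_cell = cell == coh
            ref = merged[in_cell]
            if reference_group != "all":
                ref = ref[ref["group"] == reference_group]
            curve = fit_reference_curve(ref, analyte, cohort=coh, min_n=min_n)
            curves[(coh, analyte)] = curve
            mom.loc[in_cell] = to_mom(
                merged.loc[in_cell, analyte], merged.loc[in_cell, "ga_sample_wk"], curve
            )
        out[f"{analyte}_mom"] = mom
        out[f"{analyte}_z"] = log_z_standardize(mom, cell)
    return out, curves
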