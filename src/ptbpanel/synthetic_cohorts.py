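"""Synthetic nested case-control cohorts for the serum biomarker pipeline.

Emulates a four-site pregnancy biomarker study: each cohort enrolls term
and spontaneous-preterm-birth (sPTB) participants, every participant
contributes one or more pre-outcome serum draws inside a cohort-specific
gestational-age (GA) sampling window, and each draw carries abundances for
the five analytes the pipeline scores (GPX3, NID1, PAPPA2, IBP4, SHBG).

Analyte generation model, on the natural-log concentration scale::

    log C = baseline(GA) + delta * 1[sPTB] + b_participant + eps

with ``b_participant ~ N(0, participant_sd^2)`` shared across a
participant's draws and ``eps ~ N(0, residual_sd^2)`` per draw.  Default
SDs are 0.6 and 0.8 so the total per-draw SD is exactly 1, which makes the
standardized case shift ``delta`` directly interpretable through the
binormal equal-variance identity ``AUC = Phi(delta / sqrt(2))``.

The module also plants differential genes into multi-study expression
matrices so the meta-analysis stage can be exercised without any download,
and subsamples registry-scale tables into case-enriched analytic sets the
way a nested case-control design does.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

ANALYTES = ("GPX3", "NID1", "PAPPA2", "IBP4", "SHBG")

__all__ = [
    "ANALYTES",
    "CohortSpec",
    "AnalyteModel",
    "MetaStudySpec",
    "calibrate_effect_size",
    "panel_effect_size",
    "default_analyte_models",
    "default_cohort_specs",
    "generate_cohort",
    "generate_meta_studies",
    "enrich_case_control",
]


def calibrate_effect_size(target_auc: float) -> float:
    """Standardized shift delta achieving ``target_auc`` under the binormal
    equal-variance model: delta = sqrt(2) * Phi^{-1}(AUC)."""
    if not 0.5 <= target_auc < 1.0:
        raise ValueError(f"target AUC must lie in [0.5, 1), got {target_auc}")
    return float(np.sqrt(2.0) * stats.norm.ppf(target_auc))


def panel_effect_size(target_auc: float, n_analytes: int = 3) -> float:
    """Per-analyte shift so that the *sum of z-scores* of ``n_analytes``
    independent equally-shifted analytes hits ``target_auc``.

    The composite of n unit-SD scores has SD sqrt(n), so the per-analyte
    shift is the calibrated composite delta divided by sqrt(n).
    """
    return calibrate_effect_size(target_auc) / float(np.sqrt(n_analytes))


@dataclass(frozen=True)
class AnalyteModel:
    """Generation model for one serum analyte.

    ``case_shift`` is the standardized sPTB shift on the log scale (added
    directly; total log SD is participant_sd^2 + residual_sd^2 = 1 at the
    defaults).  ``cohort_shift_overrides`` replaces the shift in named
    cohorts — used to emulate SHBG's inconsistent cross-population trends.
    """

    analyte: str
    baseline: tuple[float, float] = (2.0, 0.0)  # (intercept, slope) of log-median vs GA week
    case_shift: float = 0.0
    participant_sd: float = 0.6
    residual_sd: float = 0.8
    cohort_shift_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.participant_sd < 0:
            raise ValueError("participant_sd must be >= 0")

    def baseline_curve(self, ga_week) -> np.ndarray:
        """Median log-concentration as a function of GA in weeks."""
        a, b = self.baseline
        return a + b * np.asarray(ga_week, dtype=float)

    def shift_for(self, cohort_id: str) -> float:
        return self.cohort_shift_overrides.get(cohort_id, self.case_shift)


@dataclass(frozen=True)
class CohortSpec:
    """Design of one synthetic cohort (sizes, GA windows, outcome mix)."""

    cohort_id: str
    n_term: int
    n_sptb: int
    samples_per_participant: tuple[int, int] = (1, 1)
    ga_sampling_window: tuple[float, float] = (5.0, 30.0)
    ga_delivery_term: tuple[float, float] = (39.5, 1.2)  # mean, sd; truncated [37, 42]
    ga_delivery_sptb_early: tuple[float, float] = (30.5, 2.5)  # < 34 wk component
    ga_delivery_sptb_late: tuple[float, float] = (35.5, 0.8)  # 34 - <37 wk component
    sptb_early_weight: float = 0.35
    pprom_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.n_term < 0 or self.n_sptb < 0:
            raise ValueError("cohort sizes must be non-negative")
        lo, hi = self.ga_sampling_window
        if not (5.0 <= lo <= hi <= 36.0):
            raise ValueError("GA sampling window must lie within [5, 36] weeks")
        if not 0.0 <= self.sptb_early_weight <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")
        kmin, kmax = self.samples_per_participant
        if kmin < 1 or kmax < kmin:
            raise ValueError("samples_per_participant range invalid")


@dataclass(frozen=True)
class MetaStudySpec:
    """Design of the multi-study expression fixture for the meta-analysis."""

    n_studies: int = 6
    n_genes: int = 1000
    n_per_group: int = 20
    de_fraction: float = 0.05
    planted_lfc: float = 1.0
    heterogeneity_sd: float = 0.0
    within_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_studies < 2:
            raise ValueError("need at least two studies")
        if not 0.0 <= self.de_fraction < 1.0:
            raise ValueError("de_fraction must lie in [0, 1)")
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be >= 0")
        if self.n_per_group < 2:
            raise ValueError("need n_per_group >= 2")


# Baseline log-median curves: PAPPA2 rises with gestation, the others vary
# gently; intercepts spread the analytes over distinct concentration ranges.
_DEFAULT_BASELINES = {
    "GPX3": (3.0, 0.010),
    "NID1": (2.0, 0.015),
    "PAPPA2": (1.0, 0.060),
    "IBP4": (2.5, 0.020),
    "SHBG": (4.0, 0.025),
}


def default_analyte_models(
    panel_target_auc: float = 0.90,
    ibp4_shift: float = 0.35,
    shbg_shift: float = 0.30,
    shbg_overrides: dict[str, float] | None = None,
) -> list[AnalyteModel]:
    """Analyte models for a cohort whose composite panel targets ``panel_target_auc``.

    GPX3/NID1/PAPPA2 share a positive per-analyte shift derived from the
    composite target; IBP4 is mildly elevated; SHBG carries per-cohort
    overrides (default: null effect in the Asian cohorts) so the IBP4/SHBG
    ratio comparator degrades outside its development population.
    """
    delta = panel_effect_size(panel_target_auc)
    if shbg_overrides is None:
        shbg_overrides = {"asia1": 0.0, "asia2": -0.05}
    models = []
    for name in ("GPX3", "NID1", "PAPPA2"):
        models.append(AnalyteModel(name, _DEFAULT_BASELINES[name], case_shift=delta))
    models.append(AnalyteModel("IBP4", _DEFAULT_BASELINES["IBP4"], case_shift=ibp4_shift))
    models.append(
        AnalyteModel(
            "SHBG",
            _DEFAULT_BASELINES["SHBG"],
            case_shift=shbg_shift,
            cohort_shift_overrides=dict(shbg_overrides),
        )
    )
    return models


def default_cohort_specs(seed: int = 0) -> dict[str, CohortSpec]:
    """The four study-design cohorts: two US sites and two Asian sites.

    Sizes and sampling windows follow the study design (UAB 11/14 single
    draws at 13-29 wk; Stanford 19/31 longitudinal at 7-36 wk; Asia 1
    194/114 longitudinal at 5-30 wk; Asia 2 50/23 single draws at 5-28 wk).
    sPTB delivery mixtures are set so printed medians (e.g. UAB 28, Asia 1
    35) are approximated: UAB is early-dominated, the others late-dominated.
    """
    return {
        "uab": CohortSpec(
            "uab", 11, 14, (1, 1), (13.0, 29.0),
            ga_delivery_sptb_early=(28.0, 2.5), sptb_early_weight=0.8,
            seed=seed + 1,
        ),
        "stanford": CohortSpec(
            "stanford", 19, 31, (1, 4), (7.0, 36.0),
            sptb_early_weight=0.4, seed=seed + 2,
        ),
        "asia1": CohortSpec(
            "asia1", 194, 114, (1, 2), (5.0, 30.0),
            sptb_early_weight=0.3, seed=seed + 3,
        ),
        "asia2": CohortSpec(
            "asia2", 50, 23, (1, 1), (5.0, 28.0),
            sptb_early_weight=0.35, seed=seed + 4,
        ),
    }


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), size=size)
    return mean + sd * stats.norm.ppf(u)


def _delivery_ga(rng, spec: CohortSpec, group: np.ndarray) -> np.ndarray:
    ga = np.empty(group.size)
    term = group == "term"
    ga[term] = _truncated_normal(rng, *spec.ga_delivery_term, 37.0, 42.0, term.sum())
    sptb = ~term
    n_sptb = int(sptb.sum())
    early = rng.random(n_sptb) < spec.sptb_early_weight
    draws = np.empty(n_sptb)
    me, se = spec.ga_delivery_sptb_early
    ml, sl = spec.ga_delivery_sptb_late
    draws[early] = _truncated_normal(rng, me, se, 22.0, 34.0, int(early.sum()))
    draws[~early] = _truncated_normal(rng, ml, sl, 34.0, 36.99, int((~early).sum()))
    ga[sptb] = draws
    return np.round(ga, 1)


# Demographic summaries loosely following the four printed cohort tables;
# simulated only so the demographics-statistics stage has realistic input.
_DEMOGRAPHICS = {
    "uab": dict(age=((25.5, 5.1), (26.9, 4.7)), bmi=((28.1, 7.6), (30.2, 10.1)),
                cesarean=(0.05, 0.45)),
    "stanford": dict(age=((31.9, 4.9), (31.7, 6.5)), bmi=((22.8, 3.5), (28.0, 6.0)),
                     cesarean=(0.32, 0.65)),
    "asia1": dict(age=((30.0, 3.0), (31.4, 3.6)), bmi=((25.6, 2.8), (24.4, 3.4)),
                  cesarean=(0.31, 0.59)),
    "asia2": dict(age=((31.5, 4.8), (32.6, 3.8)), bmi=((20.8, 2.9), (20.4, 1.7)),
                  cesarean=(0.28, 0.74)),
}
_DEFAULT_DEMO = dict(age=((30.0, 4.0), (30.5, 4.5)), bmi=((24.0, 4.0), (25.0, 5.0)),
                     cesarean=(0.3, 0.6))


def generate_cohort(
    spec: CohortSpec, models: list[AnalyteModel]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (participant table, sample table) for one cohort.

    Every sample GA is strictly below that participant's delivery GA
    (pre-outcome draws only).  Identical specs produce identical tables.
    """
    names = [m.analyte for m in models]
    if len(set(names)) != len(names):
        raise ValueError("duplicate analyte labels in models")
    rng = np.random.default_rng(spec.seed)

    n = spec.n_term + spec.n_sptb
    part_cols = [
        "participant_id", "cohort", "group", "pprom", "ga_delivery_wk",
        "mode_delivery", "age_yr", "bmi",
    ]
    samp_cols = ["sample_id", "participant_id", "ga_sample_wk", "platform", "batch"] + names
    if n == 0:
        return pd.DataFrame(columns=part_cols), pd.DataFrame(columns=samp_cols)

    group = np.array(["term"] * spec.n_term + ["sptb"] * spec.n_sptb)
    pid = np.array([f"{spec.cohort_id}-P{i:04d}" for i in range(n)])
    ga_del = _delivery_ga(rng, spec, group)

    pprom = np.where(group == "term", "na", "neg")
    is_sptb = group == "sptb"
    pprom_pos = rng.random(n) < spec.pprom_fraction
    pprom[is_sptb & pprom_pos] = "pos"

    demo = _DEMOGRAPHICS.get(spec.cohort_id, _DEFAULT_DEMO)
    age = np.where(
        is_sptb,
        rng.normal(*demo["age"][1], size=n),
        rng.normal(*demo["age"][0], size=n),
    ).round(1)
    bmi = np.where(
        is_sptb,
        rng.normal(*demo["bmi"][1], size=n),
        rng.normal(*demo["bmi"][0], size=n),
    ).round(1)
    bmi = np.clip(bmi, 15.0, 55.0)
    p_cs = np.where(is_sptb, demo["cesarean"][1], demo["cesarean"][0])
    mode = np.where(rng.random(n) < p_cs, "cesarean", "nsvd")

    participants = pd.DataFrame(
        dict(
            participant_id=pid, cohort=spec.cohort_id, group=group, pprom=pprom,
            ga_delivery_wk=ga_del, mode_delivery=mode, age_yr=age, bmi=bmi,
        )
    )

    # longitudinal schedule: k ~ uniform int in range, sorted uniform GAs in
    # the window truncated strictly below delivery
    kmin, kmax = spec.samples_per_participant
    lo, hi = spec.ga_sampling_window
    rows = []
    b_effects = {
        m.analyte: rng.normal(0.0, m.participant_sd, size=n) for m in models
    }
    for i in range(n):
        k = int(rng.integers(kmin, kmax + 1))
        upper = min(hi, ga_del[i] - 0.5)
        lower = min(lo, upper)
        gas = np.sort(np.round(rng.uniform(lower, upper, size=k), 1))
        gas = np.minimum(gas, ga_del[i] - 0.1)
        for j, ga in enumerate(gas):
            row = dict(
                sample_id=f"{pid[i]}-S{j}",
                participant_id=pid[i],
                ga_sample_wk=float(ga),
                platform="msms",
                batch=f"b{i % 4}",
            )
            for m in models:
                shift = m.shift_for(spec.cohort_id) if is_sptb[i] else 0.0
                logc = (
                    m.baseline_curve(ga)
                    + shift
                    + b_effects[m.analyte][i]
                    + rng.normal(0.0, m.residual_sd)
                )
                row[m.analyte] = float(np.exp(logc))
            rows.append(row)
    samples = pd.DataFrame(rows, columns=samp_cols)
    return participants, samples


def generate_meta_studies(
    spec: MetaStudySpec,
) -> list[tuple[pd.DataFrame, pd.Series, np.ndarray]]:
    """Multi-study expression matrices with planted differential genes.

    Returns one ``(matrix, labels, planted_mask)`` triple per study; the
    planted mask and effect signs are shared across studies, per-study
    effect magnitudes are Normal(planted_lfc, heterogeneity_sd^2).
    """
    rng = np.random.default_rng(spec.seed)
    genes = pd.Index([f"G{i:05d}" for i in range(spec.n_genes)])
    n_de = int(round(spec.de_fraction * spec.n_genes))
    planted = np.zeros(spec.n_genes, dtype=bool)
    planted[rng.choice(spec.n_genes, size=n_de, replace=False)] = True
    signs = np.where(rng.random(spec.n_genes) < 0.8, 1.0, -1.0)  # mostly up
    base = rng.normal(7.0, 1.5, size=spec.n_genes)  # gene-level log2 baseline

    out = []
    for s in range(spec.n_studies):
        effect = np.zeros(spec.n_genes)
        effect[planted] = signs[planted] * rng.normal(
            spec.planted_lfc, spec.heterogeneity_sd, size=n_de
        )
        n = spec.n_per_group
        ctrl = base[:, None] + rng.normal(0.0, spec.within_sd, size=(spec.n_genes, n))
        case = (
            base[:, None]
            + effect[:, None]
            + rng.normal(0.0, spec.within_sd, size=(spec.n_genes, n))
        )
        cols = [f"s{s}_ctrl{i}" for i in range(n)] + [f"s{s}_case{i}" for i in range(n)]
        matrix = pd.DataFrame(np.hstack([ctrl, case]), index=genes, columns=cols)
        labels = pd.Series(
            ["term"] * n + ["sptb"] * n, index=cols, name="group"
        )
        out.append((matrix, labels, planted.copy()))
    return out


def enrich_case_control(
    participants: pd.DataFrame, target_case_fraction: float, seed: int
) -> pd.DataFrame:
    """Nested case-control subsampling to a target case fraction.

    Keeps all cases and samples controls without replacement to reach the
    target fraction; if controls are the surplus class already, cases are
    subsampled against all controls instead.  The realized fraction is
    within 1/n of the target.
    """
    if not 0.0 < target_case_fraction < 1.0:
        raise ValueError("target case fraction must lie in (0, 1)")
    cases = participants[participants["group"] == "sptb"]
    controls = participants[participants["group"] == "term"]
    f = target_case_fraction
    if len(cases) == 0:
        raise ValueError("no sPTB cases available; cannot enrich")
    if len(controls) == 0:
        raise ValueError("no term controls available; cannot enrich")
    rng = np.random.default_rng(seed)
    n_ctrl_wanted = int(round(len(cases) * (1.0 - f) / f))
    if n_ctrl_wanted < 1:
        raise ValueError(
            "infeasible target case fraction: too few sPTB cases to keep even "
            "one matched term control"
        )
    if n_ctrl_wanted <= len(controls):
        keep_ctrl = controls.sample(n=n_ctrl_wanted, random_state=rng)
        out = pd.concat([cases, keep_ctrl])
    else:
        n_case_wanted = int(round(len(controls) * f / (1.0 - f)))
        if n_case_wanted > len(cases) or n_case_wanted < 1:
            raise ValueError(
                "infeasible target case fraction: too few sPTB cases to pair "
                "with the available term controls"
            )
        keep_case = cases.sample(n=n_case_wanted, random_state=rng)
        out = pd.concat([keep_case, controls])
    return out.sort_index()


def generate_peptide_screen(
    n_proteins: int = 21,
    peptides_per_protein: int = 2,
    n_term: int = 11,
    n_sptb: int = 14,
    shifted_proteins: tuple[str, ...] = ("GPX3", "NID1", "PAPPA2"),
    case_shift: float = 2.0,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic discovery-screen peptide table for the refinement funnel.

    Emulates a targeted assay quantifying ``n_proteins`` candidates in a
    small discovery cohort, of which exactly the ``shifted_proteins`` carry
    a case shift on the log2 scale.  Returns a long-format peptide frame
    (peptide_id, protein, sample_id, intensity) and sample group labels.
    """
    rng = np.random.default_rng(seed)
    extras = [f"CAND{i:02d}" for i in range(n_proteins - len(shifted_proteins))]
    proteins = list(shifted_proteins) + extras
    sample_ids = [f"D{i:03d}" for i in range(n_term + n_sptb)]
    labels = pd.Series(
        ["term"] * n_term + ["sptb"] * n_sptb, index=sample_ids, name="group"
    )
    rows = []
    for prot in proteins:
        base = rng.uniform(14.0, 20.0)  # log2 peak-area scale
        shift = case_shift if prot in shifted_proteins else 0.0
        for pep in range(peptides_per_protein):
            pep_offset = rng.normal(0.0, 0.5)
            for s, sid in enumerate(sample_ids):
                if rng.random() < missing_rate:
                    continue
                mu = base + pep_offset + (shift if labels.iloc[s] == "sptb" else 0.0)
                rows.append(
                    dict(
                        peptide_id=f"{prot}_pep{pep}",
                        protein=prot,
                        sample_id=sid,
                        intensity=float(2.0 ** rng.normal(mu, 0.8)),
                    )
                )
    return pd.DataFrame(rows), labels


def table_checksum(frame: pd.DataFrame) -> str:
    """Stable content hash of a table (order-sensitive), for determinism checks."""
    payload = frame.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()
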