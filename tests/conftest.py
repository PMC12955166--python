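import numpy as np
import pandas as pd
import pytest

from ptbpanel import ga_normalization as gn
from ptbpanel import risk_scoring as rs
from ptbpanel import synthetic_cohorts as sc


@pytest.fixture(scope="session")
def stanford_like():
    """A small longitudinal validation-style cohort calibrated to AUC 0.93."""
    spec = sc.CohortSpec(
        "stanford", 19, 31, (1, 4), (7.0, 36.0), sptb_early_weight=0.4, seed=0
    )
    models = sc.default_analyte_models(panel_target_auc=0.93)
    return sc.generate_cohort(spec, models)


@pytest.fixture(scope="session")
def asia1_like():
    """A large single/dual-draw external-validation cohort at AUC 0.80."""
    spec = sc.CohortSpec(
        "asia1", 194, 114, (1, 2), (5.0, 30.0), sptb_early_weight=0.3, seed=0
    )
    models = sc.default_analyte_models(panel_target_auc=0.80)
    return sc.generate_cohort(spec, models)


def scored_cohort(part, samp):
    """MoM -> z -> composite scores, joined with outcome labels."""
    norm, _ = gn.normalize_samples(samp, part, sc.ANALYTES)
    scored = rs.score_samples(norm)
    meta = part.set_index("participant_id")[["group", "ga_delivery_wk", "cohort"]]
    return scored.join(meta, on="participant_id")


@pytest.fixture(scope="session")
def scored_stanford(stanford_like):
    return scored_cohort(*stanford_like)


@pytest.fixture(scope="session")
def scored_asia1(asia1_like):
    return scored_cohort(*asia1_like)
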