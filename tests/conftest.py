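"""Shared fixtures: small hand-checkable cohorts and seeded simulations."""

import numpy as np
import pytest

from reopair import synthetic as syn
from reopair.io import SurvivalCohort


@pytest.fixture
def four_sample_cohort() -> SurvivalCohort:
    """All-event cohort whose Cox fit is verifiable by grid search."""
    return SurvivalCohort(
        ("a", "b", "c", "d"),
        np.array([2.0, 4.0, 6.0, 8.0]),
        np.array([1, 1, 1, 1]),
    )


@pytest.fixture(scope="session")
def planted_pair_study():
    """Training + validation cohorts whose hazard is driven by two planted
    gene-pair orderings (hazard ratio 4 per pair, n = 250)."""
    baseline = syn.ExponentialBaseline(0.02)
    train = syn.simulate_pair_signature(
        n_pairs=2, n_decoy_genes=0, n_samples=250, log_hr=np.log(4.0),
        baseline=baseline, censor_horizon=120.0, seed=1,
    )
    valid = syn.simulate_pair_signature(
        n_pairs=2, n_decoy_genes=0, n_samples=250, log_hr=np.log(4.0),
        baseline=baseline, censor_horizon=120.0, seed=2,
    )
    return train, valid


def matched_study_datasets():
    """Matched tissue/cell-line study with 12 planted genes (|beta| = 1) and
    a 90% sign-consistent cell-line experiment; two tissue cohorts plus one
    validation cohort drawn from the same generative truth."""
    n_genes = 300
    planted = {f"G{i:04d}": (1.0 if i % 2 else -1.0) for i in range(1, 13)}

    def tissue(seed):
        cfg = syn.TissueSimConfig(
            n_genes=n_genes, n_samples=250, beta_map=planted,
            baseline=syn.ExponentialBaseline(0.015),
            censor_horizon=120.0, seed=seed,
        )
        return syn.simulate_tissue(cfg)

    matched = syn.MatchedSimConfig(
        consistency_rho=0.9,
        cellline=syn.CellLineSimConfig(
            n_genes=n_genes, n_per_group=3, n_de=12, lfc=3.0,
            noise_sd=0.5, seed=104,
        ),
        tissue=syn.TissueSimConfig(
            n_genes=n_genes, n_samples=250, beta_map=planted,
            baseline=syn.ExponentialBaseline(0.015),
            censor_horizon=120.0, seed=101,
        ),
    )
    (t_expr, t_coh, _), (c_expr, c_des, c_truth) = syn.simulate_matched(matched)
    t2_expr, t2_coh, _ = tissue(102)
    v_expr, v_coh, _ = tissue(103)
    return {
        "planted": planted,
        "tissue": [("tisA", t_expr, t_coh), ("tisB", t2_expr, t2_coh)],
        "cellline": ("clX", c_expr, c_des, c_truth),
        "validation": ("val", v_expr, v_coh),
    }


@pytest.fixture(scope="session")
def matched_study():
    return matched_study_datasets()
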