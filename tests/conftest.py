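"""Shared fixtures: synthetic sessions at study and desk scale."""

import numpy as np
import pytest

from nocilabel.features import build_feature_table
from nocilabel.labeling import label_units, session_deltas
from nocilabel.synth import SyntheticConfig, generate_session


@pytest.fixture(scope="session")
def default_study():
    """A full default-scale study (14+14 wells, ~620 units/arm), seed fixed."""
    cfg = SyntheticConfig(seed=1)
    treated, truth_t = generate_session(cfg, "treated")
    untreated, truth_u = generate_session(cfg, "untreated")
    return cfg, treated, truth_t, untreated, truth_u


@pytest.fixture(scope="session")
def default_labels(default_study):
    _, treated, _, untreated, _ = default_study
    labels, model, threshold = label_units(
        session_deltas(treated), session_deltas(untreated)
    )
    return labels, model, threshold


@pytest.fixture(scope="session")
def default_features(default_study, default_labels):
    _, treated, truth_t, _, _ = default_study
    labels, _, _ = default_labels
    features, exclusions = build_feature_table(treated, labels)
    truth = features.merge(
        truth_t[["well_id", "unit_id", "is_responder"]],
        on=["well_id", "unit_id"],
    )["is_responder"].to_numpy()
    return features, exclusions, truth


@pytest.fixture(scope="session")
def small_session():
    """A quick 3-well session for unit-level tests."""
    cfg = SyntheticConfig(seed=11, n_wells_treated=3, units_per_well=(10, 14))
    session, truth = generate_session(cfg, "treated")
    return session, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
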