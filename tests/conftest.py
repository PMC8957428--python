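import numpy as np
import pytest

from hrvcdet import (
    CohortSpec,
    FeatureTable,
    default_stage_profiles,
)


@pytest.fixture(scope="session")
def calibrated_profiles():
    """Stage profiles calibrated once per session to the stage SDNN set-points."""
    return default_stage_profiles(calibrate=True, seed=12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small 3-stage cohort (uncalibrated profiles, 8 subjects/stage)."""
    from hrvcdet import simulate_cohort

    profiles = default_stage_profiles(calibrate=False)
    profiles = tuple(
        type(p)(
            stage=p.stage, mean_rr=p.mean_rr, lf_amp=p.lf_amp, hf_amp=p.hf_amp,
            noise_sd=p.noise_sd, target_sdnn=p.target_sdnn, duration=120.0,
        )
        for p in profiles
    )
    spec = CohortSpec(profiles=profiles, subjects_per_stage=8, seed=7)
    table, series = simulate_cohort(spec)
    return table, series


def random_grouped_data(rng, n_classes=3, n_per_class=6, n_features=4, sep=0.0):
    """Random grouped data as nested lists (oracle input) and a FeatureTable."""
    groups = []
    labels = []
    rows = []
    for y in range(n_classes):
        cls_rows = (rng.normal(sep * y, 1.0, size=(n_per_class, n_features))).tolist()
        groups.append(cls_rows)
        for r in cls_rows:
            labels.append(f"c{y}")
            rows.append(r)
    table = FeatureTable(
        subject_ids=tuple(f"s{i}" for i in range(len(rows))),
        class_labels=tuple(labels),
        X=np.array(rows),
        feature_names=tuple(f"f{m}" for m in range(n_features)),
    )
    return groups, table
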