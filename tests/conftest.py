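import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from faciemg import SynthConfig, make_fixture

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 noise-free sessions, grades 1 and 3, 6 patients."""
    return make_fixture("tiny_separable")


@pytest.fixture(scope="session")
def dropout_cohort():
    """6 sessions; the first misses one movement and keeps one single-rep pose."""
    return make_fixture("dropouts")


@pytest.fixture(scope="session")
def fast_cfg():
    """Light, short-trace configuration for single-session/trace tests."""
    return SynthConfig(
        sampling_rate_hz=500.0,
        trace_duration_s=2.0,
        tension_duration_s=0.8,
        relaxation_duration_s=1.2,
        band_hz=(20.0, 200.0),
        cohort_distribution={1: 1},
        unlabeled_count=0,
        patient_plan={1: 1},
    )


def synthetic_amplitude_records(rng, measurement_id="M1", muscles=None, poses=None,
                                repetitions=3, ipsi_scale=1.0):
    """Directly fabricated amplitude records (no signal processing)."""
    from faciemg import MUSCLES, POSES

    muscles = muscles or MUSCLES
    poses = poses or POSES
    rows = []
    for m in muscles:
        for p in poses:
            for rep in range(1, repetitions + 1):
                contra = rng.uniform(50, 150)
                rows.append((measurement_id, m, "ipsi", p, rep, contra * ipsi_scale, 0.0))
                rows.append((measurement_id, m, "contra", p, rep, contra, 0.0))
    return pd.DataFrame(
        rows,
        columns=[
            "measurement_id", "muscle", "side", "pose", "repetition",
            "amplitude_uv", "epoch_start_s",
        ],
    )


def synthetic_feature_table(rng, n_per_grade, separation=3.0, n_patients=None):
    """Feature table with grade-dependent LI means, bypassing the signal chain.

    Grade g gets feature mean -(g - 1) * separation / 10 with unit-free noise,
    so larger ``separation`` makes grades more distinguishable.
    """
    from faciemg.features import FLAG_NONE, feature_columns, flag_columns

    cols = feature_columns()
    rows = []
    mid = 0
    grades = [g for g, n in sorted(n_per_grade.items()) for _ in range(n)]
    n_patients = n_patients or max(2, len(grades) // 2)
    for i, g in enumerate(grades):
        mid += 1
        mean = -(g - 1) * separation / 10.0
        vals = np.clip(mean + 0.05 * rng.standard_normal(len(cols)), -1, 1)
        row = {
            "measurement_id": f"M{mid:03d}",
            "patient_id": f"P{(i % n_patients) + 1:02d}",
            "timepoint": "pre",
            "hb": g,
        }
        row.update(dict(zip(cols, vals)))
        row.update({c: FLAG_NONE for c in flag_columns()})
        rows.append(row)
    df = pd.DataFrame(rows)
    df["hb"] = df["hb"].astype("Int64")
    return df
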