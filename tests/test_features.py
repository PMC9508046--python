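"""Lateralization-index features: formula, aggregation, imputation rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from faciemg import MUSCLES, POSES, build_features, lateralization_index
from faciemg.features import (
    FLAG_NONE,
    FLAG_PARTIAL,
    FLAG_WHOLE,
    FeatureVector,
    feature_columns,
    impute_missing,
)
from conftest import synthetic_amplitude_records

amps = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)


def labels_for(mid="M1", patient="P01", hb=2):
    return pd.DataFrame(
        [{"patient_id": patient, "measurement_id": mid, "timepoint": "pre",
          "operated_side": "left", "hb": hb}]
    )


class TestLateralizationIndex:
    @pytest.mark.parametrize(
        "ipsi,contra,expected",
        [
            (5.0, 5.0, 0.0),      # symmetric activity
            (7.3, 0.0, 1.0),      # all activity on the operated side
            (0.0, 2.1, -1.0),     # all activity contralateral
            (3.0, 1.0, 0.5),
            (0.0, 0.0, 0.0),      # degenerate: no activity at all
        ],
    )
    def test_worked_examples(self, ipsi, contra, expected):
        assert lateralization_index(ipsi, contra) == pytest.approx(expected)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            lateralization_index(-1.0, 2.0)

    @given(amps, amps)
    def test_bounded_and_antisymmetric(self, a, b):
        li = lateralization_index(a, b)
        assert -1.0 <= li <= 1.0
        assert lateralization_index(b, a) == pytest.approx(-li)

    @given(amps, amps, st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, a, b, c):
        assert lateralization_index(c * a, c * b) == pytest.approx(
            lateralization_index(a, b), abs=1e-9
        )


class TestBuildFeatures:
    def test_repetition_mean(self):
        """Per-repetition LIs 0.2, 0.4, 0.6 average to 0.4."""
        rows = []
        # ipsi/contra pairs engineered to give LI 0.2, 0.4, 0.6
        for rep, li in enumerate([0.2, 0.4, 0.6], start=1):
            contra = 10.0
            ipsi = contra * (1 + li) / (1 - li)
            for m in MUSCLES:
                for p in POSES:
                    rows.append(("M1", m, "ipsi", p, rep, ipsi, 0.0))
                    rows.append(("M1", m, "contra", p, rep, contra, 0.0))
        records = pd.DataFrame(rows, columns=[
            "measurement_id", "muscle", "side", "pose", "repetition",
            "amplitude_uv", "epoch_start_s"])
        feats = build_features(records, labels_for())
        for col in feature_columns():
            assert feats[col].iloc[0] == pytest.approx(0.4)
            assert feats[f"imputed__{col.split('__')[0]}__{col.split('__')[1]}"].iloc[0] == FLAG_NONE

    def test_single_available_repetition_is_kept_and_flagged(self):
        rng = np.random.default_rng(0)
        records = synthetic_amplitude_records(rng)
        # keep only repetition 2 of one pose
        drop = (records["pose"] == "smile") & (records["repetition"] != 2)
        records = records[~drop]
        feats = build_features(records, labels_for())
        one = records[(records["pose"] == "smile") & (records["muscle"] == MUSCLES[0])]
        ipsi = one[one["side"] == "ipsi"]["amplitude_uv"].iloc[0]
        contra = one[one["side"] == "contra"]["amplitude_uv"].iloc[0]
        assert feats[f"{MUSCLES[0]}__smile"].iloc[0] == pytest.approx(
            lateralization_index(ipsi, contra)
        )
        assert feats[f"imputed__{MUSCLES[0]}__smile"].iloc[0] == FLAG_PARTIAL

    def test_unpaired_repetitions_are_dropped(self):
        rng = np.random.default_rng(1)
        records = synthetic_amplitude_records(rng)
        # remove the contra side of repetition 3 of one pose: rep 3 unpaired
        drop = ((records["pose"] == "smile") & (records["repetition"] == 3)
                & (records["side"] == "contra"))
        feats = build_features(records[~drop], labels_for())
        kept = records[(records["pose"] == "smile") & (records["muscle"] == MUSCLES[0])
                       & (records["repetition"] != 3)]
        expected = np.mean([
            lateralization_index(
                kept[(kept["repetition"] == r) & (kept["side"] == "ipsi")]["amplitude_uv"].iloc[0],
                kept[(kept["repetition"] == r) & (kept["side"] == "contra")]["amplitude_uv"].iloc[0],
            )
            for r in (1, 2)
        ])
        assert feats[f"{MUSCLES[0]}__smile"].iloc[0] == pytest.approx(expected)
        assert feats[f"imputed__{MUSCLES[0]}__smile"].iloc[0] == FLAG_PARTIAL

    def test_symmetric_amplitudes_give_zero_features(self):
        rng = np.random.default_rng(2)
        records = synthetic_amplitude_records(rng, ipsi_scale=1.0)
        feats = build_features(records, labels_for(hb=1))
        assert np.allclose(feats[feature_columns()].to_numpy(dtype=float), 0.0)

    def test_exactly_21_features_in_range(self):
        rng = np.random.default_rng(3)
        records = synthetic_amplitude_records(rng, ipsi_scale=0.4)
        feats = build_features(records, labels_for())
        vals = feats[feature_columns()].to_numpy(dtype=float)
        assert vals.shape == (1, 21)
        assert np.all((vals >= -1) & (vals <= 1))

    def test_antisymmetry_under_side_swap(self):
        rng = np.random.default_rng(4)
        records = synthetic_amplitude_records(rng, ipsi_scale=0.6)
        swapped = records.copy()
        swapped["side"] = swapped["side"].map({"ipsi": "contra", "contra": "ipsi"})
        f1 = build_features(records, labels_for())[feature_columns()].to_numpy(float)
        f2 = build_features(swapped, labels_for())[feature_columns()].to_numpy(float)
        assert np.allclose(f1, -f2)

    def test_scale_invariance_of_measurement(self):
        rng = np.random.default_rng(5)
        records = synthetic_amplitude_records(rng, ipsi_scale=0.7)
        scaled = records.copy()
        scaled["amplitude_uv"] *= 17.0
        f1 = build_features(records, labels_for())[feature_columns()].to_numpy(float)
        f2 = build_features(scaled, labels_for())[feature_columns()].to_numpy(float)
        assert np.allclose(f1, f2)

    def test_no_usable_pairs_rejected(self):
        rng = np.random.default_rng(6)
        records = synthetic_amplitude_records(rng)
        ipsi_only = records[records["side"] == "ipsi"]
        with pytest.raises(ValueError, match="usable"):
            build_features(ipsi_only, labels_for())


class TestWholeMovementImputation:
    def test_missing_pose_receives_muscle_mean_of_other_poses(self):
        rng = np.random.default_rng(7)
        records = synthetic_amplitude_records(rng, ipsi_scale=0.5)
        missing_pose = POSES[2]
        records = records[records["pose"] != missing_pose]
        feats = build_features(records, labels_for())
        for m in MUSCLES:
            others = [feats[f"{m}__{p}"].iloc[0] for p in POSES if p != missing_pose]
            assert feats[f"{m}__{missing_pose}"].iloc[0] == pytest.approx(np.mean(others))
            assert feats[f"imputed__{m}__{missing_pose}"].iloc[0] == FLAG_WHOLE

    def test_imputed_value_stays_inside_observed_hull(self):
        rng = np.random.default_rng(8)
        records = synthetic_amplitude_records(rng, ipsi_scale=0.5)
        records = records[records["pose"] != POSES[0]]
        feats = build_features(records, labels_for())
        for m in MUSCLES:
            others = [feats[f"{m}__{p}"].iloc[0] for p in POSES[1:]]
            v = feats[f"{m}__{POSES[0]}"].iloc[0]
            assert min(others) - 1e-12 <= v <= max(others) + 1e-12

    def test_impute_missing_identity_when_complete(self):
        rng = np.random.default_rng(9)
        feats = build_features(synthetic_amplitude_records(rng), labels_for())
        out = impute_missing(feats)
        pd.testing.assert_frame_equal(out, feats)

    def test_muscle_with_no_observed_poses_rejected(self):
        rng = np.random.default_rng(10)
        records = synthetic_amplitude_records(rng)
        records = records[records["muscle"] != MUSCLES[0]]
        with pytest.raises(ValueError, match="no observed poses"):
            build_features(records, labels_for())

    def test_worked_six_value_mean(self):
        """A muscle observed at 0.1..0.6 over six poses imputes 0.35."""
        rows = []
        for p, li in zip(POSES[:6], [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]):
            contra = 10.0
            ipsi = contra * (1 + li) / (1 - li)
            for m in MUSCLES:
                for rep in (1, 2, 3):
                    rows.append(("M1", m, "ipsi", p, rep, ipsi, 0.0))
                    rows.append(("M1", m, "contra", p, rep, contra, 0.0))
        records = pd.DataFrame(rows, columns=[
            "measurement_id", "muscle", "side", "pose", "repetition",
            "amplitude_uv", "epoch_start_s"])
        feats = build_features(records, labels_for())
        for m in MUSCLES:
            assert feats[f"{m}__{POSES[6]}"].iloc[0] == pytest.approx(0.35)


class TestFeatureVector:
    def test_roundtrip_from_row(self):
        rng = np.random.default_rng(11)
        feats = build_features(synthetic_amplitude_records(rng), labels_for(hb=3))
        fv = FeatureVector.from_row(feats.iloc[0])
        assert fv.measurement_id == "M1"
        assert fv.hb == 3
        assert len(fv.li) == 21
        assert all(v == FLAG_NONE for v in fv.imputed.values())

    def test_dropout_fixture_flags(self, dropout_cohort):
        """End-to-end: the session with a missing movement and a
        single-repetition pose carries the matching imputation flags."""
        from faciemg.signal import process_cohort

        records = process_cohort(dropout_cohort.sessions)
        feats = build_features(records, dropout_cohort.labels_frame())
        broken = dropout_cohort.sessions[0].measurement_id
        row = feats[feats["measurement_id"] == broken].iloc[0]
        assert all(row[f"imputed__{m}__smile"] == FLAG_WHOLE for m in MUSCLES)
        assert all(row[f"imputed__{m}__wrinkle_nose"] == FLAG_PARTIAL for m in MUSCLES)
        vals = row[feature_columns()].to_numpy(dtype=float)
        assert np.all((vals >= -1) & (vals <= 1))
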