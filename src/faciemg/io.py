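"""On-disk formats.

Raw traces use a long CSV dialect, one file per measurement session
(``<measurement_id>.csv``) with columns::

    measurement_id,channel,side,pose,repetition,sample_index,value_uv

where ``channel`` is the muscle name. Session metadata live in a single
``labels.csv`` (``patient_id,measurement_id,timepoint,operated_side,hb``;
an empty ``hb`` marks a missing clinical rating). Amplitude records and
feature tables are plain CSV as produced by their modules.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .simulate import EMGTrace, MeasurementSession, SyntheticCohort

__all__ = [
    "write_cohort_csv",
    "read_cohort_csv",
    "write_labels",
    "read_labels",
    "write_amplitudes",
    "read_amplitudes",
    "write_features",
    "read_features",
]

LABEL_COLUMNS = ("patient_id", "measurement_id", "timepoint", "operated_side", "hb")
TRACE_COLUMNS = (
    "measurement_id",
    "channel",
    "side",
    "pose",
    "repetition",
    "sample_index",
    "value_uv",
)


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels = labels[list(LABEL_COLUMNS)]
    labels.to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "measurement_id": str})
    df["hb"] = df["hb"].astype("Int64")
    return df


def session_to_frame(session: MeasurementSession) -> pd.DataFrame:
    """Long-format frame of all traces of one session."""
    frames = []
    for tr in session.traces:
        frames.append(
            pd.DataFrame(
                {
                    "measurement_id": tr.measurement_id,
                    "channel": tr.muscle,
                    "side": tr.side,
                    "pose": tr.pose,
                    "repetition": tr.repetition,
                    "sample_index": range(len(tr.samples)),
                    "value_uv": tr.samples,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_cohort_csv(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """One long CSV per session plus labels.csv (and the truth table)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for session in cohort.sessions:
        session_to_frame(session).to_csv(out / f"{session.measurement_id}.csv", index=False)
    write_labels(cohort.labels_frame(), out / "labels.csv")
    truth = pd.DataFrame(
        sorted(cohort.truth.items()), columns=["measurement_id", "true_hb"]
    )
    truth.to_csv(out / "truth.csv", index=False)


def _frame_to_session(frame: pd.DataFrame, meta: pd.Series, fs: float) -> MeasurementSession:
    traces = []
    keys = ["channel", "side", "pose", "repetition"]
    for (muscle, side, pose, rep), grp in frame.groupby(keys, sort=True):
        grp = grp.sort_values("sample_index")
        traces.append(
            EMGTrace(
                samples=grp["value_uv"].to_numpy(),
                sampling_rate_hz=fs,
                muscle=muscle,
                side=side,
                pose=pose,
                repetition=int(rep),
                measurement_id=str(meta["measurement_id"]),
            )
        )
    hb = meta["hb"]
    return MeasurementSession(
        measurement_id=str(meta["measurement_id"]),
        patient_id=str(meta["patient_id"]),
        timepoint=str(meta.get("timepoint", "")),
        operated_side=str(meta.get("operated_side", "")),
        hb=None if pd.isna(hb) else int(hb),
        traces=traces,
    )


def read_cohort_csv(data_dir: str | Path, sampling_rate_hz: float = 1000.0):
    """Read sessions and labels written by :func:`write_cohort_csv`.

    Returns (sessions, labels). The CSV dialect carries no sampling rate;
    pass the recording's rate explicitly.
    """
    data_dir = Path(data_dir)
    labels_path = data_dir / "labels.csv"
    if not labels_path.exists():
        raise FileNotFoundError(f"no labels.csv in {data_dir} (empty or wrong directory?)")
    labels = read_labels(labels_path)
    sessions = []
    for _, meta in labels.iterrows():
        path = data_dir / f"{meta['measurement_id']}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing session file {path}")
        frame = pd.read_csv(path)
        sessions.append(_frame_to_session(frame, meta, sampling_rate_hz))
    return sessions, labels


def write_amplitudes(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_amplitudes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"measurement_id": str})


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"measurement_id": str, "patient_id": str})
    df["hb"] = df["hb"].astype("Int64")
    return df
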