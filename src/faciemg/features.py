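"""Lateralization-index features.

For every muscle x pose, the lateralization index

    LI = (EMG_ipsi - EMG_contra) / (EMG_ipsi + EMG_contra)

is computed per repetition from the paired envelope amplitudes and averaged
over the available repetitions, giving 21 features per measurement (3 muscles
x 7 poses). LI is +1 if all activity is on the operated side, -1 if all is
contralateral, and 0 for perfect symmetry; it is scale-free, so gain
differences between recording setups cancel.

Missing data follow two rules: a pose with at least one usable repetition
keeps the mean over what is available (flag ``partial_repetitions``); a pose
with no usable repetitions receives the mean LI of the same muscle over all
other poses (flag ``whole_movement``), so gaps are filled with similar values
instead of zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MUSCLES, POSES

__all__ = [
    "lateralization_index",
    "build_features",
    "impute_missing",
    "FeatureVector",
    "feature_columns",
    "flag_columns",
]

FLAG_NONE = "none"
FLAG_PARTIAL = "partial_repetitions"
FLAG_WHOLE = "whole_movement"


def lateralization_index(emg_ipsi: float, emg_contra: float) -> float:
    """(ipsi - contra) / (ipsi + contra), with 0/0 defined as 0."""
    if emg_ipsi < 0 or emg_contra < 0:
        raise ValueError("amplitudes must be nonnegative (rectified envelopes)")
    total = emg_ipsi + emg_contra
    if total == 0:
        return 0.0
    return (emg_ipsi - emg_contra) / total


def feature_columns(muscles=MUSCLES, poses=POSES) -> list[str]:
    return [f"{m}__{p}" for m in muscles for p in poses]


def flag_columns(muscles=MUSCLES, poses=POSES) -> list[str]:
    return [f"imputed__{m}__{p}" for m in muscles for p in poses]


@dataclass
class FeatureVector:
    """One measurement's 21 lateralization indices with imputation flags."""

    measurement_id: str
    patient_id: str
    hb: int | None
    li: dict[tuple[str, str], float] = field(default_factory=dict)
    imputed: dict[tuple[str, str], str] = field(default_factory=dict)

    @classmethod
    def from_row(cls, row: pd.Series, muscles=MUSCLES, poses=POSES) -> "FeatureVector":
        li = {(m, p): float(row[f"{m}__{p}"]) for m in muscles for p in poses}
        imputed = {(m, p): str(row[f"imputed__{m}__{p}"]) for m in muscles for p in poses}
        hb = row.get("hb")
        return cls(
            measurement_id=str(row["measurement_id"]),
            patient_id=str(row["patient_id"]),
            hb=None if pd.isna(hb) else int(hb),
            li=li,
            imputed=imputed,
        )


def _per_measurement_li(records: pd.DataFrame) -> pd.DataFrame:
    """Per-repetition LI for one measurement's amplitude records.

    Repetitions with only one side recorded are unpaired and dropped.
    """
    wide = records.pivot_table(
        index=["muscle", "pose", "repetition"],
        columns="side",
        values="amplitude_uv",
        aggfunc="first",
    )
    for side in ("ipsi", "contra"):
        if side not in wide.columns:
            wide[side] = np.nan
    paired = wide.dropna(subset=["ipsi", "contra"])
    li = paired.apply(lambda r: lateralization_index(r["ipsi"], r["contra"]), axis=1)
    out = paired.reset_index()[["muscle", "pose", "repetition"]]
    out["li"] = li.to_numpy()
    return out


def build_features(
    records: pd.DataFrame,
    labels: pd.DataFrame,
    *,
    muscles=MUSCLES,
    poses=POSES,
    expected_repetitions: int = 3,
) -> pd.DataFrame:
    """Build one feature row per measurement from amplitude records.

    Parameters
    ----------
    records : DataFrame
        Amplitude records (measurement_id, muscle, side, pose, repetition,
        amplitude_uv, ...).
    labels : DataFrame
        Session metadata with columns patient_id, measurement_id, and
        optionally timepoint, operated_side, hb (hb may be missing/NaN).
    expected_repetitions : int
        Protocol repetition count; fewer paired repetitions than this flags
        the cell ``partial_repetitions``.

    Returns
    -------
    DataFrame with one row per measurement: metadata, 21 LI columns
    (``<muscle>__<pose>``) and 21 flag columns (``imputed__<muscle>__<pose>``),
    already imputed to a complete grid.
    """
    meta = labels.set_index("measurement_id")
    rows = []
    for mid, grp in records.groupby("measurement_id", sort=True):
        per_rep = _per_measurement_li(grp)
        if per_rep.empty:
            raise ValueError(f"measurement {mid!r} has no usable paired amplitude records")
        cell_mean = per_rep.groupby(["muscle", "pose"])["li"].agg(["mean", "count"])

        li: dict[tuple[str, str], float] = {}
        flags: dict[tuple[str, str], str] = {}
        for m in muscles:
            for p in poses:
                if (m, p) in cell_mean.index:
                    mean, count = cell_mean.loc[(m, p)]
                    li[(m, p)] = float(mean)
                    flags[(m, p)] = FLAG_NONE if count >= expected_repetitions else FLAG_PARTIAL
                else:
                    li[(m, p)] = np.nan
                    flags[(m, p)] = FLAG_WHOLE
        li, flags = _impute_cells(li, flags, muscles, poses, mid)

        if mid not in meta.index:
            raise KeyError(f"measurement {mid!r} absent from the labels table")
        info = meta.loc[mid]
        hb = info.get("hb")
        row = {
            "measurement_id": mid,
            "patient_id": info["patient_id"],
            "timepoint": info.get("timepoint", ""),
            "hb": np.nan if pd.isna(hb) else int(hb),
        }
        row.update({f"{m}__{p}": li[(m, p)] for m in muscles for p in poses})
        row.update({f"imputed__{m}__{p}": flags[(m, p)] for m in muscles for p in poses})
        rows.append(row)
    df = pd.DataFrame(rows)
    df["hb"] = df["hb"].astype("Int64")
    return df


def _impute_cells(li, flags, muscles, poses, mid):
    """Whole-movement imputation: fill a fully missing (muscle, pose) cell
    with the mean LI of that muscle over its other poses."""
    for m in muscles:
        observed = [li[(m, p)] for p in poses if not np.isnan(li[(m, p)])]
        missing = [p for p in poses if np.isnan(li[(m, p)])]
        if missing and not observed:
            raise ValueError(
                f"measurement {mid!r}: muscle {m!r} has no observed poses, cannot impute"
            )
        fill = float(np.mean(observed)) if observed else 0.0
        for p in missing:
            li[(m, p)] = fill
            flags[(m, p)] = FLAG_WHOLE
    return li, flags


def impute_missing(
    features: pd.DataFrame, *, muscles=MUSCLES, poses=POSES
) -> pd.DataFrame:
    """Impute NaN LI cells of an (possibly external) feature table in place of gaps.

    Feature tables produced by :func:`build_features` are already complete;
    this entry point serves tables assembled elsewhere. Cells are filled per
    muscle with the mean over that muscle's observed poses and flagged
    ``whole_movement``.
    """
    df = features.copy()
    for _, row in df.iterrows():
        li = {(m, p): row[f"{m}__{p}"] for m in muscles for p in poses}
        flags = {
            (m, p): row.get(f"imputed__{m}__{p}", FLAG_NONE) for m in muscles for p in poses
        }
        li, flags = _impute_cells(li, flags, muscles, poses, row.get("measurement_id", "?"))
        for m in muscles:
            for p in poses:
                df.loc[row.name, f"{m}__{p}"] = li[(m, p)]
                df.loc[row.name, f"imputed__{m}__{p}"] = flags[(m, p)]
    return df
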