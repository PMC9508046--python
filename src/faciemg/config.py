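"""Configuration objects for the synthetic cohort generator and pipeline runs."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

#: Facial muscles recorded by the three bilateral electrode pairs
#: (forehead / nasolabial fold / lateral chin).
MUSCLES: tuple[str, ...] = ("orbicularis_oculi", "nasalis", "orbicularis_oris")

#: Default enumeration of the seven standardized facial poses. The exact
#: vocabulary is configurable; these are the movements conventionally used in
#: House-Brackmann examination.
POSES: tuple[str, ...] = (
    "raise_eyebrows",
    "close_eyes_gently",
    "close_eyes_forcefully",
    "wrinkle_nose",
    "smile",
    "pucker_lips",
    "blow_cheeks",
)

SIDES: tuple[str, ...] = ("ipsi", "contra")

#: House-Brackmann grades, 1 (normal) .. 6 (total paralysis).
HB_GRADES: tuple[int, ...] = (1, 2, 3, 4, 5, 6)


def _default_attenuation() -> dict[int, float]:
    # Ipsilateral amplitude multiplier per HB grade. Monotone decreasing;
    # grade 1 is by definition symmetric. Values are a modelling choice,
    # configurable.
    return {1: 1.0, 2: 0.75, 3: 0.5, 4: 0.3, 5: 0.15, 6: 0.0}


def _default_cohort_distribution() -> dict[int, int]:
    # Labeled measurements per clinical HB grade in the emulated cohort.
    return {1: 30, 2: 17, 3: 5, 4: 3, 5: 2}


def _default_patient_plan() -> dict[int, int]:
    # sessions-per-patient -> number of patients. 15*2 + 8*3 + 5*1 = 59
    # measurements over 28 patients (pre/post for most, follow-up for some).
    return {2: 15, 3: 8, 1: 5}


@dataclass
class SynthConfig:
    """Parameters of the synthetic bilateral facial sEMG cohort.

    The defaults emulate the recording protocol of a perioperative vestibular
    schwannoma cohort: seven poses, three tension-relaxation repetitions each
    (about 1 s tension, 3 s relaxation), three muscles recorded bilaterally,
    and 59 measurement sessions distributed over 28 patients.

    Parameters
    ----------
    sampling_rate_hz : float
        EMG sampling rate. 1000 Hz is ample for envelope statistics.
    trace_duration_s : float
        Length of one recorded repetition (one tension-relaxation cycle).
    tension_duration_s : float
        Duration of the voluntary contraction burst, centered in the trace.
    baseline_noise_uv : float
        RMS of the resting (baseline) EMG noise, in microvolt.
    burst_amplitude_uv : float
        RMS of the contraction burst on a healthy (unattenuated) side.
    grade_attenuation : dict[int, float]
        HB grade -> ipsilateral amplitude multiplier in [0, 1], monotone
        non-increasing, with grade 1 mapped to 1.0 (symmetric).
    synkinesis_gain : float
        Fraction in [0, 1) of each side's drive amplitude leaking to the
        opposite side's channel (cross-talk / synkinetic co-activation).
    repetition_cv : float
        Coefficient of variation of the burst amplitude across the three
        repetitions of a pose.
    session_asymmetry_sd : float
        Log-scale SD of a per-session multiplicative gain on the ipsilateral
        side, emulating natural facial asymmetry and electrode-placement
        differences shared by all channels of one visit.
    cohort_distribution : dict[int, int]
        Labeled measurement count per HB grade.
    unlabeled_count : int
        Number of sessions emitted without a clinical HB label.
    patient_plan : dict[int, int]
        sessions-per-patient -> number of patients; total sessions must equal
        labeled + unlabeled counts.
    prob_left_operated : float
        Probability that a patient's operated side is the left.
    band_hz : tuple[float, float]
        Pass band of the synthetic EMG noise texture.
    seed : int
        Seed for all randomness in cohort generation.
    """

    sampling_rate_hz: float = 1000.0
    trace_duration_s: float = 4.0
    tension_duration_s: float = 1.0
    relaxation_duration_s: float = 3.0
    baseline_noise_uv: float = 2.0
    burst_amplitude_uv: float = 100.0
    grade_attenuation: dict[int, float] = field(default_factory=_default_attenuation)
    synkinesis_gain: float = 0.1
    repetition_cv: float = 0.15
    session_asymmetry_sd: float = 0.2
    cohort_distribution: dict[int, int] = field(default_factory=_default_cohort_distribution)
    unlabeled_count: int = 2
    patient_plan: dict[int, int] = field(default_factory=_default_patient_plan)
    prob_left_operated: float = 0.75
    muscles: tuple[str, ...] = MUSCLES
    poses: tuple[str, ...] = POSES
    repetitions: int = 3
    band_hz: tuple[float, float] = (20.0, 450.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be strictly positive")
        for name in ("trace_duration_s", "tension_duration_s", "relaxation_duration_s",
                     "burst_amplitude_uv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.tension_duration_s > self.trace_duration_s:
            raise ValueError("tension burst does not fit in the trace")
        if self.baseline_noise_uv < 0 or self.repetition_cv < 0 or self.session_asymmetry_sd < 0:
            raise ValueError("noise levels must be nonnegative")
        if not (0.0 <= self.synkinesis_gain < 1.0):
            raise ValueError("synkinesis_gain must lie in [0, 1)")

        att = self.grade_attenuation
        if set(att) != set(HB_GRADES):
            raise ValueError("grade_attenuation must map every HB grade 1-6")
        if att[1] != 1.0:
            raise ValueError("grade_attenuation[1] must be 1.0 (HB 1 is symmetric)")
        vals = [att[g] for g in HB_GRADES]
        if any(not (0.0 <= v <= 1.0) for v in vals):
            raise ValueError("grade_attenuation values must lie in [0, 1]")
        if any(b > a for a, b in zip(vals, vals[1:])):
            raise ValueError("grade_attenuation must be monotone non-increasing in grade")

        for g, n in self.cohort_distribution.items():
            if g not in HB_GRADES:
                raise ValueError(f"cohort_distribution has invalid HB grade {g}")
            if n < 0 or int(n) != n:
                raise ValueError("cohort counts must be nonnegative integers")
        if self.unlabeled_count < 0:
            raise ValueError("unlabeled_count must be nonnegative")
        for k, n in self.patient_plan.items():
            if k <= 0 or n < 0:
                raise ValueError("patient_plan entries must be positive/nonnegative")
        if len(self.poses) == 0 or len(self.muscles) == 0 or self.repetitions <= 0:
            raise ValueError("poses, muscles and repetitions must be non-empty/positive")
        lo, hi = self.band_hz
        if not (0 < lo < hi < self.sampling_rate_hz / 2):
            raise ValueError("band_hz must satisfy 0 < low < high < Nyquist")

    # -- derived quantities -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(round(self.trace_duration_s * self.sampling_rate_hz))

    @property
    def total_sessions(self) -> int:
        return sum(self.cohort_distribution.values()) + self.unlabeled_count

    @property
    def planned_sessions(self) -> int:
        return sum(k * n for k, n in self.patient_plan.items())

    # -- (de)serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["muscles"] = list(self.muscles)
        d["poses"] = list(self.poses)
        d["band_hz"] = list(self.band_hz)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SynthConfig":
        d = dict(d)
        for key in ("muscles", "poses", "band_hz"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("grade_attenuation", "cohort_distribution", "patient_plan"):
            if key in d:
                d[key] = {int(k): v for k, v in d[key].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SynthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunConfig:
    """End-to-end pipeline run: simulate (or load) -> process -> features -> grade."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    data_dir: str | None = None  # if set, read a cohort from disk instead of simulating
    out_dir: str = "faciemg_run"
    scenarios: Sequence[int] = (1, 2, 3)
    classifiers: Sequence[str] = ("logistic_regression", "svm", "knn")
    standardize: bool = True
    seed: int = 0
    write_raw: bool = False  # raw long-format traces are large; opt in
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        synth = SynthConfig.from_dict(d.pop("synth", {}))
        return cls(synth=synth, **d)
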