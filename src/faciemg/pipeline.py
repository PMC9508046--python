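"""End-to-end orchestration: simulate (or load) -> process -> features -> grade.

Also provides the deterministic miniature fixtures used by the test suite.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import io as fio
from .config import RunConfig, SynthConfig
from .features import build_features
from .grading import FacialGradingModel, GradingResults
from .signal import process_cohort
from .simulate import DropoutRule, SyntheticCohort, generate_cohort, generate_session
import numpy as np

__all__ = ["run_pipeline", "make_fixture", "FIXTURES"]

log = logging.getLogger("faciemg")


def run_pipeline(cfg: RunConfig) -> GradingResults:
    """Run every stage and write all intermediate artifacts to ``cfg.out_dir``.

    With ``cfg.data_dir`` unset a synthetic cohort is generated from
    ``cfg.synth`` (its seed overridden by ``cfg.seed`` for a single source of
    randomness). Outputs: ``amplitudes.csv``, ``features.csv``,
    ``predictions.csv``, ``report.json`` (seed recorded inside), and
    ``labels.csv``; raw long-format traces only with ``write_raw``.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.data_dir is not None:
        sessions, labels = fio.read_cohort_csv(cfg.data_dir, cfg.synth.sampling_rate_hz)
        log.info("loaded %d sessions from %s", len(sessions), cfg.data_dir)
    else:
        synth = SynthConfig.from_dict({**cfg.synth.to_dict(), "seed": cfg.seed})
        cohort = generate_cohort(synth)
        sessions, labels = cohort.sessions, cohort.labels_frame()
        log.info("simulated %d sessions (%d patients)", len(sessions),
                 labels["patient_id"].nunique())
        if cfg.write_raw:
            fio.write_cohort_csv(cohort, out / "raw")

    fio.write_labels(labels, out / "labels.csv")

    records = process_cohort(sessions)
    fio.write_amplitudes(records, out / "amplitudes.csv")
    log.info("amplitude records: %d", len(records))

    features = build_features(records, labels)
    fio.write_features(features, out / "features.csv")
    n_imputed = int((features.filter(like="imputed__") != "none").to_numpy().sum())
    log.info("features: %d measurements, %d imputed cells", len(features), n_imputed)

    model = FacialGradingModel(
        features,
        scenarios=cfg.scenarios,
        classifiers=cfg.classifiers,
        standardize=cfg.standardize,
        seed=cfg.seed,
    )
    log.info("excluded %d measurements with missing HB", model.n_excluded_unlabeled)
    results = model.fit()
    results.predictions.to_csv(out / "predictions.csv", index=False)
    results.to_json(out / "report.json")
    return results


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _fixture_tiny_separable() -> SyntheticCohort:
    """12 sessions over 6 patients, grades 1 and 3 only, noise-free: every
    classifier should separate the two grades perfectly."""
    cfg = SynthConfig(
        sampling_rate_hz=500.0,
        trace_duration_s=2.0,
        tension_duration_s=0.8,
        relaxation_duration_s=1.2,
        band_hz=(20.0, 200.0),
        baseline_noise_uv=0.5,
        repetition_cv=0.0,
        synkinesis_gain=0.0,
        session_asymmetry_sd=0.0,
        cohort_distribution={1: 6, 3: 6},
        unlabeled_count=0,
        patient_plan={2: 6},
        seed=1234,
    )
    return generate_cohort(cfg)


def _fixture_reference_cohort() -> SyntheticCohort:
    """59 sessions over 28 patients in the reference cohort composition
    (30/17/5/3/2 labeled HB 1-5 plus 2 unlabeled), light traces."""
    cfg = SynthConfig(
        sampling_rate_hz=500.0,
        trace_duration_s=2.0,
        tension_duration_s=0.8,
        relaxation_duration_s=1.2,
        band_hz=(20.0, 200.0),
        seed=59,
    )
    return generate_cohort(cfg)


def _fixture_dropouts() -> SyntheticCohort:
    """Small cohort whose first session misses one whole movement and keeps a
    single repetition of another, exercising both imputation rules."""
    cfg = SynthConfig(
        sampling_rate_hz=500.0,
        trace_duration_s=2.0,
        tension_duration_s=0.8,
        relaxation_duration_s=1.2,
        band_hz=(20.0, 200.0),
        cohort_distribution={1: 3, 2: 3},
        unlabeled_count=0,
        patient_plan={2: 3},
        seed=7,
    )
    cohort = generate_cohort(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    broken = generate_session(
        cohort.sessions[0].patient_id,
        cohort.sessions[0].timepoint,
        cohort.truth[cohort.sessions[0].measurement_id],
        cfg,
        rng,
        measurement_id=cohort.sessions[0].measurement_id,
        operated_side=cohort.sessions[0].operated_side,
        dropouts=(
            DropoutRule(pose="smile", keep_repetitions=0),
            DropoutRule(pose="wrinkle_nose", keep_repetitions=1),
        ),
    )
    cohort.sessions[0] = broken
    return cohort


FIXTURES = {
    "tiny_separable": _fixture_tiny_separable,
    "reference_cohort": _fixture_reference_cohort,
    "dropouts": _fixture_dropouts,
}


def make_fixture(name: str) -> SyntheticCohort:
    """Deterministic miniature cohorts for tests and demos."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
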