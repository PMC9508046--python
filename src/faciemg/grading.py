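"""House-Brackmann grading model: scenarios, classifiers, grouped LOO-CV.

The estimation problem is framed as three classification scenarios over the
clinical HB grade:

1. normal vs. impaired function (HB 1 vs. HB 2-6), binary;
2. normal-or-slight vs. moderate-or-worse (HB 1-2 vs. HB 3-6), binary;
3. HB 1 / HB 2 / HB 3 multiclass (grades 4-6 excluded).

Three fixed classifiers are evaluated: logistic regression (library
defaults, multinomial in the 3-class case), an RBF support-vector machine
with gamma = 1 / n_features and probability outputs, and k-nearest
neighbours with k = 5 and inverse-distance neighbour weighting. No
hyperparameter is tuned.

Cross-validation leaves one *patient* out per fold, so repeated measurements
of the same patient never straddle a train/test split; test-split class
probabilities are accumulated over folds and scored once: rank-based ROC-AUC
for the binary scenarios, one-vs-one multiclass AUC for scenario 3, plus a
concordance / under- / over-estimation breakdown of scenario-3 predictions.

The public surface follows the familiar model/results idiom::

    model = FacialGradingModel(features_df, seed=0)
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import HB_GRADES
from .features import feature_columns
from .metrics import binary_auc, concordance_analysis, multiclass_ovo_auc

__all__ = [
    "ScenarioSpec",
    "ClassifierSpec",
    "SCENARIOS",
    "CLASSIFIERS",
    "make_scenario_dataset",
    "loo_cross_validate",
    "FacialGradingModel",
    "GradingResults",
]


# ---------------------------------------------------------------------------
# scenario and classifier specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """One classification scenario: which grades participate and how they
    collapse into ordinal classes (1 = best function)."""

    id: int
    name: str
    label_map: Mapping[int, int]  # HB grade -> ordinal class
    class_names: Mapping[int, str]

    @property
    def included_grades(self) -> frozenset[int]:
        return frozenset(self.label_map)

    @property
    def classes(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.label_map.values())))

    @property
    def is_binary(self) -> bool:
        return len(self.classes) == 2


SCENARIOS: dict[int, ScenarioSpec] = {
    1: ScenarioSpec(
        id=1,
        name="HB 1 vs HB 2-6",
        label_map={1: 1, 2: 2, 3: 2, 4: 2, 5: 2, 6: 2},
        class_names={1: "HB1", 2: "HB2-6"},
    ),
    2: ScenarioSpec(
        id=2,
        name="HB 1-2 vs HB 3-6",
        label_map={1: 1, 2: 1, 3: 2, 4: 2, 5: 2, 6: 2},
        class_names={1: "HB1-2", 2: "HB3-6"},
    ),
    3: ScenarioSpec(
        id=3,
        name="HB 1 / 2 / 3",
        label_map={1: 1, 2: 2, 3: 3},
        class_names={1: "HB1", 2: "HB2", 3: "HB3"},
    ),
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier with fixed (untuned) hyperparameters."""

    name: str
    build: Callable[[int, int], object]  # (n_features, seed) -> estimator


def _build_logreg(n_features: int, seed: int):
    # defaults; multinomial handling is automatic for >2 classes
    return LogisticRegression(max_iter=1000)


def _build_svm(n_features: int, seed: int):
    # gamma = 1 / n_features; Platt-style probability calibration on the
    # training fold (probability=True)
    return SVC(kernel="rbf", gamma=1.0 / n_features, probability=True, random_state=seed)


def _build_knn(n_features: int, seed: int):
    # k = 5 with inverse-distance neighbour weights (an exact match takes
    # full weight)
    return KNeighborsClassifier(n_neighbors=5, weights="distance")


CLASSIFIERS: dict[str, ClassifierSpec] = {
    "logistic_regression": ClassifierSpec("logistic_regression", _build_logreg),
    "svm": ClassifierSpec("svm", _build_svm),
    "knn": ClassifierSpec("knn", _build_knn),
}

_ALIASES = {"logreg": "logistic_regression", "lr": "logistic_regression"}


def resolve_classifier(name: str) -> ClassifierSpec:
    key = _ALIASES.get(name.lower(), name.lower())
    if key not in CLASSIFIERS:
        raise KeyError(f"unknown classifier {name!r}; choose from {sorted(CLASSIFIERS)}")
    return CLASSIFIERS[key]


# ---------------------------------------------------------------------------
# dataset construction and cross-validation
# ---------------------------------------------------------------------------

def make_scenario_dataset(
    features: pd.DataFrame, scenario: ScenarioSpec, feature_cols: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Map HB labels to scenario classes and drop excluded grades.

    Measurements with a missing HB label must already be excluded. Returns
    (X, y, groups, meta) where groups are patient ids for fold construction.
    """
    if features["hb"].isna().any():
        raise ValueError("features contain unlabeled measurements; exclude them first")
    feature_cols = list(feature_cols) if feature_cols is not None else feature_columns()
    keep = features["hb"].astype(int).isin(scenario.included_grades)
    sub = features.loc[keep].reset_index(drop=True)
    y = sub["hb"].astype(int).map(scenario.label_map).to_numpy()
    for cls in scenario.classes:
        if not np.any(y == cls):
            raise ValueError(
                f"scenario {scenario.id}: class {scenario.class_names[cls]!r} has no "
                "members; AUC is undefined"
            )
    X = sub[feature_cols].to_numpy(dtype=float)
    groups = sub["patient_id"].to_numpy()
    meta = sub[["measurement_id", "patient_id", "hb"]].copy()
    return X, y, groups, meta


def loo_cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    clf: ClassifierSpec | str,
    *,
    meta: pd.DataFrame | None = None,
    classes: Sequence[int] | None = None,
    standardize: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-patient-out cross-validation, accumulating test probabilities.

    Every fold holds out all measurements of one patient; feature
    standardization statistics are fit on the training fold only. Returns one
    row per measurement with columns ``true_class``, ``p_<class>`` for every
    scenario class, and ``predicted_class`` (argmax probability, ties broken
    toward the lower class).
    """
    if isinstance(clf, str):
        clf = resolve_classifier(clf)
    unique_groups = np.unique(groups)
    if len(unique_groups) < 2:
        raise ValueError("leave-one-patient-out needs at least two patients")
    classes = tuple(sorted(classes)) if classes is not None else tuple(sorted(np.unique(y)))

    proba = np.zeros((len(y), len(classes)))
    for g in unique_groups:
        test = groups == g
        train = ~test
        if len(np.unique(y[train])) < len(classes):
            warnings.warn(
                f"fold holding out patient {g!r}: training data miss a class "
                "(small-sample artifact); classifier trains on remaining classes"
            )
        Xtr, Xte = X[train], X[test]
        if standardize:
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        train_classes = np.unique(y[train])
        if len(train_classes) == 1:
            # degenerate fold: only one class left to train on; predict it
            proba[test, classes.index(int(train_classes[0]))] = 1.0
            continue
        est = clf.build(X.shape[1], seed)
        # degenerate-fold guard: k cannot exceed the training-fold size
        if hasattr(est, "n_neighbors") and est.n_neighbors > train.sum():
            est.set_params(n_neighbors=int(train.sum()))
        with warnings.catch_warnings():
            # SVC(probability=True) is the intended Platt-calibrated design;
            # silence the sklearn>=1.9 deprecation advice
            warnings.filterwarnings("ignore", message=".*probability.*", category=FutureWarning)
            est.fit(Xtr, y[train])
            p = est.predict_proba(Xte)
        for j, cls in enumerate(est.classes_):
            proba[test, classes.index(int(cls))] = p[:, j]

    # argmax with ties toward the lower (better) class: np.argmax returns the
    # first maximum and columns are sorted ascending
    predicted = np.array([classes[i] for i in np.argmax(proba, axis=1)])
    out = meta.copy() if meta is not None else pd.DataFrame(index=range(len(y)))
    out["true_class"] = y
    for j, cls in enumerate(classes):
        out[f"p_{cls}"] = proba[:, j]
    out["predicted_class"] = predicted
    return out


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class FacialGradingModel:
    """Grade facial nerve function from lateralization-index features.

    Parameters
    ----------
    features : DataFrame
        One row per measurement with columns ``measurement_id``,
        ``patient_id``, ``hb`` (nullable) and the 21 LI feature columns.
        Measurements with a missing HB label are dropped at construction
        (they cannot enter supervised training or evaluation).
    scenarios, classifiers : sequences
        Which scenarios (ids 1-3) and classifiers to evaluate.
    standardize : bool
        Per-fold feature standardization with training-fold statistics.
    seed : int
        Seed for every stochastic component (SVM probability calibration).
    """

    def __init__(
        self,
        features: pd.DataFrame,
        scenarios: Sequence[int] = (1, 2, 3),
        classifiers: Sequence[str] = ("logistic_regression", "svm", "knn"),
        *,
        feature_cols: Sequence[str] | None = None,
        standardize: bool = True,
        seed: int = 0,
    ) -> None:
        required = {"measurement_id", "patient_id", "hb"}
        missing = required - set(features.columns)
        if missing:
            raise ValueError(f"features table lacks columns {sorted(missing)}")
        self.n_excluded_unlabeled = int(features["hb"].isna().sum())
        self.features = features.loc[features["hb"].notna()].reset_index(drop=True)
        if len(self.features) == 0:
            raise ValueError("no labeled measurements to fit on")
        bad = set(self.features["hb"].astype(int)) - set(HB_GRADES)
        if bad:
            raise ValueError(f"invalid HB grades in features: {sorted(bad)}")
        self.scenarios = [SCENARIOS[s] for s in scenarios]
        self.classifiers = [resolve_classifier(c) for c in classifiers]
        self.feature_cols = (
            list(feature_cols) if feature_cols is not None else feature_columns()
        )
        self.standardize = standardize
        self.seed = seed

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "FacialGradingModel":
        """Build the model straight from a synthetic cohort (runs the full
        signal-processing and feature chain)."""
        from .features import build_features
        from .signal import process_cohort

        records = process_cohort(cohort.sessions)
        feats = build_features(records, cohort.labels_frame())
        return cls(feats, **kwargs)

    def fit(self) -> "GradingResults":
        auc_rows = []
        conc_rows = []
        predictions = []
        for scen in self.scenarios:
            X, y, groups, meta = make_scenario_dataset(
                self.features, scen, self.feature_cols
            )
            for clf in self.classifiers:
                preds = loo_cross_validate(
                    X,
                    y,
                    groups,
                    clf,
                    meta=meta,
                    classes=scen.classes,
                    standardize=self.standardize,
                    seed=self.seed,
                )
                if scen.is_binary:
                    pos = max(scen.classes)  # the impaired class
                    auc = binary_auc(preds["true_class"], preds[f"p_{pos}"], pos)
                    auc_kind = "roc_auc"
                else:
                    prob = preds[[f"p_{c}" for c in scen.classes]].copy()
                    prob.columns = list(scen.classes)
                    auc = multiclass_ovo_auc(preds["true_class"].to_numpy(), prob)
                    auc_kind = "ovo_auc"
                auc_rows.append(
                    {
                        "scenario": scen.id,
                        "scenario_name": scen.name,
                        "classifier": clf.name,
                        "auc": auc,
                        "auc_kind": auc_kind,
                        "n": len(preds),
                    }
                )
                if scen.id == 3:
                    conc = concordance_analysis(preds)
                    conc_rows.append({"scenario": 3, "classifier": clf.name, **conc})
                p = preds.copy()
                p.insert(0, "scenario", scen.id)
                p.insert(1, "classifier", clf.name)
                predictions.append(p)
        return GradingResults(
            model=self,
            aucs=pd.DataFrame(auc_rows),
            concordance=pd.DataFrame(conc_rows),
            predictions=pd.concat(predictions, ignore_index=True),
        )


@dataclass
class GradingResults:
    """Fitted cross-validated grading results.

    Attributes
    ----------
    aucs : DataFrame
        One row per (scenario, classifier) with the accumulated-test AUC.
    concordance : DataFrame
        Scenario-3 concordance / under- / over-estimation percentages.
    predictions : DataFrame
        Accumulated test-split class probabilities and predicted classes for
        every (scenario, classifier, measurement).
    """

    model: FacialGradingModel
    aucs: pd.DataFrame
    concordance: pd.DataFrame
    predictions: pd.DataFrame

    def scenario_aggregates(self) -> pd.DataFrame:
        """Mean and median AUC over classifiers, per scenario."""
        return (
            self.aucs.groupby(["scenario", "scenario_name"])["auc"]
            .agg(["mean", "median"])
            .reset_index()
        )

    def auc(self, scenario: int, classifier: str) -> float:
        spec = resolve_classifier(classifier)
        row = self.aucs[
            (self.aucs["scenario"] == scenario) & (self.aucs["classifier"] == spec.name)
        ]
        if row.empty:
            raise KeyError(f"no AUC for scenario {scenario}, classifier {classifier}")
        return float(row["auc"].iloc[0])

    def to_report(self) -> dict:
        """JSON-serialisable evaluation report."""
        return {
            "seed": self.model.seed,
            "n_measurements": int(len(self.model.features)),
            "n_excluded_unlabeled": self.model.n_excluded_unlabeled,
            "n_patients": int(self.model.features["patient_id"].nunique()),
            "aucs": self.aucs.drop(columns=["scenario_name"]).to_dict("records"),
            "scenario_aggregates": self.scenario_aggregates()
            .drop(columns=["scenario_name"])
            .to_dict("records"),
            "concordance": self.concordance.to_dict("records"),
        }

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.to_report(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [
            "Facial nerve grading -- leave-one-patient-out cross-validation",
            f"measurements: {len(self.model.features)}  "
            f"patients: {self.model.features['patient_id'].nunique()}  "
            f"excluded (missing HB): {self.model.n_excluded_unlabeled}",
            "",
            f"{'scenario':<22}{'classifier':<22}{'AUC':>8}",
        ]
        for _, r in self.aucs.iterrows():
            lines.append(f"{r['scenario_name']:<22}{r['classifier']:<22}{r['auc']:>8.3f}")
        if len(self.concordance):
            lines += ["", "scenario 3 concordance (% of test predictions)"]
            lines.append(f"{'classifier':<22}{'concordant':>11}{'under':>8}{'over':>8}")
            for _, r in self.concordance.iterrows():
                lines.append(
                    f"{r['classifier']:<22}{r['concordant_pct']:>10.1f}%"
                    f"{r['under_pct']:>7.1f}%{r['over_pct']:>7.1f}%"
                )
        return "\n".join(lines)
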