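"""Supervised classification of DNA secondary structure from stalling data.

Each sequence is described by 11 features: the mean stall score sigma
at the five time points, the Fisher-combined Q value, the kinetic
constant lambda with its R^2, and three sequence features (GC fraction,
G4Hunter-style score, composition entropy). Features are centred and
scaled with training-set statistics.

Training labels come from the designed structured controls: a control
keeps its designed class (HAIRP / IMOT / QUAD) when its stalling is
significant versus the random-GC controls (Q <= 0.1) and is relabelled
UNF otherwise — the Q rule defines training labels only; at prediction
time the classifier output is authoritative. The model is a random
forest selected by 10-fold cross-validation on a stratified 70/30
split, with held-out accuracy and per-class confusion reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .kinetics import StallProfile
from .motifs import sequence_features

CLASS_LABELS = ("HAIRP", "IMOT", "QUAD", "UNF")

FEATURE_NAMES = (
    "sigma_t1",
    "sigma_t2",
    "sigma_t3",
    "sigma_t4",
    "sigma_t5",
    "q_combined",
    "lam",
    "r2",
    "gc_fraction",
    "g4h_score",
    "entropy_bits",
)

UNF_Q_THRESHOLD = 0.1


def feature_vector(profile: StallProfile, sequence: str) -> np.ndarray:
    """11-component feature vector; failed kinetic fits imputed with 0."""
    times = sorted(profile.sigma_mean)
    gc, entropy, g4h = sequence_features(sequence)
    lam = profile.lam_fit if np.isfinite(profile.lam_fit) else 0.0
    r2 = profile.r2 if np.isfinite(profile.r2) else 0.0
    vec = np.array(
        [profile.sigma_mean[t] for t in times]
        + [profile.q_combined, lam, r2, gc, g4h, entropy]
    )
    if len(vec) != len(FEATURE_NAMES):
        raise ValueError(f"expected {len(FEATURE_NAMES)} features, got {len(vec)}")
    return vec


def build_training_labels(
    control_profiles: dict[str, StallProfile],
    designed_class: dict[str, str],
    q_threshold: float = UNF_Q_THRESHOLD,
) -> pd.Series:
    """Label structured controls: designed class if Q <= threshold, else UNF."""
    labels = {}
    for entry_id, profile in control_profiles.items():
        if not np.isfinite(profile.q_combined):
            raise ValueError(f"entry {entry_id} has no Q value")
        designed = designed_class[entry_id]
        labels[entry_id] = designed if profile.q_combined <= q_threshold else "UNF"
    return pd.Series(labels, name="label")


@dataclass
class TrainedModel:
    pipeline: Pipeline
    seed: int
    holdout_accuracy: float
    confusion: np.ndarray
    classes: list[str]
    cv_results: dict = field(default_factory=dict)

    def predict_calls(self, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        proba = self.pipeline.predict_proba(features)
        calls = np.array([self.classes[i] for i in proba.argmax(axis=1)])
        return calls, proba


def train(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    n_estimators: int = 500,
    cv_folds: int = 10,
) -> TrainedModel:
    """Stratified 70/30 split; model selected by 10-fold CV on the
    training portion; held-out accuracy and confusion reported."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes to train")
    stratify = labels
    counts = pd.Series(labels).value_counts()
    if (counts < 10).any():
        stratify = None  # too few members in a class for stratification
    x_train, x_test, y_train, y_test = train_test_split(
        features, labels, test_size=0.30, random_state=seed, stratify=stratify
    )
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "forest",
                RandomForestClassifier(n_estimators=n_estimators, random_state=seed),
            ),
        ]
    )
    search = GridSearchCV(
        pipe,
        param_grid={"forest__max_features": ["sqrt", None]},
        cv=cv_folds,
        n_jobs=1,
    )
    search.fit(x_train, y_train)
    best: Pipeline = search.best_estimator_
    y_pred = best.predict(x_test)
    classes = list(best.named_steps["forest"].classes_)
    return TrainedModel(
        pipeline=best,
        seed=seed,
        holdout_accuracy=float(accuracy_score(y_test, y_pred)),
        confusion=confusion_matrix(y_test, y_pred, labels=classes),
        classes=classes,
        cv_results={"best_params": search.best_params_, "cv_score": search.best_score_},
    )


@dataclass
class StructureCall:
    entry_id: str
    predicted_class: str
    class_probabilities: dict[str, float]


def predict(model: TrainedModel, features: np.ndarray, ids: list[str]) -> list[StructureCall]:
    """One structure call per row of *features* (motif x length entries)."""
    if features.shape[1] != len(FEATURE_NAMES):
        raise ValueError(
            f"feature dimension {features.shape[1]} != {len(FEATURE_NAMES)}"
        )
    calls, proba = model.predict_calls(features)
    return [
        StructureCall(
            entry_id=ids[i],
            predicted_class=calls[i],
            class_probabilities=dict(zip(model.classes, proba[i].tolist())),
        )
        for i in range(len(ids))
    ]


def calls_dataframe(calls: list[StructureCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {"entry_id": c.entry_id, "predicted_class": c.predicted_class}
        for label in CLASS_LABELS:
            row[f"p_{label}"] = c.class_probabilities.get(label, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
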