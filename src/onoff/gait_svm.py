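"""Walk / not-walk classifier over 3.2-s segments.

An RBF-kernel support vector machine trained once on labelled segments
and then frozen; the per-patient pipeline only scores with it, mirroring
a subject-independent pre-trained gait detector.  Hyperparameters are
fixed (C=1, gamma=1/n_features, class-balanced) rather than tuned per run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import PipelineConfig
from .signals import Segment, feature_matrix


class FeatureSpecMismatch(ValueError):
    """Model was trained under a different feature-bank specification."""


@dataclass
class WalkModel:
    pipeline: Pipeline
    feature_hash: str
    metadata: dict

    def predict(self, X: np.ndarray, feature_hash: str | None = None) -> np.ndarray:
        if feature_hash is not None and feature_hash != self.feature_hash:
            raise FeatureSpecMismatch(
                f"model feature spec {self.feature_hash} != input spec {feature_hash}"
            )
        if X.shape[0] == 0:
            return np.zeros(0, dtype=bool)
        if X.shape[1] != self.metadata["n_features"]:
            raise ValueError(
                f"expected {self.metadata['n_features']} features, got {X.shape[1]}"
            )
        return self.pipeline.predict(X).astype(bool)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        joblib.dump({"pipeline": self.pipeline, "feature_hash": self.feature_hash}, path)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(self.metadata, indent=2, sort_keys=True)
        )

    @classmethod
    def load(cls, path: str | Path) -> "WalkModel":
        path = Path(path)
        blob = joblib.load(path)
        meta_path = path.with_suffix(path.suffix + ".json")
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(pipeline=blob["pipeline"], feature_hash=blob["feature_hash"], metadata=metadata)


def train_walk_model(
    X: np.ndarray,
    is_walking: np.ndarray,
    seed: int,
    config: PipelineConfig | None = None,
    holdout_fraction: float = 0.25,
) -> WalkModel:
    """Fit the frozen walk detector on labelled feature vectors.

    Requires both classes with >= 50 examples each.  A stratified held-out
    split (never used for fitting) provides the accuracy / sensitivity /
    specificity stored in the model metadata.
    """
    config = config or PipelineConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(is_walking, dtype=bool)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and labels must have matching first dimension")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if min(n_pos, n_neg) < 50:
        raise ValueError("need >= 50 examples per class")

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    gamma = config.svm_gamma if config.svm_gamma != "auto" else 1.0 / X.shape[1]
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel="rbf",
                    C=config.svm_c,
                    gamma=gamma,
                    class_weight="balanced",
                    random_state=seed,
                ),
            ),
        ]
    )
    pipe.fit(X_tr, y_tr)
    pred = pipe.predict(X_te).astype(bool)
    acc = float((pred == y_te).mean())
    sens = float(pred[y_te].mean()) if y_te.any() else float("nan")
    spec = float((~pred[~y_te]).mean()) if (~y_te).any() else float("nan")
    metadata = {
        "seed": int(seed),
        "n_segments": int(X.shape[0]),
        "n_features": int(X.shape[1]),
        "holdout_accuracy": acc,
        "holdout_sensitivity": sens,
        "holdout_specificity": spec,
    }
    return WalkModel(pipeline=pipe, feature_hash=config.feature_spec_hash(), metadata=metadata)


def detect_walking(
    model: WalkModel, segments: list[Segment], config: PipelineConfig | None = None
) -> np.ndarray:
    """Per-segment boolean walking labels (pure function of model+features)."""
    config = config or PipelineConfig()
    X = feature_matrix(segments, config.featbank)
    return model.predict(X, feature_hash=config.feature_spec_hash())


def walking_bouts(
    segments: list[Segment], walking: np.ndarray
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive walking segments, as sample spans.

    Returns (start_index, end_index) half-open sample spans; isolated
    single walking segments count as bouts of one window.
    """
    bouts = []
    i, n = 0, len(segments)
    while i < n:
        if walking[i]:
            j = i
            while j + 1 < n and walking[j + 1]:
                j += 1
            bouts.append(
                (segments[i].start_index, segments[j].start_index + segments[j].length)
            )
            i = j + 1
        else:
            i += 1
    return bouts
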