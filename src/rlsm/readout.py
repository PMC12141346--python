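"""Linear readout: reservoir state features and a multinomial classifier.

The second reservoir's spiking is summarized per sample as a firing-rate
vector (spike count / duration per neuron, in Hz) and classified with
multinomial logistic regression — the single conventionally trained
component of the architecture.  Prediction is the argmax of the class
scores with ties broken towards the lowest class index, so it is
deterministic and reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

__all__ = ["ReadoutModel", "extract_features", "fit_readout", "predict"]


@dataclass
class ReadoutModel:
    """Per-class weight vectors and intercepts over state features."""

    coef: np.ndarray  # (n_classes, n_features)
    intercept: np.ndarray  # (n_classes,)
    classes: np.ndarray  # (n_classes,) sorted ascending

    def scores(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=np.float64)
        if features.shape[-1] != self.coef.shape[1]:
            raise ValueError(
                f"feature length {features.shape[-1]} != model width {self.coef.shape[1]}"
            )
        return features @ self.coef.T + self.intercept

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "coef": self.coef.tolist(),
                    "intercept": self.intercept.tolist(),
                    "classes": self.classes.tolist(),
                },
                fh,
            )

    @classmethod
    def load(cls, path) -> "ReadoutModel":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            coef=np.asarray(raw["coef"], dtype=np.float64),
            intercept=np.asarray(raw["intercept"], dtype=np.float64),
            classes=np.asarray(raw["classes"]),
        )


def extract_features(raster: np.ndarray, duration: float) -> np.ndarray:
    """Per-neuron firing rate (Hz) over one sample.

    ``raster`` is the boolean ``(n_steps, n_neurons)`` spike raster and
    ``duration`` the sample length in seconds.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    return np.asarray(raster, dtype=np.float64).sum(axis=0) / duration


def fit_readout(
    features: np.ndarray, labels: np.ndarray, seed: int = 0
) -> ReadoutModel:
    """Fit a multinomial logistic regression on per-sample feature vectors.

    Optimized with L-BFGS to tolerance 1e-6; deterministic given the data
    and seed.  Requires at least two classes.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a (n_samples, n_features) matrix")
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes to fit the readout")
    clf = LogisticRegression(
        solver="lbfgs", tol=1e-6, max_iter=2000, random_state=seed
    )
    clf.fit(X, y)
    coef, intercept = clf.coef_, clf.intercept_
    if coef.shape[0] == 1:  # binary fit: expand to symmetric per-class scores
        coef = np.vstack([-coef[0] / 2.0, coef[0] / 2.0])
        intercept = np.asarray([-intercept[0] / 2.0, intercept[0] / 2.0])
    order = np.argsort(clf.classes_)
    return ReadoutModel(
        coef=coef[order],
        intercept=intercept[order],
        classes=clf.classes_[order],
    )


def predict(model: ReadoutModel, features: np.ndarray) -> int | np.ndarray:
    """Argmax class score; ties resolve to the lowest class index."""
    scores = model.scores(features)
    idx = np.argmax(scores, axis=-1)  # first maximum = lowest class on ties
    labels = model.classes[idx]
    return labels if np.ndim(features) > 1 else labels.item()
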