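"""Contour validation: feature extraction and error classification.

Snake evolution occasionally produces wrong contours -- two touching
cells merged into one, a cell only partially enclosed, or a spurious
contour over background or debris.  Each final contour is summarised by
a fixed-order shape/intensity feature vector and screened by three
classifiers: an RBF-kernel SVM for partial segmentations, another for
merged cells, and a small decision tree for background/artifact
detections (these are rare and well separated, so a tree suffices).
Contours intersecting the image boundary share the signature of a
partially segmented cell and are routed through the partial pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
from skimage import measure, morphology
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .contour import SnakeContour

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "area", "perimeter", "eccentricity", "solidity",
    "major_axis", "minor_axis",
    "band_intensity", "interior_contrast",
    "border_contact", "has_nucleus",
)

VERDICTS = ("valid", "partial", "merged", "artifact")

MODEL_FORMAT_VERSION = 1


@dataclass
class CellRecord:
    """One candidate cell: contour, features, and validation verdict."""

    contour: SnakeContour
    features: np.ndarray
    verdict: str = "unvalidated"
    scores: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.shape != (len(FEATURE_NAMES),):
            raise ValueError(
                f"feature vector must have length {len(FEATURE_NAMES)}"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")

    @property
    def border_contact(self) -> float:
        return float(self.features[FEATURE_NAMES.index("border_contact")])


def extract_features(contour: SnakeContour, trans: np.ndarray,
                     mu_b: float,
                     nucleus_mask: Optional[np.ndarray] = None,
                     band_width: int = 2,
                     contrast: float = 1.0) -> np.ndarray:
    """Fixed-order feature vector of one contour.

    Shape features come from the rasterised region's moments; intensity
    features are the mean bright-field intensity in a ``band_width``-px
    band inside the contour (the membrane band) and the interior mean,
    both minus the background mean and divided by ``contrast`` (the
    image's nucleus-to-background difference).  Normalising by the
    contrast makes the intensity features invariant to the affine
    contrast adjustment, so a model trained at one contrast setting
    transfers to another.  ``border_contact`` is the fraction of
    vertices within 1 px of the image edge; ``has_nucleus`` flags overlap
    with the nucleus mask.
    """
    trans = np.asarray(trans, dtype=np.float64)
    h, w = trans.shape
    mask = contour.rasterize((h, w))
    area = int(mask.sum())
    if area < 3:   # too small for meaningful moments; degenerate
        return np.zeros(len(FEATURE_NAMES))

    if contrast == 0:
        raise ValueError("contrast must be non-zero")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    eroded = morphology.erosion(mask, morphology.disk(band_width))
    band = mask & ~eroded
    band_intensity = ((float(trans[band].mean()) - mu_b) / contrast
                      if band.any() else 0.0)
    interior = eroded if eroded.any() else mask
    interior_contrast = (float(trans[interior].mean()) - mu_b) / contrast

    v = contour.vertices
    on_border = ((v[:, 0] <= 1.0) | (v[:, 0] >= w - 2.0)
                 | (v[:, 1] <= 1.0) | (v[:, 1] >= h - 2.0))
    border_contact = float(on_border.mean())

    has_nucleus = 0.0
    if nucleus_mask is not None and np.any(mask & nucleus_mask):
        has_nucleus = 1.0

    return np.array([
        float(area), contour.perimeter(), float(props.eccentricity),
        float(props.solidity), float(props.axis_major_length),
        float(props.axis_minor_length), band_intensity, interior_contrast,
        border_contact, has_nucleus,
    ])


def make_record(contour: SnakeContour, trans: np.ndarray, mu_b: float,
                nucleus_mask: Optional[np.ndarray] = None,
                contrast: float = 1.0) -> CellRecord:
    feats = extract_features(contour, trans, mu_b, nucleus_mask,
                             contrast=contrast)
    rec = CellRecord(contour=contour, features=feats)
    if contour.degenerate or feats[0] == 0:
        rec.verdict = "artifact"
    return rec


@dataclass
class ValidationModel:
    """Trained error classifiers plus training metadata.

    ``svm_partial`` separates valid from partial contours, ``svm_merged``
    valid from merged, and ``tree_artifact`` valid from
    background/artifact detections.  ``cv_accuracy`` holds the stratified
    5-fold accuracy of each binary task.
    """

    svm_partial: Pipeline
    svm_merged: Pipeline
    tree_artifact: DecisionTreeClassifier
    n_samples: int = 0
    cv_accuracy: Dict[str, float] = field(default_factory=dict)
    border_contact_threshold: float = 0.05

    @property
    def mean_cv_accuracy(self) -> float:
        return float(np.mean(list(self.cv_accuracy.values())))


def _binary_task(features: np.ndarray, verdicts: Sequence[str],
                 positive: str) -> Tuple[np.ndarray, np.ndarray]:
    keep = [i for i, v in enumerate(verdicts) if v in ("valid", positive)]
    X = features[keep]
    y = np.array([1 if verdicts[i] == positive else 0 for i in keep])
    return X, y


def train_validators(labeled: Sequence[Tuple[np.ndarray, str]],
                     seed: int = 0, n_folds: int = 5,
                     border_contact_threshold: float = 0.05,
                     ) -> ValidationModel:
    """Fit the three error classifiers on labelled (features, verdict)
    pairs and report stratified k-fold CV accuracy per task."""
    features = np.asarray([f for f, _ in labeled], dtype=np.float64)
    verdicts = [v for _, v in labeled]
    for v in verdicts:
        if v not in VERDICTS:
            raise ValueError(f"unknown verdict {v!r}")
    if len(set(verdicts)) < 2:
        raise ValueError("training data must contain at least two classes")

    cv_acc: Dict[str, float] = {}

    def fit_binary(estimator, positive: str):
        X, y = _binary_task(features, verdicts, positive)
        if len(np.unique(y)) < 2:
            raise ValueError(f"task valid-vs-{positive} has a single class")
        folds = min(n_folds, int(np.bincount(y).min()))
        if folds >= 2:
            cv = StratifiedKFold(n_splits=folds, shuffle=True,
                                 random_state=seed)
            cv_acc[positive] = float(
                cross_val_score(estimator, X, y, cv=cv).mean())
        estimator.fit(X, y)
        return estimator

    def make_svm():
        return Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(C=1.0, kernel="rbf", gamma="scale",
                        random_state=seed)),
        ])

    svm_partial = fit_binary(make_svm(), "partial")
    svm_merged = fit_binary(make_svm(), "merged")
    tree = fit_binary(DecisionTreeClassifier(random_state=seed), "artifact")

    model = ValidationModel(svm_partial=svm_partial, svm_merged=svm_merged,
                            tree_artifact=tree, n_samples=len(labeled),
                            cv_accuracy=cv_acc,
                            border_contact_threshold=border_contact_threshold)
    logger.info("validator trained on %d samples; CV accuracy %s",
                len(labeled), cv_acc)
    return model


def predict_verdict(model: ValidationModel, features: np.ndarray) -> str:
    """Verdict of a feature vector with fixed precedence: artifact, then
    merged, then partial (image-boundary contours are treated as
    partial), else valid."""
    feats = np.asarray(features, dtype=np.float64)
    if feats.shape != (len(FEATURE_NAMES),):
        raise ValueError("feature length mismatch")
    X = feats.reshape(1, -1)
    if model.tree_artifact.predict(X)[0] == 1:
        return "artifact"
    if model.svm_merged.predict(X)[0] == 1:
        return "merged"
    if feats[FEATURE_NAMES.index("border_contact")] \
            > model.border_contact_threshold:
        return "partial"
    if model.svm_partial.predict(X)[0] == 1:
        return "partial"
    return "valid"


def classify_contour(model: ValidationModel, record: CellRecord) -> str:
    """Verdict for one contour record (degenerate contours are artifacts
    outright; otherwise the feature-level precedence applies)."""
    feats = np.asarray(record.features, dtype=np.float64)
    if feats.shape != (len(FEATURE_NAMES),):
        raise ValueError("feature length mismatch")
    if record.contour.degenerate or feats[0] == 0:
        return "artifact"
    return predict_verdict(model, feats)


def filter_contours(records: Sequence[CellRecord], model: ValidationModel,
                    ) -> Tuple[List[CellRecord], List[CellRecord]]:
    """Classify every record; return (accepted, rejected)."""
    accepted: List[CellRecord] = []
    rejected: List[CellRecord] = []
    for rec in records:
        rec.verdict = classify_contour(model, rec)
        (accepted if rec.verdict == "valid" else rejected).append(rec)
    return accepted, rejected


def save_model(model: ValidationModel, path) -> None:
    """Serialise a trained validation model (versioned container)."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path) -> ValidationModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model file version")
    return payload["model"]
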