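"""Supervised pixel classification into border / gap / big fibre / small fibre.

A random forest is trained on sparse brush annotations over the 13-channel
feature stack and then assigns every pixel of an image to one of the four
texture classes.  Only 'border' pixels feed the subsequent vision stages:
the initial clusters are the connected non-border regions fully encapsulated
by border pixels.
"""

from __future__ import annotations

from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage as ndi
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .config import FeatureConfig, ValidationError
from .features import compute_features

# Fixed class codes; annotation value 0 means "unlabeled".
CLASS_UNLABELED = 0
CLASS_BORDER = 1
CLASS_GAP = 2
CLASS_BIG_FIBRE = 3
CLASS_SMALL_FIBRE = 4
CLASS_NAMES = {
    CLASS_BORDER: "border",
    CLASS_GAP: "gap",
    CLASS_BIG_FIBRE: "big_fibre",
    CLASS_SMALL_FIBRE: "small_fibre",
}

#: 4-connectivity structure used for cluster labelling throughout.
STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class FibrePixelClassifier(BaseEstimator, ClassifierMixin):
    """Random-forest pixel classifier over the Gaussian/Hessian feature stack.

    Parameters
    ----------
    feature_config : FeatureConfig
        Scales of the smoothing and Hessian-eigenvalue features.
    n_estimators : int
        Number of trees (100 is the Ilastik default this mirrors).
    random_state : int
        Seed of the forest; predictions are deterministic given it.

    Notes
    -----
    `fit` accepts either a single ``(image, annotation)`` pair or aligned
    sequences of them; annotations are sparse maps with 0 = unlabeled and
    values 1-4 for border, gap, big fibre and small fibre.  Tie votes are
    broken towards the lower class code (border first).
    """

    def __init__(
        self,
        feature_config: FeatureConfig | None = None,
        n_estimators: int = 100,
        random_state: int = 0,
    ):
        self.feature_config = feature_config
        self.n_estimators = n_estimators
        self.random_state = random_state

    def _cfg(self) -> FeatureConfig:
        return self.feature_config or FeatureConfig()

    def fit(self, X, y):
        """Fit on labeled pixels of one or more annotated images.

        ``X``: image or feature stack, or a sequence of them;
        ``y``: matching annotation map(s).
        """
        images, annotations = _as_pairs(X, y)
        cfg = self._cfg()
        feats, labels = [], []
        for img, ann in zip(images, annotations):
            ann = np.asarray(ann)
            stack = _ensure_stack(img, cfg)
            if ann.shape != stack.shape[:2]:
                raise ValidationError(
                    f"annotation shape {ann.shape} does not match image "
                    f"shape {stack.shape[:2]}"
                )
            mask = ann != CLASS_UNLABELED
            feats.append(stack[mask])
            labels.append(ann[mask])
        Xt = np.concatenate(feats, axis=0)
        yt = np.concatenate(labels, axis=0).astype(np.int64)
        present = np.unique(yt)
        if present.size < 2:
            raise ValidationError(
                "training requires annotated pixels in at least 2 distinct "
                f"classes; found classes {present.tolist()} — a classifier "
                "cannot learn a decision boundary from a single class"
            )
        bad = set(present.tolist()) - set(CLASS_NAMES)
        if bad:
            raise ValidationError(f"unknown annotation values {sorted(bad)}")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.forest_.fit(Xt, yt)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = Xt.shape[1]
        self.feature_config_ = cfg
        return self

    def predict(self, X) -> np.ndarray:
        """Predict the class map (H, W) of an image or feature stack."""
        check_is_fitted(self, "forest_")
        stack = _ensure_stack(X, self.feature_config_)
        if stack.shape[-1] != self.n_features_in_:
            raise ValidationError(
                f"feature stack has {stack.shape[-1]} channels but the "
                f"classifier was trained with {self.n_features_in_}"
            )
        flat = stack.reshape(-1, stack.shape[-1])
        pred = self.forest_.predict(flat)
        return pred.reshape(stack.shape[:2]).astype(np.uint8)

    def save(self, path) -> None:
        """Persist forest state, feature config, classes and seed."""
        check_is_fitted(self, "forest_")
        joblib.dump(
            {
                "forest": self.forest_,
                "feature_config": self.feature_config_,
                "classes": self.classes_,
                "n_features_in": self.n_features_in_,
                "n_estimators": self.n_estimators,
                "random_state": self.random_state,
            },
            Path(path),
        )

    @classmethod
    def load(cls, path) -> "FibrePixelClassifier":
        state = joblib.load(Path(path))
        clf = cls(
            feature_config=state["feature_config"],
            n_estimators=state["n_estimators"],
            random_state=state["random_state"],
        )
        clf.forest_ = state["forest"]
        clf.feature_config_ = state["feature_config"]
        clf.classes_ = state["classes"]
        clf.n_features_in_ = state["n_features_in"]
        return clf


def _ensure_stack(X, cfg: FeatureConfig) -> np.ndarray:
    """Accept an 8-bit image (2-D) or a precomputed feature stack (3-D)."""
    arr = np.asarray(X)
    if arr.ndim == 2:
        return compute_features(arr, cfg)
    if arr.ndim == 3:
        return arr
    raise ValidationError(f"expected 2-D image or 3-D feature stack, got {arr.ndim}-D")


def _as_pairs(X, y):
    if isinstance(X, np.ndarray) and X.ndim in (2, 3):
        return [X], [y]
    images, annotations = list(X), list(y)
    if len(images) != len(annotations):
        raise ValidationError(
            f"{len(images)} images but {len(annotations)} annotation maps"
        )
    return images, annotations


def train_classifier(stack, annotations, seed: int = 0,
                     feature_config: FeatureConfig | None = None
                     ) -> FibrePixelClassifier:
    """Train a :class:`FibrePixelClassifier` on one annotated feature stack."""
    clf = FibrePixelClassifier(feature_config=feature_config, random_state=seed)
    return clf.fit(stack, annotations)


def predict_classes(clf: FibrePixelClassifier, stack) -> np.ndarray:
    """Majority-vote class map for a feature stack (or image)."""
    return clf.predict(stack)


def extract_border_mask(class_map: np.ndarray) -> np.ndarray:
    """Binary mask of pixels assigned to the 'border' class."""
    cm = np.asarray(class_map)
    if cm.ndim != 2:
        raise ValidationError("class map must be 2-D")
    return cm == CLASS_BORDER


def initial_clusters(border: np.ndarray) -> np.ndarray:
    """Connected non-border regions fully encapsulated by border pixels.

    Non-border pixels are labelled with 4-connectivity; components touching
    the image boundary are not encapsulated and get label 0.  Labels 1..K
    are assigned in raster-scan order of each component's first pixel.
    """
    mask = np.asarray(border).astype(bool)
    if mask.ndim != 2:
        raise ValidationError("border mask must be 2-D")
    lab, _ = ndi.label(~mask, structure=STRUCTURE_4)
    edge_labels = np.unique(
        np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    )
    lab[np.isin(lab, edge_labels[edge_labels > 0])] = 0
    return relabel_sequential_raster(lab)


def relabel_sequential_raster(labels: np.ndarray) -> np.ndarray:
    """Compact labels to 1..K ordered by first pixel in raster scan."""
    lab = np.asarray(labels)
    flat = lab.ravel()
    uniq, first = np.unique(flat, return_index=True)
    keep = uniq > 0
    uniq, first = uniq[keep], first[keep]
    order = np.argsort(first, kind="stable")
    mapping = np.zeros(int(lab.max()) + 1 if lab.size else 1, dtype=np.int32)
    for new, old in enumerate(uniq[order], start=1):
        mapping[old] = new
    return mapping[lab]
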