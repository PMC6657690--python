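"""End-to-end pipelines and the three-way comparison workflow.

``HybridSegmenter`` is the learning+vision pipeline: preprocess, random
forest pixel classification, watershed cluster separation and geodesic
active contour reconstruction.  With ``use_watershed=False`` it degrades to
the classifier-only arm (initial clusters reconstructed directly), and
``RidgeSegmenter`` (see :mod:`myoseg.ridge`) is the vision-only arm; the
``compare`` workflow runs all three on the same inputs and feeds the
evaluation framework.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import numpy as np
from sklearn.base import BaseEstimator

from . import __version__ as _pkg_version
from .classify import FibrePixelClassifier, extract_border_mask, initial_clusters
from .config import RunConfig, ValidationError
from .contours import Fibre, fibres_to_labels, reconstruct_all
from .evaluation import evaluate_pipelines
from .io import apply_intensity_threshold
from .ridge import RidgeSegmenter
from .separation import fill_small_holes, separate

logger = logging.getLogger(__name__)


class HybridSegmenter(BaseEstimator):
    """Supervised-learning + computer-vision fibre segmentation pipeline.

    Parameters mirror :class:`~myoseg.config.RunConfig`; ``fit`` trains the
    pixel classifier on sparsely annotated images, ``predict`` returns the
    fibre label image of a new section and ``segment`` additionally returns
    the measured :class:`~myoseg.contours.Fibre` objects.
    """

    def __init__(self, config: RunConfig | None = None,
                 use_watershed: bool = True,
                 crop_margin: int | None = 48):
        self.config = config
        self.use_watershed = use_watershed
        self.crop_margin = crop_margin

    def _cfg(self) -> RunConfig:
        return self.config or RunConfig()

    def fit(self, X, y):
        """Train the pixel classifier on annotated image(s) X with maps y."""
        cfg = self._cfg()
        self.classifier_ = FibrePixelClassifier(
            feature_config=cfg.features, random_state=cfg.seed
        )
        self.classifier_.fit(X, y)
        return self

    def set_classifier(self, classifier: FibrePixelClassifier) -> "HybridSegmenter":
        """Attach an already-trained pixel classifier (e.g. loaded from disk)."""
        self.classifier_ = classifier
        return self

    def segment(self, image: np.ndarray) -> tuple[list[Fibre], np.ndarray]:
        """Segment one image; returns (fibres, final cluster label image)."""
        if not hasattr(self, "classifier_"):
            raise ValidationError(
                "no trained pixel classifier: call fit() or set_classifier() "
                "(CLI: run `myoseg train` first)"
            )
        cfg = self._cfg()
        pre = apply_intensity_threshold(image, cfg.preprocess)
        class_map = self.classifier_.predict(pre)
        border = extract_border_mask(class_map)
        if self.use_watershed:
            clusters = separate(border, cfg.separation)
        else:
            clusters = initial_clusters(fill_small_holes(border, cfg.separation))
        fibres = reconstruct_all(
            clusters, pre, cfg.gac, crop_margin=self.crop_margin
        )
        return fibres, clusters

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Fibre label image of one section."""
        fibres, _ = self.segment(image)
        return fibres_to_labels(fibres, np.asarray(image).shape)


def run_slcv(image: np.ndarray, classifier: FibrePixelClassifier,
             cfg: RunConfig | None = None) -> tuple[list[Fibre], np.ndarray]:
    """Run the full hybrid pipeline on one image with a trained classifier."""
    seg = HybridSegmenter(config=cfg).set_classifier(classifier)
    return seg.segment(image)


def run_compare(images, groundtruths, classifier: FibrePixelClassifier,
                cfg: RunConfig | None = None, B: int = 100_000,
                seed: int = 0, crop_margin: int | None = 48) -> dict:
    """Three-arm comparison: hybrid vs classifier-only vs ridge pipelines.

    Runs all arms on every image, evaluates separation sensitivity,
    restricted Dice and KL area divergence against the groundtruths, and
    returns the report with a reproducibility manifest.
    """
    cfg = cfg or RunConfig()
    images = list(images)
    groundtruths = list(groundtruths)
    if len(images) != len(groundtruths):
        raise ValidationError("images and groundtruths must be aligned")
    hybrid = HybridSegmenter(config=cfg, crop_margin=crop_margin
                             ).set_classifier(classifier)
    classifier_only = HybridSegmenter(
        config=cfg, use_watershed=False, crop_margin=crop_margin
    ).set_classifier(classifier)
    ridge_arm = RidgeSegmenter(
        ridge_config=cfg.ridge, erosion_config=cfg.erosion, gac_config=cfg.gac
    )
    outputs: dict[str, list] = {"hybrid": [], "classifier": [], "ridge": []}
    for i, img in enumerate(images):
        shape = np.asarray(img).shape
        outputs["hybrid"].append(fibres_to_labels(hybrid.segment(img)[0], shape))
        outputs["classifier"].append(
            fibres_to_labels(classifier_only.segment(img)[0], shape)
        )
        pre = apply_intensity_threshold(img, cfg.preprocess)
        outputs["ridge"].append(fibres_to_labels(ridge_arm.predict(pre), shape))
        logger.info("compare: segmented image %d/%d", i + 1, len(images))
    report = evaluate_pipelines(
        images, groundtruths, outputs, ridge_cfg=cfg.ridge, B=B, seed=seed
    )
    report["manifest"] = make_manifest(cfg, seed=seed, extra={"B": B})
    return report


def make_manifest(cfg: RunConfig, seed: int, extra: dict | None = None) -> dict:
    """Reproducibility metadata: config hash, seeds, versions."""
    cfg_dict = cfg.to_dict()
    blob = json.dumps(cfg_dict, sort_keys=True).encode()
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {
            "myoseg": _pkg_version,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    return manifest
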