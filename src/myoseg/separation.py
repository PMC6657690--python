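"""Cluster separation by distance-transform thresholding and watershed.

Initial clusters can contain several touching fibres when the detected
border has holes.  This stage fills very small holes by dilating the border,
computes the exact Euclidean distance of every cluster pixel to the nearest
border pixel, keeps only pixels whose distance exceeds ``tau * max`` (one
maximum per fibre survives as a marker), and floods the markers outward with
marker-based watershed.  Flooding stops at border pixels and where two
basins meet; the meeting ridge keeps label 0.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator, TransformerMixin

from .classify import initial_clusters, relabel_sequential_raster
from .config import SeparationConfig, ValidationError

logger = logging.getLogger(__name__)

_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


def fill_small_holes(border: np.ndarray, cfg: SeparationConfig | None = None
                     ) -> np.ndarray:
    """Dilate the border mask to close very small gaps (3x3 square kernel)."""
    cfg = cfg or SeparationConfig()
    mask = np.asarray(border).astype(bool)
    if cfg.dilation_iterations == 0:
        return mask.copy()
    return ndi.binary_dilation(
        mask, structure=_STRUCTURE_8, iterations=cfg.dilation_iterations
    )


def distance_transform(border: np.ndarray, clusters: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance to the nearest border pixel, inside clusters.

    Pixels outside any cluster (label 0) and border pixels get value 0.
    """
    mask = np.asarray(border).astype(bool)
    lab = np.asarray(clusters)
    if mask.shape != lab.shape:
        raise ValidationError("border and cluster shapes differ")
    dist = ndi.distance_transform_edt(~mask)
    dist[lab <= 0] = 0.0
    return dist


def threshold_distance(dist: np.ndarray, clusters: np.ndarray,
                       cfg: SeparationConfig | None = None) -> np.ndarray:
    """Keep distance values >= tau * max and label surviving components.

    With ``threshold_scope='per_cluster'`` (default) the maximum is taken
    within each initial cluster, so small fibres keep their markers in the
    presence of a large one; ``'global'`` applies the literal image-wide
    maximum.  Marker components are 8-connected and each lies inside exactly
    one initial cluster.
    """
    cfg = cfg or SeparationConfig()
    dist = np.asarray(dist, dtype=np.float64)
    lab = np.asarray(clusters)
    if dist.shape != lab.shape:
        raise ValidationError("distance map and cluster shapes differ")
    markers = np.zeros(lab.shape, dtype=np.int32)
    next_label = 1
    if cfg.threshold_scope == "global":
        global_max = dist.max()
    for sl, cid in _iter_clusters(lab):
        region = lab[sl] == cid
        d = dist[sl]
        ref = global_max if cfg.threshold_scope == "global" else d[region].max()
        surviving = region & (d >= cfg.tau * ref) & (d > 0)
        comp, n = ndi.label(surviving, structure=_STRUCTURE_8)
        if n:
            view = markers[sl]
            view[comp > 0] = comp[comp > 0] + (next_label - 1)
            next_label += n
    return relabel_sequential_raster(markers)


def watershed_separation(dist: np.ndarray, markers: np.ndarray,
                         border: np.ndarray) -> np.ndarray:
    """Flood markers over the negated distance map to final clusters.

    Restricted to non-border cluster pixels (``dist > 0``); ridge pixels
    where two basins meet are left at label 0.
    """
    dist = np.asarray(dist, dtype=np.float64)
    markers = np.asarray(markers)
    border = np.asarray(border).astype(bool)
    if not (dist.shape == markers.shape == border.shape):
        raise ValidationError("distance, marker and border shapes differ")
    if markers.max() == 0:
        logger.warning("empty marker image: watershed returns no clusters")
        return np.zeros(dist.shape, dtype=np.int32)
    region = (dist > 0) & ~border
    out = watershed(
        -dist, markers=markers, mask=region, connectivity=1, watershed_line=True
    )
    return out.astype(np.int32)


def separate(border: np.ndarray, cfg: SeparationConfig | None = None
             ) -> np.ndarray:
    """Full separation stage: dilation, clusters, distance, markers, watershed."""
    cfg = cfg or SeparationConfig()
    filled = fill_small_holes(border, cfg)
    clusters = initial_clusters(filled)
    dist = distance_transform(filled, clusters)
    markers = threshold_distance(dist, clusters, cfg)
    return watershed_separation(dist, markers, filled)


def _iter_clusters(labels: np.ndarray):
    """Yield (slice, cluster_id) pairs over the bounding boxes of labels."""
    objects = ndi.find_objects(labels)
    for cid, sl in enumerate(objects, start=1):
        if sl is not None:
            yield sl, cid


class WatershedSeparator(BaseEstimator, TransformerMixin):
    """Transformer wrapping the separation stage for pipeline composition.

    ``transform`` maps a border mask (or a list of them) to final-cluster
    label images.  Stateless: ``fit`` only validates parameters.
    """

    def __init__(self, tau: float = 0.3, dilation_iterations: int = 1,
                 threshold_scope: str = "per_cluster"):
        self.tau = tau
        self.dilation_iterations = dilation_iterations
        self.threshold_scope = threshold_scope

    def _cfg(self) -> SeparationConfig:
        return SeparationConfig(
            tau=self.tau,
            dilation_iterations=self.dilation_iterations,
            threshold_scope=self.threshold_scope,
        )

    def fit(self, X=None, y=None):
        self._cfg()
        return self

    def transform(self, X):
        cfg = self._cfg()
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return separate(X, cfg)
        return [separate(x, cfg) for x in X]
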