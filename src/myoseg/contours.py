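"""Area reconstruction with morphological geodesic active contours.

The separation stage loses fibre area near borders; here each final cluster
is used as the seed of a deformable curve that inflates (balloon force,
``nu=+1``) until the attraction field

    g(I) = 1 / sqrt(1 + alpha * |grad(G_sigma x I)|)

stops it at the cell border (g has its minima where intensity changes are
strong).  The contour PDE is solved with morphological operators: binary
dilation for the balloon term, a sign test on grad(g) . grad(u) for the
attraction term and ``mu`` alternating inf-sup/sup-inf passes for the
curvature smoothing term.  The alternation parity is local to each
evolution, so identical inputs always produce identical masks regardless of
what ran before.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import regionprops
from sklearn.base import BaseEstimator

from .config import GACConfig, ValidationError

_STRUCTURE_8 = np.ones((3, 3), dtype=np.int8)

# The four 3x3 line structuring elements of the curvature operator.
_P_LINES = [
    np.eye(3, dtype=np.int8),
    np.array([[0, 1, 0], [0, 1, 0], [0, 1, 0]], dtype=np.int8),
    np.flipud(np.eye(3, dtype=np.int8)),
    np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0]], dtype=np.int8),
]


@dataclass
class Fibre:
    """A reconstructed muscle fibre and its measurements (pixel units)."""

    fibre_id: int
    mask: np.ndarray
    area: int
    feret: float
    perimeter: float
    centroid_row: float
    centroid_col: float
    source_cluster_id: int


def attraction_field(image: np.ndarray, cfg: GACConfig | None = None
                     ) -> np.ndarray:
    """Edge-attraction field g(I) in (0, 1], equal to 1 where the image is flat.

    The image is normalised to [0, 1]; the gradient magnitude is computed at
    Gaussian scale ``sigma`` with reflective boundaries.
    """
    cfg = cfg or GACConfig()
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValidationError("expected a nonempty 2-D image")
    norm = img.astype(np.float64) / 255.0
    grad = ndi.gaussian_gradient_magnitude(norm, cfg.sigma, mode="reflect")
    return 1.0 / np.sqrt(1.0 + cfg.alpha * grad)


def _sup_inf(u: np.ndarray) -> np.ndarray:
    return np.stack(
        [ndi.binary_erosion(u, p).astype(np.int8) for p in _P_LINES], axis=0
    ).max(0)


def _inf_sup(u: np.ndarray) -> np.ndarray:
    return np.stack(
        [ndi.binary_dilation(u, p).astype(np.int8) for p in _P_LINES], axis=0
    ).min(0)


def gac_evolve(seed: np.ndarray, g: np.ndarray, cfg: GACConfig | None = None
               ) -> np.ndarray:
    """Evolve a binary seed mask under the morphological contour dynamics.

    Stops when the mask is unchanged for ``convergence_window`` consecutive
    iterations, or after ``max_iterations``.
    """
    cfg = cfg or GACConfig()
    u = np.asarray(seed).astype(bool)
    g = np.asarray(g, dtype=np.float64)
    if u.shape != g.shape:
        raise ValidationError("seed and attraction field shapes differ")
    if not u.any():
        raise ValidationError("seed mask is empty")
    dg = np.gradient(g)
    balloon_zone = g > cfg.theta
    u = u.astype(np.int8)
    stable = 0
    parity = 0  # local curvature-operator alternation
    # recent mask states; revisiting one means the evolution has reached a
    # fixed point or a small limit cycle (the discrete attraction term can
    # flip boundary pixels back and forth forever), so it counts as stable
    history: list[bytes] = []
    for _ in range(cfg.max_iterations):
        # balloon force, gated to regions where g is above theta
        if cfg.nu != 0:
            if cfg.nu > 0:
                aux = ndi.binary_dilation(u, _STRUCTURE_8)
            else:
                aux = ndi.binary_erosion(u, _STRUCTURE_8, border_value=1)
            u = u.copy()
            u[balloon_zone] = aux[balloon_zone]
        # image attraction: move the contour along grad(g)
        du = np.gradient(u.astype(np.float64))
        drive = dg[0] * du[0] + dg[1] * du[1]
        u = u.copy()
        u[drive > 0] = 1
        u[drive < 0] = 0
        # curvature smoothing, mu alternating passes
        for _ in range(cfg.mu):
            u = _sup_inf(_inf_sup(u)) if parity == 0 else _inf_sup(_sup_inf(u))
            parity ^= 1
        state = u.tobytes()
        if state in history:
            stable += 1
            if stable >= cfg.convergence_window:
                break
        else:
            stable = 0
        history.append(state)
        if len(history) > cfg.convergence_window + 2:
            history.pop(0)
    return u.astype(bool)


def measure_fibre(mask: np.ndarray, fibre_id: int = 1,
                  source_cluster_id: int = 0) -> Fibre:
    """Measure a fibre mask: area, feret diameter, perimeter, centroid.

    The feret diameter is the maximum pairwise distance between pixel
    centers, computed on the convex hull of the mask coordinates; the
    perimeter is the traced outer contour length.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValidationError("cannot measure an empty mask")
    coords = np.argwhere(m)
    area = int(coords.shape[0])
    centroid = coords.mean(axis=0)
    props = regionprops(m.astype(np.uint8))[0]
    return Fibre(
        fibre_id=fibre_id,
        mask=m,
        area=area,
        feret=_feret_diameter(coords),
        perimeter=float(props.perimeter),
        centroid_row=float(centroid[0]),
        centroid_col=float(centroid[1]),
        source_cluster_id=source_cluster_id,
    )


def _feret_diameter(coords: np.ndarray) -> float:
    pts = coords.astype(np.float64)
    if pts.shape[0] == 1:
        return 0.0
    if pts.shape[0] > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (collinear) sets: fall back to all pairs
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def boundary_touching_ids(labels: np.ndarray) -> np.ndarray:
    """Label ids with at least one pixel on the image boundary."""
    lab = np.asarray(labels)
    edge = np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    ids = np.unique(edge)
    return ids[ids > 0]


def reconstruct_all(final_clusters: np.ndarray, image: np.ndarray,
                    cfg: GACConfig | None = None, *,
                    attraction: np.ndarray | None = None,
                    crop_margin: int | None = 48) -> list[Fibre]:
    """Evolve every non-boundary cluster independently and measure the fibres.

    Clusters touching the image boundary are incompletely imaged and are
    excluded.  Each cluster is evolved on a window of the shared attraction
    field padded by ``crop_margin`` px around its bounding box (pass ``None``
    to evolve on the full image); evolution order does not affect results.
    Fibres are returned ordered by ``fibre_id`` (raster order of their
    source clusters); masks from different fibres may overlap.
    """
    cfg = cfg or GACConfig()
    lab = np.asarray(final_clusters)
    img = np.asarray(image)
    if lab.shape != img.shape:
        raise ValidationError(
            f"cluster shape {lab.shape} does not match image shape {img.shape}"
        )
    g = attraction if attraction is not None else attraction_field(img, cfg)
    excluded = set(boundary_touching_ids(lab).tolist())
    fibres: list[Fibre] = []
    next_id = 1
    for sl, cid in _cluster_slices(lab):
        if cid in excluded:
            continue
        if crop_margin is None:
            seed = lab == cid
            evolved = gac_evolve(seed, g, cfg)
            if not evolved.any():
                evolved = seed  # collapsed under smoothing: keep the seed
        else:
            win = _pad_slices(sl, lab.shape, crop_margin)
            seed = lab[win] == cid
            evolved_win = gac_evolve(seed, g[win], cfg)
            if not evolved_win.any():
                evolved_win = seed
            evolved = np.zeros(lab.shape, dtype=bool)
            evolved[win] = evolved_win
        fibre = measure_fibre(evolved, fibre_id=next_id, source_cluster_id=cid)
        fibres.append(fibre)
        next_id += 1
    return fibres


def fibres_to_labels(fibres, shape) -> np.ndarray:
    """Paint fibre masks into one label image.

    Pixels claimed by several fibres keep the lowest fibre_id (first paint
    wins); overlaps are rare because evolutions stop at shared borders.
    """
    out = np.zeros(shape, dtype=np.int32)
    for f in sorted(fibres, key=lambda f: f.fibre_id):
        out[(out == 0) & f.mask] = f.fibre_id
    return out


def _cluster_slices(labels: np.ndarray):
    for cid, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is not None:
            yield sl, cid


def _pad_slices(sl, shape, margin: int):
    return tuple(
        slice(max(0, s.start - margin), min(dim, s.stop + margin))
        for s, dim in zip(sl, shape)
    )


class GACReconstructor(BaseEstimator):
    """Estimator wrapping contour reconstruction for pipeline composition."""

    def __init__(self, alpha: float = 2000.0, sigma: float = 2.0, nu: int = 1,
                 mu: int = 3, theta: float = 0.3, max_iterations: int = 500,
                 convergence_window: int = 5, crop_margin: int | None = 48):
        self.alpha = alpha
        self.sigma = sigma
        self.nu = nu
        self.mu = mu
        self.theta = theta
        self.max_iterations = max_iterations
        self.convergence_window = convergence_window
        self.crop_margin = crop_margin

    def _cfg(self) -> GACConfig:
        return GACConfig(
            alpha=self.alpha, sigma=self.sigma, nu=self.nu, mu=self.mu,
            theta=self.theta, max_iterations=self.max_iterations,
            convergence_window=self.convergence_window,
        )

    def fit(self, X=None, y=None):
        self._cfg()
        return self

    def reconstruct(self, image: np.ndarray, clusters: np.ndarray) -> list[Fibre]:
        return reconstruct_all(
            clusters, image, self._cfg(), crop_margin=self.crop_margin
        )
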