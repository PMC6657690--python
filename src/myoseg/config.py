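"""Configuration objects for every pipeline stage.

Each stage of the two segmentation pipelines (the hybrid learning+vision
pipeline and the vision-only ridge/erosion reference pipeline) is controlled
by a small frozen dataclass.  Defaults are the published operating point of
the method: Gaussian/Hessian feature scales for the pixel classifier, the
distance-transform threshold ``tau`` for watershed marker extraction, the
geodesic-active-contour parameters (``alpha``, ``sigma``, ``nu``, ``mu``,
``theta``) and the ridge/erosion parameters of the reference pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple


class ValidationError(ValueError):
    """Raised when an input or configuration violates a stage contract."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Manual intensity threshold applied before vision-based detection.

    Pixels below ``tau_intensity`` are set to 0 and excluded from cell
    detection; 0 disables the step.
    """

    tau_intensity: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.tau_intensity <= 255:
            raise ValidationError(
                f"tau_intensity must be in [0, 255], got {self.tau_intensity}"
            )


@dataclass(frozen=True)
class FeatureConfig:
    """Scales (in px) of the pixel-classification feature stack.

    ``sigma_intensity`` are Gaussian-smoothing scales; ``sigma_texture`` are
    Hessian-of-Gaussian scales whose two eigenvalues per pixel capture
    line-like intensity changes (cell borders).
    """

    sigma_intensity: Tuple[float, ...] = (0.3, 0.7, 1.0, 1.6, 3.5)
    sigma_texture: Tuple[float, ...] = (1.6, 3.5, 5.0, 10.0)

    def __post_init__(self) -> None:
        for s in tuple(self.sigma_intensity) + tuple(self.sigma_texture):
            if s <= 0:
                raise ValidationError(f"feature scale must be > 0, got {s}")

    @property
    def n_channels(self) -> int:
        return len(self.sigma_intensity) + 2 * len(self.sigma_texture)


@dataclass(frozen=True)
class SeparationConfig:
    """Watershed cluster-separation parameters.

    ``tau`` is the relative distance-transform threshold: pixels with distance
    below ``tau * max(distance)`` are discarded, the surviving components
    become watershed markers.  The larger ``tau``, the more readily a cluster
    splits.  ``threshold_scope`` selects whether ``max(distance)`` is taken
    per initial cluster (default; robust to size variation between fibres) or
    globally over the image (the literal reading of the thresholding rule).
    """

    tau: float = 0.3
    dilation_iterations: int = 1
    threshold_scope: str = "per_cluster"

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValidationError(f"tau must be in [0, 1], got {self.tau}")
        if self.dilation_iterations < 0:
            raise ValidationError("dilation_iterations must be >= 0")
        if self.threshold_scope not in ("per_cluster", "global"):
            raise ValidationError(
                "threshold_scope must be 'per_cluster' or 'global', "
                f"got {self.threshold_scope!r}"
            )


@dataclass(frozen=True)
class GACConfig:
    """Morphological geodesic-active-contour parameters.

    ``alpha`` and ``sigma`` shape the attraction field
    g(I) = 1/sqrt(1 + alpha * |grad(G_sigma x I)|); ``nu`` is the balloon sign
    (+1 inflates), ``mu`` the number of curvature-smoothing passes per
    iteration and ``theta`` the gate on g below which the balloon force is
    switched off (so the contour stops at borders).
    """

    alpha: float = 2000.0
    sigma: float = 2.0
    nu: int = 1
    mu: int = 3
    theta: float = 0.3
    max_iterations: int = 500
    convergence_window: int = 5

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if self.nu not in (-1, 0, 1):
            raise ValidationError("nu must be -1, 0 or +1")
        if self.mu < 0:
            raise ValidationError("mu must be >= 0")
        if not 0.0 <= self.theta <= 1.0:
            raise ValidationError("theta must be in [0, 1]")
        if self.max_iterations < 1 or self.convergence_window < 1:
            raise ValidationError("iteration limits must be >= 1")


@dataclass(frozen=True)
class RidgeConfig:
    """Single-scale Hessian ridge likelihood parameters.

    ``sigma_star`` is the detection scale; ``alpha_r`` and ``beta_r`` weight
    the blobness ratio R_B = |lambda2/lambda1| and the structure strength
    S = lambda1^2 + lambda2^2 in the likelihood
    r = exp(-R_B/alpha_r^2) * (1 - exp(-S^2/beta_r^2)) for dark-centred
    (lambda1 <= 0) ridges, on intensities normalised to [0, 1].
    """

    sigma_star: float = 0.7
    alpha_r: float = 0.5
    beta_r: float = 0.03

    def __post_init__(self) -> None:
        if self.sigma_star <= 0:
            raise ValidationError("sigma_star must be > 0")
        if self.alpha_r <= 0 or self.beta_r <= 0:
            raise ValidationError("alpha_r and beta_r must be > 0")


@dataclass(frozen=True)
class ErosionConfig:
    """Morphology parameters of the reference pipeline's cluster stage.

    Ridges are closed with an 11x11 rectangle and dilated twice with a 3x3
    rectangle before inversion; each resulting cluster is iteratively eroded
    with an 8x8 ellipse until its area drops below ``size_threshold`` px^2,
    and pieces smaller than ``min_cluster_size`` px^2 are discarded as
    artefacts.
    """

    size_threshold: int = 5000
    min_cluster_size: int = 500
    closing_size: int = 11
    dilation_size: int = 3
    dilation_iterations: int = 2
    erosion_kernel_size: int = 8

    def __post_init__(self) -> None:
        if not self.size_threshold > self.min_cluster_size > 0:
            raise ValidationError(
                "require size_threshold > min_cluster_size > 0, got "
                f"{self.size_threshold} / {self.min_cluster_size}"
            )
        for k in (self.closing_size, self.dilation_size, self.erosion_kernel_size):
            if k < 1:
                raise ValidationError("kernel sizes must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Aggregated configuration of a full pipeline run."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    separation: SeparationConfig = field(default_factory=SeparationConfig)
    gac: GACConfig = field(default_factory=GACConfig)
    ridge: RidgeConfig = field(default_factory=RidgeConfig)
    erosion: ErosionConfig = field(default_factory=ErosionConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            preprocess=PreprocessConfig(**d.get("preprocess", {})),
            features=FeatureConfig(
                **{
                    k: tuple(v) if isinstance(v, (list, tuple)) else v
                    for k, v in d.get("features", {}).items()
                }
            ),
            separation=SeparationConfig(**d.get("separation", {})),
            gac=GACConfig(**d.get("gac", {})),
            ridge=RidgeConfig(**d.get("ridge", {})),
            erosion=ErosionConfig(**d.get("erosion", {})),
            seed=int(d.get("seed", 0)),
        )
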