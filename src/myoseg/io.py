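"""Image and table input/output plus intensity preprocessing.

The canonical in-memory image is an 8-bit grayscale ``numpy`` array
(row, col), origin top-left.  Colour inputs are converted with the Rec. 601
luminance weights; higher bit depths are rescaled linearly to [0, 255].
Label images round-trip as 16-bit single-channel PNG/TIFF.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import imageio.v3 as iio
import numpy as np

from .config import PreprocessConfig, ValidationError

PathLike = Union[str, Path]

#: Rec. 601 luminance weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

FIBRE_TABLE_HEADER = (
    "fibre_id",
    "area",
    "feret",
    "centroid_row",
    "centroid_col",
    "perimeter",
)


def _validate_image(img: np.ndarray) -> np.ndarray:
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValidationError(f"expected a nonempty 2-D image, got shape {img.shape}")
    return img


def load_grayscale(path: PathLike) -> np.ndarray:
    """Load a PNG/TIFF as canonical 8-bit grayscale.

    3-channel inputs are converted to luminance; single-channel inputs of
    higher bit depth are rescaled linearly so the dtype maximum maps to 255.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.size == 0:
        raise ValidationError(f"zero-sized image: {path}")
    if raw.ndim == 3:
        if raw.shape[2] == 4:  # drop alpha
            raw = raw[:, :, :3]
        if raw.shape[2] != 3:
            raise ValidationError(
                f"unsupported channel count {raw.shape[2]} in {path}"
            )
        raw = raw.astype(np.float64) @ _LUMA
        if raw.max() > 255:  # 16-bit RGB
            raw = raw * (255.0 / 65535.0)
        return _validate_image(np.clip(np.round(raw), 0, 255).astype(np.uint8))
    if raw.ndim != 2:
        raise ValidationError(f"unsupported image dimensionality {raw.ndim} in {path}")
    if raw.dtype == np.uint8:
        return _validate_image(raw.copy())
    if np.issubdtype(raw.dtype, np.integer):
        info = np.iinfo(raw.dtype)
        scaled = raw.astype(np.float64) * (255.0 / max(info.max, 1))
        return _validate_image(np.clip(np.round(scaled), 0, 255).astype(np.uint8))
    # float input: assume [0, 1]
    return _validate_image(
        np.clip(np.round(raw.astype(np.float64) * 255.0), 0, 255).astype(np.uint8)
    )


def write_grayscale(path: PathLike, image: np.ndarray) -> None:
    """Write an 8-bit grayscale image as PNG/TIFF."""
    img = np.asarray(image)
    _validate_image(img)
    iio.imwrite(Path(path), img.astype(np.uint8))


def apply_intensity_threshold(
    image: np.ndarray, cfg: PreprocessConfig
) -> np.ndarray:
    """Zero out pixels below the manual intensity threshold.

    Output pixel equals the input where input >= tau_intensity, else 0;
    zero-valued regions are excluded from subsequent cell detection.
    Idempotent, and monotone in the threshold.
    """
    img = _validate_image(np.asarray(image))
    out = img.copy()
    out[img < cfg.tau_intensity] = 0
    return out


def read_label_image(path: PathLike) -> np.ndarray:
    """Read a 16-bit single-channel label image (0 = background)."""
    path = Path(path)
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read label image {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.ndim != 2:
        raise ValidationError(f"label image must be single-channel: {path}")
    return raw.astype(np.int32)


def write_label_image(path: PathLike, labels: np.ndarray) -> None:
    """Write a label image as 16-bit PNG/TIFF; round-trip is bit-exact."""
    lab = np.asarray(labels)
    _validate_image(lab)
    if lab.min() < 0:
        raise ValidationError("labels must be nonnegative")
    if lab.max() > 65535:
        raise ValidationError(
            f"label {int(lab.max())} exceeds the 16-bit limit 65535"
        )
    iio.imwrite(Path(path), lab.astype(np.uint16))


def write_fibre_table(rows: Iterable[Mapping], path: PathLike) -> None:
    """Write per-fibre measurements as CSV, sorted by fibre_id.

    Each row must provide the keys of :data:`FIBRE_TABLE_HEADER` (objects with
    those attributes are accepted too).
    """
    records = []
    for row in rows:
        if isinstance(row, Mapping):
            rec = {k: row[k] for k in FIBRE_TABLE_HEADER}
        else:
            rec = {k: getattr(row, k) for k in FIBRE_TABLE_HEADER}
        records.append(rec)
    records.sort(key=lambda r: int(r["fibre_id"]))
    path = Path(path)
    try:
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=FIBRE_TABLE_HEADER)
            writer.writeheader()
            writer.writerows(records)
    except OSError as exc:
        raise IOError(f"cannot write fibre table {path}: {exc}") from exc


def read_fibre_table(path: PathLike) -> Sequence[dict]:
    """Read a fibre measurement CSV back as a list of dicts."""
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        out = []
        for row in reader:
            out.append(
                {
                    "fibre_id": int(row["fibre_id"]),
                    "area": float(row["area"]),
                    "feret": float(row["feret"]),
                    "centroid_row": float(row["centroid_row"]),
                    "centroid_col": float(row["centroid_col"]),
                    "perimeter": float(row["perimeter"]),
                }
            )
    return out
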