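"""Image loading and result output.

Images are represented throughout the package as plain 2-D ``numpy.uint8``
arrays (row-major, origin at the top-left; ``x`` is the column index and
``y`` the row index).  All inputs are normalised to that representation on
load: multi-channel images are collapsed with the standard luminance weights
and 16-bit images are rescaled onto [0, 255] with a fixed divisor so that
absolute intensity thresholds keep their meaning across bit depths.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import imageio.v3 as iio
import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import CountResult

#: Rec. 601 luminance weights for RGB -> grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])

IMAGE_EXTENSIONS = (".tif", ".tiff", ".png", ".jpg", ".jpeg")


def load_grayscale(path: str | Path) -> np.ndarray:
    """Load a TIFF/PNG/JPEG image as an 8-bit grayscale array.

    RGB(A) inputs are converted with 0.299/0.587/0.114 luminance weights
    (alpha ignored); 16-bit inputs are divided by 257 so that 65535 maps to
    255.  8-bit single-channel input is returned byte-identical.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio raises format-specific errors
        raise OSError(f"could not read image {path}") from exc
    raw = np.asarray(raw)
    if raw.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if raw.ndim == 3:
        if raw.shape[2] == 1:
            raw = raw[:, :, 0]
        else:
            raw = raw[:, :, :3] @ _LUMA  # drops alpha if present
    elif raw.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {raw.ndim}: {path}")
    if raw.dtype == np.uint16:
        # Fixed 257 divisor (65535/255), not min-max: keeps user thresholds
        # absolute rather than per-image.
        raw = raw / 257.0
    elif raw.dtype not in (np.uint8, np.float64):
        raw = raw.astype(np.float64)
    return np.clip(np.rint(raw), 0, 255).astype(np.uint8)


def mean_pixel_intensity(img: np.ndarray) -> float:
    """Arithmetic mean of all pixel intensities (the image's MPI)."""
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty image has no mean intensity")
    return float(img.mean(dtype=np.float64))


RESULT_COLUMNS = ("image_id", "total_count", "circular_count", "overlap_contour_count")
CONTOUR_COLUMNS = (
    "image_id",
    "contour_id",
    "centroid_x",
    "centroid_y",
    "area",
    "circularity",
    "is_circular",
    "cell_count",
)


def write_results(
    results: Iterable["CountResult"],
    out: str | Path,
    per_contour_out: str | Path | None = None,
) -> None:
    """Write one CSV row per image; optionally a per-contour CSV as well."""
    results = list(results)
    with open(out, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for r in results:
            writer.writerow(
                [r.image_id, r.total_count, r.circular_count, r.overlap_contour_count]
            )
    if per_contour_out is not None:
        with open(per_contour_out, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(CONTOUR_COLUMNS)
            for r in results:
                for i, c in enumerate(r.per_contour):
                    writer.writerow(
                        [
                            r.image_id,
                            i,
                            f"{c.centroid[0]:.3f}",
                            f"{c.centroid[1]:.3f}",
                            f"{c.area:.1f}",
                            f"{c.circularity:.4f}",
                            c.is_circular,
                            c.cell_count,
                        ]
                    )


def read_results(path: str | Path) -> list[dict]:
    """Parse a results CSV written by :func:`write_results`."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    for row in rows:
        for key in RESULT_COLUMNS[1:]:
            row[key] = int(row[key])
    return rows


def draw_overlay(img: np.ndarray, result: "CountResult") -> np.ndarray:
    """Render detected contours over the grayscale image.

    Returns an RGB uint8 array with circular contours traced in green and
    overlap (multi-cell) contours in red.
    """
    rgb = np.stack([img] * 3, axis=-1).astype(np.uint8)
    for c in result.per_contour:
        color = (0, 200, 0) if c.is_circular else (220, 0, 0)
        pts = np.rint(c.boundary).astype(int)
        xs = np.clip(pts[:, 0], 0, img.shape[1] - 1)
        ys = np.clip(pts[:, 1], 0, img.shape[0] - 1)
        rgb[ys, xs] = color
    return rgb


def save_overlay(img: np.ndarray, result: "CountResult", out: str | Path) -> None:
    iio.imwrite(Path(out), draw_overlay(img, result))
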