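"""End-to-end counting pipeline and parameter sweeps.

``count_cells`` chains the four processing steps — binarize, adaptive
morphological filtering, contour extraction with size/circularity selection,
and overlap counting — into a single call; ``run_batch`` applies it over an
image folder.  ``resize_sweep`` and ``threshold_sweep`` reproduce the
robustness analyses: counting under image rescaling and under thresholds set
relative to each image's mean pixel intensity.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as sk_resize

from . import io as scc_io
from .config import SCCConfig
from .metrics import abs_error
from .overlap import OverlapModel, count_in_contour, count_in_contour_fallback, make_patch
from .segmentation import binarize, iteration_count, morphological_filter
from .shapes import ContourRecord, area_filter, classify_circularity, extract_contours

logger = logging.getLogger(__name__)


@dataclass
class CountResult:
    """Cell counts for one image.

    ``total_count`` is the number of circular contours (one cell each) plus
    the classifier's cell counts over the non-circular contours;
    ``overlap_contour_count`` is how many contours were routed to the
    classifier.
    """

    image_id: str
    total_count: int
    circular_count: int
    overlap_contour_count: int
    per_contour: list[ContourRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap_total = sum(
            c.cell_count for c in self.per_contour if not c.is_circular
        )
        if self.total_count != self.circular_count + overlap_total:
            raise ValueError(
                "count conservation violated: total != circular + overlap cells"
            )


def count_cells(
    img: np.ndarray,
    config: SCCConfig | None = None,
    model: OverlapModel | None = None,
    image_id: str = "",
) -> CountResult:
    """Run the full counting pipeline on one grayscale image.

    When ``model`` is None the deterministic area-based fallback counts the
    non-circular contours (logged as a warning once per call).
    """
    config = config or SCCConfig()
    img = np.asarray(img)
    mpi = scc_io.mean_pixel_intensity(img)
    if mpi <= 0 or mpi >= 255:
        warnings.warn(
            f"degenerate image (mean intensity {mpi:.1f}); returning zero count",
            stacklevel=2,
        )
        return CountResult(image_id, 0, 0, 0, [])

    mask = binarize(img, config.threshold, config.polarity)
    iters = iteration_count(config.threshold, mpi, config.schedule)
    filtered = morphological_filter(mask, iters)
    contours = extract_contours(filtered)
    retained = area_filter(contours, config.min_radius)
    circular, non_circular = classify_circularity(retained, config.circularity_cutoff)

    if non_circular and model is None:
        logger.warning(
            "%s: no overlap model; using area-based fallback for %d contours",
            image_id or "<image>",
            len(non_circular),
        )
    overlap_cells = 0
    for idx, contour in enumerate(non_circular):
        if model is not None:
            patch = make_patch(contour, contour_id=f"{image_id}:{idx}")
            contour.cell_count = count_in_contour(model, patch)
        else:
            contour.cell_count = count_in_contour_fallback(contour, config.min_radius)
        overlap_cells += contour.cell_count

    result = CountResult(
        image_id=image_id,
        total_count=len(circular) + overlap_cells,
        circular_count=len(circular),
        overlap_contour_count=len(non_circular),
        per_contour=circular + non_circular,
    )
    logger.info(
        "%s: %d contours, %d after size filter, %d routed to classifier, total %d",
        image_id or "<image>",
        len(contours),
        len(retained),
        len(non_circular),
        result.total_count,
    )
    return result


def list_images(folder: str | Path) -> list[Path]:
    folder = Path(folder)
    paths = sorted(
        p for p in folder.iterdir() if p.suffix.lower() in scc_io.IMAGE_EXTENSIONS
    )
    return paths


def run_batch(
    folder: str | Path,
    config: SCCConfig | None = None,
    model: OverlapModel | None = None,
) -> list[CountResult]:
    """Count cells in every image of a folder, in sorted filename order.

    Unreadable images are logged and skipped; the batch continues.
    """
    paths = list_images(folder)
    if not paths:
        raise ValueError(f"no readable images in {folder}")
    results = []
    for path in paths:
        try:
            img = scc_io.load_grayscale(path)
        except (OSError, ValueError) as exc:
            logger.error("skipping %s: %s", path.name, exc)
            continue
        results.append(count_cells(img, config, model, image_id=path.name))
    return results


DEFAULT_RESIZE_FACTORS = (0.5, 1, 2, 4, 6, 8, 10)
DEFAULT_THRESHOLD_FACTORS = (0.7, 0.75, 0.8, 0.85)


def _resize_image(img: np.ndarray, factor: float) -> np.ndarray:
    """New size = original size / factor (factor 0.5 therefore enlarges)."""
    h, w = img.shape
    new_shape = (max(1, round(h / factor)), max(1, round(w / factor)))
    if new_shape == img.shape:
        return img
    # area-averaging (anti-aliased) when shrinking, bilinear when enlarging
    out = sk_resize(
        img.astype(float), new_shape, order=1, anti_aliasing=factor > 1
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def resize_sweep(
    folder: str | Path,
    config: SCCConfig | None = None,
    factors: tuple[float, ...] = DEFAULT_RESIZE_FACTORS,
    model: OverlapModel | None = None,
) -> pd.DataFrame:
    """Count each image over a range of resize factors.

    The minimum-radius criterion is scaled by 1/factor along with the image
    so counts stay comparable across sizes (recorded in the output).  Images
    that would shrink below 8 px on a side are skipped with a warning.
    Elapsed wall-clock time per row is informational only.
    """
    config = config or SCCConfig()
    if any(f <= 0 for f in factors):
        raise ValueError("resize factors must be positive")
    paths = list_images(folder)
    if not paths:
        raise ValueError(f"no readable images in {folder}")
    rows = []
    for factor in factors:
        scaled_config = config.with_(min_radius=config.min_radius / factor)
        for path in paths:
            img = scc_io.load_grayscale(path)
            h, w = img.shape
            new_shape = (max(1, round(h / factor)), max(1, round(w / factor)))
            if min(new_shape) < 8:
                logger.warning(
                    "skipping %s at factor %g: resized image %s too small",
                    path.name,
                    factor,
                    new_shape,
                )
                continue
            t0 = time.perf_counter()
            resized = _resize_image(img, factor)
            result = count_cells(resized, scaled_config, model, image_id=path.name)
            elapsed = time.perf_counter() - t0
            rows.append(
                {
                    "factor": factor,
                    "image_id": path.name,
                    "height": new_shape[0],
                    "width": new_shape[1],
                    "min_radius": scaled_config.min_radius,
                    "total_count": result.total_count,
                    "elapsed_s": elapsed,
                }
            )
    return pd.DataFrame(rows)


def threshold_sweep(
    folder: str | Path,
    config: SCCConfig | None = None,
    factors: tuple[float, ...] = DEFAULT_THRESHOLD_FACTORS,
    reference: list[int] | None = None,
    model: OverlapModel | None = None,
) -> pd.DataFrame:
    """Count with per-image thresholds set to factor x mean pixel intensity.

    When a reference count series (aligned to the sorted image order) is
    given, the mean absolute error per factor is included.
    """
    config = config or SCCConfig()
    if any(f <= 0 for f in factors):
        raise ValueError("threshold factors must be positive")
    paths = list_images(folder)
    if not paths:
        raise ValueError(f"no readable images in {folder}")
    if reference is not None and len(reference) != len(paths):
        raise ValueError("reference series not aligned with folder contents")
    rows = []
    for factor in factors:
        counts = []
        for path in paths:
            img = scc_io.load_grayscale(path)
            threshold = min(255.0, factor * scc_io.mean_pixel_intensity(img))
            cfg = config.with_(threshold=threshold)
            counts.append(count_cells(img, cfg, model, image_id=path.name).total_count)
        row = {"factor": factor, "mean_count": float(np.mean(counts))}
        if reference is not None:
            row["mean_abs_error"] = abs_error(reference, counts).mean_abs_error
        rows.append(row)
    return pd.DataFrame(rows)
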