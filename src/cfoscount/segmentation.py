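"""Global thresholding and adaptive morphological noise filtering.

The pipeline's first two processing steps: binarize the grayscale image
against a single global threshold, then clean the mask with a morphological
opening whose strength adapts to how close the threshold sits to the image's
mean pixel intensity (MPI).  Near the MPI, thresholding admits exponentially
more speckle, so the opening runs for more iterations.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import IterationSchedule, Polarity

#: 3x3 square structuring element (8-connected), the package-wide default.
STRUCTURING_ELEMENT = np.ones((3, 3), dtype=bool)


def binarize(img: np.ndarray, threshold: float, polarity: Polarity = "dark_on_light") -> np.ndarray:
    """Threshold a grayscale image into a boolean foreground mask.

    ``dark_on_light`` marks pixels strictly below the threshold as foreground
    (dark-stained cells on a bright background); ``light_on_dark`` inverts the
    comparison for fluorescent-style images.  Pixels exactly at the threshold
    are always background.
    """
    img = np.asarray(img)
    if polarity == "dark_on_light":
        return img < threshold
    if polarity == "light_on_dark":
        return img > threshold
    raise ValueError(f"unknown polarity {polarity!r}")


def iteration_count(
    threshold: float, mpi: float, schedule: IterationSchedule | None = None
) -> int:
    """Number of opening iterations for a threshold / MPI ratio.

    Monotone non-decreasing in the ratio by construction of the schedule.
    """
    if mpi <= 0:
        raise ValueError("mean pixel intensity must be positive (degenerate image)")
    if schedule is None:
        schedule = IterationSchedule()
    return schedule.iterations_for(threshold / mpi)


def morphological_filter(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Morphological opening of the foreground: erode then dilate.

    Each step runs ``iterations`` times with the 3x3 structuring element.
    Speckles smaller than the (iterated) element vanish during erosion and are
    never recovered, while larger objects regain approximately their original
    extent on dilation.  Pixels beyond the image border count as background.
    """
    mask = np.asarray(mask, dtype=bool)
    if iterations < 1:
        raise ValueError("iterations must be a positive integer")
    eroded = ndimage.binary_erosion(
        mask, structure=STRUCTURING_ELEMENT, iterations=iterations, border_value=0
    )
    return ndimage.binary_dilation(
        eroded, structure=STRUCTURING_ELEMENT, iterations=iterations, border_value=0
    )
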