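"""Accuracy metrics for comparing count series against a reference.

Implements the error analysis used to validate automated counts against a
manual or ground-truth reference: per-image absolute error, false
positives/negatives via centroid matching, and ordinary least-squares
regression of one count series on another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ErrorReport:
    """Per-image absolute errors |reference - method| and their mean."""

    image_ids: tuple[str, ...]
    reference_counts: tuple[int, ...]
    method_counts: tuple[int, ...]
    abs_errors: tuple[int, ...]
    mean_abs_error: float


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    p_value: float
    n: int


def abs_error(
    reference: Sequence[int],
    method: Sequence[int],
    image_ids: Sequence[str] | None = None,
) -> ErrorReport:
    """ABS(reference - method) per image, plus the mean across images."""
    if len(reference) != len(method):
        raise ValueError(
            f"count series are not aligned: {len(reference)} vs {len(method)}"
        )
    if image_ids is None:
        image_ids = [str(i) for i in range(len(reference))]
    errors = [abs(int(r) - int(m)) for r, m in zip(reference, method)]
    return ErrorReport(
        image_ids=tuple(image_ids),
        reference_counts=tuple(int(r) for r in reference),
        method_counts=tuple(int(m) for m in method),
        abs_errors=tuple(errors),
        mean_abs_error=float(np.mean(errors)) if errors else 0.0,
    )


def match_detections(
    reference: Sequence[tuple[float, float]],
    detected: Sequence[tuple[float, float]],
    tol: float,
) -> tuple[list[tuple[int, int]], int, int]:
    """Greedy one-to-one matching of detected centroids to reference cells.

    Candidate pairs within ``tol`` pixels are taken closest-first (ties
    broken lexicographically on the coordinates, so the result does not
    depend on input order).  Unmatched detections are false positives,
    unmatched reference cells false negatives.

    Returns ``(matched index pairs, false_positives, false_negatives)``.
    """
    if tol <= 0:
        raise ValueError("matching tolerance must be positive")
    ref = np.asarray(reference, dtype=float).reshape(-1, 2)
    det = np.asarray(detected, dtype=float).reshape(-1, 2)
    candidates = []
    for i, (rx, ry) in enumerate(ref):
        for j, (dx, dy) in enumerate(det):
            dist = float(np.hypot(rx - dx, ry - dy))
            if dist <= tol:
                candidates.append((dist, rx, ry, dx, dy, i, j))
    candidates.sort()
    ref_used = np.zeros(len(ref), dtype=bool)
    det_used = np.zeros(len(det), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for _, _, _, _, _, i, j in candidates:
        if not ref_used[i] and not det_used[j]:
            ref_used[i] = det_used[j] = True
            pairs.append((i, j))
    false_positives = int((~det_used).sum())
    false_negatives = int((~ref_used).sum())
    return pairs, false_positives, false_negatives


def fit_counts_regression(
    reference: Sequence[float], method: Sequence[float]
) -> RegressionFit:
    """OLS of method counts (y) on reference counts (x).

    The p-value is the standard two-sided t-test of slope != 0.
    """
    x = np.asarray(reference, dtype=float)
    y = np.asarray(method, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count series are not aligned")
    if x.size < 3:
        raise ValueError("need at least 3 points for a regression fit")
    if np.ptp(x) == 0:
        raise ValueError("reference counts have zero variance: degenerate fit")
    fit = stats.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )
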