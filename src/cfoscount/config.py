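"""Run configuration for the counting pipeline.

All user-tunable parameters live in :class:`SCCConfig`.  Defaults follow the
values used throughout the original experiments: intensity threshold 115,
minimum cell radius 10 px, circularity cutoff 0.7, dark cells on a light
background.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

Polarity = Literal["dark_on_light", "light_on_dark"]

#: Upper bound on the circularity cutoff: a perfect disk scores
#: -log10(1/(2*pi)) ~= 0.798, so cutoffs at or above that value would reject
#: every rasterized shape.
MAX_CIRCULARITY = -math.log10(1.0 / (2.0 * math.pi))


@dataclass(frozen=True)
class IterationSchedule:
    """Maps the threshold-to-MPI ratio to a morphological iteration count.

    As the binarization threshold approaches the image's mean pixel intensity
    (MPI), thresholding admits exponentially more noise speckles, so the
    opening filter must run for more iterations.  ``breakpoints`` is an
    ordered list of ``(ratio_upper_bound, iterations)`` pairs; a ratio is
    assigned the iterations of the first breakpoint whose bound exceeds it.
    The final bound may be ``inf``.
    """

    breakpoints: tuple[tuple[float, int], ...] = (
        (0.70, 1),
        (0.80, 2),
        (0.90, 3),
        (math.inf, 4),
    )

    def __post_init__(self) -> None:
        bounds = [b for b, _ in self.breakpoints]
        iters = [i for _, i in self.breakpoints]
        if not self.breakpoints:
            raise ValueError("schedule needs at least one breakpoint")
        if bounds != sorted(bounds):
            raise ValueError("breakpoint bounds must be increasing")
        if iters != sorted(iters):
            raise ValueError("iterations must be non-decreasing with ratio")
        if any(i < 1 for i in iters):
            raise ValueError("iterations must be positive")
        if not math.isinf(bounds[-1]):
            raise ValueError("last breakpoint bound must be inf")

    def iterations_for(self, ratio: float) -> int:
        for bound, iters in self.breakpoints:
            if ratio < bound:
                return iters
        return self.breakpoints[-1][1]  # pragma: no cover - last bound is inf


@dataclass(frozen=True)
class SCCConfig:
    """All user parameters of the counting pipeline.

    Parameters
    ----------
    threshold : float
        Global intensity cutoff in [0, 255].  With ``dark_on_light`` polarity,
        pixels strictly below the threshold are foreground.
    min_radius : float
        Minimum cell radius in pixels; contours with pixel area below
        ``pi * min_radius**2`` are discarded.
    circularity_cutoff : float
        Contours whose log-adjusted first Hu moment is at or above this value
        are counted as single cells; the rest are routed to the overlap
        classifier.
    polarity : {"dark_on_light", "light_on_dark"}
        Whether stained cells are darker (brightfield) or brighter
        (fluorescence) than the background.
    schedule : IterationSchedule
        Morphological iteration schedule, see :class:`IterationSchedule`.
    """

    threshold: float = 115
    min_radius: float = 10.0
    circularity_cutoff: float = 0.7
    polarity: Polarity = "dark_on_light"
    schedule: IterationSchedule = field(default_factory=IterationSchedule)

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValueError(f"threshold must be in [0, 255], got {self.threshold}")
        if self.min_radius <= 0:
            raise ValueError("min_radius must be positive")
        if not 0 < self.circularity_cutoff < MAX_CIRCULARITY:
            raise ValueError(
                f"circularity_cutoff must be in (0, {MAX_CIRCULARITY:.3f})"
            )
        if self.polarity not in ("dark_on_light", "light_on_dark"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def min_area(self) -> float:
        """Area cutoff implied by ``min_radius`` (pi * r**2, in pixels)."""
        return math.pi * self.min_radius**2

    def with_(self, **changes) -> "SCCConfig":
        return replace(self, **changes)


def load_config(path: str | Path) -> SCCConfig:
    """Read an :class:`SCCConfig` from a TOML file.

    Recognised keys: ``threshold``, ``min_radius``, ``circularity_cutoff``,
    ``polarity`` and an optional ``schedule`` array of ``[bound, iterations]``
    pairs (the string ``"inf"`` is accepted as the last bound).
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    kwargs: dict = {}
    for key in ("threshold", "min_radius", "circularity_cutoff", "polarity"):
        if key in raw:
            kwargs[key] = raw[key]
    if "schedule" in raw:
        pairs = []
        for bound, iters in raw["schedule"]:
            pairs.append((math.inf if bound == "inf" else float(bound), int(iters)))
        kwargs["schedule"] = IterationSchedule(tuple(pairs))
    return SCCConfig(**kwargs)
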