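"""Fabricated cFos-like images and labelled overlap patches.

Two generators with exact ground truth:

* :func:`fabricate_cfos_image` draws a random number of anti-aliased filled
  circles (5-100 by default) of varying intensity and size on a noisy gray
  background resembling tissue background staining.  Each circle is recorded
  with its centre, radius and intensity, and the ground-truth count is the
  number of circles that meet the detection criteria (dark enough for the
  threshold, large enough for the size filter).  A small fraction of
  qualifying circles is placed as fused pairs so the overlap classifier is
  exercised end to end.

* :func:`make_overlap_patch` renders k fused disks (k in 1..4) as a
  binarized chain and normalises it exactly like a pipeline contour patch;
  these are the classifier's training data.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import SCCConfig
from .overlap import patchify

# --------------------------------------------------------------------------
# specification of the fabricated world
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the fabricated-image world.

    Defaults place 5-100 circles with radii 8-15 px (bracketing the default
    10 px minimum so the size filter is exercised) and intensities drawn from
    a dark, qualifying band (60-110) or a pale, non-qualifying band (125-175)
    on a gray background of 180 +- 6, which stays comfortably above the
    default threshold of 115.

    ``radius_guard`` excludes a small band around the minimum-radius
    criterion when sampling radii: a rasterized disk within roughly half a
    pixel of the area cutoff is ambiguous by discretisation alone, so the
    generator does not claim ground truth there.
    """

    n_circles: tuple[int, int] = (5, 100)
    radius_range: tuple[float, float] = (8.0, 15.0)
    qualifying_intensity: tuple[float, float] = (60.0, 110.0)
    nonqualifying_intensity: tuple[float, float] = (125.0, 175.0)
    qualifying_fraction: float = 0.7
    background_level: float = 180.0
    background_noise_sd: float = 6.0
    image_size: tuple[int, int] = (640, 640)
    overlap_probability: float = 0.15
    #: fused-pair centre distance as a multiple of the mean member radius;
    #: below ~1.6 the union still scores above the 0.7 circularity cutoff
    #: and would (correctly, per the scoring rule) be counted as one cell.
    cluster_spacing: tuple[float, float] = (1.65, 1.9)
    #: minimum clearance in pixels between distinct objects
    min_separation: float = 4.0
    #: (below, above) exclusion margins around the minimum radius
    radius_guard: tuple[float, float] = (0.7, 1.2)

    def __post_init__(self) -> None:
        lo, hi = self.n_circles
        if not (1 <= lo <= hi):
            raise ValueError("n_circles bounds must satisfy 1 <= lo <= hi")
        if not 0 <= self.qualifying_fraction <= 1:
            raise ValueError("qualifying_fraction must be in [0, 1]")
        if self.cluster_spacing[1] >= 2.0:
            raise ValueError("cluster spacing >= 2 mean radii would split the pair")


@dataclass(frozen=True)
class Circle:
    x: float
    y: float
    radius: float
    intensity: float
    cluster_id: int | None = None  # circles sharing an id are fused


@dataclass
class GroundTruth:
    """Exact annotation of a fabricated image."""

    circles: list[Circle]
    gt_count: int = field(default=0)

    def recount(self, config: SCCConfig) -> int:
        """Number of circles meeting the threshold and size criteria."""
        return sum(1 for c in self.circles if _qualifies(c, config))

    @property
    def centers(self) -> np.ndarray:
        return np.array([(c.x, c.y) for c in self.circles], dtype=float).reshape(-1, 2)


def _qualifies(circle: Circle, config: SCCConfig) -> bool:
    if config.polarity == "dark_on_light":
        dark_enough = circle.intensity < config.threshold
    else:
        dark_enough = circle.intensity > config.threshold
    return dark_enough and circle.radius >= config.min_radius


# --------------------------------------------------------------------------
# fabricated full images
# --------------------------------------------------------------------------


def _sample_radius(
    rng: np.random.Generator, spec: SyntheticSpec, config: SCCConfig, qualifying: bool | None
) -> float:
    """Radius from the allowed range, avoiding the guard band at the cutoff."""
    rmin, rmax = spec.radius_range
    lo_band = (rmin, min(rmax, config.min_radius - spec.radius_guard[0]))
    hi_band = (max(rmin, config.min_radius + spec.radius_guard[1]), rmax)
    bands = []
    if qualifying in (True, None) and hi_band[1] >= hi_band[0]:
        bands.append(hi_band)
    if qualifying in (False, None) and lo_band[1] >= lo_band[0]:
        bands.append(lo_band)
    if not bands:
        raise ValueError("radius_range leaves no admissible radii for this config")
    widths = np.array([b - a for a, b in bands])
    if widths.sum() > 0:
        a, b = bands[rng.choice(len(bands), p=widths / widths.sum())]
    else:  # degenerate (fixed-radius) spec
        a, b = bands[int(rng.integers(len(bands)))]
    return float(rng.uniform(a, b))


def _place(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    placed: list[Circle],
    radius: float,
    partner: Circle | None = None,
    max_tries: int = 2000,
) -> tuple[float, float]:
    h, w = spec.image_size
    margin = radius + 3.0
    for _ in range(max_tries):
        if partner is None:
            x = rng.uniform(margin, w - margin)
            y = rng.uniform(margin, h - margin)
        else:
            u = rng.uniform(*spec.cluster_spacing)
            d = u * (partner.radius + radius) / 2.0
            ang = rng.uniform(0, 2 * math.pi)
            x = partner.x + d * math.cos(ang)
            y = partner.y + d * math.sin(ang)
            if not (margin <= x <= w - margin and margin <= y <= h - margin):
                continue
        ok = True
        for other in placed:
            if partner is not None and other is partner:
                continue
            gap = math.hypot(x - other.x, y - other.y) - radius - other.radius
            if gap < spec.min_separation:
                ok = False
                break
        if ok:
            return x, y
    raise ValueError(
        f"could not place a circle of radius {radius:.1f}: image "
        f"{spec.image_size} too crowded for the requested count"
    )


def _render_circle(img: np.ndarray, circle: Circle) -> None:
    """Alpha-blend one anti-aliased filled circle into the float image."""
    h, w = img.shape
    r = circle.radius
    x0 = max(0, int(circle.x - r - 2))
    x1 = min(w, int(circle.x + r + 3))
    y0 = max(0, int(circle.y - r - 2))
    y1 = min(h, int(circle.y + r + 3))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - circle.x, yy - circle.y)
    alpha = np.clip(r + 0.5 - dist, 0.0, 1.0)
    patch = img[y0:y1, x0:x1]
    img[y0:y1, x0:x1] = patch * (1 - alpha) + circle.intensity * alpha


def fabricate_cfos_image(
    spec: SyntheticSpec | None = None,
    config: SCCConfig | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Generate one fabricated image and its exact ground truth.

    Fully determined by ``seed`` (or an explicit ``rng``).  Raises
    ``ValueError`` if the image is too small to place the drawn number of
    circles at the required separations.
    """
    spec = spec or SyntheticSpec()
    config = config or SCCConfig()
    if rng is None:
        rng = np.random.default_rng(seed)

    n = int(rng.integers(spec.n_circles[0], spec.n_circles[1] + 1))
    circles: list[Circle] = []
    cluster_id = 0
    while len(circles) < n:
        remaining = n - len(circles)
        if remaining >= 2 and rng.random() < spec.overlap_probability:
            # fused pair: both members qualify so the cluster's true count
            # is recoverable by the overlap classifier
            r1 = _sample_radius(rng, spec, config, qualifying=True)
            r2 = _sample_radius(rng, spec, config, qualifying=True)
            i1 = rng.uniform(*spec.qualifying_intensity)
            i2 = rng.uniform(*spec.qualifying_intensity)
            x1, y1 = _place(rng, spec, circles, r1)
            first = Circle(x1, y1, r1, i1, cluster_id)
            circles.append(first)
            x2, y2 = _place(rng, spec, circles, r2, partner=first)
            circles.append(Circle(x2, y2, r2, i2, cluster_id))
            cluster_id += 1
        else:
            qualifying_intensity = rng.random() < spec.qualifying_fraction
            radius = _sample_radius(rng, spec, config, qualifying=None)
            band = (
                spec.qualifying_intensity
                if qualifying_intensity
                else spec.nonqualifying_intensity
            )
            intensity = rng.uniform(*band)
            x, y = _place(rng, spec, circles, radius)
            circles.append(Circle(x, y, radius, intensity))

    img = np.full(spec.image_size, spec.background_level, dtype=float)
    if spec.background_noise_sd > 0:
        img += rng.normal(0.0, spec.background_noise_sd, size=spec.image_size)
    for circle in circles:
        _render_circle(img, circle)
    img8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    gt = GroundTruth(circles=circles)
    gt.gt_count = gt.recount(config)
    return img8, gt


def fabricate_dataset(
    n_images: int,
    seed: int,
    spec: SyntheticSpec | None = None,
    config: SCCConfig | None = None,
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Generate a reproducible batch of fabricated images."""
    rng = np.random.default_rng(seed)
    return [fabricate_cfos_image(spec, config, rng=rng) for _ in range(n_images)]


def write_ground_truth(
    truths: list[GroundTruth], image_ids: list[str], out: str | Path
) -> None:
    with open(out, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "x", "y", "radius", "intensity", "cluster_id", "gt_count"])
        for image_id, gt in zip(image_ids, truths):
            for c in gt.circles:
                writer.writerow(
                    [
                        image_id,
                        f"{c.x:.2f}",
                        f"{c.y:.2f}",
                        f"{c.radius:.2f}",
                        f"{c.intensity:.1f}",
                        "" if c.cluster_id is None else c.cluster_id,
                        gt.gt_count,
                    ]
                )


# --------------------------------------------------------------------------
# overlap training patches
# --------------------------------------------------------------------------

#: Base disk radius for training patches (px, before the patch resize).
PATCH_BASE_RADIUS = 20.0
#: Per-disk radius jitter (fractional).
PATCH_RADIUS_JITTER = 0.3
#: Consecutive centre distances as multiples of the mean pair radius;
#: upper bound < 2 keeps the chain a single connected component.
PATCH_SPACING = (1.4, 1.9)
#: Maximum heading change between consecutive chain steps (radians).  Kinked
#: chains stay elongated; compact (triangle/square) clusters would score as
#: circular and never reach the classifier.
PATCH_MAX_TURN = math.radians(45)


def make_overlap_patch(
    k: int, seed: int | None = None, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, int]:
    """Render k fused disks as a normalised 64x64 binary patch.

    Disks are arranged as a jittered chain so that for k >= 2 the union is a
    single connected, clearly non-circular component.  Returns
    ``(patch, k)``.
    """
    if k not in (1, 2, 3, 4):
        raise ValueError(f"k must be in 1..4, got {k}")
    if rng is None:
        rng = np.random.default_rng(seed)
    radii = PATCH_BASE_RADIUS * (
        1.0 + rng.uniform(-PATCH_RADIUS_JITTER, PATCH_RADIUS_JITTER, size=k)
    )
    centers = [np.zeros(2)]
    heading = rng.uniform(0, 2 * math.pi)
    for i in range(1, k):
        heading += rng.uniform(-PATCH_MAX_TURN, PATCH_MAX_TURN)
        d = rng.uniform(*PATCH_SPACING) * (radii[i - 1] + radii[i]) / 2.0
        centers.append(centers[-1] + d * np.array([math.cos(heading), math.sin(heading)]))
    centers = np.array(centers)

    margin = radii.max() + 2.0
    mins = centers.min(axis=0) - margin
    maxs = centers.max(axis=0) + margin
    size = np.ceil(maxs - mins).astype(int)
    yy, xx = np.mgrid[: size[1], : size[0]]
    mask = np.zeros((size[1], size[0]), dtype=bool)
    for (cx, cy), r in zip(centers - mins, radii):
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    return patchify(mask).pixels, k
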