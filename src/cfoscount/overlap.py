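"""Counting cells inside non-circular contours.

A contour that fails the circularity test usually wraps several overlapping
cells.  Rather than watershed-splitting (which distorts cell morphology), a
small convolutional classifier reads the binarized, size-normalised contour
patch and predicts how many cells it contains, on the class set {1, 2, 3, 4}
where 4 means "4 or more".  The network is implemented directly on numpy
(two conv+maxpool blocks, a dense layer and a softmax read-out) so it trains
on a CPU in about a minute and is bit-reproducible given a seed.

A deterministic area-based fallback is provided for pipelines run without a
trained model.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .shapes import ContourRecord

logger = logging.getLogger(__name__)

PATCH_SIZE = 64
#: Relative bounding-box padding applied before size normalisation.
PATCH_PADDING = 0.10
#: Patches with fewer foreground pixels than this are degenerate.
MIN_PATCH_PIXELS = 20

MODEL_FORMAT_VERSION = "cfoscount-overlap-1"

CLASSES = (1, 2, 3, 4)

#: Fallback area divisor: an overlap contour's area per cell is assumed to be
#: about k * pi * min_radius**2 with k = 1.5 (fused cells hide part of each
#: member's area, but jittered radii run above the minimum).
FALLBACK_AREA_FACTOR = 1.5


@dataclass(frozen=True)
class ContourPatch:
    """A binarized contour normalised onto a fixed square grid.

    ``scale_factor`` is the ratio of patch size to the padded source canvas
    (values < 1 mean the object was shrunk to fit).
    """

    pixels: np.ndarray
    source_contour_id: str = ""
    scale_factor: float = 1.0


def patchify(region: np.ndarray, contour_id: str = "") -> ContourPatch:
    """Normalise a filled region mask onto the fixed patch grid.

    Crops to the region's bounding box, adds fixed relative padding, embeds
    in a square canvas (aspect preserved, centred) and resizes to
    ``PATCH_SIZE``.  Translation of the source object is removed exactly;
    scale up to resampling error.
    """
    region = np.asarray(region, dtype=bool)
    ys, xs = np.nonzero(region)
    if xs.size == 0:
        raise ValueError("cannot patchify an empty region")
    crop = region[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
    h, w = crop.shape
    long_side = max(h, w)
    pad = max(2, round(PATCH_PADDING * long_side))
    side = long_side + 2 * pad
    canvas = np.zeros((side, side), dtype=bool)
    r0 = (side - h) // 2
    c0 = (side - w) // 2
    canvas[r0 : r0 + h, c0 : c0 + w] = crop
    scaled = resize(canvas.astype(float), (PATCH_SIZE, PATCH_SIZE), order=1)
    return ContourPatch(
        pixels=scaled >= 0.5,
        source_contour_id=contour_id,
        scale_factor=PATCH_SIZE / side,
    )


def make_patch(
    contour: ContourRecord, mask: np.ndarray | None = None, contour_id: str = ""
) -> ContourPatch:
    """Build the classifier input patch for one contour.

    Only the contour's own filled pixels appear (the record's region mask is
    already isolated from neighbouring objects); ``mask`` is accepted for
    interface symmetry but unused because the record carries its region.
    """
    return patchify(contour.mask, contour_id=contour_id)


# --------------------------------------------------------------------------
# numpy CNN
# --------------------------------------------------------------------------


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid cross-correlation. x: (N,C,H,W), w: (F,C,kh,kw) -> (N,F,OH,OW)."""
    n = x.shape[0]
    f, c, kh, kw = w.shape
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (N,C,OH,OW,kh,kw)
    oh, ow = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw)
    out = cols @ w.reshape(f, -1).T + b
    return out.reshape(n, oh, ow, f).transpose(0, 3, 1, 2), cols


def _conv_backward(dout, cols, x_shape, w):
    """Gradients of valid cross-correlation; returns (dx, dw, db)."""
    n, c, h, wid = x_shape
    f, _, kh, kw = w.shape
    oh, ow = dout.shape[2], dout.shape[3]
    dflat = dout.transpose(0, 2, 3, 1).reshape(n, oh * ow, f)
    dw = np.einsum("npf,npk->fk", dflat, cols).reshape(w.shape)
    db = dflat.sum(axis=(0, 1))
    dcols = (dflat @ w.reshape(f, -1)).reshape(n, oh, ow, c, kh, kw)
    dx = np.zeros(x_shape)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + oh, j : j + ow] += dcols[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    return dx, dw, db


def _maxpool_forward(x: np.ndarray):
    """2x2 max pooling, stride 2. Keeps argmax for the backward pass."""
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0], idx


def _maxpool_backward(dout, idx, x_shape):
    n, c, h, w = x_shape
    dxr = np.zeros((n, c, h // 2, w // 2, 4))
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dxr.reshape(x_shape)


class OverlapModel:
    """Convolutional classifier for the number of cells in a contour patch.

    Architecture (input: 64x64 binary patch, mean-pooled to 32x32):
    conv 5x5x8 + ReLU, maxpool 2, conv 3x3x16 + ReLU, maxpool 2,
    dense 32 + ReLU, dense 4 + softmax.  Class labels are {1, 2, 3, 4}
    with 4 meaning "4 or more".
    """

    INPUT = 32

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)

        def he(shape, fan_in):
            return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "w1": he((8, 1, 5, 5), 25),
            "b1": np.zeros(8),
            "w2": he((16, 8, 3, 3), 8 * 9),
            "b2": np.zeros(16),
            "w3": he((576, 32), 576),
            "b3": np.zeros(32),
            "w4": he((32, 4), 32),
            "b4": np.zeros(4),
        }
        self.metadata: dict | None = None  # set by training

    # -- forward / backward ------------------------------------------------

    @staticmethod
    def _prepare(patches: np.ndarray) -> np.ndarray:
        """(N,64,64) boolean patches -> (N,1,32,32) float input."""
        x = np.asarray(patches, dtype=float)
        if x.ndim == 2:
            x = x[None]
        n, h, w = x.shape
        x = x.reshape(n, h // 2, 2, w // 2, 2).mean(axis=(2, 4))
        return x[:, None] - 0.5  # center around zero

    def _forward(self, x: np.ndarray):
        p = self.params
        z1, cols1 = _conv_forward(x, p["w1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        m1, idx1 = _maxpool_forward(a1)
        z2, cols2 = _conv_forward(m1, p["w2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        m2, idx2 = _maxpool_forward(a2)
        flat = m2.reshape(x.shape[0], -1)
        z3 = flat @ p["w3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        logits = a3 @ p["w4"] + p["b4"]
        shifted = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(shifted)
        probs /= probs.sum(axis=1, keepdims=True)
        cache = (x, z1, cols1, a1, m1, idx1, z2, cols2, a2, m2, idx2, flat, z3, a3)
        return probs, cache

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy over a batch and gradients for every parameter.

        ``y`` holds zero-based class indices.
        """
        p = self.params
        n = x.shape[0]
        probs, cache = self._forward(x)
        (x0, z1, cols1, a1, m1, idx1, z2, cols2, a2, m2, idx2, flat, z3, a3) = cache
        loss = -np.log(probs[np.arange(n), y] + 1e-12).mean()

        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads = {}
        grads["w4"] = a3.T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        da3 = dlogits @ p["w4"].T
        dz3 = da3 * (z3 > 0)
        grads["w3"] = flat.T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["w3"].T
        dm2 = dflat.reshape(m2.shape)
        da2 = _maxpool_backward(dm2, idx2, a2.shape)
        dz2 = da2 * (z2 > 0)
        dm1, grads["w2"], grads["b2"] = _conv_backward(dz2, cols2, m1.shape, p["w2"])
        da1 = _maxpool_backward(dm1, idx1, a1.shape)
        dz1 = da1 * (z1 > 0)
        _, grads["w1"], grads["b1"] = _conv_backward(dz1, cols1, x0.shape, p["w1"])
        return loss, grads

    # -- prediction --------------------------------------------------------

    @property
    def is_trained(self) -> bool:
        return self.metadata is not None

    def predict(self, patches: np.ndarray) -> np.ndarray:
        """Predicted cell counts (values in {1,2,3,4}) for (N,64,64) patches."""
        if not self.is_trained:
            raise RuntimeError("overlap model has not been trained")
        x = self._prepare(patches)
        probs, _ = self._forward(x)
        return probs.argmax(axis=1) + 1

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        if not self.is_trained:
            raise RuntimeError("refusing to save an untrained model")
        np.savez(
            path,
            format=np.array(MODEL_FORMAT_VERSION),
            metadata=np.array(json.dumps(self.metadata)),
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "OverlapModel":
        with np.load(path) as data:
            fmt = str(data["format"])
            if fmt != MODEL_FORMAT_VERSION:
                raise ValueError(
                    f"model format {fmt!r} does not match {MODEL_FORMAT_VERSION!r}"
                )
            model = cls()
            for key in model.params:
                model.params[key] = data[key]
            model.metadata = json.loads(str(data["metadata"]))
        return model


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

MIN_PATCHES_PER_CLASS = 25


def train_overlap_model(
    patch_source: Iterable[tuple[np.ndarray, int]] | None = None,
    seed: int = 0,
    epochs: int = 8,
    n_per_class: int = 500,
    batch_size: int = 32,
    learning_rate: float = 1e-3,
    holdout_fraction: float = 0.2,
) -> OverlapModel:
    """Train the overlap classifier, reproducibly for a given seed.

    ``patch_source`` yields (64x64 boolean patch, true count) pairs with
    counts in {1..4}; when omitted, synthetic fused-disk patches are
    generated (``n_per_class`` each).  A stratified holdout split is
    evaluated after training and its per-class accuracy stored in the model
    metadata.
    """
    if patch_source is None:
        patch_source = _synthetic_patch_stream(n_per_class, seed)
    patches, labels = [], []
    for patch, label in patch_source:
        if label not in CLASSES:
            raise ValueError(f"patch label {label} outside classes {CLASSES}")
        patches.append(np.asarray(patch, dtype=bool))
        labels.append(label)
    y_all = np.asarray(labels) - 1
    x_all = np.stack(patches)
    counts = np.bincount(y_all, minlength=4)
    if (counts < MIN_PATCHES_PER_CLASS).any():
        raise ValueError(
            f"need at least {MIN_PATCHES_PER_CLASS} patches per class, got {counts.tolist()}"
        )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y_all))
    n_holdout = max(4, int(round(holdout_fraction * len(y_all))))
    val_idx, train_idx = order[:n_holdout], order[n_holdout:]
    x_train = OverlapModel._prepare(x_all[train_idx])
    y_train = y_all[train_idx]

    model = OverlapModel(seed=seed)
    # Adam state
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(vv) for k, vv in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    for _ in range(epochs):
        perm = rng.permutation(len(y_train))
        for start in range(0, len(perm), batch_size):
            idx = perm[start : start + batch_size]
            _, grads = model.loss_and_grads(x_train[idx], y_train[idx])
            step += 1
            for key, g in grads.items():
                m[key] = beta1 * m[key] + (1 - beta1) * g
                v[key] = beta2 * v[key] + (1 - beta2) * g * g
                mhat = m[key] / (1 - beta1**step)
                vhat = v[key] / (1 - beta2**step)
                model.params[key] -= learning_rate * mhat / (np.sqrt(vhat) + eps)

    model.metadata = {
        "seed": int(seed),
        "epochs": int(epochs),
        "n_patches": int(len(y_all)),
        "classes": list(CLASSES),
    }
    # holdout evaluation
    pred = model.predict(x_all[val_idx])
    truth = y_all[val_idx] + 1
    per_class = {}
    for cls in CLASSES:
        sel = truth == cls
        if sel.any():
            per_class[str(cls)] = float((pred[sel] == cls).mean())
    model.metadata["holdout_accuracy"] = float((pred == truth).mean())
    model.metadata["holdout_accuracy_per_class"] = per_class
    logger.info(
        "overlap model trained: holdout accuracy %.3f (per class %s)",
        model.metadata["holdout_accuracy"],
        per_class,
    )
    return model


def _synthetic_patch_stream(
    n_per_class: int, seed: int
) -> Iterator[tuple[np.ndarray, int]]:
    from .synth import make_overlap_patch  # local import: synth imports patchify

    rng = np.random.default_rng([seed, 0x0F05])
    for i in range(n_per_class):
        for k in CLASSES:
            patch, label = make_overlap_patch(k, rng=rng)
            yield patch, label


# --------------------------------------------------------------------------
# counting
# --------------------------------------------------------------------------


def count_in_contour(model: OverlapModel, patch: ContourPatch) -> int:
    """Predicted number of cells inside one non-circular contour."""
    if patch.pixels.sum() < MIN_PATCH_PIXELS:
        warnings.warn("degenerate contour patch; counting as one cell", stacklevel=2)
        return 1
    return int(model.predict(patch.pixels[None])[0])


def count_in_contour_fallback(
    contour: ContourRecord, min_radius: float, area_factor: float = FALLBACK_AREA_FACTOR
) -> int:
    """Area-based cell count used when no trained model is available."""
    if contour.area <= 0:
        raise ValueError("contour area must be positive")
    unit = math.pi * min_radius**2 * area_factor
    return max(1, round(contour.area / unit))
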