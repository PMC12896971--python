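"""ROI identification: supervision masks, an encoder--decoder FCN with
entropy-regularized batch normalization, and candidate extraction.

The FCN maps an RGB patch to a per-pixel two-class probability map.
Supervision masks are fixed-radius disks painted at annotated mitosis
centroids; the network is trained with a Dice loss.  Candidates are the
connected components of the thresholded probability map.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from . import nn

__all__ = [
    "RoiMaskSpec",
    "FCNConfig",
    "ProbMap",
    "build_roi_mask",
    "binary_entropy",
    "entropy_regularized_batchnorm",
    "FCN",
    "fcn_forward",
    "train_fcn",
    "dice_coefficient",
    "extract_candidates",
]


@dataclass(frozen=True)
class RoiMaskSpec:
    radius: int = 8
    foreground_value: int = 1
    background_value: int = 0

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError("radius must be >= 1")


@dataclass
class FCNConfig:
    depth: int = 3
    base_filters: int = 16
    pool_size: int = 2
    entropy_bn: bool = True
    lr: float = 0.0001
    batch: int = 16
    epochs: int = 100
    seed: int = 0
    restarts: int = 2   # extra random restarts if training collapses

    def __post_init__(self):
        if self.depth < 1 or self.base_filters < 1:
            raise ValueError("depth and base_filters must be >= 1")


@dataclass
class ProbMap:
    values: np.ndarray      # H x W foreground probabilities
    threshold: float = 0.5


def build_roi_mask(centroids, shape, spec: RoiMaskSpec = RoiMaskSpec()):
    """Binary mask with a disk of ``spec.radius`` (Euclidean, pixel
    centers) at each centroid (x = column, y = row)."""
    mask = np.zeros(shape, dtype=np.uint8)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for x, y in centroids:
        if not (0 <= x < shape[1] and 0 <= y < shape[0]):
            raise ValueError(f"centroid ({x}, {y}) outside shape {shape}")
        mask |= ((xx - x) ** 2 + (yy - y) ** 2 <= spec.radius**2).astype(np.uint8)
    return mask * spec.foreground_value


def binary_entropy(p):
    """Shannon entropy (natural log) of a Bernoulli(p), with the limit
    convention H(0) = H(1) = 0."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(
            (arr <= 0) | (arr >= 1), 0.0,
            -arr * np.log(np.where(arr > 0, arr, 1.0))
            - (1 - arr) * np.log(np.where(arr < 1, 1 - arr, 1.0)),
        )
    return float(h) if np.isscalar(p) else h


def _squash(p):
    """Map a nonnegative feature-map mean into [0, 1): p -> p / (1 + p)."""
    return p / (1.0 + p)


def entropy_regularized_batchnorm(feature_map, bn_scale, bn_offset,
                                  regularized=True, p_override=None, eps=1e-5):
    """Plain or entropy-gated batch normalization of an NCHW array.

    Plain mode: per-feature-map z-score times ``bn_scale`` plus
    ``bn_offset``.  Regularized mode multiplies the result by the
    Bernoulli entropy ``H`` of the squashed feature-map mean (the gate
    quantifies how decisively the map is "present"; maps saturated at
    presence or absence are silenced).  ``p_override`` substitutes an
    explicit probability per feature map, bypassing the squash.
    """
    x = np.asarray(feature_map, dtype=float)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    mu = x.mean(axis=(0, 2, 3), keepdims=True)
    sd = np.maximum(x.std(axis=(0, 2, 3), keepdims=True), eps)
    out = (x - mu) / sd * np.asarray(bn_scale).reshape(1, -1, 1, 1) \
        + np.asarray(bn_offset).reshape(1, -1, 1, 1)
    if regularized:
        if p_override is None:
            p = _squash(np.maximum(x.mean(axis=(0, 2, 3)), 0.0))
        else:
            p = np.broadcast_to(np.asarray(p_override, float), (x.shape[1],))
        out = out * binary_entropy(p).reshape(1, -1, 1, 1)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# FCN
# ---------------------------------------------------------------------------


class FCN:
    """Encoder--decoder FCN with skip connections.

    Encoder blocks: conv3x3 -> entropy-regularized BN -> ReLU -> maxpool.
    Decoder blocks: nearest-neighbor upsample -> concat matching encoder
    features -> conv3x3 -> ReLU.  A final 1x1 convolution produces
    two-class logits; per-pixel softmax gives the probability map.
    """

    def __init__(self, config: FCNConfig, in_channels=3):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.base_filters
        self.params = {}
        c_in = in_channels
        enc_channels = []
        for d in range(config.depth):
            c_out = f * 2**d
            self._conv(rng, f"enc{d}", c_in, c_out)
            self.params[f"enc{d}_bn_a"] = nn.parameter(np.ones(c_out))
            self.params[f"enc{d}_bn_b"] = nn.parameter(np.zeros(c_out))
            enc_channels.append(c_out)
            c_in = c_out
        self._conv(rng, "mid", c_in, c_in)
        for d in reversed(range(config.depth)):
            c_out = enc_channels[d]
            self._conv(rng, f"dec{d}", c_in + enc_channels[d], c_out)
            c_in = c_out
        self._conv(rng, "head", c_in, 2, k=1)
        self.enc_channels = enc_channels

    def _conv(self, rng, name, c_in, c_out, k=3):
        self.params[f"{name}_w"] = nn.he_init(rng, (c_out, c_in, k, k), c_in * k * k)
        self.params[f"{name}_b"] = nn.parameter(np.zeros(c_out))

    def parameters(self):
        return list(self.params.values())

    def _bn(self, x, d):
        a = self.params[f"enc{d}_bn_a"]
        b = self.params[f"enc{d}_bn_b"]
        gate = None
        if self.config.entropy_bn:
            p = _squash(np.maximum(x.data.mean(axis=(0, 2, 3)), 0.0))
            gate = binary_entropy(p)  # constant in the backward pass
        return nn.batchnorm2d(x, a, b, gate=gate)

    def forward(self, images):
        """images: (N, H, W, 3) in [0,1] -> softmax probs (N, 2, H, W).

        Spatial sizes not divisible by ``pool_size**depth`` are
        replicate-padded and the output cropped back.
        """
        x = np.asarray(images, dtype=float).transpose(0, 3, 1, 2)
        # center each image per channel: with all-positive inputs the
        # first convolution's gradients are strongly correlated and
        # Dice training frequently collapses to the background optimum
        x = x - x.mean(axis=(2, 3), keepdims=True)
        n, _, h, w = x.shape
        m = self.config.pool_size ** self.config.depth
        ph, pw = (-h) % m, (-w) % m
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge")
        t = nn.constant(x)
        skips = []
        for d in range(self.config.depth):
            t = nn.conv2d(t, self.params[f"enc{d}_w"], self.params[f"enc{d}_b"])
            t = self._bn(t, d).relu()
            skips.append(t)
            t = nn.max_pool2d(t, self.config.pool_size)
        t = nn.conv2d(t, self.params["mid_w"], self.params["mid_b"]).relu()
        for d in reversed(range(self.config.depth)):
            t = nn.upsample_nearest(t, self.config.pool_size)
            t = nn.concat([t, skips[d]], axis=1)
            t = nn.conv2d(t, self.params[f"dec{d}_w"], self.params[f"dec{d}_b"]).relu()
        logits = nn.conv2d(t, self.params["head_w"], self.params["head_b"])
        probs = nn.softmax(logits, axis=1)
        if ph or pw:
            probs = probs[:, :, : h, : w]
        return probs


def fcn_forward(image, model: FCN, threshold=0.5) -> ProbMap:
    """Single-image inference; returns the foreground probability map."""
    probs = model.forward(np.asarray(image)[None])
    return ProbMap(values=probs.data[0, 1], threshold=threshold)


def dice_coefficient(pred, target, eps=1e-6):
    p = np.asarray(pred, dtype=float).ravel()
    t = np.asarray(target, dtype=float).ravel()
    return (2 * (p * t).sum() + eps) / (p.sum() + t.sum() + eps)


def _dice_loss(probs, masks, eps=1e-6):
    """1 - soft Dice of the foreground channel, pooled over the batch."""
    fg = probs[:, 1]
    t = nn.constant(masks)
    inter = (fg * t).sum()
    return 1.0 - (2.0 * inter + eps) / (fg.sum() + t.sum() + eps)


def train_fcn(patches, config: FCNConfig, val_patches=None, log=None):
    """Train the FCN on LabeledPatch supervision masks with Dice loss.

    Returns (model, history).  ``epochs=0`` returns the freshly
    initialized model.  Requires both mask classes to be present across
    the training set.
    """
    masks = np.stack([p.mask_true for p in patches]).astype(float)
    if masks.max() == masks.min():
        raise ValueError("training masks contain a single class")
    images = np.stack([p.image for p in patches])
    if config.epochs == 0:
        return FCN(config), {"loss": [], "val_dice": [], "attempts": 0}
    n = len(patches)

    def attempt(seed):
        model = FCN(replace(config, seed=seed))
        history = {"loss": [], "val_dice": []}
        rng = np.random.default_rng(seed + 1)
        opt = nn.Adam(model.parameters(), lr=config.lr)
        for epoch in range(config.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, config.batch):
                idx = order[start : start + config.batch]
                loss = _dice_loss(model.forward(images[idx]), masks[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history["loss"].append(float(np.mean(losses)))
            if val_patches is not None:
                probs = model.forward(np.stack([p.image for p in val_patches]))
                history["val_dice"].append(float(np.mean([
                    dice_coefficient(probs.data[i, 1] > 0.5, p.mask_true)
                    for i, p in enumerate(val_patches)])))
            if log:
                log(f"fcn epoch {epoch}: loss={history['loss'][-1]:.4f}")
        probs = model.forward(images)
        train_dice = dice_coefficient(probs.data[:, 1] > 0.5, masks)
        return model, history, train_dice

    # Dice training on scarce foreground occasionally collapses to the
    # all-background optimum or an over-segmenting basin; restart with a
    # fresh initialization while the *training* Dice stays below 0.9
    # (healthy runs reach ~0.95; degenerate basins stay below ~0.85),
    # keeping the best attempt.
    best = None
    for k in range(1 + max(config.restarts, 0)):
        model, history, train_dice = attempt(config.seed + 1000 * k)
        history["attempts"] = k + 1
        if best is None or train_dice > best[2]:
            best = (model, history, train_dice)
        if train_dice >= 0.9:
            break
    return best[0], best[1]


def extract_candidates(probmap: ProbMap, image, threshold=None, patch_size=32,
                       min_area=5):
    """Connected components of the thresholded map -> candidate crops.

    Returns a list of dicts with keys ``centroid`` (x, y), ``score``
    (mean component probability), and ``patch`` (edge-clamped crop
    centered at the centroid).
    """
    thr = probmap.threshold if threshold is None else threshold
    if not 0 < thr < 1:
        raise ValueError("threshold must lie in (0, 1)")
    binary = probmap.values > thr
    labeled, n_comp = ndimage.label(binary)
    img = np.asarray(image)
    h, w = probmap.values.shape
    out = []
    for comp in range(1, n_comp + 1):
        sel = labeled == comp
        if sel.sum() < min_area:
            continue
        cy, cx = ndimage.center_of_mass(sel)
        score = float(probmap.values[sel].mean())
        half = patch_size // 2
        y0 = int(np.clip(round(cy) - half, 0, max(h - patch_size, 0)))
        x0 = int(np.clip(round(cx) - half, 0, max(w - patch_size, 0)))
        crop = img[y0 : y0 + patch_size, x0 : x0 + patch_size]
        out.append({"centroid": (float(cx), float(cy)), "score": score,
                    "patch": crop})
    return out
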