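"""Preprocessing for H&E patches.

Four stages, applied in this fixed order by :func:`preprocess_patch`:

1. per-channel zero-mean / unit-variance normalization,
2. Macenko stain normalization (SVD-plane stain-vector estimation with
   robust angular extremes, pseudo-inverse color deconvolution, and
   99th-percentile concentration rescaling against a target stain model),
3. median filtering for small artifact removal,
4. histogram equalization of the intensity channel for contrast.

Optical density convention: ``OD = -log10(I)`` for transmitted intensity
``I`` in (0, 1] with unit incident intensity, so pixel OD is linear in
stain concentration under Beer--Lambert.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .feat_hand import rgb_to_hsi

__all__ = [
    "ZScoreParams",
    "StainModel",
    "HistEqMap",
    "DegenerateInputError",
    "InsufficientTissueError",
    "zero_mean_normalize",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_vectors",
    "stain_concentrations",
    "macenko_normalize",
    "median_filter",
    "histogram_equalize",
    "preprocess_patch",
]

EPSILON = 1.0 / 255.0


class DegenerateInputError(ValueError):
    """Raised for inputs on which the operation is undefined (constant
    channel, single-stain tissue, ...)."""


class InsufficientTissueError(ValueError):
    """Raised when too few pixels exceed the OD threshold to estimate
    stain vectors."""


@dataclass
class ZScoreParams:
    mu: np.ndarray     # per-channel mean
    sigma: np.ndarray  # per-channel standard deviation (n-1 denominator)


@dataclass
class StainModel:
    V: np.ndarray       # 3x2, columns = (hematoxylin, eosin), unit norm
    maxC: np.ndarray    # robust (99th percentile) concentration per stain
    alpha: float = 1.0  # angular percentile
    beta: float = 0.15  # OD magnitude threshold

    def to_json(self):
        return json.dumps({"V": self.V.tolist(), "maxC": self.maxC.tolist(),
                           "alpha": self.alpha, "beta": self.beta}, indent=1)

    @classmethod
    def from_json(cls, text):
        d = json.loads(text)
        return cls(V=np.array(d["V"]), maxC=np.array(d["maxC"]),
                   alpha=d["alpha"], beta=d["beta"])


@dataclass
class HistEqMap:
    pdf: np.ndarray    # P(I_x) per gray level
    cdf: np.ndarray    # c(i), non-decreasing, ends at 1
    lut: np.ndarray    # f(i), rounded transform
    levels: int


# ---------------------------------------------------------------------------
# Stage 1: zero-mean normalization
# ---------------------------------------------------------------------------


def zero_mean_normalize(image):
    """Standardize each channel to mean 0, sd 1 (sample sd, n-1)."""
    img = np.asarray(image, dtype=float)
    x = img.reshape(-1, img.shape[-1]) if img.ndim == 3 else img.reshape(-1, 1)
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=1)
    if np.any(sigma <= 0):
        bad = np.nonzero(sigma <= 0)[0].tolist()
        raise DegenerateInputError(f"constant channel(s) {bad}: sd is zero")
    out = (img - mu) / sigma
    return out, ZScoreParams(mu=mu, sigma=sigma)


# ---------------------------------------------------------------------------
# Stage 2: Macenko stain normalization
# ---------------------------------------------------------------------------


def rgb_to_od(image, epsilon=EPSILON):
    """``OD = -log10(max(I, epsilon))``; nonnegative, monotone in I."""
    img = np.asarray(image, dtype=float)
    return -np.log10(np.maximum(img, epsilon))


def od_to_rgb(od):
    return np.power(10.0, -np.asarray(od, dtype=float))


def estimate_stain_vectors(od_pixels, alpha=1.0, beta=0.15) -> StainModel:
    """Estimate the two H&E stain vectors from OD pixels (Macenko).

    Pixels with OD norm below ``beta`` are discarded; the surviving
    pixels are projected onto the plane of the two leading SVD
    directions; each projection is normalized to unit length and its
    angle computed; the ``alpha``-th and (100-alpha)-th percentile
    angles give the two robust extreme directions, mapped back to
    3-space as unit stain vectors.  The more blue-absorbing vector
    (hematoxylin) is placed first.
    """
    od = np.asarray(od_pixels, dtype=float).reshape(-1, 3)
    keep = np.linalg.norm(od, axis=1) > beta
    od = od[keep]
    if od.shape[0] < 3:
        raise InsufficientTissueError(
            f"only {od.shape[0]} pixels exceed the OD threshold beta={beta}"
        )
    # two leading right-singular directions span the stain plane
    _, _, vt = np.linalg.svd(od, full_matrices=False)
    plane = vt[:2]                       # 2 x 3
    # orient basis vectors toward positive OD mass
    for i in range(2):
        if plane[i].sum() < 0:
            plane[i] = -plane[i]
    proj = od @ plane.T                  # n x 2
    norms = np.linalg.norm(proj, axis=1)
    proj = proj[norms > 1e-12] / norms[norms > 1e-12, None]
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(angles, alpha)
    hi = np.percentile(angles, 100.0 - alpha)
    if hi - lo < 1e-6:
        raise DegenerateInputError(
            "zero angular spread: single-stain or degenerate tissue"
        )
    vecs = []
    for ang in (lo, hi):
        v = np.cos(ang) * plane[0] + np.sin(ang) * plane[1]
        if v.sum() < 0:
            v = -v
        vecs.append(v / np.linalg.norm(v))
    V = np.stack(vecs, axis=1)
    # hematoxylin absorbs more in the blue channel (index 2)
    if V[2, 0] < V[2, 1]:
        V = V[:, ::-1]
    model = StainModel(V=V, maxC=np.ones(2), alpha=float(alpha), beta=float(beta))
    C = stain_concentrations(od, model)
    model.maxC = np.maximum(np.percentile(C, 99, axis=0), 1e-6)
    return model


def stain_concentrations(od_pixels, stain_model: StainModel, clamp=True):
    """Least-squares concentrations ``S`` with ``OD ~ V S`` via the
    pseudo-inverse of the 3x2 stain matrix (a true inverse does not
    exist).  Negative concentrations are clamped to zero by default:
    they are physical quantities."""
    od = np.asarray(od_pixels, dtype=float)
    flat = od.reshape(-1, 3)
    S = flat @ np.linalg.pinv(stain_model.V).T
    if clamp:
        S = np.maximum(S, 0.0)
    return S.reshape(od.shape[:-1] + (2,))


def macenko_normalize(image, target: StainModel, alpha=1.0, beta=0.15,
                      epsilon=EPSILON):
    """Map an image's stain appearance onto ``target``.

    Estimates the source stain model, deconvolves concentrations,
    rescales each stain by ``target.maxC / source.maxC`` and
    reconstructs through the target stain matrix.
    """
    od = rgb_to_od(image, epsilon)
    source = estimate_stain_vectors(od.reshape(-1, 3), alpha=alpha, beta=beta)
    S = stain_concentrations(od, source)
    S = S * (np.asarray(target.maxC) / source.maxC)
    out = od_to_rgb(S @ target.V.T)
    return np.clip(out, 1e-6, 1.0)


# ---------------------------------------------------------------------------
# Stage 3: median filtering
# ---------------------------------------------------------------------------


def median_filter(image, window=3):
    """Exact moving median with replicate-edge padding (per channel)."""
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    img = np.asarray(image)
    if img.ndim == 2:
        return ndimage.median_filter(img, size=window, mode="nearest")
    return np.stack(
        [ndimage.median_filter(img[..., c], size=window, mode="nearest")
         for c in range(img.shape[-1])], axis=-1,
    )


# ---------------------------------------------------------------------------
# Stage 4: histogram equalization
# ---------------------------------------------------------------------------


def histogram_equalize(channel, levels=256):
    """Global histogram equalization of an integer gray-level channel.

    ``f(i) = I_0 + (I_{L-1} - I_0) * c(i)`` with ``I_0 = 0``,
    ``I_{L-1} = L - 1`` and ``c`` the empirical CDF, rounded to the
    nearest level and applied per pixel.
    """
    ch = np.asarray(channel)
    if ch.size == 0:
        raise ValueError("empty image")
    if not np.issubdtype(ch.dtype, np.integer):
        raise TypeError("histogram_equalize expects integer gray levels")
    if ch.min() < 0 or ch.max() > levels - 1:
        raise ValueError(f"gray levels must lie in [0, {levels - 1}]")
    counts = np.bincount(ch.ravel(), minlength=levels)
    pdf = counts / counts.sum()
    cdf = np.cumsum(counts) / counts.sum()  # exact integer accumulation
    lut = np.rint(0 + (levels - 1 - 0) * cdf).astype(ch.dtype)
    out = lut[ch]
    return out, HistEqMap(pdf=pdf, cdf=cdf, lut=lut, levels=levels)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def _hsi_to_rgb(h_deg, s, i):
    """Inverse of the HSI transform used for the intensity-equalized path."""
    h = np.deg2rad(np.mod(h_deg, 360.0))
    r = np.empty_like(i)
    g = np.empty_like(i)
    b = np.empty_like(i)
    for k in range(3):
        sector = (h >= k * 2 * np.pi / 3) & (h < (k + 1) * 2 * np.pi / 3)
        hs = h[sector] - k * 2 * np.pi / 3
        x = i[sector] * (1 - s[sector])
        y = i[sector] * (1 + s[sector] * np.cos(hs) / np.cos(np.pi / 3 - hs))
        z = 3 * i[sector] - (x + y)
        first, second, third = [(r, g, b), (g, b, r), (b, r, g)][k]
        first[sector], second[sector], third[sector] = y, z, x
    return np.clip(np.stack([r, g, b], axis=-1), 0.0, 1.0)


def preprocess_patch(image, target: StainModel | None = None, alpha=1.0,
                     beta=0.15, median_window=3, levels=256):
    """Run all four stages on an RGB image in [0, 1].

    The z-score stage standardizes each channel; because the stain model
    operates on transmitted intensities in (0, 1], the standardized
    channels are affinely rescaled back into (0, 1] (per-channel
    min-max) before the OD transform.  If ``target`` is None the image's
    own estimated stain model is the target (appearance is left in
    place; concentrations are still cleaned through the deconvolution).
    Returns (image, info dict).
    """
    img = np.asarray(image, dtype=float)
    info = {}
    z, zp = zero_mean_normalize(img)
    info["zscore"] = zp
    lo = z.min(axis=(0, 1), keepdims=True)
    hi = z.max(axis=(0, 1), keepdims=True)
    img = (z - lo) / np.maximum(hi - lo, 1e-12)
    img = np.clip(img, EPSILON, 1.0)

    if target is None:
        target = estimate_stain_vectors(
            rgb_to_od(img).reshape(-1, 3), alpha=alpha, beta=beta
        )
    img = macenko_normalize(img, target, alpha=alpha, beta=beta)
    info["stain"] = target

    img = median_filter(img, window=median_window)

    h, s, i = rgb_to_hsi(img)
    iq = np.clip(np.rint(i * (levels - 1)), 0, levels - 1).astype(np.int64)
    ieq, heqmap = histogram_equalize(iq, levels=levels)
    info["histeq"] = heqmap
    img = _hsi_to_rgb(h, s, ieq.astype(float) / (levels - 1))
    return np.clip(img, 0.0, 1.0), info


def save_stain_model(model: StainModel, path):
    Path(path).write_text(model.to_json())


def load_stain_model(path) -> StainModel:
    return StainModel.from_json(Path(path).read_text())
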