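"""Handcrafted texture, color and shape descriptors.

The feature blocks assembled by :func:`handcrafted_vector`:

* ``lbp``     - 256-bin normalized histogram of 8-neighbor local binary
                pattern codes (texture),
* ``gabor``   - mean and standard deviation of complex Gabor filter
                response magnitudes over a frequency x orientation bank,
* ``hsi``     - first two moments of hue (as a sin/cos pair, hue being
                circular), saturation and intensity,
* ``moments`` - normalized central moments eta_pq for p+q <= 3 of the
                segmentation mask (translation- and scale-invariant),
* ``fd``      - Fourier-descriptor magnitudes |a_n|/|a_1| of the mask
                boundary (similarity-invariant shape signature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from skimage import measure

__all__ = [
    "GaborBankConfig",
    "MomentSet",
    "FourierDescriptorSet",
    "lbp_code",
    "lbp_histogram",
    "gabor_kernel",
    "gabor_features",
    "rgb_to_hsi",
    "hsi_statistics",
    "apply_similarity_transform",
    "moment_invariants",
    "fourier_descriptors",
    "shape_distance",
    "mask_contour",
    "handcrafted_vector",
]

# Neighbor order for the LBP code: clockwise from the top-left neighbor,
# bit n = 0 at top-left.  (row offset, col offset) pairs.
_LBP_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, 1),
                (1, 1), (1, 0), (1, -1), (0, -1)]


@dataclass(frozen=True)
class GaborBankConfig:
    center_freqs: tuple = (0.1, 0.2, 0.4)        # cycles / pixel
    orientations: tuple = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    sigma_x: float = 2.0
    sigma_y: float = 2.0

    def __post_init__(self):
        if not self.orientations:
            raise ValueError("need at least one orientation")
        if any(w <= 0 for w in self.center_freqs):
            raise ValueError("center frequencies must be positive")
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("envelope scales must be positive")


@dataclass
class MomentSet:
    raw: dict          # (p, q) -> m_pq
    centroid: tuple    # (x_bar, y_bar)
    central: dict      # (p, q) -> mu_pq
    normalized: dict   # (p, q) -> eta_pq, gamma = (p + q + 2) / 2


@dataclass
class FourierDescriptorSet:
    coeffs: np.ndarray      # a_n, n = 0..N-1
    normalized: np.ndarray  # |a_n| / |a_1| for n = 2..N-1  (length N-2)


# ---------------------------------------------------------------------------
# Texture: LBP
# ---------------------------------------------------------------------------


def lbp_code(window):
    """8-bit LBP code of a 3x3 window: bit n set iff neighbor_n >= center."""
    w = np.asarray(window, dtype=float)
    if w.shape != (3, 3):
        raise ValueError("lbp_code expects a 3x3 window")
    c = w[1, 1]
    z = 0
    for n, (dr, dc) in enumerate(_LBP_OFFSETS):
        if w[1 + dr, 1 + dc] - c >= 0:
            z |= 1 << n
    return z


def lbp_histogram(image):
    """Normalized 256-bin histogram of LBP codes over all interior pixels."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("lbp_histogram needs a grayscale image >= 3x3")
    center = img[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int64)
    for n, (dr, dc) in enumerate(_LBP_OFFSETS):
        nb = img[1 + dr : img.shape[0] - 1 + dr, 1 + dc : img.shape[1] - 1 + dc]
        codes |= ((nb - center) >= 0).astype(np.int64) << n
    hist = np.bincount(codes.ravel(), minlength=256).astype(float)
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# Texture: Gabor bank
# ---------------------------------------------------------------------------


def gabor_kernel(W, theta, sigma_x, sigma_y):
    """Complex 2-D Gabor kernel: Gaussian envelope times a complex plane
    wave at center frequency ``W`` along the theta-rotated abscissa."""
    half = int(np.ceil(4 * max(sigma_x, sigma_y)))
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    envelope = np.exp(-0.5 * (x**2 / sigma_x**2 + y**2 / sigma_y**2))
    envelope /= 2 * np.pi * sigma_x * sigma_y
    x_rot = x * np.cos(theta) + y * np.sin(theta)
    return envelope * np.exp(2j * np.pi * W * x_rot)


def gabor_features(image, bank: GaborBankConfig = GaborBankConfig()):
    """Mean and standard deviation of response magnitude per (W, theta)
    filter; length = 2 * |freqs| * |orientations|."""
    img = np.asarray(image, dtype=float)
    feats = []
    for W in bank.center_freqs:
        for theta in bank.orientations:
            k = gabor_kernel(W, theta, bank.sigma_x, bank.sigma_y)
            half = k.shape[0] // 2
            padded = np.pad(img, half, mode="edge")  # no border roll-off
            resp = fftconvolve(padded, k, mode="valid")
            mag = np.abs(resp)
            feats.extend([mag.mean(), mag.std()])
    return np.array(feats)


# ---------------------------------------------------------------------------
# Color: HSI
# ---------------------------------------------------------------------------


def rgb_to_hsi(image):
    """HSI transform; H in degrees [0, 360), S in [0, 1], I = (R+G+B)/3.

    Achromatic pixels (R = G = B, including black) get H = 0, S = 0 by
    convention.
    """
    arr = np.asarray(image, dtype=float)
    scalar = arr.ndim == 1
    rgb = np.atleast_2d(arr).reshape(-1, 3)
    R, G, B = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    total = R + G + B
    I = total / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(total > 0, 1.0 - 3.0 * rgb.min(axis=1) / np.where(total > 0, total, 1.0), 0.0)
    num = 0.5 * ((R - G) + (R - B))
    den = np.sqrt((R - G) ** 2 + (R - B) * (G - B))
    achro = den < 1e-12
    theta = np.arccos(np.clip(np.where(achro, 1.0, num / np.where(achro, 1.0, den)), -1.0, 1.0))
    H = np.where(G >= B, theta, 2 * np.pi - theta)
    H = np.where(achro | (S <= 1e-12), 0.0, H)
    H = np.degrees(H) % 360.0
    if scalar:
        return float(H[0]), float(S[0]), float(I[0])
    shape = arr.shape[:-1]
    return H.reshape(shape), S.reshape(shape), I.reshape(shape)


def hsi_statistics(image):
    """8 values: mean and sd of sin(H), cos(H), S, I (hue is circular,
    so its raw angle is summarized through the sin/cos pair)."""
    H, S, I = rgb_to_hsi(image)
    h = np.deg2rad(np.asarray(H, dtype=float))
    parts = [np.sin(h), np.cos(h), np.asarray(S, float), np.asarray(I, float)]
    return np.array([f(p) for p in parts for f in (np.mean, np.std)])


# ---------------------------------------------------------------------------
# Shape: similarity transforms, moments, Fourier descriptors
# ---------------------------------------------------------------------------


def apply_similarity_transform(contour, a=0.0, b=0.0, Sx=1.0, Sy=1.0, theta=0.0):
    """Rotate by theta (counter-clockwise), scale by (Sx, Sy), then
    translate by (a, b), in that fixed order.  ``contour``: (n, 2) x-y."""
    if Sx == 0 or Sy == 0:
        raise ValueError("scale factors must be nonzero")
    pts = np.asarray(contour, dtype=float)
    if pts.size == 0:
        raise ValueError("empty contour")
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    out = pts @ rot.T
    out = out * np.array([Sx, Sy])
    return out + np.array([a, b])


def moment_invariants(mask) -> MomentSet:
    """Raw, central and normalized moments of a binary mask, p+q <= 3.

    Coordinates: x = column, y = row.  ``eta_pq = mu_pq / mu00**gamma``
    with ``gamma = (p + q + 2) / 2``; central moments are exactly
    translation-invariant, eta additionally scale-invariant up to
    discretization.
    """
    m = np.asarray(mask, dtype=float)
    if m.sum() <= 0:
        raise ValueError("empty mask")
    yy, xx = np.mgrid[0 : m.shape[0], 0 : m.shape[1]].astype(float)
    raw = {(p, q): float((m * xx**p * yy**q).sum())
           for p in range(4) for q in range(4) if p + q <= 3}
    xbar = raw[(1, 0)] / raw[(0, 0)]
    ybar = raw[(0, 1)] / raw[(0, 0)]
    central = {(p, q): float((m * (xx - xbar) ** p * (yy - ybar) ** q).sum())
               for p in range(4) for q in range(4) if p + q <= 3}
    normalized = {pq: central[pq] / central[(0, 0)] ** ((pq[0] + pq[1] + 2) / 2.0)
                  for pq in central}
    return MomentSet(raw=raw, centroid=(xbar, ybar), central=central,
                     normalized=normalized)


#: eta exponents reported as the shape block, in fixed order
ETA_ORDER = [(1, 1), (0, 2), (2, 0), (1, 2), (2, 1), (0, 3), (3, 0)]


def _resample_closed(contour, N):
    """Resample a closed contour to N points equally spaced in arc length."""
    pts = np.asarray(contour, dtype=float)
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate contour with zero perimeter")
    targets = np.linspace(0.0, total, N, endpoint=False)
    x = np.interp(targets, s, pts[:, 0])
    y = np.interp(targets, s, pts[:, 1])
    return np.stack([x, y], axis=1)


def fourier_descriptors(contour, N=64) -> FourierDescriptorSet:
    """DFT coefficients of the centroid-subtracted complex boundary.

    ``a_n = (1/N) sum_t u(t) exp(-j 2 pi n t / N)``.  The normalized
    magnitudes ``|a_n| / |a_1|`` for n >= 2 are invariant to
    translation (centroid subtraction), rotation and starting point
    (phase only) and scale (ratio).
    """
    pts = np.asarray(contour, dtype=float)
    if pts.shape[0] > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if pts.shape[0] < 8:
        raise ValueError("need a closed contour with >= 8 points")
    # a contour already sampled at N points is used verbatim (cyclic
    # shifts of the samples are then exactly start-point invariant);
    # other lengths are resampled uniformly in arc length
    rs = pts if pts.shape[0] == N else _resample_closed(pts, N)
    u = rs[:, 0] + 1j * rs[:, 1]
    u = u - u.mean()
    a = np.fft.fft(u) / N
    if np.abs(a[1]) < 1e-12:
        raise ValueError("degenerate contour: |a_1| ~ 0")
    normalized = np.abs(a[2:]) / np.abs(a[1])
    return FourierDescriptorSet(coeffs=a, normalized=normalized)


def shape_distance(fd_q: FourierDescriptorSet, fd_t: FourierDescriptorSet):
    """Euclidean distance between normalized FD magnitude vectors."""
    if len(fd_q.normalized) != len(fd_t.normalized):
        raise ValueError("descriptor length mismatch")
    return float(np.linalg.norm(fd_q.normalized - fd_t.normalized))


def mask_contour(mask):
    """Longest closed iso-contour of a binary mask as (x, y) points, or
    None if the mask has no usable boundary."""
    m = np.asarray(mask, dtype=float)
    contours = measure.find_contours(np.pad(m, 1), 0.5)
    if not contours:
        return None
    c = max(contours, key=len)
    if len(c) < 8:
        return None
    return np.stack([c[:, 1] - 1, c[:, 0] - 1], axis=1)  # (row,col) -> (x,y)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

FD_HARMONICS = slice(0, 11)  # |a_n|/|a_1| for n = 2..12


def handcrafted_vector(patch, mask=None, gabor_bank: GaborBankConfig = GaborBankConfig()):
    """Concatenated handcrafted block for one RGB patch.

    ``mask`` is the segmentation used for the shape blocks; when it is
    empty or degenerate those blocks are zero (finite output on any
    valid input is part of the contract).  Returns (vector, block_index).
    """
    img = np.asarray(patch, dtype=float)
    gray = img.mean(axis=-1) if img.ndim == 3 else img

    blocks = []
    index = {}

    def add(name, values):
        start = sum(len(b) for b in blocks)
        blocks.append(np.asarray(values, dtype=float))
        index[name] = (start, start + len(blocks[-1]))

    add("lbp", lbp_histogram(gray))
    add("gabor", gabor_features(gray, gabor_bank))
    add("hsi", hsi_statistics(img) if img.ndim == 3 else np.zeros(8))

    eta = np.zeros(len(ETA_ORDER))
    fd = np.zeros(FD_HARMONICS.stop - FD_HARMONICS.start)
    if mask is not None and np.asarray(mask).sum() > 0:
        ms = moment_invariants(mask)
        eta = np.array([ms.normalized[pq] for pq in ETA_ORDER])
        contour = mask_contour(mask)
        if contour is not None:
            try:
                fd = fourier_descriptors(contour).normalized[FD_HARMONICS]
            except ValueError:
                pass
    add("moments", eta)
    add("fd", fd)

    vec = np.concatenate(blocks)
    if not np.all(np.isfinite(vec)):
        raise FloatingPointError("non-finite handcrafted feature")
    return vec, index
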