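"""Synthetic H&E-like patch and feature-table generation.

Every downstream stage of the pipeline is exercised on data from this
module, so it encodes the physical model the preprocessing stage inverts:
two-stain Beer--Lambert color formation.  A patch is built in optical
density (OD) space as ``OD = V @ S + noise`` with ``V`` a 3x2 matrix of
unit stain vectors (hematoxylin, eosin) and ``S`` per-pixel stain
concentrations, then exponentiated to transmitted intensity
``I = 10**(-OD)`` with unit incident intensity.

Tissue layout: a smooth eosin-dominated background (cytoplasm/stroma),
elliptical hematoxylin-stained nuclei, and - in mitotic patches - one or
more darker, irregular star-convex figures at recorded centroids.
Mitotic figures in real tissue are tiny hyperchromatic objects of highly
variable shape; the star-convex perturbation of a disk gives the shape
descriptors a class signal while staying cheap to rasterize.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "RUIFROK_HE",
    "SynthConfig",
    "LabeledPatch",
    "FeatureTable",
    "generate_patch",
    "generate_dataset",
    "generate_feature_table",
    "write_dataset",
    "write_feature_table",
    "read_feature_table",
]

#: Conventional H&E stain OD vectors (columns: hematoxylin, eosin), unit norm.
RUIFROK_HE = np.array(
    [[0.650, 0.072], [0.704, 0.990], [0.286, 0.105]]
)
RUIFROK_HE = RUIFROK_HE / np.linalg.norm(RUIFROK_HE, axis=0, keepdims=True)


def _check_stain_matrix(V):
    V = np.asarray(V, dtype=float)
    if V.shape != (3, 2):
        raise ValueError("stain matrix must be 3x2")
    norms = np.linalg.norm(V, axis=0)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("stain vectors must have unit Euclidean norm")
    cosang = float(np.clip(V[:, 0] @ V[:, 1], -1, 1))
    if np.degrees(np.arccos(cosang)) <= 10.0:
        raise ValueError("stain vectors are near-collinear (angle <= 10 deg)")
    return V


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic generator.

    ``mitosis_contrast`` is the multiplicative excess of a mitotic
    figure's hematoxylin concentration over ordinary nuclei;
    ``roi_radius`` is the fixed-size supervision disk painted at each
    planted centroid; ``n_hpfs`` pseudo high-power fields mirror the ten
    annotated HPFs per slide of the benchmark protocol.
    """

    patch_size: int = 128
    n_patches: int = 100
    stain_matrix_true: np.ndarray = field(default_factory=lambda: RUIFROK_HE.copy())
    n_nuclei: int = 8
    mitosis_prob: float = 0.5
    noise_sd: float = 0.02
    seed: int = 0
    roi_radius: int = 8
    n_hpfs: int = 10
    nucleus_radius: float = 6.0
    nucleus_conc: float = 0.7
    background_conc: float = 0.35
    mitosis_contrast: float = 1.8
    mitosis_radius: float = 7.0
    subtle: bool = False

    def __post_init__(self):
        _check_stain_matrix(self.stain_matrix_true)
        if self.patch_size < 32:
            raise ValueError("patch_size must be >= 32")
        if not 0.0 <= self.mitosis_prob <= 1.0:
            raise ValueError("mitosis_prob must lie in [0, 1]")


@dataclass
class LabeledPatch:
    image: np.ndarray            # H x W x 3 in (0, 1]
    label: int                   # 1 = mitotic
    centroids: list              # [(x, y), ...] pixel coordinates
    mask_true: np.ndarray        # H x W binary ground-truth ROI
    hpf_id: int = 0
    patch_id: int = 0


@dataclass
class FeatureTable:
    matrix: np.ndarray           # n_samples x n_features
    labels: np.ndarray           # binary, length n_samples
    informative_idx: np.ndarray  # ground-truth informative columns
    block_index: dict            # block name -> (start, stop)


# ---------------------------------------------------------------------------
# Rasterization helpers
# ---------------------------------------------------------------------------


def _paint_ellipse(conc, cx, cy, rx, ry, angle, value):
    h, w = conc.shape
    yy, xx = np.mgrid[0:h, 0:w]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    inside = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    conc[inside] = np.maximum(conc[inside], value)
    return inside


def _paint_star(conc, cx, cy, radius, value, rng, n_lobes=9, roughness=0.45):
    """Star-convex irregular blob: per-angle radius perturbation of a disk."""
    h, w = conc.shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    theta = np.arctan2(dy, dx)
    amps = rng.uniform(-roughness, roughness, size=n_lobes)
    phases = rng.uniform(0, 2 * np.pi, size=n_lobes)
    rad = radius * (1.0 + sum(a * np.cos((k + 2) * theta + p)
                              for k, (a, p) in enumerate(zip(amps, phases))) / 3.0)
    rad = np.maximum(rad, radius * 0.35)
    inside = dx * dx + dy * dy <= rad * rad
    conc[inside] = np.maximum(conc[inside], value)
    return inside


def _disk_mask(shape, cx, cy, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


# ---------------------------------------------------------------------------
# Patch generation
# ---------------------------------------------------------------------------


def generate_patch(config: SynthConfig, label: int, seed: int) -> LabeledPatch:
    """Render one patch from the two-stain forward model.

    ``label=1`` plants a single mitotic figure at a recorded centroid and
    paints the corresponding ground-truth ROI disk.  In ``subtle`` mode
    the planted figure is an ordinary nucleus (same size, shape and stain
    uptake as the background nuclei) and the class signal is instead a
    faint signed eosin-density gradient across the patch: every pooled
    handcrafted statistic (histograms, filter energies, color moments,
    translation-invariant shape moments) is insensitive to signed
    spatial structure, so the class is recoverable only by learned
    convolutional features.
    """
    rng = np.random.default_rng(seed)
    n = config.patch_size
    V = config.stain_matrix_true
    margin = int(config.mitosis_radius + 4)

    # Eosin background with smooth spatial variation (stroma texture).
    gx = rng.normal(0, 1, size=(8, 8))
    coarse = np.kron(gx, np.ones((n // 8 + 1, n // 8 + 1)))[:n, :n]
    c_eos = config.background_conc * (1.0 + 0.25 * np.tanh(coarse))
    c_hem = np.zeros((n, n))

    # in subtle mode the planted figure is an ordinary nucleus, so keep
    # the total nucleus count identical across classes
    n_background = config.n_nuclei - (1 if (label and config.subtle) else 0)
    for _ in range(max(n_background, 0)):
        cx, cy = rng.uniform(4, n - 4, size=2)
        rx = config.nucleus_radius * rng.uniform(0.75, 1.25)
        ry = config.nucleus_radius * rng.uniform(0.75, 1.25)
        _paint_ellipse(c_hem, cx, cy, rx, ry, rng.uniform(0, np.pi), config.nucleus_conc)

    centroids = []
    if label:
        cx = rng.uniform(margin, n - margin)
        cy = rng.uniform(margin, n - margin)
        if config.subtle:
            # the designated figure is indistinguishable from any nucleus
            _paint_ellipse(c_hem, cx, cy, config.nucleus_radius,
                           config.nucleus_radius * 0.9,
                           rng.uniform(0, np.pi), config.nucleus_conc)
        else:
            _paint_star(
                c_hem, cx, cy, config.mitosis_radius,
                config.nucleus_conc * config.mitosis_contrast, rng,
            )
        centroids.append((float(cx), float(cy)))

    if config.subtle:
        # Class signal: the sign of a faint stain-ratio (hue) ramp that
        # leaves the gray image unchanged to first order.  Hematoxylin
        # and eosin background densities are modulated in opposition
        # along the direction that cancels d(R+G+B)/dx, so gray-level
        # descriptors see nothing; the two classes are mirror images in
        # distribution, so pooled color statistics match as well.  Only
        # features sensitive to signed spatial structure in color -
        # learned convolutions - can read the label.
        base_hem = 0.12
        c0 = np.array([base_hem, config.background_conc])
        I_nom = np.power(10.0, -(V @ c0))
        w = I_nom * np.log(10.0)
        # gray-gradient direction per unit concentration change
        gH, gE = float(w @ V[:, 0]), float(w @ V[:, 1])
        dE = 0.3 * config.background_conc
        dH = dE * gE / gH       # cancels the gray slope
        ramp = (np.arange(n) - (n - 1) / 2.0) / n   # in [-0.5, 0.5)
        sign = 1.0 if label else -1.0
        c_eos = c_eos + sign * dE * ramp[None, :]
        c_hem = c_hem + base_hem - sign * dH * ramp[None, :]

    # nuclei exclude cytoplasmic eosin: the angular-extreme stain
    # estimator relies on near-pure pixels of each stain existing
    # (threshold sits between the background hematoxylin level and the
    # weakest painted nucleus)
    c_eos = np.where(c_hem > 0.3, 0.0, c_eos)

    S = np.stack([c_hem, c_eos], axis=-1)            # H x W x 2
    od = S @ V.T                                      # H x W x 3
    if config.noise_sd > 0:
        od = od + rng.normal(0, config.noise_sd, size=od.shape)
    od = np.maximum(od, 0.0)
    image = np.power(10.0, -od)
    image = np.clip(image, 1e-4, 1.0)

    mask = np.zeros((n, n), dtype=np.uint8)
    for cx, cy in centroids:
        mask |= _disk_mask(mask.shape, cx, cy, config.roi_radius).astype(np.uint8)
    return LabeledPatch(image=image, label=int(label), centroids=centroids,
                        mask_true=mask)


def generate_dataset(config: SynthConfig) -> list:
    """Draw ``n_patches`` patches; labels ~ Bernoulli(mitosis_prob),
    pseudo-HPF identities assigned round-robin."""
    if config.n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    rng = np.random.default_rng(config.seed)
    labels = rng.random(config.n_patches) < config.mitosis_prob
    seeds = rng.integers(0, 2**31 - 1, size=config.n_patches)
    patches = []
    for i in range(config.n_patches):
        p = generate_patch(config, int(labels[i]), int(seeds[i]))
        p.hpf_id = i % config.n_hpfs
        p.patch_id = i
        patches.append(p)
    return patches


# ---------------------------------------------------------------------------
# Labeled feature tables (test bed for wrapper feature selection)
# ---------------------------------------------------------------------------


def generate_feature_table(n_samples, n_informative, n_noise, effect_size, seed,
                           ) -> FeatureTable:
    """Class-conditional Gaussian table with a known informative subset.

    Informative columns have class means separated by ``effect_size``
    standard deviations; noise columns are class-independent N(0,1).
    """
    if n_informative < 1:
        raise ValueError("n_informative must be >= 1")
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_samples, dtype=int)
    labels[n_samples // 2 :] = 1
    rng.shuffle(labels)
    d = n_informative + n_noise
    X = rng.normal(0, 1, size=(n_samples, d))
    X[:, :n_informative] += effect_size * labels[:, None]
    block_index = {"informative": (0, n_informative),
                   "noise": (n_informative, d)}
    return FeatureTable(matrix=X, labels=labels,
                        informative_idx=np.arange(n_informative),
                        block_index=block_index)


# ---------------------------------------------------------------------------
# Disk formats (PNG patches, CSV annotations, TSV tables + JSON sidecar)
# ---------------------------------------------------------------------------


def write_dataset(patches, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patches:
        img8 = (np.clip(p.image, 0, 1) * 255).round().astype(np.uint8)
        Image.fromarray(img8).save(out / f"patch_{p.patch_id:05d}.png")
        Image.fromarray(p.mask_true * 255).save(out / f"mask_{p.patch_id:05d}.png")
        if p.centroids:
            for x, y in p.centroids:
                rows.append((p.patch_id, p.hpf_id, p.label, x, y))
        else:
            rows.append((p.patch_id, p.hpf_id, p.label, np.nan, np.nan))
    pd.DataFrame(rows, columns=["patch_id", "hpf_id", "label", "x", "y"]).to_csv(
        out / "annotations.csv", index=False
    )
    return out / "annotations.csv"


def write_feature_table(table: FeatureTable, tsv_path):
    tsv_path = Path(tsv_path)
    df = pd.DataFrame(table.matrix,
                      columns=[f"f{i}" for i in range(table.matrix.shape[1])])
    df.insert(0, "label", table.labels)
    df.to_csv(tsv_path, sep="\t", index=False)
    sidecar = {
        "block_index": {k: list(v) for k, v in table.block_index.items()},
        "informative_idx": [int(i) for i in np.asarray(table.informative_idx)],
    }
    tsv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return tsv_path


def read_feature_table(tsv_path) -> FeatureTable:
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t")
    side = json.loads(tsv_path.with_suffix(".json").read_text())
    return FeatureTable(
        matrix=df.drop(columns="label").to_numpy(float),
        labels=df["label"].to_numpy(int),
        informative_idx=np.array(side.get("informative_idx", []), dtype=int),
        block_index={k: tuple(v) for k, v in side["block_index"].items()},
    )


def with_seed(config: SynthConfig, seed: int) -> SynthConfig:
    return replace(config, seed=seed)


def desk_config(patch_size=64, n_patches=100, seed=0, mitosis_prob=0.5,
                subtle=False, n_nuclei=None) -> SynthConfig:
    """Desk-scale study conditions used by the end-to-end runs and tests:
    nucleus / mitotic-figure / ROI radii proportioned to the patch size
    (4 / 5 / 6 px at 64-px patches)."""
    s = patch_size / 64.0
    return SynthConfig(
        patch_size=patch_size, n_patches=n_patches, seed=seed,
        mitosis_prob=mitosis_prob, subtle=subtle,
        n_nuclei=n_nuclei if n_nuclei is not None else (7 if subtle else 8),
        nucleus_radius=4.0 * s, mitosis_radius=5.0 * s,
        roi_radius=max(3, round(6 * s)),
    )
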