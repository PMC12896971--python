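"""Metrics, HPF-disjoint cross-validation, and the ablation harness.

The anti-leakage rule of the benchmark protocol is enforced here: folds
partition high-power-field (HPF) identities, never individual patches,
so no HPF contributes patches to more than one fold.

Metrics follow the standard confusion-count definitions; any metric
whose denominator vanishes is reported as *undefined* (NaN), never
silently zero.  Markedness = precision + NPV - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import nn
from .feat_deep import MIV4Config, extract_deep_features, train_miv4
from .feat_hand import handcrafted_vector
from .preprocess import preprocess_patch
from .quartet import QuartetConfig, quartet_forward, train_quartet
from .roi import FCNConfig, train_fcn
from .select import SOAConfig, select_features
from .synth import FeatureTable

__all__ = [
    "ConfusionCounts", "MetricSet", "compute_metrics", "confusion_from_pairs",
    "kfold_by_hpf", "PipelineSpec", "extract_features", "run_fold",
    "cross_validate", "run_ablation", "ABLATION_ROWS",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.TP + self.TN + self.FP + self.FN == 0:
            raise ValueError("empty confusion matrix")


@dataclass
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    fnr: float
    fpr: float
    fmi: float
    markedness: float

    def as_dict(self):
        return dict(self.__dict__)


def _safe(num, den):
    return num / den if den > 0 else float("nan")


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """The eight confusion-derived metrics.

    accuracy (TP+TN)/total; sensitivity TP/(TP+FN); specificity
    TN/(TN+FP); F = 2PR/(P+R); FNR = 1 - sensitivity; FPR = 1 -
    specificity; FMI = sqrt(precision * sensitivity); markedness =
    precision + NPV - 1.
    """
    total = c.TP + c.TN + c.FP + c.FN
    sens = _safe(c.TP, c.TP + c.FN)
    spec = _safe(c.TN, c.TN + c.FP)
    prec = _safe(c.TP, c.TP + c.FP)
    npv = _safe(c.TN, c.TN + c.FN)
    f = _safe(2 * prec * sens, prec + sens) if np.isfinite(prec) and np.isfinite(sens) else float("nan")
    fmi = float(np.sqrt(prec * sens)) if np.isfinite(prec) and np.isfinite(sens) else float("nan")
    mark = prec + npv - 1 if np.isfinite(prec) and np.isfinite(npv) else float("nan")
    return MetricSet(
        accuracy=(c.TP + c.TN) / total,
        sensitivity=sens, specificity=spec, precision=prec, f_measure=f,
        fnr=_safe(c.FN, c.FN + c.TP), fpr=_safe(c.FP, c.FP + c.TN),
        fmi=fmi, markedness=mark,
    )


def confusion_from_pairs(labels, predictions) -> ConfusionCounts:
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    return ConfusionCounts(
        TP=int(np.sum((y == 1) & (p == 1))), TN=int(np.sum((y == 0) & (p == 0))),
        FP=int(np.sum((y == 0) & (p == 1))), FN=int(np.sum((y == 1) & (p == 0))),
    )


def kfold_by_hpf(dataset, k, seed=0):
    """HPF-disjoint folds: partition hpf_ids, fold sizes within 1 HPF.

    Returns a list of (train_indices, test_indices) over patches.
    """
    hpfs = sorted({p.hpf_id for p in dataset})
    if k > len(hpfs):
        raise ValueError(f"k={k} exceeds the {len(hpfs)} distinct HPFs")
    rng = np.random.default_rng(seed)
    hpfs = list(rng.permutation(hpfs))
    groups = [hpfs[i::k] for i in range(k)]
    splits = []
    for g in groups:
        test = [i for i, p in enumerate(dataset) if p.hpf_id in g]
        train = [i for i, p in enumerate(dataset) if p.hpf_id not in g]
        splits.append((np.array(train), np.array(test)))
    return splits


# ---------------------------------------------------------------------------
# Stage pipeline (shared by cross-validation, ablation and the CLI)
# ---------------------------------------------------------------------------


@dataclass
class PipelineSpec:
    """Desk-scale stage configuration with module toggles.

    The toggles realize the ablation rows: each removes one module while
    holding everything else fixed.
    """

    use_preprocess: bool = True
    use_roi: bool = True
    use_deep: bool = True
    use_select: bool = True
    classifier: str = "quartet"   # or "simple_cnn"
    select_lam: float = 0.002     # pipeline sparsity weight (milder than the
                                  # table-selection default: blocks are redundant)
    fcn: FCNConfig = field(default_factory=lambda: FCNConfig(
        depth=2, base_filters=8, lr=3e-3, batch=8, epochs=6, restarts=0))
    miv4: MIV4Config = field(default_factory=lambda: MIV4Config(
        input_size=32, feature_dim=16, lr=3e-3, batch=16, epochs=12, patience=6))
    soa: SOAConfig = field(default_factory=lambda: SOAConfig(
        pop_size=20, max_iter=30, bounds=(-4.0, 4.0)))
    quartet: QuartetConfig = field(default_factory=lambda: QuartetConfig(
        lr=3e-3, batch=16, epochs=25, early_stopping_patience=8,
        use_patch=True))


def _resize_to(img, size):
    if img.shape[0] == size:
        return img
    return resize(img, (size, size, img.shape[2]), anti_aliasing=True,
                  preserve_range=True)


class SimpleCNN:
    """Plain small CNN classifier, the ablation comparator for the
    quartet (conv-pool x2, dense, softmax)."""

    def __init__(self, side, seed=0, filters=(6, 8), fc=32, lr=3e-3,
                 batch=16, epochs=25):
        rng = np.random.default_rng(seed)
        self.lr, self.batch, self.epochs = lr, batch, epochs
        self.params = {}
        c_in, s = 3, side
        for i, f in enumerate(filters):
            self.params[f"c{i}_w"] = nn.he_init(rng, (f, c_in, 3, 3), c_in * 9)
            self.params[f"c{i}_b"] = nn.parameter(np.zeros(f))
            c_in, s = f, s // 4
        self.flat = c_in * s * s
        self.params["fc_w"] = nn.glorot_init(rng, (self.flat, fc), self.flat, fc)
        self.params["fc_b"] = nn.parameter(np.zeros(fc))
        self.params["out_w"] = nn.glorot_init(rng, (fc, 2), fc, 2)
        self.params["out_b"] = nn.parameter(np.zeros(2))
        self.n_filters = len(filters)

    def forward(self, images):
        t = nn.constant(np.asarray(images, float).transpose(0, 3, 1, 2))
        for i in range(self.n_filters):
            t = nn.conv2d(t, self.params[f"c{i}_w"], self.params[f"c{i}_b"])
            t = nn.avg_pool2d(t.relu(), 4)
        t = t.reshape(t.shape[0], self.flat)
        t = (t @ self.params["fc_w"] + self.params["fc_b"]).relu()
        return t @ self.params["out_w"] + self.params["out_b"]

    def fit(self, images, labels, seed=0):
        rng = np.random.default_rng(seed)
        opt = nn.Adam(self.params.values(), lr=self.lr)
        n = len(labels)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for s in range(0, n, self.batch):
                idx = order[s : s + self.batch]
                loss = nn.softmax_cross_entropy(self.forward(images[idx]),
                                                labels[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
        return self

    def predict(self, images):
        return self.forward(images).data.argmax(axis=1)


def extract_features(patches, masks, deep_model, spec: PipelineSpec):
    """Handcrafted (+ deep) feature table for a list of images.

    ``masks[i]`` may be None (shape blocks fall back to zero).
    """
    rows, block_index = [], None
    for img, mask in zip(patches, masks):
        vec, block_index = handcrafted_vector(img, mask)
        rows.append(vec)
    X = np.stack(rows)
    if deep_model is not None:
        small = np.stack([_resize_to(p, spec.miv4.input_size) for p in patches])
        deep = extract_deep_features(small, deep_model)
        start = X.shape[1]
        block_index = dict(block_index)
        block_index["deep"] = (start, start + deep.shape[1])
        X = np.concatenate([X, deep], axis=1)
    return X, block_index


def run_fold(dataset, train_idx, test_idx, spec: PipelineSpec, seed=0,
             _cache=None):
    """Train all enabled stages on the training patches and classify the
    test patches.  Returns (ConfusionCounts, details dict).

    Per-stage seeds derive from ``seed`` by fixed offsets, so disabling
    one stage leaves every other stage's randomness untouched (the
    ablation harness relies on this to hold all else fixed).  ``_cache``
    (a dict) lets the ablation harness share identical stage outputs
    between configurations that only differ downstream.
    """
    cache = _cache if _cache is not None else {}
    order = list(np.concatenate([train_idx, test_idx]))

    key = ("images", spec.use_preprocess)
    if key not in cache:
        imgs = {}
        for i in order:
            img = dataset[i].image
            if spec.use_preprocess:
                img, _ = preprocess_patch(img)
            imgs[i] = img
        cache[key] = imgs
    images = cache[key]

    # ROI stage: predicted masks drive the shape descriptors.  Masks are
    # predicted out-of-fold (each training half by the FCN trained on the
    # other half, test patches by a half-trained model as well) so the
    # mask-derived features have the same in/out-of-sample character on
    # the training and test sides; in-sample masks would let the feature
    # selector favor shape features that do not transfer across folds.
    key = ("masks", spec.use_preprocess, spec.use_roi)
    if key not in cache:
        masks = {i: None for i in images}
        if spec.use_roi:
            half_rng = np.random.default_rng(seed + 11)
            # stratified halves: both must contain positive masks
            pos = [i for i in train_idx if dataset[i].label == 1]
            neg = [i for i in train_idx if dataset[i].label == 0]
            half_a, half_b = [], []
            for group in (pos, neg):
                perm = half_rng.permutation(group)
                half_a.extend(perm[: len(perm) // 2])
                half_b.extend(perm[len(perm) // 2 :])
            half_a, half_b = np.array(half_a), np.array(half_b)
            fcn_a, _ = train_fcn([dataset[i] for i in half_a],
                                 replace(spec.fcn, seed=seed + 1))
            fcn_b, _ = train_fcn([dataset[i] for i in half_b],
                                 replace(spec.fcn, seed=seed + 101))
            for model, targets in ((fcn_a, list(half_b) + list(test_idx)),
                                   (fcn_b, list(half_a))):
                probs = model.forward(np.stack([images[i] for i in targets]))
                for j, i in enumerate(targets):
                    masks[i] = (probs.data[j, 1] > 0.5).astype(np.uint8)
        cache[key] = masks
    masks = cache[key]

    key = ("deep", spec.use_preprocess, spec.use_deep)
    if key not in cache:
        deep_model = None
        if spec.use_deep:
            miv4_cfg = replace(spec.miv4, seed=seed + 2)
            small = np.stack([_resize_to(images[i], miv4_cfg.input_size)
                              for i in train_idx])
            deep_model, _ = train_miv4(
                small, [dataset[i].label for i in train_idx], miv4_cfg)
        cache[key] = deep_model
    deep_model = cache[key]

    key = ("features", spec.use_preprocess, spec.use_roi, spec.use_deep)
    if key not in cache:
        cache[key] = extract_features(
            [images[i] for i in order], [masks[i] for i in order],
            deep_model, spec)
    X, block_index = cache[key]
    pos = {i: j for j, i in enumerate(order)}
    Xtr = X[[pos[i] for i in train_idx]]
    Xte = X[[pos[i] for i in test_idx]]
    ytr = np.array([dataset[i].label for i in train_idx])
    yte = np.array([dataset[i].label for i in test_idx])

    keep = np.ones(X.shape[1], dtype=bool)
    if spec.use_select:
        table = FeatureTable(matrix=Xtr, labels=ytr,
                             informative_idx=np.array([]),
                             block_index=block_index)
        soa_cfg = replace(spec.soa, seed=seed + 3)
        mask = select_features(table, soa_cfg, lam=spec.select_lam)
        keep = mask.bits.astype(bool)
        # the sequence branches need at least seq_len inputs: top up a
        # degenerately small mask with the strongest remaining columns
        # (standardized class-mean difference on the training split)
        floor = spec.quartet.seq_len
        if keep.sum() < floor:
            d = np.abs(Xtr[ytr == 1].mean(0) - Xtr[ytr == 0].mean(0))
            d = d / np.maximum(Xtr.std(0), 1e-9)
            d[keep] = np.inf
            for j in np.argsort(-d)[:floor]:
                keep[j] = True
    Xtr, Xte = Xtr[:, keep], Xte[:, keep]
    mu, sd = Xtr.mean(axis=0), np.maximum(Xtr.std(axis=0), 1e-9)
    Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd

    if spec.classifier == "simple_cnn":
        side = images[order[0]].shape[0]
        clf = SimpleCNN(side, seed=seed + 4)
        clf.fit(np.stack([images[i] for i in train_idx]), ytr, seed=seed + 5)
        pred = clf.predict(np.stack([images[i] for i in test_idx]))
    else:
        q_cfg = replace(spec.quartet, seed=seed + 4,
                        patch_size=images[order[0]].shape[0])
        tr_patches = np.stack([images[i] for i in train_idx]) \
            if q_cfg.use_patch else None
        te_patches = np.stack([images[i] for i in test_idx]) \
            if q_cfg.use_patch else None
        model, _ = train_quartet(Xtr, ytr, q_cfg, patches=tr_patches)
        pred = quartet_forward(model, Xte, te_patches).argmax(axis=1)

    counts = confusion_from_pairs(yte, pred)
    return counts, {"n_features": int(keep.sum()), "block_index": block_index}


TABLE3_COLUMNS = ["sensitivity", "specificity", "precision", "accuracy",
                  "f_measure", "fpr", "fnr"]


def cross_validate(dataset, spec: PipelineSpec, k=5, seed=0):
    """HPF-disjoint k-fold cross-validation of the full pipeline.

    Returns a DataFrame with one row per fold plus an 'Average' row, in
    the five-fold report column layout.
    """
    splits = kfold_by_hpf(dataset, k, seed=seed)
    rows = []
    for f, (tr, te) in enumerate(splits):
        counts, _ = run_fold(dataset, tr, te, spec, seed=seed + 1000 * (f + 1))
        m = compute_metrics(counts).as_dict()
        rows.append({"fold": f"Fold-{f + 1}", **{c: m[c] for c in TABLE3_COLUMNS}})
    avg = {c: float(np.mean([r[c] for r in rows])) for c in TABLE3_COLUMNS}
    rows.append({"fold": "Average", **avg})
    return pd.DataFrame(rows)


def deep_only_regime(seed, n_patches=140):
    """Dataset + stage spec for the constructed ablation regime in which
    only the learned deep features carry the class signal.

    The subtle synthetic mode encodes the label as the sign of a faint,
    gray-neutral stain-ratio ramp; every pooled handcrafted statistic is
    blind to signed spatial structure, and the ROI supervision marks an
    ordinary nucleus, so predicted masks carry no class signal either.
    The deep network gets a larger stem and input size here because the
    cue is spatially extended rather than focal; the classifier runs in
    vector-only mode so the comparison isolates the feature table.
    """
    from .synth import desk_config, generate_dataset

    dataset = generate_dataset(desk_config(
        patch_size=64, n_patches=n_patches, seed=seed, subtle=True))
    spec = PipelineSpec(
        fcn=FCNConfig(depth=2, base_filters=8, lr=3e-3, batch=8, epochs=4,
                      restarts=0),
        miv4=MIV4Config(input_size=64, stem_channels=(12, 16, 24),
                        feature_dim=32, lr=3e-3, epochs=30, patience=15),
        quartet=QuartetConfig(lr=3e-3, batch=16, epochs=25,
                              early_stopping_patience=10, use_patch=False),
    )
    return dataset, spec


ABLATION_ROWS = [
    "Without Preprocessing",
    "Without Modified FCN (ROI)",
    "Without Deep Feature Extraction",
    "Without SA-SOA Optimization",
    "Without Mito-Quartet (Simple CNN)",
    "Proposed (Full Model)",
]

TABLE4_COLUMNS = ["precision", "sensitivity", "f_measure", "specificity",
                  "accuracy", "fpr", "fnr"]


def run_ablation(dataset, base_spec: PipelineSpec | None = None, seed=0,
                 test_frac=0.3):
    """Evaluate the six ablation configurations on one HPF-disjoint split.

    Each row removes or replaces exactly one module of ``base_spec``;
    'Recall' in the emitted table is sensitivity.
    """
    spec = base_spec or PipelineSpec()
    hpfs = sorted({p.hpf_id for p in dataset})
    rng = np.random.default_rng(seed)
    hpfs = list(rng.permutation(hpfs))
    n_test = max(int(round(test_frac * len(hpfs))), 1)
    test_h = set(hpfs[:n_test])
    te = np.array([i for i, p in enumerate(dataset) if p.hpf_id in test_h])
    tr = np.array([i for i, p in enumerate(dataset) if p.hpf_id not in test_h])

    variants = [
        replace(spec, use_preprocess=False),
        replace(spec, use_roi=False),
        replace(spec, use_deep=False),
        replace(spec, use_select=False),
        replace(spec, classifier="simple_cnn"),
        spec,
    ]
    rows = []
    cache = {}
    for name, var in zip(ABLATION_ROWS, variants):
        counts, _ = run_fold(dataset, tr, te, var, seed=seed + 17, _cache=cache)
        m = compute_metrics(counts).as_dict()
        rows.append({"configuration": name,
                     **{("recall" if c == "sensitivity" else c): m[c]
                        for c in TABLE4_COLUMNS}})
    return pd.DataFrame(rows)
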