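"""Deep-feature extraction with a reduced Modified Inception V4 (M-IV4).

Topology-faithful, capacity-reduced: a convolutional stem, a feature
reuse path (1x1 convolution on the 3rd stem convolution's output,
concatenated with the trunk), three inception blocks with identity
residual shortcuts, reduction (pooling) blocks between them, and an
auxiliary softmax head after a configurable block for regularization
and gradient flow.  The embedding is the global-average-pooled pre-logit
activation.  Channel counts are configurable; the defaults are sized
for CPU-scale training, and the publication-scale 512-filter reuse
projection is accepted by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["MIV4Config", "MIV4", "build_miv4", "extract_deep_features",
           "train_miv4"]


@dataclass
class MIV4Config:
    input_size: int = 32
    stem_channels: tuple = (8, 12, 16)
    reuse_projection_filters: int = 64   # publication scale: 512
    n_inception_blocks: int = 3
    aux_after_block: int = 2             # 1-based; head after this block
    aux_loss_weight: float = 0.3
    feature_dim: int = 32
    n_classes: int = 2
    lr: float = 0.0001
    batch: int = 16
    epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.aux_after_block < self.n_inception_blocks:
            raise ValueError("aux_after_block must be >= 1 and < n_inception_blocks")
        if self.feature_dim < 8:
            raise ValueError("feature_dim must be >= 8")
        if len(self.stem_channels) < 3:
            raise ValueError("stem needs >= 3 convolutions")


class MIV4:
    """Reduced Modified-Inception-V4 feature network."""

    def __init__(self, config: MIV4Config):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.params = {}
        c_in = 3
        for i, c_out in enumerate(config.stem_channels):
            self._conv(rng, f"stem{i}", c_in, c_out)
            c_in = c_out
        self.trunk_channels = c_in
        for b in range(config.n_inception_blocks):
            self._inception(rng, f"inc{b}", c_in)
        self._conv(rng, "reuse", config.stem_channels[2],
                   config.reuse_projection_filters, k=1)
        self._conv(rng, "embed",
                   c_in + config.reuse_projection_filters, config.feature_dim, k=1)
        self._dense(rng, "head", config.feature_dim, config.n_classes)
        self._dense(rng, "aux", c_in, config.n_classes)

    # -- layer factories -------------------------------------------------
    def _conv(self, rng, name, c_in, c_out, k=3):
        self.params[f"{name}_w"] = nn.he_init(rng, (c_out, c_in, k, k), c_in * k * k)
        self.params[f"{name}_b"] = nn.parameter(np.zeros(c_out))

    def _dense(self, rng, name, d_in, d_out):
        self.params[f"{name}_w"] = nn.glorot_init(rng, (d_in, d_out), d_in, d_out)
        self.params[f"{name}_b"] = nn.parameter(np.zeros(d_out))

    def _inception(self, rng, name, c):
        half = max(c // 2, 1)
        self._conv(rng, f"{name}_b1", c, half, k=1)     # 1x1 branch
        self._conv(rng, f"{name}_b3", c, half, k=3)     # 3x3 branch
        self._conv(rng, f"{name}_bp", c, half, k=1)     # pooled branch
        self._conv(rng, f"{name}_merge", 3 * half, c, k=1)

    def parameters(self):
        return list(self.params.values())

    # -- forward ----------------------------------------------------------
    def _apply_conv(self, t, name):
        return nn.conv2d(t, self.params[f"{name}_w"], self.params[f"{name}_b"])

    def _apply_dense(self, t, name):
        return t @ self.params[f"{name}_w"] + self.params[f"{name}_b"]

    def _inception_forward(self, t, name):
        b1 = self._apply_conv(t, f"{name}_b1").relu()
        b3 = self._apply_conv(t, f"{name}_b3").relu()
        pooled = nn.avg_pool2d(t, 2)
        pooled = nn.upsample_nearest(pooled, 2)
        bp = self._apply_conv(pooled, f"{name}_bp").relu()
        merged = self._apply_conv(nn.concat([b1, b3, bp], axis=1), f"{name}_merge")
        return merged + t  # identity residual shortcut

    def forward(self, images):
        """images (N, H, W, 3) -> (embedding, logits, aux_logits)."""
        x = np.asarray(images, dtype=float)
        if x.shape[1] != self.config.input_size:
            raise ValueError(
                f"input size {x.shape[1]} != configured {self.config.input_size}")
        t = nn.constant(x.transpose(0, 3, 1, 2))
        t = self._apply_conv(t, "stem0").relu()
        t = nn.max_pool2d(t, 2)
        t = self._apply_conv(t, "stem1").relu()
        stem3 = self._apply_conv(t, "stem2").relu()
        t = nn.max_pool2d(stem3, 2)
        aux_logits = None
        for b in range(self.config.n_inception_blocks):
            t = self._inception_forward(t, f"inc{b}")
            if b + 1 == self.config.aux_after_block:
                gap = t.mean(axis=(2, 3))
                aux_logits = self._apply_dense(gap, "aux")
            if b + 1 < self.config.n_inception_blocks:
                t = nn.max_pool2d(t, 2)  # reduction block
        reuse = self._apply_conv(stem3, "reuse").relu()
        factor = reuse.shape[2] // t.shape[2]
        if factor > 1:
            reuse = nn.avg_pool2d(reuse, factor)
        t = nn.concat([t, reuse], axis=1)
        t = self._apply_conv(t, "embed").relu()
        embedding = t.mean(axis=(2, 3))
        logits = self._apply_dense(embedding, "head")
        return embedding, logits, aux_logits


def build_miv4(config: MIV4Config) -> MIV4:
    return MIV4(config)


def extract_deep_features(patches, model: MIV4):
    """Deterministic feed-forward embeddings; (N, feature_dim) or a
    single vector for a single patch."""
    arr = np.asarray(patches, dtype=float)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    emb, _, _ = model.forward(arr)
    return emb.data[0] if single else emb.data


def train_miv4(patches, labels, config: MIV4Config, val_frac=0.2, log=None):
    """Train with main + weighted auxiliary cross-entropy, Adam, and
    early stopping on validation loss.  Returns (model, history)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    images = np.stack([np.asarray(p, dtype=float) for p in patches])
    model = MIV4(config)
    history = {"loss": [], "val_loss": [], "val_acc": []}
    if config.epochs == 0:
        return model, history
    rng = np.random.default_rng(config.seed + 1)
    n = len(labels)
    order = rng.permutation(n)
    n_val = max(int(round(val_frac * n)), 2)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    opt = nn.Adam(model.parameters(), lr=config.lr)
    best_val, best_state, since = np.inf, None, 0
    for epoch in range(config.epochs):
        perm = rng.permutation(len(tr_idx))
        losses = []
        for start in range(0, len(tr_idx), config.batch):
            idx = tr_idx[perm[start : start + config.batch]]
            _, logits, aux = model.forward(images[idx])
            loss = nn.softmax_cross_entropy(logits, labels[idx])
            if aux is not None and config.aux_loss_weight > 0:
                loss = loss + config.aux_loss_weight * nn.softmax_cross_entropy(
                    aux, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        _, vlogits, _ = model.forward(images[val_idx])
        vloss = float(nn.softmax_cross_entropy(vlogits, labels[val_idx]).data)
        vacc = float(np.mean(vlogits.data.argmax(axis=1) == labels[val_idx]))
        history["loss"].append(float(np.mean(losses)))
        history["val_loss"].append(vloss)
        history["val_acc"].append(vacc)
        if log:
            log(f"miv4 epoch {epoch}: loss={history['loss'][-1]:.4f} "
                f"val_loss={vloss:.4f} val_acc={vacc:.3f}")
        if vloss < best_val - 1e-6:
            best_val, since = vloss, 0
            best_state = {k: p.data.copy() for k, p in model.params.items()}
        else:
            since += 1
            if since > config.patience:
                break
    if best_state is not None:
        for k, p in model.params.items():
            p.data = best_state[k]
    return model, history
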