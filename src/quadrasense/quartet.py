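"""The Mito-Quartet classifier: CNN + dual-GRU RNN + self-attention +
Bi-LSTM, integrated through concatenation and fully connected layers
into a two-class softmax.

The CNN branch consumes the (preprocessed) patch; the sequence branches
consume the selected feature vector, chunked into ``seq_len`` contiguous
frames.  The recurrent cells follow their printed formulations exactly:
the GRU mixes previous and candidate state through the ``q`` gate
(``v_t = (1 - q) v_prev + q v_hat``), and the LSTM output gate sees the
*current* cell state among its inputs (a peephole-style term), with no
biases by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "QuartetConfig", "GRUParams", "AttentionParams", "LSTMParams",
    "vector_to_sequence", "gru_cell", "lstm_cell", "self_attention",
    "Quartet", "quartet_forward", "train_quartet",
]


@dataclass
class QuartetConfig:
    cnn_filters: tuple = (6, 8)
    cnn_pool: int = 4
    rnn_hidden: int = 16
    attn_dim: int = 16
    lstm_hidden: int = 16
    seq_len: int = 8
    fc_size: int = 64
    n_classes: int = 2
    patch_size: int = 64
    use_patch: bool = True
    lr: float = 0.0001
    batch: int = 16
    epochs: int = 100
    early_stopping_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.seq_len < 2:
            raise ValueError("seq_len must be >= 2")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass
class GRUParams:
    Wq: np.ndarray  # (hidden, hidden + input)
    Wu: np.ndarray
    Wv: np.ndarray
    bq: np.ndarray
    bu: np.ndarray
    bv: np.ndarray


@dataclass
class AttentionParams:
    WQ1: np.ndarray  # (width, attn_dim)
    WK1: np.ndarray
    WV1: np.ndarray


@dataclass
class LSTMParams:
    Wi: np.ndarray  # (hidden, hidden + input)
    Wf: np.ndarray
    Wo: np.ndarray  # (hidden, hidden + hidden + input) -- sees c_t
    Wc: np.ndarray


# ---------------------------------------------------------------------------
# Sequence plumbing
# ---------------------------------------------------------------------------


def vector_to_sequence(feature_vector, T):
    """Zero-pad to a multiple of T and split into T contiguous frames."""
    v = np.atleast_2d(np.asarray(feature_vector, dtype=float))
    if v.shape[1] < T:
        raise ValueError("vector shorter than the number of frames")
    width = -(-v.shape[1] // T)
    padded = np.pad(v, ((0, 0), (0, width * T - v.shape[1])))
    seq = padded.reshape(v.shape[0], T, width)
    return seq[0] if np.asarray(feature_vector).ndim == 1 else seq


# ---------------------------------------------------------------------------
# Cells (Tensor-generic; public wrappers take plain arrays)
# ---------------------------------------------------------------------------


def _cat_rows(tensors):
    return nn.concat(tensors, axis=-1)


def _gru_cell(x_t, v_prev, Wq, Wu, Wv, bq, bu, bv):
    vx = _cat_rows([v_prev, x_t])
    q = (vx @ Wq.transpose(1, 0) + bq).sigmoid()
    u = (vx @ Wu.transpose(1, 0) + bu).sigmoid()
    cand_in = _cat_rows([u * v_prev, x_t])
    v_hat = (cand_in @ Wv.transpose(1, 0) + bv).tanh()
    return (1.0 - q) * v_prev + q * v_hat


def gru_cell(x_t, v_prev, params: GRUParams):
    """One GRU step on plain arrays (batched or single)."""
    args = [np.atleast_2d(np.asarray(a, dtype=float)) for a in (x_t, v_prev)]
    out = _gru_cell(
        nn.constant(args[0]), nn.constant(args[1]),
        *[nn.constant(np.atleast_2d(getattr(params, k))) for k in ("Wq", "Wu", "Wv")],
        *[nn.constant(np.atleast_1d(getattr(params, k))) for k in ("bq", "bu", "bv")],
    ).data
    return out[0] if np.asarray(v_prev).ndim <= 1 else out


def _lstm_cell(x_t, h_prev, c_prev, Wi, Wf, Wo, Wc):
    hx = _cat_rows([h_prev, x_t])
    i = (hx @ Wi.transpose(1, 0)).sigmoid()
    f = (hx @ Wf.transpose(1, 0)).sigmoid()
    c = f * c_prev + i * (hx @ Wc.transpose(1, 0)).tanh()
    o = (_cat_rows([c, h_prev, x_t]) @ Wo.transpose(1, 0)).sigmoid()
    h = o * c.tanh()
    return h, c


def lstm_cell(x_t, h_prev, c_prev, params: LSTMParams):
    """One LSTM step on plain arrays; returns (h_t, c_t)."""
    xs = [np.atleast_2d(np.asarray(a, dtype=float)) for a in (x_t, h_prev, c_prev)]
    h, c = _lstm_cell(
        nn.constant(xs[0]), nn.constant(xs[1]), nn.constant(xs[2]),
        *[nn.constant(np.atleast_2d(getattr(params, k)))
          for k in ("Wi", "Wf", "Wo", "Wc")],
    )
    if np.asarray(h_prev).ndim <= 1:
        return h.data[0], c.data[0]
    return h.data, c.data


def _self_attention(y, WQ1, WK1, WV1):
    q = y @ WQ1
    k = y @ WK1
    v = y @ WV1
    scores = q @ k.transpose(0, 2, 1)
    weights = nn.softmax(scores, axis=-1)
    return weights @ v, weights


def self_attention(y, params: AttentionParams):
    """Scaled-free dot-product self-attention on plain arrays.

    ``y``: (T, width) or (N, T, width).  Returns (output, weights);
    each weight row sums to 1.
    """
    arr = np.asarray(y, dtype=float)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    out, w = _self_attention(
        nn.constant(arr),
        *[nn.constant(np.atleast_2d(getattr(params, k)))
          for k in ("WQ1", "WK1", "WV1")],
    )
    if single:
        return out.data[0], w.data[0]
    return out.data, w.data


# ---------------------------------------------------------------------------
# The full model
# ---------------------------------------------------------------------------


class Quartet:
    def __init__(self, config: QuartetConfig, feature_dim):
        self.config = config
        self.feature_dim = int(feature_dim)
        rng = np.random.default_rng(config.seed)
        self.params = {}
        p = self.params
        self.frame_width = -(-self.feature_dim // config.seq_len)

        # CNN branch
        if config.use_patch:
            c_in, side = 3, config.patch_size
        else:
            # smallest square holding the vector whose side survives pooling
            m = config.cnn_pool ** len(config.cnn_filters)
            side = int(np.ceil(np.sqrt(self.feature_dim)))
            side = -(-side // m) * m
            c_in = 1
        self.cnn_in = (c_in, side)
        for i, f in enumerate(config.cnn_filters):
            p[f"cnn{i}_w"] = nn.he_init(rng, (f, c_in, 3, 3), c_in * 9)
            p[f"cnn{i}_b"] = nn.parameter(np.zeros(f))
            c_in = f
            side //= config.cnn_pool
        self.cnn_flat = c_in * side * side
        p["cnn_fc_w"] = nn.glorot_init(rng, (self.cnn_flat, config.fc_size // 2),
                                       self.cnn_flat, config.fc_size // 2)
        p["cnn_fc_b"] = nn.parameter(np.zeros(config.fc_size // 2))

        # dual GRU layers
        h, d = config.rnn_hidden, self.frame_width
        for layer, din in enumerate((d, h)):
            for gate in ("q", "u", "v"):
                p[f"gru{layer}_W{gate}"] = nn.glorot_init(
                    rng, (h, h + din), h + din, h)
                p[f"gru{layer}_b{gate}"] = nn.parameter(np.zeros(h))

        # self-attention over GRU states
        a = config.attn_dim
        for m in ("Q", "K", "V"):
            p[f"attn_W{m}1"] = nn.glorot_init(rng, (h, a), h, a)

        # Bi-LSTM over the frame sequence
        lh = config.lstm_hidden
        for direction in ("fwd", "bwd"):
            p[f"lstm_{direction}_Wi"] = nn.glorot_init(rng, (lh, lh + d), lh + d, lh)
            p[f"lstm_{direction}_Wf"] = nn.glorot_init(rng, (lh, lh + d), lh + d, lh)
            p[f"lstm_{direction}_Wc"] = nn.glorot_init(rng, (lh, lh + d), lh + d, lh)
            p[f"lstm_{direction}_Wo"] = nn.glorot_init(
                rng, (lh, 2 * lh + d), 2 * lh + d, lh)

        width = config.fc_size // 2 + a + 2 * lh
        p["fc1_w"] = nn.glorot_init(rng, (width, config.fc_size), width,
                                    config.fc_size)
        p["fc1_b"] = nn.parameter(np.zeros(config.fc_size))
        p["fc2_w"] = nn.glorot_init(rng, (config.fc_size, config.n_classes),
                                    config.fc_size, config.n_classes)
        p["fc2_b"] = nn.parameter(np.zeros(config.n_classes))

    def parameters(self):
        return list(self.params.values())

    # -- branches ---------------------------------------------------------
    def _cnn_branch(self, x):
        t = x
        for i in range(len(self.config.cnn_filters)):
            t = nn.conv2d(t, self.params[f"cnn{i}_w"], self.params[f"cnn{i}_b"])
            t = nn.avg_pool2d(t.relu(), self.config.cnn_pool)
        t = t.reshape(t.shape[0], self.cnn_flat)
        return (t @ self.params["cnn_fc_w"] + self.params["cnn_fc_b"]).relu()

    def _rnn_branch(self, frames):
        n = frames[0].shape[0]
        states = frames
        for layer in range(2):
            v = nn.constant(np.zeros((n, self.config.rnn_hidden)))
            out = []
            for x_t in states:
                v = _gru_cell(
                    x_t, v,
                    self.params[f"gru{layer}_Wq"], self.params[f"gru{layer}_Wu"],
                    self.params[f"gru{layer}_Wv"], self.params[f"gru{layer}_bq"],
                    self.params[f"gru{layer}_bu"], self.params[f"gru{layer}_bv"],
                )
                out.append(v)
            states = out
        return states  # list of T tensors (n, hidden)

    def _bilstm_branch(self, frames):
        n = frames[0].shape[0]
        finals = []
        for direction, seq in (("fwd", frames), ("bwd", frames[::-1])):
            h = nn.constant(np.zeros((n, self.config.lstm_hidden)))
            c = nn.constant(np.zeros((n, self.config.lstm_hidden)))
            for x_t in seq:
                h, c = _lstm_cell(
                    x_t, h, c,
                    self.params[f"lstm_{direction}_Wi"],
                    self.params[f"lstm_{direction}_Wf"],
                    self.params[f"lstm_{direction}_Wo"],
                    self.params[f"lstm_{direction}_Wc"],
                )
            finals.append(h)
        return _cat_rows(finals)

    # -- forward ----------------------------------------------------------
    def forward(self, features, patches=None):
        """features (N, D); patches (N, H, W, 3) when ``use_patch``.
        Returns softmax class probabilities as a Tensor (N, n_classes)."""
        feats = np.asarray(features, dtype=float)
        n = feats.shape[0]
        seq = vector_to_sequence(feats, self.config.seq_len)  # (N, T, w)
        frames = [nn.constant(seq[:, t]) for t in range(self.config.seq_len)]

        if self.config.use_patch:
            if patches is None:
                raise ValueError("patch input required (use_patch=True)")
            x = nn.constant(np.asarray(patches, float).transpose(0, 3, 1, 2))
        else:
            c, side = self.cnn_in
            img = np.zeros((n, c, side, side))
            flat = img.reshape(n, -1)
            flat[:, : feats.shape[1]] = feats
            x = nn.constant(flat.reshape(n, c, side, side))
        cnn_out = self._cnn_branch(x)

        states = self._rnn_branch(frames)
        y = nn.concat([s.reshape(n, 1, self.config.rnn_hidden) for s in states],
                      axis=1)
        attended, _ = _self_attention(
            y, self.params["attn_WQ1"], self.params["attn_WK1"],
            self.params["attn_WV1"])
        attn_pooled = attended.mean(axis=1)

        bilstm_out = self._bilstm_branch(frames)

        z = _cat_rows([cnn_out, attn_pooled, bilstm_out])
        z = (z @ self.params["fc1_w"] + self.params["fc1_b"]).relu()
        logits = z @ self.params["fc2_w"] + self.params["fc2_b"]
        return logits


def quartet_forward(model: Quartet, features, patches=None):
    """Inference: class probabilities (N, n_classes), rows sum to 1."""
    logits = model.forward(np.atleast_2d(features), patches)
    return nn.softmax(logits, axis=-1).data


def train_quartet(features, labels, config: QuartetConfig, patches=None,
                  val_frac=0.2, log=None):
    """Adam training with early stopping on validation loss and
    inverse-frequency class weights.  Returns (model, history)."""
    feats = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    model = Quartet(config, feats.shape[1])
    history = {"loss": [], "val_loss": [], "val_acc": []}
    if config.epochs == 0:
        return model, history
    rng = np.random.default_rng(config.seed + 1)
    n = len(labels)
    order = rng.permutation(n)
    n_val = max(int(round(val_frac * n)), 2)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    freq = np.bincount(labels, minlength=config.n_classes).astype(float)
    class_w = freq.sum() / np.maximum(freq, 1) / config.n_classes
    opt = nn.Adam(model.parameters(), lr=config.lr)
    best_val, best_state, since = np.inf, None, 0
    pat = np.asarray(patches, float) if patches is not None else None
    for epoch in range(config.epochs):
        perm = rng.permutation(len(tr_idx))
        losses = []
        for start in range(0, len(tr_idx), config.batch):
            idx = tr_idx[perm[start : start + config.batch]]
            logits = model.forward(feats[idx],
                                   pat[idx] if pat is not None else None)
            loss = nn.softmax_cross_entropy(logits, labels[idx],
                                            sample_weight=class_w[labels[idx]])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        vlogits = model.forward(feats[val_idx],
                                pat[val_idx] if pat is not None else None)
        vloss = float(nn.softmax_cross_entropy(vlogits, labels[val_idx]).data)
        vacc = float(np.mean(vlogits.data.argmax(axis=1) == labels[val_idx]))
        history["loss"].append(float(np.mean(losses)))
        history["val_loss"].append(vloss)
        history["val_acc"].append(vacc)
        if log:
            log(f"quartet epoch {epoch}: loss={history['loss'][-1]:.4f} "
                f"val_loss={vloss:.4f} val_acc={vacc:.3f}")
        if vloss < best_val - 1e-6:
            best_val, since = vloss, 0
            best_state = {k: p.data.copy() for k, p in model.params.items()}
        else:
            since += 1
            if since > config.early_stopping_patience:
                break
    if best_state is not None:
        for k, p in model.params.items():
            p.data = best_state[k]
    return model, history
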