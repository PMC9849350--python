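"""The deep memory capsule network.

Architecture, per input channel (MBF windows and/or language-model
embeddings):

1. a *deep memory* encoder — several bidirectional recurrent stacks with
   different hidden sizes run in parallel over the residue sequence, and
   their per-position outputs are concatenated, capturing residue-residue
   context at multiple scales.  Each cell uses three sigmoid gates
   (forget ``f_t``, input-rate ``r_t``, output ``g_t``) on the concatenated
   ``[h_{t-1}, m_t]``; the cell state updates as
   ``M_t = f_t * M_{t-1} + r_t * tanh(W_M [h_{t-1}, m_t] + b_M)`` and the
   emitted hidden state is ``h_t = O_t = g_t * tanh(M_t)``;
2. a capsule layer with routing by agreement — the encoder output is sliced
   into input capsules, pose-transformed (``c_hat_{j|i} = W_ij c_i``),
   coupled through a routing softmax, summed and squashed, with coupling
   logits updated by the agreement ``<c_hat_{j|i}, v_j>`` for a fixed number
   of iterations.

The flattened capsule outputs of all channels are concatenated, standardized
layer-wise, and passed through a dense softmax head giving per-residue
probabilities for {non-binding, binding}.

Training minimizes (optionally class-weighted) cross-entropy with Adam, a
20% stratified validation split at residue level, and early stopping on
validation loss.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _tape as T
from .features import FeatureBundle

logger = logging.getLogger("capsite")

_EPS = 1e-12


# -- configuration -------------------------------------------------------------


@dataclass
class ModelConfig:
    """Hyperparameters of one deep memory capsule network.

    Published candidate grids: hidden sizes {32, 64, 128, 256}, capsule
    counts {32, 64, 128, 256}, capsule dims {3, 5, 7, 10}; the chosen grid
    point was not reported, so the defaults below are this package's declared
    choice, not an inference.
    """

    channels: tuple[str, ...] = ("mbf", "embedding")
    window_size: int = 25
    hidden_sizes: tuple[int, ...] = (64, 128)
    caps_in_dim: int = 8
    caps_count: int = 32
    caps_dim: int = 10
    routing_iters: int = 3
    normalization: str = "standard"  # {none, standard, l2}
    batch_size: int | None = 8  # proteins per gradient update; None = full batch
    learning_rate: float = 1e-3
    epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.2
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not self.channels:
            raise ValueError("at least one channel must be enabled")
        if unknown := set(self.channels) - {"mbf", "embedding"}:
            raise ValueError(f"unknown channels {unknown}")
        if not self.hidden_sizes:
            raise ValueError("at least one recurrent stack is required")
        if self.routing_iters < 1:
            raise ValueError("routing_iters must be >= 1")
        if self.normalization not in {"none", "standard", "l2"}:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        width = 2 * sum(self.hidden_sizes)
        if width % self.caps_in_dim:
            raise ValueError(
                f"encoder output width {width} is not divisible by "
                f"caps_in_dim={self.caps_in_dim}"
            )

    @property
    def encoder_width(self) -> int:
        return 2 * sum(self.hidden_sizes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = list(self.channels)
        d["hidden_sizes"] = list(self.hidden_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["channels"] = tuple(d["channels"])
        d["hidden_sizes"] = tuple(d["hidden_sizes"])
        return cls(**{k: v for k, v in d.items() if k in _CONFIG_FIELDS})


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(ModelConfig)}


# -- parameters ----------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class LstmParams:
    """Gate weights of one memory cell (right-multiplied: (H+F) x H)."""

    W_f: T.Tensor
    W_r: T.Tensor
    W_M: T.Tensor
    W_g: T.Tensor
    b_f: T.Tensor
    b_r: T.Tensor
    b_M: T.Tensor
    b_g: T.Tensor
    hidden_size: int

    @classmethod
    def init(cls, rng, input_size: int, hidden_size: int) -> "LstmParams":
        def w():
            return T.Tensor(
                _glorot(rng, input_size + hidden_size, hidden_size),
                requires_grad=True,
            )

        def b():
            return T.Tensor(np.zeros(hidden_size), requires_grad=True)

        return cls(w(), w(), w(), w(), b(), b(), b(), b(), hidden_size)

    def tensors(self):
        return [
            self.W_f, self.W_r, self.W_M, self.W_g,
            self.b_f, self.b_r, self.b_M, self.b_g,
        ]


@dataclass
class CapsuleLayerParams:
    """Pose-transform tensor W_ij: (in_caps, out_caps, out_dim, in_dim)."""

    W: T.Tensor
    routing_iters: int = 3

    @classmethod
    def init(cls, rng, num_in, in_dim, num_out, out_dim, routing_iters=3):
        if routing_iters < 1:
            raise ValueError("routing_iters must be >= 1")
        scale = np.sqrt(6.0 / (in_dim + out_dim))
        W = rng.uniform(-scale, scale, size=(num_in, num_out, out_dim, in_dim))
        return cls(T.Tensor(W, requires_grad=True), routing_iters)

    @property
    def num_out_capsules(self) -> int:
        return self.W.shape[1]

    @property
    def out_dim(self) -> int:
        return self.W.shape[2]


@dataclass
class ChannelParams:
    stacks: list[tuple[LstmParams, LstmParams]]  # (forward, backward) pairs
    capsule: CapsuleLayerParams

    def tensors(self):
        out = []
        for fwd, bwd in self.stacks:
            out.extend(fwd.tensors())
            out.extend(bwd.tensors())
        out.append(self.capsule.W)
        return out


@dataclass
class ModelParams:
    """All weights of one network plus the configuration that shaped them."""

    channels: dict[str, ChannelParams]
    dense_W: T.Tensor
    dense_b: T.Tensor
    config: ModelConfig
    feature_dims: dict[str, int] = field(default_factory=dict)

    def tensors(self):
        out = []
        for ch in self.channels.values():
            out.extend(ch.tensors())
        out.extend([self.dense_W, self.dense_b])
        return out

    def copy_arrays(self) -> list[np.ndarray]:
        return [t.data.copy() for t in self.tensors()]

    def load_arrays(self, arrays) -> None:
        for t, arr in zip(self.tensors(), arrays, strict=True):
            t.data = arr.copy()


def init_params(
    cfg: ModelConfig, feature_dims: dict[str, int], seed: int | None = None
) -> ModelParams:
    """Glorot-uniform initialization of every weight block, from one seed."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    channels: dict[str, ChannelParams] = {}
    for name in cfg.channels:
        F = feature_dims[name]
        stacks = [
            (LstmParams.init(rng, F, h), LstmParams.init(rng, F, h))
            for h in cfg.hidden_sizes
        ]
        num_in = cfg.encoder_width // cfg.caps_in_dim
        capsule = CapsuleLayerParams.init(
            rng, num_in, cfg.caps_in_dim, cfg.caps_count, cfg.caps_dim,
            cfg.routing_iters,
        )
        channels[name] = ChannelParams(stacks, capsule)
    fused_dim = len(cfg.channels) * cfg.caps_count * cfg.caps_dim
    dense_W = T.Tensor(_glorot(rng, fused_dim, 2), requires_grad=True)
    dense_b = T.Tensor(np.zeros(2), requires_grad=True)
    return ModelParams(channels, dense_W, dense_b, cfg, dict(feature_dims))


# -- core operations -----------------------------------------------------------


def lstm_step(m_t, h_prev, M_prev, params: LstmParams):
    """One memory-cell step; returns ``(h_t, M_t, O_t)`` with ``h_t = O_t``.

    Accepts 1-D vectors or ``(batch, dim)`` matrices, NumPy arrays or tape
    tensors.
    """
    m_t, h_prev, M_prev = map(T.as_tensor, (m_t, h_prev, M_prev))
    z = T.concatenate([h_prev, m_t], axis=m_t.ndim - 1)
    f = T.sigmoid(z @ params.W_f + params.b_f)
    r = T.sigmoid(z @ params.W_r + params.b_r)
    M_tilde = T.tanh(z @ params.W_M + params.b_M)
    M_t = f * M_prev + r * M_tilde
    g = T.sigmoid(z @ params.W_g + params.b_g)
    O_t = g * T.tanh(M_t)
    return O_t, M_t, O_t


def _run_lstm(X: T.Tensor, params: LstmParams) -> T.Tensor:
    """Unroll one direction over a padded batch ``(B, T, F)`` -> ``(B, T, H)``."""
    B, n_steps, _ = X.shape
    h = T.Tensor(np.zeros((B, params.hidden_size)))
    M = T.Tensor(np.zeros((B, params.hidden_size)))
    outputs = []
    for t in range(n_steps):
        h, M, _ = lstm_step(X[:, t, :], h, M, params)
        outputs.append(h.reshape(B, 1, params.hidden_size))
    return T.concatenate(outputs, axis=1)


def deep_memory_forward(X: np.ndarray, stacks) -> np.ndarray:
    """Run the parallel bidirectional stacks over one ``L x F`` sequence.

    Returns the ``L x H`` multi-scale context matrix, ``H = 2 * sum(hidden)``:
    per position, the forward and backward hidden states of every stack,
    concatenated.
    """
    if not stacks:
        raise ValueError("at least one bidirectional stack is required")
    X = np.asarray(X, dtype=float)
    L = X.shape[0]
    Xf = T.Tensor(X[None])
    Xb = T.Tensor(X[::-1][None].copy())
    parts = []
    for fwd, bwd in stacks:
        Hf = _run_lstm(Xf, fwd).data[0]
        Hb = _run_lstm(Xb, bwd).data[0][::-1]
        parts.extend([Hf, Hb])
    return np.concatenate(parts, axis=1)


def squash(s, axis: int = -1):
    """Capsule nonlinearity ``v = (|s|^2 / (1 + |s|^2)) * s / |s|``.

    Total on finite input; returns the zero vector at ``s = 0``.
    """
    s = T.as_tensor(s)
    n2 = (s * s).sum(axis=axis, keepdims=True)
    scale = n2 / (1.0 + n2) / (n2 + _EPS) ** 0.5
    return s * scale


def routing_softmax(b, axis: int = -1):
    """Coupling coefficients from routing logits (max-shifted softmax)."""
    return T.softmax(T.as_tensor(b), axis=axis)


def dynamic_routing(caps_in, params: CapsuleLayerParams):
    """Routing by agreement.

    ``caps_in``: ``(N, num_in, in_dim)`` input capsule poses (a single
    ``(num_in, in_dim)`` matrix is promoted to a batch of one).  Logits start
    at zero; each iteration computes couplings, the weighted vote sum, the
    squashed output, and adds the agreement ``<c_hat_{j|i}, v_j>`` to the
    logits.  Returns ``(N, num_out, out_dim)`` (or 2-D for 2-D input).
    """
    if params.routing_iters < 1:
        raise ValueError("routing_iters must be >= 1")
    caps_in = T.as_tensor(caps_in)
    single = caps_in.ndim == 2
    if single:
        caps_in = caps_in.reshape(1, *caps_in.shape)
    N, num_in, in_dim = caps_in.shape
    if (num_in, in_dim) != (params.W.shape[0], params.W.shape[3]):
        raise ValueError(
            f"input capsules {(num_in, in_dim)} do not match pose tensor "
            f"{(params.W.shape[0], params.W.shape[3])}"
        )
    # votes c_hat_{j|i}: (N, num_in, num_out, out_dim)
    c_hat = T.einsum("ijkl,nil->nijk", params.W, caps_in)
    logits = T.Tensor(np.zeros((N, num_in, params.W.shape[1])))
    v = None
    for it in range(params.routing_iters):
        o = routing_softmax(logits, axis=2)
        s = (o.reshape(*o.shape, 1) * c_hat).sum(axis=1)  # (N, num_out, out_dim)
        v = squash(s, axis=-1)
        if it < params.routing_iters - 1:
            agreement = (c_hat * v.reshape(N, 1, *v.shape[1:])).sum(axis=-1)
            logits = logits + agreement
    return v.reshape(*v.shape[1:]) if single else v


# -- batched forward -----------------------------------------------------------


@dataclass
class _Batch:
    """Padded per-channel inputs plus index maps from residues to pad slots."""

    channels: dict[str, tuple[np.ndarray, np.ndarray]]  # name -> (fwd, bwd)
    idx_fwd: np.ndarray  # residue k -> b * T + t
    idx_bwd: np.ndarray  # residue k -> b * T + (L_b - 1 - t)
    labels: np.ndarray | None
    lengths: np.ndarray
    n_residues: int


def prepare_batch(bundles: list[FeatureBundle], channels) -> _Batch:
    lengths = np.array([len(b) for b in bundles])
    B, n_steps = len(bundles), int(lengths.max())
    data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in channels:
        mats = [getattr(b, "mbf" if name == "mbf" else "embedding") for b in bundles]
        if any(m is None for m in mats):
            missing = [b.protein_id for b, m in zip(bundles, mats) if m is None]
            raise ValueError(f"channel {name!r} missing for {missing}")
        F = mats[0].shape[1]
        fwd = np.zeros((B, n_steps, F))
        bwd = np.zeros((B, n_steps, F))
        for b, m in enumerate(mats):
            fwd[b, : lengths[b]] = m
            bwd[b, : lengths[b]] = m[::-1]
        data[name] = (fwd, bwd)
    idx_fwd, idx_bwd = [], []
    for b, L in enumerate(lengths):
        for t in range(L):
            idx_fwd.append(b * n_steps + t)
            idx_bwd.append(b * n_steps + (L - 1 - t))
    labels = None
    if all(b.labels is not None for b in bundles):
        labels = np.concatenate([b.labels for b in bundles])
    return _Batch(
        data, np.array(idx_fwd), np.array(idx_bwd), labels, lengths,
        int(lengths.sum()),
    )


def _forward_batch(params: ModelParams, batch: _Batch) -> T.Tensor:
    """Logits ``(N, 2)`` for every residue of the batch, on the tape."""
    cfg = params.config
    fused_parts = []
    for name in cfg.channels:
        Xf, Xb = batch.channels[name]
        reps = []
        for fwd, bwd in params.channels[name].stacks:
            Hf = _run_lstm(T.Tensor(Xf), fwd)
            Hb = _run_lstm(T.Tensor(Xb), bwd)
            B, n_steps, H = Hf.shape
            reps.append(Hf.reshape(B * n_steps, H).take_rows(batch.idx_fwd))
            reps.append(Hb.reshape(B * n_steps, H).take_rows(batch.idx_bwd))
        rep = T.concatenate(reps, axis=1)  # (N, encoder_width)
        caps_in = rep.reshape(
            batch.n_residues, cfg.encoder_width // cfg.caps_in_dim,
            cfg.caps_in_dim,
        )
        v = dynamic_routing(caps_in, params.channels[name].capsule)
        fused_parts.append(
            v.reshape(batch.n_residues, cfg.caps_count * cfg.caps_dim)
        )
    fused = T.concatenate(fused_parts, axis=1)
    if cfg.normalization == "standard":
        mu = fused.mean(axis=1, keepdims=True)
        centred = fused - mu
        var = (centred * centred).mean(axis=1, keepdims=True)
        fused = centred * (var + 1e-6) ** -0.5
    elif cfg.normalization == "l2":
        n2 = (fused * fused).sum(axis=1, keepdims=True)
        fused = fused * (n2 + _EPS) ** -0.5
    return fused @ params.dense_W + params.dense_b


def model_forward(
    bundle: FeatureBundle | list[FeatureBundle], params: ModelParams
) -> np.ndarray | list[np.ndarray]:
    """Per-residue class probabilities {non-binding, binding}.

    A single bundle returns an ``(L, 2)`` array; a list returns one array per
    protein.  Rows sum to 1.
    """
    single = isinstance(bundle, FeatureBundle)
    bundles = [bundle] if single else list(bundle)
    for b in bundles:
        have = {n for n in ("mbf", "embedding") if getattr(b, n) is not None}
        if not set(params.config.channels) <= have:
            raise ValueError(
                f"{b.protein_id}: bundle channels {have} do not cover model "
                f"channels {set(params.config.channels)}"
            )
    batch = prepare_batch(bundles, params.config.channels)
    logits = _forward_batch(params, batch)
    probs = T.softmax(logits, axis=1).data
    out, pos = [], 0
    for L in batch.lengths:
        out.append(probs[pos : pos + L])
        pos += L
    return out[0] if single else out


# -- training ------------------------------------------------------------------


class Adam:
    """Plain Adam over a list of tape tensors."""

    def __init__(self, tensors, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.tensors = list(tensors)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(t.data) for t in self.tensors]
        self.v = [np.zeros_like(t.data) for t in self.tensors]
        self.t = 0

    def step(self):
        self.t += 1
        for i, tensor in enumerate(self.tensors):
            g = tensor.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            tensor.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for tensor in self.tensors:
            tensor.grad = None


def stratified_split(labels: np.ndarray, val_fraction: float, seed: int):
    """Residue-level stratified split; returns (train_idx, val_idx)."""
    rng = np.random.default_rng(seed)
    train, val = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_val = int(round(val_fraction * idx.size))
        val.append(idx[:n_val])
        train.append(idx[n_val:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(val))


def _ce_loss(logits: T.Tensor, idx, labels, weights=None) -> T.Tensor:
    logp = T.log_softmax(logits.take_rows(idx), axis=1)
    onehot = np.zeros((len(idx), 2))
    onehot[np.arange(len(idx)), labels[idx]] = 1.0
    nll = -(logp * T.Tensor(onehot)).sum(axis=1)
    if weights is None:
        return nll.mean()
    w = T.Tensor(weights)
    return (nll * w).sum() * (1.0 / weights.sum())


def train_model(
    bundles: list[FeatureBundle],
    cfg: ModelConfig,
    *,
    train_idx: np.ndarray | None = None,
    val_idx: np.ndarray | None = None,
    sample_weights: np.ndarray | None = None,
    init_seed: int | None = None,
) -> tuple[ModelParams, list[dict]]:
    """Fit one network; returns the trained parameters and the epoch log.

    ``train_idx``/``val_idx`` index the flattened residues (protein order,
    then residue order); when omitted, a seeded stratified split at
    ``val_fraction`` is made.  ``sample_weights`` (aligned with
    ``train_idx``) implements cost-sensitive training; duplicated indices in
    ``train_idx`` implement over-sampling.  Early stopping restores the
    parameters of the best validation epoch.
    """
    if any(b.labels is None for b in bundles):
        raise ValueError("every training bundle must carry labels")
    batch = prepare_batch(bundles, cfg.channels)
    y = batch.labels
    if train_idx is None or val_idx is None:
        if len(np.unique(y)) < 2:
            raise ValueError("training data contain a single class")
        train_idx, val_idx = stratified_split(y, cfg.val_fraction, cfg.seed)
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    if len(np.unique(y[train_idx])) < 2:
        raise ValueError("training split contains a single class")
    feature_dims = {n: batch.channels[n][0].shape[2] for n in cfg.channels}
    params = init_params(cfg, feature_dims, seed=init_seed)
    opt = Adam(params.tensors(), lr=cfg.learning_rate)

    # fixed protein-level minibatches (seeded); group order reshuffled per epoch
    rng = np.random.default_rng(cfg.seed if init_seed is None else init_seed)
    n_prot = len(bundles)
    bsz = n_prot if cfg.batch_size is None else min(cfg.batch_size, n_prot)
    prot_order = rng.permutation(n_prot)
    groups = [np.sort(prot_order[i : i + bsz]) for i in range(0, n_prot, bsz)]
    offsets = np.r_[0, np.cumsum([len(b) for b in bundles])]
    minibatches = []
    for group in groups:
        local_global = np.concatenate(
            [np.arange(offsets[p], offsets[p + 1]) for p in group]
        )
        in_group = np.isin(train_idx, local_global)
        if not in_group.any():
            continue
        local_train = np.searchsorted(local_global, train_idx[in_group])
        w = None if sample_weights is None else sample_weights[in_group]
        sub = prepare_batch([bundles[p] for p in group], cfg.channels)
        minibatches.append((sub, local_train, y[local_global], w))

    history: list[dict] = []
    best_loss, best_arrays, since_best = np.inf, params.copy_arrays(), 0
    for epoch in range(cfg.epochs):
        epoch_loss = n_seen = 0
        for mb in rng.permutation(len(minibatches)):
            sub, local_train, y_local, w = minibatches[mb]
            opt.zero_grad()
            logits = _forward_batch(params, sub)
            loss = _ce_loss(logits, local_train, y_local, w)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(local_train)
            n_seen += len(local_train)
        eval_logits = _forward_batch(params, batch)
        val_loss = float(_ce_loss(eval_logits, val_idx, y).data)
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / n_seen,
                "val_loss": val_loss,
            }
        )
        if val_loss < best_loss - 1e-9:
            best_loss, best_arrays, since_best = val_loss, params.copy_arrays(), 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                logger.info("early stop at epoch %d (best val %.4f)", epoch, best_loss)
                break
    params.load_arrays(best_arrays)
    return params, history


# -- persistence ---------------------------------------------------------------


def save_model(params: ModelParams, directory) -> None:
    """Write a model directory: weights (npz) + resolved config (json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {f"w{i}": t.data for i, t in enumerate(params.tensors())}
    np.savez(directory / "weights.npz", **arrays)
    meta = {"config": params.config.to_dict(), "feature_dims": params.feature_dims}
    (directory / "config.json").write_text(json.dumps(meta, indent=2))


def load_model(directory) -> ModelParams:
    directory = Path(directory)
    meta = json.loads((directory / "config.json").read_text())
    cfg = ModelConfig.from_dict(meta["config"])
    params = init_params(cfg, meta["feature_dims"])
    with np.load(directory / "weights.npz") as npz:
        params.load_arrays([npz[f"w{i}"] for i in range(len(params.tensors()))])
    return params
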