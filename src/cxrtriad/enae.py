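"""Enhanced Auto-Encoder (EnAE): stacked autoencoder with per-layer attention.

A stack of autoencoder stages is trained greedily, layer by layer, then
fine-tuned jointly. Two things distinguish the model from a classical
stacked autoencoder:

* **Per-layer dot-product attention.** After every encoder and decoder
  layer a self-attention block treats the layer's features as tokens of
  width 1, projects them to queries/keys (width ``attention_dim``) and
  scalar values, scores them by the unscaled dot product ``Q·Kᵀ``,
  softmax-normalizes over keys, and emits the weighted value sum. The
  block reweights features by learned relevance while preserving width.
* **Dual reconstruction.** Each stage minimizes a blend of its own
  layer-input reconstruction and the reconstruction of the *original raw
  input* routed down through the already-trained lower decoders:
  ``L_s = (1−λ)·MSE(stage input, stage recon) + λ·MSE(raw, raw recon)``.
  This counters the cumulative degradation of purely layerwise training.

The decoder is an untied mirror of the encoder (tied weights available by
flag); the hidden nonlinearity is ReLU, and the final reconstruction layer
is linear so standardized (signed) inputs can be reproduced.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import Adam, Linear, Module, Tensor, mse


@dataclass
class EnaeConfig:
    layer_dims: tuple[int, ...] = (64, 32)
    attention_dim: int = 8
    lambda_raw: float = 0.5
    epochs: int = 30
    finetune_epochs: int | None = None  # None -> same as epochs
    batch_size: int = 32
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    tied_weights: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.layer_dims = tuple(int(d) for d in self.layer_dims)
        if not self.layer_dims or any(d <= 0 for d in self.layer_dims):
            raise ValueError("layer_dims must be strictly positive")
        if not (0.0 <= self.lambda_raw <= 1.0):
            raise ValueError("lambda_raw must lie in [0, 1]")


def attention(queries: np.ndarray, keys: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plain dot-product attention: scores Q·Kᵀ, softmax over keys, value sum.

    ``queries`` is (n_q, a), ``keys`` (n_k, a), ``values`` (n_k, w); returns
    ``(context (n_q, w), weights (n_q, n_k))``. Each weight row sums to 1.
    No scale factor is applied to the scores; the softmax is computed with
    max-subtraction for numerical stability.
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    keys = np.atleast_2d(np.asarray(keys, dtype=np.float64))
    values = np.atleast_2d(np.asarray(values, dtype=np.float64))
    if keys.shape[0] != values.shape[0]:
        raise ValueError("key and value counts must match")
    if queries.shape[1] != keys.shape[1]:
        raise ValueError("query and key widths must match")
    scores = queries @ keys.T
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    weights = e / e.sum(axis=1, keepdims=True)
    return weights @ values, weights


class AttentionBlock(Module):
    """Feature-wise self-attention: each of the d features is a token."""

    def __init__(self, n_features: int, attention_dim: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(attention_dim)
        self.wq = Tensor(rng.normal(0, scale, size=(1, attention_dim)), requires_grad=True)
        self.bq = Tensor(np.zeros(attention_dim), requires_grad=True)
        self.wk = Tensor(rng.normal(0, scale, size=(1, attention_dim)), requires_grad=True)
        self.bk = Tensor(np.zeros(attention_dim), requires_grad=True)
        self.wv = Tensor(rng.normal(0, 1.0, size=(1, 1)), requires_grad=True)
        self.bv = Tensor(np.zeros(1), requires_grad=True)
        self.n_features = n_features

    def __call__(self, x: Tensor) -> Tensor:
        b, d = x.shape
        tokens = x.reshape(b, d, 1)
        q = tokens @ self.wq + self.bq  # (B, d, a)
        k = tokens @ self.wk + self.bk
        v = tokens @ self.wv + self.bv  # (B, d, 1)
        scores = q @ k.transpose(0, 2, 1)  # (B, d, d), unscaled
        weights = scores.softmax(axis=-1)
        return (weights @ v).reshape(b, d)


class _Stage(Module):
    """One affine layer + optional ReLU + attention.

    With ``tied_to`` set, the affine map reuses the transposed weight of the
    paired encoder layer (weight tying) and keeps only its own bias.
    """

    def __init__(self, d_in: int, d_out: int, attention_dim: int,
                 rng: np.random.Generator, relu: bool = True, tied_to: Linear | None = None):
        if tied_to is None:
            self.linear = Linear(d_in, d_out, rng)
        else:
            self.linear = None
            self.tied_weight = tied_to.weight  # shared Tensor, transposed in forward
            self.bias = Tensor(np.zeros(d_out), requires_grad=True)
        self.tied = tied_to is not None
        self.attn = AttentionBlock(d_out, attention_dim, rng)
        self.relu = relu

    def parameters(self):
        if not self.tied:
            return super().parameters()
        # the shared weight is reported by the encoder stage that owns it
        return [self.bias] + self.attn.parameters()

    def __call__(self, x: Tensor) -> Tensor:
        if self.tied:
            h = x @ self.tied_weight.transpose(1, 0) + self.bias
        else:
            h = self.linear(x)
        if self.relu:
            h = h.relu()
        return self.attn(h)


class EnaeModel(Module):
    """Stacked encoder/decoder stages with per-stage attention blocks."""

    def __init__(self, input_dim: int, cfg: EnaeConfig):
        self.cfg = cfg
        self.input_dim = input_dim
        rng = np.random.default_rng(cfg.seed)
        dims = (input_dim, *cfg.layer_dims)
        self.encoder_stages = [
            _Stage(dims[s], dims[s + 1], cfg.attention_dim, rng) for s in range(len(cfg.layer_dims))
        ]
        # untied mirror by default; the outermost reconstruction layer is linear
        self.decoder_stages = [
            _Stage(
                dims[s + 1], dims[s], cfg.attention_dim, rng, relu=(s != 0),
                tied_to=self.encoder_stages[s].linear if cfg.tied_weights else None,
            )
            for s in range(len(cfg.layer_dims))
        ]
        self.loss_history: list[float] = []
        self.phase_boundaries: list[int] = []
        self.trained = False

    # -- forward passes ------------------------------------------------------

    def encode_t(self, x: Tensor, n_stages: int | None = None) -> Tensor:
        stages = self.encoder_stages if n_stages is None else self.encoder_stages[:n_stages]
        for stage in stages:
            x = stage(x)
        return x

    def decode_t(self, latent: Tensor, from_stage: int | None = None) -> Tensor:
        start = len(self.decoder_stages) - 1 if from_stage is None else from_stage
        for s in range(start, -1, -1):
            latent = self.decoder_stages[s](latent)
        return latent


def encode(model: EnaeModel, x: np.ndarray) -> np.ndarray:
    """Map inputs (N, input_dim) to the final latent (N, layer_dims[-1])."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.shape[1] != model.input_dim:
        raise ValueError(f"input width {x.shape[1]} != model input_dim {model.input_dim}")
    return model.encode_t(Tensor(x)).data


def decode(model: EnaeModel, latent: np.ndarray) -> np.ndarray:
    """Map latents (N, layer_dims[-1]) back to reconstructions (N, input_dim)."""
    latent = np.atleast_2d(np.asarray(latent, dtype=np.float64))
    if latent.shape[1] != model.cfg.layer_dims[-1]:
        raise ValueError("latent width does not match the last stage")
    return model.decode_t(Tensor(latent)).data


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_enae(data: np.ndarray, cfg: EnaeConfig | None = None) -> EnaeModel:
    """Greedy layerwise training with the dual objective, then joint fine-tune.

    ``data`` is the preprocessed (N, D) matrix (flattened images). The
    recorded ``loss_history`` concatenates per-epoch mean losses of every
    phase; ``phase_boundaries`` marks where each phase ends, and the last
    entries are the joint-phase losses.
    """
    cfg = cfg or EnaeConfig()
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("train_enae expects an (N, D) matrix")
    model = EnaeModel(data.shape[1], cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    lam = cfg.lambda_raw

    def record(loss_value: float, context: str) -> None:
        if not np.isfinite(loss_value):
            raise FloatingPointError(f"non-finite loss during {context}: {loss_value}")
        model.loss_history.append(loss_value)

    # greedy layerwise phases
    for s in range(len(cfg.layer_dims)):
        params = model.encoder_stages[s].parameters() + model.decoder_stages[s].parameters()
        opt = Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
        with_raw = lam > 0 and s > 0
        for _ in range(cfg.epochs):
            losses = []
            for idx in _epoch_batches(len(data), cfg.batch_size, rng):
                raw = Tensor(data[idx])
                stage_in = model.encode_t(raw, n_stages=s) if s > 0 else raw
                stage_in = Tensor(stage_in.data)  # lower stages are frozen in this phase
                code = model.encoder_stages[s](stage_in)
                stage_recon = model.decoder_stages[s](code)
                loss = mse(stage_recon, stage_in) * (1.0 - lam if with_raw else 1.0)
                if with_raw:
                    raw_recon = model.decode_t(stage_recon, from_stage=s - 1)
                    loss = loss + mse(raw_recon, raw) * lam
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
            record(float(np.mean(losses)), f"stage {s}")
        model.phase_boundaries.append(len(model.loss_history))

    # joint fine-tune: full-network raw reconstruction (the two objective
    # terms coincide at the whole-stack level)
    opt = Adam(model.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    for _ in range(cfg.finetune_epochs if cfg.finetune_epochs is not None else cfg.epochs):
        losses = []
        for idx in _epoch_batches(len(data), cfg.batch_size, rng):
            raw = Tensor(data[idx])
            loss = mse(model.decode_t(model.encode_t(raw)), raw)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        record(float(np.mean(losses)), "joint fine-tune")
    model.phase_boundaries.append(len(model.loss_history))
    model.trained = True
    return model


def extract_features(model: EnaeModel, images: np.ndarray) -> np.ndarray:
    """Rows = images, columns = final post-attention latent features."""
    if not model.trained:
        raise RuntimeError("extract_features requires a trained model")
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:  # (N, H, W) -> flatten
        images = images.reshape(len(images), -1)
    return encode(model, images)


# ---------------------------------------------------------------------------
# checkpointing: portable array archive + JSON config sidecar


def save_enae(model: EnaeModel, path: str | Path) -> None:
    path = Path(path)
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "config": asdict(model.cfg),
        "input_dim": model.input_dim,
        "loss_history": model.loss_history,
        "phase_boundaries": model.phase_boundaries,
        "trained": model.trained,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_enae(path: str | Path) -> EnaeModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = sidecar["config"]
    cfg_dict["layer_dims"] = tuple(cfg_dict["layer_dims"])
    cfg = EnaeConfig(**cfg_dict)
    model = EnaeModel(sidecar["input_dim"], cfg)
    with np.load(path.with_suffix(".npz")) as archive:
        for i, p in enumerate(model.parameters()):
            p.data = archive[f"p{i}"]
    model.loss_history = list(sidecar["loss_history"])
    model.phase_boundaries = list(sidecar["phase_boundaries"])
    model.trained = sidecar["trained"]
    return model
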