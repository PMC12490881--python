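"""Factorized spatio-temporal transformer regressor from grid-video sEMG
windows to the 16 finger joint angles.

Each ``(S, 4, 4)`` window is split into non-overlapping temporal patches;
every (patch, grid-cell) pair becomes a token embedded by a linear patch
projection with learned temporal and spatial position embeddings.  The
encoder is factorized self-attention: a stack of transformer blocks
attending across the 16 grid cells within each temporal slot, followed by
a stack attending across temporal slots within each grid cell.  Token
features are mean-pooled and a final fully connected layer maps them to
the 16-dimensional joint-angle vector (degrees).

Training minimizes mean-squared error with Adam, applies the channel
silencing / additive-noise augmentation to training batches only, early
stops on validation loss, and restores the best checkpoint.  Everything
is driven by explicit seeds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .session_io import N_JOINTS
from .windowing import AugmentConfig, WindowTensor, augment_batch

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainedDecoder",
    "build_model",
    "train",
    "predict",
    "save_decoder",
    "load_decoder",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``temporal_patch`` is the number of raw samples per token patch (the
    window length in samples must be divisible by it); ``output_dim`` is
    fixed at 16 joints.  Defaults are intentionally small so training is
    feasible on one CPU; every dimension is configurable.
    """

    temporal_patch: int = 32
    embed_dim: int = 64
    spatial_depth: int = 2
    temporal_depth: int = 2
    n_heads: int = 4
    mlp_ratio: float = 2.0
    dropout: float = 0.0
    embed_activation: bool = True
    tied_patch_embed: bool = False
    output_dim: int = N_JOINTS

    def __post_init__(self) -> None:
        if self.output_dim != N_JOINTS:
            raise ValueError(f"output_dim is fixed at {N_JOINTS}")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} must be divisible by n_heads {self.n_heads}"
            )
        if min(self.temporal_patch, self.spatial_depth + self.temporal_depth) < 1:
            raise ValueError("temporal_patch and total depth must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    def n_temporal_tokens(self, window_samples: int) -> int:
        if window_samples % self.temporal_patch != 0:
            raise ValueError(
                f"window of {window_samples} samples is not divisible by "
                f"temporal_patch={self.temporal_patch} "
                f"(would give {window_samples / self.temporal_patch:.2f} tokens)"
            )
        return window_samples // self.temporal_patch


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Loss is mean-squared error on degrees by default (switchable to
    ``"mae"``).  ``augment`` applies channel silencing + Gaussian noise to
    training batches only; validation and inference are never augmented.
    ``max_train_windows`` caps the training set by seeded subsampling — a
    throughput control for the heavily overlapping rolling windows.
    """

    loss: str = "mse"
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    early_stopping_patience: int = 5
    seed: int = 0
    augment: AugmentConfig | None = None
    max_train_windows: int | None = None
    normalize_targets: bool = False
    lr_decay: float = 1.0  # per-epoch multiplicative decay of the learning rate

    def __post_init__(self) -> None:
        if self.loss not in ("mse", "mae"):
            raise ValueError("loss must be 'mse' or 'mae'")
        if self.early_stopping_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must be in (0, 1]")


class _PerCellLinear(nn.Module):
    """Linear patch projection with untied weights per grid cell.

    Input ``(..., ns, p)`` -> output ``(..., ns, d)`` where cell ``c`` uses
    its own ``(p, d)`` weight matrix and bias.
    """

    def __init__(self, ns: int, d_in: int, d_out: int, rng: np.random.Generator, name: str):
        bound = float(np.sqrt(6.0 / (d_in + d_out)))
        self.w = nn.Parameter(rng.uniform(-bound, bound, (ns, d_in, d_out)), f"{name}.w")
        self.b = nn.Parameter(np.zeros((ns, d_out)), f"{name}.b")

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        w, b = self.w, self.b
        out_val = np.einsum("...cp,cpd->...cd", x.value, w.value, optimize=True) + b.value

        def bwd(g):
            if x.requires_grad:
                x._accumulate(
                    np.einsum("...cd,cpd->...cp", g, w.value, optimize=True)
                )
            w._accumulate(
                np.einsum("...cp,...cd->cpd", x.value, g, optimize=True)
            )
            b._accumulate(g.reshape(-1, *b.value.shape).sum(axis=0))

        return nn.Tensor(out_val, parents=(x, w, b), backward=bwd)


class _ViViTRegressor(nn.Module):
    """The factorized spatio-temporal transformer network."""

    def __init__(self, config: ModelConfig, window_samples: int, rng: np.random.Generator):
        self.config = config
        self.window_samples = window_samples
        self.nt = config.n_temporal_tokens(window_samples)
        self.ns = 16  # 4x4 grid cells
        d = config.embed_dim
        if config.tied_patch_embed:
            self.patch_embed = nn.Linear(config.temporal_patch, d, rng, "patch_embed")
        else:
            # One projection per electrode: the 4x4 array is a fixed set of
            # distinct physical sensors, so there is no translation
            # structure to justify weight sharing across grid cells.
            self.patch_embed = _PerCellLinear(
                self.ns, config.temporal_patch, d, rng, "patch_embed"
            )
        self.pos_temporal = nn.Parameter(
            0.02 * rng.standard_normal((self.nt, 1, d)), "pos_temporal"
        )
        self.pos_spatial = nn.Parameter(
            0.02 * rng.standard_normal((1, self.ns, d)), "pos_spatial"
        )
        self.spatial_blocks = [
            nn.EncoderLayer(d, config.n_heads, config.mlp_ratio, config.dropout, rng, f"spatial{i}")
            for i in range(config.spatial_depth)
        ]
        self.temporal_blocks = [
            nn.EncoderLayer(d, config.n_heads, config.mlp_ratio, config.dropout, rng, f"temporal{i}")
            for i in range(config.temporal_depth)
        ]
        self.final_ln = nn.LayerNorm(d, "final_ln")
        self.head = nn.Linear(d, config.output_dim, rng, "head")
        # Single precision throughout: CPU throughput matters more than the
        # extra mantissa for this regression task.
        for p in self.parameters():
            p.value = p.value.astype(np.float32)

    def forward(self, x: np.ndarray, rng: np.random.Generator, training: bool) -> nn.Tensor:
        b, s, w, h = x.shape
        if (w, h) != (4, 4):
            raise ValueError(f"expected 4x4 grid windows, got {w}x{h}")
        if s != self.window_samples:
            raise ValueError(
                f"model built for {self.window_samples}-sample windows, got {s}"
            )
        nt, ns, d = self.nt, self.ns, self.config.embed_dim
        p = self.config.temporal_patch
        t = nn.Tensor(np.ascontiguousarray(x, dtype=np.float32).reshape(b, nt, p, ns))
        t = nn.transpose(t, (0, 1, 3, 2))  # (B, nt, ns, p)
        tok = self.patch_embed(t)  # (B, nt, ns, d)
        if self.config.embed_activation:
            # GELU here maps carrier scale into token mean: for a zero-mean
            # sEMG patch the linear projection alone is zero-mean whatever
            # the amplitude, and amplitude is the feature that codes muscle
            # activation.
            tok = nn.gelu(tok)
        tok = tok + self.pos_temporal + self.pos_spatial
        # Spatial attention: across grid cells within each temporal slot.
        tok = nn.reshape(tok, (b * nt, ns, d))
        for blk in self.spatial_blocks:
            tok = blk(tok, rng, training)
        tok = nn.reshape(tok, (b, nt, ns, d))
        # Temporal attention: across temporal slots within each grid cell.
        tok = nn.transpose(tok, (0, 2, 1, 3))  # (B, ns, nt, d)
        tok = nn.reshape(tok, (b * ns, nt, d))
        for blk in self.temporal_blocks:
            tok = blk(tok, rng, training)
        tok = nn.reshape(tok, (b, ns, nt, d))
        pooled = nn.mean(tok, axis=(1, 2))  # (B, d)
        return self.head(self.final_ln(pooled))


@dataclass
class TrainedDecoder:
    """A (possibly still untrained) decoder with its config and history."""

    model: _ViViTRegressor
    config: ModelConfig
    window_samples: int
    fs: float
    target_mean: np.ndarray | None = None
    target_sd: np.ndarray | None = None
    history: dict = field(default_factory=lambda: {"train_loss": [], "val_loss": []})
    best_epoch: int | None = None

    @property
    def n_parameters(self) -> int:
        return self.model.n_parameters()


def build_model(
    config: ModelConfig = ModelConfig(),
    window_samples: int = 2048,
    fs: float = 4000.0,
    seed: int = 0,
) -> TrainedDecoder:
    """Instantiate an untrained decoder for ``window_samples``-long windows.

    Raises if the token geometry is inconsistent (window length not
    divisible by the temporal patch), reporting the computed token counts.
    """
    rng = np.random.default_rng(seed)
    model = _ViViTRegressor(config, window_samples, rng)
    return TrainedDecoder(model=model, config=config, window_samples=window_samples, fs=fs)


def parameter_count(config: ModelConfig, window_samples: int) -> int:
    """Closed-form parameter count for the architecture (used as an oracle)."""
    d = config.embed_dim
    p = config.temporal_patch
    nt = config.n_temporal_tokens(window_samples)
    ns = 16
    hidden = int(round(d * config.mlp_ratio))
    per_layer = (
        2 * 2 * d  # two layer norms
        + d * 3 * d + 3 * d  # qkv
        + d * d + d  # attention projection
        + d * hidden + hidden  # mlp fc1
        + hidden * d + d  # mlp fc2
    )
    embed = (p * d + d) if config.tied_patch_embed else ns * (p * d + d)
    return (
        embed  # patch embedding (per-cell when untied)
        + nt * d + ns * d  # position embeddings
        + (config.spatial_depth + config.temporal_depth) * per_layer
        + 2 * d  # final layer norm
        + d * config.output_dim + config.output_dim  # head
    )


def _loss_fn(name: str):
    return nn.mse_loss if name == "mse" else nn.mae_loss


def train(
    decoder: TrainedDecoder,
    train_tensor: WindowTensor,
    val_tensor: WindowTensor,
    config: TrainConfig = TrainConfig(),
) -> TrainedDecoder:
    """Fit the decoder on training windows with validation early stopping.

    Stops when validation loss has not improved for
    ``early_stopping_patience`` consecutive epochs and restores the
    parameters of the best-validation epoch exactly.
    """
    if len(train_tensor) == 0 or len(val_tensor) == 0:
        raise ValueError("train and validation tensors must be non-empty")
    if train_tensor.targets is None or val_tensor.targets is None:
        raise ValueError("window tensors need targets; run assign_targets first")
    rng = np.random.default_rng(config.seed)
    model = decoder.model
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    loss_fn = _loss_fn(config.loss)

    if config.normalize_targets:
        mu = train_tensor.targets.mean(axis=0)
        sd = train_tensor.targets.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        decoder.target_mean, decoder.target_sd = mu, sd
    else:
        mu, sd = np.zeros(decoder.config.output_dim), np.ones(decoder.config.output_dim)
        decoder.target_mean = decoder.target_sd = None

    train_idx = np.arange(len(train_tensor))
    if config.max_train_windows is not None and len(train_idx) > config.max_train_windows:
        train_idx = rng.choice(train_idx, config.max_train_windows, replace=False)
        train_idx.sort()

    best_val = np.inf
    best_state = model.state()
    best_epoch = -1
    since_best = 0
    history = {"train_loss": [], "val_loss": []}

    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            x = train_tensor.batch(idx)
            if config.augment is not None:
                x = augment_batch(x, config.augment, rng, train_tensor.fs)
            y = ((train_tensor.targets[idx] - mu) / sd).astype(np.float32)
            pred = model.forward(x, rng, training=True)
            loss = loss_fn(pred, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.value)
            n_batches += 1
        val_loss = _evaluate_loss(model, val_tensor, loss_fn, config.batch_size, mu, sd)
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stopping_patience:
                break
        opt.lr *= config.lr_decay
    model.load_state(best_state)
    decoder.history = history
    decoder.best_epoch = best_epoch
    return decoder


def _evaluate_loss(
    model: _ViViTRegressor,
    tensor: WindowTensor,
    loss_fn,
    batch_size: int,
    mu: np.ndarray,
    sd: np.ndarray,
) -> float:
    rng = np.random.default_rng(0)  # unused in eval mode
    total = 0.0
    n = 0
    for start in range(0, len(tensor), batch_size):
        idx = np.arange(start, min(start + batch_size, len(tensor)))
        pred = model.forward(tensor.batch(idx), rng, training=False)
        y = ((tensor.targets[idx] - mu) / sd).astype(np.float32)
        total += float(loss_fn(pred, y).value) * len(idx)
        n += len(idx)
    return total / n


def predict(
    decoder: TrainedDecoder,
    tensor: WindowTensor | np.ndarray,
    batch_size: int = 128,
) -> np.ndarray:
    """Per-window 16-joint angle predictions (degrees), no augmentation."""
    rng = np.random.default_rng(0)
    model = decoder.model

    def denorm(y: np.ndarray) -> np.ndarray:
        if decoder.target_mean is not None:
            return y * decoder.target_sd + decoder.target_mean
        return y

    if isinstance(tensor, np.ndarray):
        if tensor.ndim == 3:
            tensor = tensor[None]
        return denorm(model.forward(tensor, rng, training=False).value)
    out = np.empty((len(tensor), decoder.config.output_dim))
    for start in range(0, len(tensor), batch_size):
        idx = np.arange(start, min(start + batch_size, len(tensor)))
        out[idx] = model.forward(tensor.batch(idx), rng, training=False).value
    return denorm(out)


# ---------------------------------------------------------------------------
# checkpoint serialization
# ---------------------------------------------------------------------------

def save_decoder(decoder: TrainedDecoder, path: str | Path) -> Path:
    """Write weights (.npz) + config/history (.json) under ``path`` stem."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    params = decoder.model.parameters()
    np.savez(
        path.with_suffix(".npz"),
        **{f"p{i:03d}": p.value for i, p in enumerate(params)},
    )
    meta = {
        "model_config": asdict(decoder.config),
        "window_samples": decoder.window_samples,
        "fs": decoder.fs,
        "history": decoder.history,
        "best_epoch": decoder.best_epoch,
        "target_mean": None if decoder.target_mean is None else decoder.target_mean.tolist(),
        "target_sd": None if decoder.target_sd is None else decoder.target_sd.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path.with_suffix(".npz")


def load_decoder(path: str | Path) -> TrainedDecoder:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig(**meta["model_config"])
    decoder = build_model(config, meta["window_samples"], meta["fs"], seed=0)
    with np.load(path.with_suffix(".npz")) as data:
        state = [data[k] for k in sorted(data.files)]
    decoder.model.load_state(state)
    decoder.history = meta["history"]
    decoder.best_epoch = meta["best_epoch"]
    if meta.get("target_mean") is not None:
        decoder.target_mean = np.asarray(meta["target_mean"])
        decoder.target_sd = np.asarray(meta["target_sd"])
    return decoder
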