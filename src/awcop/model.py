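"""The adaptive-weight multimodal fusion network and its sklearn wrapper.

Four branch encoders map each modality to a 128-dimensional embedding:

* tongue / face images: 3x3 conv (3->64) + BN + ReLU + 2x2 max-pool, four
  64-channel residual blocks, global average pooling, a 64->128 dense layer,
  and single-head self-attention over the embedding reshaped into tokens;
* pulse waveform: single-layer LSTM (hidden 64) over the 300-sample 6-s
  segment, final hidden state through a 64->128 dense layer;
* clinical vector: dense 15->128 with ReLU over the 15 screened features.

The decision layer supports six fusion strategies. ``adaptive`` — the
model's own mechanism — keeps one learnable raw scalar per modality,
softmax-normalizes them, scales each embedding by its weight and
concatenates (128 x 4 = 512), recording the regularizer R = sum of squared
raw weights for the loss. ``concat`` is plain concatenation; ``max``,
``mean`` and ``sum`` are elementwise across embeddings; ``attention`` mixes
the four embeddings as tokens through one scaled-dot-product layer and
averages them. A dense head maps the fused vector to 2 logits.

:class:`AWCOPClassifier` packages training (Adam, cross-entropy with
inverse-frequency class weights plus ``reg_lambda * R`` for adaptive fusion)
behind the scikit-learn estimator protocol. Because the input is inherently
multimodal, ``X`` is a dict of per-modality arrays rather than a single 2-D
matrix; everything else (get_params/set_params, fitted attributes with a
trailing underscore, predict/predict_proba) follows the sklearn contract.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .nn import Tensor

FUSION_STRATEGIES = ("concat", "max", "mean", "sum", "attention", "adaptive")
ALL_MODALITIES = ("tongue", "face", "pulse", "clinical")


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyperparameters (printed-architecture defaults)."""

    image_size: tuple[int, int] = (64, 64)
    conv_channels: int = 64
    embed_dim: int = 128
    lstm_hidden: int = 64
    n_residual_blocks: int = 4
    n_clinical_in: int = 15
    pulse_len: int = 300
    fusion: str = "adaptive"
    attention_tokens: int = 8
    reg_lambda: float = 1e-4
    seed: int = 0
    modalities: tuple[str, ...] = ALL_MODALITIES
    use_lstm: bool = True        # pulse via LSTM; else dense on 15 parameters
    use_resnet: bool = True      # residual blocks in the image stems
    use_attention: bool = True   # branch self-attention layers

    def __post_init__(self):
        h, w = self.image_size
        if h % 2 or w % 2:
            raise ValueError("image dimensions must be even (2x2 max-pool)")
        if self.fusion not in FUSION_STRATEGIES:
            raise ValueError(f"unknown fusion strategy {self.fusion!r}; "
                             f"choose from {FUSION_STRATEGIES}")
        if self.embed_dim % self.attention_tokens:
            raise ValueError("embed_dim must be divisible by attention_tokens")
        unknown = set(self.modalities) - set(ALL_MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities {sorted(unknown)}")
        if not self.modalities:
            raise ValueError("at least one modality required")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d["image_size"] = tuple(d["image_size"])
        d["modalities"] = tuple(d["modalities"])
        return cls(**d)


class ImageBranch(nn.Module):
    """Conv stem -> (residual blocks) -> GAP -> FC -> (self-attention)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        ch = cfg.conv_channels
        self.stem_conv = nn.Conv2d(3, ch, rng)
        self.stem_bn = nn.BatchNorm2d(ch)
        self.pool = nn.MaxPool2d()
        self.blocks = ([nn.ResidualBlock(ch, rng) for _ in range(cfg.n_residual_blocks)]
                       if cfg.use_resnet else [])
        self.fc = nn.Linear(ch, cfg.embed_dim, rng)
        self.attn = (nn.TokenSelfAttention(cfg.embed_dim // cfg.attention_tokens, rng)
                     if cfg.use_attention else None)
        self.tokens = cfg.attention_tokens
        self.embed_dim = cfg.embed_dim
        self._feature_map: Tensor | None = None

    @property
    def last_feature_map(self) -> Tensor | None:
        """Feature map retained by the last forward pass (Grad-CAM input)."""
        return self._feature_map

    def __call__(self, x: Tensor) -> Tensor:
        h = self.pool(self.stem_bn(self.stem_conv(x)).relu())
        for blk in self.blocks:
            h = blk(h)
        self._feature_map = h
        e = self.fc(nn.global_avg_pool(h))
        if self.attn is not None:
            n = e.shape[0]
            tok = e.reshape(n, self.tokens, self.embed_dim // self.tokens)
            e = self.attn(tok).reshape(n, self.embed_dim)
        return e


class PulseBranch(nn.Module):
    """LSTM over the 6-s segment; final hidden state -> 128-d embedding."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.lstm = nn.LSTM(1, cfg.lstm_hidden, rng)
        self.fc = nn.Linear(cfg.lstm_hidden, cfg.embed_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim != 3 or x.shape[2] != 1:
            raise ValueError("pulse batch must have shape (N, seq_len, 1)")
        return self.fc(self.lstm.last_hidden(x))


class DenseBranch(nn.Module):
    """Dense encoder with ReLU; clinical branch and the LSTM-free pulse path."""

    def __init__(self, n_in: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.fc = nn.Linear(n_in, cfg.embed_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc(x).relu()


class FusionHead(nn.Module):
    """Decision layer: modality fusion + 2-logit classifier head."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        m = len(cfg.modalities)
        self.strategy = cfg.fusion
        self.raw_weights = (Tensor(np.zeros(m), requires_grad=True)
                            if cfg.fusion == "adaptive" else None)
        self.attn = (nn.TokenSelfAttention(cfg.embed_dim, rng)
                     if cfg.fusion == "attention" else None)
        fused = cfg.embed_dim * m if cfg.fusion in ("concat", "adaptive") else cfg.embed_dim
        self.head = nn.Linear(fused, 2, rng)
        self.fused_dim = fused

    def fuse(self, embeddings: list[Tensor]) -> tuple[Tensor, Tensor | None]:
        """Returns (fused vector, R regularizer or None)."""
        s = self.strategy
        if s == "concat":
            return nn.concat(embeddings, axis=1), None
        if s == "adaptive":
            w = nn.softmax(self.raw_weights, axis=0)
            scaled = [w[i] * e for i, e in enumerate(embeddings)]
            r = (self.raw_weights * self.raw_weights).sum()
            return nn.concat(scaled, axis=1), r
        if s == "max":
            out = embeddings[0]
            for e in embeddings[1:]:
                out = nn.maximum(out, e)
            return out, None
        if s == "mean":
            return nn.stack_mean(embeddings), None
        if s == "sum":
            out = embeddings[0]
            for e in embeddings[1:]:
                out = out + e
            return out, None
        if s == "attention":
            n, d = embeddings[0].shape
            tok = nn.concat([e.reshape(n, 1, d) for e in embeddings], axis=1)
            return self.attn(tok).mean(axis=1), None
        raise ValueError(f"unknown fusion strategy {s!r}")

    def __call__(self, embeddings: list[Tensor]) -> tuple[Tensor, Tensor | None]:
        fused, r = self.fuse(embeddings)
        return self.head(fused), r

    def normalized_weights(self) -> np.ndarray | None:
        if self.raw_weights is None:
            return None
        e = np.exp(self.raw_weights.data - self.raw_weights.data.max())
        return e / e.sum()


class AWCOPNet(nn.Module):
    """Composition of the branch encoders and the fusion decision layer."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        # branch init order is fixed so a given seed is reproducible
        self.branches: dict[str, nn.Module] = {}
        for name in ALL_MODALITIES:
            if name not in cfg.modalities:
                continue
            if name in ("tongue", "face"):
                self.branches[name] = ImageBranch(cfg, rng)
            elif name == "pulse":
                self.branches[name] = (PulseBranch(cfg, rng) if cfg.use_lstm
                                       else DenseBranch(15, cfg, rng))
            else:
                self.branches[name] = DenseBranch(cfg.n_clinical_in, cfg, rng)
        self.branch_list = [self.branches[m] for m in cfg.modalities]
        self.fusion = FusionHead(cfg, rng)

    def forward(self, batch: dict[str, Tensor]) -> tuple[Tensor, dict]:
        embeddings = []
        for name in self.cfg.modalities:
            key = name
            if name == "pulse" and not self.cfg.use_lstm:
                key = "pulse_feats"
            if key not in batch:
                raise KeyError(f"batch is missing modality input {key!r}")
            embeddings.append(self.branches[name](batch[key]))
        logits, r = self.fusion(embeddings)
        diagnostics = {
            "embeddings": dict(zip(self.cfg.modalities, embeddings)),
            "fusion_weights": self.fusion.normalized_weights(),
            "raw_weights": (None if self.fusion.raw_weights is None
                            else self.fusion.raw_weights.data.copy()),
            "R": None if r is None else float(r.data),
        }
        return logits, diagnostics

    __call__ = forward


def _as_tensors(batch: dict[str, np.ndarray],
                requires_grad: bool = False) -> dict[str, Tensor]:
    return {k: Tensor(v, requires_grad=requires_grad) for k, v in batch.items()}


class AWCOPClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn estimator around :class:`AWCOPNet`.

    ``X`` is a dict of modality arrays (see :func:`awcop.train.assemble_dataset`):
    ``tongue``/``face`` as ``(n, 3, H, W)`` floats in [0, 1], ``pulse`` as
    ``(n, 300, 1)`` per-sequence z-scored segments, ``pulse_feats`` as
    ``(n, 15)`` scaled pulse parameters (used when ``use_lstm=False``) and
    ``clinical`` as ``(n, 15)`` scaled screened features. Only the keys named
    in ``modalities`` are consumed.
    """

    def __init__(self, image_size=(64, 64), fusion="adaptive",
                 modalities=ALL_MODALITIES, use_lstm=True, use_resnet=True,
                 use_attention=True, embed_dim=128, lstm_hidden=64,
                 n_residual_blocks=4, attention_tokens=8, reg_lambda=1e-4,
                 learning_rate=0.001, epochs=30, batch_size=16,
                 early_stop_patience=8, class_weight="balanced", seed=0):
        self.image_size = image_size
        self.fusion = fusion
        self.modalities = modalities
        self.use_lstm = use_lstm
        self.use_resnet = use_resnet
        self.use_attention = use_attention
        self.embed_dim = embed_dim
        self.lstm_hidden = lstm_hidden
        self.n_residual_blocks = n_residual_blocks
        self.attention_tokens = attention_tokens
        self.reg_lambda = reg_lambda
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.early_stop_patience = early_stop_patience
        self.class_weight = class_weight
        self.seed = seed

    # -- helpers -------------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            image_size=tuple(self.image_size), fusion=self.fusion,
            modalities=tuple(self.modalities), use_lstm=self.use_lstm,
            use_resnet=self.use_resnet, use_attention=self.use_attention,
            embed_dim=self.embed_dim, lstm_hidden=self.lstm_hidden,
            n_residual_blocks=self.n_residual_blocks,
            attention_tokens=self.attention_tokens,
            reg_lambda=self.reg_lambda, seed=self.seed)

    def _batch_keys(self) -> list[str]:
        keys = []
        for m in self.modalities:
            keys.append("pulse_feats" if (m == "pulse" and not self.use_lstm) else m)
        return keys

    def _subset(self, X: dict, idx) -> dict:
        return {k: np.asarray(X[k])[idx] for k in self._batch_keys()}

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X: dict, y, validation: tuple | None = None):
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        self.classes_ = np.array([0, 1])
        cfg = self._model_config()
        self.net_ = AWCOPNet(cfg)
        params = self.net_.parameters()
        opt = nn.Adam(params, lr=self.learning_rate)
        rng = np.random.default_rng(self.seed + 1)
        n = len(y)
        if self.class_weight == "balanced":
            counts = np.bincount(y, minlength=2)
            cw = n / (2.0 * np.maximum(counts, 1))
        else:
            cw = np.ones(2)
        history = {"loss": [], "val_auc": [], "fusion_weights": [], "R": []}
        best_val, best_state, patience = -np.inf, None, 0
        for _epoch in range(self.epochs):
            self.net_.train()
            order = rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                batch = _as_tensors(self._subset(X, idx))
                logits, diag = self.net_(batch)
                loss = nn.cross_entropy(logits, y[idx], class_weights=cw)
                if self.fusion == "adaptive" and self.reg_lambda > 0:
                    raw = self.net_.fusion.raw_weights
                    loss = loss + self.reg_lambda * (raw * raw).sum()
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
                seen += len(idx)
            history["loss"].append(epoch_loss / seen)
            w = self.net_.fusion.normalized_weights()
            history["fusion_weights"].append(None if w is None else w.tolist())
            raw = self.net_.fusion.raw_weights
            history["R"].append(None if raw is None else float((raw.data ** 2).sum()))
            if validation is not None:
                from .metrics import auc_score
                xv, yv = validation
                val_auc = auc_score(yv, self.predict_proba(xv)[:, 1])
                history["val_auc"].append(val_auc)
                if val_auc >= best_val - 1e-9:  # on ties keep the later,
                    # better-calibrated state
                    improved = val_auc > best_val + 1e-9
                    best_val = max(best_val, val_auc)
                    best_state = self.net_.named_state()
                    best_state = {k: v.copy() for k, v in best_state.items()}
                    patience = 0 if improved else patience + 1
                else:
                    patience += 1
                if patience >= self.early_stop_patience:
                    break
        if best_state is not None:
            self.net_.load_state(best_state)
        self.history_ = history
        self.fusion_weights_ = self.net_.fusion.normalized_weights()
        return self

    def decision_function(self, X: dict) -> np.ndarray:
        self.net_.eval()
        n = len(next(iter(self._subset(X, slice(None)).values())))
        outs = []
        for start in range(0, n, max(self.batch_size, 1)):
            idx = slice(start, start + self.batch_size)
            logits, _ = self.net_(_as_tensors(self._subset(X, idx)))
            outs.append(logits.data)
        return np.concatenate(outs, axis=0)

    def predict_proba(self, X: dict) -> np.ndarray:
        z = self.decision_function(X)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: dict) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    # -- checkpointing -------------------------------------------------------
    def save(self, path) -> None:
        """Single-file parameter archive + JSON config sidecar."""
        path = Path(path)
        np.savez(path, **self.net_.named_state())
        sidecar = path.with_suffix(".json")
        sidecar.write_text(self._model_config().to_json())

    @classmethod
    def load(cls, path) -> "AWCOPClassifier":
        path = Path(path)
        cfg = ModelConfig.from_json(path.with_suffix(".json").read_text())
        clf = cls(image_size=cfg.image_size, fusion=cfg.fusion,
                  modalities=cfg.modalities, use_lstm=cfg.use_lstm,
                  use_resnet=cfg.use_resnet, use_attention=cfg.use_attention,
                  embed_dim=cfg.embed_dim, lstm_hidden=cfg.lstm_hidden,
                  n_residual_blocks=cfg.n_residual_blocks,
                  attention_tokens=cfg.attention_tokens,
                  reg_lambda=cfg.reg_lambda, seed=cfg.seed)
        clf.net_ = AWCOPNet(cfg)
        archive = np.load(str(path) if str(path).endswith(".npz") else f"{path}.npz")
        clf.net_.load_state({k: archive[k] for k in archive.files})
        clf.classes_ = np.array([0, 1])
        clf.fusion_weights_ = clf.net_.fusion.normalized_weights()
        clf.history_ = {}
        return clf
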