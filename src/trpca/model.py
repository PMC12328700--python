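"""Transformer over RPCA component scores (the TRPCA network).

A length-j score vector is expanded by a linear "multi-view" projection into j
tokens of width ``projection_dim`` (one token per principal component), each
L2-normalized to the unit sphere. Tokens pass through normalized transformer
blocks whose residual updates are gated by learnable scalars:

    h_A = Norm(x + alpha_A * (Attention(x) - x))
    h_M = Norm(h_A + alpha_M * (MLP(h_A) - h_A))

with Norm = per-token L2 normalization, so every update stays on the sphere.
Global average pooling over the projection axis collapses the sequence back to
one scalar per component, feeding a linear regression or classification head.
The multi-task variant routes the encoder output through a classification head
and through one extra attention block whose pooled output, concatenated with
the class scores, feeds the regression head.

Multi-head attention with nhead=8 cannot act directly on 4-wide tokens, so the
attention sub-layer works in a wider internal space (``attention_width``,
default nhead × 1) reached by learned up/down projections around it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._autograd import Tensor, concat, gelu, l2_normalize, softmax

logger = logging.getLogger("trpca")

__all__ = ["ModelConfig", "TrpcaModel"]

ALPHA_INIT = 0.05  # small residual gain: blocks start near identity


@dataclass
class ModelConfig:
    """Architecture configuration.

    ``pca_dim`` is the number of principal components and doubles as the
    sequence length; ``projection_dim`` is the token width. ``task`` selects
    the head: plain regression, classification over ``n_classes``, or joint
    multi-task learning (mtl). ``pool_axis`` chooses what global average
    pooling collapses — the projection axis (default) or the sequence axis.
    """

    pca_dim: int = 256
    num_transformer_layers: int = 1
    nhead: int = 8
    projection_dim: int = 4
    dropout: float = 0.0
    attention_width: int | None = None
    mlp_ratio: int = 4
    n_classes: int = 0
    task: str = "regression"
    pool_axis: str = "projection"

    def __post_init__(self) -> None:
        if self.attention_width is None:
            self.attention_width = self.nhead  # head_dim 1 per head
        if self.attention_width % self.nhead != 0:
            raise ValueError("attention_width must be divisible by nhead")
        if self.task not in {"regression", "classification", "mtl"}:
            raise ValueError(f"unknown task {self.task!r}")
        if self.task in {"classification", "mtl"} and self.n_classes < 2:
            raise ValueError(f"task={self.task!r} requires n_classes >= 2")
        if self.pool_axis not in {"projection", "sequence"}:
            raise ValueError("pool_axis must be 'projection' or 'sequence'")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")

    @property
    def pooled_dim(self) -> int:
        return self.pca_dim if self.pool_axis == "projection" else self.projection_dim


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _linear_params(rng, fan_in, fan_out):
    return (Tensor(_xavier(rng, fan_in, fan_out), requires_grad=True),
            Tensor(np.zeros(fan_out), requires_grad=True))


def _block_params(rng, cfg: ModelConfig) -> dict:
    d, a = cfg.projection_dim, cfg.attention_width
    p = {}
    p["up_w"], p["up_b"] = _linear_params(rng, d, a)
    for nm in ("q", "k", "v", "o"):
        p[f"{nm}_w"], p[f"{nm}_b"] = _linear_params(rng, a, a)
    p["down_w"], p["down_b"] = _linear_params(rng, a, d)
    hidden = cfg.mlp_ratio * d
    p["mlp1_w"], p["mlp1_b"] = _linear_params(rng, d, hidden)
    p["mlp2_w"], p["mlp2_b"] = _linear_params(rng, hidden, d)
    p["alpha_a"] = Tensor(ALPHA_INIT, requires_grad=True)
    p["alpha_m"] = Tensor(ALPHA_INIT, requires_grad=True)
    return p


class TrpcaModel:
    """The TRPCA network: parameters, forward passes and (de)serialization."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        cfg = config
        j, d = cfg.pca_dim, cfg.projection_dim
        self.params: dict[str, Tensor] = {}
        self.params["proj_w"], self.params["proj_b"] = _linear_params(rng, j, j * d)
        self.blocks = [_block_params(rng, cfg) for _ in range(cfg.num_transformer_layers)]
        for i, blk in enumerate(self.blocks):
            for k, v in blk.items():
                self.params[f"block{i}.{k}"] = v
        pooled = cfg.pooled_dim
        if cfg.task in {"regression"}:
            self.params["reg_w"], self.params["reg_b"] = _linear_params(rng, pooled, 1)
        if cfg.task in {"classification", "mtl"}:
            self.params["cls_w"], self.params["cls_b"] = _linear_params(rng, pooled, cfg.n_classes)
        if cfg.task == "mtl":
            self.mtl_block = _block_params(rng, cfg)
            for k, v in self.mtl_block.items():
                self.params[f"mtl_block.{k}"] = v
            self.params["reg_w"], self.params["reg_b"] = _linear_params(
                rng, pooled + cfg.n_classes, 1)
        self._drop_rng = np.random.default_rng(self.seed + 1)
        self.training = False

    # -- plumbing ---------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def _check_finite(self, t: Tensor, where: str) -> None:
        if not np.isfinite(t.data).all():
            raise FloatingPointError(f"non-finite values produced in {where}")

    def _dropout(self, t: Tensor) -> Tensor:
        p = self.config.dropout
        if not self.training or p == 0.0:
            return t
        mask = (self._drop_rng.random(t.shape) >= p) / (1.0 - p)
        return t * Tensor(mask)

    # -- forward pieces ---------------------------------------------------
    def project_multiview(self, x: Tensor | np.ndarray) -> Tensor:
        """Linear map to (batch, pca_dim, projection_dim) + per-token L2 norm."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        cfg = self.config
        if x.shape[-1] != cfg.pca_dim:
            raise ValueError(
                f"embedding width {x.shape[-1]} != pca_dim {cfg.pca_dim}")
        h = x @ self.params["proj_w"] + self.params["proj_b"]
        h = h.reshape((x.shape[0], cfg.pca_dim, cfg.projection_dim))
        return l2_normalize(h, axis=-1)

    def _attention(self, x: Tensor, p: dict) -> Tensor:
        cfg = self.config
        b, j = x.shape[0], x.shape[1]
        a, h = cfg.attention_width, cfg.nhead
        dh = a // h
        up = x @ p["up_w"] + p["up_b"]  # (b, j, a)
        q = up @ p["q_w"] + p["q_b"]
        k = up @ p["k_w"] + p["k_b"]
        v = up @ p["v_w"] + p["v_b"]

        def split(t: Tensor) -> Tensor:  # (b, j, a) -> (b, h, j, dh)
            return t.reshape((b, j, h, dh)).transpose((0, 2, 1, 3))

        q, k, v = split(q), split(k), split(v)
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(dh))
        attn = softmax(scores, axis=-1)
        attn = self._dropout(attn)
        ctx = attn @ v  # (b, h, j, dh)
        ctx = ctx.transpose((0, 2, 1, 3)).reshape((b, j, a))
        out = ctx @ p["o_w"] + p["o_b"]
        return out @ p["down_w"] + p["down_b"]  # back to token width

    def _mlp(self, x: Tensor, p: dict) -> Tensor:
        h = gelu(x @ p["mlp1_w"] + p["mlp1_b"])
        h = self._dropout(h)
        return h @ p["mlp2_w"] + p["mlp2_b"]

    def normalized_block(self, x: Tensor, p: dict) -> Tensor:
        """One normalized transformer block (attention then MLP residual)."""
        att = self._attention(x, p)
        self._check_finite(att, "attention sub-layer")
        h_a = l2_normalize(x + p["alpha_a"] * (att - x), axis=-1)
        m = self._mlp(h_a, p)
        self._check_finite(m, "MLP sub-layer")
        h_m = l2_normalize(h_a + p["alpha_m"] * (m - h_a), axis=-1)
        return h_m

    def pool(self, seq: Tensor) -> Tensor:
        """Global average pooling (over the projection axis by default)."""
        axis = 2 if self.config.pool_axis == "projection" else 1
        return seq.mean(axis=axis)

    def encode(self, x: Tensor | np.ndarray) -> Tensor:
        seq = self.project_multiview(x)
        for blk in self.blocks:
            seq = self.normalized_block(seq, blk)
        return seq

    # -- heads ------------------------------------------------------------
    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        """Regression → (batch, 1) ages; classification → (batch, n_classes)."""
        cfg = self.config
        pooled = self.pool(self.encode(x))
        if cfg.task == "regression":
            return pooled @ self.params["reg_w"] + self.params["reg_b"]
        if cfg.task == "classification":
            return pooled @ self.params["cls_w"] + self.params["cls_b"]
        raise ValueError("use forward_mtl for task='mtl'")

    def forward_mtl(self, x: Tensor | np.ndarray) -> tuple[Tensor, Tensor]:
        """Joint heads: (class scores (batch, n_classes), ages (batch, 1)).

        The shared encoder output feeds the classification head directly and,
        through one extra attention block, the regression branch; the pooled
        regression-attention output and the class scores are concatenated into
        the regression head.
        """
        if self.config.task != "mtl":
            raise ValueError("forward_mtl requires task='mtl'")
        enc = self.encode(x)
        logits = self.pool(enc) @ self.params["cls_w"] + self.params["cls_b"]
        reg_seq = self.normalized_block(enc, self.mtl_block)
        reg_pooled = self.pool(reg_seq)
        joint = concat([reg_pooled, logits], axis=1)
        ages = joint @ self.params["reg_w"] + self.params["reg_b"]
        return logits, ages

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Deterministic forward in eval mode, returned as plain arrays."""
        self.training = False
        outs = []
        for i in range(0, x.shape[0], batch_size):
            xb = x[i:i + batch_size]
            if self.config.task == "mtl":
                logits, ages = self.forward_mtl(xb)
                outs.append(np.concatenate([logits.data, ages.data], axis=1))
            else:
                outs.append(self.forward(xb).data)
        return np.concatenate(outs, axis=0)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {k: v.data for k, v in self.params.items()}
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"config": asdict(self.config), "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "TrpcaModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig(**meta["config"]), seed=meta["seed"])
        with np.load(path.with_suffix(".npz")) as arrays:
            for k in model.params:
                model.params[k].data = arrays[k].astype(np.float64)
        return model
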