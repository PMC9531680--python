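"""Scale-aware transformer diagnosis network.

A whole-slide tile rendered at several magnifications is classified in three
steps: (1) the tile at each scale is cut into non-overlapping patches and a
small CNN embeds each patch independently; (2) a per-scale transformer over
the patch tokens (with sinusoidal positional embeddings added) produces
contextualized patch embeddings which are averaged into one embedding per
scale; (3) the scale embeddings, augmented with learnable per-scale
embeddings, pass through a cross-scale transformer, are flattened to an
(S*e)-vector and classified linearly into diagnostic categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor
from .synthio.multiscale import MultiScaleCase

__all__ = ["ScAtNetConfig", "PatchGrid", "tile_image", "sinusoidal_pos_embed",
           "ScAtNet", "train_scatnet", "evaluate_scatnet"]

DEFAULT_SCALES = ("7.5x", "10x", "12.5x")


@dataclass(frozen=True)
class ScAtNetConfig:
    scales: tuple[str, ...] = DEFAULT_SCALES
    patch_size: int = 32
    embed_dim: int = 16
    n_heads: int = 2
    n_layers_scale: int = 1
    n_layers_fusion: int = 1
    n_classes: int = 4
    use_positional: bool = True
    epochs: int = 30
    batch_size: int = 8
    lr: float = 3e-3
    seed: int = 0

    def __post_init__(self):
        if len(self.scales) < 1:
            raise ValueError("at least one scale required")
        if self.embed_dim % 2:
            raise ValueError("embedding dim must be even for sinusoidal pairs")
        if self.n_classes < 2:
            raise ValueError("need at least 2 diagnostic classes")


@dataclass
class PatchGrid:
    patches: np.ndarray          # (m, p, p, 3)
    positions: list[tuple[int, int]]  # row-major (row, col)
    scale: str = ""


def tile_image(image: np.ndarray, patch_size: int, scale: str = "") -> PatchGrid:
    """Pad with white to multiples of ``patch_size`` and cut a row-major grid."""
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    if image.size == 0:
        raise ValueError("empty image")
    h, w = image.shape[:2]
    p = patch_size
    nh, nw = -(-h // p), -(-w // p)
    padded = np.full((nh * p, nw * p, 3), 255, dtype=image.dtype)
    padded[:h, :w] = image
    patches = []
    positions = []
    for r in range(nh):
        for c in range(nw):
            patches.append(padded[r * p:(r + 1) * p, c * p:(c + 1) * p])
            positions.append((r, c))
    return PatchGrid(patches=np.stack(patches), positions=positions, scale=scale)


def sinusoidal_pos_embed(positions, e: int) -> np.ndarray:
    """Standard transformer sin/cos embedding over linearized indices.

    ``positions`` may be integers or (row, col) pairs; pairs are linearized
    row-major using the maximum column index present.
    """
    if e % 2:
        raise ValueError("embedding dim must be even")
    pos = list(positions)
    if pos and isinstance(pos[0], tuple):
        ncol = max(c for _, c in pos) + 1
        idx = np.array([r * ncol + c for r, c in pos], dtype=float)
    else:
        idx = np.array(pos, dtype=float)
    half = e // 2
    freqs = 1.0 / (10000.0 ** (np.arange(half) / half))
    ang = idx[:, None] * freqs[None, :]
    out = np.empty((len(idx), e))
    out[:, 0::2] = np.sin(ang)
    out[:, 1::2] = np.cos(ang)
    return out


class _PatchEncoder(nn.Module):
    """Small CNN applied to each patch independently."""

    def __init__(self, e: int, rng):
        self.net = nn.Sequential(
            nn.Conv2d(3, 8, 3, rng, stride=2), nn.ReLU(),
            nn.Conv2d(8, 16, 3, rng, stride=2), nn.ReLU(),
        )
        self.proj = nn.Linear(16, e, rng)

    def forward(self, patches: Tensor) -> Tensor:
        h = self.net(patches).mean(axis=(2, 3))
        return self.proj(h)


class ScAtNet(nn.Module):
    def __init__(self, config: ScAtNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        e = config.embed_dim
        self.encoder = _PatchEncoder(e, rng)
        # per-scale transformers are scale-specific (statistics differ)
        self.scale_blocks = {
            sc: [nn.TransformerBlock(e, config.n_heads, rng)
                 for _ in range(config.n_layers_scale)]
            for sc in config.scales}
        self.scale_embed = nn.Parameter(rng.normal(0, 0.5, size=(len(config.scales), e)))
        self.fusion_blocks = [nn.TransformerBlock(e, config.n_heads, rng)
                              for _ in range(config.n_layers_fusion)]
        self.classifier = nn.Linear(len(config.scales) * e, config.n_classes, rng)

    # -- stages, exposed for inspection and tests -----------------------------

    def embed_patches(self, grid: PatchGrid) -> Tensor:
        """(m, e) patch embeddings; row i depends only on patch i."""
        x = Tensor(grid.patches.astype(np.float64).transpose(0, 3, 1, 2)
                   / 255.0 - 0.5)
        return self.encoder(x)

    def contextualize_scale(self, emb: Tensor, grid: PatchGrid,
                            scale: str) -> Tensor:
        """Transformer over patch tokens, then mean -> one e-vector."""
        if self.config.use_positional:
            emb = emb + sinusoidal_pos_embed(grid.positions, self.config.embed_dim)
        tokens = emb.reshape(1, *emb.shape)
        for block in self.scale_blocks[scale]:
            tokens = block(tokens)
        return tokens.mean(axis=1).reshape(-1)

    def scale_fuse(self, per_scale: list[Tensor]) -> Tensor:
        """(S, e) contextualized scale embeddings."""
        dims = {t.shape[-1] for t in per_scale}
        if len(dims) != 1:
            raise ValueError(f"mismatched embedding dims across scales: {dims}")
        stackd = nn.concat([t.reshape(1, -1) for t in per_scale], axis=0)
        tokens = (stackd + self.scale_embed[:len(per_scale)]).reshape(
            1, len(per_scale), self.config.embed_dim)
        for block in self.fusion_blocks:
            tokens = block(tokens)
        return tokens.reshape(len(per_scale), self.config.embed_dim)

    def classify(self, scale_embeddings: Tensor) -> Tensor:
        """Flatten (S, e) -> (S*e,) and map to class probabilities."""
        flat = scale_embeddings.reshape(1, -1)
        return F.softmax(self.classifier(flat), axis=-1).reshape(-1)

    def logits(self, case: MultiScaleCase) -> Tensor:
        per_scale = []
        for sc in self.config.scales:
            if sc not in case.images:
                raise ValueError(f"case {case.case_id} missing scale {sc}")
            grid = tile_image(case.images[sc], self.config.patch_size, scale=sc)
            emb = self.embed_patches(grid)
            per_scale.append(self.contextualize_scale(emb, grid, sc))
        fused = self.scale_fuse(per_scale)
        return self.classifier(fused.reshape(1, -1)).reshape(-1)

    def predict_proba(self, case: MultiScaleCase) -> np.ndarray:
        return F.softmax(self.logits(case).reshape(1, -1), axis=-1).data[0]


@dataclass
class ScAtNetTrainLog:
    losses: list[float] = field(default_factory=list)
    metrics: list[dict] = field(default_factory=list)


def train_scatnet(cases: list[MultiScaleCase], config: ScAtNetConfig,
                  val_cases: list[MultiScaleCase] | None = None
                  ) -> tuple[ScAtNet, ScAtNetTrainLog]:
    """End-to-end training on a multi-scale cohort.

    Every case must provide all configured scales; per-epoch metrics on the
    validation cohort (or the training cohort if none is given) are logged.
    """
    for case in cases:
        missing = [sc for sc in config.scales if sc not in case.images]
        if missing:
            raise ValueError(f"case {case.case_id} missing scales {missing}")
    model = ScAtNet(config)
    opt = nn.Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    labels = np.array([c.label for c in cases])
    log = ScAtNetTrainLog()
    eval_set = val_cases if val_cases is not None else cases
    for epoch in range(config.epochs):
        # cosine learning-rate decay stabilizes the late epochs
        opt.lr = config.lr * 0.5 * (1.0 + np.cos(np.pi * epoch / config.epochs))
        order = rng.permutation(len(cases))
        total = 0.0
        for start in range(0, len(cases), config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            logit_rows = nn.concat(
                [model.logits(cases[i]).reshape(1, -1) for i in idx], axis=0)
            loss = F.cross_entropy(logit_rows, labels[idx])
            if not np.isfinite(loss.item()):
                raise FloatingPointError(f"divergent loss at epoch {epoch}")
            loss.backward()
            opt.step()
            total += loss.item() * len(idx)
        log.losses.append(total / len(cases))
        log.metrics.append(evaluate_scatnet(model, eval_set))
    return model, log


def evaluate_scatnet(model: ScAtNet, cases: list[MultiScaleCase]) -> dict:
    from .evalmetrics import multiclass_metrics

    probs = np.stack([model.predict_proba(c) for c in cases])
    labels = np.array([c.label for c in cases])
    return multiclass_metrics(probs, labels)
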