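"""Mitosis-vs-normal patch classification.

The pipeline operates on 101x101 RGB patches centered on a candidate
nucleus: extraction with edge padding at image borders, a six-fold
augmentation (rotations by 45/90/135/225 degrees plus horizontal and
vertical mirrors), a stratified 80/20 split with the configured 3:1
normal-to-mitosis class ratio, training of a small CNN with a pluggable
encoder, and confusion-count evaluation with mitosis as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["PATCH_SIZE", "LabeledPatch", "SplitSpec", "extract_patch",
           "augment", "split_dataset", "PatchClassifier",
           "train_patch_classifier", "evaluate_patch_classifier"]

PATCH_SIZE = 101
MITOSIS, NORMAL = 1, 0


@dataclass(frozen=True)
class LabeledPatch:
    pixels: np.ndarray  # (101, 101, 3) uint8
    label: int          # 1 = mitosis, 0 = normal
    source_id: str = ""

    def __post_init__(self):
        if self.pixels.shape != (PATCH_SIZE, PATCH_SIZE, 3):
            raise ValueError(
                f"patch must be {PATCH_SIZE}x{PATCH_SIZE}x3, got {self.pixels.shape}")
        if self.label not in (MITOSIS, NORMAL):
            raise ValueError("label must be 0 (normal) or 1 (mitosis)")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    class_ratio: float = 3.0  # normals per mitosis
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def extract_patch(image: np.ndarray, center: tuple[int, int]) -> np.ndarray:
    """101x101 window centered at ``center`` = (row, col).

    The center pixel maps to window index (50, 50); areas beyond the image
    border are filled by edge replication.
    """
    h, w = image.shape[:2]
    r, c = center
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"center {center} outside image of shape {h}x{w}")
    half = PATCH_SIZE // 2
    padded = np.pad(image, ((half, half), (half, half), (0, 0)), mode="edge")
    return padded[r:r + PATCH_SIZE, c:c + PATCH_SIZE]


def augment(patch: LabeledPatch) -> list[LabeledPatch]:
    """Six label-preserving variants: rotations 45/90/135/225 + two mirrors.

    Non-right-angle rotations use edge padding and are recropped to the
    patch size; the 90-degree rotation is exact (counter-clockwise).
    """
    px = patch.pixels
    out = []
    for angle in (45, 90, 135, 225):
        if angle == 90:
            rot = np.rot90(px)
        else:
            rot = ndimage.rotate(px.astype(np.float64), angle, axes=(1, 0),
                                 reshape=False, order=1, mode="nearest")
            rot = np.clip(np.rint(rot), 0, 255).astype(px.dtype)
        out.append(LabeledPatch(rot, patch.label, f"{patch.source_id}|rot{angle}"))
    out.append(LabeledPatch(px[:, ::-1].copy(), patch.label,
                            f"{patch.source_id}|hflip"))
    out.append(LabeledPatch(px[::-1].copy(), patch.label,
                            f"{patch.source_id}|vflip"))
    return out


def split_dataset(patches: list[LabeledPatch],
                  spec: SplitSpec) -> tuple[list[LabeledPatch], list[LabeledPatch]]:
    """Stratified train/validation partition, deterministic given the seed."""
    by_class: dict[int, list[int]] = {MITOSIS: [], NORMAL: []}
    for i, p in enumerate(patches):
        by_class[p.label].append(i)
    for lab, idxs in by_class.items():
        if len(idxs) < 2:
            raise ValueError(f"class {lab} has fewer than 2 patches")
    rng = np.random.default_rng(spec.seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for lab in (MITOSIS, NORMAL):
        idxs = np.array(by_class[lab])
        rng.shuffle(idxs)
        n_train = int(round(len(idxs) * spec.train_fraction))
        train_idx.extend(idxs[:n_train])
        val_idx.extend(idxs[n_train:])
    return ([patches[i] for i in sorted(train_idx)],
            [patches[i] for i in sorted(val_idx)])


# -- models -------------------------------------------------------------------

class _SmallEncoder(nn.Module):
    """Compact strided CNN (stands in for an efficient pyramid encoder)."""

    def __init__(self, rng):
        self.net = nn.Sequential(
            nn.Conv2d(3, 8, 3, rng, stride=2), nn.ReLU(),
            nn.Conv2d(8, 16, 3, rng, stride=2), nn.ReLU(),
            nn.Conv2d(16, 16, 3, rng, stride=2), nn.ReLU(),
        )
        self.out_dim = 16

    def forward(self, x: Tensor) -> Tensor:
        h = self.net(x)
        return h.mean(axis=(2, 3))  # global average pool -> (N, C)


class _DenseEncoder(nn.Module):
    """Encoder with dense (concatenative) feature reuse between stages."""

    def __init__(self, rng):
        self.c1 = nn.Conv2d(3, 8, 3, rng, stride=2)
        self.c2 = nn.Conv2d(8, 8, 3, rng, stride=1)
        self.c3 = nn.Conv2d(16, 16, 3, rng, stride=2)  # consumes [c1, c2]
        self.c4 = nn.Conv2d(16, 16, 3, rng, stride=2)
        self.out_dim = 32

    def forward(self, x: Tensor) -> Tensor:
        h1 = self.c1(x).relu()
        h2 = self.c2(h1).relu()
        dense = nn.concat([h1, h2], axis=1)
        h3 = self.c3(dense).relu()
        h4 = self.c4(h3).relu()
        pooled3 = h3.mean(axis=(2, 3))
        pooled4 = h4.mean(axis=(2, 3))
        return nn.concat([pooled3, pooled4], axis=1)


ENCODERS = {"small": _SmallEncoder, "dense": _DenseEncoder}


class PatchClassifier(nn.Module):
    """Encoder + linear head mapping a patch to a mitosis probability."""

    def __init__(self, encoder: str = "small", seed: int = 0):
        if encoder not in ENCODERS:
            raise ValueError(f"unknown encoder {encoder!r}; choose from {sorted(ENCODERS)}")
        rng = np.random.default_rng(seed)
        self.encoder = ENCODERS[encoder](rng)
        self.head = nn.Linear(self.encoder.out_dim, 1, rng)
        self.encoder_name = encoder

    def logits(self, batch: np.ndarray) -> Tensor:
        x = Tensor(batch.astype(np.float64).transpose(0, 3, 1, 2) / 255.0 - 0.5)
        return self.head(self.encoder(x)).reshape(-1)

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Mitosis probability for a (N, 101, 101, 3) batch."""
        return self.logits(patches).sigmoid().data


@dataclass
class TrainLog:
    losses: list[float]


def _as_arrays(patches: list[LabeledPatch]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.pixels for p in patches])
    y = np.array([p.label for p in patches], dtype=float)
    return x, y


def train_patch_classifier(train: list[LabeledPatch], encoder: str = "small",
                           epochs: int = 10, batch_size: int = 16,
                           lr: float = 1e-2, seed: int = 0
                           ) -> tuple[PatchClassifier, TrainLog]:
    """Train a binary patch classifier; returns (model, loss-per-epoch log)."""
    if not train:
        raise ValueError("empty training set")
    model = PatchClassifier(encoder=encoder, seed=seed)
    opt = nn.Adam(model.parameters(), lr=lr)
    rng = np.random.default_rng(seed + 1)
    x, y = _as_arrays(train)
    log = TrainLog(losses=[])
    for epoch in range(epochs):
        order = rng.permutation(len(x))
        total = 0.0
        for start in range(0, len(x), batch_size):
            idx = order[start:start + batch_size]
            opt.zero_grad()
            loss = F.bce_with_logits(model.logits(x[idx]), y[idx])
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"divergent loss at epoch {epoch}: {loss.item()}")
            loss.backward()
            opt.step()
            total += loss.item() * len(idx)
        log.losses.append(total / len(x))
    return model, log


def evaluate_patch_classifier(model: PatchClassifier,
                              val: list[LabeledPatch],
                              threshold: float = 0.5):
    """Confusion counts on a validation set; mitosis is the positive class."""
    from .evalmetrics import ConfusionCounts

    if not val:
        raise ValueError("empty validation set")
    x, y = _as_arrays(val)
    prob = model.predict_proba(x)
    pred = prob >= threshold
    truth = y == 1
    return ConfusionCounts(
        tp=int((pred & truth).sum()), tn=int((~pred & ~truth).sum()),
        fp=int((pred & ~truth).sum()), fn=int((~pred & truth).sum()))
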