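"""Two-stage semantic segmentation of skin tissue.

Stage 1 is a small U-Net over the four coarse classes (background, stratum
corneum, epidermis, dermis), trained with sparse labels: unlabeled (UL)
pixels are excluded from the loss.  Stage 2 holds two region-restricted nest
segmenters — one for dermal nests on dermis-masked input, one for epidermal
nests on epidermis-masked input — whose inputs have all pixels outside the
kept region replaced by a white fill.  Deterministic composition overlays the
nest predictions on the stage-1 mask, keeping only nest pixels that fall
inside their parent region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from . import palette as P
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["SegConfig", "StageModel", "train_stage1", "mask_region",
           "train_stage2", "compose_masks", "run_pipeline"]

STAGE1_CLASSES = (P.BG, P.COR, P.EP, P.DE)
REGION_CODES = {"dermis": P.DE, "epidermis": P.EP}
NEST_CODES = {"dermis": P.DMN, "epidermis": P.EPN}


@dataclass(frozen=True)
class SegConfig:
    base_channels: int = 8
    steps: int = 200
    batch_size: int = 4
    lr: float = 5e-3
    seed: int = 0


class _UNet(nn.Module):
    """Two-level U-Net: strided-conv encoder, nearest-upsample decoder."""

    def __init__(self, n_out: int, base: int, rng):
        c = base
        self.enc1 = nn.Conv2d(3, c, 3, rng)
        self.enc2 = nn.Conv2d(c, 2 * c, 3, rng, stride=2)
        self.mid = nn.Conv2d(2 * c, 2 * c, 3, rng)
        self.dec1 = nn.Conv2d(3 * c, c, 3, rng)  # up(mid) concat enc1
        self.head = nn.Conv2d(c, n_out, 1, rng, padding=0)

    def forward(self, x: Tensor) -> Tensor:
        e1 = self.enc1(x).relu()
        e2 = self.enc2(e1).relu()
        m = self.mid(e2).relu()
        up = F.upsample_nearest2d(m, 2)
        d1 = self.dec1(nn.concat([up, e1], axis=1)).relu()
        return self.head(d1)  # (N, n_out, H, W) logits


@dataclass
class StageModel:
    """A trained stage network plus its class bookkeeping.

    ``classes`` maps network output channels to palette codes.
    """

    stage: str  # stage1 | stage2_dermis | stage2_epidermis
    classes: tuple[int, ...]
    net: _UNet
    losses: list[float] = field(default_factory=list)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Per-pixel palette labels for a (N, H, W, 3) uint8 batch."""
        x = Tensor(images.astype(np.float64).transpose(0, 3, 1, 2) / 255.0 - 0.5)
        logits = self.net(x).data
        idx = logits.argmax(axis=1)
        return np.asarray(self.classes)[idx].astype(np.uint8)


def _to_batch(images: np.ndarray) -> Tensor:
    return Tensor(images.astype(np.float64).transpose(0, 3, 1, 2) / 255.0 - 0.5)


def _train(images: np.ndarray, masks: np.ndarray, classes: tuple[int, ...],
           stage: str, config: SegConfig) -> StageModel:
    rng = np.random.default_rng(config.seed)
    net = _UNet(len(classes), config.base_channels, np.random.default_rng(config.seed))
    opt = nn.Adam(net.parameters(), lr=config.lr)
    # palette code -> channel index; UL handled by the ignore mask
    lut = np.full(P.N_CLASSES, -1, dtype=int)
    for ch, code in enumerate(classes):
        lut[code] = ch
    target = lut[masks]
    ignore = masks == P.UL
    model = StageModel(stage=stage, classes=classes, net=net)
    n = len(images)
    for step in range(config.steps):
        idx = rng.integers(0, n, size=min(config.batch_size, n))
        logits = net(_to_batch(images[idx]))
        loss = F.cross_entropy(logits, np.clip(target[idx], 0, None),
                               ignore_mask=ignore[idx], axis=1)
        if not np.isfinite(loss.item()):
            raise FloatingPointError(f"divergent loss at step {step}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        model.losses.append(loss.item())
    return model


def train_stage1(images: np.ndarray, masks: np.ndarray,
                 config: SegConfig = SegConfig()) -> StageModel:
    """Train the coarse-tissue segmenter on possibly sparse masks."""
    bad = set(np.unique(masks)) - {P.UL, *STAGE1_CLASSES}
    if bad:
        names = [P.CLASS_NAMES[b] for b in sorted(bad)]
        raise ValueError(f"stage-1 masks may not contain {names}")
    return _train(images, masks, STAGE1_CLASSES, "stage1", config)


def mask_region(image: np.ndarray, stage1_mask: np.ndarray, keep: int,
                fill=P.FILL_WHITE) -> np.ndarray:
    """White-out every pixel whose stage-1 label is not the kept region."""
    if keep not in (P.DE, P.EP):
        raise ValueError(f"keep must be DE ({P.DE}) or EP ({P.EP}), got {keep}")
    if image.shape[:2] != stage1_mask.shape:
        raise ValueError("mask dimensions do not match image")
    out = image.copy()
    out[stage1_mask != keep] = fill
    return out


def train_stage2(masked_images: np.ndarray, nest_masks: np.ndarray,
                 region: str, config: SegConfig = SegConfig()) -> StageModel:
    """Train a nest-vs-region segmenter on region-masked images.

    ``nest_masks`` may contain only UL, the region's own code (non-nest
    tissue) and the region's nest code.
    """
    if region not in REGION_CODES:
        raise ValueError(f"region must be one of {sorted(REGION_CODES)}")
    region_code = REGION_CODES[region]
    nest_code = NEST_CODES[region]
    allowed = {P.UL, region_code, nest_code}
    bad = set(np.unique(nest_masks)) - allowed
    if bad:
        names = [P.CLASS_NAMES[b] for b in sorted(bad)]
        raise ValueError(
            f"stage-2 {region} masks may not contain {names}")
    return _train(masked_images, nest_masks, (region_code, nest_code),
                  f"stage2_{region}", config)


def compose_masks(stage1_mask: np.ndarray, dermis_nest_mask: np.ndarray,
                  epidermis_nest_mask: np.ndarray) -> np.ndarray:
    """Overlay nest predictions on the coarse mask, inside parent regions only."""
    if not (stage1_mask.shape == dermis_nest_mask.shape ==
            epidermis_nest_mask.shape):
        raise ValueError("mask dimension mismatch")
    out = stage1_mask.copy()
    out[(dermis_nest_mask == P.DMN) & (stage1_mask == P.DE)] = P.DMN
    out[(epidermis_nest_mask == P.EPN) & (stage1_mask == P.EP)] = P.EPN
    return out


def run_pipeline(image: np.ndarray, stage1: StageModel,
                 stage2_dermis: StageModel,
                 stage2_epidermis: StageModel) -> np.ndarray:
    """stage 1 -> region masking -> stage 2 -> composition, one image."""
    for m, tag in ((stage1, "stage1"), (stage2_dermis, "stage2_dermis"),
                   (stage2_epidermis, "stage2_epidermis")):
        if m is None or m.stage != tag:
            raise ValueError(f"missing or mismatched model for {tag}")
    coarse = stage1.predict(image[None])[0]
    de_input = mask_region(image, coarse, P.DE)
    ep_input = mask_region(image, coarse, P.EP)
    dmn = stage2_dermis.predict(de_input[None])[0]
    epn = stage2_epidermis.predict(ep_input[None])[0]
    return compose_masks(coarse, dmn, epn)
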