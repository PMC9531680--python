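"""Virtual-staining-guided melanocyte detection, scaled to the desk.

A U-Net-style generator translates H&E-like tiles into SOX10-like tiles; two
identical patch discriminators judge realness at fine and half-resolution
scales; a detection branch reads the generator's decoder features and
proposes melanocyte boxes.  All three are trained jointly, so detection
gradients flow back into the decoder.  Inference uses only the generator and
the detection branch.

The generator objective combines the non-saturating adversarial term, a
paired L1 reconstruction term toward the reference stain, and the detection
loss.  The detection branch is anchor-free: a dense objectness map over the
finest decoder level plus per-pixel box-size regression, decoded by local
maximum extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .instances import Box, InstanceSet
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["VSGDConfig", "Detection", "VSGDModel", "generator_forward",
           "discriminator_forward", "detection_forward", "joint_train_step",
           "infer_melanocytes", "VSGDState", "train_vsgd"]


@dataclass(frozen=True)
class VSGDConfig:
    depth: int = 2                  # number of 2x downsamplings in G
    base_channels: int = 12
    attention_skips: bool = True
    disc_channels: int = 12
    det_levels: tuple[int, ...] = (0,)  # decoder levels feeding Det (0 = finest)
    det_score_threshold: float = 0.5
    w_adversarial: float = 1.0
    w_detection: float = 1.0
    w_reconstruction: float = 10.0
    lr: float = 2e-3
    pos_weight: float = 60.0        # objectness class-imbalance weight
    seed: int = 0

    def __post_init__(self):
        if len(self.det_levels) < 1:
            raise ValueError("at least one decoder level must feed Det")
        if not 0.0 <= self.det_score_threshold <= 1.0:
            raise ValueError("score threshold must lie in [0, 1]")


@dataclass(frozen=True)
class Detection:
    box: Box
    score: float
    label: str = "melanocyte"

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


class _Generator(nn.Module):
    def __init__(self, cfg: VSGDConfig, rng):
        c = cfg.base_channels
        self.depth = cfg.depth
        self.attention = cfg.attention_skips
        self.enc_in = nn.Conv2d(3, c, 3, rng)
        self.down = [nn.Conv2d(c * 2 ** i, c * 2 ** (i + 1), 3, rng, stride=2)
                     for i in range(cfg.depth)]
        self.mid = nn.Conv2d(c * 2 ** cfg.depth, c * 2 ** cfg.depth, 3, rng)
        self.up = []
        self.gates = []
        for i in reversed(range(cfg.depth)):
            skip_c = c * 2 ** i
            self.up.append(nn.Conv2d(c * 2 ** (i + 1) + skip_c, skip_c, 3, rng))
            self.gates.append(nn.Conv2d(skip_c, skip_c, 1, rng, padding=0))
        self.out = nn.Conv2d(c, 3, 1, rng, padding=0)

    def forward(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        h = self.enc_in(x).relu()
        skips = [h]
        for down in self.down:
            h = down(h).relu()
            skips.append(h)
        h = self.mid(h).relu()
        features: list[Tensor] = []
        for i, up in enumerate(self.up):
            skip = skips[self.depth - 1 - i]
            if self.attention:
                skip = skip * self.gates[i](skip).sigmoid()
            h = up(nn.concat([F.upsample_nearest2d(h, 2), skip], axis=1)).relu()
            features.append(h)
        stain = self.out(h).sigmoid()
        # features[-1] is the finest decoder level; expose finest-first
        return stain, features[::-1]


class _Discriminator(nn.Module):
    def __init__(self, c: int, rng):
        self.net = nn.Sequential(
            nn.Conv2d(3, c, 3, rng, stride=2), nn.LeakyReLU(0.2),
            nn.Conv2d(c, 2 * c, 3, rng, stride=2), nn.LeakyReLU(0.2),
            nn.Conv2d(2 * c, 1, 3, rng),
        )
        self.calls = 0  # forward-call accounting (inference must not use D)

    def forward(self, x: Tensor) -> Tensor:
        self.calls += 1
        return self.net(x)


class _DetHead(nn.Module):
    def __init__(self, c_in: int, rng):
        self.trunk = nn.Conv2d(c_in, c_in, 3, rng)
        self.obj = nn.Conv2d(c_in, 1, 1, rng, padding=0)
        self.size = nn.Conv2d(c_in, 2, 1, rng, padding=0)
        self.size.b.data = np.array([6.0, 6.0])  # start near nucleus size

    def forward(self, feat: Tensor) -> tuple[Tensor, Tensor]:
        h = self.trunk(feat).relu()
        return self.obj(h), self.size(h)


class VSGDModel(nn.Module):
    def __init__(self, config: VSGDConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.generator = _Generator(config, rng)
        self.disc_fine = _Discriminator(config.disc_channels, rng)
        self.disc_coarse = _Discriminator(config.disc_channels, rng)
        c = config.base_channels
        det_in = sum(c * 2 ** lvl for lvl in config.det_levels)
        self.det = _DetHead(det_in, rng)
        self.trained = False

    def det_input(self, features: list[Tensor]) -> Tensor:
        """Concatenate the configured decoder levels, upsampled to finest."""
        if not features:
            raise ValueError("empty decoder feature list")
        parts = []
        for lvl in self.config.det_levels:
            f = features[lvl]
            if lvl > 0:
                f = F.upsample_nearest2d(f, 2 ** lvl)
            parts.append(f)
        return parts[0] if len(parts) == 1 else nn.concat(parts, axis=1)


def _to_float(images: np.ndarray) -> Tensor:
    """(N, H, W, 3) uint8 -> NCHW float in [0, 1]."""
    return Tensor(images.astype(np.float64).transpose(0, 3, 1, 2) / 255.0)


def generator_forward(model: VSGDModel,
                      images: np.ndarray) -> tuple[np.ndarray, list[Tensor]]:
    """Translate H&E tiles to stain tiles; also return decoder features.

    Returns the stain batch as (N, H, W, 3) float in [0, 1].
    """
    h, w = images.shape[1:3]
    mult = 2 ** model.config.depth
    if h % mult or w % mult:
        raise ValueError(
            f"image dims {h}x{w} must be divisible by {mult} (2^depth)")
    stain, feats = model.generator(_to_float(images))
    return stain.data.transpose(0, 2, 3, 1), feats


def discriminator_forward(model: VSGDModel,
                          images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fine and coarse realness logit maps for an image batch.

    The coarse discriminator sees the input average-pooled by 2; the two
    discriminators are architecturally identical.
    """
    x = _to_float(images)
    fine = model.disc_fine(x).data
    coarse = model.disc_coarse(F.avg_pool2d(x, 2)).data
    return fine, coarse


def detection_forward(model: VSGDModel, features: list[Tensor],
                      image_shape: tuple[int, int] | None = None
                      ) -> list[list[Detection]]:
    """Decode melanocyte detections from decoder features.

    Peaks of the sigmoid objectness map (3x3 local maxima at or above the
    configured score threshold) become boxes with the regressed size,
    clipped to image bounds.
    """
    feat = model.det_input(features)
    obj_logit, size = model.det(feat)
    prob = 1.0 / (1.0 + np.exp(-obj_logit.data[:, 0]))
    sizes = size.data
    n, fh, fw = prob.shape
    ih, iw = image_shape if image_shape is not None else (fh, fw)
    out: list[list[Detection]] = []
    thr = model.config.det_score_threshold
    for i in range(n):
        p = prob[i]
        peaks = (p == ndimage.maximum_filter(p, size=3)) & (p >= thr) if thr < 1.0 \
            else np.zeros_like(p, dtype=bool)
        dets = []
        for cy, cx in zip(*np.nonzero(peaks)):
            bw = float(np.clip(sizes[i, 0, cy, cx], 2.0, iw))
            bh = float(np.clip(sizes[i, 1, cy, cx], 2.0, ih))
            x0 = int(np.clip(round(cx - bw / 2), 0, iw - 1))
            y0 = int(np.clip(round(cy - bh / 2), 0, ih - 1))
            x1 = int(np.clip(round(cx + bw / 2), x0 + 1, iw))
            y1 = int(np.clip(round(cy + bh / 2), y0 + 1, ih))
            dets.append(Detection(box=Box(x0, y0, x1, y1),
                                  score=float(p[cy, cx])))
        dets.sort(key=lambda d: -d.score)
        out.append(dets)
    return out


def _det_targets(instances: list[InstanceSet], shape: tuple[int, int, int],
                 pos_weight: float):
    """Objectness / size targets on the finest decoder grid (full res)."""
    n, h, w = shape
    obj = np.zeros((n, h, w))
    size = np.zeros((n, 2, h, w))
    weight = np.ones((n, h, w))
    for i, inst in enumerate(instances):
        for b in inst.boxes:
            cy = min(h - 1, (b.y0 + b.y1) // 2)
            cx = min(w - 1, (b.x0 + b.x1) // 2)
            obj[i, cy, cx] = 1.0
            weight[i, cy, cx] = pos_weight
            size[i, 0, cy, cx] = b.x1 - b.x0
            size[i, 1, cy, cx] = b.y1 - b.y0
    return obj, size, weight


@dataclass
class VSGDState:
    model: VSGDModel
    opt_g: nn.Adam
    opt_d: nn.Adam
    history: list[dict] = field(default_factory=list)

    @classmethod
    def init(cls, config: VSGDConfig) -> "VSGDState":
        model = VSGDModel(config)
        g_params = model.generator.parameters() + model.det.parameters()
        d_params = model.disc_fine.parameters() + model.disc_coarse.parameters()
        return cls(model=model, opt_g=nn.Adam(g_params, lr=config.lr),
                   opt_d=nn.Adam(d_params, lr=config.lr))


def joint_train_step(state: VSGDState, he_batch: np.ndarray,
                     stain_batch: np.ndarray,
                     instances: list[InstanceSet]) -> dict[str, float]:
    """One optimization step of G+Det and D on aligned triples.

    Returns the loss components.  Non-finite losses abort with a state dump
    (parameter norms per submodule).
    """
    model, cfg = state.model, state.model.config
    x = _to_float(he_batch)
    target = _to_float(stain_batch)

    # --- generator + detection update ---------------------------------------
    state.opt_g.zero_grad()
    stain, feats = model.generator(x)
    adv_fine = F.bce_with_logits(model.disc_fine(stain),
                                 np.ones((1,)))  # broadcast target 1
    adv_coarse = F.bce_with_logits(model.disc_coarse(F.avg_pool2d(stain, 2)),
                                   np.ones((1,)))
    adv_g = (adv_fine + adv_coarse) * 0.5
    rec = abs(stain - target).mean()

    feat = model.det_input(feats)
    obj_logit, size_pred = model.det(feat)
    n, _, fh, fw = obj_logit.shape
    obj_t, size_t, wgt = _det_targets(instances, (n, fh, fw), cfg.pos_weight)
    det_obj = F.bce_with_logits(obj_logit.reshape(n, fh, fw), obj_t, weight=wgt)
    pos = obj_t[:, None].repeat(2, axis=1)
    n_pos = pos.sum()
    if n_pos > 0:
        det_size = (abs(size_pred - size_t) * pos).sum() / n_pos * 0.1
    else:
        det_size = det_obj * 0.0
    det_loss = det_obj + det_size

    g_loss = (cfg.w_adversarial * adv_g + cfg.w_reconstruction * rec
              + cfg.w_detection * det_loss)
    values = {"adv_g": adv_g.item(), "reconstruction": rec.item(),
              "detection": det_loss.item()}
    if not all(np.isfinite(v) for v in values.values()):
        dump = {k: float(np.linalg.norm(p.data)) for k, p in zip(
            ("generator", "det"), (model.generator.parameters()[0],
                                   model.det.parameters()[0]))}
        raise FloatingPointError(f"non-finite generator loss {values}; "
                                 f"state {dump}")
    g_loss.backward()
    state.opt_g.step()

    # --- discriminator update ------------------------------------------------
    state.opt_d.zero_grad()
    fake = Tensor(stain.data)  # detached
    d_loss = (
        F.bce_with_logits(model.disc_fine(target), np.ones((1,)))
        + F.bce_with_logits(model.disc_fine(fake), np.zeros((1,)))
        + F.bce_with_logits(model.disc_coarse(F.avg_pool2d(target, 2)),
                            np.ones((1,)))
        + F.bce_with_logits(model.disc_coarse(F.avg_pool2d(fake, 2)),
                            np.zeros((1,)))
    ) * 0.25
    values["adv_d"] = d_loss.item()
    if not np.isfinite(values["adv_d"]):
        raise FloatingPointError(f"non-finite discriminator loss {values}")
    d_loss.backward()
    state.opt_d.step()

    state.history.append(values)
    return values


def train_vsgd(he: np.ndarray, stains: np.ndarray,
               instances: list[InstanceSet], config: VSGDConfig,
               steps: int = 300, batch_size: int = 4) -> VSGDState:
    """Joint training loop over aligned (H&E, stain, instances) triples."""
    state = VSGDState.init(config)
    rng = np.random.default_rng(config.seed + 1)
    n = len(he)
    for _ in range(steps):
        idx = rng.integers(0, n, size=min(batch_size, n))
        joint_train_step(state, he[idx], stains[idx], [instances[i] for i in idx])
    state.model.trained = True
    return state


def infer_melanocytes(he_image: np.ndarray, model: VSGDModel
                      ) -> tuple[np.ndarray, list[Detection]]:
    """Inference pass: generator and detection branch only (no discriminator)."""
    if not model.trained:
        import warnings
        warnings.warn("model has not been trained; detections will be noise",
                      stacklevel=2)
    batch = he_image[None] if he_image.ndim == 3 else he_image
    stain, feats = generator_forward(model, batch)
    dets = detection_forward(model, feats, image_shape=batch.shape[1:3])
    return stain[0], dets[0]
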