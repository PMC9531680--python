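"""Shared fixtures.

The expensive trained-model fixtures are session-scoped so each model is
trained exactly once per test run and shared between the module tests and
the end-to-end recovery tests.
"""

import numpy as np
import pytest

from melanopath import palette as P
from melanopath import segtwostage as st
from melanopath import synthio, vsgd
from melanopath.instances import InstanceSet


def make_tissue_batch(n, seed0, size=64, n_dermal=2, n_epidermal=1,
                      n_melanocytes=8, radius=(4, 6)):
    """Render n tissue tiles; returns (images, masks, instance sets)."""
    imgs, masks, insts = [], [], []
    for i in range(n):
        params = synthio.TissueParams(
            image_height=size, image_width=size, n_dermal_nests=n_dermal,
            n_epidermal_nests=n_epidermal, nest_radius_range=radius,
            n_melanocytes=n_melanocytes, seed=seed0 + i)
        img, mask, inst = synthio.gen_tissue_image(params)
        imgs.append(img)
        masks.append(mask)
        insts.append(inst)
    return np.stack(imgs), np.stack(masks), insts


@pytest.fixture(scope="session")
def seg_data():
    tr_img, tr_mask, _ = make_tissue_batch(12, 100)
    te_img, te_mask, _ = make_tissue_batch(6, 900)
    return {"train": (tr_img, tr_mask), "test": (te_img, te_mask)}


@pytest.fixture(scope="session")
def seg_models(seg_data):
    """Three trained stage models on the toy tissue cohort."""
    tr_img, tr_mask = seg_data["train"]
    coarse = np.stack([synthio.coarse_labels(m) for m in tr_mask])
    cfg = st.SegConfig(steps=200, seed=0)
    stage1 = st.train_stage1(tr_img, coarse, cfg)
    de_in = np.stack([st.mask_region(im, cm, P.DE)
                      for im, cm in zip(tr_img, coarse)])
    de_masks = np.where(tr_mask == P.DMN, P.DMN,
                        np.where(coarse == P.DE, P.DE, P.UL)).astype(np.uint8)
    stage2_de = st.train_stage2(de_in, de_masks, "dermis", cfg)
    ep_in = np.stack([st.mask_region(im, cm, P.EP)
                      for im, cm in zip(tr_img, coarse)])
    ep_masks = np.where(tr_mask == P.EPN, P.EPN,
                        np.where(coarse == P.EP, P.EP, P.UL)).astype(np.uint8)
    stage2_ep = st.train_stage2(ep_in, ep_masks, "epidermis", cfg)
    return stage1, stage2_de, stage2_ep


@pytest.fixture(scope="session")
def vsgd_trained():
    """Jointly trained VSGD model plus held-out stain/detection test data."""
    he, masks, insts = make_tissue_batch(12, 0, n_dermal=1)
    stains = np.stack([synthio.gen_virtual_stain_pair(im, i)
                       for im, i in zip(he, insts)])
    he_te, _, inst_te = make_tissue_batch(6, 500, n_dermal=1)
    stain_te = np.stack([synthio.gen_virtual_stain_pair(im, i)
                         for im, i in zip(he_te, inst_te)])
    state = vsgd.train_vsgd(he, stains, insts, vsgd.VSGDConfig(seed=0),
                            steps=300)
    return {"state": state, "test": (he_te, stain_te, inst_te)}


@pytest.fixture(scope="session")
def scatnet_separable():
    """ScAtNet trained on the nest-density cohort; returns final metrics."""
    from melanopath import scatnet as sn

    cases = synthio.gen_multiscale_cohort(22, seed=0)
    tr, te = cases[:48], cases[48:]
    cfg = sn.ScAtNetConfig(n_classes=3, epochs=80, lr=5e-3, seed=0)
    model, log = sn.train_scatnet(tr, cfg, val_cases=te)
    return {"model": model, "log": log, "test": te}


@pytest.fixture(scope="session")
def scatnet_crossscale():
    """Accuracy of multi-scale vs each single scale on the cross-cue cohort."""
    from melanopath import scatnet as sn

    cases = synthio.gen_crossscale_cohort(20, seed=0)
    tr, te = cases[:45], cases[45:]
    accs = {}
    for scales in (("7.5x", "10x", "12.5x"), ("7.5x",), ("10x",), ("12.5x",)):
        cfg = sn.ScAtNetConfig(scales=scales, n_classes=3, epochs=40,
                               lr=5e-3, seed=0)
        _, log = sn.train_scatnet(tr, cfg, val_cases=te)
        accs[scales] = log.metrics[-1]["accuracy"]
    return accs


def detections_to_instances(dets) -> InstanceSet:
    return InstanceSet(boxes=[d.box for d in dets],
                       labels=[d.label for d in dets],
                       scores=[d.score for d in dets])
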