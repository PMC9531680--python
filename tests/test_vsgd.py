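"""Tests for the virtual-staining GAN with joint melanocyte detection."""

import numpy as np
import pytest

from melanopath import nn, synthio, vsgd
from melanopath.evalmetrics import ConfusionCounts, detection_prf, match_detections

from conftest import detections_to_instances, make_tissue_batch


@pytest.fixture()
def fresh_state():
    return vsgd.VSGDState.init(vsgd.VSGDConfig(seed=0))


@pytest.fixture()
def tiny_batch():
    he, _, insts = make_tissue_batch(2, 0, n_dermal=1)
    stains = np.stack([synthio.gen_virtual_stain_pair(im, i)
                       for im, i in zip(he, insts)])
    return he, stains, insts


class TestGeneratorForward:
    def test_output_matches_input_dims(self, fresh_state, tiny_batch):
        he = tiny_batch[0]
        stain, feats = vsgd.generator_forward(fresh_state.model, he)
        assert stain.shape == he.shape
        assert len(feats) == fresh_state.model.config.depth
        # finest decoder level has full spatial resolution
        assert feats[0].shape[2:] == he.shape[1:3]

    def test_indivisible_dims_error_names_multiple(self, fresh_state):
        he = np.zeros((1, 63, 64, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="divisible by 4"):
            vsgd.generator_forward(fresh_state.model, he)

    def test_inference_is_bit_deterministic(self, fresh_state, tiny_batch):
        he = tiny_batch[0]
        a, _ = vsgd.generator_forward(fresh_state.model, he)
        b, _ = vsgd.generator_forward(fresh_state.model, he)
        assert a.tobytes() == b.tobytes()

    def test_output_in_valid_range(self, fresh_state, tiny_batch):
        stain, _ = vsgd.generator_forward(fresh_state.model, tiny_batch[0])
        assert stain.min() >= 0.0 and stain.max() <= 1.0


class TestDiscriminators:
    def test_identical_architectures(self, fresh_state):
        fine = fresh_state.model.disc_fine.param_shapes()
        coarse = fresh_state.model.disc_coarse.param_shapes()
        assert fine == coarse

    def test_coarse_map_is_half_resolution(self, fresh_state, tiny_batch):
        fine, coarse = vsgd.discriminator_forward(fresh_state.model,
                                                  tiny_batch[0])
        assert coarse.shape[2] == pytest.approx(fine.shape[2] / 2, abs=1)
        assert coarse.shape[3] == pytest.approx(fine.shape[3] / 2, abs=1)

    def test_trained_discriminator_prefers_real(self, vsgd_trained):
        state = vsgd_trained["state"]
        he_te, stain_te, _ = vsgd_trained["test"]
        frozen = vsgd.VSGDModel(vsgd.VSGDConfig(seed=0))  # untrained generator
        fake, _ = vsgd.generator_forward(frozen, he_te)
        fake_u8 = (fake * 255).astype(np.uint8)
        real_fine, _ = vsgd.discriminator_forward(state.model, stain_te)
        fake_fine, _ = vsgd.discriminator_forward(state.model, fake_u8)
        assert real_fine.mean() > fake_fine.mean()


class TestDetectionForward:
    def test_threshold_one_yields_no_detections(self, fresh_state, tiny_batch):
        model = vsgd.VSGDModel(vsgd.VSGDConfig(det_score_threshold=1.0, seed=0))
        _, feats = vsgd.generator_forward(model, tiny_batch[0])
        dets = vsgd.detection_forward(model, feats)
        assert all(len(d) == 0 for d in dets)

    def test_boxes_clipped_to_image_bounds(self, vsgd_trained):
        state = vsgd_trained["state"]
        he_te = vsgd_trained["test"][0]
        _, dets = vsgd.infer_melanocytes(he_te[0], state.model)
        h, w = he_te[0].shape[:2]
        for d in dets:
            assert 0 <= d.box.x0 < d.box.x1 <= w
            assert 0 <= d.box.y0 < d.box.y1 <= h
            assert 0.0 <= d.score <= 1.0

    def test_empty_feature_list_rejected(self, fresh_state):
        with pytest.raises(ValueError, match="empty"):
            vsgd.detection_forward(fresh_state.model, [])


class TestJointTrainStep:
    def test_losses_finite_at_random_init(self, fresh_state, tiny_batch):
        he, stains, insts = tiny_batch
        losses = vsgd.joint_train_step(fresh_state, he, stains, insts)
        assert set(losses) == {"adv_g", "reconstruction", "detection", "adv_d"}
        assert all(np.isfinite(v) for v in losses.values())

    def test_zero_detection_weight_sgd_leaves_det_unchanged(self, tiny_batch):
        he, stains, insts = tiny_batch
        state = vsgd.VSGDState.init(vsgd.VSGDConfig(w_detection=0.0, seed=0))
        g_params = state.model.generator.parameters()
        det_params = state.model.det.parameters()
        state.opt_g = nn.SGD(g_params + det_params, lr=1e-3)
        before = [p.data.copy() for p in det_params]
        g_before = [p.data.copy() for p in g_params]
        vsgd.joint_train_step(state, he, stains, insts)
        for p, b in zip(det_params, before):
            np.testing.assert_array_equal(p.data, b)
        assert any(not np.array_equal(p.data, b)
                   for p, b in zip(g_params, g_before))

    def test_loss_decreases_on_fixed_batch(self, tiny_batch):
        he, stains, insts = tiny_batch
        state = vsgd.VSGDState.init(vsgd.VSGDConfig(seed=1))

        def total_g(entry):
            cfg = state.model.config
            return (cfg.w_adversarial * entry["adv_g"]
                    + cfg.w_reconstruction * entry["reconstruction"]
                    + cfg.w_detection * entry["detection"])

        for _ in range(50):
            vsgd.joint_train_step(state, he, stains, insts)
        assert total_g(state.history[-1]) < total_g(state.history[0])

    def test_no_nan_across_training(self, vsgd_trained):
        history = vsgd_trained["state"].history
        assert len(history) == 300
        for entry in history:
            assert all(np.isfinite(v) for v in entry.values())


class TestInference:
    def test_discriminators_unused_during_inference(self, vsgd_trained):
        state = vsgd_trained["state"]
        he = vsgd_trained["test"][0][0]
        before = (state.model.disc_fine.calls, state.model.disc_coarse.calls)
        vsgd.infer_melanocytes(he, state.model)
        after = (state.model.disc_fine.calls, state.model.disc_coarse.calls)
        assert before == after

    def test_repeated_inference_identical(self, vsgd_trained):
        state = vsgd_trained["state"]
        he = vsgd_trained["test"][0][0]
        s1, d1 = vsgd.infer_melanocytes(he, state.model)
        s2, d2 = vsgd.infer_melanocytes(he, state.model)
        assert s1.tobytes() == s2.tobytes()
        assert d1 == d2

    def test_untrained_model_warns(self, fresh_state, tiny_batch):
        with pytest.warns(UserWarning, match="not been trained"):
            vsgd.infer_melanocytes(tiny_batch[0][0], fresh_state.model)


class TestToyRecovery:
    def test_stain_mae_below_bound(self, vsgd_trained):
        state = vsgd_trained["state"]
        he_te, stain_te, _ = vsgd_trained["test"]
        stain_pred, _ = vsgd.generator_forward(state.model, he_te)
        mae = np.abs(stain_pred - stain_te / 255.0).mean()
        assert mae < 0.15

    def test_detection_f1_at_iou_half(self, vsgd_trained):
        state = vsgd_trained["state"]
        he_te, _, inst_te = vsgd_trained["test"]
        tp = fp = fn = 0
        for i in range(len(he_te)):
            _, dets = vsgd.infer_melanocytes(he_te[i], state.model)
            c = match_detections(detections_to_instances(dets), inst_te[i], 0.5)
            tp, fp, fn = tp + c.tp, fp + c.fp, fn + c.fn
        score = detection_prf(ConfusionCounts(tp, 0, fp, fn))
        assert score.f1 >= 0.7

    def test_per_image_count_within_30pct(self, vsgd_trained):
        state = vsgd_trained["state"]
        he_te, _, inst_te = vsgd_trained["test"]
        for i in range(len(he_te)):
            _, dets = vsgd.infer_melanocytes(he_te[i], state.model)
            planted = len(inst_te[i])
            assert abs(len(dets) - planted) / planted <= 0.3

    def test_joint_and_detection_only_conditions_both_run(self, tiny_batch):
        # ablation harness: both conditions run and log their losses
        he, stains, insts = tiny_batch
        logs = {}
        for name, cfg in (
                ("joint", vsgd.VSGDConfig(seed=2)),
                ("det_only", vsgd.VSGDConfig(w_adversarial=0.0,
                                             w_reconstruction=0.0, seed=2))):
            state = vsgd.train_vsgd(he, stains, insts, cfg, steps=10)
            logs[name] = state.history
        assert len(logs["joint"]) == 10 and len(logs["det_only"]) == 10
        assert all(np.isfinite(e["detection"]) for e in logs["det_only"])
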