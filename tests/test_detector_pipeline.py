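"""Detector assembly, decoding, NMS, loss, profiling, checkpoints."""

import dataclasses

import numpy as np
import pytest

from yolobt.nn import autograd as ag
from yolobt.detector_pipeline import (
    DetectorConfig, TrainConfig, build_model, detection_loss, Detection,
    detect, decode_predictions, nms, kmeans_anchors, DetectionDataset,
    save_checkpoint, load_checkpoint, mosaic4, mixup, profile_model)
from yolobt.detector_pipeline.train import evaluate_detector
from yolobt.detector_pipeline.loss import build_targets, ciou


TINY = dict(width_multiple=0.125, depth_multiple=0.33, input_size=96,
            gicm_branch=(4, 3, 2), gicm_dk=8, gicm_token_pool=(400, 400, 400),
            hfgm_hidden=(None, None))


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(DetectorConfig(**TINY, seed=0))


class TestBuildModel:
    def test_head_grid_sizes(self, tiny_model):
        tiny_model.eval()
        x = ag.tensor(np.zeros((1, 3, 96, 96), dtype=np.float32))
        with ag.no_grad():
            preds = tiny_model(x)
        assert [p.shape[2:] for p in preds] == [(12, 12), (6, 6), (3, 3)]

    def test_640_grids_stride_arithmetic(self):
        cfg = DetectorConfig(clab=False, hfgm=False, gicm=False)
        model = build_model(cfg)
        model.eval()
        x = ag.tensor(np.zeros((1, 3, 640, 640), dtype=np.float32))
        with ag.no_grad():
            preds = model(x)
        assert [p.shape[2:] for p in preds] == [(80, 80), (40, 40), (20, 20)]

    def test_toggles_off_reduces_to_baseline_graph(self):
        cfg = DetectorConfig(**TINY, clab=False, hfgm=False, gicm=False)
        model = build_model(cfg)
        names = [n for n, _ in model.named_parameters()]
        assert not any("clam" in n or "gates" in n or "fuse1.gate" in n
                       for n in names)
        full = build_model(DetectorConfig(**TINY))
        full_names = [n for n, _ in full.named_parameters()]
        assert any("clam" in n for n in full_names)
        assert any("gates" in n for n in full_names)
        assert any("fuse1.up" in n for n in full_names)

    def test_same_seed_same_param_count_and_values(self):
        a = build_model(DetectorConfig(**TINY, seed=3))
        b = build_model(DetectorConfig(**TINY, seed=3))
        assert a.num_parameters() == b.num_parameters()
        for (na_, pa), (nb_, pb) in zip(a.named_parameters(),
                                        b.named_parameters()):
            assert na_ == nb_
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(input_size=100)
        with pytest.raises(ValueError):
            DetectorConfig(n_classes=0)


class TestDecodeAndNMS:
    def test_single_cell_decode_matches_hand_computation(self):
        # one-anchor-equivalent synthetic head output on a 1x1 grid
        anchors = np.array([[[16, 160]] * 3, [[16, 160]] * 3,
                            [[16, 160]] * 3], dtype=np.float32)
        no, na = 6, 3
        raw = np.full((1, na * no, 1, 1), -20.0, dtype=np.float32)
        tx, ty, tw, th, tobj, tcls = 0.3, -0.2, 0.1, 0.4, 2.0, 1.5
        raw[0, 0:6, 0, 0] = [tx, ty, tw, th, tobj, tcls]
        s = lambda z: 1 / (1 + np.exp(-z))
        boxes, confs, _ = decode_predictions([raw, raw * 0 - 20, raw * 0 - 20],
                                             anchors, input_size=8)
        # hand decode for stride 8, cell (0, 0), anchor (16, 160)
        ex = (s(tx) * 2 - 0.5) * 8 / 8
        ey = (s(ty) * 2 - 0.5) * 8 / 8
        ew = (s(tw) * 2) ** 2 * 16 / 8
        eh = (s(th) * 2) ** 2 * 160 / 8
        econf = s(tobj) * s(tcls)
        i = np.argmax(confs)
        np.testing.assert_allclose(boxes[i], [ex, ey, ew, eh], rtol=1e-5)
        assert confs[i] == pytest.approx(econf, rel=1e-5)

    def test_nms_keeps_highest_confidence(self):
        boxes = np.array([[0.5, 0.5, 0.1, 1.0], [0.5, 0.5, 0.1, 1.0]])
        keep = nms(boxes, np.array([0.8, 0.9]))
        assert list(keep) == [1]

    def test_nms_keeps_disjoint(self):
        boxes = np.array([[0.2, 0.5, 0.1, 1.0], [0.8, 0.5, 0.1, 1.0]])
        keep = nms(boxes, np.array([0.9, 0.8]))
        assert len(keep) == 2

    def test_blank_input_low_bias_no_detections(self):
        model = build_model(DetectorConfig(**TINY, seed=1))
        img = np.full((96, 96, 3), 255, dtype=np.uint8)
        for head in model.detect.heads:
            head.bias.data[:] = -12.0
        assert detect(model, img) == []

    def test_wrong_image_size_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            detect(tiny_model, np.zeros((64, 64, 3), dtype=np.uint8))


class TestLoss:
    def _targets(self):
        return np.array([[0, 0, 0.15, 0.5, 0.1, 1.0],
                         [0, 0, 0.45, 0.5, 0.1, 1.0]], dtype=np.float32)

    def test_loss_finite_for_all_ablation_configs(self):
        t = self._targets()
        for toggles in (dict(clab=False, hfgm=False, gicm=False),
                        dict(clab=True, hfgm=False, gicm=False),
                        dict(clab=True, hfgm=True, gicm=False),
                        dict(clab=True, hfgm=True, gicm=True)):
            cfg = DetectorConfig(**{**TINY, **toggles})
            model = build_model(cfg)
            model.train()
            x = ag.tensor(np.random.default_rng(0).random(
                (2, 3, 96, 96)).astype(np.float32))
            preds = model(x)
            loss, parts = detection_loss(preds, t, model.detect.anchors)
            assert np.isfinite(loss.data)
            loss.backward()

    def test_ciou_identical_boxes_is_one(self):
        b = ag.tensor(np.array([[1.0, 2.0, 3.0, 4.0]]))
        np.testing.assert_allclose(ciou(b, b).data, 1.0, atol=1e-6)

    def test_ciou_bounded(self):
        rng = np.random.default_rng(0)
        a = ag.tensor(rng.random((20, 4)) + 0.1)
        b = ag.tensor(rng.random((20, 4)) + 0.1)
        v = ciou(a, b).data
        assert (v <= 1.0 + 1e-6).all() and (v >= -1.5).all()

    def test_build_targets_empty(self):
        out = build_targets(np.zeros((0, 6)), np.ones((3, 3, 2)),
                            (8, 16, 32), [(12, 12), (6, 6), (3, 3)])
        assert out == [None, None, None]

    def test_anchor_ratio_filter(self):
        anchors = np.array([[[1, 1]] * 3] * 3, dtype=np.float32) * 8
        # a box 100x too large for every anchor matches nowhere
        t = np.array([[0, 0, 0.5, 0.5, 1.0, 1.0]], dtype=np.float32)
        out = build_targets(t, anchors, (8,), [(4, 4)])
        assert out[0] is None


class TestKMeansAnchors:
    def test_degenerate_all_identical(self):
        wh = np.tile([[16.0, 160.0]], (40, 1))
        anc = kmeans_anchors(wh)
        assert anc.shape == (3, 3, 2)
        areas = anc.reshape(-1, 2).prod(axis=1)
        assert (np.diff(areas) >= 0).all()

    def test_clusters_recovered(self):
        rng = np.random.default_rng(0)
        centers = np.array([[10, 20], [50, 80], [200, 300]])
        wh = np.concatenate([c + rng.normal(0, 1, (30, 2)) for c in centers])
        anc = kmeans_anchors(wh).reshape(-1, 2)
        for c in centers:
            assert np.min(np.linalg.norm(anc - c, axis=1)) < 10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            kmeans_anchors(np.zeros((0, 2)))


class TestData:
    def _dataset(self, n=6, size=64):
        rng = np.random.default_rng(0)
        imgs = [rng.integers(0, 255, (size, size, 3), dtype=np.uint8).astype(np.uint8)
                for _ in range(n)]
        labs = [np.array([[0, 0.25, 0.5, 0.1, 1.0]], dtype=np.float32)
                for _ in range(n)]
        return DetectionDataset(imgs, labs, [str(i) for i in range(n)])

    def test_mosaic_boxes_remapped(self):
        ds = self._dataset(4)
        img, lab = mosaic4(ds.images, ds.labels)
        assert img.shape == (64, 64, 3)
        assert lab.shape == (4, 5)
        np.testing.assert_allclose(sorted(lab[:, 1]),
                                   [0.125, 0.125, 0.625, 0.625])
        np.testing.assert_allclose(lab[:, 3], 0.05)

    def test_mixup_unions_labels(self):
        ds = self._dataset(2)
        img, lab = mixup(ds.images[0], ds.labels[0], ds.images[1], ds.labels[1],
                         rng=np.random.default_rng(0))
        assert lab.shape == (2, 5)
        assert img.shape == (64, 64, 3)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            DetectionDataset([], [], [])


class TestProfile:
    def test_deterministic(self):
        cfg = DetectorConfig(**TINY)
        assert profile_model(cfg, input_size=96) == \
            profile_model(cfg, input_size=96)

    def test_profile_uses_80_class_heads(self):
        cfg = DetectorConfig(**TINY, n_classes=1)
        p80, _ = profile_model(cfg, input_size=96)
        model1 = build_model(dataclasses.replace(cfg, n_classes=1))
        assert p80 * 1e6 > model1.num_parameters()


class TestCheckpoint:
    def test_roundtrip_reproduces_detections(self, tmp_path):
        cfg = DetectorConfig(**TINY, seed=7)
        model = build_model(cfg)
        model.detect.anchors = kmeans_anchors(np.tile([[10.0, 90.0]], (20, 1)))
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (96, 96, 3)).astype(np.uint8)
        before = detect(model, img, conf_thresh=0.001)
        save_checkpoint(model, tmp_path / "w.npz")
        loaded = load_checkpoint(tmp_path / "w.npz")
        after = detect(loaded, img, conf_thresh=0.001)
        assert len(before) == len(after)
        for a, b in zip(before, after):
            np.testing.assert_allclose(a.box, b.box, rtol=1e-5)
            assert a.confidence == pytest.approx(b.confidence, rel=1e-5)


class TestTrainConfig:
    def test_table_recipe_defaults(self):
        cfg = TrainConfig()
        assert cfg.epochs == 600
        assert cfg.patience == 50
        assert cfg.batch_size == 16
        assert cfg.initial_lr == 0.01
        assert cfg.momentum == 0.937
        assert cfg.weight_decay == 0.0005
        assert cfg.mixup_alpha == 0.2
        assert cfg.split == (0.70, 0.15, 0.15)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(split=(0.5, 0.2, 0.2))

    def test_cosine_schedule_starts_at_initial_lr(self):
        from yolobt.nn import cosine_lr
        assert cosine_lr(0.01, 0, 600) == pytest.approx(0.01)
        assert cosine_lr(0.01, 599, 600) == pytest.approx(0.0001, rel=1e-6)
        mid = cosine_lr(0.01, 300, 600)
        assert 0.0001 < mid < 0.01
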