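"""Second stage: RoIAlign, GRoIE, sampling, losses, assembly, training."""

import math

import numpy as np
import pytest

from foalwatch import autodiff as ag
from foalwatch.autodiff import Tensor
from foalwatch.boxes import DetectionBox
from foalwatch.detector import (GRoIE, DetectorConfig, LossConfig,
                                SamplerConfig, TrainConfig, assemble_lmpd,
                                balanced_l1_loss, detect, groie_extract,
                                iou_balanced_sample, roi_align,
                                roi_align_tensor, train_tiny)
from foalwatch.synthetic import SceneSpec, generate_dataset

RNG = np.random.default_rng(55)


def brute_force_roi_align(fmap, box, out=14, sampling=2):
    """Independent per-cell bilinear oracle (explicit loops)."""
    C, H, W = fmap.shape
    x, y, w, h = box
    res = np.zeros((C, out, out))
    for i in range(out):
        for j in range(out):
            acc = np.zeros(C)
            for sy in range(sampling):
                for sx in range(sampling):
                    py = y + (i + (sy + 0.5) / sampling) * h / out
                    px = x + (j + (sx + 0.5) / sampling) * w / out
                    py = min(max(py, 0.0), H - 1.0)
                    px = min(max(px, 0.0), W - 1.0)
                    y0, x0 = int(math.floor(py)), int(math.floor(px))
                    y1, x1 = min(y0 + 1, H - 1), min(x0 + 1, W - 1)
                    wy, wx = py - y0, px - x0
                    acc += (
                        fmap[:, y0, x0] * (1 - wy) * (1 - wx)
                        + fmap[:, y0, x1] * (1 - wy) * wx
                        + fmap[:, y1, x0] * wy * (1 - wx)
                        + fmap[:, y1, x1] * wy * wx
                    )
            res[:, i, j] = acc / (sampling * sampling)
    return res


class TestRoiAlign:
    def test_constant_map_fills_all_cells(self):
        fmap = np.full((3, 6, 6), 4.5)
        out = roi_align(fmap, (1.2, 0.7, 3.3, 4.1))
        assert out.shape == (3, 14, 14)
        assert np.allclose(out, 4.5)

    def test_grid_is_14x14_regardless_of_box(self):
        fmap = RNG.normal(size=(2, 8, 8))
        for box in [(0, 0, 8, 8), (2.5, 3.1, 0.9, 0.4)]:
            assert roi_align(fmap, box).shape == (2, 14, 14)

    def test_ramp_increases_along_box_axis(self):
        fmap = np.tile(np.arange(8.0), (1, 8, 1))
        out = roi_align(fmap, (0.5, 0.5, 7.0, 7.0))
        rowmeans = out[0].mean(axis=0)
        assert np.all(np.diff(rowmeans) > 0)

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_bruteforce_bilinear_oracle(self, trial):
        rng = np.random.default_rng(trial)
        fmap = rng.normal(size=(3, 8, 8))
        box = (rng.uniform(0, 3), rng.uniform(0, 3),
               rng.uniform(0.5, 4.5), rng.uniform(0.5, 4.5))
        ours = roi_align(fmap, box)
        oracle = brute_force_roi_align(fmap, box)
        assert np.max(np.abs(ours - oracle)) <= 1e-6

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            roi_align(np.zeros((1, 4, 4)), (0, 0, 0.0, 2.0))


def _toy_pyramid(value_by_level):
    strides = {"P2": 4, "P3": 8, "P4": 16, "P5": 32}
    return (
        {k: np.full((4, 32 // s * 2, 32 // s * 2), float(v))
         for (k, s), v in zip(strides.items(), value_by_level)},
        strides,
    )


class TestGRoIE:
    def test_onehot_level_weights_equal_single_level(self):
        pyramid = {k: RNG.normal(size=(4, hw, hw))
                   for k, hw in [("P2", 16), ("P3", 8), ("P4", 4), ("P5", 2)]}
        strides = {"P2": 4, "P3": 8, "P4": 16, "P5": 32}
        mod = GRoIE(4, pre="identity", post="identity")
        mod.level_logits.data = np.array([-1e9, 0.0, -1e9, -1e9])
        box = (6.0, 5.0, 20.0, 14.0)
        fused = groie_extract(pyramid, [box], mod, strides)[0]
        scaled = tuple(v / strides["P3"] for v in box)
        direct = roi_align(pyramid["P3"], scaled)
        assert np.allclose(fused, direct, atol=1e-12)

    def test_uniform_weights_average_per_level_constants(self):
        pyramid, strides = _toy_pyramid((1.0, 2.0, 3.0, 6.0))
        mod = GRoIE(4, pre="identity", post="identity")
        fused = groie_extract(pyramid, [(2.0, 2.0, 10.0, 8.0)], mod, strides)[0]
        assert np.allclose(fused, np.mean([1.0, 2.0, 3.0, 6.0]))

    def test_identical_levels_equal_single_level_alignment(self):
        base = RNG.normal(size=(4, 16, 16))
        pyramid = {k: base for k in ("P2", "P3", "P4", "P5")}
        strides = {k: 4 for k in pyramid}  # same geometry on every level
        mod = GRoIE(4, pre="identity", post="identity")
        box = (8.0, 4.0, 24.0, 20.0)
        fused = groie_extract(pyramid, [box], mod, strides)[0]
        direct = roi_align(base, tuple(v / 4 for v in box))
        assert np.allclose(fused, direct, atol=1e-12)

    def test_empty_pyramid_rejected(self):
        mod = GRoIE(4, levels=())
        with pytest.raises(ValueError):
            mod({}, np.zeros((1, 4)), np.zeros(1, dtype=int))


class TestIoUBalancedSampler:
    def test_even_bins_get_equal_quotas(self):
        ious = np.concatenate([
            np.linspace(0.0, 0.0999, 30),
            np.linspace(0.1, 0.1999, 30),
            np.linspace(0.2, 0.2999, 30),
        ])
        cfg = SamplerConfig(n_samples=30, pos_fraction=0.0, k_bins=3)
        _, neg = iou_balanced_sample(ious, np.zeros(90, bool), cfg, seed=0)
        assert len(neg) == 30
        bins = np.floor(ious[neg] / 0.1).astype(int)
        assert (np.bincount(bins, minlength=3) == [10, 10, 10]).all()

    def test_request_beyond_supply_returns_everything(self):
        ious = np.array([0.05, 0.15, 0.25])
        cfg = SamplerConfig(n_samples=64, pos_fraction=0.0)
        _, neg = iou_balanced_sample(ious, np.zeros(3, bool), cfg, seed=1)
        assert sorted(neg) == [0, 1, 2]

    def test_single_bin_degenerates_to_plain_sampling(self):
        ious = RNG.uniform(0, 0.3, size=50)
        cfg = SamplerConfig(n_samples=20, pos_fraction=0.0, k_bins=1)
        _, neg = iou_balanced_sample(ious, np.zeros(50, bool), cfg, seed=2)
        assert len(neg) == 20 and len(set(neg)) == 20

    def test_no_candidates_gives_empty_sample(self):
        pos, neg = iou_balanced_sample(np.array([]), np.array([], bool),
                                       SamplerConfig(), seed=3)
        assert len(pos) == 0 and len(neg) == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_quotas_respected_when_bins_populated(self, seed):
        rng = np.random.default_rng(seed)
        ious = rng.uniform(0, 0.2999, size=120)
        cfg = SamplerConfig(n_samples=30, pos_fraction=0.0, k_bins=3)
        _, neg = iou_balanced_sample(ious, np.zeros(120, bool), cfg, seed=seed)
        bins = np.floor(ious[neg] / 0.1).astype(int)
        counts = np.bincount(bins, minlength=3)
        # every sufficiently-populated bin contributes its share
        for b in range(3):
            avail = np.sum((ious >= b * 0.1) & (ious < (b + 1) * 0.1))
            assert counts[b] >= min(avail, 10) - 1

    def test_deterministic_per_seed(self):
        ious = RNG.uniform(0, 0.3, size=40)
        cfg = SamplerConfig(n_samples=16, pos_fraction=0.0)
        a = iou_balanced_sample(ious, np.zeros(40, bool), cfg, seed=9)
        b = iou_balanced_sample(ious, np.zeros(40, bool), cfg, seed=9)
        assert np.array_equal(a[1], b[1])


def closed_form_balanced_l1(x, alpha=0.5, gamma=1.5):
    b = math.exp(gamma / alpha) - 1.0
    u = abs(x)
    if u < 1.0:
        return alpha / b * (b * u + 1) * math.log(b * u + 1) - alpha * u
    C = alpha / b * (b + 1) * math.log(b + 1) - alpha - gamma
    return gamma * u + C


class TestBalancedL1:
    def test_zero_at_zero(self):
        assert balanced_l1_loss(0.0) == 0.0

    def test_continuous_at_one(self):
        lo = balanced_l1_loss(1.0 - 1e-10)
        hi = balanced_l1_loss(1.0 + 1e-10)
        assert abs(lo - hi) < 1e-9

    def test_matches_independent_closed_form(self):
        for x in (-2.0, -0.7, 0.1, 0.5, 1.0, 2.0, 5.0):
            assert balanced_l1_loss(x) == pytest.approx(
                closed_form_balanced_l1(x), abs=1e-12
            )

    def test_even_nonnegative_and_asymptotically_linear(self):
        xs = np.linspace(-6, 6, 201)
        vals = balanced_l1_loss(xs)
        assert np.allclose(vals, vals[::-1])
        assert np.all(vals >= 0)
        assert vals[np.abs(xs) > 0].min() > 0
        slope = (balanced_l1_loss(100.0) - balanced_l1_loss(99.0))
        assert slope == pytest.approx(1.5, abs=1e-9)

    def test_gradient_matches_analytic_derivative(self):
        x = Tensor(np.array([-1.5, -0.4, 0.3, 2.0]), requires_grad=True)
        ag.sum_(balanced_l1_loss(x)).backward()
        eps = 1e-7
        for i, v in enumerate([-1.5, -0.4, 0.3, 2.0]):
            num = (closed_form_balanced_l1(v + eps)
                   - closed_form_balanced_l1(v - eps)) / (2 * eps)
            assert x.grad[i] == pytest.approx(num, abs=1e-5)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(alpha=0.0)


TINY = DetectorConfig(widths=(16, 32, 64, 128), neck_channels=16, head_width=32)


def _tiny_dataset(n=3, seed=0):
    template = SceneSpec(width=96, height=64, n_mares=1,
                         postures=("standing",), classes=("MNP",), seed=seed)
    buf = []
    ds = generate_dataset(n, 0.5, template, scenes_out=buf)
    return ds, {im.id: buf[i].image for i, im in enumerate(ds.images)}


class TestDetectorAssembly:
    def test_untrained_detect_contract(self):
        model = assemble_lmpd(TINY)
        ds, images = _tiny_dataset(1)
        dets = detect(model, images[1])
        for d in dets:
            assert isinstance(d, DetectionBox)
            assert 0.0 <= d.score <= 1.0
            assert d.label in ("MP", "MNP")

    def test_inference_is_deterministic(self):
        model = assemble_lmpd(TINY)
        ds, images = _tiny_dataset(1)
        a, b = detect(model, images[1]), detect(model, images[1])
        assert a == b

    def test_too_small_image_rejected(self):
        model = assemble_lmpd(TINY)
        with pytest.raises(ValueError):
            detect(model, np.zeros((32, 32, 3), dtype=np.uint8))


class TestTraining:
    def test_zero_learning_rate_leaves_weights_unchanged(self):
        model = assemble_lmpd(TINY)
        before = {k: v.copy() for k, v in model.state_dict().items()
                  if not k.endswith(("running_mean", "running_var"))}
        ds, images = _tiny_dataset(2)
        train_tiny(model, ds, images, TrainConfig(iterations=2, lr=0.0, seed=0))
        after = model.state_dict()
        for k, v in before.items():
            assert np.array_equal(v, after[k]), k

    def test_loss_decreases_on_small_fixture(self):
        ds, images = _tiny_dataset(4, seed=3)
        finals, initials = [], []
        for seed in range(3):
            model = assemble_lmpd(DetectorConfig(
                widths=TINY.widths, neck_channels=TINY.neck_channels,
                head_width=TINY.head_width, seed=seed))
            hist = train_tiny(model, ds, images,
                              TrainConfig(iterations=40, seed=seed))
            initials.append(np.mean(hist[:5]))
            finals.append(np.mean(hist[-5:]))
        assert np.median(finals) < np.median(initials)

    def test_empty_dataset_rejected(self):
        from foalwatch.coco import CocoDataset

        model = assemble_lmpd(TINY)
        with pytest.raises(ValueError):
            train_tiny(model, CocoDataset(), {}, TrainConfig(iterations=1))


class TestConfigIO:
    def test_yaml_config_roundtrip(self, tmp_path):
        from foalwatch.detector import load_detector_config

        cfg_file = tmp_path / "model.yaml"
        cfg_file.write_text(
            "layout: [1, 1, 2, 1]\n"
            "attention: {kind: SE, reduction: 8}\n"
            "neck_channels: 24\n"
            "carafe: {k_up: 5, c_mid: 16}\n"
        )
        cfg = load_detector_config(cfg_file)
        assert cfg.layout == (1, 1, 2, 1)
        assert cfg.attention.kind == "SE" and cfg.attention.reduction == 8
        assert cfg.neck_channels == 24
        assert cfg.carafe.c_mid == 16

    def test_null_attention_disables_gates(self, tmp_path):
        from foalwatch.detector import load_detector_config

        cfg_file = tmp_path / "plain.yaml"
        cfg_file.write_text("attention: null\n")
        assert load_detector_config(cfg_file).attention is None
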