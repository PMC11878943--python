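"""CARAFE reassembly and the balanced feature pyramid."""

import numpy as np
import pytest

from foalwatch import autodiff as ag
from foalwatch.autodiff import Tensor
from foalwatch.pyramid import (BFPRefine, CarafeBFP, CarafeParams,
                               CarafeUpsample, FPNTopDown, bfp_integrate,
                               bfp_refine, carafe_bfp, carafe_reassemble,
                               carafe_upsample, delta_kernels, fpn_topdown,
                               uniform_kernels)

RNG = np.random.default_rng(21)


def brute_force_uniform_mean(x: np.ndarray, k: int, sigma: int) -> np.ndarray:
    """Zero-padded k×k neighbourhood mean at each upsampled location."""
    C, H, W = x.shape
    out = np.zeros((C, sigma * H, sigma * W))
    r = k // 2
    for i in range(sigma * H):
        for j in range(sigma * W):
            si, sj = i // sigma, j // sigma
            acc = np.zeros(C)
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    y, xx = si + di, sj + dj
                    if 0 <= y < H and 0 <= xx < W:
                        acc += x[:, y, xx]
            out[:, i, j] = acc / (k * k)
    return out


class TestCarafe:
    def test_uniform_kernels_match_bruteforce_neighbourhood_mean(self):
        x = RNG.normal(size=(2, 4, 5))
        alpha = uniform_kernels(1, 5, (8, 10))
        with ag.no_grad():
            out = carafe_reassemble(Tensor(x[None]), alpha, 5, 2,
                                    pad_mode="zero").numpy()[0]
        expected = brute_force_uniform_mean(x, 5, 2)
        assert np.allclose(out, expected, atol=1e-10)

    def test_delta_kernels_reduce_to_nearest_neighbour(self):
        x = RNG.normal(size=(3, 4, 6))
        alpha = delta_kernels(1, 5, (8, 12))
        with ag.no_grad():
            out = carafe_reassemble(Tensor(x[None]), alpha, 5, 2).numpy()[0]
        nearest = np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)
        assert np.array_equal(out, nearest)

    def test_predicted_kernels_sum_to_one_everywhere(self):
        mod = CarafeUpsample(8, CarafeParams(c_mid=16))
        x = Tensor(RNG.normal(size=(1, 8, 6, 7)))
        with ag.no_grad():
            alpha = mod.predict_kernels(x).numpy()
        assert np.max(np.abs(alpha.sum(axis=1) - 1.0)) <= 1e-6

    def test_constants_are_fixed_points(self):
        mod = CarafeUpsample(4, CarafeParams(c_mid=8, pad_mode="edge"))
        x = np.stack([np.full((5, 6), v) for v in (2.0, -1.0, 0.0, 7.5)])
        out = carafe_upsample(x, mod)
        for c, v in enumerate((2.0, -1.0, 0.0, 7.5)):
            assert np.allclose(out[c], v, atol=1e-9)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            CarafeParams(k_up=4)

    def test_output_dims_scale_by_sigma(self):
        mod = CarafeUpsample(4, CarafeParams(c_mid=8))
        out = carafe_upsample(RNG.normal(size=(4, 5, 7)), mod)
        assert out.shape == (4, 10, 14)


def _const_maps(values, channels=(8, 16, 32, 64), base=16):
    maps = {}
    for i, (k, c, v) in enumerate(zip(("C2", "C3", "C4", "C5"), channels, values)):
        h = base // (2 ** i)
        maps[k] = np.full((c, h, 2 * h), float(v))
    return maps


class TestFPNTopDown:
    def test_constant_inputs_accumulate_laterals(self):
        mod = FPNTopDown((8, 16, 32, 64), out_channels=8, upsampler="nearest")
        maps = _const_maps((1.0, 2.0, -1.0, 0.5))
        out = fpn_topdown(maps, mod)
        # closed form: each lateral 1x1 conv maps a constant to a constant;
        # the top-down sum of constants stays constant
        with ag.no_grad():
            lat_consts = []
            for lat, (k, m) in zip(mod.laterals, maps.items()):
                v = lat(Tensor(m[None])).numpy()[0][:, :1, :1]
                lat_consts.append(v)
        expected_p2 = sum(lat_consts)[:, 0, 0]
        assert np.allclose(out["P2"], expected_p2[:, None, None], atol=1e-9)
        for k, v in out.items():
            flat = v.reshape(v.shape[0], -1)
            assert np.allclose(flat, flat[:, :1], atol=1e-9), k

    def test_five_output_levels(self):
        mod = FPNTopDown((8, 16, 32, 64), out_channels=8)
        out = fpn_topdown(_const_maps((1, 1, 1, 1)), mod)
        assert set(out) == {"P2", "P3", "P4", "P5", "P6"}

    def test_p2_keeps_finest_resolution(self):
        mod = FPNTopDown((8, 16, 32, 64), out_channels=8, upsampler="carafe",
                         carafe_params=CarafeParams(c_mid=8))
        maps = _const_maps((1, 2, 3, 4))
        out = fpn_topdown(maps, mod)
        assert out["P2"].shape[1:] == maps["C2"].shape[1:]
        assert out["P6"].shape[1:] == (maps["C5"].shape[1] // 2,
                                       maps["C5"].shape[2] // 2)


class TestIntegrateRefine:
    def test_mean_of_equal_constants_is_that_constant(self):
        levels = [Tensor(np.full((1, 4, s, s), 3.0)) for s in (16, 8, 4, 2)]
        out = bfp_integrate(levels, reference=2).numpy()
        assert np.allclose(out, 3.0)
        assert out.shape == (1, 4, 4, 4)

    def test_two_levels_average(self):
        levels = [Tensor(np.full((1, 2, 8, 8), 1.0)),
                  Tensor(np.full((1, 2, 4, 4), 3.0))]
        out = bfp_integrate(levels, reference=0).numpy()
        assert np.allclose(out, 2.0)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            bfp_integrate([Tensor(np.zeros((1, 2, 4, 4)))])

    def test_identity_initialised_refine_is_identity(self):
        mod = BFPRefine(4, kind="conv", identity_init=True)
        x = RNG.normal(size=(4, 6, 6))
        assert np.allclose(bfp_refine(x, mod), x, atol=1e-12)

    def test_refine_preserves_shape(self):
        mod = BFPRefine(5, kind="conv")
        x = RNG.normal(size=(5, 7, 9))
        assert bfp_refine(x, mod).shape == x.shape

    def test_nonlocal_refine_on_uniform_input_stays_uniform(self):
        mod = BFPRefine(4, kind="nonlocal")
        x = np.full((4, 5, 5), 1.7)
        out = bfp_refine(x, mod)
        flat = out.reshape(4, -1)
        assert np.allclose(flat, flat[:, :1], atol=1e-9)


class TestCarafeBFP:
    def test_identity_refine_adds_shared_mean_to_constants(self):
        neck = CarafeBFP((8, 16, 32, 64), out_channels=8, upsampler="nearest",
                         refine="conv")
        # identity-initialise the refiner so refined == integrated
        w = np.zeros_like(neck.refiner.conv.weight.data)
        for c in range(8):
            w[c, c, 1, 1] = 1.0
        neck.refiner.conv.weight.data = w
        neck.refiner.conv.bias.data[:] = 0.0
        maps = _const_maps((1.0, 2.0, 3.0, 4.0))
        prime = fpn_topdown(maps, neck.topdown)
        out = carafe_bfp(maps, neck)
        mean_prime = np.mean(
            [prime[k][:, 0, 0] for k in ("P2", "P3", "P4", "P5")], axis=0
        )
        for k in ("P2", "P3", "P4", "P5"):
            expected = prime[k][:, 0, 0] + mean_prime
            assert np.allclose(out[k], expected[:, None, None], atol=1e-9), k
        assert np.allclose(out["P6"], prime["P6"], atol=1e-12)

    def test_output_levels_and_dims(self):
        neck = CarafeBFP((8, 16, 32, 64), out_channels=8,
                         carafe_params=CarafeParams(c_mid=8))
        maps = {k: RNG.normal(size=s) for k, s in
                [("C2", (8, 16, 24)), ("C3", (16, 8, 12)),
                 ("C4", (32, 4, 6)), ("C5", (64, 2, 3))]}
        out = carafe_bfp(maps, neck)
        assert out["P2"].shape[1:] == (16, 24)
        assert out["P5"].shape[1:] == (2, 3)
        assert len(out) == 5

    def test_deterministic_given_weights(self):
        neck = CarafeBFP((8, 16, 32, 64), out_channels=8,
                         carafe_params=CarafeParams(c_mid=8))
        maps = {k: RNG.normal(size=s) for k, s in
                [("C2", (8, 16, 16)), ("C3", (16, 8, 8)),
                 ("C4", (32, 4, 4)), ("C5", (64, 2, 2))]}
        a = carafe_bfp(maps, neck)
        b = carafe_bfp(maps, neck)
        for k in a:
            assert np.array_equal(a[k], b[k])
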