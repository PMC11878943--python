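"""Content-aware upsampling and the balanced feature pyramid."""

import numpy as np

from foalwatch import CarafeParams, CarafeUpsample, carafe_upsample
from foalwatch.autodiff import Tensor, no_grad
from foalwatch.pyramid import CarafeBFP, carafe_bfp, carafe_reassemble, \
    delta_kernels

rng = np.random.default_rng(5)

mod = CarafeUpsample(8, CarafeParams(k_up=5, c_mid=16))
x = rng.normal(size=(8, 6, 6))
up = carafe_upsample(x, mod)
with no_grad():
    alpha = mod.predict_kernels(Tensor(x[None])).numpy()
print(f"CARAFE: {x.shape} -> {up.shape}; "
      f"kernel sums deviate from 1 by at most "
      f"{np.abs(alpha.sum(axis=1) - 1).max():.1e}")

const = np.full((8, 6, 6), 3.25)
print("constant input stays constant:",
      np.allclose(carafe_upsample(const, mod), 3.25, atol=1e-9))

with no_grad():
    nearest = carafe_reassemble(Tensor(x[None]),
                                delta_kernels(1, 5, (12, 12)), 5, 2).numpy()[0]
print("one-hot center kernels reproduce nearest-neighbour upsampling:",
      np.array_equal(nearest, np.repeat(np.repeat(x, 2, 1), 2, 2)))

neck = CarafeBFP((8, 16, 32, 64), out_channels=16,
                 carafe_params=CarafeParams(c_mid=16))
maps = {k: rng.normal(size=s) for k, s in
        [("C2", (8, 32, 48)), ("C3", (16, 16, 24)),
         ("C4", (32, 8, 12)), ("C5", (64, 4, 6))]}
out = carafe_bfp(maps, neck)
print("\nbalanced pyramid levels:",
      {k: tuple(v.shape[1:]) for k, v in out.items()})
print("P2-P5 rebalanced by Integrate/Refine; P6 passes through for the RPN.")
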