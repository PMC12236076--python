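"""Complexity accounting: parameters, FLOPs, serialized size.

* **Params** — exact trainable-weight count, summing every parameter array
  (equivalently, the closed form ``K_w·K_h·C_in·C_out`` per convolution plus
  the linear/normalisation terms).
* **FLOPs** — layer-wise multiply–accumulate counts gathered during a real
  forward pass at the stated input size, doubled (one multiply + one add per
  MAC).  Convolutions and linear/matmul products are counted;
  normalisation, activations and softmax are not, matching the profiler
  convention under which the reference figures for this model family are
  reported.
* **Size** — ``params × B_params / 1024²`` MB; the default ``B_params = 2``
  corresponds to half-precision serialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn import modules as _m

__all__ = ["ComplexityReport", "profile", "conv_params", "conv_flops"]


def conv_params(kw: int, kh: int, c_in: int, c_out: int, groups: int = 1) -> int:
    """Closed-form convolution weight count  K_w·K_h·C_in·C_out / groups."""
    return kw * kh * (c_in // groups) * c_out


def conv_flops(h_out: int, w_out: int, params: int) -> int:
    """Closed-form convolution FLOPs  H_out·W_out·Params under MAC×2."""
    return 2 * h_out * w_out * params


@dataclass
class ComplexityReport:
    params: int
    flops: int
    size_mb: float
    input_hw: tuple
    bytes_per_param: int = 2

    @property
    def params_m(self) -> float:
        return self.params / 1e6

    @property
    def gflops(self) -> float:
        return self.flops / 1e9

    def as_dict(self) -> dict:
        return {
            "params": int(self.params), "params_M": round(self.params_m, 4),
            "flops": int(self.flops), "GFLOPs": round(self.gflops, 4),
            "size_MB": round(self.size_mb, 4),
            "input_hw": list(self.input_hw),
            "bytes_per_param": self.bytes_per_param,
        }

    def __str__(self) -> str:
        return (f"{self.gflops:.1f} GFLOPs @ {self.input_hw[0]}x{self.input_hw[1]}, "
                f"{self.params_m:.2f} M params, {self.size_mb:.1f} MB")


def profile(model: nn.Module, input_hw=(640, 640), bytes_per_param: int = 2,
            batch: int = 1) -> ComplexityReport:
    """Profile a model by a counted forward pass in inference mode."""
    counter = [0]
    model.eval()
    _m.set_mac_counter(counter)
    try:
        with nn.no_grad():
            x = Tensor(np.zeros((batch, 3, *input_hw), dtype=np.float32))
            model(x)
    finally:
        _m.set_mac_counter(None)
    params = model.param_count()
    flops = 2 * counter[0] // batch
    size_mb = params * bytes_per_param / 1024**2
    return ComplexityReport(params, flops, size_mb, tuple(input_hw),
                            bytes_per_param)
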