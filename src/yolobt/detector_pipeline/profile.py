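"""Architecture profiling: trainable parameters and forward-pass compute.

GFLOPs are reported as 2x multiply-accumulates of the dense operations
(convolutions, linear layers and attention matrix products) for one forward
pass; normalization, activations, pooling and elementwise products are not
counted. Profiling always uses the canonical 80-class head configuration so
the figures are comparable with conventionally reported detector sizes; the
deployed bad-trial model uses a single class.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from ..nn import autograd as ag
from .model import DetectorConfig, build_model

__all__ = ["profile_model", "PROFILE_CLASSES"]

PROFILE_CLASSES = 80


def profile_model(cfg: DetectorConfig, input_size: int | None = None,
                  profile_classes: int = PROFILE_CLASSES) -> tuple[float, float]:
    """Return (parameters in millions, GFLOPs at ``input_size``)."""
    size = cfg.input_size if input_size is None else input_size
    pcfg = replace(cfg, n_classes=profile_classes, input_size=size)
    model = build_model(pcfg)
    model.eval()
    params = model.num_parameters()
    x = ag.tensor(np.zeros((1, 3, size, size), dtype=np.float32))
    with ag.no_grad(), ag.count_macs() as macs:
        model(x)
    return params / 1e6, 2.0 * macs[0] / 1e9
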