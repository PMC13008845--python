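"""Re-export of the shared detector building blocks."""

from ..blocks import Conv, Bottleneck, C3, SPPF, make_divisible

__all__ = ["Conv", "Bottleneck", "C3", "SPPF", "make_divisible"]
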