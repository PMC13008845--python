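"""Render EEG screens to waveform images with YOLO-format ground truth.

Conventions (fixed by this package, documented rather than inherited from
any GUI): the plot area is the full image (no margins), channels are stacked
top-to-bottom as equal-height rows, the 10 trials run left-to-right each
occupying a tenth of the width, adjacent trials are separated by dashed
vertical lines (6 px on / 6 px off), channels flagged bad are drawn in gray,
and per-channel amplitude is mapped linearly to a fraction of the row
half-height up to ``amplitude_clip``, with logarithmic gain compression
beyond it, so extreme artifacts saturate visibly (at graded heights) instead
of invading neighboring rows. Bad-trial boxes span the full image height and
one trial column width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, ImageDraw

from .synthetic_eeg import EEGScreen, ConfigurationError

__all__ = [
    "RenderConfig", "RenderedSample", "LabelParseError",
    "render_screen", "boxes_for_bad_trials", "write_labels", "read_labels",
    "render_dataset",
]


@dataclass(frozen=True)
class RenderConfig:
    width: int = 640
    height: int = 640
    waveform_color: tuple[int, int, int] = (20, 20, 20)
    bad_channel_color: tuple[int, int, int] = (150, 150, 150)
    separator_color: tuple[int, int, int] = (20, 20, 120)  # dark blue
    background_color: tuple[int, int, int] = (255, 255, 255)
    line_width: int = 1
    amplitude_clip: float = 200.0   # uV spanned by the linear display region
    linear_fraction: float = 0.4    # fraction of row half-height used linearly
    max_overdrive: float = 64.0     # amplitudes beyond clip*max_overdrive rail
    dash_on: int = 6
    dash_off: int = 6

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ConfigurationError("image dimensions must be positive")
        if self.amplitude_clip <= 0:
            raise ConfigurationError("amplitude_clip must be positive")
        if not 0 < self.linear_fraction <= 1 or self.max_overdrive < 1:
            raise ConfigurationError("invalid compression parameters")
        for c in (self.waveform_color, self.bad_channel_color,
                  self.separator_color, self.background_color):
            if len(c) != 3 or any(not 0 <= v <= 255 for v in c):
                raise ConfigurationError(f"invalid RGB color {c}")


def compress_amplitude(v: np.ndarray, config: RenderConfig) -> np.ndarray:
    """Map amplitudes (uV) to [-1, 1] row units: linear to ``amplitude_clip``
    (occupying ``linear_fraction`` of the half-row), log-compressed beyond."""
    clip, lam = config.amplitude_clip, config.linear_fraction
    a = np.abs(v)
    lin = lam * np.minimum(a, clip) / clip
    with np.errstate(divide="ignore", invalid="ignore"):
        over = np.where(a > clip,
                        (1 - lam) * np.minimum(
                            np.log(np.maximum(a / clip, 1.0)) /
                            np.log(config.max_overdrive), 1.0),
                        0.0)
    return np.sign(v) * (lin + over)


@dataclass
class RenderedSample:
    image: np.ndarray                      # (H, W, 3) uint8
    boxes: list[tuple[int, float, float, float, float]]
    source: str = ""


class LabelParseError(ValueError):
    pass


def boxes_for_bad_trials(screen: EEGScreen) -> list[tuple[int, float, float, float, float]]:
    """One full-height, tenth-width box per bad trial: (class, cx, cy, w, h)."""
    n = len(screen.trial_labels)
    return [(0, (t + 0.5) / n, 0.5, 1.0 / n, 1.0)
            for t in range(n) if screen.trial_labels[t]]


def render_screen(screen: EEGScreen, config: RenderConfig = RenderConfig(),
                  source: str = "") -> RenderedSample:
    """Rasterize a screen; deterministic in (screen, config)."""
    nch, ntr, ns = screen.data.shape
    W, H = config.width, config.height
    img = Image.new("RGB", (W, H), config.background_color)
    draw = ImageDraw.Draw(img)

    # dashed separators between adjacent trials
    trial_w = W / ntr
    for t in range(1, ntr):
        x = int(round(t * trial_w))
        y = 0
        while y < H:
            draw.line([(x, y), (x, min(y + config.dash_on - 1, H - 1))],
                      fill=config.separator_color, width=1)
            y += config.dash_on + config.dash_off

    # waveforms: one polyline per (channel, trial)
    row_h = H / nch
    xs_rel = np.linspace(0, trial_w - 1, ns)
    disp = compress_amplitude(screen.data, config)
    for ch in range(nch):
        color = (config.bad_channel_color if screen.bad_channel_mask[ch]
                 else config.waveform_color)
        y_center = (ch + 0.5) * row_h
        half = row_h / 2 - 0.5
        for t in range(ntr):
            ys = y_center - disp[ch, t] * half
            x0 = t * trial_w
            pts = list(zip((x0 + xs_rel).tolist(), ys.tolist()))
            draw.line(pts, fill=color, width=config.line_width)

    return RenderedSample(image=np.asarray(img, dtype=np.uint8),
                          boxes=boxes_for_bad_trials(screen), source=source)


# ---------------------------------------------------------------------------
# YOLO-dialect label files
# ---------------------------------------------------------------------------


def write_labels(path: str | Path, boxes) -> None:
    """One line per box: ``class cx cy w h``, space-separated, 6 decimals."""
    lines = []
    for b in boxes:
        cls, cx, cy, w, h = b
        for v in (cx, cy, w, h):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"box coordinate {v} outside [0, 1]")
        lines.append(f"{int(cls)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_labels(path: str | Path) -> list[tuple[int, float, float, float, float]]:
    boxes = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 5:
            raise LabelParseError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
        try:
            cls = int(parts[0])
            vals = [float(p) for p in parts[1:]]
        except ValueError as e:
            raise LabelParseError(f"{path}:{ln}: {e}") from e
        boxes.append((cls, *vals))
    return boxes


# ---------------------------------------------------------------------------
# Dataset rendering with split manifest
# ---------------------------------------------------------------------------


def render_dataset(screens: list[EEGScreen], out_dir: str | Path,
                   config: RenderConfig = RenderConfig(),
                   split: tuple[float, float, float] = (0.70, 0.15, 0.15),
                   seed: int = 0) -> dict:
    """Write PNG images + label .txt files and a split manifest YAML.

    Screens are shuffled with ``seed`` and partitioned train/val/test by
    ``split`` (fractions summing to 1).
    """
    if abs(sum(split) - 1.0) > 1e-6:
        raise ConfigurationError("split fractions must sum to 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    names = []
    for i, s in enumerate(screens):
        stem = f"screen_{i:05d}"
        sample = render_screen(s, config, source=stem)
        Image.fromarray(sample.image).save(out_dir / "images" / f"{stem}.png")
        write_labels(out_dir / "labels" / f"{stem}.txt", sample.boxes)
        names.append(stem)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(names))
    n_train = int(round(split[0] * len(names)))
    n_val = int(round(split[1] * len(names)))
    splits = {
        "train": [names[i] for i in order[:n_train]],
        "val": [names[i] for i in order[n_train:n_train + n_val]],
        "test": [names[i] for i in order[n_train + n_val:]],
    }
    manifest = {
        "path": str(out_dir), "nc": 1, "names": ["bad"],
        "image_size": [config.width, config.height],
        "splits": {k: sorted(v) for k, v in splits.items()},
    }
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return manifest
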