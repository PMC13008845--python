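"""Dataset container and augmentation (mosaic, mixup) for detector training."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from ..waveform_renderer import read_labels

__all__ = ["DetectionDataset", "load_rendered_dataset", "mosaic4", "mixup"]


@dataclass
class DetectionDataset:
    """Images (uint8, H x W x 3, all same size) with normalized label boxes."""

    images: list[np.ndarray]
    labels: list[np.ndarray]     # each (n, 5) of (cls, cx, cy, w, h)
    names: list[str]

    def __post_init__(self):
        if len(self.images) != len(self.labels):
            raise ValueError("images/labels length mismatch")
        if not self.images:
            raise ValueError("empty dataset")
        self.labels = [np.asarray(l, dtype=np.float32).reshape(-1, 5)
                       for l in self.labels]

    def __len__(self):
        return len(self.images)

    @property
    def size(self) -> int:
        return self.images[0].shape[0]

    def subset(self, idx) -> "DetectionDataset":
        return DetectionDataset([self.images[i] for i in idx],
                                [self.labels[i] for i in idx],
                                [self.names[i] for i in idx])

    def box_sizes_px(self) -> np.ndarray:
        whs = [l[:, 3:5] * self.size for l in self.labels if l.shape[0]]
        return (np.concatenate(whs) if whs
                else np.zeros((0, 2), dtype=np.float32))


def load_rendered_dataset(manifest_path: str | Path,
                          split: str | None = None) -> DetectionDataset:
    manifest = yaml.safe_load(Path(manifest_path).read_text())
    root = Path(manifest["path"])
    if split is None:
        names = sorted(n for v in manifest["splits"].values() for n in v)
    else:
        names = list(manifest["splits"][split])
    images, labels = [], []
    for stem in names:
        img = np.asarray(Image.open(root / "images" / f"{stem}.png").convert("RGB"))
        boxes = read_labels(root / "labels" / f"{stem}.txt")
        images.append(img)
        labels.append(np.array([list(b) for b in boxes], dtype=np.float32)
                      .reshape(-1, 5))
    return DetectionDataset(images, labels, names)


def _half(img: np.ndarray) -> np.ndarray:
    """Exact 2x area downsample (images are even-sized)."""
    h, w = img.shape[:2]
    return img.reshape(h // 2, 2, w // 2, 2, 3).mean(axis=(1, 3))


def mosaic4(imgs: list[np.ndarray], labels: list[np.ndarray]
            ) -> tuple[np.ndarray, np.ndarray]:
    """Four images half-sized into a 2x2 mosaic with remapped boxes."""
    s = imgs[0].shape[0]
    out = np.zeros((s, s, 3), dtype=np.float32)
    shifts = [(0, 0), (0, 1), (1, 0), (1, 1)]
    new_labels = []
    for (ry, rx), img, lab in zip(shifts, imgs, labels):
        out[ry * s // 2:(ry + 1) * s // 2,
            rx * s // 2:(rx + 1) * s // 2] = _half(img.astype(np.float32))
        if lab.shape[0]:
            l2 = lab.copy()
            l2[:, 1] = lab[:, 1] / 2 + rx / 2
            l2[:, 2] = lab[:, 2] / 2 + ry / 2
            l2[:, 3:5] = lab[:, 3:5] / 2
            new_labels.append(l2)
    lab = (np.concatenate(new_labels) if new_labels
           else np.zeros((0, 5), dtype=np.float32))
    return out, lab


def mixup(img1, lab1, img2, lab2, alpha: float = 0.2,
          rng: np.random.Generator | None = None):
    """Beta(alpha, alpha) convex blend of two images; labels are unioned."""
    lam = 0.5 if rng is None else float(rng.beta(alpha, alpha))
    img = lam * img1.astype(np.float32) + (1 - lam) * img2.astype(np.float32)
    lab = np.concatenate([lab1, lab2]) if (lab1.shape[0] or lab2.shape[0]) \
        else np.zeros((0, 5), dtype=np.float32)
    return img, lab


def batches(dataset: DetectionDataset, batch_size: int,
            rng: np.random.Generator, use_mosaic: bool = False,
            mixup_alpha: float = 0.0, mixup_prob: float = 0.1):
    """Yield (x (B,3,S,S) float32 in [0,1], targets (M,6)) batches."""
    order = rng.permutation(len(dataset))
    for start in range(0, len(order), batch_size):
        idx = order[start:start + batch_size]
        xs, targets = [], []
        for bi, i in enumerate(idx):
            if use_mosaic:
                others = rng.integers(0, len(dataset), size=3)
                img, lab = mosaic4(
                    [dataset.images[i]] + [dataset.images[j] for j in others],
                    [dataset.labels[i]] + [dataset.labels[j] for j in others])
            else:
                img, lab = dataset.images[i].astype(np.float32), dataset.labels[i]
            if mixup_alpha > 0 and rng.random() < mixup_prob:
                j = int(rng.integers(0, len(dataset)))
                if use_mosaic:
                    others = rng.integers(0, len(dataset), size=3)
                    img2, lab2 = mosaic4(
                        [dataset.images[j]] + [dataset.images[k] for k in others],
                        [dataset.labels[j]] + [dataset.labels[k] for k in others])
                else:
                    img2, lab2 = dataset.images[j].astype(np.float32), \
                        dataset.labels[j]
                img, lab = mixup(img, lab, img2, lab2, mixup_alpha, rng)
            xs.append(img.transpose(2, 0, 1) / 255.0)
            if lab.shape[0]:
                t = np.zeros((lab.shape[0], 6), dtype=np.float32)
                t[:, 0] = bi
                t[:, 1:] = lab
                targets.append(t)
        x = np.stack(xs).astype(np.float32)
        t = (np.concatenate(targets) if targets
             else np.zeros((0, 6), dtype=np.float32))
        yield x, t
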