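"""Synthetic benchmark assembly: screens -> rendered detection datasets.

Two standard regimes:

* :func:`easy_benchmark` — severe artifacts on clean backgrounds; the
  sanity-check regime for end-to-end training at reduced scale.
* :func:`adaptive_benchmark` — identical moderate artifacts embedded in
  clean vs noisy screens, labeled by the context-adaptive rule, so that
  telling bad from tolerated requires global signal-quality context.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import synthetic_eeg as se
from . import waveform_renderer as wr
from .detector_pipeline.data import DetectionDataset

__all__ = ["screens_to_dataset", "split_dataset", "easy_benchmark",
           "adaptive_benchmark"]


def screens_to_dataset(screens, render_config: wr.RenderConfig,
                       prefix: str = "screen") -> DetectionDataset:
    imgs, labs, names = [], [], []
    for i, s in enumerate(screens):
        sample = wr.render_screen(s, render_config, source=f"{prefix}_{i:05d}")
        imgs.append(sample.image)
        labs.append(np.array([list(b) for b in sample.boxes],
                             dtype=np.float32).reshape(-1, 5))
        names.append(sample.source)
    return DetectionDataset(imgs, labs, names)


def split_dataset(ds: DetectionDataset, seed: int = 0,
                  fractions=(0.70, 0.15, 0.15)):
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ds))
    n_train = int(round(fractions[0] * len(ds)))
    n_val = int(round(fractions[1] * len(ds)))
    return (ds.subset(order[:n_train]),
            ds.subset(order[n_train:n_train + n_val]),
            ds.subset(order[n_train + n_val:]))


def easy_benchmark(n_screens: int = 200, image_size: int = 320,
                   n_channels: int = 16, seed: int = 0):
    """Severe-on-clean regime: every bad trial carries an unmistakable
    high-amplitude artifact over several channels."""
    cfg = se.GenConfig(n_channels=n_channels, seed=seed)
    screens = se.make_screen_dataset(
        cfg, n_screens, {"clean": 0.7, "severe": 0.3},
        quality_range=(0.9, 1.0), bad_channel_prob=0.2,
        channels_range=(3, 6), duration_range=(0.4, 0.9))
    rc = wr.RenderConfig(width=image_size, height=image_size, line_width=2)
    ds = screens_to_dataset(screens, rc)
    return (*split_dataset(ds, seed=seed), screens)


def adaptive_benchmark(n_screens: int = 120, image_size: int = 256,
                       n_channels: int = 16, seed: int = 0,
                       moderate_amplitude: float = 1100.0):
    """Half clean, half noisy screens; each carries the same fixed moderate
    artifact in 1-3 trials plus severe artifacts in 1-2 trials. Adaptive
    labels mark the moderate ones bad on clean screens and tolerated on
    noisy ones (severe is bad everywhere)."""
    rng = np.random.default_rng(seed)
    screens = []
    for i in range(n_screens):
        noisy = i % 2 == 1
        q = float(rng.uniform(0.0, 0.1)) if noisy else float(rng.uniform(0.95, 1.0))
        cfg = se.GenConfig(n_channels=n_channels, quality_level=q,
                           seed=int(rng.integers(0, 2 ** 31 - 1)))
        scr = se.generate_background(cfg)
        trials = list(rng.permutation(cfg.trials_per_screen))
        injected: set[int] = set()
        n_sev = int(rng.integers(1, 3))
        n_mod = int(rng.integers(1, 4))
        for _ in range(n_sev):
            t = trials.pop()
            spec = se.ArtifactSpec(
                kind=str(rng.choice(se.ARTIFACT_KINDS)),
                channels=tuple(int(c) for c in rng.choice(
                    n_channels, size=int(rng.integers(3, 7)), replace=False)),
                onset=float(rng.uniform(0, 0.4)),
                duration=float(rng.uniform(0.4, 0.6)),
                amplitude=6000.0)
            scr = se.inject_artifact(scr, t, spec, rng=rng)
            injected.add(t)
        for _ in range(n_mod):
            t = trials.pop()
            spec = se.ArtifactSpec(
                kind=str(rng.choice(se.ARTIFACT_KINDS)),
                channels=tuple(int(c) for c in rng.choice(
                    n_channels, size=int(rng.integers(3, 7)), replace=False)),
                onset=float(rng.uniform(0, 0.4)),
                duration=float(rng.uniform(0.4, 0.6)),
                amplitude=moderate_amplitude)
            scr = se.inject_artifact(scr, t, spec, rng=rng)
            injected.add(t)
        scr.trial_labels = se.adaptive_labels(scr, injected)
        screens.append(scr)
    rc = wr.RenderConfig(width=image_size, height=image_size, line_width=2)
    ds = screens_to_dataset(screens, rc)
    return (*split_dataset(ds, seed=seed), screens)
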