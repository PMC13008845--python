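"""Anchor estimation by k-means over training-set box sizes.

Bad-trial boxes are tall and narrow (full height, one tenth width), far from
natural-image anchor priors, so anchors are re-estimated from the data. With
near-degenerate size distributions (all boxes identical) k-means collapses;
centroids are then spread by fixed scale factors so the three anchors per
scale stay distinct.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kmeans_anchors"]


def kmeans_anchors(wh_px: np.ndarray, n_anchors: int = 9, n_iter: int = 50,
                   seed: int = 0) -> np.ndarray:
    """Cluster (N, 2) box sizes in pixels into (3, 3, 2) anchors by area order."""
    wh = np.asarray(wh_px, dtype=np.float64).reshape(-1, 2)
    if wh.shape[0] == 0:
        raise ValueError("no boxes to estimate anchors from")
    rng = np.random.default_rng(seed)
    uniq = np.unique(wh, axis=0)
    if uniq.shape[0] >= n_anchors:
        centroids = uniq[rng.choice(uniq.shape[0], n_anchors, replace=False)]
        for _ in range(n_iter):
            d = ((wh[:, None] - centroids[None]) ** 2).sum(-1)
            lab = d.argmin(axis=1)
            for k in range(n_anchors):
                if (lab == k).any():
                    centroids[k] = wh[lab == k].mean(axis=0)
    else:
        # degenerate: spread each distinct size over log-spaced scale factors
        scales = np.geomspace(0.7, 1.4, int(np.ceil(n_anchors / uniq.shape[0])))
        centroids = np.concatenate([uniq * s for s in scales])[:n_anchors]
    order = np.argsort(centroids.prod(axis=1))
    centroids = np.maximum(centroids[order], 1.0)
    return centroids.reshape(3, n_anchors // 3, 2).astype(np.float32)
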