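"""Box decoding, non-maximum suppression, and the detect() entry point."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import autograd as ag
from ..eval_metrics import iou_xywh
from .model import Detector, STRIDES

__all__ = ["Detection", "decode_predictions", "nms", "detect"]

CONF_THRESH = 0.25
NMS_IOU = 0.45


@dataclass(frozen=True)
class Detection:
    box: tuple[float, float, float, float]   # normalized cx, cy, w, h
    confidence: float
    class_id: int = 0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    from ..nn.autograd import _stable_sigmoid
    return _stable_sigmoid(np.asarray(x, dtype=np.float32))


def decode_predictions(preds: list[np.ndarray], anchors_px: np.ndarray,
                       input_size: int, n_classes: int = 1
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw head outputs -> (boxes_norm (N,4), conf (N,), cls (N,)) for batch 1."""
    na = anchors_px.shape[1]
    no = 5 + n_classes
    boxes, confs, clss = [], [], []
    for si, (p, stride) in enumerate(zip(preds, STRIDES)):
        b, _, gh, gw = p.shape
        if b != 1:
            raise ValueError("decode_predictions expects batch size 1")
        p = _sigmoid(p.reshape(na, no, gh, gw).transpose(0, 2, 3, 1))
        gy, gx = np.mgrid[0:gh, 0:gw].astype(np.float32)
        xy = (p[..., 0:2] * 2.0 - 0.5 +
              np.stack([gx, gy], axis=-1)[None]) * stride
        wh = (p[..., 2:4] * 2.0) ** 2 * anchors_px[si][:, None, None]
        conf_cls = p[..., 4:5] * p[..., 5:]
        cls_id = conf_cls.argmax(axis=-1)
        conf = conf_cls.max(axis=-1)
        boxes.append(np.concatenate([xy, wh], axis=-1).reshape(-1, 4)
                     / input_size)
        confs.append(conf.reshape(-1))
        clss.append(cls_id.reshape(-1))
    return (np.concatenate(boxes), np.concatenate(confs),
            np.concatenate(clss))


def nms(boxes: np.ndarray, confs: np.ndarray,
        iou_thresh: float = NMS_IOU) -> np.ndarray:
    """Greedy NMS; returns kept indices in descending-confidence order."""
    order = np.argsort(-confs, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        ious = iou_xywh(boxes[i][None], boxes[order[1:]])[0]
        order = order[1:][ious <= iou_thresh]
    return np.array(keep, dtype=int)


def detect(model: Detector, image: np.ndarray,
           conf_thresh: float = CONF_THRESH,
           iou_thresh: float = NMS_IOU) -> list[Detection]:
    """Run the detector on one RGB image (H, W, 3) sized to cfg.input_size."""
    size = model.cfg.input_size
    if image.shape[:2] != (size, size):
        raise ValueError(f"expected {size}x{size} input, got {image.shape[:2]}")
    x = np.ascontiguousarray(image.transpose(2, 0, 1)[None], dtype=np.float32)
    if x.max() > 1.5:
        x = x / 255.0
    model.eval()
    with ag.no_grad():
        preds = [p.data for p in model(ag.tensor(x))]
    boxes, confs, clss = decode_predictions(
        preds, model.detect.anchors, size, model.cfg.n_classes)
    mask = confs > conf_thresh
    boxes, confs, clss = boxes[mask], confs[mask], clss[mask]
    dets: list[Detection] = []
    for c in np.unique(clss):
        sel = clss == c
        for i in nms(boxes[sel], confs[sel], iou_thresh):
            bx = np.clip(boxes[sel][i], 0.0, 1.0)
            dets.append(Detection(box=tuple(float(v) for v in bx),
                                  confidence=float(confs[sel][i]),
                                  class_id=int(c)))
    dets.sort(key=lambda d: -d.confidence)
    return dets
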