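"""Composite detection loss: CIoU box regression + objectness BCE + class BCE.

Target assignment follows the standard one-stage recipe: anchors whose
width/height ratio to the target is below 4 match, and each target is
assigned to its cell plus the two nearest neighboring cells.
"""

from __future__ import annotations

import math

import numpy as np

from ..nn import autograd as ag

__all__ = ["build_targets", "detection_loss", "ciou"]

_OFF = np.array([[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1]], dtype=np.float32)
ANCHOR_T = 4.0  # anchor ratio threshold
BALANCE = (4.0, 1.0, 0.4)


def build_targets(targets: np.ndarray, anchors_px: np.ndarray,
                  strides, grid_sizes):
    """Assign normalized targets to (image, anchor, cell) slots per scale.

    targets: (N, 6) of (img, cls, cx, cy, w, h) normalized to [0, 1].
    Returns per scale: dict with index arrays b, a, gj, gi, target boxes in
    grid units (txy within-cell offset target, twh absolute grid units),
    anchor wh in grid units, and class ids.
    """
    out = []
    targets = np.asarray(targets, dtype=np.float32).reshape(-1, 6)
    na = anchors_px.shape[1]
    for si, (stride, (gh, gw)) in enumerate(zip(strides, grid_sizes)):
        anc = anchors_px[si] / stride                    # (na, 2) grid units
        if targets.shape[0] == 0:
            out.append(None)
            continue
        gain = np.array([1, 1, gw, gh, gw, gh], dtype=np.float32)
        t = targets * gain
        # anchor ratio filter
        t = np.repeat(t[None], na, axis=0)               # (na, N, 6)
        ai = np.repeat(np.arange(na)[:, None], t.shape[1], axis=1)
        r = t[..., 4:6] / anc[:, None]
        keep = np.maximum(r, 1 / r).max(axis=-1) < ANCHOR_T
        t, ai = t[keep], ai[keep]
        if t.shape[0] == 0:
            out.append(None)
            continue
        # neighbor cells
        gxy = t[:, 2:4]
        gxi = np.array([gw, gh], dtype=np.float32) - gxy
        j, k = ((gxy % 1 < 0.5) & (gxy > 1)).T
        l, m = ((gxi % 1 < 0.5) & (gxi > 1)).T
        sel = np.stack([np.ones_like(j), j, k, l, m])
        t = np.repeat(t[None], 5, axis=0)[sel]
        ai = np.repeat(ai[None], 5, axis=0)[sel]
        offsets = (np.zeros((5, gxy.shape[0], 2), dtype=np.float32)
                   + _OFF[:, None] * 0.5)[sel]
        gxy = t[:, 2:4]
        gij = (gxy - offsets).astype(int)
        gi = np.clip(gij[:, 0], 0, gw - 1)
        gj = np.clip(gij[:, 1], 0, gh - 1)
        out.append({
            "b": t[:, 0].astype(int), "a": ai.astype(int), "gj": gj, "gi": gi,
            "txy": gxy - np.stack([gi, gj], axis=1),     # in (-0.5, 1.5)
            "twh": t[:, 4:6],
            "anchor_wh": anc[ai.astype(int)],
            "cls": t[:, 1].astype(int),
        })
    return out


def ciou(pred: ag.Tensor, txy: ag.Tensor, eps: float = 1e-7) -> ag.Tensor:
    """Complete IoU between predicted and target (cx, cy, w, h) box tensors."""
    px, py, pw, ph = (pred[:, i] for i in range(4))
    tx, ty, tw, th = (txy[:, i] for i in range(4))
    p_x1, p_x2 = px - pw * 0.5, px + pw * 0.5
    p_y1, p_y2 = py - ph * 0.5, py + ph * 0.5
    t_x1, t_x2 = tx - tw * 0.5, tx + tw * 0.5
    t_y1, t_y2 = ty - th * 0.5, ty + th * 0.5
    iw = ag.clip(ag.minimum(p_x2, t_x2) - ag.maximum(p_x1, t_x1), 0.0, None)
    ih = ag.clip(ag.minimum(p_y2, t_y2) - ag.maximum(p_y1, t_y1), 0.0, None)
    inter = iw * ih
    union = pw * ph + tw * th - inter + eps
    iou = inter / union
    cw = ag.maximum(p_x2, t_x2) - ag.minimum(p_x1, t_x1)
    ch = ag.maximum(p_y2, t_y2) - ag.minimum(p_y1, t_y1)
    c2 = cw * cw + ch * ch + eps
    rho2 = (px - tx) * (px - tx) + (py - ty) * (py - ty)
    v = (4.0 / math.pi ** 2) * \
        (ag.atan(tw / (th + eps)) - ag.atan(pw / (ph + eps))) ** 2
    alpha = (v.data / (1.0 - iou.data + v.data + eps))   # detached weighting
    return iou - rho2 / c2 - ag.mul(v, alpha)


def detection_loss(preds: list, targets: np.ndarray, anchors_px: np.ndarray,
                   strides=(8, 16, 32), n_classes: int = 1,
                   box_gain: float = 0.05, obj_gain: float = 1.0,
                   cls_gain: float = 0.5, obj_pw: float = 1.0,
                   cls_pw: float = 1.0):
    """Total loss plus components over raw head outputs.

    preds: per-scale tensors (B, na*(5+nc), H, W).
    Returns (loss, {"box": f, "obj": f, "cls": f}).
    """
    na = anchors_px.shape[1]
    no = 5 + n_classes
    grid_sizes = [p.shape[2:] for p in preds]
    assigned = build_targets(targets, anchors_px, strides, grid_sizes)
    lbox = ag.tensor(0.0)
    lobj = ag.tensor(0.0)
    lcls = ag.tensor(0.0)
    for si, (p, asg) in enumerate(zip(preds, assigned)):
        b, _, gh, gw = p.shape
        p = ag.reshape(p, (b, na, no, gh, gw))
        p = ag.transpose(p, (0, 1, 3, 4, 2))             # (B, na, H, W, no)
        tobj = np.zeros((b, na, gh, gw), dtype=np.float32)
        if asg is not None and asg["b"].size:
            idx = (asg["b"], asg["a"], asg["gj"], asg["gi"])
            pm = p[idx]                                  # (M, no)
            pxy = ag.sigmoid(pm[:, 0:2]) * 2.0 - 0.5
            pwh = (ag.sigmoid(pm[:, 2:4]) * 2.0) ** 2 * asg["anchor_wh"]
            pbox = ag.concat([pxy, pwh], axis=1)
            tbox = np.concatenate([asg["txy"], asg["twh"]], axis=1)
            iou = ciou(pbox, ag.tensor(tbox))
            lbox = lbox + ag.mean(1.0 - iou)
            tobj[idx] = np.clip(iou.data, 0, None)
            tcls = np.zeros((pm.shape[0], n_classes), dtype=np.float32)
            tcls[np.arange(pm.shape[0]), asg["cls"]] = 1.0
            lcls = lcls + ag.bce_with_logits(pm[:, 5:], tcls,
                                             pos_weight=cls_pw)
        lobj = lobj + BALANCE[si] * ag.bce_with_logits(p[..., 4], tobj,
                                                       pos_weight=obj_pw)
    batch = preds[0].shape[0]
    loss = (box_gain * lbox + obj_gain * lobj + cls_gain * lcls) * float(batch)
    parts = {"box": float(lbox.data), "obj": float(lobj.data),
             "cls": float(lcls.data)}
    return loss, parts
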