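"""Detection evaluation: precision/recall, AP/mAP, F1, severity-stratified reports.

Boxes are normalized ``(cx, cy, w, h)``. AP follows the raw threshold-sweep
area accumulation ``sum_n (R(n) - R(n-1)) * P(n)`` with no interpolation by
default; 11-point and 101-point interpolated variants are available behind
the ``interpolation`` flag for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MatchCounts", "EvalReport", "iou_xywh", "match_detections",
    "precision_recall", "average_precision", "mean_ap", "f1_score",
    "assign_severity", "stratified_report", "SEVERITY_BANDS",
]

#: PTP severity band edges in microvolts: (moderate lower edge, severe lower edge)
SEVERITY_BANDS = (500.0, 3000.0)


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.tp + other.tp, self.fp + other.fp,
                           self.fn + other.fn)


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    ap: float | None = None
    map50: float | None = None
    counts: MatchCounts | None = None
    per_severity: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"precision": self.precision, "recall": self.recall, "f1": self.f1}
        if self.ap is not None:
            d["ap"] = self.ap
        if self.map50 is not None:
            d["map50"] = self.map50
        if self.counts is not None:
            d["tp"], d["fp"], d["fn"] = self.counts.tp, self.counts.fp, self.counts.fn
        if self.per_severity:
            d["per_severity"] = {k: v.to_dict() if isinstance(v, EvalReport) else v
                                 for k, v in self.per_severity.items()}
        return d


def _validate_boxes(boxes: np.ndarray) -> np.ndarray:
    boxes = np.atleast_2d(np.asarray(boxes, dtype=float))
    if boxes.size == 0:
        return boxes.reshape(0, 4)
    if boxes.shape[1] != 4 or not np.isfinite(boxes).all():
        raise ValueError("boxes must be a finite (N, 4) array of cx, cy, w, h")
    return boxes


def iou_xywh(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N,4) and (M,4) center-format boxes."""
    a, b = _validate_boxes(a), _validate_boxes(b)
    ax1, ay1 = a[:, 0] - a[:, 2] / 2, a[:, 1] - a[:, 3] / 2
    ax2, ay2 = a[:, 0] + a[:, 2] / 2, a[:, 1] + a[:, 3] / 2
    bx1, by1 = b[:, 0] - b[:, 2] / 2, b[:, 1] - b[:, 3] / 2
    bx2, by2 = b[:, 0] + b[:, 2] / 2, b[:, 1] + b[:, 3] / 2
    iw = np.clip(np.minimum(ax2[:, None], bx2) - np.maximum(ax1[:, None], bx1), 0, None)
    ih = np.clip(np.minimum(ay2[:, None], by2) - np.maximum(ay1[:, None], by1), 0, None)
    inter = iw * ih
    union = (a[:, 2] * a[:, 3])[:, None] + b[:, 2] * b[:, 3] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(union > 0, inter / union, 0.0)


def match_flags(det_boxes: np.ndarray, det_conf: np.ndarray,
                truth_boxes: np.ndarray, iou_thresh: float = 0.5
                ) -> tuple[np.ndarray, np.ndarray]:
    """Greedy confidence-ordered matching.

    Returns ``(tp_flags, matched_truth)``: per-detection booleans in the
    *confidence-sorted* order is undone — flags are returned in the original
    detection order — and per-truth matched indicators.
    """
    det_boxes = _validate_boxes(det_boxes)
    truth_boxes = _validate_boxes(truth_boxes)
    det_conf = np.asarray(det_conf, dtype=float).reshape(-1)
    if det_conf.shape[0] != det_boxes.shape[0]:
        raise ValueError("confidence/box count mismatch")
    nd, nt = det_boxes.shape[0], truth_boxes.shape[0]
    tp = np.zeros(nd, dtype=bool)
    matched = np.zeros(nt, dtype=bool)
    if nd == 0 or nt == 0:
        return tp, matched
    order = np.argsort(-det_conf, kind="stable")
    ious = iou_xywh(det_boxes, truth_boxes)
    for di in order:
        cand = np.where(~matched & (ious[di] >= iou_thresh))[0]
        if cand.size:
            best = cand[np.argmax(ious[di, cand])]
            matched[best] = True
            tp[di] = True
    return tp, matched


def match_detections(det_boxes, det_conf, truth_boxes,
                     iou_thresh: float = 0.5) -> MatchCounts:
    tp, matched = match_flags(det_boxes, det_conf, truth_boxes, iou_thresh)
    n_tp = int(tp.sum())
    return MatchCounts(tp=n_tp, fp=int(tp.size - n_tp),
                       fn=int((~matched).sum()))


def precision_recall(counts: MatchCounts) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); zero denominators yield 0."""
    if min(counts.tp, counts.fp, counts.fn) < 0:
        raise ValueError("negative match counts")
    if counts.tp + counts.fp == 0:
        warnings.warn("no detections: precision defined as 0", stacklevel=2)
        p = 0.0
    else:
        p = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        warnings.warn("no ground truths: recall defined as 0", stacklevel=2)
        r = 0.0
    else:
        r = counts.tp / (counts.tp + counts.fn)
    return p, r


def f1_score(p: float, r: float) -> float:
    """Harmonic mean 2PR/(P+R); accepts fraction or percent scale symmetrically."""
    if p < 0 or r < 0:
        raise ValueError("precision/recall must be non-negative")
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def average_precision(tp_flags: np.ndarray, confidences: np.ndarray,
                      n_truth: int, interpolation: str | None = None
                      ) -> tuple[float, np.ndarray, np.ndarray]:
    """AP from per-detection TP flags via a descending-confidence threshold sweep.

    Returns ``(ap, precisions, recalls)`` where the series are evaluated at
    each distinct confidence threshold, highest first.
    """
    tp_flags = np.asarray(tp_flags, dtype=bool).reshape(-1)
    confidences = np.asarray(confidences, dtype=float).reshape(-1)
    if tp_flags.shape != confidences.shape:
        raise ValueError("tp_flags/confidences shape mismatch")
    if n_truth <= 0:
        return 0.0, np.zeros(0), np.zeros(0)
    if tp_flags.size == 0:
        return 0.0, np.zeros(0), np.zeros(0)
    order = np.argsort(-confidences, kind="stable")
    conf = confidences[order]
    tp = tp_flags[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    # threshold at each distinct confidence: keep last occurrence per value
    keep = np.r_[conf[1:] != conf[:-1], True]
    precisions = (cum_tp / (cum_tp + cum_fp))[keep]
    recalls = (cum_tp / n_truth)[keep]
    if interpolation is None:
        prev_r = np.r_[0.0, recalls[:-1]]
        ap = float(np.sum((recalls - prev_r) * precisions))
    elif interpolation in ("11point", "101point"):
        n = 11 if interpolation == "11point" else 101
        ap = 0.0
        for rt in np.linspace(0, 1, n):
            mask = recalls >= rt
            ap += (precisions[mask].max() if mask.any() else 0.0) / n
        ap = float(ap)
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return ap, precisions, recalls


def ap_from_detections(det_boxes, det_conf, truth_boxes_per_image,
                       iou_thresh: float = 0.5,
                       interpolation: str | None = None) -> float:
    """AP over a set of images.

    ``det_boxes``/``det_conf`` are lists (one entry per image);
    ``truth_boxes_per_image`` likewise.
    """
    flags, confs = [], []
    n_truth = 0
    for db, dc, tb in zip(det_boxes, det_conf, truth_boxes_per_image):
        tp, _ = match_flags(db, dc, tb, iou_thresh)
        flags.append(tp)
        confs.append(np.asarray(dc, dtype=float).reshape(-1))
        n_truth += _validate_boxes(tb).shape[0]
    if not flags:
        return 0.0
    ap, _, _ = average_precision(np.concatenate(flags), np.concatenate(confs),
                                 n_truth, interpolation)
    return ap


def mean_ap(aps) -> float:
    aps = np.asarray(list(aps), dtype=float)
    if aps.size == 0:
        raise ValueError("mean_ap over zero classes")
    return float(aps.mean())


# ---------------------------------------------------------------------------
# Severity stratification
# ---------------------------------------------------------------------------

SEVERE, MODERATE, BAD_CHANNEL, CLEAN = "severe", "moderate", "bad_channel", "clean"


def assign_severity(max_ptp: float, has_bad_channels: bool,
                    bands: tuple[float, float] = SEVERITY_BANDS) -> str:
    """Stratum for one trial from its Max PTP and the screen's bad-channel state.

    severe: Max PTP > 3000; moderate: 500 < Max PTP <= 3000;
    bad_channel: Max PTP <= 500 with at least one flagged channel;
    clean otherwise (explicit fourth stratum so the partition is total).
    """
    lo, hi = bands
    if max_ptp > hi:
        return SEVERE
    if max_ptp > lo:
        return MODERATE
    if has_bad_channels:
        return BAD_CHANNEL
    return CLEAN


def stratified_report(screens, detections_per_screen,
                      iou_thresh: float = 0.5,
                      bands: tuple[float, float] = SEVERITY_BANDS) -> EvalReport:
    """Overall + per-severity P/R/F1 for a list of screens and their detections.

    Each screen must expose ``trial_stats`` (list of (max_ptp, max_std)),
    ``trial_labels`` and ``bad_channel_mask``; detections are ``(boxes, conf)``
    with normalized boxes. Truth boxes are the full-height tenth-width columns
    of bad trials. Every detection is attributed to the trial column containing
    its center so per-stratum counts partition the match counts.
    """
    from .waveform_renderer import boxes_for_bad_trials

    strata = [SEVERE, MODERATE, BAD_CHANNEL, CLEAN]
    counts = {s: MatchCounts() for s in strata}
    total = MatchCounts()
    for screen, (boxes, conf) in zip(screens, detections_per_screen):
        if screen.trial_stats is None:
            raise ValueError("screen lacks trial_stats; run compute_trial_stats")
        has_bad = bool(np.asarray(screen.bad_channel_mask).any())
        n_trials = len(screen.trial_labels)
        trial_sev = [assign_severity(screen.trial_stats[t][0], has_bad, bands)
                     for t in range(n_trials)]
        truth = boxes_for_bad_trials(screen)
        truth_boxes = np.array([b[1:] for b in truth]).reshape(-1, 4)
        truth_trials = [int(round(b[1] * n_trials - 0.5)) for b in truth]
        boxes = _validate_boxes(boxes)
        conf = np.asarray(conf, dtype=float).reshape(-1)
        tp, matched = match_flags(boxes, conf, truth_boxes, iou_thresh)
        det_trials = np.clip((boxes[:, 0] * n_trials).astype(int), 0, n_trials - 1)
        for di in range(boxes.shape[0]):
            sev = trial_sev[det_trials[di]]
            if tp[di]:
                counts[sev].tp += 1
                total.tp += 1
            else:
                counts[sev].fp += 1
                total.fp += 1
        for ti in range(truth_boxes.shape[0]):
            if not matched[ti]:
                sev = trial_sev[truth_trials[ti]]
                counts[sev].fn += 1
                total.fn += 1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r = precision_recall(total)
        per = {}
        for s in strata:
            sp, sr = precision_recall(counts[s])
            per[s] = EvalReport(precision=sp, recall=sr, f1=f1_score(sp, sr),
                                counts=counts[s])
    return EvalReport(precision=p, recall=r, f1=f1_score(p, r), counts=total,
                      per_severity=per)
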