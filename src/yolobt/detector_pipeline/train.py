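"""Training loop: SGD + cosine annealing, mosaic/mixup, early stopping on
validation mAP, best-checkpoint return, CSV history."""

from __future__ import annotations

import copy
import csv
import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..nn import autograd as ag
from ..nn import SGD, cosine_lr
from ..eval_metrics import (ap_from_detections, match_detections,
                            precision_recall, f1_score)
from .model import Detector, DetectorConfig, build_model
from .loss import detection_loss
from .infer import detect
from .data import DetectionDataset, batches
from .anchors import kmeans_anchors

__all__ = ["TrainConfig", "train", "evaluate_detector", "save_checkpoint",
           "load_checkpoint", "run_ablation"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 600
    patience: int = 50
    batch_size: int = 16
    initial_lr: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    warmup_epochs: float = 3.0
    warmup_momentum: float = 0.8
    obj_pw: float = 1.0
    cls_pw: float = 1.0
    mosaic: bool = True
    mixup_alpha: float = 0.2
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    estimate_anchors: bool = True
    eval_conf_thresh: float = 0.25
    eval_interval: int = 1

    def __post_init__(self):
        if min(self.epochs, self.patience, self.batch_size) <= 0:
            raise ValueError("epochs/patience/batch_size must be positive")
        if abs(sum(self.split) - 1.0) > 1e-6:
            raise ValueError("split fractions must sum to 100%")


def evaluate_detector(model: Detector, dataset: DetectionDataset,
                      conf_thresh: float = 0.25) -> dict:
    """P/R/F1 at ``conf_thresh`` plus mAP@0.5 over all confidences."""
    det_boxes, det_confs, truths = [], [], []
    counts = None
    for img, lab in zip(dataset.images, dataset.labels):
        dets = detect(model, img, conf_thresh=0.001)
        boxes = np.array([d.box for d in dets]).reshape(-1, 4)
        confs = np.array([d.confidence for d in dets])
        tb = lab[:, 1:5].reshape(-1, 4)
        det_boxes.append(boxes)
        det_confs.append(confs)
        truths.append(tb)
        keep = confs >= conf_thresh
        c = match_detections(boxes[keep], confs[keep], tb)
        counts = c if counts is None else counts + c
    ap = ap_from_detections(det_boxes, det_confs, truths)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r = precision_recall(counts)
    return {"precision": p, "recall": r, "f1": f1_score(p, r),
            "map50": ap, "tp": counts.tp, "fp": counts.fp, "fn": counts.fn}


def _param_groups(model: Detector, weight_decay: float):
    decay, no_decay = [], []
    for name, p in model.named_parameters():
        (decay if p.data.ndim >= 2 else no_decay).append(p)
    return [{"params": decay, "weight_decay": weight_decay},
            {"params": no_decay, "weight_decay": 0.0}]


def train(model: Detector, train_ds: DetectionDataset,
          val_ds: DetectionDataset, cfg: TrainConfig,
          log_csv: str | Path | None = None,
          verbose: bool = False) -> tuple[Detector, list[dict]]:
    """Train in place; returns (model restored to best-val-mAP weights, history)."""
    if len(train_ds) == 0:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    if cfg.estimate_anchors:
        wh = train_ds.box_sizes_px()
        if wh.shape[0]:
            scale = model.cfg.input_size / train_ds.size
            model.detect.anchors = kmeans_anchors(wh * scale, seed=cfg.seed)
    opt = SGD(_param_groups(model, cfg.weight_decay),
              lr=cfg.initial_lr, momentum=cfg.momentum)
    history: list[dict] = []
    best_map, best_state, best_epoch = -1.0, None, -1
    steps_per_epoch = max(1, -(-len(train_ds) // cfg.batch_size))
    warmup_steps = max(1, int(cfg.warmup_epochs * steps_per_epoch))
    step = 0
    for epoch in range(cfg.epochs):
        epoch_lr = cosine_lr(cfg.initial_lr, epoch, cfg.epochs)
        model.train()
        losses = []
        for x, targets in batches(train_ds, cfg.batch_size, rng,
                                  use_mosaic=cfg.mosaic,
                                  mixup_alpha=cfg.mixup_alpha):
            if step < warmup_steps:
                frac = (step + 1) / warmup_steps
                opt.lr = frac * epoch_lr
                opt.momentum = (cfg.warmup_momentum
                                + frac * (cfg.momentum - cfg.warmup_momentum))
            else:
                opt.lr = epoch_lr
                opt.momentum = cfg.momentum
            step += 1
            preds = model(ag.tensor(x))
            loss, parts = detection_loss(
                preds, targets, model.detect.anchors,
                n_classes=model.cfg.n_classes,
                obj_pw=cfg.obj_pw, cls_pw=cfg.cls_pw)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append((float(loss.data), parts))
        last = epoch == cfg.epochs - 1
        if epoch % cfg.eval_interval == 0 or last:
            val = evaluate_detector(model, val_ds, cfg.eval_conf_thresh)
        else:
            val = {"precision": np.nan, "recall": np.nan, "f1": np.nan,
                   "map50": -1.0}
        mean_loss = float(np.mean([l for l, _ in losses])) if losses else 0.0
        rec = {"epoch": epoch, "lr": epoch_lr, "loss": mean_loss,
               "box": float(np.mean([p["box"] for _, p in losses])),
               "obj": float(np.mean([p["obj"] for _, p in losses])),
               "cls": float(np.mean([p["cls"] for _, p in losses])),
               "val_precision": val["precision"], "val_recall": val["recall"],
               "val_map50": val["map50"], "val_f1": val["f1"]}
        history.append(rec)
        if verbose:
            print(f"epoch {epoch}: loss {mean_loss:.4f} "
                  f"(box {rec['box']:.3f} obj {rec['obj']:.3f} "
                  f"cls {rec['cls']:.3f}) "
                  f"val mAP {val['map50']:.3f} P {val['precision']:.3f} "
                  f"R {val['recall']:.3f}")
        if val["map50"] >= 0 and val["map50"] > best_map:
            best_map, best_epoch = val["map50"], epoch
            best_state = copy.deepcopy(model.state_dict())
        elif epoch - best_epoch >= cfg.patience:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    if log_csv is not None and history:
        with open(log_csv, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
            w.writeheader()
            w.writerows(history)
    return model, history


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: Detector, path: str | Path) -> None:
    state = model.state_dict()
    cfg = dataclasses.asdict(model.cfg)
    np.savez(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8),
        __anchors__=model.detect.anchors, **state)


def load_checkpoint(path: str | Path) -> Detector:
    data = np.load(path, allow_pickle=False)
    cfg_d = json.loads(bytes(data["__config__"]).decode())
    for key in ("anchors", "gicm_branch", "gicm_token_pool", "hfgm_hidden"):
        if key in cfg_d and isinstance(cfg_d[key], list):
            cfg_d[key] = tuple(tuple(v) if isinstance(v, list) else v
                               for v in cfg_d[key])
    cfg = DetectorConfig(**cfg_d)
    model = build_model(cfg)
    model.load_state_dict({k: data[k] for k in data.files
                           if not k.startswith("__")})
    model.detect.anchors = data["__anchors__"]
    return model


# ---------------------------------------------------------------------------
# Ablation harness
# ---------------------------------------------------------------------------

ABLATION_GRID = (
    ("baseline", dict(clab=False, hfgm=False, gicm=False)),
    ("clab", dict(clab=True, hfgm=False, gicm=False)),
    ("clab+hfgm", dict(clab=True, hfgm=True, gicm=False)),
    ("full", dict(clab=True, hfgm=True, gicm=True)),
)


def run_ablation(base_cfg: DetectorConfig, train_ds: DetectionDataset,
                 val_ds: DetectionDataset, test_ds: DetectionDataset,
                 tcfg: TrainConfig, verbose: bool = False) -> dict:
    """Train and evaluate the four module-toggle configurations."""
    results = {}
    for name, toggles in ABLATION_GRID:
        cfg = dataclasses.replace(base_cfg, **toggles)
        model = build_model(cfg)
        model, history = train(model, train_ds, val_ds, tcfg, verbose=verbose)
        results[name] = {"test": evaluate_detector(model, test_ds,
                                                   tcfg.eval_conf_thresh),
                         "epochs_run": len(history)}
    return results
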