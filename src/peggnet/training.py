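"""Training/evaluation loop tying trunk, neck, loss, and metrics together.

Nothing here is exotic: AdamW with cosine decay on the blended
cross-entropy/focal objective, per-epoch validation, best-checkpoint
selection by validation accuracy, and a JSON manifest recording every seed
so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autograd as ag
from . import nn
from .backbone import BackboneConfig, build_backbone, count_parameters, \
    format_param_count
from .data import (AugmentSpec, EggLabel, SplitSpec, SyntheticEggParams,
                   augment_training_set, compute_normalization_stats,
                   generate_synthetic_dataset, load_image_folder, preprocess,
                   split_dataset)
from .evaluation import accuracy, confusion, consolidate_grades, report_table
from .losses import LossParams, alpha_from_frequencies, combined_loss_logits
from .network import build_msff, build_pegg

__all__ = ["TrainConfig", "AdamW", "build_variant", "run_training",
           "evaluate_model", "evaluate_checkpoint", "save_checkpoint",
           "load_checkpoint"]

VARIANTS = ("tiny", "small", "base", "large", "xlarge", "nano", "msff", "pegg")


@dataclass
class TrainConfig:
    variant: str = "pegg"
    epochs: int = 100
    batch_size: int = 16
    lr: float = 5e-4
    weight_decay: float = 0.05
    schedule: str = "cosine"
    gamma: float = 2.0
    alpha: str = "inverse_frequency"   # or an explicit 5-vector
    mix_ce: float = 0.5
    mix_fl: float = 0.5
    input_size: int = 224
    augment_factor: int = 1
    split_ratios: tuple = (0.7, 0.2, 0.1)
    split_seed: int = 0
    augment_seed: int = 0
    init_seed: int = 0
    out_dir: str = None
    stop_at_train_accuracy: float = None   # early stop once reached

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; valid: {VARIANTS}")


class AdamW:
    """Decoupled weight decay Adam."""

    def __init__(self, params, lr=5e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.05):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)


def build_variant(name, input_size=224, drop_path_rate=0.0):
    """Any named model: a plain backbone, the MSFF ablation, or full PEgg."""
    if name in ("msff", "pegg"):
        cfg = BackboneConfig.preset("nano", drop_path_rate=drop_path_rate)
        builder = build_pegg if name == "pegg" else build_msff
        return builder(backbone_cfg=cfg, input_size=input_size)
    cfg = BackboneConfig.preset(name, drop_path_rate=drop_path_rate)
    model = build_backbone(cfg)
    model.input_size = input_size
    return model


def save_checkpoint(model, path):
    np.savez(path, **model.state_dict())


def load_checkpoint(model, path):
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


def _cosine_lr(base, epoch, total):
    return base * 0.5 * (1 + np.cos(np.pi * epoch / max(total, 1)))


def _stack(pairs, input_size, mean, std):
    xs = np.stack([preprocess(img, input_size, mean, std) for img, _ in pairs])
    ys = np.array([label.value for _, label in pairs])
    return xs.astype(np.float32), ys


def _predict(model, x, batch_size=8):
    out = []
    for i in range(0, len(x), batch_size):
        out.append(model(ag.Tensor(x[i : i + batch_size])).data)
    return np.concatenate(out)


def evaluate_model(model, x, y, model_name="model"):
    """5-class and consolidated 3-grade reports for preprocessed data."""
    was_training = model.training
    model.eval()
    try:
        logits = _predict(model, x)
    finally:
        model.train(was_training)
    preds = logits.argmax(axis=1)
    cm5 = confusion(y, preds)
    cm3 = consolidate_grades(cm5)
    n_params = count_parameters(model)
    return {
        "model": model_name,
        "parameters": n_params,
        "parameters_rounded": format_param_count(n_params),
        "classification_accuracy": accuracy(cm5),
        "grading_accuracy": accuracy(cm3),
        "confusion_5class": cm5,
        "confusion_3grade": cm3,
        "classification_table": report_table(
            cm5, model_name, format_param_count(n_params)),
        "grading_table": report_table(
            cm3, model_name, format_param_count(n_params)),
    }


def run_training(config: TrainConfig, dataset_root=None, dataset=None,
                 synthetic_counts=None, verbose=False):
    """Train a variant and return {model, history, manifest, best_*}.

    Data comes from one of: a directory-per-class ``dataset_root``, an
    in-memory ``dataset`` ([(uint8 image, EggLabel), ...]), or freshly
    generated synthetic images (``synthetic_counts`` per class).
    """
    if dataset is None and dataset_root is None and synthetic_counts is None:
        raise ValueError(
            "no dataset: pass dataset_root, dataset, or synthetic_counts "
            "(or create images with `peggnet generate-data`)"
        )
    if dataset is None:
        if dataset_root is not None:
            root = Path(dataset_root)
            if not root.is_dir():
                raise FileNotFoundError(
                    f"dataset root {root} not found; generate one with "
                    "`peggnet generate-data`"
                )
            by_label = load_image_folder(root)
            dataset = [(img, lab) for lab, imgs in by_label.items()
                       for img in imgs]
        else:
            dataset = generate_synthetic_dataset(
                SyntheticEggParams(image_size=config.input_size,
                                   seed=config.split_seed),
                synthetic_counts,
            )
    by_label = {}
    for img, lab in dataset:
        by_label.setdefault(lab, []).append(img)
    split = split_dataset(
        by_label, SplitSpec(tuple(config.split_ratios), config.split_seed))
    train_pairs = split.train
    if config.augment_factor > 1:
        train_pairs = augment_training_set(
            train_pairs, AugmentSpec(factor=config.augment_factor,
                                     seed=config.augment_seed))
    mean, std = compute_normalization_stats([im for im, _ in train_pairs])

    nn.set_rng(config.init_seed)
    model = build_variant(config.variant, input_size=config.input_size)
    x_train, y_train = _stack(train_pairs, config.input_size, mean, std)
    x_val, y_val = (_stack(split.val, config.input_size, mean, std)
                    if split.val else (None, None))

    class_counts = np.bincount(y_train, minlength=len(EggLabel))
    alpha = (alpha_from_frequencies(np.maximum(class_counts, 1))
             if config.alpha == "inverse_frequency"
             else np.asarray(config.alpha, dtype=float))
    params = LossParams(alpha=alpha, gamma=config.gamma,
                        mix_ce=config.mix_ce, mix_fl=config.mix_fl)

    opt = AdamW(model.parameters(), lr=config.lr,
                weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.init_seed)
    history = []
    best = {"epoch": -1, "val_accuracy": -1.0, "state": model.state_dict()}
    for epoch in range(config.epochs):
        if config.schedule == "cosine":
            opt.lr = _cosine_lr(config.lr, epoch, config.epochs)
        model.train()
        order = rng.permutation(len(x_train))
        tot = ce_tot = fl_tot = 0.0
        correct = 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            model.zero_grad()
            logits = model(ag.Tensor(xb))
            loss, ce, fl = combined_loss_logits(logits, yb, params,
                                                return_components=True)
            loss.backward()
            opt.step()
            w = len(idx) / len(order)
            tot += float(loss.data) * w
            ce_tot += ce * w
            fl_tot += fl * w
            correct += int((logits.data.argmax(axis=1) == yb).sum())
        entry = {
            "epoch": epoch,
            "loss": tot,
            "loss_ce": ce_tot,
            "loss_fl": fl_tot,
            "train_accuracy": correct / len(order),
        }
        if x_val is not None:
            model.eval()
            val_preds = _predict(model, x_val).argmax(axis=1)
            entry["val_accuracy"] = float((val_preds == y_val).mean())
            if entry["val_accuracy"] > best["val_accuracy"]:
                best = {"epoch": epoch, "val_accuracy": entry["val_accuracy"],
                        "state": model.state_dict()}
        history.append(entry)
        stop = (config.stop_at_train_accuracy is not None
                and entry["train_accuracy"] >= config.stop_at_train_accuracy)
        if verbose:
            print(
                f"epoch {epoch:3d}  loss {tot:.4f} (ce {ce_tot:.4f} "
                f"fl {fl_tot:.4f})  train_acc {entry['train_accuracy']:.3f}"
                + (f"  val_acc {entry['val_accuracy']:.3f}"
                   if "val_accuracy" in entry else "")
            )
        if stop:
            break

    manifest = {
        "config": asdict(config),
        "normalization_mean": list(map(float, mean)),
        "normalization_std": list(map(float, std)),
        "n_train": len(x_train),
        "n_val": 0 if x_val is None else len(x_val),
        "parameters": count_parameters(model),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    result = {"model": model, "history": history, "manifest": manifest,
              "best_epoch": best["epoch"],
              "best_val_accuracy": best["val_accuracy"],
              "best_state": best["state"],
              "split": split, "norm": (mean, std)}
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "history.json").write_text(json.dumps(history, indent=2))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if config.epochs > 0:
            state = best["state"] if best["epoch"] >= 0 else model.state_dict()
            np.savez(out / "best.npz", **state)
    return result


def evaluate_checkpoint(checkpoint, variant, x, y, input_size=224,
                        model_name=None):
    """Load a checkpoint into a fresh variant and emit both report tables."""
    model = build_variant(variant, input_size=input_size)
    load_checkpoint(model, checkpoint)
    return evaluate_model(model, x, y, model_name or variant)
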