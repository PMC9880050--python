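"""Training, evaluation, prediction, and the FPB ablation harness.

Training minimizes the dice loss with Adam (the stated epsilon and learning
rate) plus global L2 weight decay, seeded shuffling, and best-loss
checkpointing.  Runs are deterministic given the seed on a fixed device.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import yaml

from .config import NetworkConfig, TrainConfig
from .data import SampleRecord, ValidationError
from .losses import batch_dice_from_logits, score_image, score_report
from .nn.network import FPMNet, build_network
from .nn.optim import Adam


@dataclass
class TrainResult:
    net: FPMNet
    history: list[float] = field(default_factory=list)  # per-iteration dice loss
    best_loss: float = np.inf
    best_params: Optional[dict] = None
    final_scores: Optional[dict] = None


def _stack(records: list[SampleRecord], dtype) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([r.image.transpose(2, 0, 1) for r in records]).astype(dtype)
    y = np.stack([r.mask for r in records]).astype(np.float64)
    return x, y


def _snapshot(net: FPMNet) -> dict:
    return {name: p.value.copy() for name, p in net.named_parameters()}


def _restore(net: FPMNet, params: dict) -> None:
    for name, p in net.named_parameters():
        p.value[...] = params[name]


def train(net_config: NetworkConfig, train_config: TrainConfig,
          records: list[SampleRecord],
          net: Optional[FPMNet] = None) -> TrainResult:
    """Train FPM-Net on the given (already augmented) training records.

    Stops at ``min(epochs * steps_per_epoch, max_iterations)``.  The best
    (lowest-loss) parameter snapshot is kept alongside the final weights.
    """
    train_config.validate()
    train_recs = [r for r in records if r.split == "train"]
    if not train_recs:
        raise ValidationError("empty training split")
    if net is None:
        net = build_network(net_config, seed=train_config.seed)
    net.set_training(True)
    opt = Adam(list(net.parameters()),
               learning_rate=train_config.learning_rate,
               epsilon=train_config.optimizer_epsilon,
               weight_decay=train_config.l2_coefficient)
    rng = np.random.default_rng(train_config.seed)
    result = TrainResult(net=net)
    bs = train_config.batch_size
    n = len(train_recs)
    iteration = 0
    for _epoch in range(train_config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            batch = [train_recs[i] for i in order[start:start + bs]]
            x, y = _stack(batch, net.dtype)
            logits, _ = net.forward_features(x)
            loss, dlogits = batch_dice_from_logits(logits, y)
            opt.zero_grad()
            net.backward_from_logits(dlogits)
            opt.step()
            result.history.append(loss)
            if loss < result.best_loss:
                result.best_loss = loss
                result.best_params = _snapshot(net)
            iteration += 1
            if iteration >= train_config.max_iterations:
                return result
    return result


def evaluate(net: FPMNet, records: list[SampleRecord],
             threshold: float = 0.5,
             region_masks: Optional[dict[str, np.ndarray]] = None) -> dict:
    """Per-image and aggregate SE/SP/Acc/AUC on original test images.

    Augmented images are rejected (leakage guard): evaluation is only ever
    on provenance=original records.
    """
    test = [r for r in records if r.split == "test"]
    if not test:
        raise ValidationError("empty test split")
    for r in test:
        if r.provenance != "original":
            raise ValidationError(
                f"test record {r.id} has provenance {r.provenance!r}; "
                "evaluation requires originals only")
    per_image = []
    for r in test:
        out = net.predict(r.image, threshold=threshold)
        region = region_masks.get(r.id) if region_masks else None
        c, s = score_image(out.prob_map[:, :, 1], r.mask,
                           threshold=threshold, region=region)
        per_image.append({"id": r.id, "tp": c.tp, "fp": c.fp, "tn": c.tn,
                          "fn": c.fn, "se": s.se, "sp": s.sp, "acc": s.acc,
                          "auc": s.auc})
    return score_report(per_image)


def ablation_study(net_config: NetworkConfig, train_config: TrainConfig,
                   records: list[SampleRecord],
                   threshold: float = 0.5) -> dict:
    """Train the network with and without the feature-preserving block under
    identical seeds and data orderings; report both score sets and parameter
    counts side by side (SE, SP, Acc, AUC, Parameters)."""
    report = {}
    for label, use_fpb in (("with_fpb", True), ("without_fpb", False)):
        cfg = net_config.with_updates(use_fpb=use_fpb)
        res = train(cfg, train_config, records)
        if res.best_params is not None:
            _restore(res.net, res.best_params)
        scores = evaluate(res.net, records, threshold=threshold)
        report[label] = {
            "SE": scores["micro"]["se"], "SP": scores["micro"]["sp"],
            "Acc": scores["micro"]["acc"], "AUC": scores["micro"]["auc"],
            "Parameters": res.net.num_parameters(),
            "final_loss": res.history[-1],
        }
    return report


# ---------------------------------------------------------------- checkpoints

def save_checkpoint(net: FPMNet, path: str | Path) -> None:
    """Save weights + config as a numpy ``.npz`` archive."""
    arrays = {f"param/{name}": p.value for name, p in net.named_parameters()}
    # batch-norm running statistics travel with the weights
    for name, child in _walk_bn(net):
        arrays[f"stat/{name}/mean"] = child.running_mean
        arrays[f"stat/{name}/var"] = child.running_var
    arrays["config_yaml"] = np.frombuffer(
        yaml.safe_dump(asdict(net.config)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def _walk_bn(module, prefix=""):
    from .nn.layers import BatchNorm2d
    for name, child in module._children.items():
        full = name if not prefix else f"{prefix}.{name}"
        if isinstance(child, BatchNorm2d):
            yield full, child
        yield from _walk_bn(child, full)


def load_checkpoint(path: str | Path) -> FPMNet:
    try:
        data = np.load(path)
    except OSError as e:
        raise IOError(f"cannot read checkpoint {path}: {e}") from e
    cfg = NetworkConfig(**yaml.safe_load(
        bytes(data["config_yaml"]).decode()))
    net = build_network(cfg, seed=0)
    for name, p in net.named_parameters():
        p.value[...] = data[f"param/{name}"]
    for name, child in _walk_bn(net):
        child.running_mean = data[f"stat/{name}/mean"]
        child.running_var = data[f"stat/{name}/var"]
    return net


# ------------------------------------------------------------------- predict

def _pad_to_divisible(image: np.ndarray, div: int) -> tuple[np.ndarray, tuple]:
    h, w = image.shape[:2]
    ph, pw = (-h) % div, (-w) % div
    top, left = ph // 2, pw // 2
    padded = np.pad(image, ((top, ph - top), (left, pw - left), (0, 0)))
    return padded, (top, left, h, w)


def predict_image(net: FPMNet, image_path: str | Path,
                  out_path: str | Path, threshold: float = 0.5,
                  save_probs: bool = False) -> dict:
    """Segment one image file; write the binary mask PNG ({0, 255}) and
    optionally the float vessel-probability map.

    Images whose size is not divisible by ``2^pooling_ops`` are symmetrically
    zero-padded and the output cropped back; the applied padding is recorded
    in the returned metadata.
    """
    try:
        img = iio.imread(image_path)
    except OSError as e:
        raise IOError(f"cannot read image {image_path}: {e}") from e
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    image = img[..., :3].astype(np.float32) / 255.0
    div = 2 ** net.config.pooling_ops
    padded, (top, left, h, w) = _pad_to_divisible(image, div)
    cfg = net.config
    try:
        if padded.shape[:2] != (cfg.input_height, cfg.input_width):
            net.config = cfg.with_updates(input_height=padded.shape[0],
                                          input_width=padded.shape[1])
        out = net.predict(padded, threshold=threshold)
    finally:
        net.config = cfg
    mask = out.mask[top:top + h, left:left + w]
    probs = out.prob_map[top:top + h, left:left + w, 1]
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_path, (mask * 255).astype(np.uint8))
    meta = {"input": str(image_path), "mask": str(out_path),
            "padding": [top, left], "size": [h, w], "threshold": threshold}
    if save_probs:
        prob_path = out_path.with_suffix(".probs.npy")
        np.save(prob_path, probs.astype(np.float32))
        meta["probs"] = str(prob_path)
    out_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return meta
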