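"""Progressive training: composite BCE+Dice loss, RMSProp, plateau schedule.

The model is trained sequentially over each patient's fractions in
chronological order (batch size 1).  The LSTM memory is cleared before and
after every patient so it only ever describes the current patient; between
the fractions of one patient it is carried forward.  By default
backpropagation is truncated at fraction boundaries (the carried memory is
detached, one optimizer step per fraction); ``detach_memory=False``
instead accumulates the loss over the whole course and takes one step per
patient with gradients flowing through the full sequence.

Training uses teacher forcing: the prior-contour channel holds the
*ground-truth* contours of the previous fraction, mirroring the clinical
workflow in which the previous fraction's contours were clinician-approved.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .fractions import PatientSeries
from .model import SegmentationUNet
from .nn import ReduceLROnPlateau, RMSProp, Tensor
from .runtime import assemble_input

DICE_EPS = 1e-6
BCE_CLAMP = 1e-7


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 1e-5
    min_learning_rate: float = 1e-8
    pretrain_epochs: int = 40
    finetune_epochs: int = 30
    bce_weight: float = 0.5
    dice_weight: float = 0.5
    plateau_patience: int = 3
    plateau_factor: float = 0.1
    grad_clip_norm: float | None = None  # global-norm clip; None disables
    detach_memory: bool = True
    reset_lr_for_finetune: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.min_learning_rate > self.learning_rate:
            raise ValueError("min learning rate must be <= initial learning rate")
        if self.pretrain_epochs < 1:
            raise ValueError("epochs must be >= 1")


# -- losses -------------------------------------------------------------

def soft_dice_loss(pred, target) -> Tensor:
    """1 - (2*sum(p*g)+eps) / (sum(p)+sum(g)+eps), averaged over channels."""
    pred = nn.as_tensor(pred)
    tgt = np.asarray(target, dtype=np.float64)
    if pred.shape != tgt.shape:
        raise ValueError(f"pred shape {pred.shape} != target shape {tgt.shape}")
    axes = tuple(range(1, pred.data.ndim))
    inter = (pred * tgt).sum(axis=axes)
    denom = pred.sum(axis=axes) + tgt.sum(axis=axes)
    dice = (2.0 * inter + DICE_EPS) / (denom + DICE_EPS)
    return (1.0 - dice).mean()


def bce_loss(pred, target) -> Tensor:
    """Voxelwise binary cross-entropy, probabilities clamped away from {0,1}."""
    pred = nn.as_tensor(pred)
    tgt = np.asarray(target, dtype=np.float64)
    if pred.shape != tgt.shape:
        raise ValueError(f"pred shape {pred.shape} != target shape {tgt.shape}")
    p = pred.clip(BCE_CLAMP, 1.0 - BCE_CLAMP)
    return -(tgt * p.log() + (1.0 - tgt) * (1.0 - p).log()).mean()


def composite_loss(pred, target, bce_weight: float = 0.5, dice_weight: float = 0.5) -> Tensor:
    """Equal-weight sum of binary cross-entropy and soft Dice loss."""
    return bce_weight * bce_loss(pred, target) + dice_weight * soft_dice_loss(pred, target)


def _target_stack(series: PatientSeries, k: int) -> np.ndarray:
    contours = series.fractions[k].contours
    return np.stack([contours[name] for name in series.structure_names]).astype(np.float64)


# -- logs ---------------------------------------------------------------

@dataclasses.dataclass
class TrainLog:
    epochs: list[dict] = dataclasses.field(default_factory=list)

    def record(self, **kw) -> None:
        self.epochs.append(kw)

    @property
    def lr_trajectory(self) -> list[float]:
        return [e["lr"] for e in self.epochs]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{k: v for k, v in e.items() if k != "patient_losses"} for e in self.epochs]
        return pd.DataFrame(rows)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = float(np.sqrt(sum(float((p.grad ** 2).sum())
                              for p in params if p.grad is not None)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total


# -- training loops -----------------------------------------------------

def train_patient_pass(model: SegmentationUNet, series: PatientSeries,
                       optimizer: RMSProp, config: TrainConfig) -> list[float]:
    """One sequential pass over a patient's fractions; returns per-fraction losses.

    Memory is zeroed on entry and on exit; within the pass it is carried
    between fractions (detached from the graph under truncated BPTT).
    """
    if series.n_fractions < 1:
        raise ValueError("series has no fractions")
    spatial = series.planning_image.shape
    model.memory = model.init_memory(spatial) if model.has_lstm else None
    losses: list[float] = []
    total = None
    prior_img, prior_cts = series.planning_image, series.planning_contours
    for k, frac in enumerate(series.fractions):
        x = (frac.image.data[None] if model.config.in_channels == 1
             else assemble_input(prior_img, prior_cts, frac.image))
        probs, mem = model(x, model.memory)
        loss = composite_loss(probs, _target_stack(series, k),
                              config.bce_weight, config.dice_weight)
        if not np.isfinite(loss.item()):
            raise RuntimeError(
                f"non-finite loss at patient {series.patient_id} fraction {frac.index}")
        losses.append(loss.item())
        if config.detach_memory:
            optimizer.zero_grad()
            loss.backward()
            if config.grad_clip_norm is not None:
                clip_grad_norm(optimizer.params, config.grad_clip_norm)
            optimizer.step()
            if mem is not None:
                model.memory = model.detach_memory(mem)
        else:
            total = loss if total is None else total + loss
            if mem is not None:
                model.memory = mem  # keep the graph across fractions
        prior_img, prior_cts = frac.image, frac.contours  # teacher forcing
    if not config.detach_memory:
        optimizer.zero_grad()
        total.backward()
        if config.grad_clip_norm is not None:
            clip_grad_norm(optimizer.params, config.grad_clip_norm)
        optimizer.step()
    model.memory = model.init_memory(spatial) if model.has_lstm else None
    return losses


def _epoch_permutation(seed: int, epoch: int, n: int) -> np.ndarray:
    return np.random.default_rng(np.random.SeedSequence([seed, epoch])).permutation(n)


def train_epoch(model: SegmentationUNet, cohort: Sequence[PatientSeries],
                optimizer: RMSProp, config: TrainConfig, epoch: int) -> dict:
    """Visit each patient once in a seed-derived per-epoch permutation."""
    if not cohort:
        raise ValueError("cohort is empty")
    order = _epoch_permutation(config.seed, epoch, len(cohort))
    patient_losses = {}
    for idx in order:
        series = cohort[idx]
        patient_losses[series.patient_id] = train_patient_pass(model, series, optimizer, config)
    mean_loss = float(np.mean([v for ls in patient_losses.values() for v in ls]))
    return {
        "order": [cohort[i].patient_id for i in order],
        "patient_losses": patient_losses,
        "train_loss": mean_loss,
    }


def evaluate_loss(model: SegmentationUNet, cohort: Sequence[PatientSeries],
                  config: TrainConfig) -> float:
    """Teacher-forced forward-only composite loss over a cohort."""
    total, count = 0.0, 0
    with nn.no_grad():
        for series in cohort:
            memory = model.init_memory(series.planning_image.shape) if model.has_lstm else None
            prior_img, prior_cts = series.planning_image, series.planning_contours
            for k, frac in enumerate(series.fractions):
                x = (frac.image.data[None] if model.config.in_channels == 1
                     else assemble_input(prior_img, prior_cts, frac.image))
                probs, mem = model(x, memory)
                loss = composite_loss(probs, _target_stack(series, k),
                                      config.bce_weight, config.dice_weight)
                total += loss.item()
                count += 1
                if mem is not None:
                    memory = model.detach_memory(mem)
                prior_img, prior_cts = frac.image, frac.contours
    return total / max(count, 1)


def _run_phase(model, cohort, val_cohort, optimizer, scheduler, config,
               n_epochs, phase, log, epoch_offset):
    for e in range(n_epochs):
        lr_used = optimizer.lr
        frag = train_epoch(model, cohort, optimizer, config, epoch_offset + e)
        val = evaluate_loss(model, val_cohort, config) if val_cohort else frag["train_loss"]
        scheduler.step(val)
        log.record(phase=phase, epoch=e + 1, lr=lr_used,
                   train_loss=frag["train_loss"], val_loss=val,
                   order=frag["order"], patient_losses=frag["patient_losses"])


def save_training_state(path, model: SegmentationUNet, optimizer: RMSProp,
                        scheduler: ReduceLROnPlateau | None = None) -> None:
    """Checkpoint model + optimizer (+ scheduler) for training resumption."""
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    opt = optimizer.state_dict()
    for i, s in enumerate(opt.pop("square_avg")):
        payload[f"opt/square_avg/{i}"] = s
    scalars = {"opt": opt}
    if scheduler is not None:
        scalars["sched"] = scheduler.state_dict()
    import json

    payload["scalars_json"] = np.frombuffer(json.dumps(scalars).encode(), dtype=np.uint8)
    np.savez_compressed(str(path), **payload)


def load_training_state(path, model: SegmentationUNet, optimizer: RMSProp,
                        scheduler: ReduceLROnPlateau | None = None) -> None:
    import json

    with np.load(str(path)) as z:
        model.load_state_dict({k[len("param/"):]: z[k] for k in z.files
                               if k.startswith("param/")})
        n = sum(1 for k in z.files if k.startswith("opt/square_avg/"))
        sq = [z[f"opt/square_avg/{i}"] for i in range(n)]
        scalars = json.loads(bytes(z["scalars_json"].tobytes()).decode())
    state = dict(scalars["opt"], square_avg=sq)
    optimizer.load_state_dict(state)
    if scheduler is not None and "sched" in scalars:
        scheduler.load_state_dict(scalars["sched"])


def fit(model: SegmentationUNet,
        pretrain_cohort: Sequence[PatientSeries],
        finetune_cohort: Sequence[PatientSeries] | None = None,
        validation_cohort: Sequence[PatientSeries] | None = None,
        config: TrainConfig | None = None,
        save_state_to=None) -> TrainLog:
    """Pre-train, then fine-tune from the final pre-trained weights.

    RMSProp starts at the configured learning rate; a reduce-on-plateau
    schedule monitors the validation loss (the training loss when no
    validation cohort is given) and decays the rate toward the floor.
    Fine-tuning continues in place from the last pre-trained state, with
    the learning rate and schedule restarted by default.
    """
    config = config or TrainConfig()
    log = TrainLog()
    optimizer = RMSProp(model.parameters(), lr=config.learning_rate)
    scheduler = ReduceLROnPlateau(optimizer, factor=config.plateau_factor,
                                  patience=config.plateau_patience,
                                  min_lr=config.min_learning_rate)
    _run_phase(model, pretrain_cohort, validation_cohort, optimizer, scheduler,
               config, config.pretrain_epochs, "pretrain", log, epoch_offset=0)
    if finetune_cohort:
        if config.reset_lr_for_finetune:
            optimizer.lr = config.learning_rate
            scheduler = ReduceLROnPlateau(optimizer, factor=config.plateau_factor,
                                          patience=config.plateau_patience,
                                          min_lr=config.min_learning_rate)
        _run_phase(model, finetune_cohort, validation_cohort, optimizer, scheduler,
                   config, config.finetune_epochs, "finetune", log,
                   epoch_offset=10_000 + config.pretrain_epochs)
    if save_state_to is not None:
        save_training_state(save_state_to, model, optimizer, scheduler)
    return log
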