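"""Training orchestration.

Three ways of consuming two (or more) expert annotations are supported:

* ``r1r2`` — each annotator's mask is an independent ground truth; every
  image appears once per annotator, doubling the corpus for two experts.
* ``and`` — the pixel-wise intersection of the annotations is the target.
* ``cm`` — all annotations are kept and the model's confusion heads explain
  each one as a corruption of a shared underlying segmentation; the
  confusion heads are warmed up for a few epochs with the trace sign flipped
  (maximizing the trace) to start from diagonally dominant, i.e. mostly
  reliable, annotators.

Splits are grouped by patient so both views of one woman never straddle
train/test.  The only augmentation is a random vertical flip, valid because
every image is left-oriented.  The checkpoint returned is the epoch with the
lowest validation loss (the same composite objective used for training).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize as sk_resize

from .errors import (AnnotatorCountMismatch, DivergedLoss, EmptyLoader,
                     InsufficientPatients)
from .losses import (LossWeights, annotator_loss, dice_loss, parametric_loss,
                     soft_reconstruct_t, total_loss, trace_term)
from .models import DenseTissueNet
from .nn import AdamW, Tensor

__all__ = ["TrainingConfig", "Sample", "make_splits", "augment",
           "build_targets", "train", "TrainResult", "resize_sample",
           "grid_search_weights"]

VARIATIONS = ("r1r2", "and", "cm")


@dataclass
class TrainingConfig:
    max_epochs: int = 500
    batch_size: int = 8
    learning_rate: float = 1e-4
    warmup_epochs: int = 10          # cm variation only
    warmup_learning_rate: float | None = None   # defaults to learning_rate
    cm_head_learning_rate: float | None = None  # joint phase, cm heads only
    # The parametric term joins the objective only once the trunk's map has
    # sharpened: against a near-uniform early map, the Dice objective
    # rewards an all-ones reconstruction and the parameter branch runs away
    # into clip saturation it cannot exit.  Activation requires BOTH the
    # epoch floor and the previous epoch's training Dice loss to fall below
    # the gate.
    rho_warmup_epochs: int = 5
    rho_gate_loss: float = 0.45
    variation: str = "cm"
    input_size: int = 256
    seed: int = 0
    validation_fraction: float = 0.10   # of the training portion
    test_fraction: float = 0.25
    alpha_loss: float = 0.9
    beta_loss: float = 0.1
    trace_reduction: str = "mean"
    soft_steepness: float = 50.0

    def __post_init__(self):
        if self.variation not in VARIATIONS:
            raise ValueError(f"variation must be one of {VARIATIONS}")
        if min(self.max_epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch size and learning rate must be positive")

    @property
    def weights(self) -> LossWeights:
        return LossWeights(self.alpha_loss, self.beta_loss)


@dataclass
class Sample:
    """One image with its annotations, aligned on a common grid."""

    image: np.ndarray                 # normalized intensities in [0, 1]
    breast: np.ndarray                # bool breast mask
    annotations: list[np.ndarray]     # one bool mask per annotator
    patient_id: str = ""
    sample_id: str = ""
    true_dense: np.ndarray | None = None   # phantom ground truth, if known
    center_id: str = ""


def resize_sample(sample: Sample, size: int) -> Sample:
    """Bilinear for the image, nearest-neighbor for every mask."""
    img = sk_resize(sample.image, (size, size), order=1, anti_aliasing=False,
                    preserve_range=True)
    def _nn(m):
        return sk_resize(m.astype(float), (size, size), order=0,
                         preserve_range=True).astype(bool)
    return replace(sample, image=img, breast=_nn(sample.breast),
                   annotations=[_nn(a) for a in sample.annotations],
                   true_dense=None if sample.true_dense is None
                   else _nn(sample.true_dense))


def make_splits(samples: Sequence[Sample], cfg: TrainingConfig
                ) -> tuple[list[Sample], list[Sample], list[Sample]]:
    """Patient-grouped random (train, val, test) split.

    The test fraction is taken over patients; the validation fraction is
    taken from the remaining training portion.  Deterministic given
    ``cfg.seed``."""
    patients = sorted({s.patient_id for s in samples})
    n = len(patients)
    need = (cfg.test_fraction > 0) + (cfg.validation_fraction > 0) + 1
    if n < need:
        raise InsufficientPatients(f"{n} patients cannot fill {need} splits")
    rng = np.random.default_rng(cfg.seed)
    order = [patients[i] for i in rng.permutation(n)]
    n_test = int(round(cfg.test_fraction * n))
    n_val = int(round(cfg.validation_fraction * (n - n_test)))
    if cfg.test_fraction > 0:
        n_test = max(1, n_test)
    if cfg.validation_fraction > 0:
        n_val = max(1, n_val)
    test_p = set(order[:n_test])
    val_p = set(order[n_test:n_test + n_val])
    train = [s for s in samples if s.patient_id not in test_p | val_p]
    val = [s for s in samples if s.patient_id in val_p]
    test = [s for s in samples if s.patient_id in test_p]
    return train, val, test


def augment(image: np.ndarray, masks: Sequence[np.ndarray],
            rng: np.random.Generator) -> tuple[np.ndarray, list[np.ndarray]]:
    """Random vertical (top-to-bottom) flip applied jointly, p = 0.5."""
    if rng.random() < 0.5:
        return image[::-1].copy(), [m[::-1].copy() for m in masks]
    return np.asarray(image), [np.asarray(m) for m in masks]


@dataclass
class _Item:
    sample: Sample
    target: np.ndarray | None          # r1r2 / and
    labels: list[np.ndarray] | None    # cm


def build_targets(samples: Sequence[Sample], variation: str) -> list[_Item]:
    """Materialize training targets for the chosen variation."""
    if variation not in VARIATIONS:
        raise ValueError(f"unknown variation {variation!r}")
    items: list[_Item] = []
    for s in samples:
        n = len(s.annotations)
        if variation == "r1r2":
            for a in s.annotations:
                items.append(_Item(s, np.asarray(a, bool), None))
        elif variation == "and":
            if n < 2:
                raise AnnotatorCountMismatch("AND fusion needs >= 2 annotators")
            inter = np.logical_and.reduce([np.asarray(a, bool)
                                           for a in s.annotations])
            items.append(_Item(s, inter, None))
        else:
            if n < 2:
                raise AnnotatorCountMismatch("cm variation needs >= 2 annotators")
            items.append(_Item(s, None, [np.asarray(a, bool)
                                         for a in s.annotations]))
    return items


@dataclass
class TrainResult:
    state: dict
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float


def _batch_losses(model: DenseTissueNet, xs: np.ndarray, breasts: np.ndarray,
                  targets: list, cfg: TrainingConfig, warmup: bool,
                  rho_active: bool = True):
    """Forward one batch and assemble (l_theta, l_phi, l_rho)."""
    out = model(Tensor(xs[:, None]))
    l_theta = l_phi = l_rho = None
    if cfg.variation == "cm":
        labels = [np.stack([t[r] for t in targets])
                  for r in range(len(targets[0]))]
        l_theta = annotator_loss(out["probs"], out["cms"], labels)
        tr = trace_term(out["cms"], cfg.trace_reduction)
        l_phi = (-1.0) * tr if warmup else tr
    elif "probs" in out:
        l_theta = dice_loss(out["probs"][:, 1], np.stack(targets))
    if "params" in out and not warmup and rho_active:
        if "probs" in out:
            l_rho = parametric_loss(out["probs"], xs, out["params"], breasts,
                                    cfg.soft_steepness)
        else:   # ECNN: the reconstruction is scored against the target mask
            recon = soft_reconstruct_t(xs, out["params"], breasts,
                                       cfg.soft_steepness)
            ref = np.stack(targets) if cfg.variation != "cm" else \
                np.stack([np.logical_and.reduce(t) for t in targets])
            l_rho = dice_loss(recon, ref)
    return l_theta, l_phi, l_rho


def _epoch_pass(model, items, cfg, rng, opts=None, warmup=False,
                rho_active=True):
    """One pass over ``items``; trains when optimizers are given."""
    training = opts is not None
    order = rng.permutation(len(items)) if training else np.arange(len(items))
    sums = {"theta": 0.0, "phi": 0.0, "rho": 0.0, "total": 0.0}
    n_batches = 0
    for start in range(0, len(items), cfg.batch_size):
        batch = [items[i] for i in order[start:start + cfg.batch_size]]
        xs, breasts, targets = [], [], []
        for it in batch:
            masks = [it.sample.breast]
            masks += it.labels if it.labels is not None else [it.target]
            if training:
                img, masks = augment(it.sample.image, masks, rng)
            else:
                img = it.sample.image
            xs.append(img)
            breasts.append(masks[0])
            targets.append(masks[1:] if it.labels is not None else masks[1])
        xs = np.stack(xs).astype(np.float64)
        breasts = np.stack(breasts).astype(np.float64)
        l_theta, l_phi, l_rho = _batch_losses(model, xs, breasts, targets,
                                              cfg, warmup, rho_active)
        loss = total_loss(l_theta, l_phi, l_rho, cfg.weights)
        if not np.isfinite(loss.data):
            raise DivergedLoss(f"loss became {loss.data}")
        if training:
            model.zero_grad()
            loss.backward()
            for opt in opts:
                opt.step()
        for key, t in (("theta", l_theta), ("phi", l_phi), ("rho", l_rho)):
            if t is not None:
                sums[key] += float(t.data)
        sums["total"] += float(loss.data)
        n_batches += 1
    return {k: v / max(n_batches, 1) for k, v in sums.items()}


def train(model: DenseTissueNet, train_samples: Sequence[Sample],
          val_samples: Sequence[Sample], cfg: TrainingConfig) -> TrainResult:
    """Optimize ``model``; return the best-validation checkpoint and history.

    The cm variation runs ``cfg.warmup_epochs`` of annotation-head warm-up
    first (trace sign flipped, parametric term off), then the joint
    objective.  Fully deterministic given ``cfg.seed``."""
    items = build_targets(train_samples, cfg.variation)
    val_items = build_targets(val_samples, cfg.variation) if val_samples else []
    if not items:
        raise EmptyLoader("no training samples")
    rng = np.random.default_rng(cfg.seed)
    warmup_n = cfg.warmup_epochs if cfg.variation == "cm" and \
        "cm" in model.cfg.heads else 0
    warm_lr = cfg.warmup_learning_rate or cfg.learning_rate

    def joint_optimizers() -> list[AdamW]:
        # The annotation heads may train faster than the trunk: a slow trunk
        # keeps the joint objective in the identifiable (diagonally
        # dominant) basin while fast heads absorb each annotator's bias.
        if cfg.cm_head_learning_rate is not None and hasattr(model, "cm_heads"):
            cm_params = [p for h in model.cm_heads for p in h.parameters()]
            cm_ids = {id(p) for p in cm_params}
            trunk = [p for p in model.parameters() if id(p) not in cm_ids]
            return [AdamW(trunk, lr=cfg.learning_rate),
                    AdamW(cm_params, lr=cfg.cm_head_learning_rate)]
        return [AdamW(model.parameters(), lr=cfg.learning_rate)]

    opts = ([AdamW(model.parameters(), lr=warm_lr)] if warmup_n
            else joint_optimizers())
    rows = []
    best_state, best_val, best_epoch = None, np.inf, -1
    has_params = "params" in model.cfg.heads
    n_readers = len(items[0].labels) if items[0].labels is not None else 1
    rho_on = not has_params
    last_theta = np.inf
    for epoch in range(cfg.max_epochs):
        warm = epoch < warmup_n
        if has_params and not rho_on:
            rho_on = (epoch >= max(warmup_n, cfg.rho_warmup_epochs) and
                      last_theta / n_readers < cfg.rho_gate_loss)
        if epoch == warmup_n and warmup_n:
            # pre-training over: fresh optimizer state for the joint phase
            opts = joint_optimizers()
        tr = _epoch_pass(model, items, cfg, rng, opts, warmup=warm,
                         rho_active=rho_on)
        last_theta = tr["theta"]
        rows.append({"epoch": epoch, "L_theta": tr["theta"], "L_phi": tr["phi"],
                     "L_rho": tr["rho"], "L_total": tr["total"],
                     "split": "train", "warmup": warm})
        if val_items:
            va = _epoch_pass(model, val_items, cfg, rng, opts=None,
                             warmup=warm, rho_active=rho_on)
            rows.append({"epoch": epoch, "L_theta": va["theta"],
                         "L_phi": va["phi"], "L_rho": va["rho"],
                         "L_total": va["total"], "split": "val",
                         "warmup": warm})
            score = va["total"]
        else:
            score = tr["total"]
        if not warm and rho_on and score < best_val:
            best_val, best_epoch = score, epoch
            best_state = model.state_dict()
    if best_state is None:       # all epochs were warm-up
        best_state, best_epoch, best_val = model.state_dict(), cfg.max_epochs - 1, score
    model.load_state_dict(best_state)
    return TrainResult(best_state, pd.DataFrame(rows), best_epoch, best_val)


def grid_search_weights(model_factory, train_samples, val_samples,
                        cfg: TrainingConfig,
                        grid=(0.1, 0.3, 0.5, 0.9)) -> pd.DataFrame:
    """Search (alpha_loss, beta_loss) over the grid; returns one row per pair
    with the best validation loss.  Not run by default anywhere."""
    rows = []
    for a in grid:
        for b in grid:
            c = replace(cfg, alpha_loss=a, beta_loss=b)
            res = train(model_factory(), train_samples, val_samples, c)
            rows.append({"alpha_loss": a, "beta_loss": b,
                         "best_val_loss": res.best_val_loss,
                         "best_epoch": res.best_epoch})
    return pd.DataFrame(rows)
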