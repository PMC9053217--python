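"""Hybrid segmentation loss, training loop, and snapshot selection.

The loss supervises the fused output and every decoder side output:

    L_final  = L_fuse + sum_i L_i,side
    L_fuse   = w_gds * L_gds + w_bbc * L_bbc + w_r * L_1
    L_i,side = w_gds * L_gds + w_bbc * L_bbc

with the generalized Dice loss (inverse-squared class-volume weights over
lesion and background), class-balanced binary cross-entropy (negative-class
fraction beta weighting the positive term), and an L1 penalty on all
predicted voxels that discourages false-positive claiming.  Default weights
are w_gds = w_bbc = 1 and w_r = 1e-5.

Training uses Adam at 3e-4 (halved after a 5-epoch validation plateau,
floor 1e-5), batches of 4 subjects, and per subject per step one of the 16
stride-phase subvolumes chosen uniformly at random; DWI and ADC channels
are standardized to zero mean / unit variance within the brain mask of the
subvolume.  Snapshots are stored every 10 epochs and the checkpoint with
the best validation Dice wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, ReduceLROnPlateau, Tensor
from .nn.tensor import backward_multi
from .volspace import SUBVOLUME_STRIDE

__all__ = [
    "LossWeights", "LossTerms", "TrainConfig", "Sample", "TrainResult",
    "generalized_dice_loss", "balanced_bce", "l1_predict_reg", "hybrid_loss",
    "train", "standardize_channels",
]

_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    w_gds: float = 1.0
    w_bbc: float = 1.0
    w_r: float = 1e-5

    def __post_init__(self):
        if min(self.w_gds, self.w_bbc, self.w_r) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossTerms:
    """Decomposition of the final training loss."""

    L_final: float
    L_fuse: float
    L_side: list[float]
    gds: list[float]   # fuse first, then the four side outputs
    bbc: list[float]
    L_1: float


def _gds(pred: np.ndarray, truth: np.ndarray):
    """Generalized Dice loss and its gradient w.r.t. the prediction."""
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(truth, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError("prediction and truth must share a shape")
    w_les = 1.0 / (g.sum() ** 2 + _EPS)
    w_bg = 1.0 / ((1.0 - g).sum() ** 2 + _EPS)
    num = w_les * (p * g).sum() + w_bg * ((1 - p) * (1 - g)).sum()
    den = w_les * (p + g).sum() + w_bg * ((1 - p) + (1 - g)).sum()
    loss = 1.0 - 2.0 * num / den
    dnum = w_les * g - w_bg * (1 - g)
    dden = w_les - w_bg
    grad = -2.0 * (dnum * den - num * dden) / den ** 2
    return float(loss), grad


def _bbc(pred: np.ndarray, truth: np.ndarray):
    """Balanced BCE and its gradient; probabilities clipped to [eps, 1-eps]."""
    p = np.clip(np.asarray(pred, dtype=np.float64), _EPS, 1.0 - _EPS)
    g = np.asarray(truth, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError("prediction and truth must share a shape")
    n = g.size
    beta = (1.0 - g).sum() / n
    loss = -(beta * g * np.log(p)
             + (1.0 - beta) * (1.0 - g) * np.log(1.0 - p)).sum() / n
    grad = -(beta * g / p - (1.0 - beta) * (1.0 - g) / (1.0 - p)) / n
    return float(loss), grad


def _l1(pred: np.ndarray):
    p = np.asarray(pred, dtype=np.float64)
    return float(np.abs(p).sum()), np.sign(p)


def generalized_dice_loss(pred, truth) -> float:
    """Generalized Dice loss over {lesion, background} with 1/volume^2
    class weights; 0 for a perfect binary prediction, up to 1."""
    return _gds(pred, truth)[0]


def balanced_bce(pred, truth) -> float:
    """Class-balanced binary cross-entropy with beta = negative fraction."""
    return _bbc(pred, truth)[0]


def l1_predict_reg(pred) -> float:
    """Sum of absolute predicted values over all voxels."""
    return _l1(pred)[0]


def downsample_truth(truth: np.ndarray, levels: int = 4) -> list[np.ndarray]:
    """Max-pooled ground truth per level so a lesion voxel survives pooling.

    Level 1 is the full-resolution mask; each deeper level max-pools by
    (2, 2, 2).
    """
    out = [np.asarray(truth, dtype=np.float32)]
    for _ in range(levels - 1):
        t = out[-1]
        d, h, w = t.shape[-3:]
        v = t.reshape(*t.shape[:-3], d // 2, 2, h // 2, 2, w // 2, 2)
        out.append(v.max(axis=(-5, -3, -1)))
    return out


def hybrid_loss(outputs, truths, w: LossWeights = LossWeights(),
                do_backward: bool = False) -> LossTerms:
    """Evaluate the deep-supervision hybrid loss.

    ``outputs``: dict with 'fuse' and 'side' (list of 4), as Tensors or
    arrays; ``truths``: level-matched binary masks (full resolution first).
    With ``do_backward`` the gradient of L_final flows into the graph in a
    single multi-root sweep.
    """
    outs = [outputs["fuse"], *outputs["side"]]
    if len(truths) != len(outs):
        raise ValueError(f"need {len(outs)} level-matched truths")
    gds_vals, bbc_vals, seeds = [], [], []
    l1_val = l1_grad = None
    for i, (out, truth) in enumerate(zip(outs, truths)):
        pred = out.data if isinstance(out, Tensor) else np.asarray(out)
        gv, gg = _gds(pred, truth)
        bv, bg = _bbc(pred, truth)
        gds_vals.append(gv)
        bbc_vals.append(bv)
        grad = w.w_gds * gg + w.w_bbc * bg
        if i == 0:
            l1_val, l1_grad = _l1(pred)
            grad = grad + w.w_r * l1_grad
        if isinstance(out, Tensor) and out.requires_grad:
            seeds.append((out, grad))
    L_fuse = w.w_gds * gds_vals[0] + w.w_bbc * bbc_vals[0] + w.w_r * l1_val
    L_side = [w.w_gds * g + w.w_bbc * b
              for g, b in zip(gds_vals[1:], bbc_vals[1:])]
    terms = LossTerms(L_final=L_fuse + sum(L_side), L_fuse=L_fuse,
                      L_side=L_side, gds=gds_vals, bbc=bbc_vals, L_1=l1_val)
    if do_backward and seeds:
        backward_multi(seeds)
    return terms


# ------------------------------------------------------------------ training

@dataclass
class Sample:
    """One training subject in the standardized space.

    ``image``: (X, Y, Z, C) float32 channel-last volume (DWI, ADC[, IS]);
    ``truth``: binary lesion mask; ``brain``: binary brain mask.
    """

    image: np.ndarray
    truth: np.ndarray
    brain: np.ndarray
    name: str = ""

    def __post_init__(self):
        if self.image.ndim != 4:
            raise ValueError("image must be (X, Y, Z, C)")
        if self.truth.shape != self.image.shape[:3]:
            raise ValueError("truth grid does not match image")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 3e-4
    min_lr: float = 1e-5
    plateau_patience: int = 5
    plateau_threshold: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 200
    early_stop_epoch: int = 100
    snapshot_every: int = 10
    val_fraction: float = 0.2
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0


@dataclass
class TrainResult:
    model: object
    history: list[dict]
    best_epoch: int
    best_val_dice: float
    snapshots: list[dict]


def standardize_channels(sub: np.ndarray, brain_sub: np.ndarray,
                         n_standardize: int = 2) -> np.ndarray:
    """Zero-mean / unit-variance DWI and ADC channels within the brain mask
    of a subvolume; further channels (the IS probability map) pass through."""
    out = sub.astype(np.float32, copy=True)
    mask = brain_sub > 0.5
    if not mask.any():
        return out
    for c in range(min(n_standardize, sub.shape[-1])):
        vox = out[..., c][mask]
        sd = vox.std()
        out[..., c] = (out[..., c] - vox.mean()) / (sd if sd > 1e-6 else 1.0)
    return out


def _phase_slices(phase, stride=SUBVOLUME_STRIDE):
    return tuple(slice(p, None, s) for p, s in zip(phase, stride))


def _extract(sample: Sample, phase):
    sl = _phase_slices(phase)
    img = sample.image[sl]
    brain = sample.brain[sl]
    x = standardize_channels(img, brain)
    # channel-first for the engine
    return np.ascontiguousarray(np.moveaxis(x, -1, 0)), sample.truth[sl]


def _all_phases(stride=SUBVOLUME_STRIDE):
    return [(i, j, k) for i in range(stride[0]) for j in range(stride[1])
            for k in range(stride[2])]


def _epoch_pass(model, samples, phases, w, batch=4, optimizer=None, rng=None):
    """One pass over ``samples``; trains when an optimizer is given.
    Returns (mean loss, mean batch Dice at 0.5)."""
    losses, dices = [], []
    order = (rng.permutation(len(samples)) if rng is not None
             else np.arange(len(samples)))
    for start in range(0, len(order), batch):
        idx = order[start:start + batch]
        xs, ts = [], []
        for i in idx:
            phase = phases[i] if rng is None else \
                phases[int(rng.integers(len(phases)))]
            x, t = _extract(samples[i], phase)
            xs.append(x)
            ts.append(t)
        x = Tensor(np.stack(xs), requires_grad=optimizer is not None)
        truth = np.stack(ts)[:, None]          # (N, 1, D, H, W)
        out = model(x)
        levels = downsample_truth(truth)
        truths = [levels[0]] + levels[:len(out["side"])]
        terms = hybrid_loss(out, truths, w, do_backward=optimizer is not None)
        if optimizer is not None:
            optimizer.step()
            model.zero_grad()
        losses.append(terms.L_final)
        pred = out["fuse"].data > 0.5
        inter = (pred & (truth > 0.5)).sum()
        denom = pred.sum() + (truth > 0.5).sum()
        dices.append(2.0 * inter / denom if denom else 1.0)
    return float(np.mean(losses)), float(np.mean(dices))


def train(model, cohort: list[Sample], cfg: TrainConfig = TrainConfig()
          ) -> TrainResult:
    """Train a segmentation network on a preprocessed cohort.

    The cohort is split (seeded) into training and validation subjects;
    the plateau monitor watches validation loss; the returned model carries
    the snapshot with the best validation Dice.
    """
    if not cohort:
        raise ValueError("empty training cohort")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(cohort))
    n_val = max(1, int(round(cfg.val_fraction * len(cohort)))) \
        if len(cohort) > 2 else 0
    val = [cohort[i] for i in order[:n_val]]
    tr = [cohort[i] for i in order[n_val:]]
    phases = _all_phases()
    # fixed validation phase per subject, drawn once
    val_phases = [phases[int(rng.integers(len(phases)))] for _ in val]

    optimizer = Adam(model.parameters(), lr=cfg.lr)
    sched = ReduceLROnPlateau(optimizer, factor=0.5,
                              patience=cfg.plateau_patience,
                              min_lr=cfg.min_lr,
                              threshold=cfg.plateau_threshold)
    history, snapshots = [], []
    stale = 0
    for epoch in range(1, cfg.max_epochs + 1):
        model.train()
        tr_loss, tr_dice = _epoch_pass(model, tr, phases, cfg.weights,
                                       batch=cfg.batch_size,
                                       optimizer=optimizer, rng=rng)
        model.eval()
        if val:
            val_loss, val_dice = _epoch_pass(model, val, val_phases,
                                             cfg.weights,
                                             batch=cfg.batch_size)
        else:
            val_loss, val_dice = tr_loss, tr_dice
        improved = val_loss < sched.best - cfg.plateau_threshold
        stale = 0 if improved else stale + 1
        sched.step(val_loss)
        history.append({"epoch": epoch, "train_loss": tr_loss,
                        "train_dice": tr_dice, "val_loss": val_loss,
                        "val_dice": val_dice, "lr": optimizer.lr})
        if epoch % cfg.snapshot_every == 0 or epoch == cfg.max_epochs:
            snapshots.append({"epoch": epoch, "val_dice": val_dice,
                              "state": model.state_dict()})
        converged = stale >= 2 * cfg.plateau_patience
        if epoch >= cfg.early_stop_epoch and converged:
            break
    if not snapshots:
        snapshots.append({"epoch": history[-1]["epoch"],
                          "val_dice": history[-1]["val_dice"],
                          "state": model.state_dict()})
    best = max(snapshots, key=lambda s: s["val_dice"])
    model.load_state_dict(best["state"])
    model.eval()
    return TrainResult(model=model, history=history,
                       best_epoch=best["epoch"],
                       best_val_dice=best["val_dice"],
                       snapshots=[{k: v for k, v in s.items() if k != "state"}
                                  for s in snapshots])
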