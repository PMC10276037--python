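"""Dataset assembly, augmentation, training loops and evaluation protocol.

Two supervised tasks share the same input encoding (single-channel geometry
image, solid = 1, fluid = 0):

* **scalar task** — predict the pair (porosity, effective diffusion
  coefficient) from geometry;
* **field task** — reconstruct the steady concentration map (0 on solid
  nodes) from geometry.

Training minimises the mean-square error; when the model carries a
self-normalization head the unit-normalization penalty is added per sample.
Model development follows a cross-type protocol: train and validate on one
geometry class, then test on the other.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .geometry import PorousSample
from .lbm import BoundarySpec
from .metrics import chibar2, field_error_stats
from .models import Model, mc_dropout_predict
from .nn import Adam

__all__ = [
    "Task",
    "TrainConfig",
    "split_dataset",
    "augment_hflip",
    "geometry_image",
    "train",
    "evaluate_scalar",
    "evaluate_field",
]


class Task(str, enum.Enum):
    SCALAR = "SCALAR"
    FIELD = "FIELD"


@dataclass
class TrainConfig:
    task: Task = Task.SCALAR
    train_type: str = "A"
    eval_type: str = "A"
    split_fraction: float = 0.7
    batch_size: int = 16
    epochs: int = 200
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    seed: int = 0
    augment: bool = True  # horizontal flip; stated for the scalar task
    lr_drop_epoch: int | None = None  # optional x0.3 step decay
    early_stopping_patience: int | None = None

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")


def split_dataset(records, fraction: float, seed: int, rounding: str = "floor"):
    """Seeded disjoint/exhaustive random split into (train, val).

    ``rounding='floor'`` gives ``floor(fraction*N)`` training items;
    ``rounding='round'`` rounds to nearest (2017 samples at 0.7 then split
    1412/605 rather than 1411/606).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = int(np.floor(fraction * n)) if rounding == "floor" else int(
        np.rint(fraction * n)
    )
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    pick = lambda idx: [records[i] for i in idx]
    return pick(perm[:n_train]), pick(perm[n_train:])


def geometry_image(sample: PorousSample) -> np.ndarray:
    """Network input encoding: solid = 1, fluid = 0, single channel."""
    return (~sample.fluid_mask).astype(np.float32)[None]


def augment_hflip(sample_img: np.ndarray, label, task: Task = Task.SCALAR,
                  bc: BoundarySpec | None = None):
    """Left-right mirror of a geometry image and its label.

    Scalar labels (phi, D) are invariant.  A mirrored geometry with the fixed
    inlet/outlet convention has the complemented mirrored field
    ``c -> (c_in + c_out) - c`` on fluid nodes (solid nodes keep the sentinel
    0), so field labels are mirrored and complemented inside the mirrored
    fluid mask.
    """
    sample_img = np.asarray(sample_img)
    flipped = sample_img[..., ::-1].copy()
    if task is Task.SCALAR:
        return flipped, label
    bc = bc or BoundarySpec()
    lab = np.asarray(label)[..., ::-1].copy()
    fluid = flipped[-1] == 0.0 if flipped.ndim == 3 else flipped == 0.0
    lab = np.where(fluid, (bc.c_in + bc.c_out) - lab, 0.0).astype(lab.dtype)
    return flipped, lab


def _as_batches(n: int, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for s in range(0, n, batch_size):
        yield idx[s : s + batch_size]


def _mse_and_grad(pred: np.ndarray, target: np.ndarray):
    """Mean-square error over all elements and its gradient wrt pred."""
    diff = pred - target
    mse = float((diff**2).mean())
    return mse, (2.0 / diff.size) * diff


def train(model: Model, train_set, val_set, cfg: TrainConfig):
    """Minibatch Adam on MSE (+ SN penalty when the head is present).

    ``train_set``/``val_set`` are ``(X, Y)`` array pairs: X of shape
    ``(N, 1, L, L)``; Y of shape ``(N, 2)`` for the scalar task or
    ``(N, 1, L, L)`` for the field task.  Returns a history dict with per-
    epoch train/val loss (and SN factor statistics when applicable).
    """
    X, Y = train_set
    Xv, Yv = val_set
    rng = np.random.default_rng(cfg.seed)
    model.set_rng(np.random.default_rng(np.random.SeedSequence([cfg.seed, 1])))
    opt = Adam(model.params(), lr=cfg.learning_rate)
    sn = model.sn_head
    history = {"train_loss": [], "val_loss": [], "sn_mean_abs_dev": []}
    best_val, best_epoch = np.inf, -1
    for epoch in range(cfg.epochs):
        if cfg.lr_drop_epoch is not None and epoch == cfg.lr_drop_epoch:
            opt.lr *= 0.3
        ep_loss = 0.0
        n_seen = 0
        sn_dev = []
        for batch in _as_batches(X.shape[0], cfg.batch_size, rng):
            xb, yb = X[batch], Y[batch]
            pred = model.forward(xb, training=True)
            mse, grad = _mse_and_grad(pred, yb)
            loss = mse
            if sn is not None:
                loss += sn.mean_penalty()
                sn_dev.append(float(np.abs(sn.last_y_bottom - 1.0).mean()))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            opt.zero_grad()
            model.backward(grad.astype(pred.dtype))
            opt.step()
            ep_loss += mse * xb.shape[0]
            n_seen += xb.shape[0]
        val_pred = _predict_in_batches(model, Xv, cfg.batch_size)
        val_loss = float(((val_pred - Yv) ** 2).mean())
        history["train_loss"].append(ep_loss / max(n_seen, 1))
        history["val_loss"].append(val_loss)
        history["sn_mean_abs_dev"].append(float(np.mean(sn_dev)) if sn_dev else np.nan)
        if val_loss < best_val - 1e-12:
            best_val, best_epoch = val_loss, epoch
        if (
            cfg.early_stopping_patience is not None
            and epoch - best_epoch >= cfg.early_stopping_patience
        ):
            break
    history["best_val_loss"] = best_val
    history["best_epoch"] = best_epoch
    return history


def _predict_in_batches(model: Model, X: np.ndarray, batch_size: int) -> np.ndarray:
    outs = [model.predict(X[s : s + batch_size]) for s in range(0, X.shape[0], batch_size)]
    return np.concatenate(outs, axis=0)


def _mc_in_batches(model: Model, X: np.ndarray, M: int, seed: int, batch_size: int = 16):
    means, sigmas = [], []
    for s in range(0, X.shape[0], batch_size):
        res = mc_dropout_predict(model, X[s : s + batch_size], M=M, seed=seed + s)
        means.append(res.mean)
        sigmas.append(res.sigma)
    return np.concatenate(means), np.concatenate(sigmas)


def evaluate_scalar(model: Model, dataset, M: int = 20, seed: int = 0) -> dict:
    """MC-dropout evaluation of a scalar (phi, D) predictor.

    Returns per-sample predictions with 1-sigma uncertainties, the MSE of
    the mean predictions, the uncertainty-weighted chi-bar-squared, and the
    fraction of samples whose true values fall within the 1- and 2-sigma
    bands (both outputs simultaneously).
    """
    X, Y = dataset
    mean, sigma = _mc_in_batches(model, X, M, seed)
    mse = float(((mean - Y) ** 2).mean())
    sig = np.maximum(sigma, 1e-12)  # dropout-p=0 edge: zero spread
    chi2 = chibar2(mean, Y, sig)
    within1 = np.all(np.abs(mean - Y) <= sig, axis=1)
    within2 = np.all(np.abs(mean - Y) <= 2 * sig, axis=1)
    return {
        "pred_mean": mean,
        "pred_sigma": sigma,
        "true": Y,
        "mse": mse,
        "chibar2": chi2,
        "coverage_1sigma": float(within1.mean()),
        "coverage_2sigma": float(within2.mean()),
        "residuals": mean - Y,
    }


def evaluate_field(model: Model, dataset, M: int = 20, seed: int = 0,
                   fluid_masks: np.ndarray | None = None) -> dict:
    """MC-dropout evaluation of a concentration-field reconstructor.

    Per-sample mean absolute error over all nodes and mean per-node
    1-sigma uncertainty, plus their dataset aggregates.
    """
    X, Y = dataset
    mean, sigma = _mc_in_batches(model, X, M, seed, batch_size=8)
    per_sample = []
    for i in range(X.shape[0]):
        mask = fluid_masks[i] if fluid_masks is not None else None
        stats = field_error_stats(Y[i, 0], mean[i, 0], fluid_mask=mask,
                                  uncertainty=sigma[i, 0])
        per_sample.append(
            {
                "mean_abs_error": stats["mean_abs_error"],
                "mean_uncertainty": stats["mean_uncertainty"],
            }
        )
    mae = float(np.mean([s["mean_abs_error"] for s in per_sample]))
    return {
        "pred_mean": mean,
        "pred_sigma": sigma,
        "per_sample": per_sample,
        "mean_abs_error": mae,
        "mean_uncertainty": float(np.mean([s["mean_uncertainty"] for s in per_sample])),
    }
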