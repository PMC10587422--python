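"""Seeded training loops, 5-fold cross-validation, and the hyper-parameter grid.

The grid spans the four experimental axes — window length (101/201/501),
loss (plain cross-entropy vs hard-negative mining), mining ratio
(0.3/0.5/0.7) and global-average-pooling context (on/off) — which expands to
24 combinations, 8 per window length.  Model selection follows the
length-then-metrics rule: fix the window length, maximize iou_1, break ties
on miou.

Optimizer defaults (Adam, lr 1e-3, batch 32, <= 30 epochs, early stop on the
training loss with patience 5) are this package's choices.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataprep import FoldSplit, LabeledWindow, encode_batch, make_folds
from .fcn_model import FCNModel, ModelConfig, build_model, make_config
from .nn import Adam
from .objectives import HNMConfig, IouReport, bce_loss, hnm_loss, iou

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    model: ModelConfig = field(default_factory=make_config)
    loss: str = "hnml"  # "hnml" | "bce"
    hnm_ratio: float = 0.7
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    patience: int = 5  # early stop on training loss

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss not in ("hnml", "bce"):
            raise ValueError("loss must be 'hnml' or 'bce'")

    def loss_fn(self):
        if self.loss == "hnml":
            cfg = HNMConfig(self.hnm_ratio)
            return lambda logits, labels: hnm_loss(logits, labels, cfg, return_grad=True)
        return lambda logits, labels: bce_loss(logits, labels, return_grad=True)


@dataclass
class FoldResult:
    fold: int
    report: IouReport
    history: list[float]


def train(
    dataset: list[LabeledWindow] | tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> tuple[FCNModel, list[float]]:
    """Train a model on labeled windows; returns (model, per-epoch loss history).

    Fully reproducible given ``cfg.seed`` (initialization, dropout and batch
    shuffling all derive from it).  Training aborts on a non-finite loss.
    The returned model carries the parameters of the best (lowest training
    loss) epoch.
    """
    if isinstance(dataset, tuple):
        X, y = dataset
    else:
        if not dataset:
            raise ValueError("empty dataset")
        X, y = encode_batch(dataset)
    model = build_model(cfg.model, seed=cfg.seed)
    opt = Adam(model.params(), lr=cfg.learning_rate)
    loss_fn = cfg.loss_fn()
    shuffle_rng = np.random.default_rng((cfg.seed, 2))

    history: list[float] = []
    best_loss = np.inf
    best_state: list[np.ndarray] | None = None
    best_bn: list[tuple[np.ndarray, np.ndarray]] | None = None
    stale = 0
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(len(X))
        epoch_losses = []
        for i in range(0, len(X), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model.forward(X[idx], training=True)
            value, grad = loss_fn(logits, y[idx])
            if not np.isfinite(value.total):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={value.total}"
                )
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_losses.append(value.total)
        mean_loss = float(np.mean(epoch_losses))
        history.append(mean_loss)
        log.debug("epoch %d: loss %.4f", epoch, mean_loss)
        if mean_loss < best_loss - 1e-6:
            best_loss = mean_loss
            best_state = [p.value.copy() for p in model.params()]
            best_bn = [
                (st.bn.running_mean.copy(), st.bn.running_var.copy())
                for st in model.dec_stages
            ]
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                log.debug("early stop at epoch %d", epoch)
                break
    if best_state is not None:
        for p, v in zip(model.params(), best_state):
            p.value[...] = v
        for st, (m, v) in zip(model.dec_stages, best_bn):
            st.bn.running_mean[...] = m
            st.bn.running_var[...] = v
    return model, history


def evaluate(model: FCNModel, windows: list[LabeledWindow] | tuple[np.ndarray, np.ndarray]) -> IouReport:
    """Micro-IoU of a model's per-site predictions on a window set."""
    X, y = windows if isinstance(windows, tuple) else encode_batch(windows)
    pred = model.predict(X)
    return iou(pred, y)


def cross_validate(
    dataset: list[LabeledWindow],
    cfg: TrainConfig,
    k: int = 5,
    folds: FoldSplit | None = None,
) -> tuple[list[FoldResult], IouReport]:
    """k train/test cycles on a stratified fold split; pooled micro-IoU.

    Every window is tested exactly once; pooled counts are the sum of the
    per-fold confusion counts.
    """
    if folds is None:
        folds = make_folds(dataset, k=k, seed=cfg.seed)
    X, y = encode_batch(dataset)
    results: list[FoldResult] = []
    pooled = IouReport()
    for f in range(folds.k):
        test_idx = folds.fold_indices(f)
        train_mask = np.ones(len(dataset), dtype=bool)
        train_mask[test_idx] = False
        model, history = train((X[train_mask], y[train_mask]), replace(cfg, seed=cfg.seed + f))
        rep = evaluate(model, (X[test_idx], y[test_idx]))
        results.append(FoldResult(fold=f, report=rep, history=history))
        pooled = pooled + rep
    return results, pooled


@dataclass
class GridSpec:
    """The four-axis hyper-parameter grid; expands to 24 combinations."""

    lengths: tuple[int, ...] = (101, 201, 501)
    losses: tuple[str, ...] = ("bce", "hnml")
    ratios: tuple[float, ...] = (0.3, 0.5, 0.7)
    pooling: tuple[bool, ...] = (True, False)

    def combinations(self) -> list[dict]:
        combos = []
        for length, pool in itertools.product(self.lengths, self.pooling):
            for loss in self.losses:
                if loss == "hnml":
                    for r in self.ratios:
                        combos.append(
                            dict(length=length, loss="hnml", ratio=r, pooling=pool)
                        )
                else:
                    combos.append(
                        dict(length=length, loss="bce", ratio=np.nan, pooling=pool)
                    )
        return combos


def run_grid(
    datasets: dict[int, list[LabeledWindow]],
    grid: GridSpec,
    base_cfg: TrainConfig,
    k: int = 5,
    variant: str = "fcn-3x4",
) -> pd.DataFrame:
    """One cross-validated row per grid combination.

    ``datasets`` maps window length -> windows of that length.  Lengths
    missing from the mapping raise, so a restricted grid is expressed by
    restricting ``grid.lengths``.
    """
    rows = []
    for combo in grid.combinations():
        length = combo["length"]
        if length not in datasets:
            raise KeyError(f"no dataset provided for window length {length}")
        model_cfg = make_config(
            variant, input_length=length, use_global_avg_pool=combo["pooling"]
        )
        cfg = replace(
            base_cfg,
            model=model_cfg,
            loss=combo["loss"],
            hnm_ratio=combo["ratio"] if combo["loss"] == "hnml" else base_cfg.hnm_ratio,
        )
        _, pooled = cross_validate(datasets[length], cfg, k=k)
        rows.append(
            {
                "length": length,
                "loss": combo["loss"],
                "ratio": combo["ratio"],
                "pooling": combo["pooling"],
                "iou_0": pooled.iou_0,
                "iou_1": pooled.iou_1,
                "miou": pooled.miou,
            }
        )
        log.info("grid row %s -> miou %.3f", combo, rows[-1]["miou"])
    return pd.DataFrame(rows)


def select_optimum(results: pd.DataFrame, length: int = 101) -> pd.Series:
    """Fix the window length, then maximize iou_1, breaking ties on miou."""
    sub = results[results["length"] == length]
    if sub.empty:
        raise ValueError(f"no grid rows at length {length}")
    best = sub.sort_values(["iou_1", "miou"], ascending=False, kind="stable").iloc[0]
    best = best.copy()
    best["criterion"] = f"length=={length}, argmax iou_1 then miou"
    return best
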