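"""Loss functions and per-class IoU metrics for per-site binding prediction.

Binding sites are a small fraction of every window, so plain cross-entropy
is dominated by easy negatives.  The hard-negative-mining loss (HNML) keeps
the full positive term but restricts the negative term to the hardest
(highest-loss) fraction of label-0 sites:

    loss = mean(CE at label-1 sites) + mean(top-k of CE at label-0 sites),
    k = max(1, floor(ratio * N_neg)),  ratio in (0, 1]

mined over the whole batch.  ratio = 1 recovers an unweighted two-term
cross-entropy; the plain BCE baseline averages over all sites jointly.

Evaluation uses per-class intersection-over-union: for class c,
iou_c = |pred==c ∩ true==c| / |pred==c ∪ true==c|, and miou is their mean.
Counts pool across all positions of all evaluated windows before division
(micro-IoU).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class HNMConfig:
    """Mining fraction for the hard-negative loss; grid values 0.3/0.5/0.7."""

    ratio: float = 0.7

    def __post_init__(self) -> None:
        if not 0 < self.ratio <= 1:
            raise ValueError("ratio must lie in (0, 1]")

    def top_k(self, n_neg: int) -> int:
        return max(1, int(np.floor(self.ratio * n_neg)))


@dataclass
class LossValue:
    total: float
    pos_term: float
    neg_term: float


def _flatten(logits: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    if logits.shape[-1] != 2:
        raise ValueError("logits must have a trailing class axis of size 2")
    flat_logits = logits.reshape(-1, 2)
    flat_labels = labels.reshape(-1)
    if flat_logits.shape[0] != flat_labels.shape[0]:
        raise ValueError("logits and labels are not aligned")
    if flat_labels.size == 0:
        raise ValueError("batch contains no sites")
    if not np.isin(flat_labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    return flat_logits, flat_labels.astype(np.int64)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def per_site_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """-log softmax-probability of the true class at every site.

    Accepts (..., 2) logits with matching label shape; returns the per-site
    loss array in the labels' shape.
    """
    flat_logits, flat_labels = _flatten(logits, labels)
    z = flat_logits - flat_logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    losses = -logp[np.arange(len(flat_labels)), flat_labels]
    return losses.reshape(np.asarray(labels).shape)


def hnm_loss(
    logits: np.ndarray,
    labels: np.ndarray,
    cfg: HNMConfig | float = 0.7,
    return_grad: bool = False,
) -> LossValue | tuple[LossValue, np.ndarray]:
    """Hard-negative-mining loss over a batch of per-site logits.

    With no positive sites the positive term is 0 (purely-negative batches
    remain trainable).  Top-k selection is deterministic: ties broken by
    site order.
    """
    if not isinstance(cfg, HNMConfig):
        cfg = HNMConfig(ratio=float(cfg))
    flat_logits, flat_labels = _flatten(logits, labels)
    losses = per_site_cross_entropy(flat_logits, flat_labels)

    pos_mask = flat_labels == 1
    neg_idx = np.flatnonzero(~pos_mask)
    n_pos = int(pos_mask.sum())
    pos_term = float(losses[pos_mask].mean()) if n_pos else 0.0

    if len(neg_idx):
        k = cfg.top_k(len(neg_idx))
        order = np.argsort(-losses[neg_idx], kind="stable")
        selected = neg_idx[order[:k]]
        neg_term = float(losses[selected].mean())
    else:
        k, selected, neg_term = 0, np.array([], dtype=int), 0.0

    value = LossValue(total=pos_term + neg_term, pos_term=pos_term, neg_term=neg_term)
    if not return_grad:
        return value

    p = softmax(flat_logits)
    g = p.copy()
    g[np.arange(len(flat_labels)), flat_labels] -= 1.0
    w = np.zeros(len(flat_labels))
    if n_pos:
        w[pos_mask] = 1.0 / n_pos
    if k:
        w[selected] = 1.0 / k
    grad = (g * w[:, None]).reshape(np.asarray(logits, dtype=np.float64).shape)
    return value, grad


def bce_loss(
    logits: np.ndarray,
    labels: np.ndarray,
    return_grad: bool = False,
) -> LossValue | tuple[LossValue, np.ndarray]:
    """Plain mean per-site cross-entropy over all sites (the non-mined
    baseline); positive/negative means are reported for diagnostics."""
    flat_logits, flat_labels = _flatten(logits, labels)
    losses = per_site_cross_entropy(flat_logits, flat_labels)
    pos_mask = flat_labels == 1
    value = LossValue(
        total=float(losses.mean()),
        pos_term=float(losses[pos_mask].mean()) if pos_mask.any() else 0.0,
        neg_term=float(losses[~pos_mask].mean()) if (~pos_mask).any() else 0.0,
    )
    if not return_grad:
        return value
    p = softmax(flat_logits)
    g = p.copy()
    g[np.arange(len(flat_labels)), flat_labels] -= 1.0
    grad = (g / len(flat_labels)).reshape(np.asarray(logits, dtype=np.float64).shape)
    return value, grad


@dataclass
class IouReport:
    """Per-class intersection/union counts and the derived IoU values.

    Reports add positionally, so per-fold counts pool into a micro-IoU.
    An empty union (class absent from both prediction and truth) scores 1.0
    — vacuous agreement; the raw counts stay available for re-aggregation.
    """

    inter_0: int = 0
    union_0: int = 0
    inter_1: int = 0
    union_1: int = 0

    @property
    def iou_0(self) -> float:
        return self.inter_0 / self.union_0 if self.union_0 else 1.0

    @property
    def iou_1(self) -> float:
        return self.inter_1 / self.union_1 if self.union_1 else 1.0

    @property
    def miou(self) -> float:
        return 0.5 * (self.iou_0 + self.iou_1)

    def __add__(self, other: "IouReport") -> "IouReport":
        return IouReport(
            self.inter_0 + other.inter_0,
            self.union_0 + other.union_0,
            self.inter_1 + other.inter_1,
            self.union_1 + other.union_1,
        )

    def as_dict(self) -> dict:
        return {
            "iou_0": self.iou_0,
            "iou_1": self.iou_1,
            "miou": self.miou,
            "inter_0": self.inter_0,
            "union_0": self.union_0,
            "inter_1": self.inter_1,
            "union_1": self.union_1,
        }


def iou(pred: np.ndarray, true: np.ndarray) -> IouReport:
    """Per-class IoU over 0/1 label arrays of any (matching) shape."""
    pred = np.asarray(pred).reshape(-1)
    true = np.asarray(true).reshape(-1)
    if pred.shape != true.shape:
        raise ValueError("pred and true must have the same number of sites")
    for arr, what in ((pred, "pred"), (true, "true")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{what} labels must be 0 or 1")
    rep = IouReport()
    rep.inter_1 = int(((pred == 1) & (true == 1)).sum())
    rep.union_1 = int(((pred == 1) | (true == 1)).sum())
    rep.inter_0 = int(((pred == 0) & (true == 0)).sum())
    rep.union_0 = int(((pred == 0) | (true == 0)).sum())
    return rep
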