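"""Loss and metric implementations checked against independent brute-force
oracles: an explicit softmax/log loop for cross-entropy, a full sort for the
hard-negative top-k, and set arithmetic for IoU."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circseg.objectives import (
    HNMConfig,
    IouReport,
    bce_loss,
    hnm_loss,
    iou,
    per_site_cross_entropy,
)

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def ce_oracle(logits, labels):
    """Explicit per-site -log softmax via plain Python floats."""
    out = []
    for (a, b), y in zip(logits, labels):
        m = max(a, b)
        za, zb = math.exp(a - m), math.exp(b - m)
        p = (za if y == 0 else zb) / (za + zb)
        out.append(-math.log(p))
    return out


def hnm_oracle(logits, labels, ratio):
    """Full-sort top-k oracle for the mined loss."""
    losses = ce_oracle(logits, labels)
    pos = [l for l, y in zip(losses, labels) if y == 1]
    neg = sorted((l for l, y in zip(losses, labels) if y == 0), reverse=True)
    pos_term = sum(pos) / len(pos) if pos else 0.0
    if neg:
        k = max(1, int(math.floor(ratio * len(neg))))
        neg_term = sum(neg[:k]) / k
    else:
        neg_term = 0.0
    return pos_term + neg_term


def iou_oracle(pred, true):
    """Set-arithmetic IoU oracle over explicit position sets."""
    out = {}
    for c in (0, 1):
        p = {i for i, v in enumerate(pred) if v == c}
        t = {i for i, v in enumerate(true) if v == c}
        union = p | t
        out[c] = len(p & t) / len(union) if union else 1.0
    return out[0], out[1], (out[0] + out[1]) / 2


# ---------------------------------------------------------------------------
# cross-entropy
# ---------------------------------------------------------------------------

class TestPerSiteCrossEntropy:
    def test_uniform_logits_give_ln2(self):
        logits = np.zeros((4, 2))
        labels = np.array([0, 1, 0, 1])
        assert per_site_cross_entropy(logits, labels) == pytest.approx([LN2] * 4)

    def test_confident_correct_loss_vanishes(self):
        logits = np.array([[30.0, -30.0], [-30.0, 30.0]])
        labels = np.array([0, 1])
        assert per_site_cross_entropy(logits, labels).max() < 1e-12

    def test_matches_oracle_random(self, rng):
        logits = rng.normal(size=(5, 2)) * 3
        labels = rng.integers(0, 2, size=5)
        expected = ce_oracle(logits, labels)
        np.testing.assert_allclose(
            per_site_cross_entropy(logits, labels), expected, atol=1e-6
        )

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            per_site_cross_entropy(np.zeros((2, 2)), np.array([0, 2]))


# ---------------------------------------------------------------------------
# hard-negative-mining loss
# ---------------------------------------------------------------------------

class TestHnmLoss:
    def test_analytic_uniform_case(self):
        # 4 sites, labels (1,0,0,0), uniform logits, ratio 0.5:
        # k = 1, pos = ln2, neg = ln2, total = 2 ln2
        v = hnm_loss(np.zeros((4, 2)), np.array([1, 0, 0, 0]), HNMConfig(0.5))
        assert v.pos_term == pytest.approx(LN2)
        assert v.neg_term == pytest.approx(LN2)
        assert v.total == pytest.approx(2 * LN2)

    def test_ratio_one_uses_all_negatives(self, rng):
        logits = rng.normal(size=(50, 2))
        labels = rng.integers(0, 2, size=50)
        v = hnm_loss(logits, labels, HNMConfig(1.0))
        losses = per_site_cross_entropy(logits, labels)
        assert v.neg_term == pytest.approx(losses[labels == 0].mean())
        assert v.pos_term == pytest.approx(losses[labels == 1].mean())

    @pytest.mark.parametrize("ratio", [0.3, 0.5, 0.7, 1.0])
    def test_matches_sort_oracle(self, ratio, rng):
        for _ in range(30):
            n = int(rng.integers(5, 200))
            logits = rng.normal(size=(n, 2)) * 2
            labels = (rng.random(n) < 0.2).astype(int)
            v = hnm_loss(logits, labels, HNMConfig(ratio))
            assert v.total == pytest.approx(hnm_oracle(logits, labels, ratio), abs=1e-6)

    def test_no_positive_sites_trainable(self):
        v = hnm_loss(np.zeros((6, 2)), np.zeros(6, dtype=int), HNMConfig(0.5))
        assert v.pos_term == 0.0
        assert v.total == pytest.approx(LN2)

    def test_permutation_invariance(self, rng):
        logits = rng.normal(size=(40, 2))
        labels = (rng.random(40) < 0.3).astype(int)
        perm = rng.permutation(40)
        a = hnm_loss(logits, labels, HNMConfig(0.5))
        b = hnm_loss(logits[perm], labels[perm], HNMConfig(0.5))
        assert a.total == pytest.approx(b.total)

    def test_neg_term_nonincreasing_in_k(self, rng):
        # top-k mean of descending values can only fall as k grows
        logits = rng.normal(size=(100, 2))
        labels = np.zeros(100, dtype=int)
        terms = [hnm_loss(logits, labels, HNMConfig(r)).neg_term
                 for r in (0.1, 0.3, 0.5, 0.7, 1.0)]
        assert all(a >= b - 1e-12 for a, b in zip(terms, terms[1:]))

    def test_gradient_matches_finite_difference(self, rng):
        logits = rng.normal(size=(12, 2))
        labels = (rng.random(12) < 0.4).astype(int)
        _, grad = hnm_loss(logits, labels, HNMConfig(0.5), return_grad=True)
        eps = 1e-6
        for i in (0, 5, 11):
            for j in (0, 1):
                lp = logits.copy(); lp[i, j] += eps
                lm = logits.copy(); lm[i, j] -= eps
                num = (hnm_loss(lp, labels, HNMConfig(0.5)).total
                       - hnm_loss(lm, labels, HNMConfig(0.5)).total) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-5)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="no sites"):
            hnm_loss(np.zeros((0, 2)), np.zeros(0), HNMConfig(0.5))

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError, match="ratio"):
            HNMConfig(0.0)


class TestBceLoss:
    def test_uniform_logits(self):
        v = bce_loss(np.zeros((8, 2)), np.array([0, 1] * 4))
        assert v.total == pytest.approx(LN2)

    def test_equals_mean_cross_entropy(self, rng):
        logits = rng.normal(size=(64, 2))
        labels = rng.integers(0, 2, size=64)
        v = bce_loss(logits, labels)
        assert v.total == pytest.approx(per_site_cross_entropy(logits, labels).mean())

    def test_relation_to_hnm_on_balanced_batch(self, rng):
        # with ratio 1 and an exactly balanced batch, HNML = 2 * BCE would
        # hold only if pos and neg means coincide; in general
        # hnm(ratio=1).total = pos_mean + neg_mean while bce = overall mean
        logits = rng.normal(size=(40, 2))
        labels = np.array([0, 1] * 20)
        hv = hnm_loss(logits, labels, HNMConfig(1.0))
        bv = bce_loss(logits, labels)
        assert bv.total == pytest.approx(0.5 * (hv.pos_term + hv.neg_term))

    def test_perfect_predictions(self):
        logits = np.array([[20.0, -20.0], [-20.0, 20.0]] * 5)
        labels = np.array([0, 1] * 5)
        assert bce_loss(logits, labels).total < 1e-3


# ---------------------------------------------------------------------------
# IoU
# ---------------------------------------------------------------------------

class TestIou:
    def test_perfect_prediction(self, rng):
        y = rng.integers(0, 2, size=50)
        rep = iou(y, y)
        assert rep.iou_0 == rep.iou_1 == rep.miou == 1.0

    def test_worked_example(self):
        rep = iou(np.array([0, 0, 0, 0]), np.array([0, 0, 1, 1]))
        assert rep.iou_0 == pytest.approx(0.5)
        assert rep.iou_1 == 0.0
        assert rep.miou == pytest.approx(0.25)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_set_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 1000))
        pred = r.integers(0, 2, size=n)
        true = r.integers(0, 2, size=n)
        rep = iou(pred, true)
        i0, i1, m = iou_oracle(pred.tolist(), true.tolist())
        assert (rep.iou_0, rep.iou_1, rep.miou) == (i0, i1, m)

    def test_vacuous_class_scores_one(self):
        rep = iou(np.zeros(10, dtype=int), np.zeros(10, dtype=int))
        assert rep.iou_1 == 1.0 and rep.union_1 == 0

    def test_reports_pool_additively(self, rng):
        a_p, a_t = rng.integers(0, 2, 30), rng.integers(0, 2, 30)
        b_p, b_t = rng.integers(0, 2, 70), rng.integers(0, 2, 70)
        pooled = iou(a_p, a_t) + iou(b_p, b_t)
        joint = iou(np.concatenate([a_p, b_p]), np.concatenate([a_t, b_t]))
        assert pooled.as_dict() == joint.as_dict()

    def test_miou_is_midpoint(self, rng):
        pred, true = rng.integers(0, 2, 40), rng.integers(0, 2, 40)
        rep = iou(pred, true)
        assert rep.miou == pytest.approx(0.5 * (rep.iou_0 + rep.iou_1))
        assert 0 <= rep.iou_0 <= 1 and 0 <= rep.iou_1 <= 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same number"):
            iou(np.zeros(3, dtype=int), np.zeros(4, dtype=int))
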