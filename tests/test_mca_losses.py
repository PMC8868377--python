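"""The loss family: closed-form oracles, reductions, margin audits, baselines."""

import numpy as np
import pytest

import mcagent as mc
from mcagent import autodiff as ad
from mcagent.mca_losses import per_sample_mca_loss

from conftest import naive_softmax


def normface_oracle(feats, centers, labels, scale):
    """Independent single-center normalized-SoftMax implementation (scalar loops)."""
    total = 0.0
    for i, f in enumerate(feats):
        logits = np.array([scale * float(f @ w) for w in centers])
        z = logits - logits.max()
        total += -(z[labels[i]] - np.log(np.exp(z).sum()))
    return total / len(feats)


def orthogonal_construction():
    """Two classes, single orthogonal centers, features sitting exactly on them."""
    feats = np.array([[1.0, 0.0], [0.0, 1.0]])
    labels = np.array([0, 1])
    bank = mc.CenterBank(np.array([[[1.0, 0.0]], [[0.0, 1.0]]]))
    return feats, labels, bank


class TestCenterDiversityReg:
    def test_single_center_is_zero(self):
        assert mc.center_diversity_reg(np.ones((3, 1, 4))) == 0.0

    def test_identical_centers_near_zero(self):
        w = np.tile(np.array([1.0, 0.0, 0.0]), (2, 3, 1))
        assert mc.center_diversity_reg(w) < 1e-9

    def test_two_orthogonal_centers_hand_value(self):
        # one class, centers e1 and e2: two ordered pairs at distance sqrt(2),
        # normalizer 1*2*1 -> sqrt(2)
        w = np.array([[[1.0, 0.0], [0.0, 1.0]]])
        assert abs(mc.center_diversity_reg(w) - np.sqrt(2)) < 1e-9

    def test_loop_oracle(self, small_state):
        _, _, bank = small_state
        w = bank.normalized()
        Y, C, _ = w.shape
        acc = sum(
            np.linalg.norm(w[j, s] - w[j, t])
            for j in range(Y) for s in range(C) for t in range(C)
        )
        expected = acc / (Y * C * (C - 1))
        assert abs(mc.center_diversity_reg(bank) - expected) < 1e-9


class TestSoftmaxAgentLoss:
    def test_symmetric_two_class_is_ln2(self):
        # both agent logits equal for every sample -> cross-entropy ln 2
        feats = mc.normalize_rows(np.array([[1.0, 1.0]]))
        bank = mc.CenterBank(np.array([[[1.0, 0.0]], [[0.0, 1.0]]]))
        for lam in (1.0, 24.0):
            cfg = mc.MCAConfig(lam=lam, centers_per_class=1)
            sm, _ = mc.softmax_agent_loss(feats, bank, cfg, labels=np.array([0]))
            assert abs(sm - np.log(2)) < 1e-9

    def test_orthogonal_single_center_value(self):
        feats, labels, bank = orthogonal_construction()
        cfg = mc.MCAConfig(lam=24.0, centers_per_class=1)
        sm, reg = mc.softmax_agent_loss(feats, bank, cfg, labels=labels)
        assert abs(sm - np.log(1 + np.exp(-24.0))) < 1e-12
        assert reg == 0.0

    def test_relabeling_invariance(self, small_state):
        feats, labels, bank = small_state
        cfg = mc.MCAConfig(centers_per_class=bank.centers_per_class)
        sm, _ = mc.softmax_agent_loss(feats, bank, cfg, labels=labels)
        perm = np.array([2, 0, 3, 1])
        bank2 = mc.CenterBank(bank.normalized()[perm])
        inv = np.argsort(perm)
        sm2, _ = mc.softmax_agent_loss(feats, bank2, cfg, labels=inv[labels])
        assert abs(sm - sm2) < 1e-9


class TestKnnNegativeAgents:
    def test_two_classes_single_negative(self):
        with pytest.warns(UserWarning, match="clamped"):
            idx = mc.knn_negative_agents(np.array([[0.9, 0.1]]), np.array([0]), k=5)
        np.testing.assert_array_equal(idx, [[1]])

    def test_top2_by_similarity(self):
        logits = np.array([[0.99, 0.7, 0.5, 0.3]])
        idx = mc.knn_negative_agents(logits, np.array([0]), k=2)
        np.testing.assert_array_equal(idx, [[1, 2]])

    def test_full_sort_oracle(self, rng):
        for _ in range(20):
            n, Y = rng.integers(2, 9), rng.integers(2, 9)
            logits = rng.standard_normal((n, Y))
            labels = rng.integers(0, Y, size=n)
            k = int(rng.integers(1, Y))
            idx = mc.knn_negative_agents(logits, labels, k)
            for i in range(n):
                negs = [j for j in range(Y) if j != labels[i]]
                expect = sorted(negs, key=lambda j: -logits[i, j])[:k]
                assert list(idx[i]) == expect

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mc.knn_negative_agents(np.array([[1.0]]), np.array([0]), k=1)


class TestKnnatLoss:
    def test_satisfied_margin_is_zero(self):
        logits = np.array([[0.9, 0.1, 0.2]])
        assert mc.knnat_loss(logits, np.array([0]), k=2, margin=0.4) == 0.0

    def test_hand_evaluated_hinges(self):
        logits = np.array([[0.8, 0.7, 0.5, 0.3]])
        val = mc.knnat_loss(logits, np.array([0]), k=2, margin=0.4)
        assert abs(val - ((0.7 - 0.8 + 0.4) + (0.5 - 0.8 + 0.4))) < 1e-12

    def test_single_neighbor_hinge_arithmetic(self):
        pos, delta = 0.6, 0.4
        logits = np.array([[pos, pos - delta + 0.05]])
        assert abs(mc.knnat_loss(logits, np.array([0]), k=1, margin=delta) - 0.05) < 1e-12


class TestMCALoss:
    def test_beta_zero_reduces_to_softmax_agent(self, small_state):
        feats, labels, bank = small_state
        cfg = mc.MCAConfig(centers_per_class=bank.centers_per_class, beta=0.0)
        bd = mc.mca_loss(feats, bank, cfg, labels=labels)
        sm, reg = mc.softmax_agent_loss(feats, bank, cfg, labels=labels)
        assert abs(bd.total - (sm + cfg.tau * reg)) < 1e-12

    def test_single_center_matches_normface_oracle(self, rng):
        feats = mc.normalize_rows(rng.standard_normal((5, 4)))
        labels = rng.integers(0, 3, size=5)
        bank = mc.CenterBank.random(3, 1, 4, seed=3)
        cfg = mc.MCAConfig(centers_per_class=1, beta=0.0, tau=0.37)
        bd = mc.mca_loss(feats, bank, cfg, labels=labels)
        assert bd.reg_term == 0.0
        assert abs(bd.total - normface_oracle(feats, bank.normalized()[:, 0], labels, cfg.lam)) < 1e-9

    def test_zero_loss_orthogonal_construction(self):
        feats, labels, bank = orthogonal_construction()
        cfg = mc.MCAConfig(centers_per_class=1, k_neg=1)
        bd = mc.mca_loss(feats, bank, cfg, labels=labels)
        assert bd.triplet_term == 0.0  # gap 1 > margin 0.4
        assert abs(bd.total - np.log(1 + np.exp(-24.0))) < 1e-12

    def test_decomposition_on_random_states(self, rng):
        for _ in range(10):
            n, Y, C, d = (int(rng.integers(2, 8)) for _ in range(4))
            d = max(d, 2)
            feats = mc.normalize_rows(rng.standard_normal((n, d)))
            labels = rng.integers(0, Y, size=n)
            bank = mc.CenterBank.random(max(Y, 2), C, d, seed=int(rng.integers(1000)))
            cfg = mc.MCAConfig(centers_per_class=C, k_neg=1)
            bd = mc.mca_loss(feats, bank, cfg, labels=labels)
            assert abs(bd.total - (bd.softmax_term + cfg.tau * bd.reg_term + cfg.beta * bd.triplet_term)) < 1e-9
            assert bd.softmax_term >= 0 and bd.reg_term >= 0 and bd.triplet_term >= 0

    def test_special_case_chain_by_config_only(self, small_state):
        """C=1/beta=0 combinations reproduce the ablation family from one code path."""
        feats, labels, bank = small_state
        single = mc.CenterBank(bank.normalized()[:, :1])
        ln = np.log  # noqa: F841  (kept local for readability of values below)
        cases = {
            "single_softmax": (single, dict(centers_per_class=1, beta=0.0)),
            "single_agent": (single, dict(centers_per_class=1, beta=0.1)),
            "multi_softmax": (bank, dict(centers_per_class=3, beta=0.0)),
            "full_mca": (bank, dict(centers_per_class=3, beta=0.1)),
        }
        vals = {}
        for name, (b, kw) in cases.items():
            vals[name] = mc.mca_loss(feats, b, mc.MCAConfig(**kw), labels=labels)
        assert vals["single_softmax"].triplet_term == 0.0
        assert vals["single_agent"].softmax_term == pytest.approx(vals["single_softmax"].softmax_term)
        assert vals["full_mca"].softmax_term == pytest.approx(vals["multi_softmax"].softmax_term)
        assert vals["full_mca"].triplet_term > 0 or vals["single_agent"].triplet_term >= 0

    def test_gradients_match_finite_differences(self, rng):
        n, Y, C, d = 4, 3, 2, 5
        f0 = rng.standard_normal((n, d))
        w0 = rng.standard_normal((Y, C, d))
        labels = rng.integers(0, Y, size=n)
        cfg = mc.MCAConfig(centers_per_class=C)

        def loss_fn(ft, wt):
            w = mc.normalize_rows(wt.reshape((Y * C, d))).reshape((Y, C, d))
            return mc.mca_loss(mc.normalize_rows(ft), w, cfg, labels=labels).total

        ft = ad.Tensor(f0, requires_grad=True)
        wt = ad.Tensor(w0, requires_grad=True)
        assert ad.check_gradients(loss_fn, [ft, wt]) < 1e-3


class TestEuclideanCosineIdentity:
    def test_identity_on_random_unit_triples(self, rng):
        """||u-v||^2 - ||u-w||^2 = 2(u.w - u.v) for unit vectors."""
        u, v, w = (mc.normalize_rows(rng.standard_normal((1000, 6))) for _ in range(3))
        lhs = np.sum((u - v) ** 2, axis=1) - np.sum((u - w) ** 2, axis=1)
        rhs = 2 * (np.sum(u * w, axis=1) - np.sum(u * v, axis=1))
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestMarginAudit:
    def test_zero_loss_construction_passes_t1(self):
        feats, labels, bank = orthogonal_construction()
        cfg = mc.MCAConfig(centers_per_class=1, k_neg=1)
        rep = mc.margin_audit(feats, bank, cfg, delta0=0.1, labels=labels)
        assert rep.qualifying.size == 2
        assert rep.t1_pass and rep.t1_violations.size == 0
        assert rep.cosine_gaps.min() == pytest.approx(1.0)  # gap 1 > 0.4 - 0.1
        assert rep.t2_triangle_pass
        assert rep.theta == pytest.approx(0.0)

    def test_high_loss_samples_vacuously_pass(self, small_state):
        feats, labels, bank = small_state
        cfg = mc.MCAConfig(centers_per_class=bank.centers_per_class)
        losses = per_sample_mca_loss(feats, bank, cfg, labels=labels)
        delta0 = losses.min() * 0.5 if losses.min() > 0 else 1e-6
        rep = mc.margin_audit(feats, bank, cfg, delta0=delta0, labels=labels)
        assert rep.qualifying.size == 0
        assert rep.t1_pass and rep.t2_sq_pass and rep.t2_triangle_pass

    def test_theorem1_property_from_triplet_bound(self, rng):
        """Per-sample triplet < delta0 forces the worst-case gap over ALL
        negatives above margin - delta0 (nearest negatives are most similar)."""
        for _ in range(50):
            Y = int(rng.integers(3, 8))
            logits = rng.uniform(-1, 1, size=(1, Y))
            label = np.array([int(rng.integers(0, Y))])
            cfg = mc.MCAConfig(centers_per_class=1, k_neg=2)
            trip = float(mc.knnat_loss(logits, label, cfg.k_neg, cfg.margin))
            delta0 = 0.25
            if trip < delta0:
                negs = np.delete(logits[0], label[0])
                gap = logits[0, label[0]] - negs.max()
                assert gap > cfg.margin - delta0


class TestTripletBaseline:
    def test_collapsed_classes_far_apart_is_zero(self):
        feats = np.array([[1.0, 0], [1.0, 0], [0, 1.0], [0, 1.0]])
        labels = np.array([0, 0, 1, 1])
        assert mc.triplet_hard_mining_loss(feats, margin=0.5, labels=labels) == 0.0

    def test_hand_distance_arithmetic(self):
        # anchors: e1 (pos e2 at sqrt2, neg e1 at 0) and e2 (pos e1, neg e1 at sqrt2)
        feats = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        labels = np.array([0, 0, 1])
        val = mc.triplet_hard_mining_loss(feats, margin=0.5, labels=labels)
        expect = (max(0, np.sqrt(2) - 0 + 0.5) + max(0, np.sqrt(2) - np.sqrt(2) + 0.5)) / 2
        assert abs(val - expect) < 1e-9

    def test_easy_triplet_is_zero_and_no_anchor_warns(self):
        feats = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        labels = np.array([0, 0, 1])
        assert mc.triplet_hard_mining_loss(feats, margin=0.5, labels=labels) == 0.0
        with pytest.warns(UserWarning, match="no valid triplet"):
            out = mc.triplet_hard_mining_loss(np.eye(2), margin=0.5, labels=np.array([0, 1]))
        assert out == 0.0


class TestArcFace:
    def test_margin_zero_reduces_to_normface(self, rng):
        feats = mc.normalize_rows(rng.standard_normal((6, 4)))
        labels = rng.integers(0, 3, size=6)
        bank = mc.CenterBank.random(3, 1, 4, seed=5)
        val = mc.arcface_loss(feats, bank, m=0.0, r=32.0, labels=labels)
        assert abs(val - normface_oracle(feats, bank.normalized()[:, 0], labels, 32.0)) < 1e-9

    def test_scalar_evaluation_at_center(self):
        feats, labels, bank = orthogonal_construction()
        val = mc.arcface_loss(feats, bank, m=0.1, r=32.0, labels=labels)
        expect = np.log(1 + np.exp(-32 * np.cos(0.1)))
        assert abs(val - expect) < 1e-9

    def test_margin_monotone(self, rng):
        feats = mc.normalize_rows(rng.standard_normal((5, 4)))
        labels = rng.integers(0, 3, size=5)
        bank = mc.CenterBank.random(3, 1, 4, seed=6)
        vals = [float(mc.arcface_loss(feats, bank, m=m, r=32.0, labels=labels))
                for m in (0.0, 0.05, 0.1, 0.2)]
        assert vals == sorted(vals)

    def test_multi_center_rejected(self):
        bank = mc.CenterBank.random(2, 3, 4, seed=0)
        with pytest.raises(ValueError, match="single center"):
            mc.arcface_loss(np.eye(4)[:2], bank, labels=np.array([0, 1]))


class TestSoftTriple:
    def test_margin_zero_equals_mca_softmax_term(self, small_state):
        feats, labels, bank = small_state
        st_cfg = mc.SoftTripleConfig(gamma=0.1, margin=0.0, tau=0.2)
        mca_cfg = mc.MCAConfig(gamma=0.1, tau=0.2, centers_per_class=bank.centers_per_class)
        st_val = mc.softtriple_loss(feats, bank, st_cfg, labels=labels)
        sm, reg = mc.softmax_agent_loss(feats, bank, mca_cfg, labels=labels)
        assert abs(st_val - (sm + 0.2 * reg)) < 1e-9

    def test_two_class_symmetric_scalar_value(self):
        feats = mc.normalize_rows(np.array([[1.0, 1.0]]))
        bank = mc.CenterBank(np.array([[[1.0, 0.0]], [[0.0, 1.0]]]))
        cfg = mc.SoftTripleConfig(lam=24.0, margin=0.01, tau=0.0, centers_per_class=1)
        val = mc.softtriple_loss(feats, bank, cfg, labels=np.array([0]))
        assert abs(val - np.log(1 + np.exp(24 * 0.01))) < 1e-9

    def test_permutation_invariance(self, small_state):
        feats, labels, bank = small_state
        cfg = mc.SoftTripleConfig(centers_per_class=bank.centers_per_class)
        v1 = mc.softtriple_loss(feats, bank, cfg, labels=labels)
        perm = np.array([1, 3, 0, 2])
        bank2 = mc.CenterBank(bank.normalized()[perm])
        v2 = mc.softtriple_loss(feats, bank2, cfg, labels=np.argsort(perm)[labels])
        assert abs(v1 - v2) < 1e-9
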