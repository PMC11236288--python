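"""Hand-evaluated loss values, zero configurations, and gradient checks.

Expected numbers follow directly from the loss definitions: per-set
cross-entropies divide by the number of cells only (summing over sets),
the separation hinge counts ordered prototype pairs, and the labeled
cell-to-prototype pull takes no minimum.
"""

import numpy as np
import pytest

from protogsea._autograd import Tensor
from protogsea.losses import (LossWeights, build_assignments, combined_loss,
                              loss_c2p, loss_c2p_labeled, loss_clf,
                              loss_final, loss_p2c, loss_p2p,
                              loss_p2p_labeled)
from protogsea.network import EncoderSpec, PrototypeNetwork

LN2 = np.log(2.0)


def make_net(T=1, C=2, B=1, z_dim=2, seed=0):
    rng = np.random.default_rng(seed)
    masks = np.ones((T, 4))
    spec = EncoderSpec(input_dim=4, hidden_layers=[3], h_dim=3, z_dim=z_dim)
    return PrototypeNetwork(masks, C, spec, B=B, seed=seed)


class TestClassificationLosses:
    def test_one_hot_correct_is_zero(self):
        post = np.zeros((3, 2, 2))
        post[:, :, 0] = 1.0
        assert loss_clf(Tensor(post), np.ones(3, int)).item() == \
            pytest.approx(0.0, abs=1e-10)

    def test_uniform_posterior_single_set(self):
        post = np.full((1, 1, 2), 0.5)
        assert loss_clf(Tensor(post), np.array([1])).item() == \
            pytest.approx(LN2, rel=1e-12)

    def test_sums_over_sets_divides_by_n_only(self):
        # n=1, T=2, uniform posteriors: loss = 2 ln 2
        post = np.full((1, 2, 2), 0.5)
        assert loss_clf(Tensor(post), np.array([1])).item() == \
            pytest.approx(2 * LN2, rel=1e-12)

    def test_final_uniform_two_class(self):
        y_hat = np.full((4, 2), 0.5)
        assert loss_final(Tensor(y_hat), np.ones(4, int)).item() == \
            pytest.approx(LN2, rel=1e-12)

    def test_final_hand_value(self):
        y_hat = np.array([[0.9, 0.1], [0.2, 0.8]])
        got = loss_final(Tensor(y_hat), np.array([1, 2])).item()
        assert got == pytest.approx(-(np.log(0.9) + np.log(0.8)) / 2,
                                    rel=1e-12)

    def test_final_zero_iff_confident_correct(self):
        y_hat = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert loss_final(Tensor(y_hat), np.array([1, 2])).item() == \
            pytest.approx(0.0, abs=1e-10)


class TestPrototypeSeparation:
    def test_single_prototype_is_exactly_zero(self):
        net = make_net(B=1)
        assert loss_p2p(net).item() == 0.0

    def test_coincident_pair_hand_value(self):
        # B=2, prototypes coincide, d_min=1, T=C=1:
        # two ordered pairs, each hinge 1 -> 2 / (1*1*4) = 0.5
        net = make_net(T=1, C=1, B=2)
        net.centers.data[:] = 0.0
        assert loss_p2p(net).item() == pytest.approx(0.5, rel=1e-9)

    def test_separated_pair_is_zero(self):
        net = make_net(T=1, C=1, B=2)
        net.centers.data[0, 0, 0] = [0.0, 0.0]
        net.centers.data[0, 0, 1] = [2.0, 0.0]
        assert loss_p2p(net).item() == 0.0


class TestCellToPrototype:
    def test_cells_at_prototypes_zero(self):
        net = make_net(T=1, C=2, B=1)
        net.centers.data[0, 0, 0] = [1.0, 0.0]
        net.centers.data[0, 1, 0] = [0.0, 1.0]
        z = Tensor(np.array([[[1.0, 0.0]], [[0.0, 1.0]]]))
        assert loss_c2p(z, net, np.array([1, 2])).item() == \
            pytest.approx(0.0, abs=1e-12)

    def test_squared_distance(self):
        net = make_net(T=1, C=1, B=1)
        net.centers.data[:] = 0.0
        z = Tensor(np.array([[[2.0, 0.0]]]))
        assert loss_c2p(z, net, np.array([1])).item() == \
            pytest.approx(4.0, rel=1e-12)

    def test_min_over_prototypes(self):
        net = make_net(T=1, C=1, B=2)
        net.centers.data[0, 0, 0] = [1.0, 0.0]   # distance 1
        net.centers.data[0, 0, 1] = [3.0, 0.0]   # distance 3
        z = Tensor(np.zeros((1, 1, 2)))
        assert loss_c2p(z, net, np.array([1])).item() == \
            pytest.approx(1.0, rel=1e-12)

    def test_labeled_variant_takes_no_min(self):
        net = make_net(T=1, C=1, B=2)
        net.centers.data[0, 0, 0] = [3.0, 0.0]   # the (y,q) prototype
        net.centers.data[0, 0, 1] = [0.5, 0.0]   # nearer, but not q's
        z = Tensor(np.zeros((1, 1, 2)))
        got = loss_c2p_labeled(z, net, np.array([1]), np.array([1])).item()
        assert got == pytest.approx(9.0, rel=1e-12)

    def test_labeled_hand_value_two_cells(self):
        net = make_net(T=1, C=1, B=2)
        net.centers.data[0, 0, 0] = [0.0, 0.0]
        net.centers.data[0, 0, 1] = [0.0, 0.0]
        z = Tensor(np.array([[[1.0, 0.0]], [[2.0, 0.0]]]))
        got = loss_c2p_labeled(z, net, np.array([1, 1]),
                               np.array([1, 2])).item()
        assert got == pytest.approx(2.5, rel=1e-12)   # (1 + 4) / 2


class TestPrototypeToCenter:
    def test_prototype_at_centroid_zero(self):
        net = make_net(T=1, C=1, B=1)
        net.centers.data[0, 0, 0] = [0.0, 0.0]
        z = Tensor(np.array([[[1.0, 0.0]], [[-1.0, 0.0]]]))
        w = np.ones((2, 1, 1, 1))
        assert loss_p2c(z, net, w).item() == pytest.approx(0.0, abs=1e-12)

    def test_offset_prototype_hand_value(self):
        net = make_net(T=1, C=1, B=1)
        net.centers.data[0, 0, 0] = [1.0, 0.0]
        z = Tensor(np.array([[[1.0, 0.0]], [[-1.0, 0.0]]]))
        w = np.ones((2, 1, 1, 1))
        assert loss_p2c(z, net, w).item() == pytest.approx(1.0, rel=1e-9)

    def test_empty_assignment_contributes_nothing(self):
        net = make_net(T=1, C=2, B=1)
        net.centers.data[:] = 3.0
        z = Tensor(np.array([[[0.0, 0.0]]]))
        w = np.zeros((1, 1, 2, 1))
        w[0, 0, 0, 0] = 1.0   # class 2's set empty
        got_empty = loss_p2c(z, net, np.zeros((1, 1, 2, 1))).item()
        assert got_empty == pytest.approx(0.0, abs=1e-10)


class TestLabeledAssignmentLoss:
    def test_one_hot_assignment_zero(self):
        u = np.zeros((2, 1, 2))
        u[:, :, 0] = 1.0
        assert loss_p2p_labeled(Tensor(u), np.ones(2, int)).item() == \
            pytest.approx(0.0, abs=1e-10)

    def test_uniform_assignment(self):
        u = np.full((1, 1, 2), 0.5)
        assert loss_p2p_labeled(Tensor(u), np.array([1])).item() == \
            pytest.approx(LN2, rel=1e-12)

    def test_sums_over_sets(self):
        u = np.full((1, 2, 4), 0.25)
        assert loss_p2p_labeled(Tensor(u), np.array([1])).item() == \
            pytest.approx(2 * np.log(4.0), rel=1e-12)


class TestAssignmentSets:
    def test_unlabeled_partition_within_phenotype(self):
        net = make_net(T=2, C=2, B=3)
        rng = np.random.default_rng(0)
        z = rng.normal(size=(20, 2, 2))
        y = rng.integers(1, 3, size=20)
        w = build_assignments(z, net, y)
        # every cell lands in exactly one (k, l) cell of its own phenotype
        assert np.all(w.sum(axis=(2, 3)) == 1.0)
        own = w[np.arange(20), :, y - 1, :]
        assert np.all(own.sum(axis=-1) == 1.0)

    def test_labeled_partition_is_by_y_q(self):
        net = make_net(T=1, C=2, B=2)
        y = np.array([1, 1, 2, 2])
        q = np.array([1, 2, 1, 2])
        w = build_assignments(np.zeros((4, 1, 2)), net, y, q)
        for i in range(4):
            assert w[i, 0, y[i] - 1, q[i] - 1] == 1.0
        assert w.sum() == 4.0


class TestCombined:
    def test_all_zero_weights(self):
        parts = {"clf": Tensor(3.0), "final": Tensor(2.0),
                 "p2p": Tensor(1.0), "c2p": Tensor(1.0), "p2c": Tensor(1.0)}
        w = LossWeights(clf=0, final=0, p2p=0, c2p=0, p2c=0)
        assert combined_loss(parts, w).item() == 0.0

    def test_stage1_drops_final_term(self):
        parts = {"clf": Tensor(1.0), "final": Tensor(100.0)}
        w = LossWeights(clf=1.0, final=7.0, p2p=0, c2p=0, p2c=0, stage=1)
        assert combined_loss(parts, w).item() == pytest.approx(1.0)
        w2 = LossWeights(clf=1.0, final=7.0, p2p=0, c2p=0, p2c=0, stage=2)
        assert combined_loss(parts, w2).item() == pytest.approx(701.0)

    def test_single_term_recovers_clf(self):
        parts = {"clf": Tensor(2.5), "p2p": Tensor(9.0)}
        w = LossWeights(clf=1.0, final=0, p2p=0, c2p=0, p2c=0)
        assert combined_loss(parts, w).item() == pytest.approx(2.5)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(clf=-1.0)


def _combined_loss_value(net, X, y, q, assign, labeled, weights):
    """Recompute the full stage-2 objective from current parameter data."""
    z = net.latent(X)
    log_s = net.log_similarity(z)
    s = log_s.exp()
    posteriors = log_s.log_softmax(axis=2).exp()
    parts = {"clf": loss_clf(posteriors, y),
             "final": loss_final(net.predict_proba_t(s), y)}
    if labeled:
        parts["p2p"] = loss_p2p_labeled(net.assignment(z), q)
        parts["c2p"] = loss_c2p_labeled(z, net, y, q)
    else:
        parts["p2p"] = loss_p2p(net)
        parts["c2p"] = loss_c2p(z, net, y)
    parts["p2c"] = loss_p2c(z, net, assign)
    return combined_loss(parts, weights)


@pytest.mark.parametrize("labeled", [False, True])
def test_analytic_gradients_match_finite_differences(labeled):
    """Gradients of the full objective agree with central differences."""
    net = make_net(T=2, C=2, B=2, z_dim=3, seed=4)
    rng = np.random.default_rng(11)
    X = rng.normal(size=(6, 4))
    y = np.array([1, 2, 1, 2, 1, 2])
    q = np.array([1, 1, 2, 2, 1, 2])
    net.centers.data[:] = rng.normal(size=net.centers.shape)
    weights = LossWeights(clf=1.0, final=1.0, p2p=0.3, c2p=0.2, p2c=0.4,
                          stage=2)
    assign = build_assignments(net.latent(X).data, net, y,
                               q if labeled else None)
    loss = _combined_loss_value(net, X, y, q, assign, labeled, weights)
    for p in net.parameters():
        p.grad = None
    loss.backward()
    h = 1e-6
    for p in net.parameters():
        analytic = p.grad if p.grad is not None else np.zeros_like(p.data)
        flat = p.data.ravel()
        picks = rng.choice(flat.size, size=min(6, flat.size), replace=False)
        for i in picks:
            orig = flat[i]
            flat[i] = orig + h
            fp = _combined_loss_value(net, X, y, q, assign, labeled,
                                      weights).item()
            flat[i] = orig - h
            fm = _combined_loss_value(net, X, y, q, assign, labeled,
                                      weights).item()
            flat[i] = orig
            numeric = (fp - fm) / (2 * h)
            denom = max(abs(numeric), abs(analytic.ravel()[i]), 1e-3)
            assert abs(analytic.ravel()[i] - numeric) / denom < 1e-4, \
                f"param grad mismatch at {i}"
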