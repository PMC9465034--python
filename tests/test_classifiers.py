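"""Identification models: residual-network structure and identities,
training behavior, transfer updates, PSO-SVM and BPNN baselines."""

import numpy as np
import pytest

from pestwatch.classifiers import (BPNNConfig, PSOConfig, ResNetV2Spec,
                                   ResidualUnit, TrainConfig, bpnn_loss,
                                   build_resnet_v2, train_bpnn, train_pso_svm,
                                   train_resnet, transfer_update)
from pestwatch.classifiers.bpnn import _fit as bpnn_fit
from pestwatch.preprocess import split
from pestwatch.synthgen import ClassSpec, DEFAULT_CLASSES, make_insect_dataset

SMALL_SPEC = ResNetV2Spec(depth=8, widths=(8, 12, 16), n_classes=3)


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------

class TestArchitecture:
    def test_depth_56_unit_arithmetic(self):
        net = build_resnet_v2(ResNetV2Spec(depth=56), seed=0)
        assert len(net.units) == 27          # 9 per stage
        assert net.weighted_layers == 56     # stem + 54 unit convs + head

    def test_invalid_depth_reports_nearest_valid(self):
        with pytest.raises(ValueError, match="56"):
            ResNetV2Spec(depth=57).units_per_stage

    def test_identity_skip_only_inside_stages(self):
        net = build_resnet_v2(SMALL_SPEC, seed=0)
        proj_units = [i for i, u in enumerate(net.units)
                      if not u.identity_skip]
        assert proj_units == [1, 2]  # the two stage boundaries

    def test_zeroed_residual_branches_propagate_identity(self):
        """With F = 0 in every unit, an identity-skip stack is the identity:
        the deep activation equals the shallow one exactly."""
        rng = np.random.default_rng(0)
        units = [ResidualUnit(4, 4, 1, rng, dtype=np.float64)
                 for _ in range(3)]
        for u in units:
            u.conv2.W.v[...] = 0
        x = rng.normal(size=(2, 4, 6, 6))
        h = x
        for u in units:
            h = u.forward(h, train=False)
        np.testing.assert_allclose(h, x, atol=1e-12)

    def test_deep_activation_is_shallow_plus_branch_sum(self):
        """x_L = x_l + sum_i F(x_i, W_i) over identity-skip units."""
        rng = np.random.default_rng(1)
        units = [ResidualUnit(3, 3, 1, rng, dtype=np.float64)
                 for _ in range(2)]
        x0 = rng.normal(size=(2, 3, 5, 5))
        x1 = units[0].forward(x0, train=False)
        x2 = units[1].forward(x1, train=False)
        want = x0 + units[0].branch(x0) + units[1].branch(x1)
        np.testing.assert_allclose(x2, want, atol=1e-10)

    def test_backward_carries_additive_identity_term(self):
        """The gradient through a unit stack is R plus the gradient of the
        residual-branch sum: finite differences on a 2-unit network."""
        rng = np.random.default_rng(2)
        units = [ResidualUnit(2, 2, 1, rng, dtype=np.float64)
                 for _ in range(2)]
        x = rng.normal(size=(1, 2, 4, 4))
        R = rng.normal(size=x.shape)

        def forward(z):
            h = z
            for u in units:
                h = u.forward(h, train=True)
            return h

        out = forward(x)
        dy = R.copy()
        for u in reversed(units):
            dy = u.backward(dy)
        # numerical gradient of sum(stack(x) * R)
        eps = 1e-6
        num = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = x[i]
            x[i] = old + eps
            fp = float((forward(x) * R).sum())
            x[i] = old - eps
            fm = float((forward(x) * R).sum())
            x[i] = old
            num[i] = (fp - fm) / (2 * eps)
        np.testing.assert_allclose(dy, num, atol=1e-5)
        # the skip path contributes the identity term: dx - dF equals R,
        # where dF is the numerical gradient of the branch-sum path alone
        def branch_sum(z):
            h = z
            total = np.zeros_like(z)
            for u in units:
                f = u.branch(h, train=True)
                total = total + f
                h = h + f
            return total

        numF = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            old = x[i]
            x[i] = old + eps
            fp = float((branch_sum(x) * R).sum())
            x[i] = old - eps
            fm = float((branch_sum(x) * R).sum())
            x[i] = old
            numF[i] = (fp - fm) / (2 * eps)
        np.testing.assert_allclose(dy - numF, R, atol=1e-5)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_splits():
    ds = make_insect_dataset(DEFAULT_CLASSES[:3], n_per_class=12,
                             image_size=32, seed=21)
    return split(ds, (7, 1.5, 1.5), seed=21)


class TestTrainResnet:
    def test_history_bookkeeping_at_smoke_scale(self, tiny_splits):
        tr, va, te = tiny_splits
        model = train_resnet(tr, va, spec=SMALL_SPEC,
                             tc=TrainConfig(epochs=3), seed=0)
        assert len(model.history) == 3
        assert all(np.isfinite(h["train_loss"]) for h in model.history)
        assert 0 <= model.best_epoch < 3

    def test_training_is_seed_deterministic(self, tiny_splits):
        tr, va, _ = tiny_splits
        a = train_resnet(tr, va, spec=SMALL_SPEC,
                         tc=TrainConfig(epochs=2), seed=5)
        b = train_resnet(tr, va, spec=SMALL_SPEC,
                         tc=TrainConfig(epochs=2), seed=5)
        assert a.history == b.history

    def test_empty_split_rejected(self, tiny_splits):
        tr, va, _ = tiny_splits
        empty = tr.subset(np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty"):
            train_resnet(empty, va)


def _shifted_field_dataset(n_per_class, seed):
    """Same three species with shifted color statistics plus the
    non-target class — a stand-in for new field conditions."""
    shifted = [ClassSpec(c.class_name,
                         tuple(np.add(c.body_color_mean, (10, -8, 6))),
                         c.body_color_sigma, c.texture_period,
                         c.shape_elongation, c.size_px, c.distorted)
               for c in DEFAULT_CLASSES]
    return make_insect_dataset(shifted, n_per_class=n_per_class,
                               image_size=32, seed=seed)


@pytest.fixture(scope="module")
def base_model():
    ds = make_insect_dataset(DEFAULT_CLASSES[:3], n_per_class=40,
                             image_size=32, seed=31)
    tr, va, _ = split(ds, (7, 1.5, 1.5), seed=31)
    return train_resnet(tr, va, spec=SMALL_SPEC,
                        tc=TrainConfig(epochs=25,
                                       stop_at_zero_val_error=True),
                        seed=31)


class TestTransferUpdate:

    def test_head_replaced_convs_copied_at_step_zero(self, base_model):
        field = _shifted_field_dataset(10, seed=32)
        tr, va, _ = split(field, (6, 2, 2), seed=32)
        updated = transfer_update(base_model, tr, va, n_classes_new=4,
                                  tc=TrainConfig(epochs=0), seed=32)
        assert updated.network.head.W.v.shape[1] == 4
        assert (updated.network.head.W.v == 0).all()
        for s, d in zip(base_model.network.stem.params(),
                        updated.network.stem.params()):
            assert (s.v == d.v).all()
        for us, ud in zip(base_model.network.units, updated.network.units):
            assert (us.conv1.W.v == ud.conv1.W.v).all()
            assert (us.conv2.W.v == ud.conv2.W.v).all()

    def test_class_count_mismatch_rejected(self, base_model):
        field = _shifted_field_dataset(10, seed=33)
        tr, va, _ = split(field, (6, 2, 2), seed=33)
        with pytest.raises(ValueError):
            transfer_update(base_model, tr, va, n_classes_new=3)

    def test_transfer_reaches_target_accuracy_in_fewer_epochs(self,
                                                              base_model):
        """Warm-started updates should hit a validation-accuracy target in
        fewer epochs than training from scratch (median over 5 seeds)."""
        max_epochs, target = 6, 0.6

        def epochs_to_target(model):
            for h in model.history:
                if h["val_accuracy"] >= target:
                    return h["epoch"] + 1
            return max_epochs + 1

        t_epochs, s_epochs = [], []
        for seed in range(5):
            field = _shifted_field_dataset(10, seed=40 + seed)
            tr, va, _ = split(field, (6, 2, 2), seed=40 + seed)
            tc = TrainConfig(epochs=max_epochs)
            t = transfer_update(base_model, tr, va, n_classes_new=4, tc=tc,
                                seed=40 + seed)
            s = train_resnet(tr, va,
                             spec=ResNetV2Spec(depth=8, widths=(8, 12, 16),
                                               n_classes=4),
                             tc=tc, seed=40 + seed)
            t_epochs.append(epochs_to_target(t))
            s_epochs.append(epochs_to_target(s))
        assert np.median(t_epochs) < np.median(s_epochs)


# ---------------------------------------------------------------------------
# PSO-SVM
# ---------------------------------------------------------------------------

def _blobs(n=30, sep=8.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.concatenate([rng.normal(0, 1, (n, 2)),
                        rng.normal(sep, 1, (n, 2))])
    y = np.repeat([0, 1], n)
    return X, y


class TestPsoSvm:
    def test_separable_blobs_reach_perfect_cv_fitness(self):
        X, y = _blobs()
        res = train_pso_svm(X, y, PSOConfig(swarm_size=8, iterations=5),
                            seed=0)
        assert res.fitness == 1.0
        assert (res.model.predict(X) == y).all()

    def test_trace_is_nondecreasing(self):
        X, y = _blobs(sep=2.0, seed=1)
        res = train_pso_svm(X, y, PSOConfig(swarm_size=6, iterations=8),
                            seed=1)
        assert (np.diff(res.trace) >= 0).all()

    def test_optimum_within_search_ranges(self):
        X, y = _blobs(seed=2)
        cfg = PSOConfig(swarm_size=5, iterations=3)
        res = train_pso_svm(X, y, cfg, seed=2)
        assert cfg.gamma_range[0] <= res.gamma <= cfg.gamma_range[1]
        assert cfg.C_range[0] <= res.C <= cfg.C_range[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            train_pso_svm(np.ones((10, 2)), np.zeros(10))

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_pso_svm(np.ones((10, 0)), np.repeat([0, 1], 5))


# ---------------------------------------------------------------------------
# BPNN
# ---------------------------------------------------------------------------

def _xor_data(n=50, seed=0):
    rng = np.random.default_rng(seed)
    centers = [(0, 0, 0), (3, 3, 0), (0, 3, 1), (3, 0, 1)]
    X, y = [], []
    for cx, cy, label in centers:
        X.append(rng.normal([cx, cy], 0.4, size=(n, 2)))
        y += [label] * n
    return np.concatenate(X), np.array(y)


class TestBpnn:
    def test_xor_style_data_learned_with_three_hidden_nodes(self):
        X, y = _xor_data()
        cfg = BPNNConfig(n_input=2, n_hidden=3, n_output=2, lr=1.0,
                         decay_rate=0.9, decay_steps=5000, l2=1e-5,
                         epochs=1500, batch_size=8, cv_folds=2)
        res = train_bpnn(X, y, cfg, seed=1)
        assert (res.model.predict(X) == y).mean() > 0.9

    def test_feature_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="expects"):
            train_bpnn(np.ones((20, 5)), np.repeat([0, 1], 10),
                       BPNNConfig(n_input=11))

    def test_l2_penalty_never_lowers_the_loss(self):
        X, y = _xor_data(n=10, seed=3)
        cfg = BPNNConfig(n_input=2, n_hidden=3, n_output=2, epochs=5,
                         cv_folds=2)
        model = bpnn_fit(X, y, cfg, np.random.default_rng(0))
        assert bpnn_loss(model, X, y, l2=1e-3) >= bpnn_loss(model, X, y, l2=0)

    def test_init_std_follows_configured_convention(self):
        assert BPNNConfig(n_input=16).init_std() == pytest.approx(1 / 16)
        assert BPNNConfig(n_input=16, init="sqrt").init_std() \
            == pytest.approx(0.25)

    def test_cross_validation_reports_per_fold_accuracy(self):
        X, y = _xor_data(n=20, seed=4)
        cfg = BPNNConfig(n_input=2, n_hidden=3, n_output=2, epochs=50,
                         cv_folds=4)
        res = train_bpnn(X, y, cfg, seed=2)
        assert len(res.fold_accuracies) == 4
        assert res.cv_accuracy == pytest.approx(res.fold_accuracies.mean())
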