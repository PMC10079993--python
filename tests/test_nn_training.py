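"""Optimizer algebra, loss closed forms, fold assignment, training loop."""

import numpy as np
import pytest

from plinet.containers import ValidationError
from plinet.nn import (ArchitectureSpec, ClassifiedDataset, TrainConfig,
                       assign_folds, evaluation_report, nll_loss, train)
from plinet.nn.layers import Layer
from plinet.nn.model import Sequential
from plinet.nn.optim import Adam


class ParamHolder(Layer):
    """Bare parameter container for optimizer unit tests."""

    name = "holder"

    def __init__(self, value, decay=False):
        super().__init__()
        self.params["w"] = np.asarray(value, dtype=np.float64)
        if decay:
            self.decay.add("w")


def holder_model(value, decay=False):
    holder = ParamHolder(value, decay)
    model = Sequential([holder], spec=None)
    return model, holder


class TestAdam:
    def test_zero_gradient_no_decay_leaves_parameters(self):
        model, h = holder_model([1.0, -2.0, 3.0])
        opt = Adam(model, TrainConfig(weight_decay=0.0))
        h.grads["w"] = np.zeros(3)
        opt.step()
        assert np.array_equal(h.params["w"], [1.0, -2.0, 3.0])

    def test_first_step_bias_correction_recovers_gradient(self):
        """After one step, m_hat equals the raw gradient exactly."""
        model, h = holder_model([0.0])
        cfg = TrainConfig(weight_decay=0.0, learning_rate=0.01)
        opt = Adam(model, cfg)
        g = np.array([0.37])
        h.grads["w"] = g.copy()
        opt.step()
        m_hat = opt.m[(0, "w")] / (1 - cfg.beta1)
        v_hat = opt.v[(0, "w")] / (1 - cfg.beta2)
        assert m_hat == pytest.approx(g)
        expected = -cfg.learning_rate * m_hat / (np.sqrt(v_hat) + cfg.eps)
        assert h.params["w"] == pytest.approx(expected)

    def test_quadratic_convergence(self):
        """100 steps on f(w) = w^2 reduce the loss below 1e-3 of start."""
        model, h = holder_model([1.0])
        opt = Adam(model, TrainConfig(weight_decay=0.0, learning_rate=0.05))
        losses = []
        for _ in range(100):
            w = h.params["w"]
            losses.append(float(w[0] ** 2))
            h.grads["w"] = 2 * w
            opt.step()
        assert losses[-1] < 1e-3 * losses[0]
        # monotone while far from the optimum
        assert all(b < a for a, b in zip(losses[:15], losses[1:16]))

    def test_decoupled_decay_shrinks_weights(self):
        model, h = holder_model([10.0], decay=True)
        cfg = TrainConfig(weight_decay=0.2, learning_rate=0.01)
        opt = Adam(model, cfg)
        h.grads["w"] = np.zeros(1)
        opt.step()
        # pure decay: w <- (1 - alpha*lambda) * w
        assert h.params["w"][0] == pytest.approx(10.0 * (1 - 0.01 * 0.2))

    def test_nonfinite_gradient_is_named(self):
        model, h = holder_model([1.0])
        opt = Adam(model, TrainConfig())
        h.grads["w"] = np.array([np.nan])
        with pytest.raises(FloatingPointError, match="holder.w"):
            opt.step()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            TrainConfig(beta1=1.0)
        with pytest.raises(ValidationError):
            TrainConfig(learning_rate=0.0)


class TestNllLoss:
    def test_perfect_prediction_is_zero(self):
        logp = np.log(np.array([[1.0 - 2e-16, 1e-16, 1e-16]]))
        loss, _ = nll_loss(logp, np.array([0]))
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_uniform_prediction_is_ln3(self):
        logp = np.full((4, 3), np.log(1 / 3))
        loss, _ = nll_loss(logp, np.array([0, 1, 2, 1]))
        assert loss == pytest.approx(np.log(3))

    def test_weighted_batch_matches_hand_computation(self):
        # two samples, classes 0 and 1, weights (1, 2, 1):
        # L = (1*0.5 + 2*1.0) / (1 + 2)
        logp = np.array([[-0.5, -2.0, -3.0], [-2.0, -1.0, -3.0]])
        loss, grad = nll_loss(logp, np.array([0, 1]), np.array([1.0, 2.0, 1.0]))
        assert loss == pytest.approx((1 * 0.5 + 2 * 1.0) / 3)
        assert grad[0, 0] == pytest.approx(-1 / 3)
        assert grad[1, 1] == pytest.approx(-2 / 3)
        assert grad[0, 1] == grad[1, 0] == 0.0

    def test_label_out_of_range(self):
        with pytest.raises(ValidationError):
            nll_loss(np.zeros((2, 3)), np.array([0, 3]))


class TestFoldAssignment:
    def test_divisible_case_one_per_group_per_fold(self):
        subjects = {f"{g}{i}": g for g in "abc" for i in range(10)}
        fa = assign_folds(subjects, k=10, seed=0)
        for fold in range(10):
            members = [s for s, f in fa.fold_of.items() if f == fold]
            assert len(members) == 3
            assert {subjects[s] for s in members} == {"a", "b", "c"}

    def test_uneven_cohort_group_counts_differ_by_at_most_one(self):
        sizes = {"a": 23, "b": 22, "c": 22}
        subjects = {f"{g}{i}": g for g, n in sizes.items() for i in range(n)}
        fa = assign_folds(subjects, k=10, seed=3)
        for g in sizes:
            per_fold = [sum(1 for s, f in fa.fold_of.items()
                            if f == fold and subjects[s] == g)
                        for fold in range(10)]
            assert max(per_fold) - min(per_fold) <= 1

    def test_split_partitions_subjects(self):
        subjects = {f"s{i}": "abc"[i % 3] for i in range(30)}
        fa = assign_folds(subjects, k=10, seed=1)
        train_s, val_s, test_s = fa.split(4)
        assert not (set(train_s) & set(val_s))
        assert not (set(train_s) & set(test_s))
        assert not (set(val_s) & set(test_s))
        assert len(train_s) + len(val_s) + len(test_s) == 30
        # 1:2:7 fold ratio
        assert len({fa.fold_of[s] for s in test_s}) == 1
        assert len({fa.fold_of[s] for s in val_s}) == 2

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValidationError):
            assign_folds({"a": "x", "b": "y"}, k=10, seed=0)

    def test_deterministic_per_seed(self):
        subjects = {f"s{i}": "abc"[i % 3] for i in range(30)}
        assert (assign_folds(subjects, 10, seed=5).fold_of
                == assign_folds(subjects, 10, seed=5).fold_of)


def toy_arch():
    return ArchitectureSpec(variant="pli", n_channels=6, input_width=6,
                            temporal_kernel=5, separable_kernel=4,
                            pool1_width=2)


def toy_dataset(rng, n_subjects=12, trials=4):
    """Tiny 3-class dataset with class-dependent mean patterns."""
    X, y, owners = [], [], []
    for i in range(n_subjects):
        label = i % 3
        base = np.zeros((6, 6))
        base[label, :] = 2.0
        for _ in range(trials):
            X.append(base + 0.3 * rng.normal(size=(6, 6)))
            y.append(label)
            owners.append(f"s{i}")
    return ClassifiedDataset(np.asarray(X)[:, None], np.array(y),
                             np.array(owners), ("g0", "g1", "g2"))


class TestTrainLoop:
    def test_curve_bookkeeping_two_epochs(self, rng):
        ds = toy_dataset(rng)
        folds = assign_folds(ds.subject_groups, k=4, seed=0)
        res = train(ds, folds, toy_arch(),
                    TrainConfig(epochs=2, batch_size=8, seed=0), test_fold=0)
        assert len(res.curves) == 2
        assert {"train_loss", "val_loss", "train_accuracy",
                "val_accuracy"} <= set(res.curves.columns)

    def test_bitwise_reproducibility(self, rng):
        ds = toy_dataset(rng)
        folds = assign_folds(ds.subject_groups, k=4, seed=0)
        cfg = TrainConfig(epochs=3, batch_size=8, seed=11)
        r1 = train(ds, folds, toy_arch(), cfg, test_fold=1)
        r2 = train(ds, folds, toy_arch(), cfg, test_fold=1)
        for s1, s2 in zip(r1.model.get_state(), r2.model.get_state()):
            for k in s1:
                assert np.array_equal(s1[k], s2[k]), k
        assert r1.curves.equals(r2.curves)

    def test_subject_exclusivity_enforced(self, rng):
        ds = toy_dataset(rng)
        folds = assign_folds(ds.subject_groups, k=4, seed=0)
        folds.fold_of[list(folds.fold_of)[0]] = 0  # still a valid partition
        train_s, val_s, test_s = folds.split(0)
        assert not (set(train_s) & set(test_s))


class TestEvaluate:
    def test_perfect_predictions(self):
        rep = evaluation_report([0, 1, 2, 0], [0, 1, 2, 0], 3)
        assert rep.accuracy == 1.0 and rep.macro_f1 == 1.0

    def test_hand_worked_confusion_matrix(self):
        # confusion [[2,1,0],[0,3,0],[1,0,3]]
        y_true = [0, 0, 0, 1, 1, 1, 2, 2, 2, 2]
        y_pred = [0, 0, 1, 1, 1, 1, 0, 2, 2, 2]
        rep = evaluation_report(y_true, y_pred, 3)
        assert rep.confusion.tolist() == [[2, 1, 0], [0, 3, 0], [1, 0, 3]]
        # per class: P0=2/3, R0=2/3 -> F1=2/3; P1=3/4, R1=1 -> F1=6/7;
        # P2=1, R2=3/4 -> F1=6/7
        assert rep.f1[0] == pytest.approx(2 / 3)
        assert rep.f1[1] == pytest.approx(6 / 7)
        assert rep.f1[2] == pytest.approx(6 / 7)
        assert rep.macro_f1 == pytest.approx((2 / 3 + 6 / 7 + 6 / 7) / 3)

    def test_single_class_predictions_on_balanced_data(self):
        rep = evaluation_report([0, 1, 2] * 4, [1] * 12, 3)
        assert rep.accuracy == pytest.approx(1 / 3)

    def test_absent_class_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="class 2"):
            rep = evaluation_report([0, 1, 0, 1], [0, 1, 1, 1], 3)
        assert set(rep.f1) == {0, 1}
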