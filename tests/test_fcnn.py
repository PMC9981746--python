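"""The classifier: forward/cost/gradient oracles, training recipe, splits."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fusdecode.fcnn import (
    FCNNModel,
    TrainConfig,
    cost,
    forward,
    gradients,
    init_model,
    kfold,
    load_model,
    make_split,
    onehot,
    predict,
    save_model,
    train,
    uncertainty_from_probs,
)
from fusdecode.preprocess import FeatureDataset


# ---------------------------------------------------------------------------
# independent naive-loop oracles (kept deliberately dumb)


def naive_forward(model, X):
    out = np.zeros((len(X), model.C))
    for i, x in enumerate(X):
        h = []
        for j in range(model.hidden):
            z = model.b1[j]
            for d in range(model.D):
                z += x[d] * model.W1[d, j]
            h.append(max(z, 0.0))
        logits = []
        for c in range(model.C):
            z = model.b2[c]
            for j in range(model.hidden):
                z += h[j] * model.W2[j, c]
            logits.append(z)
        mx = max(logits)
        exps = [np.exp(z - mx) for z in logits]
        s = sum(exps)
        out[i] = [e / s for e in exps]
    return out


def naive_cost(model, X, Y, lam):
    P = naive_forward(model, X)
    total = 0.0
    for i in range(len(X)):
        for c in range(model.C):
            total += (P[i, c] - Y[i, c]) ** 2
    reg = 0.0
    for W in (model.W1, model.W2):
        for v in np.ravel(W):
            reg += v * v
    return (total + lam * reg) / (2.0 * len(X))


def random_model(rng, D, C, hidden=3):
    m = init_model(D, C, seed=int(rng.integers(2**31)), hidden=hidden)
    m.b1 = rng.normal(size=hidden)
    m.b2 = rng.normal(size=C)
    return m


def make_ds(X, y):
    return FeatureDataset(
        X=np.asarray(X, dtype=float),
        feature_ids=[f"f{i}" for i in range(np.asarray(X).shape[1])],
        y=np.asarray(y, dtype=object),
        frame_index=np.arange(len(y)),
    )


class TestInit:
    def test_seed_reproducible_and_biases_zero(self):
        a = init_model(8, 4, seed=3)
        b = init_model(8, 4, seed=3)
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.W2, b.W2)
        assert np.all(a.b1 == 0.0) and np.all(a.b2 == 0.0)

    def test_weight_mean_near_zero(self):
        m = init_model(500, 4, seed=0)
        r = np.sqrt(6.0 / (500 + 3))
        se = r / np.sqrt(3.0) / np.sqrt(m.W1.size)  # SD of Uniform(-r, r) mean
        assert abs(m.W1.mean()) < 3 * se


class TestForward:
    def test_zero_weight_model_uniform_output(self):
        for C in (2, 4):
            m = FCNNModel(
                W1=np.zeros((5, 3)), b1=np.zeros(3),
                W2=np.zeros((3, C)), b2=np.zeros(C),
                class_names=[str(i) for i in range(C)],
            )
            P = forward(m, np.random.default_rng(0).normal(size=(7, 5)))
            assert np.array_equal(P, np.full((7, C), 1.0 / C))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        m = random_model(rng, 6, 4)
        P = forward(m, rng.normal(size=(20, 6)))
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_hand_evaluated_single_feature_model(self):
        m = FCNNModel(
            W1=np.array([[1.0, 0.0, 0.0]]), b1=np.zeros(3),
            W2=np.array([[2.0, -1.0], [0.0, 0.0], [0.0, 0.0]]), b2=np.zeros(2),
            class_names=["a", "b"],
        )
        # x=1: h=(1,0,0); logits=(2,-1); softmax by hand
        e = np.exp([2.0, -1.0])
        assert np.allclose(forward(m, [[1.0]]), e / e.sum(), atol=1e-15)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            D, C = int(rng.integers(1, 8)), int(rng.choice([2, 4]))
            m = random_model(rng, D, C)
            X = rng.normal(size=(6, D))
            assert np.allclose(forward(m, X), naive_forward(m, X), atol=1e-12)

    def test_nonfinite_input_rejected(self):
        m = init_model(3, 2, seed=0)
        with pytest.raises(ValueError):
            forward(m, np.array([[1.0, np.nan, 0.0]]))


class TestCost:
    def test_saturated_softmax_zero_cost(self):
        # logits so far apart that the softmax is exactly one-hot in floats
        m = FCNNModel(
            W1=np.zeros((2, 3)), b1=np.zeros(3),
            W2=np.zeros((3, 2)), b2=np.array([800.0, 0.0]),
            class_names=["a", "b"],
        )
        X = np.ones((3, 2))
        Y = np.tile([1.0, 0.0], (3, 1))
        assert cost(m, X, Y, lam=0.0) == 0.0

    def test_uniform_output_arithmetic(self):
        m = FCNNModel(
            W1=np.zeros((2, 3)), b1=np.zeros(3),
            W2=np.zeros((3, 2)), b2=np.zeros(2),
            class_names=["a", "b"],
        )
        J = cost(m, np.ones((1, 2)), np.array([[1.0, 0.0]]), lam=0.0)
        assert np.isclose(J, 0.25, atol=1e-15)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(3)
        for lam in (0.0, 0.3):
            m = random_model(rng, 5, 4)
            X = rng.normal(size=(9, 5))
            Y = onehot(rng.choice(["0", "1", "2", "3"], 9), m.class_names)
            assert abs(cost(m, X, Y, lam) - naive_cost(m, X, Y, lam)) < 1e-12

    def test_shape_mismatch_rejected(self):
        m = init_model(3, 2, seed=0)
        with pytest.raises(ValueError):
            cost(m, np.ones((2, 3)), np.ones((3, 2)))


class TestGradients:
    def test_zero_residual_is_stationary(self):
        m = FCNNModel(
            W1=np.zeros((2, 3)), b1=np.zeros(3),
            W2=np.zeros((3, 2)), b2=np.array([800.0, 0.0]),
            class_names=["a", "b"],
        )
        g = gradients(m, np.ones((3, 2)), np.tile([1.0, 0.0], (3, 1)), lam=0.0)
        assert all(np.all(v == 0.0) for v in g.values())

    @pytest.mark.parametrize("C", [2, 4])
    def test_matches_central_finite_differences(self, C):
        rng = np.random.default_rng(C)
        h = 1e-6
        for rep in range(10):
            D = int(rng.integers(1, 11))
            m = random_model(rng, D, C)
            X = rng.normal(size=(5, D))
            Y = onehot(rng.choice([str(i) for i in range(C)], 5), m.class_names)
            lam = float(rng.choice([0.0, 0.1]))
            g = gradients(m, X, Y, lam)
            for name in ("W1", "b1", "W2", "b2"):
                arr = getattr(m, name)
                flat = arr.ravel()
                for k in range(flat.size):
                    orig = flat[k]
                    flat[k] = orig + h
                    jp = cost(m, X, Y, lam)
                    flat[k] = orig - h
                    jm = cost(m, X, Y, lam)
                    flat[k] = orig
                    fd = (jp - jm) / (2 * h)
                    ga = g[name].ravel()[k]
                    assert abs(ga - fd) <= 1e-5 * max(abs(ga), abs(fd)) + 1e-8

    def test_regularization_adds_lambda_theta_over_m(self):
        rng = np.random.default_rng(9)
        m = random_model(rng, 4, 2)
        X = rng.normal(size=(6, 4))
        Y = onehot(rng.choice(["0", "1"], 6), m.class_names)
        g0 = gradients(m, X, Y, lam=0.0)
        g1 = gradients(m, X, Y, lam=0.7)
        assert np.allclose(g1["W1"] - g0["W1"], 0.7 * m.W1 / 6, atol=1e-14)
        assert np.allclose(g1["W2"] - g0["W2"], 0.7 * m.W2 / 6, atol=1e-14)
        assert np.allclose(g1["b1"], g0["b1"])  # biases unregularized


def separable_dataset(n=120, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["a", "b"] * (n // 2), dtype=object)
    X = np.where(y[:, None] == "a", 0.8, -0.8) + rng.normal(0, 0.05, (n, 2))
    return make_ds(np.clip(X, -1, 1), y)


class TestTraining:
    def test_zero_learning_rate_is_identity(self):
        ds = separable_dataset()
        m0 = init_model(2, 2, seed=0, class_names=["a", "b"])
        m, hist = train(m0, ds, ds, TrainConfig(alpha0=0.0, max_epochs=3, seed=0))
        assert np.array_equal(m.W1, m0.W1) and np.array_equal(m.W2, m0.W2)

    def test_converges_and_early_stops_on_separable_data(self):
        ds = separable_dataset()
        m0 = init_model(2, 2, seed=1, class_names=["a", "b"])
        cfg = TrainConfig(alpha0=0.5, minibatch=6, max_epochs=2000, seed=1)
        m, hist = train(m0, ds, ds, cfg)
        assert hist["val_acc"].iloc[-1] == 1.0
        assert len(hist) < cfg.max_epochs  # early stopping fired

    def test_learning_rate_follows_harmonic_decay(self):
        ds = separable_dataset(n=20)
        m0 = init_model(2, 2, seed=0, class_names=["a", "b"])
        _, hist = train(m0, ds, ds, TrainConfig(alpha0=0.1, max_epochs=4, seed=0,
                                                early_stop_epochs=1000))
        assert np.allclose(hist["alpha"], [0.1 / (1 + ep) for ep in (1, 2, 3, 4)])

    def test_full_batch_descent_is_monotone(self):
        ds = separable_dataset(n=60)
        m0 = init_model(2, 2, seed=2, class_names=["a", "b"])
        cfg = TrainConfig(alpha0=0.01, minibatch=60, max_epochs=60, seed=2,
                          early_stop_epochs=1000)
        _, hist = train(m0, ds, ds, cfg)
        diffs = np.diff(hist["train_cost"].to_numpy())
        assert np.all(diffs <= 1e-9)

    def test_training_is_bit_reproducible(self):
        ds = separable_dataset()
        cfg = TrainConfig(alpha0=0.2, max_epochs=20, seed=5)
        runs = []
        for _ in range(2):
            m0 = init_model(2, 2, seed=5, class_names=["a", "b"])
            m, _ = train(m0, ds, ds, cfg)
            runs.append(m)
        assert np.array_equal(runs[0].W1, runs[1].W1)
        assert np.array_equal(runs[0].W2, runs[1].W2)


class TestPredictionMetric:
    @pytest.mark.parametrize(
        "probs,expected",
        [
            ([1.0, 0.0, 0.0, 0.0], 0.0),
            ([0.25, 0.25, 0.25, 0.25], 1.0),
            ([0.7, 0.2, 0.06, 0.04], 0.5),
        ],
    )
    def test_uncertainty_formula(self, probs, expected):
        assert np.isclose(uncertainty_from_probs(np.array([probs]))[0], expected)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_uncertainty_bounded(self, seed):
        rng = np.random.default_rng(seed)
        logits = rng.normal(size=(10, 4)) * 5
        P = np.exp(logits)
        P /= P.sum(axis=1, keepdims=True)
        u = uncertainty_from_probs(P)
        assert np.all((u >= 0.0) & (u <= 1.0))

    def test_argmax_ties_break_low(self):
        m = FCNNModel(
            W1=np.zeros((1, 3)), b1=np.zeros(3),
            W2=np.zeros((3, 2)), b2=np.zeros(2), class_names=["a", "b"],
        )
        pred = predict(m, [[0.3]])
        assert pred.label[0] == "a"
        assert pred.uncertainty[0] == 1.0


class TestSplits:
    def balanced_ds(self, n=100):
        y = np.array(["a", "b"] * (n // 2), dtype=object)
        return make_ds(np.random.default_rng(0).normal(size=(n, 3)), y)

    def test_fractions_and_stratification(self):
        ds = self.balanced_ds(100)
        plan = make_split(ds, seed=0)
        assert len(plan.train) == 70 and len(plan.val) == 15 and len(plan.test) == 15
        for part in (plan.train, plan.val, plan.test):
            labs, counts = np.unique(ds.y[part].astype(str), return_counts=True)
            assert abs(counts[0] - counts[1]) <= 1

    def test_kfold_partitions_all_frames(self):
        ds = self.balanced_ds(100)
        plans = kfold(ds, k=5, seed=1)
        tests = np.concatenate([p.test for p in plans])
        assert sorted(tests.tolist()) == list(range(100))
        for p in plans:
            assert not (set(p.train) & set(p.val))
            assert not (set(p.train) | set(p.val)) & set(p.test)

    def test_kfold_class_ratios_near_global(self):
        ds = self.balanced_ds(100)
        for p in kfold(ds, k=5, seed=2):
            for part in (p.train, p.val, p.test):
                labs, counts = np.unique(ds.y[part].astype(str), return_counts=True)
                assert abs(counts[0] - counts[1]) <= 2

    def test_too_small_class_rejected(self):
        y = np.array(["a"] * 30 + ["b"] * 3, dtype=object)
        ds = make_ds(np.zeros((33, 2)), y)
        with pytest.raises(ValueError):
            kfold(ds, k=5)


def test_model_serialization_round_trip(tmp_path):
    m = init_model(6, 4, seed=8, class_names=["w", "x", "y", "z"],
                   feature_ids=[f"r{i}" for i in range(6)])
    save_model(m, tmp_path / "model.json")
    back = load_model(tmp_path / "model.json")
    assert np.array_equal(back.W1, m.W1) and np.array_equal(back.b2, m.b2)
    assert back.class_names == m.class_names
    assert back.feature_ids == m.feature_ids
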