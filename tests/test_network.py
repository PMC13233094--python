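"""The parsimonious two-layer ReLU network: forward pass, abstention, SGD."""

import numpy as np
import pytest

from curriculumnet import (
    NetworkParams,
    accuracy,
    batch_logits,
    bayes_accuracy,
    bce_loss,
    forward,
    init_network,
    make_task,
    sample_batch,
    sgd_step,
    xor_network,
)


@pytest.fixture()
def hand_net():
    # four axis-aligned units in the plane; readout adds mu1-units, subtracts mu0-units
    W1 = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
    w2 = np.array([1.0, 1.0, -1.0, -1.0])
    return NetworkParams(W1=W1, w2=w2)


class TestInit:
    def test_seeded_determinism(self):
        a = init_network(4, 100, 0.05, seed=11)
        b = init_network(4, 100, 0.05, seed=11)
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.w2, b.w2)

    def test_gaussian_moments(self):
        params = init_network(K=100, d=1000, init_std=0.05, seed=0)
        entries = np.concatenate([params.W1.ravel(), params.w2])
        assert abs(entries.mean()) < 3 * 0.05 / np.sqrt(entries.size)
        assert abs(entries.std() / 0.05 - 1) < 0.02

    def test_nonpositive_std_rejected(self):
        with pytest.raises(ValueError):
            init_network(4, 10, 0.0, seed=0)


class TestForward:
    def test_hand_evaluated_relu_arithmetic(self, hand_net):
        # x = (2, 0): h = (2, 0, 0, 0); logit = w2 . h = 2
        out = forward(hand_net, np.array([2.0, 0.0]))
        assert out.logit == pytest.approx(2.0)
        assert out.decision == "label1"

    def test_zero_readout_abstains_everywhere(self, rng):
        params = NetworkParams(W1=rng.standard_normal((4, 6)), w2=np.zeros(4))
        for _ in range(5):
            out = forward(params, rng.standard_normal(6))
            assert out.logit == 0.0
            assert out.decision == "abstain"

    def test_dead_network_abstains(self):
        # all units point along +e1; any x with x1 <= 0 closes every gate
        params = NetworkParams(W1=np.tile([1.0, 0.0], (4, 1)), w2=np.ones(4))
        out = forward(params, np.array([-3.0, 5.0]))
        assert out.logit == 0.0
        assert out.decision == "abstain"

    def test_shape_mismatch(self, hand_net):
        with pytest.raises(ValueError):
            forward(hand_net, np.zeros(3))

    def test_gate_scale_covariance(self, rng):
        # multiplying x by c > 0 multiplies every hidden activation by c
        params = init_network(4, 8, 0.05, seed=1)
        x = rng.standard_normal(8)
        h = np.maximum(params.W1 @ x, 0.0)
        for c in (0.5, 2.0, 7.3):
            np.testing.assert_allclose(np.maximum(params.W1 @ (c * x), 0.0), c * h)


class TestSgdStep:
    def test_closed_gate_leaves_row_unchanged(self, hand_net):
        x = np.array([-1.0, 0.5])  # unit 0 (along +e1) has W1_0 . x < 0
        new = sgd_step(hand_net, x, y=1, eta_step=0.5)
        np.testing.assert_array_equal(new.W1[0], hand_net.W1[0])
        assert not np.array_equal(new.W1[1], hand_net.W1[1])

    def test_gradient_matches_finite_differences(self, rng):
        eps = 1e-6
        for _ in range(20):
            K, d = 4, 5
            params = NetworkParams(
                W1=rng.normal(0, 0.5, (K, d)), w2=rng.normal(0, 0.5, K)
            )
            x = rng.standard_normal(d)
            y = int(rng.integers(0, 2))
            eta = 1.0
            new = sgd_step(params, x, y, eta)
            gW1 = (params.W1 - new.W1) / eta
            gw2 = (params.w2 - new.w2) / eta
            for arr, grad, name in ((params.W1, gW1, "W1"), (params.w2, gw2, "w2")):
                it = np.nditer(arr, flags=["multi_index"])
                for _val in it:
                    idx = it.multi_index
                    hi = arr.copy()
                    lo = arr.copy()
                    hi[idx] += eps
                    lo[idx] -= eps
                    if name == "W1":
                        p_hi = NetworkParams(W1=hi, w2=params.w2)
                        p_lo = NetworkParams(W1=lo, w2=params.w2)
                    else:
                        p_hi = NetworkParams(W1=params.W1, w2=hi)
                        p_lo = NetworkParams(W1=params.W1, w2=lo)
                    fd = (bce_loss(p_hi, x, y) - bce_loss(p_lo, x, y)) / (2 * eps)
                    if abs(fd) > 1e-8 or abs(grad[idx]) > 1e-8:
                        assert grad[idx] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_saturated_loss_gives_negligible_update(self):
        params = NetworkParams(W1=np.array([[50.0, 0.0]] * 4), w2=np.ones(4))
        x = np.array([1.0, 0.0])  # logit = 200, sigmoid ~ 1, y = 1 -> delta ~ 0
        new = sgd_step(params, x, y=1, eta_step=1.0)
        assert np.abs(new.W1 - params.W1).max() < 1e-6 * np.linalg.norm(x)
        assert np.abs(new.w2 - params.w2).max() < 1e-6 * np.linalg.norm(x)

    def test_bad_label_rejected(self, hand_net):
        with pytest.raises(ValueError):
            sgd_step(hand_net, np.zeros(2), y=2, eta_step=0.1)


class TestAccuracy:
    def test_all_abstain_scores_zero(self, task2):
        params = NetworkParams(W1=np.ones((4, 2)), w2=np.zeros(4))
        batch = sample_batch(task2, sigma=0.3, n=100, seed=0)
        assert accuracy(params, batch) == 0.0

    def test_xor_solution_on_easy_batch(self, task2):
        batch = sample_batch(task2, sigma=0.01, n=2000, seed=1)
        assert accuracy(xor_network(task2), batch) > 0.99

    def test_random_init_near_chance_on_hard_batch(self, task2):
        params = init_network(4, 2, 0.05, seed=2)
        batch = sample_batch(task2, sigma=0.65, n=10_000, seed=3)
        assert accuracy(params, batch) <= 0.55

    def test_xor_solution_attains_bayes(self, task10):
        # the hand construction computes |x.mu1| - |x.mu0|: the Bayes rule itself
        sigma, n = 0.3, 50_000
        batch = sample_batch(task10, sigma=sigma, n=n, seed=4)
        net_acc = accuracy(xor_network(task10), batch)
        bayes = bayes_accuracy(task10, sigma=sigma, n_mc=n, seed=5)
        se = np.sqrt(bayes * (1 - bayes) / n)
        assert abs(net_acc - bayes) < 2 * 2 * se  # 2 SE on each independent MC estimate

    def test_batch_logits_match_forward(self, task10, rng):
        params = init_network(4, task10.d, 0.05, seed=6)
        X = rng.standard_normal((20, task10.d))
        expected = [forward(params, x).logit for x in X]
        np.testing.assert_allclose(batch_logits(params, X), expected)


def test_online_bce_decreases_in_expectation(task10):
    """Prequential BCE over the last 100 of 1,000 online steps at sigma = 0.3
    is lower on average (over seeded runs) than over the first 100."""
    first, last = [], []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        params = init_network(4, task10.d, 0.05, seed=rng)
        losses = np.empty(1000)
        batch = sample_batch(task10, sigma=0.3, n=1000, seed=rng)
        for t in range(1000):
            x, y = batch.inputs[t], int(batch.labels[t])
            losses[t] = bce_loss(params, x, y)
            params = sgd_step(params, x, y, eta_step=0.1)
        first.append(losses[:100].mean())
        last.append(losses[-100:].mean())
    assert np.mean(last) < np.mean(first)
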