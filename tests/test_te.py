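"""Transfer-entropy estimators: plug-in oracle and KSG k-NN estimator."""

import copy
import math

import numpy as np
import pytest

from dyadte import (
    EstimatorConfig,
    plugin_te_from_joint,
    te_both_directions,
    te_ksg,
    te_plugin,
    total_te,
)
from dyadte.preprocess import embed
from dyadte.te import DegenerateSeriesWarning, TEResult


def brute_force_te(joint: np.ndarray) -> float:
    """Literal triple-sum evaluation of the defining TE expression (bits).

    Independent of the implementation: explicit loops, explicit
    conditional probabilities, no entropy identities.
    """
    p_y_yp = joint.sum(axis=2)
    p_yp_xp = joint.sum(axis=0)
    p_yp = joint.sum(axis=(0, 2))
    te = 0.0
    for yf in range(joint.shape[0]):
        for yp in range(joint.shape[1]):
            for xp in range(joint.shape[2]):
                p = joint[yf, yp, xp]
                if p == 0:
                    continue
                te += p * math.log2(
                    (p / p_yp_xp[yp, xp]) / (p_y_yp[yf, yp] / p_yp[yp])
                )
    return te


def copy_process_joint():
    """y_{t+1} = x_t with x i.i.d. fair binary, y past independent."""
    joint = np.zeros((2, 2, 2))
    for yf in range(2):
        for yp in range(2):
            joint[yf, yp, yf] = 0.25  # x_t must equal y_{t+1}
    return joint


class TestPlugin:
    def test_copy_process_is_one_bit(self):
        assert plugin_te_from_joint(copy_process_joint()) == pytest.approx(1.0, abs=1e-12)
        assert brute_force_te(copy_process_joint()) == pytest.approx(1.0, abs=1e-12)

    def test_independent_distribution_is_zero(self):
        joint = np.full((2, 2, 2), 1 / 8)
        assert plugin_te_from_joint(joint) == pytest.approx(0.0, abs=1e-12)

    def test_source_equal_target_adds_nothing(self):
        """x_t = y_t: conditioning on x's past duplicates y's past."""
        T = np.array([[0.7, 0.3], [0.2, 0.8]])  # y transition matrix
        pi = np.array([0.4, 0.6])
        joint = np.zeros((2, 2, 2))
        for yp in range(2):
            for yf in range(2):
                joint[yf, yp, yp] = pi[yp] * T[yp, yf]
        assert plugin_te_from_joint(joint) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_joints(self, seed):
        rng = np.random.default_rng(seed)
        joint = rng.random((3, 2, 3))
        joint /= joint.sum()
        assert plugin_te_from_joint(joint) == pytest.approx(
            brute_force_te(joint), abs=1e-12
        )

    def test_empirical_estimate_approaches_copy_process_value(self):
        rng = np.random.default_rng(1)
        n = 20000
        x = rng.integers(0, 2, n).astype(float)
        y = np.empty(n)
        y[0] = 0.0
        y[1:] = x[:-1]
        emb = embed(x, y, EstimatorConfig())
        assert te_plugin(emb) == pytest.approx(1.0, abs=0.01)

    def test_plugin_nonnegative_on_random_discrete_data(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.integers(0, 3, 500).astype(float)
            y = rng.integers(0, 3, 500).astype(float)
            assert te_plugin(embed(x, y, EstimatorConfig(m=2, n=1))) >= -1e-12

    def test_continuous_data_rejected_by_alphabet_cap(self):
        rng = np.random.default_rng(3)
        emb = embed(rng.normal(size=200), rng.normal(size=200), EstimatorConfig())
        with pytest.raises(ValueError, match="alphabet"):
            te_plugin(emb)

    def test_invalid_joint_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            plugin_te_from_joint(np.full((2, 2, 2), 1.0))


class TestKSG:
    def test_independent_white_noise_is_near_zero(self):
        cfg = EstimatorConfig(k=4)
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x, y = rng.normal(size=(2, 3000))
            vals.append(te_ksg(embed(x, y, cfg), cfg))
        assert abs(np.mean(vals)) < 0.02

    def test_linear_gaussian_matches_closed_form(self):
        """y_{t+1} = 0.4 y_t + 0.5 x_t + 0.5 eta: TE = 0.5*log2(2) = 0.5 bits."""
        cfg = EstimatorConfig(k=4)
        vals = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = 5000
            x, eta = rng.normal(size=(2, n))
            y = np.zeros(n)
            for t in range(n - 1):
                y[t + 1] = 0.4 * y[t] + 0.5 * x[t] + 0.5 * eta[t]
            vals.append(te_ksg(embed(x, y, cfg), cfg))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_agrees_with_plugin_on_quantized_chain(self):
        """Discretization bridge: KSG on (tie-jittered) symbols ~ plug-in."""
        rng = np.random.default_rng(0)
        n = 10000
        x = rng.integers(0, 2, n).astype(float)
        flip = rng.random(n) < 0.2
        y = np.zeros(n)
        y[1:] = np.abs(x[:-1] - flip[:-1])
        cfg = EstimatorConfig(k=4)
        tp = te_plugin(embed(x, y, cfg))
        tk = te_ksg(embed(x, y, cfg), cfg)
        assert tk == pytest.approx(tp, abs=0.05)

    def test_invariant_under_monotone_rescaling(self):
        cfg = EstimatorConfig(k=4)
        rng = np.random.default_rng(5)
        n = 2000
        x, eta = rng.normal(size=(2, n))
        y = np.zeros(n)
        for t in range(n - 1):
            y[t + 1] = 0.5 * y[t] + 0.5 * x[t] + 0.5 * eta[t]
        base = te_ksg(embed(x, y, cfg), cfg)
        zs = te_ksg(
            embed((x - x.mean()) / x.std(), (y - y.mean()) / y.std(), cfg), cfg
        )
        assert abs(base - zs) < 0.01

    def test_self_prediction_is_null(self):
        cfg = EstimatorConfig(k=4)
        rng = np.random.default_rng(6)
        x = rng.normal(size=3000).cumsum()  # smooth-ish series
        assert abs(te_ksg(embed(x, x, cfg), cfg)) < 0.02

    def test_estimate_error_shrinks_with_sample_size(self):
        """KSG converges toward the Gaussian closed form as N grows."""
        cfg = EstimatorConfig(k=4)
        errs = {2000: [], 20000: []}
        for seed in range(10):
            for n in errs:
                rng = np.random.default_rng(seed)
                x, eta = rng.normal(size=(2, n))
                y = np.zeros(n)
                for t in range(n - 1):
                    y[t + 1] = 0.4 * y[t] + 0.5 * x[t] + 0.5 * eta[t]
                errs[n].append(abs(te_ksg(embed(x, y, cfg), cfg) - 0.5))
        assert np.mean(errs[20000]) < np.mean(errs[2000])
        assert np.mean(errs[20000]) < 0.02

    def test_constant_channel_returns_zero_with_warning(self):
        cfg = EstimatorConfig(k=4)
        rng = np.random.default_rng(7)
        emb = embed(np.ones(100), rng.normal(size=100), cfg)
        with pytest.warns(DegenerateSeriesWarning):
            assert te_ksg(emb, cfg) == 0.0

    def test_k_must_be_below_row_count(self):
        cfg = EstimatorConfig(k=50)
        rng = np.random.default_rng(8)
        emb = embed(rng.normal(size=20), rng.normal(size=20), cfg)
        with pytest.raises(ValueError, match="k="):
            te_ksg(emb, cfg)

    def test_deterministic_given_seed(self):
        cfg = EstimatorConfig(k=4, seed=9)
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(2, 500))
        assert te_ksg(embed(x, y, cfg), cfg) == te_ksg(embed(x, y, cfg), cfg)

    def test_nats_units_scale_by_ln2(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=(2, 800))
        bits = te_ksg(embed(x, y, EstimatorConfig()), EstimatorConfig())
        nats = te_ksg(embed(x, y, EstimatorConfig(units="nats")), EstimatorConfig(units="nats"))
        assert nats == pytest.approx(bits * math.log(2), abs=1e-12)


class TestBothDirections:
    def test_leader_transfers_more_entropy(self, leader_follower_trial, config):
        res = te_both_directions(leader_follower_trial, config)
        assert res.te_ab > res.te_ba
        assert res.diff_ab == res.te_ab - res.te_ba
        assert res.n_samples_used == leader_follower_trial.n_samples - 1

    def test_channel_swap_exchanges_directions_exactly(self, leader_follower_trial, config):
        res = te_both_directions(leader_follower_trial, config)
        swapped = copy.copy(leader_follower_trial)
        swapped.gyro = leader_follower_trial.gyro[::-1].copy()
        res_sw = te_both_directions(swapped, config)
        assert res.te_ab == res_sw.te_ba
        assert res.te_ba == res_sw.te_ab

    def test_seat_metadata_controls_person_indexing(self, leader_follower_trial, config):
        """Swapping channels AND the seat label leaves person TE unchanged."""
        res = te_both_directions(leader_follower_trial, config)
        relabeled = copy.copy(leader_follower_trial)
        relabeled.gyro = leader_follower_trial.gyro[::-1].copy()
        relabeled.seat_of_player_A = "B"
        res_rl = te_both_directions(relabeled, config)
        assert res.te_ab == res_rl.te_ab
        assert res.te_ba == res_rl.te_ba

    def test_total_te_is_the_sum(self, config):
        res = TEResult(te_ab=0.1, te_ba=0.15, config=config, n_samples_used=10)
        assert total_te(res) == pytest.approx(0.25)
        zero = TEResult(te_ab=0.0, te_ba=0.0, config=config, n_samples_used=10)
        assert total_te(zero) == 0.0
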