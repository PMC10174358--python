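"""The echo-state Discourse Reservoir: dynamics, training, tracking."""

import math

import numpy as np
import pytest

from discourse_n400.reservoir import (
    DiscourseReservoir,
    DiscourseReservoirResults,
    ReservoirConfig,
    evaluate_average_tracking,
    train_discourse_reservoir,
    train_readout,
)
from discourse_n400.semantic_space import (
    SyntheticSpaceSpec,
    TokenStream,
    generate_synthetic_space,
    generate_training_stream,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"leak_rate": 0.0},
            {"leak_rate": 1.5},
            {"ridge_penalty": -1.0},
            {"spectral_radius": 0.0},
            {"recurrent_density": 0.0},
            {"feedback": True},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ReservoirConfig(**kwargs)


class TestInit:
    def test_same_seed_same_weights(self):
        cfg = ReservoirConfig(n_units=20, seed=5)
        m1 = DiscourseReservoir(cfg, input_dim=8)
        m2 = DiscourseReservoir(cfg, input_dim=8)
        assert np.array_equal(m1.W_in, m2.W_in)
        assert np.array_equal(m1.W_rec, m2.W_rec)
        assert np.array_equal(m1.bias, m2.bias)

    def test_different_seeds_differ(self):
        m1 = DiscourseReservoir(ReservoirConfig(n_units=20, seed=5), input_dim=8)
        m2 = DiscourseReservoir(ReservoirConfig(n_units=20, seed=6), input_dim=8)
        assert np.max(np.abs(m1.W_rec - m2.W_rec)) > 0

    @pytest.mark.parametrize("radius", [0.5, 0.95, 1.2])
    def test_spectral_radius_matches_eigenvalue_oracle(self, radius):
        cfg = ReservoirConfig(n_units=30, spectral_radius=radius, seed=1)
        m = DiscourseReservoir(cfg, input_dim=4)
        eig = np.max(np.abs(np.linalg.eigvals(m.W_rec)))
        assert eig == pytest.approx(radius, rel=1e-6)


class TestStep:
    def _toy(self, leak, W_in, W_rec, bias):
        cfg = ReservoirConfig(n_units=2, leak_rate=leak, seed=0)
        m = DiscourseReservoir(cfg, input_dim=2)
        m.W_in = np.array(W_in, dtype=float)
        m.W_rec = np.array(W_rec, dtype=float)
        m.bias = np.array(bias, dtype=float)
        return m

    def test_memoryless_limit(self, rng):
        m = self._toy(1.0, rng.standard_normal((2, 2)), np.zeros((2, 2)), np.zeros(2))
        u = rng.standard_normal(2)
        x1 = m.step(rng.standard_normal(2), u)
        x2 = m.step(np.zeros(2), u)
        assert np.allclose(x1, np.tanh(m.W_in @ u))
        assert np.allclose(x1, x2)

    def test_pure_decay_without_input(self):
        m = self._toy(0.25, np.zeros((2, 2)), np.zeros((2, 2)), np.zeros(2))
        x = np.array([0.8, -0.4])
        assert np.allclose(m.step(x, np.zeros(2)), 0.75 * x)

    def test_three_step_trajectory_matches_scalar_hand_computation(self):
        """2-unit reservoir with hand-fixed weights, checked against explicit
        per-component scalar arithmetic."""
        a = 0.2
        W_in = [[0.5, -0.3], [0.1, 0.4]]
        W_rec = [[0.0, 0.2], [-0.1, 0.3]]
        bias = [0.05, -0.05]
        m = self._toy(a, W_in, W_rec, bias)
        inputs = [(1.0, 0.0), (0.0, 1.0), (0.5, 0.5)]
        x = [0.0, 0.0]
        for u in inputs:
            pre0 = W_in[0][0] * u[0] + W_in[0][1] * u[1] + W_rec[0][0] * x[0] + W_rec[0][1] * x[1] + bias[0]
            pre1 = W_in[1][0] * u[0] + W_in[1][1] * u[1] + W_rec[1][0] * x[0] + W_rec[1][1] * x[1] + bias[1]
            x = [(1 - a) * x[0] + a * math.tanh(pre0), (1 - a) * x[1] + a * math.tanh(pre1)]
        xs = m.initial_state()
        for u in inputs:
            xs = m.step(xs, np.array(u))
        assert xs == pytest.approx(x, abs=1e-12)

    def test_state_bounded_after_update(self, small_reservoir, small_space):
        m = small_reservoir.model
        x = m.initial_state()
        for w in list(small_space.words())[:5]:
            x = m.step(x, small_space[w])
        assert np.all(np.abs(x) < 1.0)

    def test_dimension_mismatch_rejected(self):
        m = DiscourseReservoir(ReservoirConfig(n_units=4, seed=0), input_dim=3)
        with pytest.raises(ValueError):
            m.step(m.initial_state(), np.ones(5))


class TestCollectStates:
    def test_single_token_target_is_the_token_vector(self, small_space):
        m = DiscourseReservoir(ReservoirConfig(n_units=8, seed=0), input_dim=small_space.dim)
        word = small_space.words()[0]
        _, T = m.collect_states(TokenStream([[word]]), small_space)
        assert np.allclose(T[0], small_space[word])

    def test_targets_are_running_means_by_brute_force(self, small_space):
        m = DiscourseReservoir(ReservoirConfig(n_units=8, seed=0), input_dim=small_space.dim)
        doc = list(small_space.words())[:7]
        _, T = m.collect_states(TokenStream([doc]), small_space)
        vecs = small_space.vectors(doc)
        for k in range(len(doc)):
            assert np.allclose(T[k], vecs[: k + 1].mean(axis=0), atol=1e-12)

    def test_state_resets_at_document_boundary(self, small_space):
        m = DiscourseReservoir(ReservoirConfig(n_units=8, seed=0), input_dim=small_space.dim)
        words = list(small_space.words())
        doc_a, doc_b = words[:6], words[6:10]
        S_two, _ = m.collect_states(TokenStream([doc_a, doc_b]), small_space)
        S_fresh, _ = m.collect_states(TokenStream([doc_b]), small_space)
        assert np.array_equal(S_two[len(doc_a):], S_fresh)

    def test_washout_rows_excluded(self, small_space):
        m = DiscourseReservoir(
            ReservoirConfig(n_units=8, washout=2, seed=0), input_dim=small_space.dim
        )
        doc = list(small_space.words())[:5]
        S, T = m.collect_states(TokenStream([doc]), small_space)
        assert S.shape[0] == T.shape[0] == 3


class TestTrainReadout:
    def test_interpolates_with_zero_penalty(self, rng):
        S = rng.standard_normal((6, 6)) + 3 * np.eye(6)
        T = rng.standard_normal((6, 2))
        W = train_readout(S, T, 0.0)
        assert np.max(np.abs(S @ W.T - T)) < 1e-10

    def test_matches_closed_form_and_sklearn_oracles(self, rng):
        from sklearn.linear_model import Ridge

        for _ in range(5):
            S = rng.standard_normal((50, 10))
            T = rng.standard_normal((50, 3))
            lam = 0.01
            W = train_readout(S, T, lam)
            oracle = np.linalg.inv(S.T @ S + lam * np.eye(10)) @ S.T @ T
            assert np.allclose(W, oracle.T, rtol=1e-8, atol=1e-10)
            sk = Ridge(alpha=lam, fit_intercept=False).fit(S, T)
            assert np.allclose(W, sk.coef_, rtol=1e-6, atol=1e-8)

    def test_norm_shrinks_with_penalty(self, rng):
        S = rng.standard_normal((40, 8))
        T = rng.standard_normal((40, 2))
        norms = [np.linalg.norm(train_readout(S, T, lam)) for lam in (0.0, 1.0, 100.0)]
        assert norms[0] > norms[1] > norms[2]

    def test_row_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            train_readout(rng.standard_normal((5, 3)), rng.standard_normal((4, 2)), 0.1)


class TestFit:
    def test_training_is_deterministic(self, small_space, small_stream):
        cfg = ReservoirConfig(n_units=16, seed=44)
        r1 = train_discourse_reservoir(small_space, small_stream, cfg)
        r2 = train_discourse_reservoir(small_space, small_stream, cfg)
        assert np.array_equal(r1.W_out, r2.W_out)

    def test_empty_stream_rejected(self, small_space):
        with pytest.raises(ValueError):
            train_discourse_reservoir(small_space, TokenStream([]), ReservoirConfig(seed=0))

    def test_tracking_improves_with_position(self, small_reservoir, small_space):
        held = generate_training_stream(
            small_space, 40, (12, 30), topic_concentration=9.0, seed=301
        )
        curve = dict(small_reservoir.tracking_curve(held, small_space, max_position=10))
        assert curve[10] > curve[1]

    def test_toy_two_cluster_reservoir_tracks_above_half_at_position_five(self):
        """Dim-4 two-cluster space: held-out mean tracking cosine > 0.5 at k=5."""
        space = generate_synthetic_space(
            SyntheticSpaceSpec(dim=4, n_clusters=2, words_per_cluster=20, seed=21)
        )
        train = generate_training_stream(space, 120, (10, 30), seed=22)
        held = generate_training_stream(space, 30, (8, 20), seed=23)
        res = train_discourse_reservoir(space, train, ReservoirConfig(n_units=16, seed=24))
        curve = dict(res.tracking_curve(held, space, max_position=6))
        assert curve[5] > 0.5

    def test_summary_mentions_key_hyperparameters(self, small_reservoir):
        s = small_reservoir.summary()
        assert "leak rate" in s and "0.2" in s and "training MSE" in s

    def test_save_load_round_trip(self, small_reservoir, tmp_path):
        p = tmp_path / "model.npz"
        small_reservoir.save(p)
        loaded = DiscourseReservoirResults.load(p)
        assert np.array_equal(loaded.W_out, small_reservoir.W_out)
        assert np.array_equal(loaded.model.W_rec, small_reservoir.model.W_rec)
        assert loaded.config == small_reservoir.config


class TestTrackingEvaluation:
    def test_oracle_readout_scores_cosine_one_everywhere(self, small_space, small_stream):
        """A stub model whose state IS the true running average, with an
        identity readout, must score cosine 1.0 at every position."""

        class PerfectModel:
            def __init__(self, dim):
                self.output_dim = dim
                self._count = 0

            def initial_state(self):
                self._count = 0
                return np.zeros(self.output_dim)

            def step(self, state, u):
                self._count += 1
                return state + (np.asarray(u, dtype=float) - state) / self._count

        model = PerfectModel(small_space.dim)
        oracle = DiscourseReservoirResults(model, np.eye(small_space.dim), 0.0, 0, 0)
        curve = evaluate_average_tracking(oracle, small_stream, small_space, max_position=10)
        assert curve  # several positions present
        for _, mean_cos in curve:
            assert mean_cos == pytest.approx(1.0, abs=1e-12)

    def test_trained_readout_beats_random_readout(self, small_reservoir, small_space):
        held = generate_training_stream(small_space, 30, (12, 25), seed=305)
        trained = dict(small_reservoir.tracking_curve(held, small_space, max_position=10))
        rng = np.random.default_rng(0)
        random_res = DiscourseReservoirResults(
            small_reservoir.model,
            rng.standard_normal(small_reservoir.W_out.shape),
            0.0, 0, 0,
        )
        random_curve = dict(random_res.tracking_curve(held, small_space, max_position=10))
        assert trained[10] > random_curve[10]

    def test_positions_with_few_documents_are_omitted(self, small_reservoir, small_space):
        held = generate_training_stream(small_space, 6, (5, 9), seed=306)
        curve = evaluate_average_tracking(
            small_reservoir, held, small_space, max_position=9, min_documents=5
        )
        positions = [k for k, _ in curve]
        assert max(positions) <= 9
        # all six docs have >= 5 tokens, so position 5 must be present
        assert 5 in positions
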