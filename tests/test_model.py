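import numpy as np
import pytest

from simdta.core import Drug
from simdta.features import PairInput
from simdta.metrics import mse
from simdta.model import (
    ModelConfig,
    SimCNNRegressor,
    TrainedModel,
    attach_rosters,
    build_model,
    layer_output_shapes,
    load_model,
    min_input_size,
    predict,
    rank_candidates,
    save_model,
    train,
)

TINY = dict(conv_filters=(2, 2), conv_kernels=((3, 3), (2, 2)),
            dropout_rate=0.0, fc_width=4)


def weights_of(est):
    return [p.copy() for layer in est.layers_ for p in layer.params]


class TestArchitectureArithmetic:
    def test_flatten_length_20x20(self):
        # 20 -(5x5)-> 16 -(pool)-> 15 -(3x3)-> 13 -(pool)-> 12
        shapes = dict(layer_output_shapes(20, 20))
        assert shapes["flatten"] == (12 * 12 * 18,)

    def test_regression_head_emits_scalar(self):
        shapes = layer_output_shapes(68, 442)
        assert shapes[-1][1] == (1,)

    def test_too_small_input_raises_with_minimum(self):
        with pytest.raises(ValueError, match="at least 9"):
            layer_output_shapes(8, 20)
        with pytest.raises(ValueError, match="at least 9"):
            build_model(8, 20)
        assert min_input_size() == 9
        assert isinstance(build_model(9, 9), SimCNNRegressor)

    def test_shapes_match_closed_form_for_random_sizes(self):
        """Per-layer shapes follow valid-conv/pool arithmetic: each conv
        removes k-1, each overlapping 2x2 pool removes 1."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            nd = int(rng.integers(9, 40))
            nt = int(rng.integers(9, 40))
            shapes = layer_output_shapes(nd, nt)
            h, w = nd, nt
            idx = 1
            for f, k in zip((32, 18), (5, 3)):
                h, w = h - k + 1, w - k + 1
                assert shapes[idx][1] == (f, h, w)
                h, w = h - 1, w - 1
                assert shapes[idx + 1][1] == (f, h, w)
                idx += 2
            assert shapes[idx][1] == (18 * h * w,)

    def test_forward_shapes_agree_with_arithmetic(self):
        est = SimCNNRegressor(epochs=0, seed=0)
        X = np.random.default_rng(1).random((3, 11, 13))
        est.fit(X, np.zeros(3))
        assert est.predict(X).shape == (3,)
        flat = dict(layer_output_shapes(11, 13))["flatten"][0]
        assert est.layers_[-3].W.shape[0] == flat  # dense-in matches flatten

    def test_parameter_shapes(self):
        est = SimCNNRegressor(epochs=0, seed=0)
        est.fit(np.zeros((1, 9, 9)), np.zeros(1))
        conv1, _, conv2 = est.layers_[0], est.layers_[1], est.layers_[2]
        assert conv1.W.shape == (32, 1, 5, 5)
        assert conv2.W.shape == (18, 32, 3, 3)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Backprop through conv/pool/dense agrees with numerical
        differentiation of the batch MSE loss."""
        est = SimCNNRegressor(epochs=0, seed=3, **TINY)
        rng = np.random.default_rng(4)
        X = rng.random((4, 7, 7))
        y = rng.normal(size=4)
        est.fit(X, y)

        def loss():
            pred = est._forward(X[:, None, :, :], train=False).ravel()
            return float(np.mean((pred - y) ** 2))

        pred = est._forward(X[:, None, :, :], train=True).ravel()
        est._backward((2.0 / len(y)) * (pred - y)[:, None])
        params = [p for l in est.layers_ for p in l.params]
        grads = [g for l in est.layers_ for g in l.grads]
        eps = 1e-6
        rng2 = np.random.default_rng(5)
        for p, g in zip(params, grads):
            flat_p, flat_g = p.ravel(), g.ravel()
            for idx in rng2.choice(flat_p.size, size=min(6, flat_p.size),
                                   replace=False):
                orig = flat_p[idx]
                flat_p[idx] = orig + eps
                up = loss()
                flat_p[idx] = orig - eps
                down = loss()
                flat_p[idx] = orig
                assert flat_g[idx] == pytest.approx((up - down) / (2 * eps),
                                                    rel=1e-3, abs=1e-6)


class TestTrainingContracts:
    def test_same_seed_identical_weights(self):
        rng = np.random.default_rng(0)
        X, y = rng.random((20, 9, 9)), rng.normal(size=20)
        w1 = weights_of(SimCNNRegressor(epochs=3, seed=7, **TINY).fit(X, y))
        w2 = weights_of(SimCNNRegressor(epochs=3, seed=7, **TINY).fit(X, y))
        for a, b in zip(w1, w2):
            assert np.array_equal(a, b)

    def test_zero_epochs_leaves_initialization(self):
        rng = np.random.default_rng(1)
        X, y = rng.random((5, 9, 9)), rng.normal(size=5)
        est = SimCNNRegressor(epochs=0, seed=2, **TINY).fit(X, y)
        ref = SimCNNRegressor(epochs=0, seed=2, **TINY).fit(X, y)
        for a, b in zip(weights_of(est), weights_of(ref)):
            assert np.array_equal(a, b)
        assert est.loss_history_ == []

    def test_loss_finite_and_beats_constant_baseline(self, synth_Xy, fold5,
                                                     fitted_fold0):
        X, y = synth_Xy
        tr = fold5.train_indices(0)
        assert np.isfinite(fitted_fold0.loss_history_).all()
        train_mse = mse(y[tr], fitted_fold0.predict(X[tr]))
        const_mse = mse(y[tr], np.full(tr.size, y[tr].mean()))
        assert train_mse < const_mse

    def test_shape_mismatch_rejected(self):
        est = SimCNNRegressor(epochs=0, seed=0, **TINY)
        est.fit(np.zeros((2, 9, 9)), np.zeros(2))
        with pytest.raises(ValueError, match="shape"):
            est.predict(np.zeros((2, 10, 10)))

    def test_sklearn_param_round_trip(self):
        est = SimCNNRegressor(epochs=5, seed=3)
        clone_params = est.get_params()
        assert clone_params["epochs"] == 5
        est.set_params(epochs=1)
        assert est.epochs == 1


class TestPrediction:
    def test_order_preserved_and_duplicates_equal(self, synth_Xy, fitted_fold0):
        X, _ = synth_Xy
        batch = np.concatenate([X[:3], X[:1]])
        out = fitted_fold0.predict(batch)
        assert out.shape == (4,)
        assert out[0] == out[3]

    def test_invariant_to_batch_partitioning(self, synth_Xy, fitted_fold0):
        X, _ = synth_Xy
        all_at_once = fitted_fold0.predict(X[:10])
        one_by_one = np.array(
            [fitted_fold0.predict(X[i:i + 1])[0] for i in range(10)]
        )
        assert np.allclose(all_at_once, one_by_one, atol=1e-10)


class TestPersistence:
    def _trained(self):
        rng = np.random.default_rng(0)
        X, y = rng.random((12, 9, 10)), rng.normal(5, 1, size=12)
        pairs = [
            (PairInput(x, tuple(f"d{i}" for i in range(9)),
                       tuple(f"t{j}" for j in range(10))), yy)
            for x, yy in zip(X, y)
        ]
        return train(pairs, ModelConfig(epochs=2, seed=1, **TINY)), X

    def test_round_trip_predicts_bitwise_equal(self, tmp_path):
        model, X = self._trained()
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        grids = [PairInput(x, model.drug_roster_ids, model.target_roster_ids)
                 for x in X]
        assert np.array_equal(predict(model, grids), predict(back, grids))

    def test_rosters_preserved(self, tmp_path):
        model, _ = self._trained()
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        assert back.drug_roster_ids == model.drug_roster_ids
        assert back.target_roster_ids == model.target_roster_ids

    def test_load_nonexistent_path_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "missing")

    def test_version_mismatch_rejected(self, tmp_path):
        model, _ = self._trained()
        save_model(model, tmp_path / "m")
        manifest = (tmp_path / "m" / "manifest.json")
        manifest.write_text(manifest.read_text().replace(
            '"format_version": 1', '"format_version": 99'))
        with pytest.raises(ValueError, match="version"):
            load_model(tmp_path / "m")


@pytest.fixture(scope="module")
def ranked_setup(synth_ds, synth_Xy, fold5):
    X, y = synth_Xy
    tr = fold5.train_indices(0)
    est = SimCNNRegressor(epochs=2, seed=0).fit(X[tr], y[tr])
    model = TrainedModel(est, synth_ds.drug_ids, synth_ds.target_ids)
    attach_rosters(model, list(synth_ds.drugs), list(synth_ds.targets))
    return model, synth_ds


class TestRanking:
    def test_sorted_descending_with_dense_ranks(self, ranked_setup):
        model, ds = ranked_setup
        candidates = [Drug("c1", "c1ccccc1CCO"), Drug("c2", "CCCCN"),
                      Drug("c3", "c1ccncc1CC")]
        rows = rank_candidates(model, candidates, ds.targets[0])
        preds = [r[1] for r in rows]
        assert preds == sorted(preds, reverse=True)
        assert [r[2] for r in rows] == [1, 2, 3]

    def test_duplicate_candidates_get_adjacent_ranks(self, ranked_setup):
        model, ds = ranked_setup
        rows = rank_candidates(
            model, [Drug("a", "CCO"), Drug("b", "CCO")], ds.targets[0]
        )
        assert rows[0][1] == rows[1][1]
        assert {rows[0][0], rows[1][0]} == {"a", "b"}
        assert rows[0][0] == "a"  # stable tie-break keeps input order

    def test_invalid_candidate_skipped_with_warning(self, ranked_setup):
        model, ds = ranked_setup
        with pytest.warns(UserWarning, match="broken"):
            rows = rank_candidates(
                model, [Drug("ok", "CCO"), Drug("broken", ")(")], ds.targets[0]
            )
        assert [r[0] for r in rows] == ["ok"]
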