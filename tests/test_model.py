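import numpy as np
import pytest

from netbim.model import (
    FEATURE_NAMES,
    ModelConfig,
    build_model,
    grid_search,
    train,
)

TINY = dict(n_filters=4, fc_dims=(6, 3), attention_hidden=5, n_copies=1, dropout=0.0)


def make_data(rng, n=64, net_signal=1.0):
    x_pep = rng.normal(0, 0.3, size=(n, 9, 21))
    x_net = rng.normal(size=(n, 8))
    logits = net_signal * (x_net[:, 0] + 0.5 * x_net[:, 5]) + rng.normal(0, 0.1, n)
    y = 1.0 / (1.0 + np.exp(-logits))
    return x_pep, x_net, y


class TestConfig:
    def test_task_defaults(self):
        b = ModelConfig(task="binding")
        assert (b.loss, b.optimizer) == ("mse", "adam")
        i = ModelConfig(task="immunogenic")
        assert (i.loss, i.optimizer) == ("bce", "rmsprop")

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(task="other")
        with pytest.raises(ValueError):
            ModelConfig(dropout=1.0)
        with pytest.raises(ValueError):
            ModelConfig(ablation="drop_metric:bogus")


class TestArchitecture:
    def test_forward_bounds_and_shapes(self, rng):
        m = build_model(ModelConfig(task="binding", **TINY))
        xp, xn, _ = make_data(rng, n=10)
        p = m.predict(xp, xn)
        assert p.shape == (10,)
        assert np.all((p >= 0) & (p <= 1))
        # zero inputs still give a finite score in [0, 1]
        pz = m.predict(np.zeros((1, 9, 21)), np.zeros((1, 8)))
        assert 0.0 <= pz[0] <= 1.0

    def test_pep_only_ignores_metrics(self, rng):
        m = build_model(ModelConfig(task="binding", ablation="pep_only", **TINY))
        xp, xn, _ = make_data(rng, n=6)
        assert np.allclose(m.predict(xp), m.predict(xp, xn))
        assert m.met_branch is None

    def test_drop_metric_consumes_seven(self, rng):
        m = build_model(ModelConfig(task="binding", ablation="drop_metric:PEP_closeness", **TINY))
        xp, xn, _ = make_data(rng, n=6)
        assert m.cfg.n_metric_features == 7
        # dropping the column by hand must equal passing the full 8-vector
        xn7 = np.delete(xn, FEATURE_NAMES.index("PEP_closeness"), axis=1)
        assert np.allclose(m.predict(xp, xn), m.predict(xp, xn7))

    def test_determinism_same_seed(self, rng):
        xp, xn, y = make_data(rng, n=48)
        runs = []
        for _ in range(2):
            cfg = ModelConfig(task="binding", epochs=3, batch_size=16, seed=7, **TINY)
            m = train(build_model(cfg), xp, xn, y)
            runs.append(m.history[-1]["val_loss"])
        assert runs[0] == runs[1]

    def test_duplicated_rows_identical_scores(self, rng):
        m = build_model(ModelConfig(task="binding", **TINY))
        xp, xn, _ = make_data(rng, n=4)
        xp2 = np.concatenate([xp, xp[:1]])
        xn2 = np.concatenate([xn, xn[:1]])
        p = m.predict(xp2, xn2)
        assert p[0] == p[-1]


class TestGradients:
    @pytest.mark.parametrize("task", ["binding", "immunogenic"])
    def test_backprop_matches_finite_differences(self, task, rng):
        cfg = ModelConfig(task=task, n_filters=3, fc_dims=(5, 2),
                          attention_hidden=4, n_copies=1, dropout=0.0, seed=0)
        m = build_model(cfg)
        xp = rng.normal(size=(5, 9, 21))
        xn = rng.normal(size=(5, 8))
        y = rng.random(5) if task == "binding" else (rng.random(5) > 0.5).astype(float)
        xm = m._metrics_input(xn)
        p, caches = m._forward(xp, xm)
        _, dz = m._loss_and_dz(p, y)
        grads = m._backward(caches, dz)
        eps = 1e-6
        for key, param in m.params.items():
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in param.shape)
                orig = param[idx]
                param[idx] = orig + eps
                lp = m._loss_and_dz(m._forward(xp, xm)[0], y)[0]
                param[idx] = orig - eps
                lm = m._loss_and_dz(m._forward(xp, xm)[0], y)[0]
                param[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[key][idx] == pytest.approx(num, rel=1e-4, abs=1e-8), key


class TestTraining:
    def test_loss_decreases_on_separable_data(self, rng):
        xp, xn, y = make_data(rng, n=256, net_signal=2.0)
        cfg = ModelConfig(task="binding", epochs=60, patience=60, batch_size=64,
                          seed=3, **TINY)
        m = train(build_model(cfg), xp, xn, y)
        losses = [h["train_loss"] for h in m.history]
        assert losses[-1] < losses[0] * 0.5
        # and the early epochs already trend downward
        assert losses[5] <= losses[0]

    def test_immunogenic_category_threshold(self, rng):
        xp, xn, y = make_data(rng, n=32)
        cfg = ModelConfig(task="immunogenic", epochs=2, batch_size=16, seed=0, **TINY)
        m = train(build_model(cfg), xp, xn, (y > 0.5).astype(float))
        cat = m.predict_category(xp, xn)
        assert set(np.unique(cat)) <= {0, 1}
        assert np.array_equal(cat, (m.predict(xp, xn) >= 0.5).astype(int))

    def test_save_load_round_trip(self, tmp_path, rng):
        xp, xn, y = make_data(rng, n=32)
        cfg = ModelConfig(task="binding", epochs=2, batch_size=16, seed=0, **TINY)
        m = train(build_model(cfg), xp, xn, y)
        path = tmp_path / "model.npz"
        m.save(path)
        m2 = m.load(path)
        assert np.allclose(m.predict(xp, xn), m2.predict(xp, xn))
        assert m2.cfg == m.cfg


class TestGridSearch:
    def test_singleton_returns_that_config(self, rng):
        xp, xn, y = make_data(rng, n=48)
        cfg = ModelConfig(task="binding", epochs=2, batch_size=16, seed=0, **TINY)
        best, table = grid_search([cfg], (xp, xn, y), (xp, xn, y))
        assert best is cfg
        assert len(table) == 1

    def test_exhaustive_matches_rerun(self, rng):
        xp, xn, y = make_data(rng, n=48)
        grid = [
            ModelConfig(task="binding", kernel_peptide=k, epochs=2, batch_size=16,
                        seed=0, **TINY)
            for k in (2, 3)
        ]
        best, table = grid_search(grid, (xp, xn, y), (xp, xn, y))
        # re-evaluating each cell independently reproduces the table
        from netbim.model import build_model as bm, train as tr
        for row, cfg in zip(table.itertuples(), grid):
            m = tr(bm(cfg), xp, xn, y)
            assert row.loss == pytest.approx(m.loss_on(xp, xn, y))
        assert best.kernel_peptide == grid[int(table["loss"].idxmin())].kernel_peptide

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search([], None, None)
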