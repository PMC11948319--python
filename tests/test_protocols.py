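"""Training-protocol behaviour: checkpoint selection, determinism, folds,
and the sklearn-style estimator surface.  Runs are tiny (a few epochs on a
few dozen structures) — they check protocol properties, not accuracy."""

import numpy as np
import pytest

from tautrank.estimators import EnergyNetRegressor, PairDeltaRegressor
from tautrank.nn.model import ModelConfig, build_graph
from tautrank.synthetic import make_energy_dataset, make_pair_dataset
from tautrank.training import (
    FinetuneConfig,
    PretrainConfig,
    SplitPlan,
    run_finetuning,
    run_pretraining,
)

CFG = ModelConfig(embedding_dim=8, n_interaction=1, n_residual=1, n_output_residual=1, n_rbf=8)


@pytest.fixture(scope="module")
def tiny_dataset():
    ds = make_energy_dataset(40, seed=21, n_conformers=2)
    graphs = [build_graph(s.conf, atomic_numbers=s.z, cutoff=CFG.cutoff) for s in ds]
    y = np.array([s.triple.as_array() for s in ds])
    return graphs, y


@pytest.fixture(scope="module")
def tiny_pairs():
    return make_pair_dataset(30, noise_sd=0.2, seed=22, n_conformers=2)


class TestPretrainProtocol:
    def test_learning_happens(self, tiny_dataset):
        graphs, y = tiny_dataset
        ckpt, history = run_pretraining(
            (graphs[8:], y[8:]), (graphs[:8], y[:8]),
            model_cfg=CFG, cfg=PretrainConfig(epochs=25, seed=1, eval_every=5),
        )
        assert history[-1]["val_rmse"] < history[0]["val_rmse"]

    def test_best_checkpoint_is_minimum_of_log(self, tiny_dataset):
        graphs, y = tiny_dataset
        ckpt, history = run_pretraining(
            (graphs[8:], y[8:]), (graphs[:8], y[:8]),
            model_cfg=CFG, cfg=PretrainConfig(epochs=15, seed=2, eval_every=3),
        )
        assert ckpt.provenance["val_rmse"] == pytest.approx(
            min(h["val_rmse"] for h in history)
        )

    def test_seeded_determinism(self, tiny_dataset):
        graphs, y = tiny_dataset
        outs = []
        for _ in range(2):
            ckpt, _ = run_pretraining(
                (graphs[8:], y[8:]), (graphs[:8], y[:8]),
                model_cfg=CFG, cfg=PretrainConfig(epochs=5, seed=3),
            )
            outs.append(ckpt.predict(graphs[:4]))
        assert np.array_equal(outs[0], outs[1])

    def test_constant_zero_targets_converge(self, tiny_dataset):
        """With all-zero labels the model collapses toward zero output."""
        graphs, _ = tiny_dataset
        y = np.zeros((len(graphs), 3))
        ckpt, history = run_pretraining(
            (graphs[8:], y[8:]), (graphs[:8], y[:8]),
            model_cfg=CFG,
            cfg=PretrainConfig(epochs=40, seed=4, eval_every=10, learning_rate=0.005),
        )
        assert history[-1]["train_loss"] < 0.1 * history[0]["train_loss"] + 1e-9


class TestFinetuneProtocol:
    def test_fold_partition(self, tiny_pairs):
        plan = SplitPlan(n_folds=5)
        folds = plan.folds(len(tiny_pairs), seed=5)
        val_all = np.concatenate([v for _, v in folds])
        assert sorted(val_all.tolist()) == list(range(len(tiny_pairs)))

    def test_cv_produces_fold_checkpoints(self, tiny_pairs):
        cv = run_finetuning(
            None, tiny_pairs, SplitPlan(n_folds=3),
            FinetuneConfig(epochs=5, seed=6, eval_every=5, from_scratch=True,
                           learning_rate=0.001),
            model_cfg=CFG,
        )
        assert len(cv.fold_checkpoints) == 3
        preds = cv.predict_pair_deltas(tiny_pairs[:5])
        assert preds.shape == (5,)
        stack = np.stack([c.predict_pair_deltas(tiny_pairs[:5]) for c in cv.fold_checkpoints])
        assert np.allclose(preds, stack.mean(axis=0))

    def test_determinism(self, tiny_pairs):
        kw = dict(
            plan=SplitPlan(n_folds=2),
            cfg=FinetuneConfig(epochs=5, seed=7, eval_every=5, from_scratch=True,
                               learning_rate=0.001),
            model_cfg=CFG,
        )
        a = run_finetuning(None, tiny_pairs, **kw).predict_pair_deltas(tiny_pairs[:4])
        b = run_finetuning(None, tiny_pairs, **kw).predict_pair_deltas(tiny_pairs[:4])
        assert np.array_equal(a, b)

    def test_too_few_records_rejected(self, tiny_pairs):
        with pytest.raises(ValueError):
            run_finetuning(
                None, tiny_pairs[:3], SplitPlan(n_folds=5),
                FinetuneConfig(epochs=1, from_scratch=True), model_cfg=CFG,
            )


class TestEstimators:
    def test_energy_regressor_fit_predict(self, tiny_dataset):
        graphs, y = tiny_dataset
        est = EnergyNetRegressor(
            embedding_dim=8, n_interaction=1, n_residual=1, n_output_residual=1,
            n_rbf=8, epochs=5, seed=8,
        )
        est.fit(graphs, y)
        assert est.predict(graphs[:3]).shape == (3, 3)
        assert est.best_epoch_ >= 1
        # clone-compatible param surface
        from sklearn.base import clone

        clone(est)

    def test_pair_regressor_over_pretrained_base(self, tiny_dataset, tiny_pairs):
        graphs, y = tiny_dataset
        base = EnergyNetRegressor(
            embedding_dim=8, n_interaction=1, n_residual=1, n_output_residual=1,
            n_rbf=8, epochs=3, seed=9,
        ).fit(graphs, y)
        pair_est = PairDeltaRegressor(base=base, epochs=3, n_folds=2, seed=9, eval_every=3)
        pair_est.fit(tiny_pairs)
        preds = pair_est.predict(tiny_pairs[:6])
        assert preds.shape == (6,)
        assert len(pair_est.fold_checkpoints_) == 2

    def test_unfitted_predict_raises(self, tiny_pairs):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            PairDeltaRegressor().predict(tiny_pairs[:1])

    def test_checkpoint_file_roundtrip(self, tiny_dataset, tmp_path):
        from tautrank.training import Checkpoint

        graphs, y = tiny_dataset
        est = EnergyNetRegressor(
            embedding_dim=8, n_interaction=1, n_residual=1, n_output_residual=1,
            n_rbf=8, epochs=3, seed=10,
        ).fit(graphs, y)
        path = tmp_path / "ckpt.npz"
        est.checkpoint_.save(path)
        loaded = Checkpoint.load(path)
        assert np.array_equal(loaded.predict(graphs[:3]), est.predict(graphs[:3]))
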