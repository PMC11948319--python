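"""scikit-learn-style estimators over the energy network.

:class:`EnergyNetRegressor` fits the multitask network on labeled
structures (list of distance graphs X, (n, 3) energy triples y) and
predicts energy triples.  :class:`PairDeltaRegressor` wraps the Siamese
fine-tuning protocol: it fits on pair records and predicts pairwise
aqueous free-energy differences with the fold-mean ensemble.  Both follow
the fit/predict, ``get_params``/``set_params`` conventions, so they
compose with sklearn model selection; the protocol functions in
:mod:`tautrank.training` are the underlying drivers.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .nn.model import ModelConfig, MolecularGraph
from .training import (
    Checkpoint,
    FinetuneConfig,
    PairRecord,
    PretrainConfig,
    SplitPlan,
    run_finetuning,
    run_pretraining,
)


class EnergyNetRegressor(BaseEstimator, RegressorMixin):
    """Multitask energy regressor: graphs in, (E_gas, E_water, dE_transfer) out.

    Parameters mirror the architecture and pretraining defaults; the
    fitted model keeps the best-on-validation shadow weights.
    """

    def __init__(
        self,
        embedding_dim: int = 128,
        n_interaction: int = 3,
        n_residual: int = 2,
        n_output_residual: int = 2,
        n_rbf: int = 64,
        cutoff: float = 10.0,
        learning_rate: float = 0.001,
        epochs: int = 500,
        batch_size: int = 32,
        val_fraction: float = 0.2,
        seed: int = 0,
        eval_every: int = 1,
    ):
        self.embedding_dim = embedding_dim
        self.n_interaction = n_interaction
        self.n_residual = n_residual
        self.n_output_residual = n_output_residual
        self.n_rbf = n_rbf
        self.cutoff = cutoff
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.seed = seed
        self.eval_every = eval_every

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            embedding_dim=self.embedding_dim,
            n_interaction=self.n_interaction,
            n_residual=self.n_residual,
            n_output_residual=self.n_output_residual,
            n_rbf=self.n_rbf,
            cutoff=self.cutoff,
        )

    def fit(self, X: Sequence[MolecularGraph], y) -> "EnergyNetRegressor":
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 3 or len(X) != len(y):
            raise ValueError("y must be (n_samples, 3) aligned with X")
        rng = np.random.default_rng(self.seed)
        n_val = max(1, round(len(X) * self.val_fraction))
        order = rng.permutation(len(X))
        val_idx, train_idx = order[:n_val], order[n_val:]
        if len(train_idx) == 0:
            raise ValueError("not enough samples for a train/validation split")
        ckpt, history = run_pretraining(
            ([X[i] for i in train_idx], y[train_idx]),
            ([X[i] for i in val_idx], y[val_idx]),
            model_cfg=self._model_config(),
            cfg=PretrainConfig(
                learning_rate=self.learning_rate,
                epochs=self.epochs,
                batch_size=self.batch_size,
                seed=self.seed,
                eval_every=self.eval_every,
            ),
        )
        self.checkpoint_ = ckpt
        self.history_ = history
        self.best_epoch_ = ckpt.provenance["best_epoch"]
        self.val_rmse_ = ckpt.provenance["val_rmse"]
        return self

    def predict(self, X: Sequence[MolecularGraph]) -> np.ndarray:
        check_is_fitted(self, "checkpoint_")
        return self.checkpoint_.predict(list(X))


class PairDeltaRegressor(BaseEstimator, RegressorMixin):
    """Siamese pairwise regressor with k-fold fine-tuning and fold-mean
    inference.

    ``base`` is a fitted :class:`EnergyNetRegressor`, a
    :class:`~tautrank.training.Checkpoint`, or None (training from scratch,
    in which case the architecture arguments are used).
    """

    def __init__(
        self,
        base=None,
        learning_rate: float = 0.0001,
        epochs: int = 2000,
        batch_size: int = 16,
        alpha: float = 0.8,
        beta: float = 0.2,
        n_folds: int = 5,
        from_scratch: bool = False,
        seed: int = 0,
        eval_every: int = 10,
        embedding_dim: int = 128,
        n_interaction: int = 3,
        n_residual: int = 2,
        n_output_residual: int = 2,
        n_rbf: int = 64,
        cutoff: float = 10.0,
    ):
        self.base = base
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.alpha = alpha
        self.beta = beta
        self.n_folds = n_folds
        self.from_scratch = from_scratch
        self.seed = seed
        self.eval_every = eval_every
        self.embedding_dim = embedding_dim
        self.n_interaction = n_interaction
        self.n_residual = n_residual
        self.n_output_residual = n_output_residual
        self.n_rbf = n_rbf
        self.cutoff = cutoff

    def _init_checkpoint(self) -> Checkpoint | None:
        if self.base is None:
            return None
        if isinstance(self.base, Checkpoint):
            return self.base
        if isinstance(self.base, EnergyNetRegressor):
            check_is_fitted(self.base, "checkpoint_")
            return self.base.checkpoint_
        raise TypeError("base must be None, a Checkpoint, or a fitted EnergyNetRegressor")

    def fit(self, X: Sequence[PairRecord], y=None) -> "PairDeltaRegressor":
        """Fit on pair records; ``y`` defaults to each record's dG_exp."""
        X = list(X)
        if y is not None:
            y = np.asarray(y, dtype=float)
            if len(y) != len(X):
                raise ValueError("y must align with X")
            for rec, v in zip(X, y):
                rec.dG_exp = float(v)
        init = self._init_checkpoint()
        model_cfg = (
            init.config
            if init is not None
            else ModelConfig(
                embedding_dim=self.embedding_dim,
                n_interaction=self.n_interaction,
                n_residual=self.n_residual,
                n_output_residual=self.n_output_residual,
                n_rbf=self.n_rbf,
                cutoff=self.cutoff,
            )
        )
        cv = run_finetuning(
            init,
            X,
            plan=SplitPlan(n_folds=self.n_folds),
            cfg=FinetuneConfig(
                learning_rate=self.learning_rate,
                epochs=self.epochs,
                batch_size=self.batch_size,
                alpha=self.alpha,
                beta=self.beta,
                from_scratch=self.from_scratch or init is None,
                seed=self.seed,
                eval_every=self.eval_every,
            ),
            model_cfg=model_cfg,
        )
        self.cv_result_ = cv
        self.fold_checkpoints_ = cv.fold_checkpoints
        self.fold_val_rmse_ = cv.fold_val_rmse
        self.mean_val_rmse_ = cv.mean_val_rmse
        return self

    def predict(self, X: Sequence[PairRecord]) -> np.ndarray:
        check_is_fitted(self, "cv_result_")
        return self.cv_result_.predict_pair_deltas(list(X))
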