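"""Training protocols: multitask pretraining, Siamese fine-tuning, EmaAmsGrad.

Pretraining minimizes the sum of L1 losses over the three energy heads on
labeled structures.  Fine-tuning wraps the same network in a Siamese
configuration and minimizes

    alpha * mean|dG_pred − dG_exp|  +  beta * mean|E_gas_pred − E_gas_target|

with the gas-phase anchor averaged over both pair members (alpha = 0.8,
beta = 0.2 by default); the anchor term keeps the absolute energy surface
from drifting while the pairwise term fits the experimental free-energy
differences.  The optimizer is AMSGrad with an exponential-moving-average
shadow copy of the weights; evaluation and checkpointing always read the
shadow.  Model selection is best-on-validation RMSE; the fine-tuning
protocol is k-fold cross-validation with fold-mean ensembling at inference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold

from .chem import Conformer3D
from .nn.autodiff import Tensor, parameter
from .nn.model import (
    WATER,
    GraphBatch,
    ModelConfig,
    MolecularGraph,
    build_graph,
    clone_params,
    fit_element_shifts,
    forward_batch,
    init_params,
    load_checkpoint,
    save_checkpoint,
    shift_energy,
)

logger = logging.getLogger(__name__)

GAS = 0  # head index of E_gas


class DivergenceError(RuntimeError):
    """Raised when training produces a non-finite loss; carries the last
    good checkpoint on the ``checkpoint`` attribute."""

    def __init__(self, msg: str, checkpoint=None):
        super().__init__(msg)
        self.checkpoint = checkpoint


# ---------------------------------------------------------------------------
# configs


@dataclass
class PretrainConfig:
    learning_rate: float = 0.001
    epochs: int = 500
    batch_size: int = 32
    epsilon: float = 1e-8
    ema_decay_start: float = 0.0
    ema_decay_end: float = 0.99
    ema_warmup_steps: int = 100
    seed: int = 0
    eval_every: int = 1

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("learning_rate > 0 and epochs >= 1 required")


@dataclass
class FinetuneConfig:
    learning_rate: float = 0.0001
    epochs: int = 2000
    batch_size: int = 16
    alpha: float = 0.8
    beta: float = 0.2
    from_scratch: bool = False
    epsilon: float = 1e-8
    ema_decay_start: float = 0.0
    ema_decay_end: float = 0.99
    ema_warmup_steps: int = 100
    seed: int = 0
    eval_every: int = 10

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")


@dataclass
class SplitPlan:
    """k-fold plan over non-test records, each fold a train:val = 8:2 split."""

    n_folds: int = 5
    train_fraction: float = 0.8
    test_ids: frozenset = frozenset()

    def split_sizes(self, n_records: int) -> tuple[int, int]:
        """(train, validation) sizes of one fold over ``n_records``."""
        n_val = round(n_records * (1.0 - self.train_fraction))
        return n_records - n_val, n_val

    def folds(self, n_records: int, seed: int = 0):
        kf = KFold(n_splits=self.n_folds, shuffle=True, random_state=seed)
        return list(kf.split(np.arange(n_records)))


@dataclass
class PairRecord:
    """Two tautomeric states with an experimental label.

    At least one of ``dG_exp`` (kcal/mol, convention E_water(B) − E_water(A),
    positive = A preferred) or ``preferred`` must be present.
    """

    smiles_a: str
    smiles_b: str
    conf_a: Conformer3D
    conf_b: Conformer3D
    z_a: np.ndarray
    z_b: np.ndarray
    dG_exp: float | None = None
    preferred: str | None = None  # "A" or "B"
    gas_targets: tuple[float, float] | None = None
    source: str = ""
    _graphs: tuple | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.dG_exp is None and self.preferred is None:
            raise ValueError("PairRecord needs dG_exp or preferred")
        if self.preferred not in (None, "A", "B"):
            raise ValueError("preferred must be 'A' or 'B'")

    def graphs(self, cutoff: float = 10.0) -> tuple[MolecularGraph, MolecularGraph]:
        if self._graphs is None:
            self._graphs = (
                build_graph(self.conf_a, atomic_numbers=self.z_a, cutoff=cutoff),
                build_graph(self.conf_b, atomic_numbers=self.z_b, cutoff=cutoff),
            )
        return self._graphs


# ---------------------------------------------------------------------------
# losses


def pretrain_loss(pred: Tensor | np.ndarray, target: np.ndarray) -> Tensor:
    """Sum over the three heads of the mean absolute error."""
    pred = pred if isinstance(pred, Tensor) else Tensor(pred)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return (pred - target).abs().mean(axis=0).sum()


def finetune_loss(
    dg_pred: Tensor | np.ndarray,
    dg_exp: np.ndarray,
    gas_pred: Tensor | np.ndarray | None = None,
    gas_target: np.ndarray | None = None,
    alpha: float = 0.8,
    beta: float = 0.2,
) -> Tensor:
    """Weighted L1: pairwise free-energy term plus optional gas anchor.

    The anchor averages over both pair members; when gas labels are absent
    the beta term is skipped (logged once by the caller).
    """
    dg_pred = dg_pred if isinstance(dg_pred, Tensor) else Tensor(dg_pred)
    dg_exp = np.asarray(dg_exp, dtype=float)
    if dg_pred.shape != dg_exp.shape:
        raise ValueError(f"shape mismatch: {dg_pred.shape} vs {dg_exp.shape}")
    loss = alpha * (dg_pred - dg_exp).abs().mean()
    if gas_pred is not None and gas_target is not None:
        gas_pred = gas_pred if isinstance(gas_pred, Tensor) else Tensor(gas_pred)
        gas_target = np.asarray(gas_target, dtype=float)
        if gas_pred.shape != gas_target.shape:
            raise ValueError("gas anchor shape mismatch")
        loss = loss + beta * (gas_pred - gas_target).abs().mean()
    return loss


# ---------------------------------------------------------------------------
# optimizer


class EmaAmsGrad:
    """AMSGrad with an exponential-moving-average shadow of the weights.

    The second-moment estimate keeps a running maximum (AMSGrad); there is
    no weight decay and no bias correction.  The EMA decay ramps linearly
    from ``decay_start`` to ``decay_end`` over ``warmup_steps`` so the
    shadow tracks the live weights closely at first.  Evaluation and
    checkpointing read the shadow.
    """

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        decay_start: float = 0.0,
        decay_end: float = 0.99,
        warmup_steps: int = 100,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.decay_start, self.decay_end = decay_start, decay_end
        self.warmup_steps = max(1, warmup_steps)
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.vhat = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.shadow = {k: v.data.copy() for k, v in params.items()}

    def current_decay(self) -> float:
        frac = min(1.0, self.t / self.warmup_steps)
        return self.decay_start + frac * (self.decay_end - self.decay_start)

    def step(self) -> None:
        self.t += 1
        decay = self.current_decay()
        for name, p in self.params.items():
            g = p.grad
            if g is None:
                g = np.zeros_like(p.data)
            if not np.isfinite(g).all():
                raise ValueError(f"non-finite gradient for parameter {name!r}")
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g**2
            self.vhat[name] = np.maximum(self.vhat[name], self.v[name])
            p.data = p.data - self.lr * self.m[name] / (np.sqrt(self.vhat[name]) + self.eps)
            self.shadow[name] = decay * self.shadow[name] + (1 - decay) * p.data

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def shadow_params(self) -> dict[str, Tensor]:
        return {k: parameter(v.copy()) for k, v in self.shadow.items()}


# ---------------------------------------------------------------------------
# checkpoints


@dataclass
class Checkpoint:
    """Trained weights + config + element shifts; the unit of model exchange."""

    params: dict[str, Tensor]
    config: ModelConfig
    shifts: np.ndarray
    provenance: dict = field(default_factory=dict)

    def predict(self, graphs: Sequence[MolecularGraph]) -> np.ndarray:
        """Energy triples (n, 3) in kcal/mol, element shifts restored."""
        batch = GraphBatch.from_graphs(list(graphs))
        out = forward_batch(self.params, batch, self.config).data
        return out + shift_energy(graphs, self.shifts, self.config.elements)

    def predict_pair_deltas(self, pairs: Sequence[PairRecord]) -> np.ndarray:
        graphs = []
        for rec in pairs:
            ga, gb = rec.graphs(self.config.cutoff)
            graphs.extend([ga, gb])
        out = forward_batch(self.params, GraphBatch.from_graphs(graphs), self.config).data
        water = out[:, WATER]  # shifts cancel in the within-pair difference
        return water[1::2] - water[0::2]

    def save(self, path) -> None:
        save_checkpoint(path, self.params, self.config, self.shifts, self.provenance)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        params, cfg, shifts, prov = load_checkpoint(path)
        if shifts is None:
            shifts = np.zeros((len(cfg.elements), cfg.n_heads))
        return cls(params, cfg, shifts, prov)


def _rmse_heads(pred: np.ndarray, target: np.ndarray) -> float:
    """Model-selection metric: RMSE per head, summed over the three heads."""
    err = pred - target
    return float(np.sqrt((err**2).mean(axis=0)).sum())


def _make_batches(n: int, batch_size: int, rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]


# ---------------------------------------------------------------------------
# pretraining


def run_pretraining(
    train: tuple[Sequence[MolecularGraph], np.ndarray],
    val: tuple[Sequence[MolecularGraph], np.ndarray],
    model_cfg: ModelConfig | None = None,
    cfg: PretrainConfig | None = None,
) -> tuple[Checkpoint, list[dict]]:
    """Multitask pretraining with best-on-validation checkpointing.

    ``train`` and ``val`` are disjoint (graphs, (n, 3) energy triples)
    splits.  Element reference shifts are fit on the training labels and
    subtracted before optimization; the checkpoint restores them at
    prediction.  Returns the best shadow-weight checkpoint and the
    training-curve log (one dict per evaluated epoch).
    """
    cfg = cfg or PretrainConfig()
    model_cfg = model_cfg or ModelConfig()
    train_graphs, train_y = list(train[0]), np.asarray(train[1], dtype=float)
    val_graphs, val_y = list(val[0]), np.asarray(val[1], dtype=float)

    shifts = fit_element_shifts(train_graphs, train_y, model_cfg.elements)
    train_res = train_y - shift_energy(train_graphs, shifts, model_cfg.elements)
    val_res = val_y - shift_energy(val_graphs, shifts, model_cfg.elements)

    rng = np.random.default_rng(cfg.seed)
    params = init_params(model_cfg, seed=cfg.seed)
    opt = EmaAmsGrad(
        params,
        lr=cfg.learning_rate,
        eps=cfg.epsilon,
        decay_start=cfg.ema_decay_start,
        decay_end=cfg.ema_decay_end,
        warmup_steps=cfg.ema_warmup_steps,
    )

    for g in train_graphs:
        g.ensure_rbf(model_cfg.rbf)  # cached per graph; batches reuse it
    val_batch = GraphBatch.from_graphs(val_graphs)

    best: Checkpoint | None = None
    best_rmse = math.inf
    history: list[dict] = []
    for epoch in range(1, cfg.epochs + 1):
        epoch_loss = 0.0
        for idx in _make_batches(len(train_graphs), cfg.batch_size, rng):
            batch = GraphBatch.from_graphs([train_graphs[i] for i in idx])
            target = train_res[idx]
            opt.zero_grad()
            loss = pretrain_loss(forward_batch(params, batch, model_cfg), target)
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite loss at epoch {epoch}", checkpoint=best)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
        n_batches = -(-len(train_graphs) // cfg.batch_size)
        if epoch % cfg.eval_every == 0 or epoch == cfg.epochs:
            shadow = opt.shadow_params()
            val_pred = forward_batch(shadow, val_batch, model_cfg).data
            val_rmse = _rmse_heads(val_pred, val_res)
            history.append(
                {"epoch": epoch, "train_loss": epoch_loss / n_batches, "val_rmse": val_rmse}
            )
            if val_rmse < best_rmse:
                best_rmse = val_rmse
                best = Checkpoint(
                    shadow,
                    model_cfg,
                    shifts,
                    provenance={"seed": cfg.seed, "best_epoch": epoch, "val_rmse": val_rmse},
                )
    assert best is not None
    return best, history


# ---------------------------------------------------------------------------
# fine-tuning


def _pair_batch(pairs: Sequence[PairRecord], cutoff: float) -> GraphBatch:
    graphs = []
    for rec in pairs:
        ga, gb = rec.graphs(cutoff)
        graphs.extend([ga, gb])
    return GraphBatch.from_graphs(graphs)


def _finetune_eval(params, pairs, batch, model_cfg) -> float:
    out = forward_batch(params, batch, model_cfg).data
    dg = out[1::2, WATER] - out[0::2, WATER]
    dg_exp = np.array([rec.dG_exp for rec in pairs])
    return float(np.sqrt(((dg - dg_exp) ** 2).mean()))


def _train_one_fold(
    init_checkpoint: Checkpoint | None,
    train_pairs: Sequence[PairRecord],
    val_pairs: Sequence[PairRecord],
    cfg: FinetuneConfig,
    model_cfg: ModelConfig,
    seed: int,
) -> tuple[Checkpoint, list[dict]]:
    rng = np.random.default_rng(seed)
    if init_checkpoint is not None and not cfg.from_scratch:
        params = clone_params(init_checkpoint.params)
        shifts = init_checkpoint.shifts
    else:
        params = init_params(model_cfg, seed=seed)
        shifts = np.zeros((len(model_cfg.elements), model_cfg.n_heads))
    opt = EmaAmsGrad(
        params,
        lr=cfg.learning_rate,
        eps=cfg.epsilon,
        decay_start=cfg.ema_decay_start,
        decay_end=cfg.ema_decay_end,
        warmup_steps=cfg.ema_warmup_steps,
    )

    have_gas = all(rec.gas_targets is not None for rec in train_pairs)
    if not have_gas and cfg.beta > 0:
        logger.warning("gas anchors missing on some records; beta term skipped")

    # per-record pieces, assembled into fresh minibatches every epoch
    pair_graphs, gas_res = [], []
    for rec in train_pairs:
        ga, gb = rec.graphs(model_cfg.cutoff)
        ga.ensure_rbf(model_cfg.rbf)
        gb.ensure_rbf(model_cfg.rbf)
        pair_graphs.append((ga, gb))
        if have_gas and cfg.beta > 0:
            raw = np.asarray(rec.gas_targets)
            gas_res.append(raw - shift_energy([ga, gb], shifts, model_cfg.elements)[:, GAS])
    dg_all = np.array([r.dG_exp for r in train_pairs])
    val_batch = _pair_batch(val_pairs, model_cfg.cutoff)

    best, best_rmse = None, math.inf
    history: list[dict] = []
    n_batches = -(-len(train_pairs) // cfg.batch_size)
    for epoch in range(1, cfg.epochs + 1):
        epoch_loss = 0.0
        for idx in _make_batches(len(train_pairs), cfg.batch_size, rng):
            batch = GraphBatch.from_graphs([g for i in idx for g in pair_graphs[i]])
            dg_exp = dg_all[idx]
            gas_target = np.concatenate([gas_res[i] for i in idx]) if gas_res else None
            opt.zero_grad()
            out = forward_batch(params, batch, model_cfg)
            water = out.col(WATER)
            n_pairs = len(dg_exp)
            dg_pred = water.take_rows(np.arange(1, 2 * n_pairs, 2)) - water.take_rows(
                np.arange(0, 2 * n_pairs, 2)
            )
            gas_pred = out.col(GAS) if gas_target is not None else None
            loss = finetune_loss(dg_pred, dg_exp, gas_pred, gas_target, cfg.alpha, cfg.beta)
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite loss at epoch {epoch}", checkpoint=best)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
        if epoch % cfg.eval_every == 0 or epoch == cfg.epochs:
            shadow = opt.shadow_params()
            val_rmse = _finetune_eval(shadow, val_pairs, val_batch, model_cfg)
            history.append(
                {"epoch": epoch, "train_loss": epoch_loss / n_batches, "val_rmse": val_rmse}
            )
            if val_rmse < best_rmse:
                best_rmse = val_rmse
                best = Checkpoint(
                    shadow,
                    model_cfg,
                    shifts,
                    provenance={"seed": seed, "best_epoch": epoch, "val_rmse": val_rmse},
                )
    assert best is not None
    return best, history


@dataclass
class CVResult:
    fold_checkpoints: list[Checkpoint]
    fold_val_rmse: list[float]
    histories: list[list[dict]]

    @property
    def mean_val_rmse(self) -> float:
        return float(np.mean(self.fold_val_rmse))

    def predict_pair_deltas(self, pairs: Sequence[PairRecord]) -> np.ndarray:
        """Fold-ensemble prediction: arithmetic mean over the fold models."""
        preds = np.stack([ckpt.predict_pair_deltas(pairs) for ckpt in self.fold_checkpoints])
        return preds.mean(axis=0)


def run_finetuning(
    init_checkpoint: Checkpoint | None,
    pairs: Sequence[PairRecord],
    plan: SplitPlan | None = None,
    cfg: FinetuneConfig | None = None,
    model_cfg: ModelConfig | None = None,
) -> CVResult:
    """k-fold Siamese fine-tuning with best-on-validation checkpoints.

    Records whose identifier is in ``plan.test_ids`` (by ``source``) are
    excluded from every fold.  Each fold trains on the remaining 80% and
    validates on the held 20%; inference averages the fold models.
    """
    plan = plan or SplitPlan()
    cfg = cfg or FinetuneConfig()
    if model_cfg is None:
        if init_checkpoint is None:
            raise ValueError("model_cfg required when training from scratch")
        model_cfg = init_checkpoint.config
    usable = [p for p in pairs if p.source not in plan.test_ids and p.dG_exp is not None]
    checkpoints, rmses, histories = [], [], []
    for fold_i, (train_idx, val_idx) in enumerate(plan.folds(len(usable), seed=cfg.seed)):
        if len(train_idx) < 2 or len(val_idx) < 1:
            raise ValueError(f"fold {fold_i} has too few records")
        ckpt, hist = _train_one_fold(
            init_checkpoint,
            [usable[i] for i in train_idx],
            [usable[i] for i in val_idx],
            cfg,
            model_cfg,
            seed=cfg.seed + fold_i,
        )
        checkpoints.append(ckpt)
        rmses.append(ckpt.provenance["val_rmse"])
        histories.append(hist)
        logger.info("fold %d: best val RMSE %.3f kcal/mol", fold_i, rmses[-1])
    return CVResult(checkpoints, rmses, histories)
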