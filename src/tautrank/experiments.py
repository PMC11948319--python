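"""Desk-scale benchmark experiments on the surrogate oracle.

These drive the full pipeline — generate oracle-labeled structures and
noisy experimental-style pairs, pretrain the multitask network, fine-tune
it in the Siamese configuration, and score held-out pairs — at problem
sizes a single CPU core handles in minutes:

* pretraining: 400 tautomeric states, small architecture (embedding 32,
  two interaction modules, 16 radial basis functions), 600 epochs;
* parameter recovery: 200 noisy pairs (noise 0.5 kcal/mol), 150 used for
  5-fold cross-validated fine-tuning (400 epochs, validation checked
  every 5) and 50 held out;
* pretrained-vs-scratch: 75 training pairs, two folds, 200 epochs, three
  seeds, scored on the same 50 held-out pairs.

The functions return plain dicts of scalars so callers (tests, the
acceptance script, notebooks) can assert or report without re-deriving
anything.
"""

from __future__ import annotations

import numpy as np

from .nn.model import ModelConfig, build_graph
from .synthetic import make_energy_dataset, make_pair_dataset
from .thermo import ranking_success_rate, rmse
from .training import (
    Checkpoint,
    FinetuneConfig,
    PretrainConfig,
    SplitPlan,
    run_finetuning,
    run_pretraining,
)

#: Small CPU-friendly architecture used by every experiment below: 32
#: radial basis functions give enough short-range resolution to separate
#: bond-length classes; two residual blocks per stage refine the atomic
#: contributions without leaving the small-model regime.
SMALL_MODEL = dict(embedding_dim=32, n_interaction=2, n_residual=2, n_output_residual=2, n_rbf=32)


def small_model_config() -> ModelConfig:
    return ModelConfig(**SMALL_MODEL)


def pretrain_surrogate(
    seed: int,
    n_molecules: int = 400,
    epochs: int = 600,
    n_conformers: int = 8,
    model_cfg: ModelConfig | None = None,
) -> tuple[Checkpoint, list[dict]]:
    """Pretrain the small model on oracle-labeled structures (1/5 held for
    validation and checkpoint selection)."""
    model_cfg = model_cfg or small_model_config()
    ds = make_energy_dataset(n_molecules, seed=seed, n_conformers=n_conformers)
    graphs = [build_graph(s.conf, atomic_numbers=s.z, cutoff=model_cfg.cutoff) for s in ds]
    y = np.array([s.triple.as_array() for s in ds])
    n_val = n_molecules // 5
    return run_pretraining(
        (graphs[n_val:], y[n_val:]),
        (graphs[:n_val], y[:n_val]),
        model_cfg=model_cfg,
        cfg=PretrainConfig(epochs=epochs, seed=seed, eval_every=10),
    )


def parameter_recovery(
    seed: int,
    n_pairs: int = 200,
    noise_sd: float = 0.5,
    n_heldout: int = 100,
    finetune_epochs: int = 400,
    pretrain_kwargs: dict | None = None,
    checkpoint: Checkpoint | None = None,
) -> dict:
    """Pretrain + 5-fold Siamese fine-tune on ``n_pairs``; score a disjoint
    held-out set.

    Returns ``heldout_rmse`` (kcal/mol), per-fold validation RMSEs, the
    ranking success rate on the held-out set, and the null RMSE of always
    predicting zero.
    """
    from .synthetic import pair_keys

    if checkpoint is None:
        checkpoint, _ = pretrain_surrogate(seed, **(pretrain_kwargs or {}))
    train = make_pair_dataset(n_pairs, noise_sd=noise_sd, seed=seed + 1, n_conformers=8)
    heldout = make_pair_dataset(
        n_heldout,
        noise_sd=noise_sd,
        seed=seed + 5,
        n_conformers=8,
        exclude_pairs=pair_keys(train),
    )
    cv = run_finetuning(
        checkpoint,
        train,
        plan=SplitPlan(n_folds=5),
        cfg=FinetuneConfig(epochs=finetune_epochs, seed=seed + 2, eval_every=5),
    )
    dg = np.array([p.dG_exp for p in heldout])
    pred = cv.predict_pair_deltas(heldout)
    pref = [p.preferred for p in heldout]
    return {
        "heldout_rmse": rmse(pred, dg),
        "heldout_success_rate": ranking_success_rate(pred, pref),
        "null_rmse": rmse(np.zeros_like(dg), dg),
        "fold_val_rmse": list(cv.fold_val_rmse),
        "n_train": len(train),
        "n_heldout": len(heldout),
        "checkpoint": checkpoint,
        "cv": cv,
        "train_pairs": train,
        "heldout_pairs": heldout,
    }


def finetune_vs_scratch(
    seed: int,
    checkpoint: Checkpoint,
    n_train_pairs: int = 75,
    n_heldout: int = 100,
    n_seeds: int = 3,
    epochs: int = 200,
    n_folds: int = 2,
    noise_sd: float = 0.5,
    train_pairs=None,
    heldout=None,
) -> dict:
    """Fine-tuned vs trained-from-scratch at a small training budget.

    Both protocols see the same pairs, folds and seeds; the only
    difference is the initialization.  Callers running several
    experiments pass ``train_pairs``/``heldout`` to reuse one dataset
    (the training budget is the first ``n_train_pairs`` records).
    Returns the per-seed held-out RMSEs and their means.
    """
    from .synthetic import pair_keys

    if train_pairs is None:
        train_pairs = make_pair_dataset(
            n_train_pairs, noise_sd=noise_sd, seed=seed + 1, n_conformers=8
        )
    if heldout is None:
        heldout = make_pair_dataset(
            n_heldout,
            noise_sd=noise_sd,
            seed=seed + 5,
            n_conformers=8,
            exclude_pairs=pair_keys(train_pairs),
        )
    train = list(train_pairs)[:n_train_pairs]
    dg = np.array([p.dG_exp for p in heldout])
    ft_rmse, sc_rmse = [], []
    for k in range(n_seeds):
        run_seed = seed + 10 + k
        common = dict(epochs=epochs, seed=run_seed, eval_every=5)
        ft = run_finetuning(
            checkpoint, train, SplitPlan(n_folds=n_folds), FinetuneConfig(**common)
        )
        sc = run_finetuning(
            checkpoint,
            train,
            SplitPlan(n_folds=n_folds),
            FinetuneConfig(from_scratch=True, **common),
            model_cfg=checkpoint.config,
        )
        ft_rmse.append(rmse(ft.predict_pair_deltas(heldout), dg))
        sc_rmse.append(rmse(sc.predict_pair_deltas(heldout), dg))
    return {
        "finetuned_rmse": ft_rmse,
        "scratch_rmse": sc_rmse,
        "finetuned_mean_rmse": float(np.mean(ft_rmse)),
        "scratch_mean_rmse": float(np.mean(sc_rmse)),
        "n_train": len(train),
        "n_heldout": len(heldout),
    }
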