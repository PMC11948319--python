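# tautrank

Predicting which tautomer of a drug-like molecule dominates in water.

A molecule with labile protons is not one structure but an equilibrium
mixture of tautomers, and the state that dominates in aqueous solution
decides the hydrogen-bond pattern a binding site actually sees.  The
experimental tautomer ratio K is related to the free-energy difference by

    ΔG = −RT ln K        (R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹, T = 298.15 K)

so ranking tautomers means predicting pairwise aqueous free-energy
differences to about a kcal/mol.

`tautrank` is a complete pipeline for this problem, aimed at
computational chemists who need fast aqueous tautomer ranking and at
method developers who want every stage testable on one CPU:

1. **Enumeration** — prototropic transformation rules (reaction SMIRKS
   with the migrating hydrogen explicitly mapped) applied as a
   breadth-first closure with ≤5 rounds, plus a pluggable fallback
   enumerator.
2. **Geometry** — ETKDG conformers optimized with MMFF94 (RDKit), keeping
   the lowest-energy conformer per state, with an identity filter that
   re-perceives bonds from the optimized 3D structure.
3. **Energy model** — a multitask atomic-contribution message-passing
   network (PhysNet lineage): radial-basis distance features under a
   10 Å cutoff, element embeddings, gated interaction modules with
   residual refinement, and per-atom sums into three heads
   (E_gas, E_water, ΔE_transfer), in kcal/mol.  The network, its
   gradients, and the EmaAmsGrad optimizer (AMSGrad with an
   exponential-moving-average shadow of the weights) are implemented in
   NumPy over a small reverse-mode autodiff tape.
4. **Siamese fine-tuning** — the pairwise prediction is
   ΔG_pred = E_water(B) − E_water(A) with shared weights; training
   minimizes α·L1(ΔG) + β·L1(E_gas anchors) with α = 0.8, β = 0.2, under
   5-fold cross-validation (8:2 train:validation per fold) with
   best-on-validation checkpointing and fold-mean inference.
5. **Ranking** — Boltzmann populations of the enumerated states and a
   low-energy flag for states within 2.76 kcal/mol (the 1 %-ratio
   convention) of the minimum.
6. **Surrogate oracle** — an analytic extensive energy function
   (per-element terms + bond-length wells + λ per polar hydrogen) that
   labels molecules and pairs so pretraining, fine-tuning and ranking are
   exercised end-to-end with no quantum chemistry and no downloads.

See `docs/methods.md` for the model, training protocols, surrogate
design, and numerical choices.

## Worked example

Enumerate and rank the tautomers of 2-pyridone with a freshly trained
surrogate model:

```bash
# pretrain a small model on surrogate-labeled fixtures (~4 min, one core)
cat > /tmp/train.yaml <<'YAML'
model: {embedding_dim: 32, n_interaction: 2, n_residual: 2, n_output_residual: 2, n_rbf: 32}
pretrain: {epochs: 600, eval_every: 10}
data: {n_molecules: 400, n_conformers: 8}
YAML
taut train pretrain --config /tmp/train.yaml --seed 1 --out /tmp/model.npz

# rank the tautomeric states of 2-pyridone
taut rank --smiles "O=c1cccc[nH]1" --model /tmp/model.npz --nconfs 8 --seed 1
```

which prints

```
LOW    0.000 kcal/mol  pop 0.6215  Oc1ccccn1
LOW    0.659 kcal/mol  pop 0.2043  O=C1C=CCC=N1
LOW    0.758 kcal/mol  pop 0.1729  O=C1CC=CC=N1
       3.643 kcal/mol  pop 0.0013  O=c1cccc[nH]1
```

Four prototropic states were enumerated and ranked by predicted relative
energy in water; `pop` is each state's Boltzmann fraction at 298.15 K
and `LOW` marks states inside the 2.76 kcal/mol low-energy cutoff.  The
ordering faithfully reproduces the *surrogate oracle's* ground truth
(which, for these four states, is 0.00 / 0.40 / 0.72 / 2.89 kcal/mol) —
note that the surrogate's bond-energy terms happen to favor the lactim
here, whereas real aqueous chemistry favors the lactam: weights trained
on surrogate labels validate the pipeline, not experimental tautomer
chemistry.  A model intended for real predictions must be pretrained on
quantum-chemistry labels and fine-tuned on experimental ratio data.
`taut pair`, `taut evaluate`, `taut curate` and
`taut fixtures` cover pairwise prediction, dataset metrics (RMSE / MAE /
ranking success rate), five-rule curation of experimental records, and
surrogate dataset generation; the same functionality is available as a
library, including scikit-learn-style estimators
(`tautrank.estimators.EnergyNetRegressor`, `PairDeltaRegressor`).

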