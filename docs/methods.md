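# Methods

## Problem

A molecule with labile protons exists in solution as an equilibrium
mixture of tautomers.  Which state dominates in water decides the
hydrogen-bonding pattern a receptor sees, so getting the aqueous tautomer
ratio right matters for virtual screening and lead optimization.  The
experimental quantity is the equilibrium constant, recorded as
log10 K and converted to a free energy by ΔG = −RT ln K
(R = 1.98720425×10⁻³ kcal/(mol·K); T defaults to 298.15 K wherever a
temperature is not recorded).

`tautrank` implements the full prediction pipeline: rule-based tautomer
enumeration, force-field geometry selection, a multitask atomic-energy
neural network with a Siamese pairwise head, two-stage training
(pretraining on labeled structures, fine-tuning on experimental pairs),
and Boltzmann ranking with a low-energy cutoff.

## Tautomer enumeration

Prototropic transformations are reaction SMIRKS applied with RDKit.  The
shipped rule file covers the common motifs (1,3- and 1,5-keto-enol,
amide/imidic acid, thioamide, imine/enamine, nitroso/oxime, amidine, and
an aza-1,5 shift); the file format (`id<TAB>name<TAB>SMIRKS`) accepts any
larger published set verbatim.  Rules are written with the migrating
hydrogen explicitly atom-mapped and are applied to kekulized molecules
with explicit hydrogens, which makes hydrogen bookkeeping exact: every
product must retain the parent's molecular formula or it is dropped with
a warning.  Hydrogen-donor carbons are constrained to sp³ (`C;X4`) so
shifts never manufacture in-ring cumulenes.

Enumeration is a breadth-first closure: round *k* applies every rule to
every state first reached in round *k−1*, deduplicating by canonical
SMILES, stopping at closure or after `max_rounds` (default 5) rounds.  A
configurable ceiling (default 256 states) guards against combinatorial
blow-up.  If the rules produce nothing beyond the parent, a pluggable
fallback enumerator is consulted (default: RDKit's tautomer enumerator)
and its products are kept only when they form a prototropic pair with the
parent — same formula, identical heavy-atom skeleton with bond orders
erased, different canonical form.

## Geometry

Each state is embedded with ETKDG and optimized with MMFF94 inside RDKit;
among `n_conformers` attempts (default 300; desk-scale runs use 4–8, see
below) the lowest-energy optimized conformer becomes the model input.
The geometry stage is a backend contract (`embed` + `optimize`) so a
quantum-chemistry optimizer, or a deterministic stub for unit tests, can
be slotted in.  An identity filter re-perceives bonds from the optimized
3D coordinates and rejects structures that walked to a different tautomer
or broke apart.  All embeddings are seeded; a fixed seed reproduces
coordinates bit-for-bit.

## Energy model

The network follows the PhysNet lineage of atomic-contribution models.

* **Input.** The distance graph: every ordered atom pair closer than the
  cutoff (default 10 Å) is an edge carrying its distance.  Distances are
  expanded in `n_rbf` Gaussian radial basis functions on exponentially
  spaced centers in (0.8 Å, cutoff], multiplied by a cosine cutoff
  envelope ½(cos(πr/r_c)+1), so every feature lies in [0, 1] and decays
  smoothly to exactly zero at the cutoff.
* **Embedding.** Element types map to learned vectors (dimension
  `embedding_dim`, default 128; supported elements H, C, N, O, F, P, S,
  Cl, Br).
* **Interaction modules** (default 3): an edge filter (linear map of the
  radial features), messages formed from transformed source-node features
  gated by the filter and scatter-summed onto destinations, a shifted-
  softplus update, `n_residual` pre-activation residual blocks, and a
  learned per-feature gate `x ← u ⊙ x + x_new`.
* **Output.** Residual refinement followed by a linear head producing
  three per-atom energies — gas-phase, aqueous, and transfer
  (ΔE_transfer = E_water − E_gas as a *trained* third target, not a hard
  constraint; the difference identity can be monitored as a diagnostic).
  Molecular energies are sums over atoms, which makes predictions exactly
  extensive, and permutation/rotation/translation invariant because only
  pair distances enter.

Before training, per-element reference energies are fit by least squares
on the training compositions and subtracted from the labels; they are
restored at prediction.  Extensive energies grow with atom count, and
removing the composition-explained part is what makes the regression
well-conditioned.  Internal units are kcal/mol throughout; readers may
convert from Hartree (×627.509) when flagged.

The network, its gradients, and the optimizer are implemented in NumPy
over a small reverse-mode autodiff tape (float64), which keeps the whole
training path dependency-light and lets analytic gradients be verified
against central finite differences to better than 1e-4 relative error.

### Siamese pairwise head

For a tautomer pair (A, B), both graphs pass through the *same* weights
and the prediction is ΔG_pred = E_water(B) − E_water(A); positive values
mean state A is more stable in water.  Each branch is evaluated through
an identical single-graph code path, so the delta is exactly
antisymmetric and exactly zero for identical inputs, independent of
floating-point summation order.

## Training

* **Pretraining loss**: sum over the three heads of the mean absolute
  error.  Default 500 epochs, learning rate 0.001, batch size 32.
* **Fine-tuning loss**: α·mean|ΔG_pred − ΔG_exp| + β·mean|E_gas_pred −
  E_gas_target| with α = 0.8, β = 0.2; the gas anchor averages over both
  pair members and is skipped (with a logged warning) when gas labels are
  absent.  Default 2000 epochs, learning rate 0.0001, batch size 16
  pairs.
* **Optimizer**: AMSGrad (running max of the second moment, β₁ = 0.9,
  β₂ = 0.999, ε = 1e-8, no weight decay, no bias correction) with an
  exponential-moving-average shadow copy of the weights.  The EMA decay
  ramps linearly from 0.0 to 0.99 over a warm-up (default 100 steps) so
  the shadow tracks the live weights early; a fixed "0.0 to 0.99" range
  only makes sense as this EMA schedule, not as an Adam moment
  coefficient.  Validation and checkpointing always read the shadow.
* **Model selection**: the checkpoint is the shadow state at the epoch of
  minimal validation RMSE (for pretraining: RMSE per head, summed over
  the three heads; configurable).
* **Cross-validation**: fine-tuning uses k-fold CV (default 5); each fold
  trains on 80% and validates on the held 20%, so 383 records split
  306/77.  Records named in the plan's test set are excluded from every
  fold.  Inference averages the fold models (arithmetic mean;
  configurable to single-fold).  Minibatches are recomposed from a fresh
  seeded shuffle every epoch (radial features are computed once per graph
  and concatenated per minibatch, so this costs almost nothing); with a
  fixed seed entire runs are bit-reproducible.

## Ranking workflow

For one input molecule: enumerate (≤5 rounds) → lowest-energy conformer
per state (states whose geometry fails are dropped with a warning) →
aqueous energy per state (fold-mean over checkpoints) → relative energies
against the minimum → Boltzmann populations exp(−ΔG/RT)/Σ → low-energy
flag for states within the cutoff.  The cutoff default is 2.76 kcal/mol,
the conventional "1% tautomer ratio" threshold; the boundary is
inclusive (≤).  The constant is kept at 2.76 even though −RT ln(0.01) at
298.15 K is 2.729 kcal/mol — the published convention is treated as a
convention, not silently recorrected, and it is configurable.  Ranking
uses the aqueous head only; gas-phase and transfer energies are attached
as diagnostics.  Ties in relative energy are broken by canonical SMILES
so reports are byte-reproducible.

Evaluation metrics are RMSE and MAE over records with quantitative ΔG,
and the ranking success rate — the fraction of pairs whose predicted sign
names the experimentally preferred state — over preference-only records.
A predicted ΔG of exactly 0 counts as a failure (no preference
expressed).

## Curation

Raw records are filtered by five rules (water; logK present; all atoms
formally neutral; elements within H/C/N/O/S/P/F/Cl/Br; prototropic pair)
plus a challenge-set exclusion list matched by canonical SMILES of either
member.  Neutrality is per-atom (zwitterions excluded) rather than
net-charge; the flag `per_atom=False` relaxes this.  Solvent matching is
case-insensitive with a synonym list ("water", "H2O", "aqueous", "aq").
Unparsable records are tallied, not fatal; rejections are tallied by the
first failing rule.  The ΔG sign convention assumed by the readers:
logK refers to K = [B]/[A], so ΔG = −RT ln K is the B-minus-A free-energy
difference, matching the Siamese output convention.  The shipped
exclusion file is a synthetic stand-in (marked as such in its header);
reproducing a published curation requires the real challenge-set list.

## Surrogate oracle and synthetic data

Desk-scale experiments need labels without quantum chemistry or
databases.  The oracle is an analytic, extensive energy:

    E_gas*   = Σ_atoms element term + Σ_bonded pairs −D·exp(−(r−r₀)²/2w²)
    E_water* = E_gas* + λ·(#O–H + #N–H)

with D = 30 kcal/mol, r₀ = 1.45 Å, w = 0.35 Å, λ = −2 kcal/mol per polar
hydrogen.  Tautomers differ in bond orders, hence in MMFF94 bond lengths,
hence in oracle bond energies; the λ term adds a solvation-driven gap
proportional to the polar-hydrogen count.  λ's magnitude was chosen to
give pair free-energy gaps of a few kcal/mol, the spread seen in aqueous
experimental tautomer data.  Pair records carry
ΔG = E_water*(B) − E_water*(A) + N(0, noise_sd) with noise_sd 0.5
kcal/mol by default (roughly the reproducibility of experimental ratio
measurements), plus noise-free gas-phase anchors.

The fixture library is ~52 curated parents spanning keto-enol, amide,
heteroaromatic, oxime, amidine and thioamide motifs, optionally extended
by template substitution (15 scaffolds × 6 substituents) to the few
hundred states pretraining needs.  Generators are fully seeded; per-state
embedding seeds derive from a CRC of the canonical SMILES so datasets are
reproducible regardless of generation order.

What the oracle does *not* emulate: electronic effects beyond
composition and bond lengths, conformational entropy, intramolecular
hydrogen bonding, and real solvation physics.  Passing the surrogate
benchmarks therefore demonstrates that the architecture, losses,
optimizer and protocols can recover a planted structure-energy
relationship from noisy pairwise data — not that this small model
reproduces experimental accuracies, which require pretraining on
hundreds of thousands of quantum-chemistry labels.

## Desk-scale benchmark sizes

The benchmark experiments (`tautrank.experiments`) use a small
architecture — embedding 32, two interaction modules, two residual blocks
per stage, 32 radial basis functions (enough short-range resolution to
separate bond-length classes; 16 under-resolve them and 64 overfit at
this data size) — and problem sizes chosen so the whole pipeline runs in
minutes on one CPU core:

* pretraining: 400 oracle-labeled states (80 validation), 600 epochs,
  8 conformers per state;
* parameter recovery: 5-fold Siamese fine-tuning on 200 noisy pairs
  (noise 0.5), 400 epochs with validation checked every 5 epochs (the
  best validation point arrives early), scored on a disjoint 100-pair
  held-out set drawn from the same pool with overlap excluded;
* pretrained-vs-scratch: the first 75 of those training pairs, 2 folds,
  200 epochs, three seeds, scored on the same held-out set — the same
  pairs, folds and seeds for both arms, so initialization is the only
  difference.

Two coverage rules keep these benchmarks well-posed.  The extended parent
pool is deliberately sized (~550 states) so that a 400-label pretraining
set covers most of the chemistry the pair records draw on — the
desk-scale analogue of pretraining on a corpus that spans the evaluation
space.  And the generator emits only elements that occur in many
structures (H, C, N, O, S, F, Cl): a lone-element structure would leave
its least-squares reference shift unconstrained whenever it falls
entirely in one split.

## Numerical choices and edge cases

* Radial features are bounded in [0, 1]; zero or negative distances are
  an error (coincident atoms are rejected when the graph is built).
* The output head is zero-initialized, so an untrained network predicts
  exactly the element-shift baseline.
* Divergence (non-finite loss) aborts training and surfaces the last
  good checkpoint; non-finite gradients raise with the parameter name.
* Empty state lists, empty metric inputs, and fold sizes below two
  records raise immediately rather than producing silent nonsense.
* Checkpoints are single-file archives carrying the config echo,
  parameter tensors, element-shift table and provenance (seed, package
  version); determinism is guaranteed within one RDKit version, which is
  recorded in output metadata.

## Known limitations

* The rule file is a representative subset; exotic prototropy (ring-chain
  or valence tautomerism, stereochemistry across shifts) is out of scope.
* Only the lowest force-field conformer per state is scored — no ensemble
  Boltzmann averaging over conformers.
* Element coverage is fixed at curation's nine-element set.
* The quantum-chemistry stage of the original data-preparation recipe is
  a backend slot; this package never runs DFT.
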