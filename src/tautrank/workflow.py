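"""End-to-end workflow: enumerate, embed, predict, rank, evaluate.

``rank_tautomers`` runs the whole user-facing pipeline for one input
molecule: tautomer enumeration (rule closure, at most five rounds),
lowest-energy MMFF94 conformer per state, aqueous-energy prediction
(fold-mean when several checkpoints are supplied), ranking by relative
energy in water, Boltzmann populations, and the low-energy cutoff flag.
Gas-phase and transfer energies are attached as diagnostics only; the
ranking uses the aqueous head alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem import Molecule, canonical_form, elements_allowed, is_neutral, parse_structure
from .geometry import EmbedConfig, GeometryBackend, GeometryError, RDKitBackend, lowest_energy_conformer
from .nn.model import build_graph
from .tautomers import TransformationRule, enumerate_tautomers, load_rules
from .thermo import LOW_ENERGY_CUTOFF, RankedState, low_energy_states, mae, populations, ranking_success_rate, rmse
from .training import Checkpoint, PairRecord

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for one ranking run."""

    n_conformers: int = 300
    seed: int = 0
    max_rounds: int = 5
    energy_cutoff: float = LOW_ENERGY_CUTOFF  # kcal/mol
    temperature: float = 298.15  # K


@dataclass
class RankingReport:
    """Ranked tautomeric states of one input, sorted by relative energy."""

    input_smiles: str
    states: list[RankedState]
    provenance: dict = field(default_factory=dict)

    def low_energy(self) -> list[RankedState]:
        return [s for s in self.states if s.low_energy]

    def to_dict(self) -> dict:
        return {
            "input": self.input_smiles,
            "states": [
                {
                    "smiles": s.smiles,
                    "relative_energy_kcal_mol": s.relative_energy,
                    "population": s.population,
                    "low_energy": s.low_energy,
                    "diagnostics": s.diagnostics,
                }
                for s in self.states
            ],
            "provenance": self.provenance,
        }


def _predict_water_energies(
    checkpoints: Sequence[Checkpoint], graphs
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fold-mean (E_gas, E_water, dE_transfer) columns for a graph list."""
    preds = np.stack([ckpt.predict(graphs) for ckpt in checkpoints])
    mean = preds.mean(axis=0)
    return mean[:, 0], mean[:, 1], mean[:, 2]


def rank_tautomers(
    smiles: str,
    checkpoints: Checkpoint | Sequence[Checkpoint],
    rules: Sequence[TransformationRule] | None = None,
    cfg: RunConfig | None = None,
    backend: GeometryBackend | None = None,
) -> RankingReport:
    """Rank the tautomeric states of one molecule by predicted aqueous energy.

    States whose geometry stage fails are dropped with a warning; if every
    state fails, a :class:`GeometryError` propagates.  Ties in relative
    energy are broken by canonical SMILES so reports are reproducible.
    """
    cfg = cfg or RunConfig()
    if isinstance(checkpoints, Checkpoint):
        checkpoints = [checkpoints]
    backend = backend or RDKitBackend()
    rules = load_rules() if rules is None else rules

    mol = parse_structure(smiles)
    if not is_neutral(mol):
        raise ValueError(f"input must be neutral: {smiles!r}")
    if not elements_allowed(mol):
        raise ValueError(f"input contains unsupported elements: {smiles!r}")

    taut_set = enumerate_tautomers(mol, rules, max_rounds=cfg.max_rounds)
    embed_cfg = EmbedConfig(n_conformers=cfg.n_conformers, seed=cfg.seed)

    states, graphs = [], []
    for smi in taut_set.members:
        state = parse_structure(smi)
        try:
            conf = lowest_energy_conformer(state, backend, embed_cfg)
        except GeometryError as exc:
            warnings.warn(f"dropping state {smi!r}: {exc}", stacklevel=2)
            continue
        z = [a.GetAtomicNum() for a in Chem.AddHs(state.rdmol).GetAtoms()]
        graphs.append(build_graph(conf, atomic_numbers=z, cutoff=checkpoints[0].config.cutoff))
        states.append(smi)
    if not states:
        raise GeometryError(f"no state of {smiles!r} could be embedded")

    e_gas, e_water, e_trans = _predict_water_energies(checkpoints, graphs)
    rel = e_water - e_water.min()
    order = sorted(range(len(states)), key=lambda i: (rel[i], states[i]))
    pops = populations(rel[order], T=cfg.temperature)
    ranked = [
        RankedState(
            smiles=states[i],
            relative_energy=float(rel[i]),
            population=float(p),
            diagnostics={
                "E_gas": float(e_gas[i]),
                "E_water": float(e_water[i]),
                "dE_transfer": float(e_trans[i]),
            },
        )
        for i, p in zip(order, pops)
    ]
    low_energy_states(ranked, cutoff=cfg.energy_cutoff)
    return RankingReport(
        input_smiles=canonical_form(mol),
        states=ranked,
        provenance={
            "n_states_enumerated": len(taut_set.members),
            "fallback_used": taut_set.fallback_used,
            "n_checkpoints": len(checkpoints),
            "seed": cfg.seed,
            "n_conformers": cfg.n_conformers,
            "energy_cutoff": cfg.energy_cutoff,
        },
    )


def evaluate_dataset(
    pairs: Sequence[PairRecord],
    checkpoints: Checkpoint | Sequence[Checkpoint],
) -> dict:
    """RMSE/MAE on records with experimental ΔG and ranking success rate on
    records with a preferred state, plus a per-record residual table."""
    if isinstance(checkpoints, Checkpoint):
        checkpoints = [checkpoints]
    if not pairs:
        raise ValueError("empty dataset")
    preds = np.stack([ckpt.predict_pair_deltas(pairs) for ckpt in checkpoints]).mean(axis=0)

    rows = []
    for rec, dg_pred in zip(pairs, preds):
        rows.append(
            {
                "source": rec.source,
                "smiles_a": rec.smiles_a,
                "smiles_b": rec.smiles_b,
                "dG_pred": float(dg_pred),
                "dG_exp": rec.dG_exp,
                "preferred": rec.preferred,
                "residual": (float(dg_pred) - rec.dG_exp) if rec.dG_exp is not None else None,
            }
        )
    with_dg = [(r["dG_pred"], r["dG_exp"]) for r in rows if r["dG_exp"] is not None]
    with_pref = [(r["dG_pred"], r["preferred"]) for r in rows if r["preferred"] in ("A", "B")]
    report: dict = {"n_records": len(rows), "records": rows}
    if with_dg:
        p, t = zip(*with_dg)
        report["rmse"] = rmse(p, t)
        report["mae"] = mae(p, t)
    if with_pref:
        p, f = zip(*with_pref)
        report["ranking_success_rate"] = ranking_success_rate(p, f)
    return report
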