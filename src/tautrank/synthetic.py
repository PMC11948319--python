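"""Surrogate oracle and dataset generators for desk-scale experiments.

The oracle is an analytic, extensive energy function that stands in for
quantum-chemistry labels and experimental measurements:

    E_gas*   = Σ_atoms element term  +  Σ_bonded pairs well(r_ij)
    E_water* = E_gas* + λ · (number of O–H and N–H bonds)
    ΔE*      = E_water* − E_gas*

The pairwise well is a Gaussian in the bond length, so tautomers — which
differ in bond orders and therefore in force-field bond lengths — acquire
distinct, geometry-dependent energies; the polar-hydrogen term λ gives
tautomer pairs a nonzero solvation-driven free-energy gap of realistic
magnitude (λ defaults to −2 kcal/mol per polar H, about the spread of
experimental aqueous tautomer ratios).  Experimental-style pair records add
Gaussian noise to the oracle gap.  Everything is seeded and reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem import Conformer3D, Molecule, canonical_form, parse_structure
from .geometry import EmbedConfig, GeometryBackend, GeometryError, RDKitBackend, lowest_energy_conformer
from .nn.model import EnergyTriple
from .tautomers import TransformationRule, enumerate_tautomers, load_rules
from .training import PairRecord

#: ~50 small neutral molecules spanning keto-enol, amide, heteroaromatic,
#: oxime, amidine and thioamide motifs; every training path is exercised on
#: tautomers enumerated from these parents.  Elements are limited to
#: H/C/N/O/S/F/Cl so that every element the oracle emits appears in many
#: structures (a lone-element structure would leave its reference-energy
#: shift unconstrained on some splits).
FIXTURE_LIBRARY: tuple[str, ...] = (
    "CC(C)=O", "CCC(C)=O", "CC(=O)CC(C)=O", "CC(=O)CC(=O)OC", "O=C1CCCCC1",
    "CC(N)=O", "CCC(N)=O", "CC(=O)NC", "O=C1CCCN1", "O=C1CCCCN1",
    "O=c1cccc[nH]1", "Cn1ccccc1=O", "Cc1ccc(O)cc1", "Oc1ccccn1",
    "CC(=N)N", "NC(=N)N", "CC(=S)N", "NC(=S)N", "CC=NO", "CCC=NO",
    "O=C1NC=CC=N1", "O=c1ccoc(C)c1", "CC(=O)C=C",
    "CC(=O)c1ccccc1", "C=C(O)C", "CC(O)=CC(C)=O", "O=C1CC(=O)CC(=O)C1",
    "CC(=O)CC#N", "N#CCC(N)=O", "O=C1NC(=O)NC(=O)C1", "Cc1cc[nH]n1",
    "c1cc[nH]n1", "Cc1cn[nH]c1", "CC1=NNC(=O)C1",
    "CC(=O)NN", "CNC(C)=O", "CC(=O)NCC", "CC(=O)NCC(C)=O",
    "CC(=O)CF", "CC(=O)CCl", "NC(=O)CCl", "CSC(C)=O",
    "CC(=O)CS", "CC(=O)C(C)=O", "NC(=O)C=O", "CC=O",
    "CCC=O", "OCC=O", "CC(=O)CO", "O=C1CCC(=O)N1", "CC1=CC(=O)CC(C)(C)C1",
    "CC(=O)CCC(N)=O", "O=C1CCCC(=O)N1",
)


#: Scaffold templates with one substitution point, expanded combinatorially
#: with small substituents to give the extended library that pretraining
#: draws on (a few hundred states once tautomers are enumerated).
SCAFFOLD_TEMPLATES: tuple[str, ...] = (
    "{R}CC(C)=O", "{R}CC(N)=O", "CC(=O)C({R})C(C)=O", "{R}CC=NO",
    "CC(=O)N{R}", "{R}C1CCC(=O)N1", "O=c1ccc({R})c[nH]1", "Cc1cc({R})[nH]n1",
    "{R}CC(=O)CC(C)=O", "{R}C(=S)N", "{R}C(=N)N", "O=C1CC({R})C(=O)N1",
    "{R}c1ccc(O)nc1", "CC(=O)C(=O){R}", "{R}CC(=O)CO",
)

#: Kept small on purpose: the extended pool (~550 states) is sized so a
#: few-hundred-label pretraining set covers most of the chemistry the pair
#: records draw on, mirroring the intended regime of broad pretraining
#: coverage over the evaluation space.
SUBSTITUENTS: tuple[str, ...] = ("C", "CC", "F", "Cl", "O", "N")


def fixture_library(extended: bool = False) -> list[str]:
    """Canonical SMILES of the fixture molecules (parse-checked).

    With ``extended=True`` the curated list is augmented with template
    expansions of the same motifs, giving the larger parent pool that the
    pretraining generator needs.
    """
    seen: set[str] = set()
    out: list[str] = []

    def add(smi: str) -> None:
        can = canonical_form(parse_structure(smi))
        if can not in seen:
            seen.add(can)
            out.append(can)

    for smi in FIXTURE_LIBRARY:
        add(smi)
    if extended:
        from .chem import elements_allowed, is_neutral

        for template in SCAFFOLD_TEMPLATES:
            for sub in SUBSTITUENTS:
                try:
                    mol = parse_structure(template.format(R=sub))
                except Exception:
                    continue
                if is_neutral(mol) and elements_allowed(mol):
                    add(canonical_form(mol))
    return out


@dataclass
class SurrogateOracle:
    """Analytic stand-in for quantum-chemistry and experimental labels."""

    element_terms: dict[int, float] = field(
        default_factory=lambda: {
            1: -12.0, 6: -38.0, 7: -55.0, 8: -72.0, 9: -25.0,
            15: -46.0, 16: -33.0, 17: -29.0, 35: -27.0,
        }
    )
    well_depth: float = 30.0  # kcal/mol
    well_r0: float = 1.45  # Å, equilibrium length of the pairwise well
    well_width: float = 0.35  # Å
    lam: float = -2.0  # kcal/mol per polar hydrogen (O–H, N–H)
    noise_sd: float = 0.0  # kcal/mol, applied by dataset generators

    def _bond_energy(self, r: float) -> float:
        return -self.well_depth * float(np.exp(-((r - self.well_r0) ** 2) / (2 * self.well_width**2)))

    def label(self, mol: Molecule, conf: Conformer3D) -> EnergyTriple:
        """Noise-free oracle energies for one conformer."""
        rdmol = Chem.AddHs(Chem.Mol(mol.rdmol))
        if rdmol.GetNumAtoms() != conf.n_atoms:
            raise ValueError("conformer must include explicit hydrogens")
        coords = np.asarray(conf.coordinates)
        e_gas = sum(self.element_terms[a.GetAtomicNum()] for a in rdmol.GetAtoms())
        n_polar_h = 0
        for bond in rdmol.GetBonds():
            i, j = bond.GetBeginAtom(), bond.GetEndAtom()
            r = float(np.linalg.norm(coords[i.GetIdx()] - coords[j.GetIdx()]))
            e_gas += self._bond_energy(r)
            zs = {i.GetAtomicNum(), j.GetAtomicNum()}
            if 1 in zs and (7 in zs or 8 in zs):
                n_polar_h += 1
        e_water = e_gas + self.lam * n_polar_h
        return EnergyTriple(float(e_gas), float(e_water), float(e_water - e_gas))


def oracle_label(mol: Molecule, conf: Conformer3D, oracle: SurrogateOracle) -> EnergyTriple:
    return oracle.label(mol, conf)


@dataclass
class LabeledStructure:
    """A structure with oracle energy labels: one pretraining sample."""

    smiles: str
    z: np.ndarray  # atomic numbers, explicit hydrogens included
    conf: Conformer3D
    triple: EnergyTriple


def _state_seed(smiles: str, base_seed: int) -> int:
    return int((zlib.crc32(smiles.encode()) + base_seed) % (2**31 - 1))


class _ConformerCache:
    """Embed each unique state once per (seed, n_conformers) setting."""

    def __init__(self, backend: GeometryBackend, n_conformers: int, base_seed: int):
        self.backend = backend
        self.n_conformers = n_conformers
        self.base_seed = base_seed
        self._cache: dict[str, tuple[Molecule, Conformer3D] | None] = {}

    def get(self, smiles: str) -> tuple[Molecule, Conformer3D] | None:
        if smiles not in self._cache:
            mol = parse_structure(smiles)
            cfg = EmbedConfig(n_conformers=self.n_conformers, seed=_state_seed(smiles, self.base_seed))
            try:
                conf = lowest_energy_conformer(mol, self.backend, cfg)
            except GeometryError:
                self._cache[smiles] = None
            else:
                self._cache[smiles] = (mol, conf)
        return self._cache[smiles]


def _enumerated_states(
    rules: Sequence[TransformationRule], library: Sequence[str]
) -> list[tuple[str, list[str]]]:
    """(parent, members) for every fixture parent, rule closure only."""
    out = []
    for smi in library:
        ts = enumerate_tautomers(parse_structure(smi), rules, fallback=None)
        out.append((ts.parent, ts.members))
    return out


def make_energy_dataset(
    n_molecules: int,
    seed: int = 0,
    noise_sd: float = 0.0,
    oracle: SurrogateOracle | None = None,
    n_conformers: int = 8,
    backend: GeometryBackend | None = None,
    extended_library: bool = True,
) -> list[LabeledStructure]:
    """Oracle-labeled structures for pretraining (tautomers of the fixture
    library, lowest-energy MMFF94 conformer each, Gaussian label noise)."""
    oracle = oracle or SurrogateOracle()
    backend = backend or RDKitBackend()
    rules = load_rules()
    rng = np.random.default_rng(seed)
    cache = _ConformerCache(backend, n_conformers, seed)

    states: list[str] = []
    for parent, members in _enumerated_states(rules, fixture_library(extended=extended_library)):
        states.extend(members)
    seen = set()
    states = [s for s in states if not (s in seen or seen.add(s))]
    if n_molecules > len(states):
        raise ValueError(f"fixture library yields only {len(states)} states (< {n_molecules})")
    rng.shuffle(states)  # uniform motif coverage instead of library order

    out: list[LabeledStructure] = []
    for smi in states:
        if len(out) >= n_molecules:
            break
        entry = cache.get(smi)
        if entry is None:
            continue
        mol, conf = entry
        triple = oracle.label(mol, conf).as_array()
        triple = triple + rng.normal(0.0, noise_sd, size=3) if noise_sd > 0 else triple
        z = np.array([a.GetAtomicNum() for a in Chem.AddHs(mol.rdmol).GetAtoms()])
        out.append(LabeledStructure(smi, z, conf, EnergyTriple.from_array(triple)))
    if len(out) < n_molecules:
        raise ValueError(f"only {len(out)} of {n_molecules} states were embeddable")
    return out


def make_pair_dataset(
    n_pairs: int,
    noise_sd: float = 0.5,
    seed: int = 0,
    oracle: SurrogateOracle | None = None,
    n_conformers: int = 8,
    backend: GeometryBackend | None = None,
    extended_library: bool = True,
    exclude_pairs: "set[frozenset[str]] | None" = None,
) -> list[PairRecord]:
    """Experimental-style tautomer-pair records from the fixture library.

    Each record pairs two enumerated tautomers of one parent;
    ``dG_exp = E_water*(B) − E_water*(A) + N(0, noise_sd)`` and the
    noise-free gas energies serve as anchors.  ``exclude_pairs`` (unordered
    SMILES pairs, see :func:`pair_keys`) lets callers draw a disjoint
    evaluation set.  Raises if the library is exhausted before ``n_pairs``
    records exist.
    """
    oracle = oracle or SurrogateOracle()
    backend = backend or RDKitBackend()
    rules = load_rules()
    rng = np.random.default_rng(seed)
    cache = _ConformerCache(backend, n_conformers, seed)

    candidates: list[tuple[str, str]] = []
    for parent, members in _enumerated_states(rules, fixture_library(extended=extended_library)):
        others = [m for m in members if m != parent]
        for other in others:
            candidates.append((parent, other))
        for i in range(len(others)):
            for j in range(i + 1, len(others)):
                candidates.append((others[i], others[j]))
    rng.shuffle(candidates)  # uniform motif coverage instead of library order

    records: list[PairRecord] = []
    for smi_a, smi_b in candidates:
        if len(records) >= n_pairs:
            break
        if exclude_pairs and frozenset((smi_a, smi_b)) in exclude_pairs:
            continue
        ea, eb = cache.get(smi_a), cache.get(smi_b)
        if ea is None or eb is None:
            continue
        (mol_a, conf_a), (mol_b, conf_b) = ea, eb
        ta, tb = oracle.label(mol_a, conf_a), oracle.label(mol_b, conf_b)
        dg = tb.E_water - ta.E_water
        if noise_sd > 0:
            dg += float(rng.normal(0.0, noise_sd))
        za = np.array([a.GetAtomicNum() for a in Chem.AddHs(mol_a.rdmol).GetAtoms()])
        zb = np.array([a.GetAtomicNum() for a in Chem.AddHs(mol_b.rdmol).GetAtoms()])
        records.append(
            PairRecord(
                smiles_a=smi_a,
                smiles_b=smi_b,
                conf_a=conf_a,
                conf_b=conf_b,
                z_a=za,
                z_b=zb,
                dG_exp=float(dg),
                preferred="A" if dg > 0 else "B",
                gas_targets=(ta.E_gas, tb.E_gas),
                source=f"synthetic-{len(records)}",
            )
        )
    if len(records) < n_pairs:
        raise ValueError(
            f"fixture library exhausted at {len(records)} pairs (requested {n_pairs})"
        )
    return records


def pair_keys(records: Sequence[PairRecord]) -> set[frozenset]:
    """Unordered SMILES-pair keys, for overlap exclusion between datasets."""
    return {frozenset((r.smiles_a, r.smiles_b)) for r in records}


def pairs_to_dataframe(records: Sequence[PairRecord]):
    """Pair records in the delimited layout the curation reader consumes."""
    import pandas as pd

    from .thermo import dg_to_logk

    rows = []
    for rec in records:
        rows.append(
            {
                "smiles_a": rec.smiles_a,
                "smiles_b": rec.smiles_b,
                "solvent": "water",
                "logK": dg_to_logk(rec.dG_exp) if rec.dG_exp is not None else "",
                "preferred": rec.preferred or "",
                "source_id": rec.source,
            }
        )
    return pd.DataFrame(rows)
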