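"""Conformer generation and force-field selection of lowest-energy geometries.

The production backend embeds conformers with ETKDG and optimizes them with
MMFF94 inside RDKit, retaining the lowest-energy optimized conformation as
the model input geometry.  The backend is a contract so the quantum-chemistry
stage of the original data-preparation pipeline (or a deterministic stub for
unit tests) can be slotted in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import Conformer3D, Molecule, canonical_form


class GeometryError(RuntimeError):
    """Raised when no conformer can be embedded for a molecule."""


@dataclass
class EmbedConfig:
    """Conformer-search settings: how many ETKDG embeddings to try."""

    n_conformers: int = 300
    seed: int = 0
    max_opt_iters: int = 500

    def __post_init__(self) -> None:
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be >= 1")


class GeometryBackend(Protocol):
    """Contract: embed conformers and locally optimize them.

    ``optimize`` must never increase the backend's own energy and must be
    deterministic for a fixed seed.
    """

    def embed(self, mol: Molecule, count: int, seed: int) -> Sequence[Conformer3D]: ...

    def optimize(self, mol: Molecule, conf: Conformer3D) -> tuple[Conformer3D, float]: ...


@dataclass
class RDKitBackend:
    """ETKDG embedding + MMFF94 optimization via RDKit.

    Coordinates include explicit hydrogens; the force-field variant and
    convergence settings are recorded in each conformer's metadata.
    """

    force_field: str = "MMFF94"
    max_opt_iters: int = 500

    def _mol_with_hs(self, mol: Molecule) -> Chem.Mol:
        return Chem.AddHs(Chem.Mol(mol.rdmol))

    def embed(self, mol: Molecule, count: int, seed: int) -> list[Conformer3D]:
        rdmol = self._mol_with_hs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed)
        params.numThreads = 1
        conf_ids = AllChem.EmbedMultipleConfs(rdmol, numConfs=int(count), params=params)
        out = []
        for cid in conf_ids:
            conf = rdmol.GetConformer(cid)
            coords = [tuple(conf.GetAtomPosition(i)) for i in range(rdmol.GetNumAtoms())]
            out.append(Conformer3D(coords, metadata={"seed": int(seed), "conf_id": int(cid)}))
        return out

    def optimize(self, mol: Molecule, conf: Conformer3D) -> tuple[Conformer3D, float]:
        rdmol = self._mol_with_hs(mol)
        if rdmol.GetNumAtoms() != conf.n_atoms:
            raise ValueError("conformer does not align with molecule (explicit-H count)")
        from rdkit.Geometry import Point3D

        c = Chem.Conformer(rdmol.GetNumAtoms())
        for i, (x, y, z) in enumerate(np.asarray(conf.coordinates)):
            c.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
        rdmol.RemoveAllConformers()
        cid = rdmol.AddConformer(c, assignId=True)
        props = AllChem.MMFFGetMoleculeProperties(rdmol, mmffVariant=self.force_field)
        if props is None:
            raise GeometryError(f"MMFF94 cannot type {canonical_form(mol)!r}")
        ff = AllChem.MMFFGetMoleculeForceField(rdmol, props, confId=cid)
        ff.Minimize(maxIts=self.max_opt_iters)
        energy = float(ff.CalcEnergy())
        opt = rdmol.GetConformer(cid)
        coords = [tuple(opt.GetAtomPosition(i)) for i in range(rdmol.GetNumAtoms())]
        meta = dict(conf.metadata)
        meta["force_field"] = self.force_field
        return Conformer3D(coords, energy=energy, metadata=meta), energy


@dataclass
class StubBackend:
    """Deterministic test backend with preset coordinates and energies."""

    conformers: list[Conformer3D] = field(default_factory=list)
    energies: list[float] = field(default_factory=list)

    def embed(self, mol: Molecule, count: int, seed: int) -> list[Conformer3D]:
        return list(self.conformers[:count])

    def optimize(self, mol: Molecule, conf: Conformer3D) -> tuple[Conformer3D, float]:
        idx = next(i for i, c in enumerate(self.conformers) if c is conf)
        energy = float(self.energies[idx])
        out = Conformer3D(np.asarray(conf.coordinates), energy=energy, metadata=dict(conf.metadata))
        return out, energy


def lowest_energy_conformer(
    mol: Molecule,
    backend: GeometryBackend | None = None,
    cfg: EmbedConfig | None = None,
) -> Conformer3D:
    """Embed ``cfg.n_conformers`` conformers, optimize each, return the minimum.

    Raises :class:`GeometryError` (carrying the canonical SMILES) when the
    backend produces no embeddings.
    """
    backend = backend if backend is not None else RDKitBackend()
    cfg = cfg if cfg is not None else EmbedConfig()
    candidates = backend.embed(mol, cfg.n_conformers, cfg.seed)
    if not candidates:
        raise GeometryError(f"embedding failed for {canonical_form(mol)!r}")
    best: Conformer3D | None = None
    for conf in candidates:
        try:
            opt, energy = backend.optimize(mol, conf)
        except GeometryError:
            continue
        if best is None or energy < best.energy:
            best = opt
    if best is None:
        raise GeometryError(f"optimization failed for every conformer of {canonical_form(mol)!r}")
    return best


def identity_filter(mol: Molecule, conf: Conformer3D) -> bool:
    """True iff bonds re-perceived from the 3D geometry give back ``mol``.

    Guards against an optimization that silently walked the structure to a
    different tautomer (or broke a bond).  Perception failures return False
    with a warning rather than raising.
    """
    from rdkit.Chem import rdDetermineBonds

    try:
        rdmol = Chem.AddHs(Chem.Mol(mol.rdmol))
        if rdmol.GetNumAtoms() != conf.n_atoms:
            if mol.rdmol.GetNumAtoms() == conf.n_atoms:
                rdmol = Chem.Mol(mol.rdmol)
            else:
                raise ValueError("conformer/molecule atom count mismatch")
        raw = Chem.RWMol()
        from rdkit.Geometry import Point3D

        c = Chem.Conformer(rdmol.GetNumAtoms())
        for atom in rdmol.GetAtoms():
            raw.AddAtom(Chem.Atom(atom.GetAtomicNum()))
        for i, (x, y, z) in enumerate(np.asarray(conf.coordinates)):
            c.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
        perceived = raw.GetMol()
        perceived.AddConformer(c)
        rdDetermineBonds.DetermineBonds(perceived, charge=0)
        return canonical_form(perceived) == canonical_form(mol)
    except Exception as exc:
        warnings.warn(f"bond perception failed for {canonical_form(mol)!r}: {exc}", stacklevel=2)
        return False
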