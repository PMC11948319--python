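"""Molecule representation, parsing, canonicalization and validity checks.

All chemistry perception is delegated to RDKit; :class:`Molecule` is a thin,
immutable-by-convention wrapper that every downstream stage (enumeration,
geometry, featurization) passes along.  Canonical SMILES from one RDKit
version is the identity key used for deduplication throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

#: Elements accepted by default: the organic-chemistry set plus P and the
#: halogens, matching the curation rule used for experimental records.
DEFAULT_ELEMENTS = frozenset({"H", "C", "N", "O", "S", "P", "F", "Cl", "Br"})


class ParseError(ValueError):
    """Raised when a SMILES or structure block cannot be parsed."""


@dataclass
class Molecule:
    """A chemical graph with perceived implicit hydrogens.

    Parameters
    ----------
    rdmol : rdkit.Chem.Mol
        Sanitized RDKit molecule (implicit-H model, no explicit conformers
        required).
    name : str, optional
        Free-text identifier carried through reports.
    """

    rdmol: Chem.Mol
    name: str = ""

    # -- derived views -------------------------------------------------
    @property
    def num_heavy_atoms(self) -> int:
        return self.rdmol.GetNumHeavyAtoms()

    @property
    def atomic_numbers(self) -> list[int]:
        """Atomic numbers including explicit hydrogens (heavy-only mol: heavy)."""
        return [a.GetAtomicNum() for a in self.rdmol.GetAtoms()]

    def formula(self) -> str:
        """Molecular formula, e.g. ``'C3H6O'``; stable under canonicalization."""
        return rdMolDescriptors.CalcMolFormula(self.rdmol)

    def polar_hydrogen_count(self) -> int:
        """Number of hydrogens bound to O or N (explicit plus implicit)."""
        n = 0
        for atom in self.rdmol.GetAtoms():
            if atom.GetSymbol() in ("O", "N"):
                n += atom.GetTotalNumHs()
            elif atom.GetAtomicNum() == 1:
                nb = atom.GetNeighbors()
                if nb and nb[0].GetSymbol() in ("O", "N"):
                    n += 1
        return n

    def with_explicit_hydrogens(self) -> "Molecule":
        return Molecule(Chem.AddHs(self.rdmol), name=self.name)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Molecule({canonical_form(self)!r}, name={self.name!r})"


@dataclass
class Conformer3D:
    """Cartesian coordinates in Å aligned to a Molecule's atom order."""

    coordinates: "list[tuple[float, float, float]]"
    energy: float | None = None  # force-field energy, kcal/mol
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        import numpy as np

        arr = np.asarray(self.coordinates, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("coordinates must be (n_atoms, 3)")
        if not np.isfinite(arr).all():
            raise ValueError("coordinates must be finite")
        self.coordinates = arr

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)


def parse_structure(text: str, name: str = "") -> Molecule:
    """Parse a SMILES string into a sanitized :class:`Molecule`.

    Raises
    ------
    ParseError
        If the SMILES is empty or chemically invalid; the message names the
        offending input.
    """
    if not text or not text.strip():
        raise ParseError("empty SMILES input")
    mol = Chem.MolFromSmiles(text.strip())
    if mol is None:
        raise ParseError(f"unparsable SMILES: {text!r}")
    return Molecule(mol, name=name)


def canonical_form(mol: Molecule | Chem.Mol) -> str:
    """Deterministic canonical SMILES (idempotent within one RDKit version)."""
    rdmol = mol.rdmol if isinstance(mol, Molecule) else mol
    return Chem.MolToSmiles(Chem.RemoveHs(rdmol), canonical=True)


def is_neutral(mol: Molecule, per_atom: bool = True) -> bool:
    """True iff the molecule carries no charge.

    With ``per_atom=True`` (default) every atom's formal charge must be zero,
    which excludes zwitterions; ``per_atom=False`` relaxes the check to net
    molecular charge.
    """
    charges = [a.GetFormalCharge() for a in mol.rdmol.GetAtoms()]
    if per_atom:
        return all(c == 0 for c in charges)
    return sum(charges) == 0


def elements_allowed(mol: Molecule, allowed: Iterable[str] = DEFAULT_ELEMENTS) -> bool:
    """True iff every atom's element symbol belongs to ``allowed``."""
    allowed = frozenset(allowed)
    return all(a.GetSymbol() in allowed for a in mol.rdmol.GetAtoms())


# ---------------------------------------------------------------------------
# readers / writers


def read_smiles_file(path: str | Path) -> Iterator[Molecule]:
    """Yield molecules from a SMILES file (one per line, optional tab name)."""
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smiles = parts[0].strip()
        name = parts[1].strip() if len(parts) > 1 else ""
        yield parse_structure(smiles, name=name)


def write_sdf(
    path: str | Path,
    entries: Sequence[tuple[Molecule, Conformer3D]],
    properties: dict | None = None,
) -> None:
    """Write (molecule, conformer) pairs as an SDF V2000 file.

    Conformer energy and any extra ``properties`` are stored as SDF data
    fields so a fixed seed yields byte-identical output.
    """
    from rdkit.Chem import SDWriter
    from rdkit.Geometry import Point3D

    writer = SDWriter(str(path))
    writer.SetKekulize(True)
    try:
        for mol, conf in entries:
            rdmol = Chem.Mol(mol.rdmol)
            if rdmol.GetNumAtoms() != conf.n_atoms:
                rdmol = Chem.AddHs(rdmol)
            if rdmol.GetNumAtoms() != conf.n_atoms:
                raise ValueError("conformer does not align with molecule atoms")
            c = Chem.Conformer(rdmol.GetNumAtoms())
            for i, (x, y, z) in enumerate(conf.coordinates):
                c.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
            rdmol.RemoveAllConformers()
            rdmol.AddConformer(c, assignId=True)
            if mol.name:
                rdmol.SetProp("_Name", mol.name)
            if conf.energy is not None:
                rdmol.SetProp("energy_kcal_mol", f"{conf.energy:.6f}")
            for key, val in {**conf.metadata, **(properties or {})}.items():
                rdmol.SetProp(str(key), str(val))
            writer.write(rdmol)
    finally:
        writer.close()


def read_sdf(path: str | Path) -> Iterator[tuple[Molecule, Conformer3D]]:
    """Yield (Molecule, Conformer3D) pairs from an SDF V2000 file."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    for rdmol in supplier:
        if rdmol is None:
            continue
        conf = rdmol.GetConformer()
        coords = [tuple(conf.GetAtomPosition(i)) for i in range(rdmol.GetNumAtoms())]
        energy = None
        if rdmol.HasProp("energy_kcal_mol"):
            energy = float(rdmol.GetProp("energy_kcal_mol"))
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
        yield Molecule(rdmol, name=name), Conformer3D(coords, energy=energy)
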