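"""Prototropic tautomer enumeration by iterative SMIRKS transformation.

Rules are reaction SMIRKS with the migrating hydrogen mapped explicitly.
They are applied to kekulized copies of the molecule with explicit
hydrogens, so hydrogen and heavy-atom bookkeeping is exact and formula
conservation can be asserted per product.  The closure protocol is
breadth-first: round *k* applies every rule to every state first seen in
round *k−1*, deduplicating by canonical SMILES, stopping at closure or
after ``max_rounds`` rounds.  A pluggable fallback enumerator is invoked
when the rules generate nothing beyond the parent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import Molecule, canonical_form, parse_structure

logger = logging.getLogger(__name__)

#: Tiny molecules used to sanity-check formula conservation of loaded rules.
_PROBE_SMILES = ("CC(C)=O", "CC(N)=O", "O=c1cccc[nH]1", "CC=NO", "CC(=N)N")


class RuleLoadError(ValueError):
    """Raised when a rule file contains an unparsable or invalid pattern."""


class EnumerationOverflow(RuntimeError):
    """Raised when the closure exceeds the configured member ceiling."""


@dataclass
class TransformationRule:
    """A single prototropic rewrite: one reactant, one product."""

    id: str
    name: str
    smirks: str
    _rxn: AllChem.ChemicalReaction | None = None

    @property
    def rxn(self) -> AllChem.ChemicalReaction:
        if self._rxn is None:
            try:
                rxn = AllChem.ReactionFromSmarts(self.smirks)
            except Exception:
                rxn = None
            if rxn is None:
                raise RuleLoadError(f"rule {self.id!r}: unparsable SMIRKS {self.smirks!r}")
            if rxn.GetNumReactantTemplates() != 1 or rxn.GetNumProductTemplates() != 1:
                raise RuleLoadError(
                    f"rule {self.id!r}: must be a one-reactant, one-product rewrite"
                )
            self._rxn = rxn
        return self._rxn


@dataclass
class TautomerSet:
    """Closed set of tautomeric states reachable from a parent molecule."""

    parent: str  # canonical SMILES
    members: list[str]  # canonical SMILES, parent included
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)
    rounds_used: int = 0
    fallback_used: bool = False

    def __len__(self) -> int:
        return len(self.members)

    def molecules(self) -> list[Molecule]:
        return [parse_structure(s) for s in self.members]


def default_rules_path() -> Path:
    return Path(str(resources.files("tautrank").joinpath("data/rules.tsv")))


def load_rules(path: str | Path | None = None, validate: bool = True) -> list[TransformationRule]:
    """Load transformation rules from a tab-delimited file.

    Each record is ``id <TAB> name <TAB> SMIRKS``; ``#`` lines are comments.
    Every rule's pattern is parsed eagerly, and with ``validate=True`` each
    rule is applied to a built-in probe set to confirm it conserves the
    molecular formula.
    """
    path = Path(path) if path is not None else default_rules_path()
    rules: list[TransformationRule] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise RuleLoadError(f"{path}:{lineno}: expected 'id<TAB>name<TAB>SMIRKS'")
        rule = TransformationRule(parts[0].strip(), parts[1].strip(), parts[2].strip())
        _ = rule.rxn  # parse now so errors name the rule id
        rules.append(rule)
    if not rules:
        warnings.warn(f"rule file {path} contains no rules", stacklevel=2)
    if validate:
        for rule in rules:
            _probe_formula_conservation(rule)
    logger.info("loaded %d transformation rules from %s", len(rules), path)
    return rules


def _probe_formula_conservation(rule: TransformationRule) -> None:
    for smi in _PROBE_SMILES:
        parent = parse_structure(smi)
        for product in _apply_rule(parent, rule):
            if product.formula() != parent.formula():
                raise RuleLoadError(
                    f"rule {rule.id!r} does not conserve the molecular formula "
                    f"on probe {smi!r}: {parent.formula()} -> {product.formula()}"
                )


def _kekulized_with_hs(mol: Molecule) -> Chem.Mol:
    rdmol = Chem.AddHs(Chem.Mol(mol.rdmol))
    Chem.Kekulize(rdmol, clearAromaticFlags=True)
    return rdmol


def _apply_rule(mol: Molecule, rule: TransformationRule) -> list[Molecule]:
    """All sanitizable products of one rule at every matching site."""
    reactant = _kekulized_with_hs(mol)
    products: list[Molecule] = []
    for (prod,) in rule.rxn.RunReactants((reactant,)):
        try:
            Chem.SanitizeMol(prod)
            prod = Chem.RemoveHs(prod)
        except Exception:  # unphysical rewrite at this site
            continue
        products.append(Molecule(prod))
    return products


def apply_rules_once(mol: Molecule, rules: Sequence[TransformationRule]) -> dict[str, str]:
    """Apply every rule at every matching site; one pass, no iteration.

    Returns a mapping ``canonical SMILES -> rule id`` of all distinct valid
    products.  Products whose formula differs from the input are dropped
    with a warning (a rule misfiring on an unusual motif must not corrupt
    the closure).
    """
    parent_formula = mol.formula()
    parent_canonical = canonical_form(mol)
    out: dict[str, str] = {}
    for rule in rules:
        for product in _apply_rule(mol, rule):
            if product.formula() != parent_formula:
                warnings.warn(
                    f"rule {rule.id!r} product {canonical_form(product)!r} changes "
                    f"formula {parent_formula} -> {product.formula()}; dropped",
                    stacklevel=2,
                )
                continue
            smi = canonical_form(product)
            if smi != parent_canonical:
                out.setdefault(smi, rule.id)
    return out


FallbackEnumerator = Callable[[Molecule], Iterable[Molecule]]


def rdkit_fallback(mol: Molecule) -> list[Molecule]:
    """Fallback tautomer generator backed by RDKit's enumerator."""
    from rdkit.Chem.MolStandardize import rdMolStandardize

    enumerator = rdMolStandardize.TautomerEnumerator()
    out = []
    for rdmol in enumerator.Enumerate(mol.rdmol):
        out.append(Molecule(rdmol))
    return out


def enumerate_tautomers(
    mol: Molecule,
    rules: Sequence[TransformationRule] | None = None,
    max_rounds: int = 5,
    fallback: FallbackEnumerator | None = rdkit_fallback,
    max_states: int = 256,
) -> TautomerSet:
    """Breadth-first closure of the transformation rules from ``mol``.

    Round *k* applies all rules to the states first reached in round *k−1*;
    enumeration stops at closure or after ``max_rounds`` rounds.  If round 1
    yields nothing beyond the parent, the ``fallback`` enumerator is invoked
    and its products are kept only if they form a prototropic pair with the
    parent.  The parent is always a member.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    rules = load_rules() if rules is None else rules
    parent = canonical_form(mol)
    provenance: dict[str, tuple[str, ...]] = {parent: ()}
    frontier = [parent]
    rounds_used = 0
    for rnd in range(1, max_rounds + 1):
        new_frontier: list[str] = []
        for smi in frontier:
            state = parse_structure(smi)
            for product_smi, rule_id in apply_rules_once(state, rules).items():
                if product_smi in provenance:
                    continue
                provenance[product_smi] = provenance[smi] + (rule_id,)
                new_frontier.append(product_smi)
                if len(provenance) > max_states:
                    raise EnumerationOverflow(
                        f"tautomer closure of {parent!r} exceeded {max_states} states"
                    )
        if not new_frontier:
            break
        rounds_used = rnd
        frontier = new_frontier

    fallback_used = False
    if len(provenance) == 1 and fallback is not None:
        parent_mol = parse_structure(parent)
        for cand in fallback(parent_mol):
            if is_prototropic_pair(parent_mol, cand):
                provenance.setdefault(canonical_form(cand), ("fallback",))
                fallback_used = True
                if len(provenance) > max_states:
                    raise EnumerationOverflow(
                        f"tautomer closure of {parent!r} exceeded {max_states} states"
                    )

    members = sorted(provenance)
    return TautomerSet(
        parent=parent,
        members=members,
        provenance=provenance,
        rounds_used=rounds_used,
        fallback_used=fallback_used,
    )


def _heavy_skeleton(mol: Molecule) -> str:
    """Canonical text of the heavy-atom connectivity with bond orders erased."""
    rdmol = Chem.RWMol(Chem.RemoveHs(Chem.Mol(mol.rdmol)))
    for atom in rdmol.GetAtoms():
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(True)
        atom.SetIsAromatic(False)
    for bond in rdmol.GetBonds():
        bond.SetBondType(Chem.BondType.SINGLE)
        bond.SetIsAromatic(False)
    Chem.SanitizeMol(rdmol, Chem.SanitizeFlags.SANITIZE_SYMMRINGS)
    return Chem.MolToSmiles(rdmol, canonical=True)


def is_prototropic_pair(a: Molecule, b: Molecule) -> bool:
    """True iff ``a`` and ``b`` are distinct prototropic tautomers.

    Same molecular formula, identical heavy-atom connectivity skeleton
    (hydrogen placement and bond orders may differ), different canonical
    forms.
    """
    if canonical_form(a) == canonical_form(b):
        return False
    if a.formula() != b.formula():
        return False
    return _heavy_skeleton(a) == _heavy_skeleton(b)
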