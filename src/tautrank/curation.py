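"""Curation of experimental tautomer-pair records into model-ready subsets.

Raw records (two SMILES, a solvent label, optionally a log10 equilibrium
constant and/or a preferred-state flag) are filtered with five rules:

1. measured in water;
2. a logK value is present;
3. all molecules neutral (per-atom formal charge zero by default);
4. elements limited to H, C, N, O, S, P, F, Cl, Br;
5. the two states form a prototropic tautomer pair.

Records passing all five and not matching the challenge-set exclusion list
form the *ratio subset* (quantitative fine-tuning data).  Water records
without a logK but with a definite preferred state that pass rules 3–5
form the *preference subset* (ranking evaluation data).  Rejections are
tallied by the first failing rule, and filtering is order-independent
record-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chem import DEFAULT_ELEMENTS, Molecule, ParseError, canonical_form, elements_allowed, is_neutral, parse_structure
from .tautomers import is_prototropic_pair

#: Solvent strings treated as water (case-insensitive).
WATER_SYNONYMS = frozenset({"water", "h2o", "aqueous", "aq"})

#: Default column mapping for delimited input files.
DEFAULT_COLUMNS = {
    "smiles_a": "smiles_a",
    "smiles_b": "smiles_b",
    "solvent": "solvent",
    "logk": "logK",
    "preferred": "preferred",
    "source_id": "source_id",
}


@dataclass
class RawRecord:
    smiles_a: str
    smiles_b: str
    solvent: str = "water"
    logk: float | None = None
    preferred: str | None = None  # "A" or "B"
    source_id: str = ""


def read_records(path: str | Path, columns: dict | None = None) -> list[RawRecord]:
    """Read raw pair records from a delimited file (CSV or TSV)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    return records_from_dataframe(df, columns=columns)


def records_from_dataframe(df: pd.DataFrame, columns: dict | None = None) -> list[RawRecord]:
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    records = []
    for i, row in df.iterrows():
        logk = row.get(cols["logk"])
        if logk is not None and (pd.isna(logk) or logk == ""):
            logk = None
        preferred = row.get(cols["preferred"])
        if preferred is not None and (pd.isna(preferred) or preferred == ""):
            preferred = None
        records.append(
            RawRecord(
                smiles_a=str(row[cols["smiles_a"]]),
                smiles_b=str(row[cols["smiles_b"]]),
                solvent=str(row.get(cols["solvent"], "water")),
                logk=float(logk) if logk is not None else None,
                preferred=str(preferred) if preferred is not None else None,
                source_id=str(row.get(cols["source_id"], i)),
            )
        )
    return records


def load_sampl2_exclusions(path: str | Path | None = None) -> frozenset[str]:
    """Canonical SMILES of challenge molecules excluded from curation.

    The shipped default file is a synthetic stand-in (see its header);
    point ``path`` at a real exclusion list to reproduce a published
    curation.
    """
    if path is None:
        path = Path(str(resources.files("tautrank").joinpath("data/sampl2_exclusions_synthetic.smi")))
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles = line.split("\t")[0].strip()
        out.add(canonical_form(parse_structure(smiles)))
    return frozenset(out)


def _parse_pair(rec: RawRecord) -> tuple[Molecule, Molecule] | None:
    try:
        return parse_structure(rec.smiles_a), parse_structure(rec.smiles_b)
    except ParseError:
        return None


def _is_water(solvent: str, synonyms: Iterable[str]) -> bool:
    return solvent.strip().lower() in {s.lower() for s in synonyms}


def filter_ratio_subset(
    records: Sequence[RawRecord],
    sampl2_ids: Iterable[str] | None = None,
    water_synonyms: Iterable[str] = WATER_SYNONYMS,
    allowed_elements: Iterable[str] = DEFAULT_ELEMENTS,
) -> tuple[list[RawRecord], dict[str, int]]:
    """Apply the five curation rules plus the challenge-set exclusion.

    Returns the kept records and a tally of rejections keyed by the first
    failing rule (``parse``, ``rule1_water`` ... ``rule5_prototropic``,
    ``sampl2``).
    """
    sampl2 = frozenset(sampl2_ids or ())
    kept: list[RawRecord] = []
    tally = {
        "parse": 0,
        "rule1_water": 0,
        "rule2_logk": 0,
        "rule3_neutral": 0,
        "rule4_elements": 0,
        "rule5_prototropic": 0,
        "sampl2": 0,
    }
    for rec in records:
        pair = _parse_pair(rec)
        if pair is None:
            tally["parse"] += 1
            continue
        mol_a, mol_b = pair
        if not _is_water(rec.solvent, water_synonyms):
            tally["rule1_water"] += 1
            continue
        if rec.logk is None:
            tally["rule2_logk"] += 1
            continue
        if not (is_neutral(mol_a) and is_neutral(mol_b)):
            tally["rule3_neutral"] += 1
            continue
        if not (elements_allowed(mol_a, allowed_elements) and elements_allowed(mol_b, allowed_elements)):
            tally["rule4_elements"] += 1
            continue
        if not is_prototropic_pair(mol_a, mol_b):
            tally["rule5_prototropic"] += 1
            continue
        if canonical_form(mol_a) in sampl2 or canonical_form(mol_b) in sampl2:
            tally["sampl2"] += 1
            continue
        kept.append(rec)
    return kept, tally


def build_preference_subset(
    records: Sequence[RawRecord],
    sampl2_ids: Iterable[str] | None = None,
    water_synonyms: Iterable[str] = WATER_SYNONYMS,
    allowed_elements: Iterable[str] = DEFAULT_ELEMENTS,
) -> list[RawRecord]:
    """Water records without logK but with a definite preferred state.

    Rules 3–5 (neutrality, elements, prototropic pair) still apply, so the
    result is disjoint from the ratio subset by construction.
    """
    sampl2 = frozenset(sampl2_ids or ())
    kept = []
    for rec in records:
        if rec.logk is not None or rec.preferred not in ("A", "B"):
            continue
        if not _is_water(rec.solvent, water_synonyms):
            continue
        pair = _parse_pair(rec)
        if pair is None:
            continue
        mol_a, mol_b = pair
        if not (is_neutral(mol_a) and is_neutral(mol_b)):
            continue
        if not (elements_allowed(mol_a, allowed_elements) and elements_allowed(mol_b, allowed_elements)):
            continue
        if not is_prototropic_pair(mol_a, mol_b):
            continue
        if canonical_form(mol_a) in sampl2 or canonical_form(mol_b) in sampl2:
            continue
        kept.append(rec)
    return kept
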