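"""Thermodynamic conversions, Boltzmann populations, and evaluation metrics.

The experimental tautomeric equilibrium constant K enters as log10 K and is
converted to a free energy by ΔG = −RT ln K.  Relative aqueous energies of
enumerated states are turned into Boltzmann population fractions, and
states within a cutoff of the minimum (default 2.76 kcal/mol, the 1%-ratio
convention) are flagged as low-energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Gas constant in kcal/(mol·K) and the default temperature in K.
R_KCAL = 1.98720425e-3
T_DEFAULT = 298.15

#: Default low-energy cutoff in kcal/mol (1% tautomer-ratio convention).
LOW_ENERGY_CUTOFF = 2.76

LN10 = np.log(10.0)


@dataclass
class RankedState:
    """One tautomeric state in a ranking report."""

    smiles: str
    relative_energy: float  # kcal/mol vs the minimum-energy state
    population: float = 0.0
    low_energy: bool = False
    diagnostics: dict = field(default_factory=dict)


def logk_to_dg(logk: float, T: float = T_DEFAULT) -> float:
    """ΔG = −RT ln K = −RT·ln10·log10(K), in kcal/mol.

    Positive logK (product-favored) gives negative ΔG.
    """
    return float(-R_KCAL * T * LN10 * np.asarray(logk, dtype=float))


def dg_to_logk(dg: float, T: float = T_DEFAULT) -> float:
    """Inverse of :func:`logk_to_dg`."""
    return float(-np.asarray(dg, dtype=float) / (R_KCAL * T * LN10))


def populations(relative_dg: Sequence[float], T: float = T_DEFAULT) -> np.ndarray:
    """Boltzmann fractions exp(−ΔG/RT), normalized to sum to one.

    Invariant under adding a constant to all energies (the shift cancels in
    the normalization, enforced here by subtracting the minimum first).
    """
    dg = np.asarray(relative_dg, dtype=float)
    if not np.isfinite(dg).all():
        raise ValueError("energies must be finite")
    w = np.exp(-(dg - dg.min()) / (R_KCAL * T))
    return w / w.sum()


def low_energy_states(
    states: Sequence[RankedState], cutoff: float = LOW_ENERGY_CUTOFF
) -> list[RankedState]:
    """Flag states with relative energy ≤ cutoff (inclusive boundary).

    The minimum-energy state (relative energy 0) is always flagged.
    """
    if not states:
        raise ValueError("empty state sequence")
    for s in states:
        s.low_energy = bool(s.relative_energy <= cutoff)
    return list(states)


def rmse(pred: Sequence[float], target: Sequence[float]) -> float:
    pred, target = np.asarray(pred, dtype=float), np.asarray(target, dtype=float)
    if pred.size == 0 or pred.shape != target.shape:
        raise ValueError("sequences must be aligned and non-empty")
    return float(np.sqrt(((pred - target) ** 2).mean()))


def mae(pred: Sequence[float], target: Sequence[float]) -> float:
    pred, target = np.asarray(pred, dtype=float), np.asarray(target, dtype=float)
    if pred.size == 0 or pred.shape != target.shape:
        raise ValueError("sequences must be aligned and non-empty")
    return float(np.abs(pred - target).mean())


def ranking_success_rate(
    pred_dg: Sequence[float], preferred: Sequence[str]
) -> float:
    """Fraction of pairs whose predicted sign names the preferred state.

    ``pred_dg`` follows the convention E_water(B) − E_water(A): positive
    predicts A.  A predicted ΔG of exactly zero counts as a failure (the
    model expressed no preference).
    """
    pred_dg = np.asarray(pred_dg, dtype=float)
    preferred = list(preferred)
    if pred_dg.size == 0 or len(preferred) != pred_dg.size:
        raise ValueError("sequences must be aligned and non-empty")
    if any(p not in ("A", "B") for p in preferred):
        raise ValueError("each entry needs a definite preference 'A' or 'B'")
    hits = sum(
        1
        for dg, p in zip(pred_dg, preferred)
        if (dg > 0 and p == "A") or (dg < 0 and p == "B")
    )
    return hits / pred_dg.size
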