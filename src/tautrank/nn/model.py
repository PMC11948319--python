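"""Multitask atomic-contribution energy network.

The architecture follows the PhysNet lineage: interatomic distances under a
10 Å cutoff are expanded in a radial basis, element types are embedded,
node embeddings are refined by a stack of interaction modules (message
passing over edges, residual refinement, a gated update), and per-atom
three-component outputs are summed into molecular energies — the gas-phase
electronic energy, the aqueous-phase energy, and the gas-to-water transfer
energy, all in kcal/mol.  Because only pair distances enter, predictions
are invariant to rotation, translation and atom permutation, and exactly
extensive over non-interacting fragments.

The Siamese pairwise prediction applies the same weights to two tautomeric
states and reports the difference of their aqueous energies:
``delta = E_water(B) − E_water(A)``, so a positive value means state A is
the more stable one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ..chem import Conformer3D, Molecule
from .autodiff import Tensor, parameter

#: Heads, in order, of every prediction: (E_gas, E_water, dE_transfer).
HEADS = ("E_gas", "E_water", "dE_transfer")
WATER = 1  # column index of E_water

#: Elements the default embedding covers (H C N O F P S Cl Br).
DEFAULT_Z = (1, 6, 7, 8, 9, 15, 16, 17, 35)


@dataclass(frozen=True)
class EnergyTriple:
    """Gas-phase, aqueous-phase, and transfer energies in kcal/mol."""

    E_gas: float
    E_water: float
    dE_transfer: float

    def as_array(self) -> np.ndarray:
        return np.array([self.E_gas, self.E_water, self.dE_transfer], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "EnergyTriple":
        a = np.asarray(arr, dtype=float)
        if a.shape != (3,) or not np.isfinite(a).all():
            raise ValueError("EnergyTriple requires three finite values")
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass
class RBFConfig:
    """Gaussian radial basis on exponentially spaced centers with a cosine
    cutoff envelope, so every component decays smoothly to zero at the
    cutoff radius."""

    n_basis: int = 64
    cutoff: float = 10.0
    r_min: float = 0.8  # Å, first center

    def __post_init__(self) -> None:
        if self.n_basis < 1 or self.cutoff <= 0:
            raise ValueError("n_basis >= 1 and cutoff > 0 required")

    def centers_widths(self) -> tuple[np.ndarray, np.ndarray]:
        centers = np.exp(np.linspace(np.log(self.r_min), np.log(self.cutoff), self.n_basis))
        if self.n_basis > 1:
            spacing = np.gradient(centers)
        else:
            spacing = np.array([self.cutoff - self.r_min or 1.0])
        widths = np.maximum(spacing, 1e-3)
        return centers, widths


@dataclass
class ModelConfig:
    """Architecture hyperparameters; defaults sized for CPU work."""

    embedding_dim: int = 128
    n_interaction: int = 3
    n_residual: int = 2
    n_output_residual: int = 2
    n_rbf: int = 64
    cutoff: float = 10.0
    activation: str = "shifted_softplus"
    elements: tuple[int, ...] = DEFAULT_Z
    n_heads: int = 3

    def __post_init__(self) -> None:
        if self.n_interaction < 1:
            raise ValueError("n_interaction must be >= 1")
        if self.n_heads != 3:
            raise ValueError("the multitask model has exactly three heads")

    @property
    def rbf(self) -> RBFConfig:
        return RBFConfig(n_basis=self.n_rbf, cutoff=self.cutoff)

    def z_index(self) -> dict[int, int]:
        return {z: i for i, z in enumerate(self.elements)}


@dataclass
class MolecularGraph:
    """Distance graph of one structure: nodes are atoms, edges are all
    ordered pairs closer than the cutoff."""

    atomic_numbers: np.ndarray  # (n,)
    edge_src: np.ndarray  # (E,) source node of each directed edge
    edge_dst: np.ndarray  # (E,)
    distances: np.ndarray  # (E,) Å
    rbf: np.ndarray | None = None  # optional precomputed (E, n_basis) features

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    def ensure_rbf(self, cfg: "RBFConfig") -> np.ndarray:
        if self.rbf is None:
            self.rbf = (
                rbf_expand(self.distances, cfg)
                if len(self.distances)
                else np.zeros((0, cfg.n_basis))
            )
        return self.rbf


@dataclass
class GraphBatch:
    """Disjoint union of graphs with per-node graph ids for segment sums."""

    atomic_numbers: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray
    distances: np.ndarray
    node_graph: np.ndarray
    n_graphs: int
    rbf_cache: np.ndarray | None = None

    @classmethod
    def from_graphs(cls, graphs: Sequence[MolecularGraph]) -> "GraphBatch":
        z, src, dst, dist, gid = [], [], [], [], []
        offset = 0
        for g_i, g in enumerate(graphs):
            z.append(g.atomic_numbers)
            src.append(g.edge_src + offset)
            dst.append(g.edge_dst + offset)
            dist.append(g.distances)
            gid.append(np.full(g.n_atoms, g_i, dtype=np.intp))
            offset += g.n_atoms
        rbf_cache = None
        if graphs and all(g.rbf is not None for g in graphs):
            rbf_cache = np.vstack([g.rbf for g in graphs])
        return cls(
            atomic_numbers=np.concatenate(z),
            edge_src=np.concatenate(src) if src else np.empty(0, dtype=np.intp),
            edge_dst=np.concatenate(dst) if dst else np.empty(0, dtype=np.intp),
            distances=np.concatenate(dist) if dist else np.empty(0),
            node_graph=np.concatenate(gid),
            n_graphs=len(graphs),
            rbf_cache=rbf_cache,
        )


def build_graph(
    conf: Conformer3D,
    mol: Molecule | None = None,
    cutoff: float = 10.0,
    atomic_numbers: Sequence[int] | None = None,
) -> MolecularGraph:
    """Distance graph from a conformer: ordered atom pairs with r < cutoff.

    Atomic numbers come from ``atomic_numbers`` if given, else from ``mol``
    with explicit hydrogens when the conformer includes them.
    """
    coords = np.asarray(conf.coordinates, dtype=float)
    n = len(coords)
    if atomic_numbers is not None:
        z = np.asarray(atomic_numbers, dtype=np.intp)
    elif mol is not None:
        rdmol = mol.rdmol
        if rdmol.GetNumAtoms() != n:
            from rdkit import Chem

            rdmol = Chem.AddHs(rdmol)
        if rdmol.GetNumAtoms() != n:
            raise ValueError("conformer does not align with molecule atom count")
        z = np.array([a.GetAtomicNum() for a in rdmol.GetAtoms()], dtype=np.intp)
    else:
        raise ValueError("provide mol or atomic_numbers")
    if len(z) != n:
        raise ValueError("atomic_numbers length must match conformer")

    diff = coords[:, None, :] - coords[None, :, :]
    dmat = np.sqrt((diff**2).sum(axis=-1))
    iu, ju = np.triu_indices(n, k=1)
    if np.any(dmat[iu, ju] == 0.0):
        raise ValueError("two atoms at identical coordinates (zero distance)")
    mask = (dmat < cutoff) & ~np.eye(n, dtype=bool)
    src, dst = np.nonzero(mask)
    return MolecularGraph(
        atomic_numbers=z,
        edge_src=src.astype(np.intp),
        edge_dst=dst.astype(np.intp),
        distances=dmat[src, dst],
    )


def rbf_expand(r, cfg: RBFConfig) -> np.ndarray:
    """Expand distances into ``n_basis`` Gaussian features with a cosine
    cutoff envelope; components lie in [0, 1] and vanish at the cutoff."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r <= 0):
        raise ValueError("distances must be positive")
    centers, widths = cfg.centers_widths()
    env = np.where(r < cfg.cutoff, 0.5 * (np.cos(np.pi * np.clip(r / cfg.cutoff, 0, 1)) + 1.0), 0.0)
    feats = np.exp(-((r[:, None] - centers[None, :]) ** 2) / (2.0 * widths[None, :] ** 2))
    return feats * env[:, None]


# ---------------------------------------------------------------------------
# parameters


def init_params(cfg: ModelConfig, seed: int = 0) -> dict[str, Tensor]:
    """Glorot-initialized parameter dictionary (seeded, reproducible)."""
    rng = np.random.default_rng(seed)
    F = cfg.embedding_dim

    def glorot(shape):
        limit = np.sqrt(6.0 / sum(shape))
        return parameter(rng.uniform(-limit, limit, size=shape))

    params: dict[str, Tensor] = {}
    params["embed"] = parameter(rng.uniform(-np.sqrt(3), np.sqrt(3), size=(len(cfg.elements), F)))
    for t in range(cfg.n_interaction):
        p = f"int{t}."
        params[p + "Wg"] = glorot((cfg.n_rbf, F))
        params[p + "Wm"] = glorot((F, F))
        params[p + "bm"] = parameter(np.zeros(F))
        params[p + "Ws"] = glorot((F, F))
        params[p + "bs"] = parameter(np.zeros(F))
        for r in range(cfg.n_residual):
            q = f"{p}res{r}."
            params[q + "W1"] = glorot((F, F))
            params[q + "b1"] = parameter(np.zeros(F))
            params[q + "W2"] = glorot((F, F))
            params[q + "b2"] = parameter(np.zeros(F))
        params[p + "gate"] = parameter(np.ones(F))
    for r in range(cfg.n_output_residual):
        q = f"out.res{r}."
        params[q + "W1"] = glorot((F, F))
        params[q + "b1"] = parameter(np.zeros(F))
        params[q + "W2"] = glorot((F, F))
        params[q + "b2"] = parameter(np.zeros(F))
    params["out.W"] = parameter(np.zeros((F, cfg.n_heads)))  # zero-init heads: start at shifts
    params["out.b"] = parameter(np.zeros(cfg.n_heads))
    return params


def _residual(x: Tensor, params: dict[str, Tensor], prefix: str, n_blocks: int) -> Tensor:
    for r in range(n_blocks):
        q = f"{prefix}res{r}."
        h = (x.shifted_softplus() @ params[q + "W1"] + params[q + "b1"]).shifted_softplus()
        x = x + (h @ params[q + "W2"] + params[q + "b2"])
    return x


def forward_batch(
    params: dict[str, Tensor], batch: GraphBatch, cfg: ModelConfig
) -> Tensor:
    """Molecular energy triples for a batch of graphs; shape (n_graphs, 3)."""
    z_index = cfg.z_index()
    try:
        z_idx = np.array([z_index[int(z)] for z in batch.atomic_numbers], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"element Z={exc.args[0]} has no embedding row") from None

    if batch.rbf_cache is None:
        batch.rbf_cache = rbf_expand(batch.distances, cfg.rbf) if len(batch.distances) else np.zeros((0, cfg.n_rbf))
    g = Tensor(batch.rbf_cache)

    n_nodes = len(batch.atomic_numbers)
    x = params["embed"].take_rows(z_idx)
    for t in range(cfg.n_interaction):
        p = f"int{t}."
        filt = g @ params[p + "Wg"]  # (E, F)
        src_feat = (x @ params[p + "Wm"] + params[p + "bm"]).shifted_softplus()
        msgs = src_feat.take_rows(batch.edge_src) * filt
        agg = msgs.segment_sum(batch.edge_dst, n_nodes)
        xt = (x @ params[p + "Ws"] + params[p + "bs"] + agg).shifted_softplus()
        xt = _residual(xt, params, p, cfg.n_residual)
        x = params[p + "gate"] * x + xt
    x = _residual(x, params, "out.", cfg.n_output_residual)
    atomic = x @ params["out.W"] + params["out.b"]  # (n_nodes, 3)
    return atomic.segment_sum(batch.node_graph, batch.n_graphs)


def forward(params: dict[str, Tensor], graph: MolecularGraph, cfg: ModelConfig) -> EnergyTriple:
    """Energy triple of one graph (kcal/mol, before element-shift restore)."""
    if graph.n_atoms < 1:
        raise ValueError("graph must contain at least one atom")
    out = forward_batch(params, GraphBatch.from_graphs([graph]), cfg)
    return EnergyTriple.from_array(out.data[0])


def predict_pair_delta(
    graph_a: MolecularGraph, graph_b: MolecularGraph, params: dict[str, Tensor], cfg: ModelConfig
) -> float:
    """Siamese aqueous-energy difference E_water(B) − E_water(A), kcal/mol.

    Both branches share one parameter set; positive values mean state A is
    predicted more stable in water.  Each branch is evaluated through the
    identical single-graph path so the delta is exactly antisymmetric and
    exactly zero for identical inputs.
    """
    e_a = forward(params, graph_a, cfg).E_water
    e_b = forward(params, graph_b, cfg).E_water
    return float(e_b - e_a)


# ---------------------------------------------------------------------------
# element reference shifts and checkpoints


def composition_matrix(graphs: Sequence[MolecularGraph], elements: Sequence[int]) -> np.ndarray:
    z_index = {z: i for i, z in enumerate(elements)}
    comp = np.zeros((len(graphs), len(elements)))
    for i, g in enumerate(graphs):
        for z in g.atomic_numbers:
            comp[i, z_index[int(z)]] += 1
    return comp


def fit_element_shifts(
    graphs: Sequence[MolecularGraph], targets: np.ndarray, elements: Sequence[int]
) -> np.ndarray:
    """Per-element reference energies (least squares on composition).

    Subtracting these from extensive labels before training centers the
    regression problem; they are restored at prediction time.
    """
    comp = composition_matrix(graphs, elements)
    targets = np.asarray(targets, dtype=float)
    shifts, *_ = np.linalg.lstsq(comp, targets, rcond=None)
    return shifts  # (n_elements, 3)


def shift_energy(graphs: Sequence[MolecularGraph], shifts: np.ndarray, elements: Sequence[int]) -> np.ndarray:
    return composition_matrix(graphs, elements) @ shifts


def save_checkpoint(
    path: str | Path,
    params: dict[str, Tensor],
    cfg: ModelConfig,
    shifts: np.ndarray | None = None,
    provenance: dict | None = None,
) -> None:
    """Single-file .npz archive: config echo, parameters, element shifts,
    provenance (seed, package version)."""
    from .. import __version__

    arrays = {f"param/{k}": v.data for k, v in params.items()}
    if shifts is not None:
        arrays["shifts"] = np.asarray(shifts)
    meta = {"config": asdict(cfg), "provenance": {"version": __version__, **(provenance or {})}}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)


def load_checkpoint(path: str | Path):
    data = np.load(str(path))
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg_dict = meta["config"]
    cfg_dict["elements"] = tuple(cfg_dict["elements"])
    cfg = ModelConfig(**cfg_dict)
    params = {
        k[len("param/") :]: parameter(data[k]) for k in data.files if k.startswith("param/")
    }
    shifts = data["shifts"] if "shifts" in data.files else None
    return params, cfg, shifts, meta["provenance"]


def clone_params(params: dict[str, Tensor]) -> dict[str, Tensor]:
    return {k: parameter(v.data.copy()) for k, v in params.items()}
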