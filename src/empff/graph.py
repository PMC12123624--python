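"""Atomic configurations, periodic neighbor lists, and molecule identification.

Conventions: Cartesian coordinates in Å, cell rows are lattice vectors,
periodic shifts are integer lattice multiples (the extended-XYZ convention).
The neighbor list is directed — both (i, j) and (j, i) edges are present —
and includes pairs with ``‖r_ij‖ ≤ r_cut`` (boundary included; the model's
smooth cutoff envelope vanishes there, so the convention is numerically
immaterial).  Cells smaller than 2·r_cut are handled by explicit image
enumeration, not minimum image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .units import COVALENT_RADII


@dataclass
class AtomicConfiguration:
    """An atomic structure with optional periodic cell and reference labels.

    species: atomic numbers (N,); positions: (N, 3) Å; cell: (3, 3) Å rows
    or None; pbc: 3 booleans; labels: energy (eV), forces (N, 3) eV/Å,
    stress (3, 3) eV/Å³.  ``info`` carries free metadata (molecule key,
    subset tag, ...).
    """

    species: np.ndarray
    positions: np.ndarray
    cell: np.ndarray | None = None
    pbc: tuple[bool, bool, bool] = (False, False, False)
    energy: float | None = None
    forces: np.ndarray | None = None
    stress: np.ndarray | None = None
    velocities: np.ndarray | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.species = np.asarray(self.species, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.species)
        if n < 1:
            raise ValueError("configuration must contain at least one atom")
        if self.positions.shape != (n, 3):
            raise ValueError("positions must have shape (N, 3)")
        self.pbc = tuple(bool(b) for b in self.pbc)
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float)
            if self.cell.shape != (3, 3):
                raise ValueError("cell must be 3×3")
        if any(self.pbc):
            if self.cell is None or abs(np.linalg.det(self.cell)) < 1e-10:
                raise ValueError("periodic configuration requires a nonsingular cell")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != (n, 3):
                raise ValueError("forces shape must match (N, 3)")
        if self.stress is not None:
            self.stress = np.asarray(self.stress, dtype=float)
            if self.stress.shape != (3, 3):
                raise ValueError("stress must be 3×3")

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def volume(self) -> float:
        if self.cell is None:
            raise ValueError("no cell defined")
        return float(abs(np.linalg.det(self.cell)))

    def copy(self) -> "AtomicConfiguration":
        return AtomicConfiguration(
            species=self.species.copy(), positions=self.positions.copy(),
            cell=None if self.cell is None else self.cell.copy(),
            pbc=self.pbc, energy=self.energy,
            forces=None if self.forces is None else self.forces.copy(),
            stress=None if self.stress is None else self.stress.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
            info=dict(self.info))


@dataclass
class NeighborList:
    """Directed edges within r_cut, with integer periodic shift vectors."""

    idx_i: np.ndarray   # (E,)
    idx_j: np.ndarray   # (E,)
    shifts: np.ndarray  # (E, 3) integers
    r_cut: float

    @property
    def n_edges(self) -> int:
        return len(self.idx_i)

    def vectors(self, config: AtomicConfiguration) -> np.ndarray:
        """Edge vectors r_ij = r_j + shift·cell − r_i (from i to j)."""
        rj = config.positions[self.idx_j]
        if config.cell is not None and self.shifts.size:
            rj = rj + self.shifts @ config.cell
        return rj - config.positions[self.idx_i]


def build_neighbor_list(config: AtomicConfiguration, r_cut: float) -> NeighborList:
    """All directed pairs with ‖r_ij‖ ≤ r_cut, sorted by (i, j, shift)."""
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    pos = config.positions
    n = config.n_atoms
    if not any(config.pbc):
        if n == 1:
            return NeighborList(np.empty(0, int), np.empty(0, int),
                                np.empty((0, 3), int), r_cut)
        tree = cKDTree(pos)
        pairs = tree.query_pairs(r_cut, output_type="ndarray")
        ii = np.concatenate([pairs[:, 0], pairs[:, 1]])
        jj = np.concatenate([pairs[:, 1], pairs[:, 0]])
        shifts = np.zeros((len(ii), 3), dtype=int)
        return _sorted_nl(ii, jj, shifts, r_cut)

    cell = config.cell
    # perpendicular widths h_a = V / |b × c| etc.; enumerate enough images
    V = abs(np.linalg.det(cell))
    nmax = []
    for a in range(3):
        b, c = cell[(a + 1) % 3], cell[(a + 2) % 3]
        h = V / np.linalg.norm(np.cross(b, c))
        nmax.append(int(np.ceil(r_cut / h)) if config.pbc[a] else 0)
    ranges = [np.arange(-m, m + 1) for m in nmax]
    shifts_all = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)

    ii_l, jj_l, sh_l = [], [], []
    for s in shifts_all:
        disp = pos[None, :, :] + s @ cell - pos[:, None, :]   # (N, N, 3)
        d = np.linalg.norm(disp, axis=-1)
        mask = d <= r_cut
        if not s.any():
            np.fill_diagonal(mask, False)
        i_idx, j_idx = np.nonzero(mask)
        if len(i_idx):
            ii_l.append(i_idx)
            jj_l.append(j_idx)
            sh_l.append(np.tile(s, (len(i_idx), 1)))
    if not ii_l:
        return NeighborList(np.empty(0, int), np.empty(0, int),
                            np.empty((0, 3), int), r_cut)
    return _sorted_nl(np.concatenate(ii_l), np.concatenate(jj_l),
                      np.vstack(sh_l), r_cut)


def _sorted_nl(ii, jj, shifts, r_cut) -> NeighborList:
    order = np.lexsort((shifts[:, 2], shifts[:, 1], shifts[:, 0], jj, ii))
    return NeighborList(ii[order].astype(int), jj[order].astype(int),
                        shifts[order].astype(int), float(r_cut))


@dataclass
class MoleculeAssignment:
    """Partition of atoms into bonded connected components.

    Labels are contiguous integers, ordered by each component's lowest
    atom index.
    """

    labels: np.ndarray

    @property
    def n_molecules(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def members(self, mol: int) -> np.ndarray:
        return np.nonzero(self.labels == mol)[0]


def identify_molecules(config: AtomicConfiguration,
                       bond_scale: float = 1.2) -> MoleculeAssignment:
    """Connected components of the covalent-radius bond graph.

    Atoms i, j are bonded when their (minimum-image) distance is at most
    ``bond_scale · (r_cov(i) + r_cov(j))``.
    """
    rcov = np.array([COVALENT_RADII[int(z)] for z in config.species])
    max_bond = 2.0 * bond_scale * rcov.max() + 1e-12
    nl = build_neighbor_list(config, max_bond)
    if nl.n_edges:
        d = np.linalg.norm(nl.vectors(config), axis=1)
        cutoffs = bond_scale * (rcov[nl.idx_i] + rcov[nl.idx_j])
        bonded = d <= cutoffs
        rows, cols = nl.idx_i[bonded], nl.idx_j[bonded]
    else:
        rows = cols = np.empty(0, int)
    n = config.n_atoms
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, raw = connected_components(adj, directed=False)
    # stable relabeling by lowest atom index
    first = {}
    for atom, lab in enumerate(raw):
        first.setdefault(lab, atom)
    order = sorted(first, key=first.get)
    remap = {lab: i for i, lab in enumerate(order)}
    return MoleculeAssignment(np.array([remap[l] for l in raw], dtype=int))


def bond_list(config: AtomicConfiguration,
              bond_scale: float = 1.2) -> np.ndarray:
    """Unique bonded pairs (i < j by convention for shift-0 bonds).

    Returns an (n_bonds, 5) integer array: i, j, shift — each undirected
    bond appears once.
    """
    rcov = np.array([COVALENT_RADII[int(z)] for z in config.species])
    max_bond = 2.0 * bond_scale * rcov.max() + 1e-12
    nl = build_neighbor_list(config, max_bond)
    if not nl.n_edges:
        return np.empty((0, 5), dtype=int)
    d = np.linalg.norm(nl.vectors(config), axis=1)
    cutoffs = bond_scale * (rcov[nl.idx_i] + rcov[nl.idx_j])
    sel = d <= cutoffs
    rows = np.column_stack([nl.idx_i[sel], nl.idx_j[sel], nl.shifts[sel]])
    # keep one direction of each bond: i<j, or i==j with lexicographically
    # positive shift; ties for i<j with nonzero shift keep both images only
    # once by shift sign convention
    keep = []
    for r in rows:
        i, j, s = r[0], r[1], r[2:]
        if i < j or (i == j and tuple(s) > (0, 0, 0)):
            keep.append(r)
        elif i == j and tuple(s) == (0, 0, 0):
            continue
    if not keep:
        return np.empty((0, 5), dtype=int)
    return np.array(keep, dtype=int)
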