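"""Evaluation statistics: RMSEs, the intermolecular force decomposition,
torsion barrier-height errors, and scan geometry RMSD.

The intermolecular force of a molecule is defined as the least-squares
projection of its atomic forces onto the 6-dimensional rigid-body space
(3 translations + 3 rotations about the center of mass); the orthogonal
residual is the intramolecular component.  A single-molecule configuration
with exactly symmetry-obeying forces therefore has zero intermolecular
force — deviations measure violations of translational/rotational force
sum rules in the reference data.  Rigid-body basis weighting is uniform
(unit masses) by default, switchable to mass weighting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .geometry import kabsch_superpose
from .graph import AtomicConfiguration, MoleculeAssignment
from .units import masses_for


# ---------------------------------------------------------------------------
# pointwise errors
# ---------------------------------------------------------------------------

def energy_force_rmse(predictions, references):
    """(per-atom energy RMSE in meV/atom, force RMSE in meV/Å).

    ``predictions`` and ``references`` are matched lists of
    configurations carrying ``energy`` (eV) and optionally ``forces``
    (eV/Å).  Energy errors are normalized per atom *before* squaring;
    the force RMSE runs over all Cartesian components.
    """
    if len(predictions) != len(references):
        raise ValueError("prediction/reference lists differ in length")
    e_sq, f_sq, n_f = [], 0.0, 0
    for p, r in zip(predictions, references):
        if p.n_atoms != r.n_atoms:
            raise ValueError("configuration size mismatch")
        e_sq.append(((p.energy - r.energy) / r.n_atoms) ** 2)
        if p.forces is not None and r.forces is not None:
            d = p.forces - r.forces
            f_sq += float(np.sum(d * d))
            n_f += d.size
    e_rmse = float(np.sqrt(np.mean(e_sq))) * 1000.0
    f_rmse = float(np.sqrt(f_sq / n_f)) * 1000.0 if n_f else float("nan")
    return e_rmse, f_rmse


# ---------------------------------------------------------------------------
# intermolecular force decomposition
# ---------------------------------------------------------------------------

@dataclass
class ForceDecomposition:
    """Split of atomic forces into rigid-body and intramolecular parts.

    ``intermolecular + residual == forces`` exactly; per molecule the
    residual has zero net force and zero net torque about the center of
    mass.
    """

    intermolecular: np.ndarray
    residual: np.ndarray

    @property
    def forces(self) -> np.ndarray:
        return self.intermolecular + self.residual


def _rigid_body_basis(positions: np.ndarray, weights: np.ndarray):
    """3N×6 basis of rigid translations and rotations about the COM."""
    com = np.average(positions, axis=0, weights=weights)
    rel = positions - com
    n = len(positions)
    basis = np.zeros((3 * n, 6))
    for a in range(3):
        basis[a::3, a] = 1.0
    for a, axis in enumerate(np.eye(3)):
        basis[:, 3 + a] = np.cross(np.tile(axis, (n, 1)), rel).ravel()
    return basis


def intermolecular_force_projection(
        config: AtomicConfiguration, forces: np.ndarray,
        molecules: MoleculeAssignment,
        mass_weighted: bool = False) -> ForceDecomposition:
    """Per-molecule least-squares projection onto the rigid-body space.

    Linear molecules have a rank-5 rigid space (rotation about the axis is
    absent); a rank-revealing solve handles the degeneracy.  Single atoms
    project entirely onto translations.
    """
    n = config.n_atoms
    if len(molecules.labels) != n:
        raise ValueError("molecule assignment does not partition the atoms")
    inter = np.zeros((n, 3))
    weights = (masses_for(config.species) if mass_weighted
               else np.ones(n))
    for mol in range(molecules.n_molecules):
        idx = molecules.members(mol)
        D = _rigid_body_basis(config.positions[idx], weights[idx])
        f = forces[idx].ravel()
        coef, *_ = np.linalg.lstsq(D, f, rcond=1e-10)
        inter[idx] = (D @ coef).reshape(-1, 3)
    return ForceDecomposition(intermolecular=inter,
                              residual=forces - inter)


def intermolecular_force_rmse(pred: ForceDecomposition,
                              ref: ForceDecomposition):
    """(RMSE of the intermolecular fields in meV/Å, reference RMS in meV/Å).

    The second value is the overall magnitude of the reference
    intermolecular forces, for relative-error reporting.
    """
    d = pred.intermolecular - ref.intermolecular
    rmse = float(np.sqrt(np.mean(d * d))) * 1000.0
    ref_rms = float(np.sqrt(np.mean(ref.intermolecular ** 2))) * 1000.0
    return rmse, ref_rms


# ---------------------------------------------------------------------------
# torsion profiles
# ---------------------------------------------------------------------------

@dataclass
class TorsionProfile:
    """Relative torsion energies (kcal/mol, min-shifted) on an angle grid."""

    angles: np.ndarray
    energies: np.ndarray
    geometries: np.ndarray | None = None
    converged: np.ndarray | None = None

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.angles.shape != self.energies.shape:
            raise ValueError("angles and energies must align")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angle grid must be strictly increasing")
        if abs(self.energies.min()) > 1e-9:
            self.energies = self.energies - self.energies.min()

    @property
    def barrier_height(self) -> float:
        return float(self.energies.max() - self.energies.min())

    def to_csv(self, path):
        np.savetxt(path, np.column_stack([self.angles, self.energies]),
                   delimiter=",", header="angle_deg,energy_kcal_mol",
                   comments="")

    @classmethod
    def from_csv(cls, path) -> "TorsionProfile":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(angles=data[:, 0], energies=data[:, 1])


def barrier_height_error(pred: TorsionProfile, ref: TorsionProfile) -> float:
    """|pred barrier − ref barrier| in kcal/mol (global max − global min)."""
    if not np.array_equal(pred.angles, ref.angles):
        raise ValueError("profiles are on different angle grids")
    return abs(pred.barrier_height - ref.barrier_height)


def mean_barrier_height_error(pred_profiles, ref_profiles) -> float:
    """Mean barrier-height error over a batch of molecules."""
    if len(pred_profiles) != len(ref_profiles):
        raise ValueError("batch length mismatch")
    return float(np.mean([barrier_height_error(p, r)
                          for p, r in zip(pred_profiles, ref_profiles)]))


def scan_geometry_rmsd(pred_geometries, ref_geometries) -> float:
    """Mean optimal-superposition RMSD (Å) over matched scan geometries.

    Rigid alignment (rotation + translation) per scan point, no atom
    reordering; averaged over the grid.
    """
    pred = np.asarray(pred_geometries, dtype=float)
    ref = np.asarray(ref_geometries, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("geometry series shape mismatch (atom count?)")
    if pred.ndim == 2:
        pred, ref = pred[None], ref[None]
    vals = [kabsch_superpose(p, q)[0] for p, q in zip(pred, ref)]
    return float(np.mean(vals))


def metrics_report(path, **metrics):
    """Write a flat JSON metrics report."""
    with open(path, "w") as fh:
        json.dump({k: float(v) for k, v in metrics.items()}, fh, indent=2)
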