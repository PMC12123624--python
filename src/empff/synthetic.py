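"""Synthetic labeled datasets: an analytic short-range "mock QM" labeler.

Real reference labels for this model family come from large quantum
chemistry calculations.  For development and testing this module supplies
an analytic stand-in: a smooth (C²) classical toy potential — harmonic
bonds and angles, cosine torsions, and a short-range intermolecular well
that vanishes identically beyond a truncation radius r_t — together with
dataset generators that emulate the structure of the real training sets
(monomers, dimers, clusters, liquid boxes, molecular crystals) with
conformers sampled by randomized perturbation plus short thermostatted
dynamics at 300 K and 500 K.

Because the toy potential is strictly short-ranged (zero beyond r_t, which
is chosen inside the model cutoff) and smooth, a short-range model can in
principle represent it exactly; parameter recovery on these datasets tests
the architecture and training loop, not missing physics.

All generated label sets carry exact analytic forces (and stress for
periodic systems); every generator is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .graph import AtomicConfiguration, bond_list, build_neighbor_list, \
    identify_molecules
from .model import EnergyResult, cutoff_envelope, cutoff_envelope_grad

# default isolated-atom reference energies of the two toy elements
# ("toy-O" → z=8, "toy-H" → z=1), loosely atom-like in magnitude (eV)
DEFAULT_E0 = {1: -13.6, 8: -2000.0}


@dataclass(frozen=True)
class ToyPotentialSpec:
    """Parameters of the analytic labeler.

    Bonded terms: harmonic bonds (r0 Å, k eV/Å²) per element pair,
    harmonic angles (θ0 rad, k eV/rad²), cosine torsions
    ``V/2·(1 + cos(nφ − γ))``.  The nonbonded term acts only between
    atoms of *different* molecules (and between periodic images): a
    Morse-style well of depth ε at radius σ, smoothly truncated to zero
    at r_t (C²).  r_t must stay inside the force-field cutoff so that a
    short-range model can represent the potential exactly.
    """

    bond_r0: tuple = ((1, 8, 0.97), (8, 8, 1.45), (1, 1, 0.74))
    bond_k: float = 30.0            # eV/Å²
    angle_theta0: float = np.deg2rad(104.5)
    angle_k: float = 3.0            # eV/rad²
    torsion_v: float = 0.1          # eV (≈ 2.3 kcal/mol barrier)
    torsion_n: int = 3
    torsion_gamma: float = 0.0
    nb_epsilon: float = 0.01        # eV
    nb_sigma: float = 3.2           # Å
    nb_a: float = 1.5               # 1/Å, well stiffness
    nb_r_t: float = 4.2             # Å, strict truncation radius
    e0: tuple = tuple(sorted(DEFAULT_E0.items()))

    def bond_length(self, zi: int, zj: int) -> float:
        for a, b, r0 in self.bond_r0:
            if {a, b} == {zi, zj}:
                return r0
        raise KeyError(f"no bond length for pair ({zi}, {zj})")

    @property
    def e0_map(self) -> dict:
        return dict(self.e0)

    def validate(self, config: AtomicConfiguration | None = None,
                 tol: float = 1e-6) -> float:
        """Finite-difference check of the analytic forces; returns max error."""
        if config is None:
            rng = np.random.default_rng(1)
            pos = molecule_template("hooh").positions + \
                rng.normal(0, 0.05, (4, 3))
            config = AtomicConfiguration([1, 8, 8, 1], pos)
        pot = ToyPotential(self)
        res = pot.compute(config)
        h = 1e-5
        err = 0.0
        for i in range(config.n_atoms):
            for a in range(3):
                pp = config.copy(); pp.positions[i, a] += h
                pm = config.copy(); pm.positions[i, a] -= h
                fd = -(pot.compute(pp, forces=False).energy
                       - pot.compute(pm, forces=False).energy) / (2 * h)
                err = max(err, abs(fd - res.forces[i, a]))
        if err > tol:
            raise RuntimeError(f"toy-potential force check failed: {err:.2e}")
        return err


class ToyPotential:
    """Calculator-compatible analytic potential (energy/forces/stress).

    Molecular topology (bonds, angles, torsions) is derived from the
    unwrapped Cartesian coordinates via covalent radii; the nonbonded well
    is evaluated over all intermolecular pairs including periodic images.

    Pass ``topology`` (a reference configuration) to freeze the bond graph:
    required for geometry optimization and scans, where a
    geometry-dependent topology would let the optimizer lower the energy
    discontinuously by breaking bonds.
    """

    def __init__(self, spec: ToyPotentialSpec | None = None,
                 topology: AtomicConfiguration | None = None):
        self.spec = spec or ToyPotentialSpec()
        self._fixed = None
        if topology is not None:
            flat = AtomicConfiguration(topology.species, topology.positions)
            self._fixed = (identify_molecules(flat), bond_list(flat))

    # -- nonbonded well -----------------------------------------------------

    def _well(self, r):
        s = self.spec
        u = 1.0 - np.exp(-s.nb_a * (r - s.nb_sigma))
        V = s.nb_epsilon * (u * u - 1.0)
        S = cutoff_envelope(r, s.nb_r_t)
        dV = 2.0 * s.nb_epsilon * u * s.nb_a * np.exp(-s.nb_a * (r - s.nb_sigma))
        dS = cutoff_envelope_grad(r, s.nb_r_t)
        return V * S, dV * S + V * dS

    def compute(self, config: AtomicConfiguration, forces: bool = True,
                stress: bool | None = None) -> EnergyResult:
        s = self.spec
        pos = config.positions
        n = config.n_atoms
        e0 = s.e0_map
        energy = float(sum(e0[int(z)] for z in config.species))
        F = np.zeros((n, 3))
        virial = np.zeros((3, 3))

        # topology: frozen reference graph, or from unwrapped coordinates
        if self._fixed is not None:
            mols, bonds = self._fixed
        else:
            flat = AtomicConfiguration(config.species, pos)
            mols = identify_molecules(flat)
            bonds = bond_list(flat)
        adj = {}
        for i, j, *_ in bonds:
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)

        def add_pair(i, j, vec, dEdr, w=1.0):
            r = np.linalg.norm(vec)
            g = w * dEdr * vec / r
            F[j] -= g
            F[i] += g
            virial[:] += np.outer(g, vec)

        for i, j, *_ in bonds:
            vec = pos[j] - pos[i]
            r = np.linalg.norm(vec)
            r0 = s.bond_length(int(config.species[i]), int(config.species[j]))
            energy += 0.5 * s.bond_k * (r - r0) ** 2
            add_pair(i, j, vec, s.bond_k * (r - r0))
        # angles: all unordered neighbor pairs around each vertex
        for j in sorted(adj):
            nbrs = sorted(adj[j])
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    i, k = nbrs[a], nbrs[b]
                    th, (gi, gj, gk) = geometry.angle_and_grad(
                        pos[i], pos[j], pos[k])
                    dE = s.angle_k * (th - s.angle_theta0)
                    energy += 0.5 * s.angle_k * (th - s.angle_theta0) ** 2
                    F[i] -= dE * gi
                    F[j] -= dE * gj
                    F[k] -= dE * gk
                    # virial from the two arm vectors
                    virial += np.outer(dE * gi, pos[i] - pos[j])
                    virial += np.outer(dE * gk, pos[k] - pos[j])
        # torsions: all bonded quadruples i-j-k-l (i≠l, proper dihedrals)
        for j, k, *_ in bonds:
            for i in sorted(adj[j] - {k}):
                for l in sorted(adj[k] - {j}):
                    if i == l:
                        continue
                    phi, gs = geometry.dihedral_and_grad(
                        pos[i], pos[j], pos[k], pos[l])
                    arg = s.torsion_n * phi - s.torsion_gamma
                    energy += 0.5 * s.torsion_v * (1.0 + np.cos(arg))
                    dE = -0.5 * s.torsion_v * s.torsion_n * np.sin(arg)
                    for idx, gr in zip((i, j, k, l), gs):
                        F[idx] -= dE * gr
                    # virial via the three difference vectors of the chain
                    db1 = -gs[0]
                    db2 = -(gs[0] + gs[1])
                    db3 = gs[3]
                    virial += dE * np.outer(db1, pos[j] - pos[i])
                    virial += dE * np.outer(db2, pos[k] - pos[j])
                    virial += dE * np.outer(db3, pos[l] - pos[k])

        # nonbonded: intermolecular pairs (incl. periodic images)
        nl = build_neighbor_list(config, s.nb_r_t)
        if nl.n_edges:
            vecs = nl.vectors(config)
            r = np.linalg.norm(vecs, axis=1)
            same_mol = mols.labels[nl.idx_i] == mols.labels[nl.idx_j]
            direct = ~nl.shifts.any(axis=1)
            exclude = same_mol & direct
            sel = ~exclude
            if sel.any():
                V, dV = self._well(r[sel])
                energy += 0.5 * float(V.sum())   # each pair appears twice
                g = 0.5 * dV[:, None] * vecs[sel] / r[sel, None]
                np.add.at(F, nl.idx_j[sel], -g)
                np.add.at(F, nl.idx_i[sel], g)
                virial += np.einsum("ea,eb->ab", g, vecs[sel])

        res = EnergyResult(energy=energy, site_energies=None, forces=F)
        res.site_energies = np.full(n, energy / n)  # not physically resolved
        want_stress = all(config.pbc) if stress is None else stress
        if want_stress:
            res.stress = 0.5 * (virial + virial.T) / config.volume
        return res


def toy_labeler(spec: ToyPotentialSpec,
                config: AtomicConfiguration) -> EnergyResult:
    """Analytic labels (energy, forces, stress for periodic) for a config."""
    return ToyPotential(spec).compute(config, stress=all(config.pbc))


# ---------------------------------------------------------------------------
# molecule templates and dataset generators
# ---------------------------------------------------------------------------

def molecule_template(name: str) -> AtomicConfiguration:
    """Rigid toy-molecule templates built from the default toy bond lengths.

    ``bent``: O(H)H water-like triatomic; ``hooh``: H-O-O-H chain with one
    soft torsion; ``oh``: diatomic.
    """
    if name == "bent":
        th = np.deg2rad(104.5)
        r0 = 0.97
        pos = [[0.0, 0.0, 0.0],
               [r0, 0.0, 0.0],
               [r0 * np.cos(th), r0 * np.sin(th), 0.0]]
        return AtomicConfiguration([8, 1, 1], pos)
    if name == "hooh":
        roo, roh = 1.45, 0.97
        th = np.deg2rad(104.5)
        phi = np.deg2rad(110.0)
        p_o1 = np.array([0.0, 0.0, 0.0])
        p_o2 = np.array([roo, 0.0, 0.0])
        p_h1 = p_o1 + roh * np.array([np.cos(np.pi - th), np.sin(np.pi - th), 0])
        p_h2 = p_o2 + roh * np.array([np.cos(th),
                                      np.sin(th) * np.cos(phi),
                                      np.sin(th) * np.sin(phi)])
        return AtomicConfiguration([1, 8, 8, 1],
                                   np.array([p_h1, p_o1, p_o2, p_h2]))
    if name == "oh":
        return AtomicConfiguration([8, 1], [[0, 0, 0], [0.97, 0, 0]])
    raise ValueError(f"unknown template {name!r} "
                     "(available: bent, hooh, oh)")


TEMPLATES = ("bent", "hooh", "oh")


def _random_rotation(rng) -> np.ndarray:
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _thermalize(config: AtomicConfiguration, pot: ToyPotential,
                temperature: float, rng, n_steps: int = 40,
                dt: float = 0.5) -> AtomicConfiguration:
    """Short seeded Langevin run to draw a thermal-ish conformer."""
    from .simulate import run_md   # local import: simulate builds on this module
    traj = run_md(pot, config, ensemble="nvt", temperature=temperature,
                  timestep=dt, n_steps=n_steps, friction=0.05,
                  seed=int(rng.integers(2**31 - 1)), stride=n_steps)
    out = config.copy()
    out.positions = traj.positions[-1]
    out.velocities = None
    return out


def _conformer(template: str, temperature: float, pot: ToyPotential, rng):
    c = molecule_template(template).copy()
    c.positions = c.positions + rng.normal(0.0, 0.03, c.positions.shape)
    c = _thermalize(c, pot, temperature, rng)
    c.positions = (c.positions - c.positions.mean(axis=0)) @ _random_rotation(rng).T
    return c


def _label(config: AtomicConfiguration, pot: ToyPotential):
    res = pot.compute(config, stress=all(config.pbc))
    config.energy = res.energy
    config.forces = res.forces
    config.stress = res.stress
    return config


def generate_dataset(kind: str, n: int, seed: int = 0,
                     spec: ToyPotentialSpec | None = None,
                     temperatures=(300.0, 500.0),
                     n_molecules: int | None = None):
    """Seeded synthetic datasets mirroring the real training-set structure.

    kinds: ``molecules`` (monomer conformers), ``dimers``, ``clusters``
    (3-6 molecules), ``liquid_box`` (periodic), ``crystal`` (periodic
    simple-cubic molecular crystal).  Each record carries a molecule key
    (conformers of one molecule identity share it), a subset tag, and the
    sampling temperature, plus analytic energy/force (and stress) labels.

    Returns a :class:`empff.training.LabeledDataset`.
    """
    from .training import LabeledDataset
    if n < 1:
        raise ValueError("n must be ≥ 1")
    spec = spec or ToyPotentialSpec()
    pot = ToyPotential(spec)
    spec.validate()
    rng = np.random.default_rng(seed)
    n_ident = n_molecules or max(1, n // 5)
    records = []
    for idx in range(n):
        T = float(temperatures[idx % len(temperatures)])
        if kind == "molecules":
            ident = idx % n_ident
            c = _conformer(TEMPLATES[ident % len(TEMPLATES)], T, pot, rng)
            key = f"mol{ident:04d}"
        elif kind == "dimers":
            ident = idx % n_ident
            t1 = TEMPLATES[ident % len(TEMPLATES)]
            t2 = TEMPLATES[(ident // len(TEMPLATES)) % len(TEMPLATES)]
            a = _conformer(t1, T, pot, rng)
            b = _conformer(t2, T, pot, rng)
            sep = rng.uniform(2.8, 5.0)
            direction = _random_rotation(rng)[:, 0]
            c = AtomicConfiguration(
                np.concatenate([a.species, b.species]),
                np.vstack([a.positions, b.positions + sep * direction]))
            key = f"dim{ident:04d}"
        elif kind == "clusters":
            ident = idx % n_ident
            n_mol = int(rng.integers(3, 7))
            parts, centers = [], []
            for _ in range(n_mol):
                m = _conformer(TEMPLATES[int(rng.integers(len(TEMPLATES)))],
                               T, pot, rng)
                for _try in range(500):
                    ctr = rng.uniform(-1.0, 1.0, 3) * (n_mol ** (1 / 3)) * 2.8
                    if all(np.linalg.norm(ctr - c0) > 4.0 for c0 in centers):
                        break
                centers.append(ctr)
                parts.append((m.species, m.positions + ctr))
            c = AtomicConfiguration(
                np.concatenate([p[0] for p in parts]),
                np.vstack([p[1] for p in parts]))
            key = f"clu{ident:04d}"
        elif kind == "liquid_box":
            ident = idx % n_ident
            n_mol = n_molecules or 8
            a_lat = 4.0
            side = int(np.ceil(n_mol ** (1 / 3)))
            cell = np.eye(3) * (side * a_lat)
            sites = [(i, j, k) for i in range(side)
                     for j in range(side) for k in range(side)][:n_mol]
            parts = []
            for site in sites:
                m = _conformer(TEMPLATES[int(rng.integers(len(TEMPLATES)))],
                               T, pot, rng)
                ctr = (np.array(site) + 0.5) * a_lat + rng.normal(0, 0.15, 3)
                parts.append((m.species, m.positions + ctr))
            c = AtomicConfiguration(
                np.concatenate([p[0] for p in parts]),
                np.vstack([p[1] for p in parts]),
                cell=cell, pbc=(True, True, True))
            key = f"liq{ident:04d}"
        elif kind == "crystal":
            ident = idx % n_ident
            a_lat = float(rng.uniform(4.0, 5.0))
            m = _conformer(TEMPLATES[ident % len(TEMPLATES)], T, pot, rng)
            c = AtomicConfiguration(
                m.species, m.positions + a_lat / 2,
                cell=np.eye(3) * a_lat, pbc=(True, True, True))
            key = f"cry{ident:04d}"
        else:
            raise ValueError(f"unknown dataset kind {kind!r}")
        c.info.update(molecule_key=key, subset=kind, temperature=T)
        records.append(_label(c, pot))
    return LabeledDataset(records)
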