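"""Extended-XYZ reading and writing.

Dialect: the comment line carries ``Lattice="ax ay az bx by bz cx cy cz"``
(rows are lattice vectors), a ``Properties=species:S:1:pos:R:3[:forces:R:3]``
descriptor, and optional per-frame ``energy=`` and ``stress="9 floats"``
keys; ``pbc="T T T"`` is written for periodic frames.  Floats are written
with 17 significant digits so a write→read round-trip is bit-exact.
Missing labels are tolerated on read.
"""

from __future__ import annotations

import re

import numpy as np

from .graph import AtomicConfiguration
from .units import CHEMICAL_SYMBOLS, SYMBOL_TO_Z


class ExtendedXYZError(ValueError):
    def __init__(self, message, line=None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


_KEY_RE = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def _parse_comment(comment: str, lineno: int) -> dict:
    out = {}
    for m in _KEY_RE.finditer(comment):
        key = m.group(1)
        out[key] = m.group(2) if m.group(2) is not None else m.group(3)
    return out


def _parse_properties(desc: str, lineno: int):
    fields = desc.split(":")
    if len(fields) % 3:
        raise ExtendedXYZError(f"malformed Properties descriptor {desc!r}",
                               lineno)
    cols = []
    for i in range(0, len(fields), 3):
        name, kind, width = fields[i], fields[i + 1], int(fields[i + 2])
        cols.append((name, kind, width))
    return cols


def read_extended_xyz(path):
    """Read all frames of an extended-XYZ file.

    Returns a list of :class:`AtomicConfiguration`; records without force
    columns simply have ``forces=None``.
    """
    configs = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise ExtendedXYZError(
                f"expected an atom count, got {lines[i].strip()!r}", i + 1)
        if i + 1 + n > len(lines):
            raise ExtendedXYZError("truncated frame", i + 1)
        header = _parse_comment(lines[i + 1], i + 2)
        props = _parse_properties(
            header.get("Properties", "species:S:1:pos:R:3"), i + 2)
        species, positions, forces, vels = [], [], [], []
        has_forces = any(p[0] == "forces" for p in props)
        has_vel = any(p[0] == "vel" for p in props)
        for a in range(n):
            parts = lines[i + 2 + a].split()
            want = sum(p[2] for p in props)
            if len(parts) < want:
                raise ExtendedXYZError(
                    f"expected {want} columns, got {len(parts)}", i + 3 + a)
            col = 0
            for name, kind, width in props:
                vals = parts[col:col + width]
                col += width
                if name == "species":
                    sym = vals[0]
                    if sym not in SYMBOL_TO_Z:
                        raise ExtendedXYZError(
                            f"unknown element symbol {sym!r}", i + 3 + a)
                    species.append(SYMBOL_TO_Z[sym])
                elif name == "pos":
                    positions.append([float(v) for v in vals])
                elif name == "forces":
                    forces.append([float(v) for v in vals])
                elif name == "vel":
                    vels.append([float(v) for v in vals])
        cell = None
        pbc = (False, False, False)
        if "Lattice" in header:
            vals = [float(v) for v in header["Lattice"].split()]
            if len(vals) != 9:
                raise ExtendedXYZError("Lattice needs 9 numbers", i + 2)
            cell = np.array(vals).reshape(3, 3)
            pbc = (True, True, True)
        if "pbc" in header:
            pbc = tuple(tok in ("T", "True", "1")
                        for tok in header["pbc"].split())
        energy = float(header["energy"]) if "energy" in header else None
        stress = None
        if "stress" in header:
            svals = [float(v) for v in header["stress"].split()]
            if len(svals) != 9:
                raise ExtendedXYZError("stress needs 9 numbers", i + 2)
            stress = np.array(svals).reshape(3, 3)
        cfg = AtomicConfiguration(
            species, positions, cell=cell, pbc=pbc, energy=energy,
            forces=np.array(forces) if has_forces else None, stress=stress,
            velocities=np.array(vels) if has_vel else None)
        for key in ("molecule_key", "subset"):
            if key in header:
                cfg.info[key] = header[key]
        if "temperature" in header:
            cfg.info["temperature"] = float(header["temperature"])
        configs.append(cfg)
        i += 2 + n
    return configs


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def write_extended_xyz(configs, path):
    """Write configurations (losslessly) to an extended-XYZ file."""
    if isinstance(configs, AtomicConfiguration):
        configs = [configs]
    with open(path, "w") as fh:
        for c in configs:
            has_forces = c.forces is not None
            has_vel = c.velocities is not None
            props = "species:S:1:pos:R:3"
            if has_forces:
                props += ":forces:R:3"
            if has_vel:
                props += ":vel:R:3"
            keys = [f"Properties={props}"]
            if c.cell is not None:
                keys.append('Lattice="' + " ".join(
                    _fmt(v) for v in c.cell.ravel()) + '"')
                keys.append('pbc="' + " ".join(
                    "T" if b else "F" for b in c.pbc) + '"')
            if c.energy is not None:
                keys.append(f"energy={_fmt(c.energy)}")
            if c.stress is not None:
                keys.append('stress="' + " ".join(
                    _fmt(v) for v in c.stress.ravel()) + '"')
            for key in ("molecule_key", "subset"):
                if key in c.info:
                    keys.append(f"{key}={c.info[key]}")
            if "temperature" in c.info:
                keys.append(f"temperature={_fmt(c.info['temperature'])}")
            fh.write(f"{c.n_atoms}\n")
            fh.write(" ".join(keys) + "\n")
            for a in range(c.n_atoms):
                row = [CHEMICAL_SYMBOLS[int(c.species[a])]]
                row += [_fmt(v) for v in c.positions[a]]
                if has_forces:
                    row += [_fmt(v) for v in c.forces[a]]
                if has_vel:
                    row += [_fmt(v) for v in c.velocities[a]]
                fh.write(" ".join(row) + "\n")


def write_trajectory_xyz(traj, path):
    """Write a trajectory's frames as an extended-XYZ series."""
    configs = [traj.frame(i) for i in range(traj.n_frames)]
    write_extended_xyz(configs, path)
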