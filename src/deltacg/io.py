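"""Readers and writers: parameter tables, Tinker-style XYZ, minimal PDB,
CSV/JSON outputs, and the run configuration.

Parameter files are flat whitespace-separated tables::

    atom  <label> <charge> <epsilon> <rmin/2> <mass>
    bond  <label_i> <label_j> <k_b> <b0>
    angle <label_i> <label_vertex> <label_k> <k_theta> <theta0_deg>

Coordinate files are Tinker-style XYZ with connectivity: a count line
followed by one line per atom of serial, name, x, y, z, type label and
the serials of bonded neighbors.  Multi-frame trajectories concatenate
such blocks.  All floating-point output is formatted to 9 significant
digits so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from importlib import resources
from pathlib import Path

import numpy as np

from .forcefield import (
    AtomRecord, MolecularSystem, ParameterError,
    ROLE_PROTEIN, ROLE_WATER_O, ROLE_WATER_H1, ROLE_WATER_H2,
)

__all__ = ["ParameterSet", "load_parameters", "packaged_parameter_path",
           "read_xyz", "write_xyz", "read_xyz_frames", "write_xyz_frames",
           "read_pdb", "system_from_skeleton", "RunConfig", "XYZParseError",
           "FLOAT_FMT"]

FLOAT_FMT = "%.9g"


class XYZParseError(ValueError):
    """Malformed coordinate file; the message carries the line number."""


@dataclass
class ParameterSet:
    """Force-field parameter tables keyed by free-form type labels."""

    atom_types: dict      # label -> {charge, lj_epsilon, lj_rmin_half, mass}
    bonds: dict           # frozenset({i_label, j_label}) -> (k_b, b0)
    angles: dict          # (outer, vertex, outer) sorted -> (k_theta, theta0_rad)

    def atom(self, label: str) -> dict:
        try:
            return self.atom_types[label]
        except KeyError:
            raise ParameterError(f"no parameters for atom type {label!r}")

    def bond_constants(self, a: str, b: str) -> tuple[float, float]:
        try:
            return self.bonds[frozenset((a, b))]
        except KeyError:
            raise ParameterError(f"no bond parameters for {a}-{b}")

    def angle_constants(self, a: str, v: str, b: str) -> tuple[float, float]:
        key = (min(a, b), v, max(a, b))
        try:
            return self.angles[key]
        except KeyError:
            raise ParameterError(f"no angle parameters for {a}-{v}-{b}")


def load_parameters(path) -> ParameterSet:
    """Parse a flat parameter table (see module docstring)."""
    atom_types: dict = {}
    bonds: dict = {}
    angles: dict = {}
    text = Path(path).read_text()
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        try:
            if tok[0] == "atom":
                atom_types[tok[1]] = {
                    "charge": float(tok[2]), "lj_epsilon": float(tok[3]),
                    "lj_rmin_half": float(tok[4]), "mass": float(tok[5])}
            elif tok[0] == "bond":
                bonds[frozenset((tok[1], tok[2]))] = (float(tok[3]), float(tok[4]))
            elif tok[0] == "angle":
                key = (min(tok[1], tok[3]), tok[2], max(tok[1], tok[3]))
                angles[key] = (float(tok[4]), np.deg2rad(float(tok[5])))
            else:
                raise ValueError(f"unknown record type {tok[0]!r}")
        except (IndexError, ValueError) as e:
            raise ParameterError(f"{path}:{ln}: {e}") from e
    return ParameterSet(atom_types=atom_types, bonds=bonds, angles=angles)


def packaged_parameter_path():
    """Path of the bundled TIP3P parameter file."""
    return resources.files("deltacg").joinpath("data/tip3p.params")


# ---------------------------------------------------------------------------
# Tinker-style XYZ with connectivity


@dataclass
class XYZSkeleton:
    """Coordinates + connectivity + type labels (no parameters yet)."""

    names: list[str]
    labels: list[str]
    coordinates: np.ndarray
    bonds: list[tuple[int, int]]    # 0-based, i < j
    title: str = ""


def _parse_xyz_block(lines: list[str], start_ln: int) -> XYZSkeleton:
    head = lines[0].split()
    try:
        n = int(head[0])
    except (IndexError, ValueError):
        raise XYZParseError(f"line {start_ln}: expected an atom count")
    title = lines[0].partition(head[0])[2].strip()
    if len(lines) < n + 1:
        raise XYZParseError(f"line {start_ln}: truncated frame (need {n} atoms)")
    names, labels, coords = [], [], []
    bonds = set()
    for k in range(n):
        ln = start_ln + 1 + k
        tok = lines[1 + k].split()
        if len(tok) < 6:
            raise XYZParseError(f"line {ln}: expected serial name x y z type "
                                "[neighbors...]")
        try:
            serial = int(tok[0])
            xyz = [float(tok[1 + a]) for a in (1, 2, 3)]
            nb = [int(t) for t in tok[6:]]
        except ValueError as e:
            raise XYZParseError(f"line {ln}: {e}") from e
        if serial != k + 1:
            raise XYZParseError(f"line {ln}: serials must be 1..n in order")
        names.append(tok[1])
        labels.append(tok[5])
        coords.append(xyz)
        for j in nb:
            if not (1 <= j <= n):
                raise XYZParseError(f"line {ln}: neighbor {j} out of range")
            if j != serial:
                bonds.add((min(serial, j) - 1, max(serial, j) - 1))
    return XYZSkeleton(names=names, labels=labels,
                       coordinates=np.array(coords, float),
                       bonds=sorted(bonds), title=title)


def read_xyz(path) -> XYZSkeleton:
    """Read the first (or only) frame of a Tinker-style XYZ file."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise XYZParseError("empty file")
    return _parse_xyz_block(lines, 1)


def read_xyz_frames(path) -> list[XYZSkeleton]:
    """Read every frame of a multi-frame Tinker-style XYZ file."""
    lines = Path(path).read_text().splitlines()
    frames = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        frame = _parse_xyz_block(lines[pos:], pos + 1)
        frames.append(frame)
        pos += 1 + len(frame.names)
    if not frames:
        raise XYZParseError("no frames found")
    return frames


def _xyz_lines(system: MolecularSystem, title: str = "") -> list[str]:
    n = system.n_atoms
    neigh: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, j, *_ in system.bonds:
        neigh[i].append(j + 1)
        neigh[j].append(i + 1)
    out = [f"{n} {title}".rstrip()]
    for i, a in enumerate(system.atoms):
        x, y, z = system.coordinates[i]
        nb = " ".join(str(s) for s in sorted(neigh[i]))
        out.append(f"{i + 1} {a.element} {FLOAT_FMT % x} {FLOAT_FMT % y} "
                   f"{FLOAT_FMT % z} {a.type_label}" + (f" {nb}" if nb else ""))
    return out


def write_xyz(system: MolecularSystem, path, title: str = "") -> None:
    Path(path).write_text("\n".join(_xyz_lines(system, title)) + "\n")


def write_xyz_frames(frames, path, title: str = "") -> None:
    blocks = []
    for k, fr in enumerate(frames):
        blocks.extend(_xyz_lines(fr, f"{title} frame {k}".strip()))
    Path(path).write_text("\n".join(blocks) + "\n")


def read_pdb(path):
    """Minimal PDB reader: coordinates + element symbols of ATOM/HETATM."""
    coords, elements = [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            coords.append([float(line[30:38]), float(line[38:46]),
                           float(line[46:54])])
        except ValueError as e:
            raise XYZParseError(f"line {ln}: bad coordinates") from e
        elem = line[76:78].strip() or line[12:16].strip()[:1]
        elements.append(elem)
    return np.array(coords, float), elements


# ---------------------------------------------------------------------------
# skeleton + parameters -> full system


def system_from_skeleton(skel: XYZSkeleton, params: ParameterSet
                         ) -> MolecularSystem:
    """Resolve a coordinate skeleton against a parameter table.

    Water molecules are recognized as 3-atom bonded components whose
    elements are one O and two H; their atoms get water roles (first file
    hydrogen = H1).  All other atoms are protein-role.
    """
    n = len(skel.names)
    # connected components
    comp = list(range(n))

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for i, j in skel.bonds:
        ri, rj = find(i), find(j)
        if ri != rj:
            comp[ri] = rj
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    roles = [ROLE_PROTEIN] * n
    for members in groups.values():
        elems = sorted(skel.names[i].upper()[:1] for i in members)
        if len(members) == 3 and elems == ["H", "H", "O"]:
            o = next(i for i in members if skel.names[i].upper().startswith("O"))
            hs = [i for i in members if i != o]
            roles[o] = ROLE_WATER_O
            roles[hs[0]] = ROLE_WATER_H1
            roles[hs[1]] = ROLE_WATER_H2

    atoms = []
    for i in range(n):
        p = params.atom(skel.labels[i])
        atoms.append(AtomRecord(index=i, element=skel.names[i],
                                type_label=skel.labels[i], charge=p["charge"],
                                lj_epsilon=p["lj_epsilon"],
                                lj_rmin_half=p["lj_rmin_half"],
                                mass=p["mass"], role=roles[i]))
    bonds = []
    for i, j in skel.bonds:
        k, b0 = params.bond_constants(skel.labels[i], skel.labels[j])
        bonds.append((i, j, k, b0))
    # angles at every atom with two or more bonded neighbors
    neigh: dict[int, list[int]] = {}
    for i, j in skel.bonds:
        neigh.setdefault(i, []).append(j)
        neigh.setdefault(j, []).append(i)
    angles = []
    for v, nb in sorted(neigh.items()):
        nb = sorted(nb)
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                kt, t0 = params.angle_constants(
                    skel.labels[nb[a]], skel.labels[v], skel.labels[nb[b]])
                angles.append((nb[a], v, nb[b], kt, t0))
    return MolecularSystem(atoms=atoms, coordinates=skel.coordinates,
                           bonds=bonds, angles=angles)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Resolved analysis parameters; defaults are the standard protocol.

    record_cutoff/bin_width/trim/zero_window/correlation_window in A and
    percent; hydrophilic_threshold in kcal/mol.
    """

    seed: int = 0
    record_cutoff: float = 12.0
    bin_width: float = 0.1
    trim: tuple[float, float] = (5.0, 95.0)
    zero_window: tuple[float, float] = (8.0, 12.0)
    correlation_window: tuple[float, float] = (5.0, 10.0)
    zeroed_modes: int = 6
    hydrophilic_threshold: float = 0.1
    min_count: int = 25
    nonbonded_mode_analysis: str = "untruncated"
    nonbonded_mode_sampling: str = "switched"
    switch_start: float = 7.8
    cutoff: float = 12.0

    def analysis_policy(self):
        from .forcefield import NonbondedPolicy
        return NonbondedPolicy(mode=self.nonbonded_mode_analysis,
                               switch_start=self.switch_start,
                               cutoff=self.cutoff)

    def sampling_policy(self):
        from .forcefield import NonbondedPolicy
        return NonbondedPolicy(mode=self.nonbonded_mode_sampling,
                               switch_start=self.switch_start,
                               cutoff=self.cutoff)

    def dump(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in data.items()})
        return cfg


def write_csv(df, path) -> None:
    """CSV with fixed 9-significant-digit float formatting."""
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
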