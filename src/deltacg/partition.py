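"""Reindexing of the all-atom expansion into coarse-graining variables.

The displacement vector of the all-atom surface is reorganized into
protein-atom displacements d_p, solvent-particle displacements d_s (the
particle sits exactly on its water's oxygen, so the oxygen's relative
displacement is identically zero and is dropped), and the relative
displacements D_1, D_2 of the two hydrogens from the particle.  The
change of variables is linear, so the transformed force vector and
Hessian are exact index-gather sums of the original blocks (the solvent
row of the force is f_o + f_1 + f_2 per water, and solvent Hessian
blocks sum over all oxygen/hydrogen constituents).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forcefield import (
    MolecularSystem,
    SecondOrderExpansion,
    TopologyError,
    ROLE_PROTEIN,
    ROLE_WATER_O,
    ROLE_WATER_H1,
    ROLE_WATER_H2,
)

__all__ = ["PartitionIndex", "AggregatedBlocks", "classify_atoms", "aggregate",
           "delta_tilde_energy", "reconstruct_displacement"]


@dataclass
class PartitionIndex:
    """Disjoint atom-index lists for protein atoms and aligned water triples.

    o_idx[k], h1_idx[k], h2_idx[k] belong to the same water; solvent
    particle k's position is its oxygen's position.
    """

    p_idx: np.ndarray
    o_idx: np.ndarray
    h1_idx: np.ndarray
    h2_idx: np.ndarray

    @property
    def n_p(self) -> int:
        return len(self.p_idx)

    @property
    def n_s(self) -> int:
        return len(self.o_idx)

    @property
    def n_units(self) -> int:
        return self.n_p + self.n_s

    def unit_of_atom(self, n_atoms: int) -> np.ndarray:
        """Map atom index -> coarse unit index (protein units first, then
        solvent particles in oxygen order)."""
        unit = np.full(n_atoms, -1, dtype=int)
        unit[self.p_idx] = np.arange(self.n_p)
        for arr in (self.o_idx, self.h1_idx, self.h2_idx):
            unit[arr] = self.n_p + np.arange(self.n_s)
        return unit

    def unit_positions(self, coordinates: np.ndarray) -> np.ndarray:
        """(n_units, 3) positions: protein atoms, then oxygen sites."""
        return np.vstack([coordinates[self.p_idx], coordinates[self.o_idx]])


@dataclass
class AggregatedBlocks:
    """Summed force/Hessian blocks of the reorganized quadratic surface.

    f_ps, H_psps cover protein atoms + solvent particles; f_12, H_1212
    cover the relative hydrogen displacements; H_ps12 couples them.
    M12 is the (diagonal of the) hydrogen mass matrix, unit_masses the
    coarse-unit masses (protein atom mass; full water mass per particle).
    """

    V0: float
    f_ps: np.ndarray      # (3(n_p+n_s),)
    f_12: np.ndarray      # (6 n_s,)
    H_psps: np.ndarray
    H_ps12: np.ndarray
    H_1212: np.ndarray
    M12: np.ndarray       # (6 n_s,) amu
    unit_masses: np.ndarray  # (n_p+n_s,) amu
    n_p: int
    n_s: int

    @property
    def H_12ps(self) -> np.ndarray:
        return self.H_ps12.T


def classify_atoms(system: MolecularSystem) -> PartitionIndex:
    """Group atoms into protein atoms and aligned (O, H1, H2) water triples.

    Solvent particles are ordered by their oxygen's atom index, protein
    atoms by atom index, so the partition does not depend on input file
    ordering beyond the identity of the atoms themselves.
    """
    roles = system.roles
    mol = system.molecule_of
    water_mols = sorted({int(mol[i]) for i, r in enumerate(roles)
                         if r in (ROLE_WATER_O, ROLE_WATER_H1, ROLE_WATER_H2)})
    o_idx, h1_idx, h2_idx = [], [], []
    for m in water_mols:
        members = [i for i in range(system.n_atoms) if mol[i] == m]
        by_role: dict[str, list[int]] = {}
        for i in members:
            by_role.setdefault(roles[i], []).append(i)
        if (sorted(by_role) != sorted([ROLE_WATER_O, ROLE_WATER_H1, ROLE_WATER_H2])
                or any(len(v) != 1 for v in by_role.values())
                or len(members) != 3):
            raise TopologyError(
                f"water molecule {m} must have exactly one O and two H atoms "
                f"with distinct roles (got {[roles[i] for i in members]})")
        o_idx.append(by_role[ROLE_WATER_O][0])
        h1_idx.append(by_role[ROLE_WATER_H1][0])
        h2_idx.append(by_role[ROLE_WATER_H2][0])
    order = np.argsort(o_idx) if o_idx else np.array([], dtype=int)
    p_idx = np.array(sorted(i for i, r in enumerate(roles) if r == ROLE_PROTEIN),
                     dtype=int)
    return PartitionIndex(
        p_idx=p_idx,
        o_idx=np.array(o_idx, dtype=int)[order],
        h1_idx=np.array(h1_idx, dtype=int)[order],
        h2_idx=np.array(h2_idx, dtype=int)[order],
    )


def _expand3(idx: np.ndarray) -> np.ndarray:
    """Atom indices -> their three coordinate indices."""
    idx = np.asarray(idx, dtype=int)
    return (3 * idx[:, None] + np.arange(3)).ravel()


def aggregate(expansion: SecondOrderExpansion, part: PartitionIndex,
              masses: np.ndarray) -> AggregatedBlocks:
    """Exact block sums of the expansion in the reorganized variable set."""
    n_atoms = len(masses)
    if expansion.f.shape[0] != 3 * n_atoms:
        raise ValueError("expansion/mass dimension mismatch")
    if part.n_p + 3 * part.n_s != n_atoms:
        raise ValueError("partition does not cover all atoms")
    P3 = _expand3(part.p_idx)
    O3 = _expand3(part.o_idx)
    A3 = _expand3(part.h1_idx)
    B3 = _expand3(part.h2_idx)
    h12 = np.concatenate([A3, B3])

    f = expansion.f
    f_p = f[P3]
    f_s = f[O3] + f[A3] + f[B3]
    f_ps = np.concatenate([f_p, f_s])
    f_12 = f[h12]

    H = expansion.H
    cols_p = H[:, P3]
    cols_s = H[:, O3] + H[:, A3] + H[:, B3]
    cols_ps = np.hstack([cols_p, cols_s])
    H_psps = np.vstack([cols_ps[P3], cols_ps[O3] + cols_ps[A3] + cols_ps[B3]])
    cols_12 = H[:, h12]
    H_ps12 = np.vstack([cols_12[P3], cols_12[O3] + cols_12[A3] + cols_12[B3]])
    H_1212 = H[np.ix_(h12, h12)]

    M12 = np.repeat(np.concatenate([masses[part.h1_idx], masses[part.h2_idx]]), 3)
    unit_masses = np.concatenate([
        masses[part.p_idx],
        masses[part.o_idx] + masses[part.h1_idx] + masses[part.h2_idx],
    ])
    return AggregatedBlocks(
        V0=expansion.V0, f_ps=f_ps, f_12=f_12,
        H_psps=H_psps, H_ps12=H_ps12, H_1212=H_1212,
        M12=M12, unit_masses=unit_masses,
        n_p=part.n_p, n_s=part.n_s,
    )


def delta_tilde_energy(blocks: AggregatedBlocks, d_ps: np.ndarray,
                       D12: np.ndarray) -> float:
    """Quadratic-surface energy at (d_ps, D12) in the reorganized variables."""
    d = np.asarray(d_ps, float).ravel()
    D = np.asarray(D12, float).ravel()
    return float(blocks.V0 - blocks.f_ps @ d - blocks.f_12 @ D
                 + 0.5 * d @ blocks.H_psps @ d
                 + d @ blocks.H_ps12 @ D
                 + 0.5 * D @ blocks.H_1212 @ D)


def reconstruct_displacement(part: PartitionIndex, d_ps: np.ndarray,
                             D12: np.ndarray) -> np.ndarray:
    """Map (d_ps, D12) back to the full 3n all-atom displacement vector."""
    n_atoms = part.n_p + 3 * part.n_s
    d_ps = np.asarray(d_ps, float).ravel()
    D12 = np.asarray(D12, float).ravel()
    d_p = d_ps[:3 * part.n_p]
    d_s = d_ps[3 * part.n_p:]
    D1 = D12[:3 * part.n_s]
    D2 = D12[3 * part.n_s:]
    delta = np.zeros(3 * n_atoms)
    delta[_expand3(part.p_idx)] = d_p
    delta[_expand3(part.o_idx)] = d_s
    delta[_expand3(part.h1_idx)] = d_s + D1
    delta[_expand3(part.h2_idx)] = d_s + D2
    return delta
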