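"""Shared fixtures and hand-assembly helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from deltacg.forcefield import AtomRecord, MolecularSystem, NonbondedPolicy
from deltacg.forcefield import (
    ROLE_PROTEIN, ROLE_WATER_O, ROLE_WATER_H1, ROLE_WATER_H2,
)
from deltacg import io, synth

# TIP3P constants mirrored from the bundled parameter file (tests assert
# against these independently of the loader)
O_PARAMS = dict(charge=-0.834, lj_epsilon=0.1521, lj_rmin_half=1.7682,
                mass=15.9994)
H_PARAMS = dict(charge=0.417, lj_epsilon=0.046, lj_rmin_half=0.2245,
                mass=1.008)
BOND_K, BOND_B0 = 450.0, 0.9572
ANGLE_K, ANGLE_T0 = 55.0, np.deg2rad(104.52)


def water_atoms(start: int) -> list[AtomRecord]:
    """O, H1, H2 AtomRecords with TIP3P parameters."""
    roles = (ROLE_WATER_O, ROLE_WATER_H1, ROLE_WATER_H2)
    params = (O_PARAMS, H_PARAMS, H_PARAMS)
    elems = ("O", "H", "H")
    labels = ("OT", "HT", "HT")
    return [AtomRecord(index=start + k, element=elems[k],
                       type_label=labels[k], role=roles[k], **params[k])
            for k in range(3)]


def water_coords(origin, rotation=None) -> np.ndarray:
    """Ideal-geometry water sites placed at ``origin``."""
    sites = synth._ideal_water_sites()
    if rotation is not None:
        sites = sites @ np.asarray(rotation).T
    return sites + np.asarray(origin, float)


def make_water_system(origins, probes=(), rng=None) -> MolecularSystem:
    """Waters at the given origins plus optional probe atoms.

    probes: iterable of (position, charge, lj_epsilon, lj_rmin_half).
    Waters get a random orientation when ``rng`` is given.
    """
    atoms, coords, bonds, angles = [], [], [], []
    for (pos, q, eps, rmh) in probes:
        atoms.append(AtomRecord(index=len(atoms), element="X",
                                type_label="PRB", charge=q, lj_epsilon=eps,
                                lj_rmin_half=rmh, mass=12.011,
                                role=ROLE_PROTEIN))
        coords.append(np.asarray(pos, float))
    for origin in origins:
        i0 = len(atoms)
        rot = synth._random_rotation(rng) if rng is not None else None
        atoms.extend(water_atoms(i0))
        coords.extend(water_coords(origin, rot))
        bonds.append((i0, i0 + 1, BOND_K, BOND_B0))
        bonds.append((i0, i0 + 2, BOND_K, BOND_B0))
        angles.append((i0 + 1, i0, i0 + 2, ANGLE_K, ANGLE_T0))
    return MolecularSystem(atoms=atoms, coordinates=np.array(coords),
                           bonds=bonds, angles=angles)


def lj_atom(index, pos_unused=None, charge=0.0, eps=0.1, rmh=2.0,
            mass=12.011, label="A"):
    return AtomRecord(index=index, element="C", type_label=label,
                      charge=charge, lj_epsilon=eps, lj_rmin_half=rmh,
                      mass=mass, role=ROLE_PROTEIN)


@pytest.fixture(scope="session")
def water_dimer() -> MolecularSystem:
    rng = np.random.default_rng(42)
    return make_water_system([(0.0, 0.0, 0.0), (2.9, 0.3, -0.2)], rng=rng)


@pytest.fixture(scope="session")
def probe_water_system() -> MolecularSystem:
    rng = np.random.default_rng(5)
    return make_water_system([(3.0, 0.0, 0.0)],
                             probes=[((0.0, 0.0, 0.0), 0.5, 0.1, 2.0)],
                             rng=rng)


@pytest.fixture(scope="session")
def small_droplet() -> MolecularSystem:
    """Six waters + one charged probe, a generic coupled system."""
    cfg = synth.SamplerConfig(n_waters=6, radius=5.5, seed=3)
    probe = synth.ProbeSpec(label="PRB", charge=0.5)
    return synth.build_droplet(cfg, [probe])


@pytest.fixture(scope="session")
def small_droplet_analysis(small_droplet):
    from deltacg.pairwise import analyze_frame
    return analyze_frame(small_droplet, NonbondedPolicy())
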