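"""Seeded generators: TIP3P water droplets, Metropolis sampling, frame
subsampling, solvent-layer selection, and random quadratic systems.

The droplet generator packs rigid ideal-geometry TIP3P waters (O-H
0.9572 A, H-O-H 104.52 deg) at liquid-like density around optional fixed
probe particles, and the Metropolis sampler draws Boltzmann-weighted
conformations at 298 K using rigid-body water moves under the switched
nonbonded policy.  Sampling stands in for a full molecular-dynamics
stage: the downstream coarse-graining analysis only needs an ensemble of
Boltzmann-weighted conformations, not dynamics.

A soft half-harmonic spherical restraint on the oxygens prevents
evaporation from the droplet surface during sampling; it is part of the
sampling energy only and never enters the analysis-stage expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcefield import (
    AtomRecord, MolecularSystem, NonbondedPolicy,
    ROLE_PROTEIN, ROLE_WATER_O, ROLE_WATER_H1, ROLE_WATER_H2,
)
from .io import load_parameters, packaged_parameter_path

__all__ = ["ProbeSpec", "SamplerConfig", "build_droplet", "mc_sample",
           "subsample_frames", "select_solvent_layer",
           "random_quadratic_system", "RandomQuadratic", "PackingError",
           "StepSizeError", "KB"]

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872041
#: liquid water number density at ambient conditions, waters per A^3
WATER_NUMBER_DENSITY = 0.0334
#: minimum oxygen-oxygen distance accepted while packing
MIN_OO_PACKING = 2.4


class PackingError(RuntimeError):
    """Could not place all waters without overlap."""


class StepSizeError(RuntimeError):
    """No Monte-Carlo move was accepted over a whole sweep window."""


@dataclass
class ProbeSpec:
    """A fixed probe particle standing in for a protein atom type."""

    label: str
    charge: float = 0.0
    lj_epsilon: float = 0.1
    lj_rmin_half: float = 2.0
    mass: float = 12.011
    sites: list | None = None  # optional [(offset 3-vector, charge), ...]


@dataclass
class SamplerConfig:
    """Droplet size and Metropolis sampling schedule.

    Lengths in A, temperature in K, steps: max rigid-body translation in
    A and max rotation in radians per move.  Sweeps count one attempted
    move per water.  ``seed`` is mandatory — every random draw of the
    generator flows from it.
    """

    n_waters: int = 80
    radius: float | None = None       # droplet radius; density-derived if None
    temperature: float = 298.0
    max_translation: float = 0.18
    max_rotation: float = 0.35
    n_sweeps: int = 2500
    burn_in: int = 500
    frame_interval: int = 10
    seed: int = 0
    restraint_k: float = 2.0          # kcal/mol/A^2 beyond the droplet radius

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_waters", "temperature", "max_translation",
                     "max_rotation", "n_sweeps", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def droplet_radius(self) -> float:
        if self.radius is not None:
            return float(self.radius)
        return (3.0 * self.n_waters / (4.0 * np.pi * WATER_NUMBER_DENSITY)) ** (1.0 / 3.0)


def _ideal_water_sites() -> np.ndarray:
    """(3, 3) offsets of O, H1, H2 for ideal TIP3P geometry, O at origin."""
    b0 = 0.9572
    theta = np.deg2rad(104.52)
    h1 = b0 * np.array([np.sin(theta / 2), np.cos(theta / 2), 0.0])
    h2 = b0 * np.array([-np.sin(theta / 2), np.cos(theta / 2), 0.0])
    return np.vstack([np.zeros(3), h1, h2])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _axis_angle_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def build_droplet(config: SamplerConfig,
                  probes: list[ProbeSpec] | None = None,
                  max_attempts: int = 10_000) -> MolecularSystem:
    """Pack ideal-geometry waters into a sphere around centered probes.

    Deterministic for a given seed.  Water parameters (charges, LJ, masses,
    flexible internal constants) come from the bundled TIP3P parameter file.
    """
    rng = np.random.default_rng(config.seed)
    params = load_parameters(packaged_parameter_path())
    R = config.droplet_radius()
    probes = probes or []

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple] = []
    angles: list[tuple] = []
    probe_positions: list[np.ndarray] = []

    # probes fixed at the droplet center (spread slightly if several)
    for k, p in enumerate(probes):
        base = np.zeros(3) if len(probes) == 1 else 3.5 * np.array(
            [np.cos(2 * np.pi * k / len(probes)),
             np.sin(2 * np.pi * k / len(probes)), 0.0])
        sites = p.sites or [(np.zeros(3), p.charge)]
        for off, q in sites:
            atoms.append(AtomRecord(index=len(atoms), element="X",
                                    type_label=p.label, charge=q,
                                    lj_epsilon=p.lj_epsilon,
                                    lj_rmin_half=p.lj_rmin_half,
                                    mass=p.mass, role=ROLE_PROTEIN))
            coords.append(base + np.asarray(off, float))
            probe_positions.append(coords[-1])

    o_params = params.atom_types["OT"]
    h_params = params.atom_types["HT"]
    kb_oh, b0_oh = params.bond_constants("OT", "HT")
    kt_hoh, t0_hoh = params.angle_constants("HT", "OT", "HT")

    template = _ideal_water_sites()
    placed_o: list[np.ndarray] = []
    for w in range(config.n_waters):
        pos = None
        for _ in range(max_attempts):
            cand = rng.uniform(-R, R, size=3)
            if np.linalg.norm(cand) > R:
                continue
            if any(np.linalg.norm(cand - o) <= MIN_OO_PACKING for o in placed_o):
                continue
            if any(np.linalg.norm(cand - pp) <= MIN_OO_PACKING
                   for pp in probe_positions):
                continue
            pos = cand
            break
        if pos is None:
            raise PackingError(
                f"failed to place water {w} of {config.n_waters} within "
                f"{max_attempts} attempts (radius {R:.2f} A)")
        placed_o.append(pos)
        rot = _random_rotation(rng)
        sites = template @ rot.T + pos
        i0 = len(atoms)
        for k, (role, p, elem) in enumerate((
                (ROLE_WATER_O, o_params, "O"),
                (ROLE_WATER_H1, h_params, "H"),
                (ROLE_WATER_H2, h_params, "H"))):
            atoms.append(AtomRecord(index=i0 + k, element=elem,
                                    type_label="OT" if k == 0 else "HT",
                                    charge=p["charge"],
                                    lj_epsilon=p["lj_epsilon"],
                                    lj_rmin_half=p["lj_rmin_half"],
                                    mass=p["mass"], role=role))
            coords.append(sites[k])
        bonds.append((i0, i0 + 1, kb_oh, b0_oh))
        bonds.append((i0, i0 + 2, kb_oh, b0_oh))
        angles.append((i0 + 1, i0, i0 + 2, kt_hoh, t0_hoh))

    return MolecularSystem(atoms=atoms, coordinates=np.array(coords),
                           bonds=bonds, angles=angles)


class _SamplingEnergy:
    """Inter-molecular switched nonbonded energy + droplet restraint.

    Evaluates the interaction of one molecule with the rest in O(n) for
    Metropolis updates."""

    def __init__(self, system: MolecularSystem, policy: NonbondedPolicy,
                 radius: float, restraint_k: float):
        self.policy = policy
        self.radius = radius
        self.k_restr = restraint_k
        self.q = system.charges
        self.eps = system.lj_epsilons
        self.rmin_half = system.lj_rmin_halves
        self.mol = np.asarray(system.molecule_of)
        self.o_mask = np.array([r == ROLE_WATER_O for r in system.roles])

    def _pair_energy(self, r, qq, eps, rmin):
        C = self.policy.coulomb_constant
        V = C * qq / r + eps * ((rmin / r) ** 12 - 2.0 * (rmin / r) ** 6)
        if self.policy.mode == "switched":
            r_on, r_off = self.policy.switch_start, self.policy.cutoff
            t = np.clip((r - r_on) / (r_off - r_on), 0.0, 1.0)
            V = V * (1.0 - t**3 * (10.0 - 15.0 * t + 6.0 * t**2))
        return V.sum()

    def molecule_energy(self, coords: np.ndarray, m: int) -> float:
        mine = np.flatnonzero(self.mol == m)
        other = np.flatnonzero(self.mol != m)
        d = coords[mine][:, None, :] - coords[other][None, :, :]
        r = np.sqrt((d * d).sum(axis=2))
        if self.policy.mode == "switched":
            keep = r < self.policy.cutoff
        else:
            keep = np.ones_like(r, bool)
        qq = np.outer(self.q[mine], self.q[other])[keep]
        eps = np.sqrt(np.outer(self.eps[mine], self.eps[other]))[keep]
        rmin = (self.rmin_half[mine][:, None] + self.rmin_half[other][None, :])[keep]
        e = self._pair_energy(r[keep], qq, eps, rmin)
        o = mine[self.o_mask[mine]]
        if len(o):
            d0 = np.linalg.norm(coords[o], axis=1)
            over = np.maximum(d0 - self.radius, 0.0)
            e += self.k_restr * float((over * over).sum())
        return float(e)


def mc_sample(system: MolecularSystem, config: SamplerConfig,
              policy: NonbondedPolicy | None = None,
              stall_window: int = 50):
    """Metropolis sampling with rigid-body water moves.

    Returns (frames, info): frames are MolecularSystem snapshots emitted
    every ``frame_interval`` sweeps after ``burn_in``; info carries the
    overall acceptance rate.  Probe (protein-role) atoms stay fixed.
    """
    policy = policy or NonbondedPolicy(mode="switched")
    rng = np.random.default_rng(config.seed + 1)
    energy = _SamplingEnergy(system, policy, config.droplet_radius(),
                             config.restraint_k)
    mol = np.asarray(system.molecule_of)
    roles = system.roles
    water_mols = sorted({int(mol[i]) for i, r in enumerate(roles)
                         if r == ROLE_WATER_O})
    water_atoms = {m: np.flatnonzero(mol == m) for m in water_mols}
    o_atom = {m: next(i for i in water_atoms[m] if roles[i] == ROLE_WATER_O)
              for m in water_mols}

    coords = system.coordinates.copy()
    beta = 1.0 / (KB * config.temperature)
    frames = []
    accepted = total = 0
    accepted_in_window = 0
    sweeps_in_window = 0

    for sweep in range(1, config.n_sweeps + 1):
        for m in rng.permutation(water_mols):
            idx = water_atoms[m]
            old = coords[idx].copy()
            e_old = energy.molecule_energy(coords, m)
            shift = rng.uniform(-config.max_translation,
                                config.max_translation, size=3)
            rot = _axis_angle_rotation(
                rng.normal(size=3),
                rng.uniform(-config.max_rotation, config.max_rotation))
            pivot = coords[o_atom[m]]
            coords[idx] = (coords[idx] - pivot) @ rot.T + pivot + shift
            e_new = energy.molecule_energy(coords, m)
            total += 1
            if e_new <= e_old or rng.random() < np.exp(-beta * (e_new - e_old)):
                accepted += 1
                accepted_in_window += 1
            else:
                coords[idx] = old
        sweeps_in_window += 1
        if sweeps_in_window >= stall_window:
            if accepted_in_window == 0:
                raise StepSizeError(
                    f"no move accepted over {stall_window} sweeps — "
                    "reduce max_translation/max_rotation")
            accepted_in_window = 0
            sweeps_in_window = 0
        if sweep >= config.burn_in and (sweep - config.burn_in) % config.frame_interval == 0:
            frames.append(system.with_coordinates(coords.copy()))

    info = {"acceptance_rate": accepted / max(total, 1),
            "n_frames": len(frames)}
    return frames, info


def subsample_frames(total_span: float, interval: float,
                     burn_in: float) -> np.ndarray:
    """Times burn_in, burn_in + interval, ..., <= total_span (inclusive)."""
    if interval <= 0:
        raise ValueError("interval must be positive")
    if burn_in > total_span:
        raise ValueError("burn_in exceeds the total span")
    n = int(np.floor((total_span - burn_in) / interval + 1e-9)) + 1
    return burn_in + interval * np.arange(n)


def select_solvent_layer(system: MolecularSystem,
                         thickness: float) -> MolecularSystem:
    """Keep protein atoms plus whole waters whose oxygen lies within
    ``thickness`` of the nearest protein atom (<= convention)."""
    roles = system.roles
    p_idx = [i for i, r in enumerate(roles) if r == ROLE_PROTEIN]
    if not p_idx:
        raise ValueError("system has no protein atoms")
    X = system.coordinates
    P = X[p_idx]
    mol = np.asarray(system.molecule_of)
    keep_atoms = set(p_idx)
    for i, r in enumerate(roles):
        if r == ROLE_WATER_O:
            dmin = np.linalg.norm(P - X[i], axis=1).min()
            if dmin <= thickness:
                keep_atoms.update(np.flatnonzero(mol == mol[i]).tolist())
    keep = sorted(keep_atoms)
    remap = {old: new for new, old in enumerate(keep)}
    atoms = []
    for new, old in enumerate(keep):
        a = system.atoms[old]
        atoms.append(AtomRecord(index=new, element=a.element,
                                type_label=a.type_label, charge=a.charge,
                                lj_epsilon=a.lj_epsilon,
                                lj_rmin_half=a.lj_rmin_half,
                                mass=a.mass, role=a.role))
    bonds = [(remap[i], remap[j], k, b0) for (i, j, k, b0) in system.bonds
             if i in remap and j in remap]
    angles = [(remap[i], remap[j], remap[k], kt, t0)
              for (i, j, k, kt, t0) in system.angles
              if i in remap and j in remap and k in remap]
    return MolecularSystem(atoms=atoms, coordinates=X[keep],
                           bonds=bonds, angles=angles)


@dataclass
class RandomQuadratic:
    """Synthetic quadratic surface with a valid partition — oracle fuel."""

    f: np.ndarray
    H: np.ndarray
    masses: np.ndarray
    part: "PartitionIndex"

    @property
    def expansion(self):
        from .forcefield import SecondOrderExpansion
        return SecondOrderExpansion(V0=0.0, f=self.f, H=self.H)


def random_quadratic_system(seed: int, n_p: int, n_s: int,
                            definiteness: str = "PD") -> RandomQuadratic:
    """Random symmetric quadratic surface over n_p atoms + n_s waters.

    definiteness "PD" gives a positive-definite Hessian; "indefinite"
    a generic symmetric one; "singular12" makes the hydrogen block
    rank-deficient (exercises the pseudo-inverse path).
    """
    from .partition import PartitionIndex

    if n_p < 0 or n_s < 1:
        raise ValueError("need n_p >= 0 and n_s >= 1")
    rng = np.random.default_rng(seed)
    n = n_p + 3 * n_s
    A = rng.normal(size=(3 * n, 3 * n))
    if definiteness == "PD":
        H = A @ A.T + 0.5 * np.eye(3 * n)
    elif definiteness == "indefinite":
        H = 0.5 * (A + A.T)
    elif definiteness == "singular12":
        H = A @ A.T
        # zero out one hydrogen's rows/columns to make H_1212 singular
        h_first = n_p + 1  # first hydrogen atom of the first water
        sl = slice(3 * h_first, 3 * h_first + 3)
        H[sl, :] = 0.0
        H[:, sl] = 0.0
    else:
        raise ValueError(f"unknown definiteness {definiteness!r}")
    f = rng.normal(size=3 * n)
    masses = np.concatenate([
        np.full(n_p, 12.011),
        np.tile([15.9994, 1.008, 1.008], n_s),
    ])
    part = PartitionIndex(
        p_idx=np.arange(n_p),
        o_idx=n_p + 3 * np.arange(n_s),
        h1_idx=n_p + 3 * np.arange(n_s) + 1,
        h2_idx=n_p + 3 * np.arange(n_s) + 2,
    )
    return RandomQuadratic(f=f, H=H, masses=masses, part=part)
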