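"""Minimal molecular-mechanics engine for protein/water droplet systems.

Energies, analytic forces and Hessians for Coulomb, 12-6 Lennard-Jones,
harmonic bond and harmonic angle terms, with per-ordered-pair force vectors
and per-pair 3x3 Hessian blocks split by interaction term.  Units are
Angstrom, kcal/mol, amu and elementary charge throughout.

The engine is deliberately small: no dihedrals, no Ewald sums, no periodic
boundaries.  It targets droplet-scale systems (a few thousand atoms) where
dense linear algebra downstream is practical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "MolecularSystem",
    "NonbondedPolicy",
    "SecondOrderExpansion",
    "PairDecomposition",
    "compute_expansion",
    "compute_pair_decomposition",
    "finite_difference_check",
    "SingularGeometryError",
    "ParameterError",
    "TopologyError",
]

# Atom roles.  Each water molecule carries exactly one of each water role.
ROLE_PROTEIN = "protein"
ROLE_WATER_O = "water_O"
ROLE_WATER_H1 = "water_H1"
ROLE_WATER_H2 = "water_H2"
WATER_ROLES = (ROLE_WATER_O, ROLE_WATER_H1, ROLE_WATER_H2)

TERMS = ("elec", "vdw", "bonded")


class SingularGeometryError(ValueError):
    """Two interacting atoms coincide (or nearly coincide)."""


class ParameterError(ValueError):
    """An atom or bonded term lacks force-field parameters."""


class TopologyError(ValueError):
    """Connectivity or role assignment is inconsistent."""


@dataclass
class AtomRecord:
    """One atom with its nonbonded parameters.

    charge in elementary charges, lj_epsilon in kcal/mol, lj_rmin_half in
    Angstrom (half the Lennard-Jones minimum distance, CHARMM convention),
    mass in amu.  ``type_label`` is free-form user typing (e.g. "ARG_CZ").
    """

    index: int
    element: str
    type_label: str
    charge: float
    lj_epsilon: float
    lj_rmin_half: float
    mass: float
    role: str = ROLE_PROTEIN

    def __post_init__(self) -> None:
        if not (self.mass > 0):
            raise ParameterError(f"atom {self.index}: mass must be > 0")
        if self.lj_epsilon < 0:
            raise ParameterError(f"atom {self.index}: lj_epsilon must be >= 0")
        if not np.isfinite([self.charge, self.lj_epsilon,
                            self.lj_rmin_half, self.mass]).all():
            raise ParameterError(f"atom {self.index}: non-finite parameter")


@dataclass
class NonbondedPolicy:
    """Treatment of nonbonded interactions.

    mode "untruncated" evaluates every pair at full strength; "switched"
    multiplies the pair potential by a C2 quintic switching function that
    falls from 1 at ``switch_start`` to 0 at ``cutoff``.  The C2 property
    matters: analytic Hessians must match finite differences even for pairs
    straddling the switch region.
    """

    mode: str = "untruncated"
    switch_start: float = 7.8
    cutoff: float = 12.0
    coulomb_constant: float = 332.0637

    def __post_init__(self) -> None:
        if self.mode not in ("untruncated", "switched"):
            raise ValueError(f"unknown nonbonded mode {self.mode!r}")
        if self.mode == "switched" and not (self.switch_start < self.cutoff):
            raise ValueError("switch_start must be < cutoff")


@dataclass
class MolecularSystem:
    """Atoms, coordinates and bonded topology of one conformation.

    bonds: (i, j, k_b, b0) with V = k_b (r - b0)^2  [CHARMM convention, no 1/2]
    angles: (i, j, k, k_theta, theta0) with j the vertex and
            V = k_theta (theta - theta0)^2, theta0 in radians.
    exclusions: unordered atom pairs removed from nonbonded sums; if None,
    the constructor derives all 1-2 and 1-3 pairs from bonds and angles.
    """

    atoms: list[AtomRecord]
    coordinates: np.ndarray
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    molecule_of: np.ndarray | None = None
    exclusions: set[frozenset[int]] | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = len(self.atoms)
        if self.coordinates.shape != (n, 3):
            raise ValueError("coordinates must be (n_atoms, 3)")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("coordinates must be finite")
        for i, j, *_ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise TopologyError("bond references invalid atom index")
        for i, j, k, *_ in self.angles:
            if not (0 <= i < n and 0 <= j < n and 0 <= k < n):
                raise TopologyError("angle references invalid atom index")
        if self.molecule_of is None:
            self.molecule_of = self._infer_molecules()
        else:
            self.molecule_of = np.asarray(self.molecule_of, dtype=int)
        if self.exclusions is None:
            self.exclusions = self.default_exclusions()

    # -- derived arrays ----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def lj_epsilons(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms])

    @property
    def lj_rmin_halves(self) -> np.ndarray:
        return np.array([a.lj_rmin_half for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def roles(self) -> list[str]:
        return [a.role for a in self.atoms]

    def default_exclusions(self) -> set[frozenset[int]]:
        """All 1-2 (bonded) and 1-3 (angle-spanning) pairs."""
        excl: set[frozenset[int]] = set()
        neigh: dict[int, set[int]] = {}
        for i, j, *_ in self.bonds:
            excl.add(frozenset((i, j)))
            neigh.setdefault(i, set()).add(j)
            neigh.setdefault(j, set()).add(i)
        for j, nb in neigh.items():
            for a in nb:
                for b in nb:
                    if a < b:
                        excl.add(frozenset((a, b)))
        for i, j, k, *_ in self.angles:
            excl.update({frozenset((i, j)), frozenset((j, k)), frozenset((i, k))})
        return excl

    def _infer_molecules(self) -> np.ndarray:
        """Connected components of the bond graph (isolated atoms are their
        own molecule)."""
        n = self.n_atoms
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j, *_ in self.bonds:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        roots = [find(i) for i in range(n)]
        remap = {r: k for k, r in enumerate(dict.fromkeys(roots))}
        return np.array([remap[r] for r in roots])

    def with_coordinates(self, coords: np.ndarray) -> "MolecularSystem":
        """Same topology/parameters at another conformation."""
        return MolecularSystem(
            atoms=self.atoms,
            coordinates=np.asarray(coords, dtype=float),
            bonds=self.bonds,
            angles=self.angles,
            molecule_of=self.molecule_of,
            exclusions=self.exclusions,
        )


@dataclass
class SecondOrderExpansion:
    """Second-order Taylor data (V0, f, H) of the all-atom surface.

    The surface as a function of displacements d from the expansion
    conformation is  V(d) = V0 - f.d + (1/2) d.H.d,  i.e. f is the force
    (negative gradient) and H the Hessian at the conformation.
    """

    V0: float
    f: np.ndarray  # (3n,) kcal/mol/A
    H: np.ndarray  # (3n, 3n) kcal/mol/A^2

    def energy_at(self, displacement: np.ndarray) -> float:
        d = np.asarray(displacement, dtype=float).ravel()
        return float(self.V0 - self.f @ d + 0.5 * d @ self.H @ d)


class PairDecomposition:
    """Per-ordered-pair force 3-vectors and per-pair Hessian 3x3 blocks,
    split by term.

    Internally stored as flat pair arrays per term; accessors return the
    conventional ordered-pair views.  Force antisymmetry per term is exact
    by construction: block(i<-j) is stored once and negated for (j<-i).
    """

    def __init__(self, n_atoms: int):
        self.n_atoms = n_atoms
        # term -> (i_idx, j_idx, F_i_from_j (m,3), K_ij (m,3,3))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        self._lookup: dict[str, dict[tuple[int, int], int]] = {}

    def set_term(self, term: str, i_idx: np.ndarray, j_idx: np.ndarray,
                 forces: np.ndarray, hblocks: np.ndarray) -> None:
        i_idx = np.asarray(i_idx, dtype=int)
        j_idx = np.asarray(j_idx, dtype=int)
        F = np.asarray(forces, float).copy()
        K = np.asarray(hblocks, float).copy()
        # canonicalize to i < j (F_i<-j = -F_j<-i, K_ij = K_ji^T) and merge
        # duplicate pairs (a bond and an angle edge can cover the same pair)
        swap = i_idx > j_idx
        i_idx, j_idx = np.where(swap, j_idx, i_idx), np.where(swap, i_idx, j_idx)
        F[swap] = -F[swap]
        K[swap] = np.swapaxes(K[swap], 1, 2)
        codes = i_idx * self.n_atoms + j_idx
        uniq, inv = np.unique(codes, return_inverse=True)
        if len(uniq) < len(codes):
            Fm = np.zeros((len(uniq), 3))
            Km = np.zeros((len(uniq), 3, 3))
            np.add.at(Fm, inv, F)
            np.add.at(Km, inv, K)
            F, K = Fm, Km
            i_idx, j_idx = uniq // self.n_atoms, uniq % self.n_atoms
        self._data[term] = (i_idx, j_idx, F, K)
        self._lookup[term] = {(int(a), int(b)): k
                              for k, (a, b) in enumerate(zip(i_idx, j_idx))}

    def terms(self) -> tuple[str, ...]:
        return tuple(self._data)

    def pair_arrays(self, term: str):
        return self._data[term]

    def force_block(self, i: int, j: int, term: str) -> np.ndarray:
        """Force exerted on i by j for one term (zero if the pair carries
        no such interaction)."""
        lut = self._lookup.get(term, {})
        if (i, j) in lut:
            return self._data[term][2][lut[(i, j)]].copy()
        if (j, i) in lut:
            return -self._data[term][2][lut[(j, i)]]
        return np.zeros(3)

    def hessian_block(self, i: int, j: int, term: str) -> np.ndarray:
        """Off-diagonal Hessian block H_(i,j) for one term (i != j)."""
        lut = self._lookup.get(term, {})
        if (i, j) in lut:
            return self._data[term][3][lut[(i, j)]].copy()
        if (j, i) in lut:
            return self._data[term][3][lut[(j, i)]].T.copy()
        return np.zeros((3, 3))

    def atom_forces(self) -> np.ndarray:
        """Sum over partners and terms of pair forces -> (n, 3)."""
        f = np.zeros((self.n_atoms, 3))
        for i_idx, j_idx, F, _ in self._data.values():
            np.add.at(f, i_idx, F)
            np.add.at(f, j_idx, -F)
        return f

    def assemble_offdiagonal(self) -> np.ndarray:
        """Dense (3n, 3n) matrix holding only the off-diagonal pair blocks."""
        n = self.n_atoms
        H = np.zeros((3 * n, 3 * n))
        for i_idx, j_idx, _, K in self._data.values():
            for a, b, blk in zip(i_idx, j_idx, K):
                H[3 * a:3 * a + 3, 3 * b:3 * b + 3] += blk
                H[3 * b:3 * b + 3, 3 * a:3 * a + 3] += blk.T
        return H


# ---------------------------------------------------------------------------
# scalar pair-potential derivatives


def _switch(r: np.ndarray, r_on: float, r_off: float):
    """Quintic smoothstep switch S(r) with S=1 below r_on, 0 above r_off.

    C2 everywhere: S' and S'' vanish at both ends of the switching window.
    Returns (S, S', S'')."""
    t = np.clip((r - r_on) / (r_off - r_on), 0.0, 1.0)
    s = 1.0 - t**3 * (10.0 - 15.0 * t + 6.0 * t**2)
    dt = 1.0 / (r_off - r_on)
    sp = -30.0 * t**2 * (1.0 - t) ** 2 * dt
    spp = -60.0 * t * (1.0 - t) * (1.0 - 2.0 * t) * dt**2
    return s, sp, spp


def _apply_switch(r, V, Vp, Vpp, policy: NonbondedPolicy):
    if policy.mode != "switched":
        return V, Vp, Vpp
    S, Sp, Spp = _switch(r, policy.switch_start, policy.cutoff)
    return (S * V,
            S * Vp + Sp * V,
            S * Vpp + 2.0 * Sp * Vp + Spp * V)


def _coulomb(r, qq, policy: NonbondedPolicy):
    C = policy.coulomb_constant
    V = C * qq / r
    Vp = -C * qq / r**2
    Vpp = 2.0 * C * qq / r**3
    return _apply_switch(r, V, Vp, Vpp, policy)


def _lennard_jones(r, eps, rmin, policy: NonbondedPolicy):
    A = (rmin / r) ** 12
    B = (rmin / r) ** 6
    V = eps * (A - 2.0 * B)
    Vp = -12.0 * eps * (A - B) / r
    Vpp = eps * (156.0 * A - 84.0 * B) / r**2
    return _apply_switch(r, V, Vp, Vpp, policy)


def _pair_blocks(dx: np.ndarray, r: np.ndarray, Vp: np.ndarray, Vpp: np.ndarray):
    """Force on i and Hessian block H_(i,j) for pair potentials V(r),
    dx = x_i - x_j.

    grad_i V = V'(r) u with u = dx/r; force on i = -V' u.
    H_(i,j) = -[V'' u u^T + (V'/r)(1 - u u^T)].
    """
    u = dx / r[:, None]
    F = -Vp[:, None] * u
    uu = u[:, :, None] * u[:, None, :]
    eye = np.eye(3)[None, :, :]
    K = -(Vpp[:, None, None] * uu + (Vp / r)[:, None, None] * (eye - uu))
    return F, K


# ---------------------------------------------------------------------------
# angle term


def _angle_terms(system: MolecularSystem):
    """Energy, per-atom forces, pairwise CFD forces and Hessian blocks of
    all harmonic angle terms.

    Returns (energy, forces(n,3), pair list [(a,b,F_ab,K_ab)],
    diag blocks dict atom -> 3x3).
    """
    x = system.coordinates
    energy = 0.0
    forces = np.zeros((system.n_atoms, 3))
    pair_entries: list[tuple[int, int, np.ndarray, np.ndarray]] = []
    diag: dict[int, np.ndarray] = {}

    for (ia, jb, kc, kt, t0) in system.angles:
        u = x[ia] - x[jb]
        v = x[kc] - x[jb]
        lu = np.linalg.norm(u)
        lv = np.linalg.norm(v)
        if lu < 1e-10 or lv < 1e-10:
            raise SingularGeometryError(
                f"angle ({ia},{jb},{kc}): coincident atoms")
        c = float(u @ v / (lu * lv))
        c = min(1.0, max(-1.0, c))
        s2 = 1.0 - c * c
        if s2 < 1e-12:
            raise SingularGeometryError(
                f"angle ({ia},{jb},{kc}): collinear geometry")
        s = np.sqrt(s2)
        theta = np.arccos(c)
        dth = theta - t0
        energy += kt * dth * dth

        # chain rule through c = cos(theta)
        Vc = -2.0 * kt * dth / s
        Vcc = 2.0 * kt / s2 - 2.0 * kt * dth * c / (s2 * s)

        # gradient of c wrt u, v
        gc_u = v / (lu * lv) - c * u / lu**2
        gc_v = u / (lu * lv) - c * v / lv**2
        # second derivatives of c
        I3 = np.eye(3)
        Cuu = (-(np.outer(v, u) + np.outer(u, v) + (u @ v) * I3) / (lu**3 * lv)
               + 3.0 * (u @ v) * np.outer(u, u) / (lu**5 * lv))
        Cvv = (-(np.outer(u, v) + np.outer(v, u) + (u @ v) * I3) / (lu * lv**3)
               + 3.0 * (u @ v) * np.outer(v, v) / (lu * lv**5))
        Cuv = (I3 / (lu * lv) - np.outer(v, v) / (lu * lv**3)
               - np.outer(u, u) / (lu**3 * lv)
               + (u @ v) * np.outer(u, v) / (lu**3 * lv**3))

        # gradient of V wrt atom coordinates
        g_i = Vc * gc_u
        g_k = Vc * gc_v
        g_j = -(g_i + g_k)
        forces[ia] -= g_i
        forces[jb] -= g_j
        forces[kc] -= g_k

        # Hessian blocks wrt (u, v), then mapped to atoms i, j, k
        Huu = Vcc * np.outer(gc_u, gc_u) + Vc * Cuu
        Hvv = Vcc * np.outer(gc_v, gc_v) + Vc * Cvv
        Huv = Vcc * np.outer(gc_u, gc_v) + Vc * Cuv

        H_ii = Huu
        H_kk = Hvv
        H_ik = Huv
        H_ij = -(Huu + Huv)          # d/dx_j = -(d/du + d/dv)
        H_kj = -(Huv.T + Hvv)
        H_jj = Huu + Huv + Huv.T + Hvv

        for a, blk in ((ia, H_ii), (jb, H_jj), (kc, H_kk)):
            diag[a] = diag.get(a, np.zeros((3, 3))) + blk

        # central-force decomposition of (f_i, f_j, f_k) onto the three axes
        f_i, f_j, f_k = -g_i, -g_j, -g_k
        d_ij = x[ia] - x[jb]
        d_ik = x[ia] - x[kc]
        d_jk = x[jb] - x[kc]
        # unknowns lam_ij, lam_ik, lam_jk; f_i = lam_ij d_ij + lam_ik d_ik,
        # f_j = -lam_ij d_ij + lam_jk d_jk, f_k = -lam_ik d_ik - lam_jk d_jk
        A = np.zeros((9, 3))
        A[0:3, 0] = d_ij; A[0:3, 1] = d_ik
        A[3:6, 0] = -d_ij; A[3:6, 2] = d_jk
        A[6:9, 1] = -d_ik; A[6:9, 2] = -d_jk
        rhs = np.concatenate([f_i, f_j, f_k])
        lam, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        pair_entries.append((ia, jb, lam[0] * d_ij, H_ij))
        pair_entries.append((ia, kc, lam[1] * d_ik, H_ik))
        pair_entries.append((jb, kc, lam[2] * d_jk, H_kj.T))

    return energy, forces, pair_entries, diag


# ---------------------------------------------------------------------------
# term computation shared by compute_expansion / compute_pair_decomposition


def _nonbonded_pair_lists(system: MolecularSystem, policy: NonbondedPolicy):
    n = system.n_atoms
    iu, ju = np.triu_indices(n, k=1)
    if system.exclusions:
        codes = iu * n + ju
        excl_codes = np.array(sorted(min(p) * n + max(p)
                                     for p in system.exclusions))
        mask = ~np.isin(codes, excl_codes)
        iu, ju = iu[mask], ju[mask]
    dx = system.coordinates[iu] - system.coordinates[ju]
    r = np.linalg.norm(dx, axis=1)
    if len(r) and r.min() < 1e-8:
        k = int(np.argmin(r))
        raise SingularGeometryError(
            f"atoms {iu[k]} and {ju[k]} coincide (r={r[k]:.2e} A)")
    if policy.mode == "switched":
        keep = r < policy.cutoff
        iu, ju, dx, r = iu[keep], ju[keep], dx[keep], r[keep]
    return iu, ju, dx, r


def _compute_terms(system: MolecularSystem, policy: NonbondedPolicy):
    """All per-term contributions at the system's conformation.

    Returns (V0, forces (n,3), pairdec, diag blocks (n,3,3))."""
    n = system.n_atoms
    pd = PairDecomposition(n)
    forces = np.zeros((n, 3))
    diag = np.zeros((n, 3, 3))
    V0 = 0.0

    iu, ju, dx, r = _nonbonded_pair_lists(system, policy)
    if len(iu):
        q = system.charges
        Ve, Vpe, Vppe = _coulomb(r, q[iu] * q[ju], policy)
        eps = np.sqrt(system.lj_epsilons[iu] * system.lj_epsilons[ju])
        rmin = system.lj_rmin_halves[iu] + system.lj_rmin_halves[ju]
        Vv, Vpv, Vppv = _lennard_jones(r, eps, rmin, policy)
        for term, (V, Vp, Vpp) in (("elec", (Ve, Vpe, Vppe)),
                                   ("vdw", (Vv, Vpv, Vppv))):
            F, K = _pair_blocks(dx, r, Vp, Vpp)
            pd.set_term(term, iu, ju, F, K)
            V0 += float(V.sum())
            np.add.at(forces, iu, F)
            np.add.at(forces, ju, -F)
            np.add.at(diag, iu, -K)
            np.add.at(diag, ju, -np.swapaxes(K, 1, 2))

    # bonded: harmonic bonds + harmonic angles share one term channel
    b_i: list[int] = []
    b_j: list[int] = []
    b_F: list[np.ndarray] = []
    b_K: list[np.ndarray] = []
    if system.bonds:
        bi = np.array([b[0] for b in system.bonds])
        bj = np.array([b[1] for b in system.bonds])
        kb = np.array([b[2] for b in system.bonds])
        b0 = np.array([b[3] for b in system.bonds])
        dxb = system.coordinates[bi] - system.coordinates[bj]
        rb = np.linalg.norm(dxb, axis=1)
        if rb.min() < 1e-10:
            raise SingularGeometryError("bonded atoms coincide")
        V = kb * (rb - b0) ** 2
        Vp = 2.0 * kb * (rb - b0)
        Vpp = 2.0 * kb
        F, K = _pair_blocks(dxb, rb, Vp, Vpp)
        V0 += float(V.sum())
        np.add.at(forces, bi, F)
        np.add.at(forces, bj, -F)
        np.add.at(diag, bi, -K)
        np.add.at(diag, bj, -np.swapaxes(K, 1, 2))
        b_i.extend(bi.tolist()); b_j.extend(bj.tolist())
        b_F.extend(F); b_K.extend(K)

    if system.angles:
        Ea, Fa, pair_entries, diag_a = _angle_terms(system)
        V0 += Ea
        forces += Fa
        for a, blk in diag_a.items():
            diag[a] += blk
        for (a, b, Fab, Kab) in pair_entries:
            b_i.append(a); b_j.append(b)
            b_F.append(Fab); b_K.append(Kab)

    if b_i:
        pd.set_term("bonded", np.array(b_i), np.array(b_j),
                    np.array(b_F), np.array(b_K))

    return V0, forces, pd, diag


def compute_expansion(system: MolecularSystem,
                      policy: NonbondedPolicy | None = None) -> SecondOrderExpansion:
    """Second-order Taylor expansion (V0, f, H) at the system conformation.

    The Hessian is assembled from exactly the same per-pair blocks that
    :func:`compute_pair_decomposition` exposes, so the off-diagonal part of
    H agrees with the pair blocks bit-for-bit.
    """
    policy = policy or NonbondedPolicy()
    V0, forces, pd, diag = _compute_terms(system, policy)
    n = system.n_atoms
    H = pd.assemble_offdiagonal()
    for a in range(n):
        H[3 * a:3 * a + 3, 3 * a:3 * a + 3] += diag[a]
    return SecondOrderExpansion(V0=V0, f=forces.ravel(), H=H)


def compute_pair_decomposition(system: MolecularSystem,
                               policy: NonbondedPolicy | None = None) -> PairDecomposition:
    """Per-ordered-pair force vectors and Hessian blocks split by term."""
    policy = policy or NonbondedPolicy()
    _, _, pd, _ = _compute_terms(system, policy)
    return pd


def finite_difference_check(system: MolecularSystem,
                            policy: NonbondedPolicy | None = None,
                            step: float = 1e-5) -> dict:
    """Compare analytic forces/Hessian against central finite differences.

    Forces are checked against differences of the energy; the Hessian
    against differences of the analytic force (better conditioned).  Used
    by the ``check`` CLI subcommand.
    """
    if not step > 0:
        raise ValueError("step must be positive")
    policy = policy or NonbondedPolicy()
    exp = compute_expansion(system, policy)
    n3 = 3 * system.n_atoms
    x0 = system.coordinates.copy()

    def energy(flat):
        return compute_expansion(
            system.with_coordinates(flat.reshape(-1, 3)), policy).V0

    def force(flat):
        return compute_expansion(
            system.with_coordinates(flat.reshape(-1, 3)), policy).f

    f_num = np.zeros(n3)
    H_num = np.zeros((n3, n3))
    flat = x0.ravel().copy()
    for k in range(n3):
        flat[k] += step
        ep = energy(flat)
        fp = force(flat)
        flat[k] -= 2 * step
        em = energy(flat)
        fm = force(flat)
        flat[k] += step
        f_num[k] = -(ep - em) / (2 * step)
        H_num[:, k] = -(fp - fm) / (2 * step)
    H_num = 0.5 * (H_num + H_num.T)
    return {
        "max_force_dev": float(np.abs(exp.f - f_num).max(initial=0.0)),
        "max_hessian_dev": float(np.abs(exp.H - H_num).max(initial=0.0)),
        "step": step,
    }
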