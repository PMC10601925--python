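"""Coarse-grained pairwise forces, antisymmetrization and decomposition.

The all-atom pairwise forces are summed into unit-level pair matrices
(units = protein atoms + solvent particles).  The coarse-grained force on
unit i from unit j splits into a direct part (summed atomic pair forces,
exactly antisymmetric) and an indirect part mediated by the collective
hydrogen dynamics,  [dF']_{i,j} = -[H_ps12 H_1212^-1 F_12<-ps]_{i,j},
which is generically NOT antisymmetric.  The antisymmetrized pair force
replaces the indirect entry by the arithmetic average
(1/2)([dF']_{i,j} - [dF']_{j,i}).

Each atom-solvent entry decomposes into five components: electrostatic
and van der Waals interactions with the water's oxygen (o_elec, o_vdw)
and with its two hydrogens together (h_elec, h_vdw), plus the indirect
component (s_indir).  Projection onto the inter-particle unit vector
r_hat = (x_i - x_j)/r gives the effective pairwise force f_ij (positive
= repulsive) and effective spring constant k_ij.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .forcefield import (
    MolecularSystem, NonbondedPolicy, PairDecomposition,
    compute_expansion, compute_pair_decomposition,
    ROLE_WATER_O, ROLE_WATER_H1, ROLE_WATER_H2,
)
from .partition import AggregatedBlocks, PartitionIndex, classify_atoms, aggregate
from .cgcore import HydrogenSolver, coarse_grain, CGSurface

__all__ = [
    "CGPairForces", "PairSprings", "ComponentSet", "FrameAnalysis",
    "build_pair_matrices", "build_pair_springs", "antisymmetrize",
    "decompose_entry", "effective_scalars", "analyze_frame",
    "collect_records", "COMPONENTS",
]

COMPONENTS = ("o_elec", "o_vdw", "h_elec", "h_vdw", "s_indir")

_SITE_OF_ROLE = {ROLE_WATER_O: "o", ROLE_WATER_H1: "h", ROLE_WATER_H2: "h"}


@dataclass
class CGPairForces:
    """Unit-level pairwise force matrices of one conformation.

    direct[i, j]   : summed atomic pair forces on unit i from unit j
    indirect[i, j] : dF' entry (hydrogen-dynamics mediated, not antisym.)
    sym[i, j]      : F'' entry after antisymmetrization (None until
                     :func:`antisymmetrize` runs)
    term_site[(term, site)] : direct entries split by interaction term
                     ("elec"/"vdw"/"bonded") and source-atom site class
                     ("o" oxygen, "h" hydrogen, "p" protein atom)
    """

    n_p: int
    n_s: int
    direct: np.ndarray
    indirect: np.ndarray
    term_site: dict
    sym: np.ndarray | None = None

    @property
    def n_units(self) -> int:
        return self.n_p + self.n_s

    def Fps_ps(self, i: int, j: int) -> np.ndarray:
        return self.direct[i, j].copy()

    def dFp(self, i: int, j: int) -> np.ndarray:
        return self.indirect[i, j].copy()

    def Fpp_sym(self, i: int, j: int) -> np.ndarray:
        if self.sym is None:
            raise ValueError("call antisymmetrize() first")
        return self.sym[i, j].copy()


@dataclass
class PairSprings:
    """Unit-level 3x3 spring blocks split like the forces.

    total entry [H']_{a,b} = sum of term/site blocks + indirect block."""

    n_p: int
    n_s: int
    term_site: dict
    indirect: np.ndarray  # (nu, nu, 3, 3)

    def entry(self, a: int, b: int) -> np.ndarray:
        out = self.indirect[a, b].copy()
        for blk in self.term_site.values():
            out += blk[a, b]
        return out


@dataclass
class ComponentSet:
    """Five-component split of one pair entry (3-vector or 3x3 context)."""

    o_elec: np.ndarray
    o_vdw: np.ndarray
    h_elec: np.ndarray
    h_vdw: np.ndarray
    s_indir: np.ndarray

    @property
    def s_dir(self) -> np.ndarray:
        return self.o_elec + self.o_vdw + self.h_elec + self.h_vdw

    @property
    def s_all(self) -> np.ndarray:
        return self.s_dir + self.s_indir


def _unit_and_site_maps(part: PartitionIndex, system: MolecularSystem):
    unit = part.unit_of_atom(system.n_atoms)
    site = np.zeros(system.n_atoms, dtype="<U1")
    site[:] = "p"
    roles = system.roles
    for a in range(system.n_atoms):
        site[a] = _SITE_OF_ROLE.get(roles[a], "p")
    return unit, site


def _hydrogen_row_index(part: PartitionIndex, n_atoms: int) -> np.ndarray:
    """Atom index -> row offset (in 3-coordinate blocks) inside the stacked
    (D1, D2) hydrogen vector; -1 for non-hydrogens."""
    row = np.full(n_atoms, -1, dtype=int)
    row[part.h1_idx] = np.arange(part.n_s)
    row[part.h2_idx] = part.n_s + np.arange(part.n_s)
    return row


def build_pair_matrices(pairdec: PairDecomposition, blocks: AggregatedBlocks,
                        part: PartitionIndex,
                        system: MolecularSystem,
                        solver: HydrogenSolver | None = None) -> CGPairForces:
    """Unit-level direct and indirect pairwise force matrices.

    The direct entries sum atomic pair forces per unit pair; the indirect
    entries apply -H_ps12 H_1212^-1 columnwise to the matrix of atomic
    forces exerted on the hydrogens by each unit.
    """
    solver = solver or HydrogenSolver(blocks)
    nu = part.n_units
    unit, site = _unit_and_site_maps(part, system)
    hrow = _hydrogen_row_index(part, system.n_atoms)

    direct = np.zeros((nu, nu, 3))
    term_site: dict = {}
    F12 = np.zeros((6 * part.n_s, nu))  # force on hydrogen coords by unit j

    for term in pairdec.terms():
        i_idx, j_idx, F, _ = pairdec.pair_arrays(term)
        ui, uj = unit[i_idx], unit[j_idx]
        inter = ui != uj
        ii, jj, Fij = ui[inter], uj[inter], F[inter]
        np.add.at(direct, (ii, jj), Fij)
        np.add.at(direct, (jj, ii), -Fij)
        for s in ("o", "h", "p"):
            key = (term, s)
            acc = term_site.setdefault(key, np.zeros((nu, nu, 3)))
            m = inter & (site[j_idx] == s)
            np.add.at(acc, (unit[i_idx][m], unit[j_idx][m]), F[m])
            m = inter & (site[i_idx] == s)
            np.add.at(acc, (unit[j_idx][m], unit[i_idx][m]), -F[m])
        # forces on hydrogens (rows of F_12<-ps); intra-unit pairs included
        # so that column sums reproduce f_12 exactly
        for a_idx, b_idx, sign in ((i_idx, j_idx, 1.0), (j_idx, i_idx, -1.0)):
            m = hrow[a_idx] >= 0
            rows = 3 * hrow[a_idx[m]]
            cols = unit[b_idx[m]]
            vals = sign * F[m]
            for ax in range(3):
                np.add.at(F12, (rows + ax, cols), vals[:, ax])

    D = -blocks.H_ps12 @ solver.solve(F12)  # (3 nu, nu)
    indirect = np.transpose(D.reshape(nu, 3, nu), (0, 2, 1))
    return CGPairForces(n_p=part.n_p, n_s=part.n_s, direct=direct,
                        indirect=indirect, term_site=term_site)


def build_pair_springs(pairdec: PairDecomposition, blocks: AggregatedBlocks,
                       part: PartitionIndex, system: MolecularSystem,
                       surface: CGSurface) -> PairSprings:
    """Unit-level spring blocks split by term/site, plus the indirect
    (Schur-correction) blocks taken from H' - H_psps."""
    nu = part.n_units
    unit, site = _unit_and_site_maps(part, system)
    term_site: dict = {}
    for term in pairdec.terms():
        i_idx, j_idx, _, K = pairdec.pair_arrays(term)
        ui, uj = unit[i_idx], unit[j_idx]
        inter = ui != uj
        for s in ("o", "h", "p"):
            key = (term, s)
            acc = term_site.setdefault(key, np.zeros((nu, nu, 3, 3)))
            m = inter & (site[j_idx] == s)
            np.add.at(acc, (ui[m], uj[m]), K[m])
            m = inter & (site[i_idx] == s)
            np.add.at(acc, (uj[m], ui[m]), np.swapaxes(K[m], 1, 2))
    Hind = surface.Hp - blocks.H_psps
    indirect = Hind.reshape(nu, 3, nu, 3).transpose(0, 2, 1, 3).copy()
    return PairSprings(n_p=part.n_p, n_s=part.n_s, term_site=term_site,
                       indirect=indirect)


def antisymmetrize(cgpf: CGPairForces) -> CGPairForces:
    """Fill the antisymmetric pair force F'' in place and return cgpf.

    [F'']_{i,j} = [direct]_{i,j} + (1/2)([dF']_{i,j} - [dF']_{j,i});
    antisymmetry is exact because both summands are.
    """
    ind = cgpf.indirect
    cgpf.sym = cgpf.direct + 0.5 * (ind - np.transpose(ind, (1, 0, 2)))
    return cgpf


def pair_energy_diagnostic(cgpf: CGPairForces, fp: np.ndarray,
                           delta_ps: np.ndarray) -> dict:
    """Compare the pairwise-difference energy form of F'' with fp.delta.

    sum_{i<j} (d_i - d_j).[F'']_{i,j}  vs  fp.d  — reported, not asserted:
    the antisymmetrization redistributes indirect forces, so the two agree
    only up to that redistribution.
    """
    if cgpf.sym is None:
        raise ValueError("call antisymmetrize() first")
    d = np.asarray(delta_ps, float).reshape(cgpf.n_units, 3)
    iu, ju = np.triu_indices(cgpf.n_units, k=1)
    pair_form = float(np.einsum("kc,kc->", d[iu] - d[ju], cgpf.sym[iu, ju]))
    return {"pair_form": pair_form, "fp_dot_delta": float(fp @ d.ravel())}


def decompose_entry(a: int, b: int, cgpf: CGPairForces,
                    springs: PairSprings) -> tuple[ComponentSet, ComponentSet]:
    """Five-component split of the (a, b) force and spring entries.

    b must be a solvent particle.  Force components come from the
    term/site-split direct matrices and the antisymmetrized indirect
    entry; spring components from the term/site spring blocks and the
    Schur-correction block.
    """
    if not (cgpf.n_p <= b < cgpf.n_units):
        raise IndexError(f"unit {b} is not a solvent particle")
    if cgpf.sym is None:
        antisymmetrize(cgpf)

    def _f(term, s):
        blk = cgpf.term_site.get((term, s))
        return blk[a, b].copy() if blk is not None else np.zeros(3)

    ind_f = 0.5 * (cgpf.indirect[a, b] - cgpf.indirect[b, a])
    comp_f = ComponentSet(o_elec=_f("elec", "o"), o_vdw=_f("vdw", "o"),
                          h_elec=_f("elec", "h"), h_vdw=_f("vdw", "h"),
                          s_indir=ind_f)

    def _k(term, s):
        blk = springs.term_site.get((term, s))
        return blk[a, b].copy() if blk is not None else np.zeros((3, 3))

    comp_k = ComponentSet(o_elec=_k("elec", "o"), o_vdw=_k("vdw", "o"),
                          h_elec=_k("elec", "h"), h_vdw=_k("vdw", "h"),
                          s_indir=springs.indirect[a, b].copy())
    return comp_f, comp_k


def effective_scalars(entry_force: np.ndarray, entry_spring: np.ndarray,
                      x_i: np.ndarray, x_j: np.ndarray) -> tuple[float, float]:
    """Project a pair entry onto the inter-particle direction.

    f_ij = F.(x_i - x_j)/r  (positive = repulsive);
    k_ij = r_hat^T K r_hat.
    """
    d = np.asarray(x_i, float) - np.asarray(x_j, float)
    r = np.linalg.norm(d)
    if r < 1e-10:
        raise ZeroDivisionError("zero separation between pair sites")
    u = d / r
    return float(np.asarray(entry_force) @ u), float(u @ np.asarray(entry_spring) @ u)


# ---------------------------------------------------------------------------
# frame pipeline


@dataclass
class FrameAnalysis:
    """Everything the record collector needs from one conformation."""

    system: MolecularSystem
    part: PartitionIndex
    blocks: AggregatedBlocks
    surface: CGSurface
    cgpf: CGPairForces
    springs: PairSprings
    unit_positions: np.ndarray
    unit_labels: list[str]


def analyze_frame(system: MolecularSystem,
                  policy: NonbondedPolicy | None = None) -> FrameAnalysis:
    """Run the full per-conformation pipeline: expansion -> aggregation ->
    coarse-graining -> pair matrices (antisymmetrized) -> spring blocks."""
    policy = policy or NonbondedPolicy()
    exp = compute_expansion(system, policy)
    pairdec = compute_pair_decomposition(system, policy)
    part = classify_atoms(system)
    blocks = aggregate(exp, part, system.masses)
    solver = HydrogenSolver(blocks)
    surface = coarse_grain(blocks, solver)
    cgpf = build_pair_matrices(pairdec, blocks, part, system, solver)
    antisymmetrize(cgpf)
    springs = build_pair_springs(pairdec, blocks, part, system, surface)
    labels = ([system.atoms[i].type_label for i in part.p_idx]
              + ["SOL"] * part.n_s)
    return FrameAnalysis(system=system, part=part, blocks=blocks,
                         surface=surface, cgpf=cgpf, springs=springs,
                         unit_positions=part.unit_positions(system.coordinates),
                         unit_labels=labels)


def _record_pairs(fa: FrameAnalysis, cutoff: float):
    """(i, j, r) unit pairs within cutoff, split into the atom-solvent and
    solvent-solvent streams (j canonical: solvent index; i < j for
    solvent-solvent)."""
    X = fa.unit_positions
    n_p, nu = fa.part.n_p, fa.part.n_units
    out = {}
    if n_p > 0 and fa.part.n_s > 0:
        ii, jj = np.meshgrid(np.arange(n_p), np.arange(n_p, nu), indexing="ij")
        ii, jj = ii.ravel(), jj.ravel()
        r = np.linalg.norm(X[ii] - X[jj], axis=1)
        keep = r <= cutoff
        out["atom_solvent"] = (ii[keep], jj[keep], r[keep])
    if fa.part.n_s > 1:
        si, sj = np.triu_indices(fa.part.n_s, k=1)
        si, sj = si + n_p, sj + n_p
        r = np.linalg.norm(X[si] - X[sj], axis=1)
        keep = r <= cutoff
        out["solvent_solvent"] = (si[keep], sj[keep], r[keep])
    return out


def _component_scalars(fa: FrameAnalysis, ii, jj, rr):
    """Vectorized effective-force/spring component scalars for pair lists."""
    X = fa.unit_positions
    u = (X[ii] - X[jj]) / rr[:, None]
    cols: dict[str, np.ndarray] = {}
    ind_f = 0.5 * (fa.cgpf.indirect[ii, jj] - fa.cgpf.indirect[jj, ii])
    fparts = {
        "o_elec": fa.cgpf.term_site.get(("elec", "o")),
        "o_vdw": fa.cgpf.term_site.get(("vdw", "o")),
        "h_elec": fa.cgpf.term_site.get(("elec", "h")),
        "h_vdw": fa.cgpf.term_site.get(("vdw", "h")),
    }
    total_f = np.zeros(len(ii))
    for name, blk in fparts.items():
        v = blk[ii, jj] if blk is not None else np.zeros((len(ii), 3))
        cols[f"f_{name}"] = np.einsum("kc,kc->k", v, u)
        total_f += cols[f"f_{name}"]
    cols["f_s_indir"] = np.einsum("kc,kc->k", ind_f, u)
    cols["f_s_dir"] = total_f
    cols["f_s_all"] = total_f + cols["f_s_indir"]

    kparts = {
        "o_elec": fa.springs.term_site.get(("elec", "o")),
        "o_vdw": fa.springs.term_site.get(("vdw", "o")),
        "h_elec": fa.springs.term_site.get(("elec", "h")),
        "h_vdw": fa.springs.term_site.get(("vdw", "h")),
    }
    total_k = np.zeros(len(ii))
    for name, blk in kparts.items():
        v = blk[ii, jj] if blk is not None else np.zeros((len(ii), 3, 3))
        cols[f"k_{name}"] = np.einsum("kc,kcd,kd->k", u, v, u)
        total_k += cols[f"k_{name}"]
    cols["k_s_indir"] = np.einsum("kc,kcd,kd->k", u, fa.springs.indirect[ii, jj], u)
    cols["k_s_dir"] = total_k
    cols["k_s_all"] = total_k + cols["k_s_indir"]
    return cols


def collect_records(ensemble: Iterable[MolecularSystem],
                    record_cutoff: float = 12.0,
                    policy: NonbondedPolicy | None = None,
                    with_correlation: bool = False,
                    zero_count: int = 6) -> pd.DataFrame:
    """Long-format interaction records over an ensemble of conformations.

    One row per (unit pair, frame) with inter-unit distance <= the record
    cutoff; atom-solvent and solvent-solvent streams are distinguished by
    the ``stream`` column.  Optionally adds the mode-based motion
    correlation ``c`` per pair.
    """
    if record_cutoff <= 0:
        raise ValueError("record_cutoff must be positive")
    frames = []
    n_frames = 0
    for fid, system in enumerate(ensemble):
        n_frames += 1
        fa = analyze_frame(system, policy)
        labels = np.array(fa.unit_labels)
        corr = None
        if with_correlation:
            from .spectra import mode_decompose, pair_correlations
            modes = mode_decompose(fa.surface.Hp, fa.blocks.unit_masses,
                                   zero_count=zero_count)
        for stream, (ii, jj, rr) in _record_pairs(fa, record_cutoff).items():
            if len(ii) == 0:
                continue
            cols = _component_scalars(fa, ii, jj, rr)
            df = pd.DataFrame({"stream": stream, "frame": fid,
                               "i_label": labels[ii], "j_label": labels[jj],
                               "r": rr, **cols})
            if with_correlation:
                from .spectra import pair_correlations
                df["c"] = pair_correlations(modes, ii, jj)
            frames.append(df)
    if n_frames == 0:
        raise ValueError("empty ensemble")
    if not frames:
        return pd.DataFrame(columns=["stream", "frame", "i_label",
                                     "j_label", "r"])
    return pd.concat(frames, ignore_index=True)
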