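"""Elimination of relative hydrogen displacements from the quadratic surface.

The hydrogens' relative displacements D12 are constrained variables:
stationarity of the quadratic surface with respect to the mass-weighted
D12 (no potential/kinetic energy exchange through those coordinates)
gives  D12* = H_1212^-1 (f_12 - H_12ps d_ps).  Substituting D12* back
yields the coarse-grained surface over atoms and solvent particles:

    H' = H_psps - H_ps12 H_1212^-1 H_12ps        (Schur complement)
    f' = f_ps  - H_ps12 H_1212^-1 f_12
    V0' = V0 - (1/2) f_12^T H_1212^-1 f_12

With zero forces this reduces to the classical normal-mode-analysis model
reduction.  The mass weighting is immaterial while H_1212 is invertible;
for (near-)singular blocks it supplies the canonical metric in which
null-space directions are truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .partition import AggregatedBlocks, delta_tilde_energy

__all__ = ["CGSurface", "DegenerateSystemError", "HydrogenSolver",
           "hydrogen_response", "coarse_grain"]

#: condition-number threshold beyond which the direct factorization is
#: abandoned for a mass-weighted eigendecomposition pseudo-inverse
CONDITION_LIMIT = 1e10
#: relative eigenvalue magnitude below which modes are treated as null
NULL_SPACE_RTOL = 1e-8


class DegenerateSystemError(np.linalg.LinAlgError):
    """H_1212 is singular and the stationarity condition has no solution."""


@dataclass
class CGSurface:
    """Coarse-grained surface (V0', f', H') over atoms + solvent particles."""

    V0p: float
    fp: np.ndarray
    Hp: np.ndarray
    solve_report: dict = field(default_factory=dict)


class HydrogenSolver:
    """Factorization of H_1212 with a pseudo-inverse fallback.

    Solves H_1212 X = B.  If the condition estimate of H_1212 exceeds
    CONDITION_LIMIT, switches to an eigendecomposition pseudo-inverse in
    mass-weighted coordinates, dropping eigenvalues with
    |lam| < NULL_SPACE_RTOL * max|lam|.
    """

    def __init__(self, blocks: AggregatedBlocks):
        self.blocks = blocks
        H = blocks.H_1212
        self.n = H.shape[0]
        self.used_pseudo_inverse = False
        self.dropped = 0
        if self.n == 0:
            self.condition = 1.0
            return
        lu, piv = sla.lu_factor(H)
        anorm = np.linalg.norm(H, 1)
        rcond, _ = sla.lapack.dgecon(lu, anorm, norm="1")
        self.condition = float(1.0 / rcond) if rcond > 0 else np.inf
        if self.condition <= CONDITION_LIMIT:
            self._lu = (lu, piv)
        else:
            self.used_pseudo_inverse = True
            m = blocks.M12
            w = 1.0 / np.sqrt(m)
            Hw = (H * w[None, :]) * w[:, None]
            lam, Q = np.linalg.eigh(0.5 * (Hw + Hw.T))
            keep = np.abs(lam) >= NULL_SPACE_RTOL * np.abs(lam).max(initial=0.0)
            self.dropped = int((~keep).sum())
            self._pinv = (w, lam[keep], Q[:, keep])

    def solve(self, B: np.ndarray) -> np.ndarray:
        if self.n == 0:
            return np.zeros_like(B)
        if not self.used_pseudo_inverse:
            return sla.lu_solve(self._lu, B)
        w, lam, Q = self._pinv
        Bw = B * w if B.ndim == 1 else B * w[:, None]
        y = Q.T @ Bw
        y = y / lam if B.ndim == 1 else y / lam[:, None]
        x = Q @ y
        return x * w if B.ndim == 1 else x * w[:, None]

    def report(self) -> dict:
        return {
            "condition": self.condition,
            "pseudo_inverse": self.used_pseudo_inverse,
            "dropped_singular_values": self.dropped,
        }


def hydrogen_response(blocks: AggregatedBlocks, delta_ps: np.ndarray,
                      solver: HydrogenSolver | None = None) -> np.ndarray:
    """Stationary relative hydrogen displacements for given d_ps.

    The returned D12 zeroes the gradient of the quadratic surface with
    respect to D12; if H_1212 is singular beyond the pseudo-inverse
    tolerance and no stationary point exists, a DegenerateSystemError
    names the offending waters.
    """
    solver = solver or HydrogenSolver(blocks)
    d = np.asarray(delta_ps, float).ravel()
    rhs = blocks.f_12 - blocks.H_12ps @ d
    D12 = solver.solve(rhs)
    grad = blocks.H_1212 @ D12 - rhs
    scale = max(np.abs(rhs).max(initial=0.0), np.abs(blocks.H_1212).max(initial=1.0))
    if np.linalg.norm(grad) > 1e-6 * max(scale, 1.0):
        per_coord = np.abs(grad)
        n_s = blocks.n_s
        per_water = (per_coord[:3 * n_s].reshape(n_s, 3).sum(axis=1)
                     + per_coord[3 * n_s:].reshape(n_s, 3).sum(axis=1))
        bad = np.argsort(per_water)[::-1][:5]
        raise DegenerateSystemError(
            "no stationary hydrogen response exists; largest residuals on "
            f"waters {bad.tolist()}")
    return D12


def coarse_grain(blocks: AggregatedBlocks,
                 solver: HydrogenSolver | None = None) -> CGSurface:
    """Coarse-grained surface (V0', f', H') by eliminating D12.

    For every d_ps, evaluating the returned surface equals evaluating the
    full reorganized quadratic form at (d_ps, hydrogen_response(d_ps)).
    """
    solver = solver or HydrogenSolver(blocks)
    z = solver.solve(blocks.f_12)
    Y = solver.solve(blocks.H_12ps)
    Hp = blocks.H_psps - blocks.H_ps12 @ Y
    Hp = 0.5 * (Hp + Hp.T)
    fp = blocks.f_ps - blocks.H_ps12 @ z
    V0p = blocks.V0 - 0.5 * float(blocks.f_12 @ z)
    return CGSurface(V0p=V0p, fp=fp, Hp=Hp, solve_report=solver.report())


def cg_energy(surface: CGSurface, d_ps: np.ndarray) -> float:
    """Evaluate the coarse-grained quadratic surface at d_ps."""
    d = np.asarray(d_ps, float).ravel()
    return float(surface.V0p - surface.fp @ d + 0.5 * d @ surface.Hp @ d)


def full_energy_at_response(blocks: AggregatedBlocks, d_ps: np.ndarray,
                            solver: HydrogenSolver | None = None) -> float:
    """Full reorganized-surface energy at (d_ps, stationary D12) —
    the plug-in check that pins the V0'/f' correction terms."""
    solver = solver or HydrogenSolver(blocks)
    D12 = hydrogen_response(blocks, d_ps, solver)
    return delta_tilde_energy(blocks, d_ps, D12)
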