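"""Eigenmode analysis of the coarse-grained surface.

Modes come from the mass-weighted Hessian M^-1/2 H' M^-1/2 (solvent
particles carry the full water mass).  Motion correlations between two
sites weight each mode's displacement dot product by 1/|eigenvalue|,
which extends the usual inverse-eigenvalue fluctuation weighting to
unstable (negative-eigenvalue) modes while keeping self-covariances
non-negative; the six smallest-|eigenvalue| modes (rigid-body for a free
droplet) are excluded by default.  Correlation-vs-distance curves decay
near-exponentially; the decay ratio per Angstrom is the exponential of
the least-squares slope of ln(correlation) against distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ModeSet", "CorrelationCurve", "mode_decompose",
           "motion_correlation", "pair_correlations", "decay_ratio",
           "UndefinedCorrelationError"]


class UndefinedCorrelationError(ValueError):
    """All modes are excluded, leaving no fluctuation to correlate."""


@dataclass
class ModeSet:
    """Eigenmodes of the mass-weighted coarse-grained Hessian.

    eigenvalues sorted by |lambda| ascending (kcal/mol/A^2/amu);
    eigenvectors orthonormal in mass-weighted coordinates (columns);
    the first ``zeroed_mode_count`` modes are flagged excluded.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    masses3: np.ndarray           # per-coordinate masses (3 n_units,)
    zeroed_mode_count: int

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def weights(self) -> np.ndarray:
        """1/|lambda| for included modes, 0 for excluded ones."""
        w = np.zeros(self.n_modes)
        inc = np.arange(self.n_modes) >= self.zeroed_mode_count
        lam = np.abs(self.eigenvalues[inc])
        if np.any(lam == 0):
            raise UndefinedCorrelationError(
                "zero eigenvalue among included modes")
        w[inc] = 1.0 / lam
        return w

    def cartesian_modes(self) -> np.ndarray:
        """Columns are Cartesian displacement patterns M^-1/2 q."""
        return self.eigenvectors / np.sqrt(self.masses3)[:, None]

    def reconstruct(self) -> np.ndarray:
        """M^1/2 Q diag(lam) Q^T M^1/2 — recovers H' (round-trip check)."""
        s = np.sqrt(self.masses3)
        Hw = (self.eigenvectors * self.eigenvalues) @ self.eigenvectors.T
        return (Hw * s[None, :]) * s[:, None]


def mode_decompose(Hp: np.ndarray, masses: np.ndarray,
                   zero_count: int = 6) -> ModeSet:
    """Eigendecomposition of M^-1/2 Hp M^-1/2, sorted by |lambda|."""
    Hp = np.asarray(Hp, float)
    if Hp.ndim != 2 or Hp.shape[0] != Hp.shape[1]:
        raise ValueError("Hp must be square")
    scale = np.abs(Hp).max(initial=1.0)
    if np.abs(Hp - Hp.T).max(initial=0.0) > 1e-8 * max(scale, 1.0):
        raise ValueError("Hp must be symmetric")
    masses = np.asarray(masses, float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    m3 = np.repeat(masses, 3)
    if len(m3) != Hp.shape[0]:
        raise ValueError("mass/Hessian dimension mismatch")
    w = 1.0 / np.sqrt(m3)
    Hw = (0.5 * (Hp + Hp.T) * w[None, :]) * w[:, None]
    lam, Q = np.linalg.eigh(Hw)
    order = np.argsort(np.abs(lam), kind="stable")
    return ModeSet(eigenvalues=lam[order], eigenvectors=Q[:, order],
                   masses3=m3, zeroed_mode_count=int(zero_count))


def _weighted_modes(modes: ModeSet) -> np.ndarray:
    w = modes.weights()
    if not np.any(w > 0):
        raise UndefinedCorrelationError("all modes are excluded")
    return modes.cartesian_modes() * np.sqrt(w)[None, :]


def motion_correlation(modes: ModeSet, i: int, j: int) -> float:
    """Normalized mode-weighted covariance of sites i and j (c_ii = 1)."""
    c = pair_correlations(modes, np.array([i]), np.array([j]))
    return float(c[0])


def pair_correlations(modes: ModeSet, ii: np.ndarray,
                      jj: np.ndarray) -> np.ndarray:
    """Vectorized motion correlations for parallel site-index arrays."""
    A = _weighted_modes(modes)
    n_sites = A.shape[0] // 3
    B = A.reshape(n_sites, 3, -1)
    var = np.einsum("scm,scm->s", B, B)
    ii = np.asarray(ii, int)
    jj = np.asarray(jj, int)
    cov = np.einsum("kcm,kcm->k", B[ii], B[jj])
    denom = np.sqrt(var[ii] * var[jj])
    # a site with zero mode-weighted variance (e.g. a fully decoupled
    # particle) has no defined correlation; report NaN rather than 0/0
    out = np.full(len(denom), np.nan)
    np.divide(cov, denom, out=out, where=denom > 0)
    return out


@dataclass
class CorrelationCurve:
    """Distance-binned mean motion correlation for one site grouping.

    x is the (possibly surface-offset) distance grid; c the trimmed-mean
    correlation per bin."""

    x: np.ndarray
    c: np.ndarray
    label: str = ""


def decay_ratio(curve, window: tuple[float, float] = (5.0, 10.0)) -> float:
    """Exponential decay ratio per Angstrom over the fit window.

    Least-squares line fit to (x, ln y); the ratio is exp(slope), so a
    pure y = a r^x yields exactly r.  Values must be positive inside the
    window."""
    if hasattr(curve, "c"):
        x, y = np.asarray(curve.x, float), np.asarray(curve.c, float)
    elif hasattr(curve, "valid"):
        x, y = np.asarray(curve.x, float), np.asarray(curve.valid("mean"), float)
    else:
        x, y = (np.asarray(v, float) for v in curve)
    lo, hi = window
    sel = (x >= lo) & (x <= hi) & np.isfinite(y)
    if sel.sum() < 2:
        raise ValueError("fewer than two curve points inside the fit window")
    if np.any(y[sel] <= 0):
        raise ValueError("nonpositive correlation values in the fit window")
    slope, _ = np.polyfit(x[sel], np.log(y[sel]), 1)
    return float(np.exp(slope))
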