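"""Distance-binned statistics of interaction records and the hydrophilic
degree.

Records are binned on a 0.1 A grid with half-open bins [x-0.05, x+0.05).
Per bin the mean and standard deviation are computed on the values inside
the 5th-95th percentile interior (outlier trimming); the reported
10/25/75/90th percentiles are computed on the untrimmed bin values.

Spring-constant curves integrate to an approximate force curve
f_hat(x) = integral from the smallest plotted x of the mean spring
constant, plus an offset g chosen so that f_hat averages to zero over a
far-field window (8-12 A by default): for an isolated pair potential the
projected spring constant equals d f_ij / d r, which pins the sign.

The hydrophilic degree of an atom type is the separation energy: the
averaged area of the negative regions of the mean effective pairwise
force and its spring-integrated approximation, i.e. the maximum work
needed to carry a solvent particle from the atom out to 12 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = ["ProfileCurve", "Curve", "HydrophilicResult", "bin_profile",
           "integrate_spring_to_force", "hydrophilic_degree",
           "integrate_force_to_potential", "potential_minimum", "GapError"]


class GapError(ValueError):
    """The binned curve has masked gaps where a contiguous grid is needed."""


@dataclass
class Curve:
    """A bare (x, y) curve on the bin-center grid."""

    x: np.ndarray
    y: np.ndarray
    label: str = ""


@dataclass
class ProfileCurve:
    """Trimmed per-bin statistics of one record component.

    Arrays cover every populated bin (sorted by center); ``mask`` is True
    for bins whose count reaches ``min_count``.  ``x``/``mean`` etc. on
    the unmasked view are available via :meth:`valid`.
    """

    centers: np.ndarray
    mean: np.ndarray
    p10: np.ndarray
    p25: np.ndarray
    p75: np.ndarray
    p90: np.ndarray
    std: np.ndarray
    count: np.ndarray
    mask: np.ndarray
    component: str = ""
    pair_label: str = ""
    bin_width: float = 0.1

    @property
    def x(self) -> np.ndarray:
        return self.centers[self.mask]

    def valid(self, attr: str = "mean") -> np.ndarray:
        return getattr(self, attr)[self.mask]

    def as_curve(self) -> Curve:
        return Curve(x=self.x, y=self.valid("mean"),
                     label=f"{self.pair_label}:{self.component}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pair_label": self.pair_label, "component": self.component,
            "x": self.centers, "mean": self.mean, "p10": self.p10,
            "p25": self.p25, "p75": self.p75, "p90": self.p90,
            "std": self.std, "n": self.count, "valid": self.mask,
        })


@dataclass
class HydrophilicResult:
    """Separation-energy summary for one atom type."""

    degree: float
    area_f: float
    area_fhat: float
    g_ij: float
    classification: str
    threshold: float = 0.1

    def to_dict(self) -> dict:
        return {"degree": self.degree, "area_f": self.area_f,
                "area_fhat": self.area_fhat, "g_ij": self.g_ij,
                "classification": self.classification,
                "threshold": self.threshold}


def degree_from_records(records: pd.DataFrame,
                        component_f: str = "f_s_all",
                        component_k: str = "k_s_all",
                        bin_width: float = 0.1,
                        trim: tuple[float, float] = (5.0, 95.0),
                        min_count: int = 25,
                        zero_window: tuple[float, float] = (8.0, 12.0),
                        upper: float = 12.0,
                        threshold: float = 0.1,
                        pair_label: str = "") -> HydrophilicResult:
    """Hydrophilic degree straight from a record table: bin the force and
    spring curves, integrate the spring curve, and average the two areas."""
    fcurve = bin_profile(records, component_f, bin_width, trim, min_count,
                         pair_label)
    kcurve = bin_profile(records, component_k, bin_width, trim, min_count,
                         pair_label)
    fhat = integrate_spring_to_force(kcurve, zero_window)
    return hydrophilic_degree(fcurve, fhat, upper=upper, threshold=threshold)


def _bin_index(r: np.ndarray, width: float) -> np.ndarray:
    # half-open [c - w/2, c + w/2) convention; the tiny epsilon pushes
    # values landing exactly on a bin edge into the upper bin
    return np.floor(np.asarray(r, float) / width + 0.5 + 1e-9).astype(int)


def bin_profile(records: pd.DataFrame, component: str,
                bin_width: float = 0.1,
                trim: tuple[float, float] = (5.0, 95.0),
                min_count: int = 25,
                pair_label: str = "") -> ProfileCurve:
    """Distance-binned trimmed statistics of one record component.

    ``records`` needs columns ``r`` and ``component`` (e.g. "f_s_all").
    """
    if len(records) == 0:
        raise ValueError("empty record stream")
    if component not in records.columns:
        raise KeyError(f"no component column {component!r}")
    r = records["r"].to_numpy(float)
    v = records[component].to_numpy(float)
    idx = _bin_index(r, bin_width)
    # sort by (bin, value) so every statistic is bit-for-bit independent
    # of the input record order
    order = np.lexsort((v, idx))
    idx, v = idx[order], v[order]
    uniq, starts = np.unique(idx, return_index=True)
    bounds = np.append(starts, len(v))

    n_bins = len(uniq)
    out = {k: np.full(n_bins, np.nan) for k in
           ("mean", "p10", "p25", "p75", "p90", "std")}
    count = np.zeros(n_bins, dtype=int)
    lo, hi = trim
    for b in range(n_bins):
        vals = v[bounds[b]:bounds[b + 1]]
        count[b] = len(vals)
        q5, q10, q25, q75, q90, q95 = np.percentile(
            vals, [lo, 10, 25, 75, 90, hi])
        interior = vals[(vals >= q5) & (vals <= q95)]
        # a 2-4 value bin can have an empty trim interior; leave it NaN
        # (such bins never reach min_count and stay masked)
        if interior.size:
            out["mean"][b] = interior.mean()
            out["std"][b] = interior.std()
        out["p10"][b], out["p25"][b] = q10, q25
        out["p75"][b], out["p90"][b] = q75, q90
    if not np.any(count >= min_count):
        raise ValueError(
            f"no bin reaches min_count={min_count} (max count {count.max()})")
    return ProfileCurve(
        centers=np.round(uniq * bin_width, 9), mean=out["mean"], p10=out["p10"],
        p25=out["p25"], p75=out["p75"], p90=out["p90"], std=out["std"],
        count=count, mask=count >= min_count, component=component,
        pair_label=pair_label, bin_width=bin_width)


def _contiguous_xy(curve: ProfileCurve | Curve):
    if isinstance(curve, ProfileCurve):
        x, y = curve.x, curve.valid("mean")
        w = curve.bin_width
        if len(x) >= 2 and np.any(np.diff(x) > w * 1.5):
            raise GapError("masked gaps inside the binned curve")
    else:
        x, y = np.asarray(curve.x, float), np.asarray(curve.y, float)
    if len(x) < 2:
        raise ValueError("need at least two bins")
    return x, y


def integrate_spring_to_force(kcurve: ProfileCurve | Curve,
                              zero_window: tuple[float, float] = (8.0, 12.0)
                              ) -> Curve:
    """Approximate force curve from the mean spring-constant curve.

    f_hat(x) = integral_{min}^{x} k(s) ds + g, with g fixing the mean of
    f_hat over the zero window to 0 (far-field forces vanish).
    """
    x, k = _contiguous_xy(kcurve)
    fhat = cumulative_trapezoid(k, x, initial=0.0)
    sel = (x >= zero_window[0]) & (x <= zero_window[1])
    if not np.any(sel):
        # curve ends before the zero window (small droplet): anchor on the
        # farthest sampled 1 A instead of leaving f_hat unanchored
        sel = x >= x.max() - 1.0
    g = -fhat[sel].mean()
    label = getattr(kcurve, "component", "") or getattr(kcurve, "label", "")
    return Curve(x=x, y=fhat + g, label=f"{label}_fhat")


def integrate_force_to_potential(fcurve: ProfileCurve | Curve) -> Curve:
    """Pairwise potential U(x) = -integral of the mean force (U(min)=0)."""
    x, f = _contiguous_xy(fcurve)
    U = -cumulative_trapezoid(f, x, initial=0.0)
    return Curve(x=x, y=U, label="potential")


def potential_minimum(curve: Curve,
                      window: tuple[float, float] = (2.0, 4.0)) -> float:
    """Location of the potential minimum inside the search window."""
    sel = (curve.x >= window[0]) & (curve.x <= window[1])
    if not np.any(sel):
        raise ValueError("no curve points inside the search window")
    xs, ys = curve.x[sel], curve.y[sel]
    return float(xs[np.argmin(ys)])


def _curve_xy(curve) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(curve, ProfileCurve):
        return curve.x, curve.valid("mean")
    return np.asarray(curve.x, float), np.asarray(curve.y, float)


def hydrophilic_degree(fcurve, fhatcurve, upper: float = 12.0,
                       threshold: float = 0.1) -> HydrophilicResult:
    """Separation energy from the force curve and its spring-integrated
    approximation.

    area = -integral of min(curve, 0) over [grid start, upper];
    degree = (area_f + area_fhat)/2; classification against ``threshold``
    (0.1 kcal/mol by default; 3.0 marks the strongly hydrophilic class).
    """
    xf, yf = _curve_xy(fcurve)
    xh, yh = _curve_xy(fhatcurve)
    if len(xf) != len(xh) or not np.allclose(xf, xh, atol=1e-9):
        raise ValueError("force and f_hat curves are on different grids")

    def _area(x, y):
        sel = x <= upper + 1e-9
        return float(-np.trapezoid(np.minimum(y[sel], 0.0), x[sel]))

    area_f = _area(xf, yf)
    area_fhat = _area(xh, yh)
    degree = 0.5 * (area_f + area_fhat)
    g = float(getattr(fhatcurve, "g_ij", 0.0))
    return HydrophilicResult(
        degree=degree, area_f=area_f, area_fhat=area_fhat, g_ij=g,
        classification="hydrophilic" if degree > threshold else "hydrophobic",
        threshold=threshold)
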