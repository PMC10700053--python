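"""Nadaraya-Watson kernel regression over the design grid.

Stochastic simulation yields noisy realizations ``y_i`` of the scheme
outputs at sampled designs ``x_i``.  The conditional mean surface is
estimated by the locally weighted average

    m_hat(x) = sum_i y_i * K((x - x_i) / h) / sum_i K((x - x_i) / h)

with a product Gaussian kernel K(u1, .., ud) = prod_d k(u_d),
k(u) = exp(-u^2 / 2) / sqrt(2 pi), and per-dimension bandwidths h.
Genetic gain and inbreeding are smoothed separately — the inbreeding
response uses bandwidths divided by 3 by convention, because kinship
changes sharply at high selection intensity (small x3) — and the
composite target surface is composed afterwards as g_hat - w * f_hat.

Smoothing operates over the two free dimensions (x2, x3) by default
(x1 is budget-determined and collinear with x2); ``nw_estimate``
accepts any dimension count.

Grid points whose total kernel weight mass falls below a configurable
floor (relative to the mass expected under uniform sampling) are
flagged missing instead of extrapolated: estimates far outside the
sampled box are dominated by a handful of distant points and are not
trustworthy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .simulator import TargetSpec

__all__ = [
    "GAUSS_NORM",
    "gaussian_kernel",
    "SampleSet",
    "Surface",
    "SurfaceBundle",
    "nw_estimate",
    "smooth_surface",
    "smooth_records",
    "linear_baseline_surface",
    "cv_bandwidth",
]

GAUSS_NORM = 1.0 / math.sqrt(2.0 * math.pi)


def gaussian_kernel(u):
    """Standard Gaussian kernel k(u) = exp(-u^2/2) / sqrt(2 pi)."""
    u = np.asarray(u, dtype=float)
    out = GAUSS_NORM * np.exp(-0.5 * u * u)
    return out if out.shape else float(out)


@dataclass
class SampleSet:
    """Sample locations (n, d) paired with one response realization each."""

    points: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        if self.points.shape[0] != self.y.shape[0]:
            raise ValueError("points and responses must have equal length")
        if not (np.isfinite(self.points).all() and np.isfinite(self.y).all()):
            raise ValueError("sample coordinates and responses must be finite")

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class Surface:
    """Smoothed estimates on a rectangular (x2, x3) grid.

    ``estimate``, ``weight_mass`` and ``missing`` are (len(x2), len(x3))
    arrays; missing cells hold NaN estimates.
    """

    x2: np.ndarray
    x3: np.ndarray
    estimate: np.ndarray
    weight_mass: np.ndarray
    missing: np.ndarray

    def at(self, x2: float, x3: float) -> float:
        i = int(np.searchsorted(self.x2, x2))
        j = int(np.searchsorted(self.x3, x3))
        if i >= len(self.x2) or self.x2[i] != x2 or j >= len(self.x3) or self.x3[j] != x3:
            raise KeyError(f"({x2}, {x3}) is not a grid point")
        return float(self.estimate[i, j])

    def to_frame(self) -> pd.DataFrame:
        g2, g3 = np.meshgrid(self.x2, self.x3, indexing="ij")
        return pd.DataFrame(
            {
                "x2": g2.ravel().astype(int),
                "x3": g3.ravel().astype(int),
                "estimate": self.estimate.ravel(),
                "weight_mass": self.weight_mass.ravel(),
                "missing": self.missing.ravel(),
            }
        )


@dataclass
class SurfaceBundle:
    """Separately smoothed gain and inbreeding surfaces plus the composite."""

    g: Surface
    f: Surface
    m: Surface

    def to_frame(self) -> pd.DataFrame:
        df = self.g.to_frame().rename(columns={"estimate": "g_hat"})
        df["f_hat"] = self.f.estimate.ravel()
        df["m_hat"] = self.m.estimate.ravel()
        df["missing"] = self.m.missing.ravel()
        return df[["x2", "x3", "g_hat", "f_hat", "m_hat", "weight_mass", "missing"]]


def nw_estimate(
    query,
    samples: SampleSet,
    h: Sequence[float],
    mass_floor: float = 0.0,
) -> tuple[float, float, bool]:
    """Kernel-weighted average at a single query point.

    Returns ``(estimate, weight_mass, missing)``; the estimate is NaN
    (and ``missing`` True) when the total kernel mass is zero or falls
    below ``mass_floor``.
    """
    if len(samples) == 0:
        raise ValueError("at least one sample is required")
    h = np.asarray(h, dtype=float)
    if (h <= 0).any():
        raise ValueError("bandwidths must be strictly positive")
    q = np.asarray(query, dtype=float)
    u = (q[None, :] - samples.points) / h[None, :]
    logw = -0.5 * (u * u).sum(axis=1)
    w = (GAUSS_NORM ** len(h)) * np.exp(logw)
    mass = float(w.sum())
    if mass <= 0.0 or mass < mass_floor:
        return (float("nan"), mass, True)
    return (float(w @ samples.y) / mass, mass, False)


def _expected_uniform_mass(samples: SampleSet, h: np.ndarray) -> float:
    """Kernel mass a query would collect were samples uniform over their box."""
    spans = samples.points.max(axis=0) - samples.points.min(axis=0)
    spans = np.maximum(spans, h)  # degenerate dimensions contribute ~full mass
    return len(samples) * float(np.prod(h / spans))


def _axis_weights(grid_vals: np.ndarray, sample_vals: np.ndarray, h: float) -> np.ndarray:
    u = (grid_vals[:, None] - sample_vals[None, :]) / h
    return GAUSS_NORM * np.exp(-0.5 * u * u)


def smooth_surface(
    samples: SampleSet,
    grid_axes: tuple[np.ndarray, np.ndarray],
    h: Sequence[float],
    mass_floor_rel: float = 1e-3,
) -> Surface:
    """Nadaraya-Watson estimates over a full rectangular (x2, x3) grid.

    Exploits the product-kernel separability: sample responses are
    accumulated per unique coordinate on each axis and the grid
    numerator/denominator become two small matrix products, so cost is
    linear rather than grid-size x sample-size.  Identical (to floating
    point reordering) to calling :func:`nw_estimate` per grid point.
    """
    ax2 = np.asarray(grid_axes[0], dtype=float)
    ax3 = np.asarray(grid_axes[1], dtype=float)
    if ax2.size == 0 or ax3.size == 0:
        raise ValueError("grid must be nonempty")
    if samples.points.shape[1] != 2:
        raise ValueError("smooth_surface operates on the 2-D (x2, x3) plane")
    h = np.asarray(h, dtype=float)
    if h.shape != (2,) or (h <= 0).any():
        raise ValueError("need two strictly positive bandwidths")

    u2, inv2 = np.unique(samples.points[:, 0], return_inverse=True)
    u3, inv3 = np.unique(samples.points[:, 1], return_inverse=True)
    sum_y = np.zeros((u2.size, u3.size))
    count = np.zeros((u2.size, u3.size))
    np.add.at(sum_y, (inv2, inv3), samples.y)
    np.add.at(count, (inv2, inv3), 1.0)

    k2 = _axis_weights(ax2, u2, h[0])
    k3 = _axis_weights(ax3, u3, h[1])
    num = k2 @ sum_y @ k3.T
    mass = k2 @ count @ k3.T

    floor = mass_floor_rel * _expected_uniform_mass(samples, h)
    missing = (mass <= 0.0) | (mass < floor)
    est = np.full(mass.shape, np.nan)
    np.divide(num, mass, out=est, where=~missing)
    return Surface(x2=ax2, x3=ax3, estimate=est, weight_mass=mass, missing=missing)


def smooth_records(
    records: pd.DataFrame,
    grid_axes: tuple[np.ndarray, np.ndarray],
    h_g: Sequence[float] = (30.0, 1.0),
    f_divisor: float = 3.0,
    target: TargetSpec | None = None,
    compose: bool = True,
    mass_floor_rel: float = 1e-3,
) -> SurfaceBundle:
    """Smooth g and f from simulation records and build the target surface.

    With ``compose`` (default) the composite surface is
    ``g_hat - w * f_hat`` from the two separately smoothed responses —
    the only coherent combination when g and f use different
    bandwidths.  With ``compose=False`` the per-record ``m``
    realizations are smoothed directly with the g bandwidths.
    """
    target = target or TargetSpec()
    pts = records[["x2", "x3"]].to_numpy(dtype=float)
    h_g = np.asarray(h_g, dtype=float)
    h_f = h_g / float(f_divisor)
    sg = smooth_surface(SampleSet(pts, records["g"].to_numpy()), grid_axes, h_g, mass_floor_rel)
    sf = smooth_surface(SampleSet(pts, records["f"].to_numpy()), grid_axes, h_f, mass_floor_rel)
    if compose:
        missing = sg.missing | sf.missing
        est = sg.estimate - target.inbreeding_weight * sf.estimate
        est = np.where(missing, np.nan, est)
        sm = Surface(sg.x2, sg.x3, est, sg.weight_mass, missing)
    else:
        if "m" not in records:
            raise ValueError("direct smoothing of m requires an m column")
        sm = smooth_surface(
            SampleSet(pts, records["m"].to_numpy()), grid_axes, h_g, mass_floor_rel
        )
    return SurfaceBundle(g=sg, f=sf, m=sm)


def linear_baseline_surface(
    samples: SampleSet,
    grid_axes: tuple[np.ndarray, np.ndarray],
) -> Surface:
    """Piecewise-linear interpolation baseline on a Delaunay triangulation.

    Duplicate sample locations are pre-averaged (a triangulation needs
    one value per vertex); grid points outside the convex hull are
    flagged missing.  Raises on degenerate geometry (fewer than three
    distinct non-collinear locations).
    """
    from scipy.interpolate import griddata
    from scipy.spatial import QhullError

    if samples.points.shape[1] != 2:
        raise ValueError("baseline operates on the 2-D (x2, x3) plane")
    df = pd.DataFrame(
        {"a": samples.points[:, 0], "b": samples.points[:, 1], "y": samples.y}
    )
    agg = df.groupby(["a", "b"], as_index=False)["y"].mean()
    pts = agg[["a", "b"]].to_numpy()
    vals = agg["y"].to_numpy()
    if len(pts) < 3:
        raise ValueError("degenerate geometry: need >= 3 distinct sample locations")
    ax2 = np.asarray(grid_axes[0], dtype=float)
    ax3 = np.asarray(grid_axes[1], dtype=float)
    g2, g3 = np.meshgrid(ax2, ax3, indexing="ij")
    try:
        est = griddata(pts, vals, (g2, g3), method="linear")
    except QhullError as exc:  # collinear locations
        raise ValueError(f"degenerate geometry for triangulation: {exc}") from exc
    missing = ~np.isfinite(est)
    if missing.all():
        raise ValueError("degenerate geometry: triangulation covers no grid point")
    mass = (~missing).astype(float)
    return Surface(x2=ax2, x3=ax3, estimate=est, weight_mass=mass, missing=missing)


def cv_bandwidth(
    samples: SampleSet,
    candidates: Sequence[Sequence[float]],
    k: int = 10,
    loo_max_n: int = 300,
    seed: int = 0,
) -> tuple[float, ...]:
    """Pick the candidate bandwidth minimizing cross-validated error.

    Leave-one-out below ``loo_max_n`` samples, seeded k-fold above (to
    bound cost).  Ties keep the earliest candidate.
    """
    if not candidates:
        raise ValueError("candidate list must be nonempty")
    n = len(samples)
    if n < 10:
        raise ValueError("cross-validation needs at least 10 samples")
    if len(candidates) == 1:
        return tuple(float(v) for v in candidates[0])

    if n <= loo_max_n:
        fold_of = np.arange(n)
        n_folds = n
    else:
        rng = np.random.default_rng(seed)
        fold_of = rng.permuted(np.arange(n) % k)
        n_folds = k

    best: tuple[float, ...] | None = None
    best_err = math.inf
    for cand in candidates:
        h = np.asarray(cand, dtype=float)
        if (h <= 0).any():
            raise ValueError("bandwidths must be strictly positive")
        sq_err = 0.0
        n_pred = 0
        for fold in range(n_folds):
            test = fold_of == fold
            train = ~test
            u = (samples.points[test][:, None, :] - samples.points[train][None, :, :]) / h
            w = np.exp(-0.5 * (u * u).sum(axis=2))
            mass = w.sum(axis=1)
            ok = mass > 0
            if not ok.any():
                continue
            pred = (w[ok] @ samples.y[train]) / mass[ok]
            sq_err += float(((pred - samples.y[test][ok]) ** 2).sum())
            n_pred += int(ok.sum())
        err = sq_err / n_pred if n_pred else math.inf
        if err < best_err:
            best_err = err
            best = tuple(float(v) for v in h)
    assert best is not None
    return best
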