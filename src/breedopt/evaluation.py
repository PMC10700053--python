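"""Meta-analyses of the smoothing-and-optimization pipeline.

Two questions are addressed, both answerable without the full breeding
simulator thanks to a synthetic objective with a known optimum:

* **Method comparison** — bootstrap subsamples of a record pool are
  smoothed by competing methods (kernel regression vs. the plain
  linear-interpolation baseline); each method's suggested optimum is
  scored on a reference surface built from the full pool, by its target
  value there and by its Euclidean distance from the full-pool optimum.
* **Simulation-budget stability** — how tightly the estimated optimum
  concentrates as the number of simulations grows, summarized by the
  fraction of repeated-run optima landing in a reference region and by
  a kernel-density map of optimum locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .search_space import (
    BudgetModel,
    ParameterBounds,
    Parametrization,
    sample_parametrizations,
)
from .simulator import RECORD_COLUMNS, TargetSpec, replicate_seed
from .smoothing import (
    SampleSet,
    Surface,
    linear_baseline_surface,
    smooth_records,
)
from .optimizer import brute_force_argmax

__all__ = [
    "SyntheticObjective",
    "generate_synthetic_records",
    "ComparisonResult",
    "bootstrap_compare",
    "StabilityResult",
    "optimum_stability",
    "nw_smoother",
    "linear_smoother",
    "product_kde",
]

Smoother = Callable[[pd.DataFrame, tuple[np.ndarray, np.ndarray]], Surface]


@dataclass(frozen=True)
class SyntheticObjective:
    """Analytic stand-in for the breeding simulator.

    ``true_g`` and ``true_f`` are vectorized functions of (x2, x3);
    realizations add independent Gaussian noise (f clipped at 0).  The
    location of the composite maximum is known, which makes optimum
    recovery, method ranking and stability measurable exactly.
    """

    true_g: Callable
    true_f: Callable
    argmax: tuple[int, int]
    noise_sd_g: float = 1.0
    noise_sd_f: float = 0.005
    target: TargetSpec = TargetSpec()

    def __post_init__(self) -> None:
        if self.noise_sd_g < 0 or self.noise_sd_f < 0:
            raise ValueError("noise scales must be >= 0")

    def true_m(self, x2, x3):
        return self.true_g(x2, x3) - self.target.inbreeding_weight * self.true_f(x2, x3)

    def evaluate(self, params: Sequence[Parametrization], seed: int) -> pd.DataFrame:
        return generate_synthetic_records_at(self, params, seed)

    @classmethod
    def quadratic(
        cls,
        center: tuple[int, int] = (400, 15),
        curvature: tuple[float, float] = (0.005, 1.0),
        peak: float = 10.0,
        f_base: float = 0.01,
        f_scale: float = 0.05,
        noise_sd_g: float = 1.0,
        noise_sd_f: float = 0.005,
        inbreeding_weight: float = 50.0,
    ) -> "SyntheticObjective":
        """Concave-paraboloid composite target with a hyperbolic f profile.

        m*(x2, x3) = peak - a (x2 - c2)^2 - b (x3 - c3)^2; the
        inbreeding component decays with the number of selected sires
        (f = f_base + f_scale / x3, echoing slower kinship accumulation
        with more sires) and the gain component is defined as
        m* + w f so the composite argmax sits exactly at ``center``.
        """
        a, b = curvature
        c2, c3 = center
        w = inbreeding_weight

        def true_f(x2, x3):
            x3 = np.asarray(x3, dtype=float)
            return f_base + f_scale / np.maximum(x3, 1.0)

        def true_g(x2, x3):
            x2 = np.asarray(x2, dtype=float)
            x3 = np.asarray(x3, dtype=float)
            m = peak - a * (x2 - c2) ** 2 - b * (x3 - c3) ** 2
            return m + w * true_f(x2, x3)

        return cls(
            true_g=true_g,
            true_f=true_f,
            argmax=center,
            noise_sd_g=noise_sd_g,
            noise_sd_f=noise_sd_f,
            target=TargetSpec(inbreeding_weight=w),
        )

    @classmethod
    def three_peak(
        cls,
        centers: Sequence[tuple[float, float]] = ((200, 10), (400, 15), (600, 22)),
        heights: Sequence[float] = (8.0, 10.0, 7.0),
        widths: tuple[float, float] = (60.0, 3.0),
        noise_sd_g: float = 0.5,
        noise_sd_f: float = 0.0,
    ) -> "SyntheticObjective":
        """Sum of Gaussian bumps; argmax at the highest bump's center."""
        w2, w3 = widths
        best = centers[int(np.argmax(heights))]

        def true_g(x2, x3):
            x2 = np.asarray(x2, dtype=float)
            x3 = np.asarray(x3, dtype=float)
            out = np.zeros(np.broadcast(x2, x3).shape)
            for (c2, c3), hgt in zip(centers, heights):
                out = out + hgt * np.exp(
                    -0.5 * (((x2 - c2) / w2) ** 2 + ((x3 - c3) / w3) ** 2)
                )
            return out

        def true_f(x2, x3):
            return np.zeros(np.broadcast(np.asarray(x2), np.asarray(x3)).shape)

        return cls(
            true_g=true_g,
            true_f=true_f,
            argmax=(int(best[0]), int(best[1])),
            noise_sd_g=noise_sd_g,
            noise_sd_f=noise_sd_f,
        )


def generate_synthetic_records_at(
    obj: SyntheticObjective, params: Sequence[Parametrization], seed: int
) -> pd.DataFrame:
    """Noisy realizations of the synthetic objective at given designs."""
    rng = np.random.default_rng(seed)
    x1 = np.array([p.x1 for p in params])
    x2 = np.array([p.x2 for p in params])
    x3 = np.array([p.x3 for p in params])
    g = obj.true_g(x2, x3) + obj.noise_sd_g * rng.standard_normal(len(params))
    f = obj.true_f(x2, x3) + obj.noise_sd_f * rng.standard_normal(len(params))
    f = np.maximum(f, 0.0)
    m = g - obj.target.inbreeding_weight * f
    return pd.DataFrame(
        {
            "replicate_id": np.arange(len(params)),
            "seed": np.full(len(params), seed, dtype=np.int64),
            "x1": x1,
            "x2": x2,
            "x3": x3,
            "g": g,
            "f": f,
            "m": m,
        }
    )[RECORD_COLUMNS]


def generate_synthetic_records(
    obj: SyntheticObjective,
    n: int,
    bounds: ParameterBounds | None = None,
    budget: BudgetModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample ``n`` designs uniformly and realize the synthetic objective."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    s_sample, s_noise = (int(v % 2**31) for v in ss.generate_state(2))
    params = sample_parametrizations(n, bounds, budget, seed=s_sample)
    return generate_synthetic_records_at(obj, params, s_noise)


def nw_smoother(
    h_g: tuple[float, float] = (30.0, 1.0),
    f_divisor: float = 3.0,
    target: TargetSpec | None = None,
    compose: bool = True,
) -> Smoother:
    """Composite-surface smoother based on kernel regression."""
    target = target or TargetSpec()

    def smoother(records: pd.DataFrame, grid_axes) -> Surface:
        return smooth_records(
            records, grid_axes, h_g=h_g, f_divisor=f_divisor, target=target,
            compose=compose,
        ).m

    return smoother


def linear_smoother(target: TargetSpec | None = None) -> Smoother:
    """Composite-surface baseline via linear interpolation of m realizations."""
    target = target or TargetSpec()

    def smoother(records: pd.DataFrame, grid_axes) -> Surface:
        m = records["g"].to_numpy() - target.inbreeding_weight * records["f"].to_numpy()
        return linear_baseline_surface(
            SampleSet(records[["x2", "x3"]].to_numpy(dtype=float), m), grid_axes
        )

    return smoother


@dataclass
class ComparisonResult:
    """Bootstrap comparison of smoothing methods on shared draws."""

    replicates: dict[str, pd.DataFrame]
    mean_value: dict[str, float]
    mean_distance: dict[str, float]
    failures: dict[str, int]
    reference_optimum: tuple[int, int]
    reference_value: float


def bootstrap_compare(
    records: pd.DataFrame,
    methods: Mapping[str, Smoother],
    n_boot: int,
    subsample_size: int,
    seed: int = 0,
    grid_axes: tuple[np.ndarray, np.ndarray] | None = None,
    reference: Smoother | None = None,
) -> ComparisonResult:
    """Score each smoothing method's suggested optima across bootstrap draws.

    Each draw (with replacement; a full-size draw uses the pool
    verbatim) is smoothed by every method; the method's argmax is then
    evaluated on the reference surface built from the complete pool
    (kernel regression by default), yielding a target value and a
    Euclidean (x2, x3) distance to the full-pool optimum.  Method
    failures on a draw are excluded and counted.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n = len(records)
    if subsample_size > n:
        raise ValueError("subsample_size exceeds the record pool")
    if grid_axes is None:
        grid_axes = SearchAxesDefault()
    reference = reference or nw_smoother()
    # canonical row order makes every metric invariant to input ordering
    records = records.sort_values(
        [c for c in RECORD_COLUMNS if c in records.columns]
    ).reset_index(drop=True)
    ref_surface = reference(records, grid_axes)
    ref_opt, ref_val = brute_force_argmax(ref_surface)

    rng = np.random.default_rng(seed)
    rows: dict[str, list[tuple[int, float, float]]] = {name: [] for name in methods}
    failures = {name: 0 for name in methods}
    for b in range(n_boot):
        if subsample_size == n:
            draw = records
        else:
            idx = rng.integers(0, n, subsample_size)
            draw = records.iloc[idx].reset_index(drop=True)
        for name, method in methods.items():
            try:
                opt, _ = brute_force_argmax(method(draw, grid_axes))
            except Exception:
                failures[name] += 1
                continue
            value = ref_surface.at(*opt)
            dist = float(np.hypot(opt[0] - ref_opt[0], opt[1] - ref_opt[1]))
            rows[name].append((b, value, dist))

    replicates = {
        name: pd.DataFrame(v, columns=["draw", "value", "distance"])
        for name, v in rows.items()
    }
    return ComparisonResult(
        replicates=replicates,
        mean_value={k: float(df["value"].mean()) for k, df in replicates.items()},
        mean_distance={k: float(df["distance"].mean()) for k, df in replicates.items()},
        failures=failures,
        reference_optimum=ref_opt,
        reference_value=ref_val,
    )


def SearchAxesDefault() -> tuple[np.ndarray, np.ndarray]:
    b = ParameterBounds()
    return (
        np.arange(b.x2_min, b.x2_max + 1, dtype=float),
        np.arange(b.x3_min, b.x3_max + 1, dtype=float),
    )


def product_kde(
    points: np.ndarray,
    grid_axes: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """2-D product-Gaussian density of optimum locations on a grid.

    Bandwidths follow Scott's plug-in rule, h_d = sd_d * n^(-1/6)
    (floored at one grid step for degenerate spreads).
    """
    from .smoothing import gaussian_kernel

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    ax2 = np.asarray(grid_axes[0], dtype=float)
    ax3 = np.asarray(grid_axes[1], dtype=float)
    h = pts.std(axis=0, ddof=1) * n ** (-1.0 / 6.0) if n > 1 else np.ones(2)
    h = np.maximum(h, 1.0)
    k2 = gaussian_kernel((ax2[:, None] - pts[None, :, 0]) / h[0])
    k3 = gaussian_kernel((ax3[:, None] - pts[None, :, 1]) / h[1])
    return (k2 @ k3.T) / (n * h[0] * h[1])


@dataclass
class StabilityResult:
    """Optimum-location spread as a function of simulation count."""

    optima: dict[int, np.ndarray]
    fraction_in_region: dict[int, float]
    region: tuple[int, int, int, int]
    density: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    grid_axes: tuple[np.ndarray, np.ndarray] | None = None


def optimum_stability(
    source,
    sizes: Sequence[int],
    n_rep: int,
    region: tuple[int, int, int, int],
    seed: int = 0,
    *,
    bounds: ParameterBounds | None = None,
    budget: BudgetModel | None = None,
    grid_axes: tuple[np.ndarray, np.ndarray] | None = None,
    smoother: Smoother | None = None,
    mode: str | None = None,
) -> StabilityResult:
    """Repeat smooth-and-argmax at several simulation counts.

    ``source`` is either a :class:`SyntheticObjective` (fresh record
    sets per repetition, ``mode='fresh'``) or a record pool DataFrame
    (subsampling without replacement, ``mode='subsample'``).  Returns
    all optima, per-size fractions inside ``region``
    ((x2_lo, x2_hi, x3_lo, x3_hi), inclusive) and a product-Gaussian
    KDE of optimum locations per size.
    """
    if min(sizes) < 1 or n_rep < 1:
        raise ValueError("sizes and n_rep must be positive")
    bounds = bounds or ParameterBounds()
    if grid_axes is None:
        grid_axes = (
            np.arange(bounds.x2_min, bounds.x2_max + 1, dtype=float),
            np.arange(bounds.x3_min, bounds.x3_max + 1, dtype=float),
        )
    smoother = smoother or nw_smoother()
    if mode is None:
        mode = "subsample" if isinstance(source, pd.DataFrame) else "fresh"
    if mode == "subsample" and not isinstance(source, pd.DataFrame):
        raise ValueError("subsample mode requires a record pool DataFrame")

    x2_lo, x2_hi, x3_lo, x3_hi = region
    optima: dict[int, np.ndarray] = {}
    frac: dict[int, float] = {}
    density: dict[int, np.ndarray] = {}
    for size in sizes:
        pts = np.empty((n_rep, 2))
        for r in range(n_rep):
            s = replicate_seed(seed, size * 100_003 + r)
            if mode == "fresh":
                recs = generate_synthetic_records(source, size, bounds, budget, seed=s)
            else:
                if size > len(source):
                    raise ValueError(f"size {size} exceeds the record pool")
                rng = np.random.default_rng(s)
                idx = rng.choice(len(source), size=size, replace=False)
                recs = source.iloc[idx].reset_index(drop=True)
            opt, _ = brute_force_argmax(smoother(recs, grid_axes))
            pts[r] = opt
        optima[size] = pts
        inside = (
            (pts[:, 0] >= x2_lo)
            & (pts[:, 0] <= x2_hi)
            & (pts[:, 1] >= x3_lo)
            & (pts[:, 1] <= x3_hi)
        )
        frac[size] = float(inside.mean())
        density[size] = product_kde(pts, grid_axes)
    return StabilityResult(
        optima=optima,
        fraction_in_region=frac,
        region=region,
        density=density,
        grid_axes=grid_axes,
    )
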