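"""Stochastic simulation of a closed progeny-testing dairy scheme.

The scheme runs in discrete yearly cycles under the infinitesimal model
of quantitative genetics:

1. the current ``x3`` selected sires are mated to randomly chosen
   breeding-age dams, producing ``x2`` candidate bulls and a cohort of
   replacement heifers;
2. each candidate bull receives ``floor(x1 / x2)`` test daughters whose
   mean phenotype yields his estimated breeding value (EBV) via the
   standard progeny-test accuracy formula;
3. the ``x3`` highest-EBV candidates are truncation-selected as the
   next year's sires (ties broken by lower animal id);
4. each year the newborn cohort's mean true breeding value and mean
   pairwise pedigree kinship are recorded.

The two scheme outputs after the final year are the genetic gain ``g``
(newborn-cohort mean true BV minus the founder mean, in units of the
initial genetic standard deviation) and the inbreeding level ``f``
(mean pairwise kinship among the newborn cohort — the expected
inbreeding coefficient of their hypothetical offspring).  A scalar
composite target ``m = g - w * f`` (default weight ``w = 50``) trades
genetic gain against diversity loss.

Test daughters are not simulated as individuals: they live in
commercial herds and only inform the sires' EBV accuracy.  The nucleus
cow herd (``founder_cows``, default the allocated ``x1``) is what the
pedigree tracks.  Kinship is propagated with the tabular method over
the live population only, which keeps memory linear in herd size while
remaining exact: an ancestor's kinship contributions are fully embedded
in its descendants' rows once it has no further offspring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .search_space import BudgetModel, InfeasibleError, Parametrization

__all__ = [
    "SchemeConfig",
    "TargetSpec",
    "AnimalRecord",
    "SimOutcome",
    "mendelian_sample",
    "progeny_accuracy",
    "progeny_test_ebv",
    "pedigree_kinship",
    "simulate_scheme",
    "simulate_records",
    "replicate_seed",
    "SimulatorObjective",
    "RECORD_COLUMNS",
]

RECORD_COLUMNS = ["replicate_id", "seed", "x1", "x2", "x3", "g", "f", "m"]


@dataclass(frozen=True)
class SchemeConfig:
    """Parameters of the yearly progeny-testing cycle.

    ``founder_cows`` is the nucleus herd size; it defaults to the
    allocated number of test daughters ``x1`` but may be set smaller to
    run the scheme at reduced scale.  ``founder_bulls`` defaults to
    ``x2``.  Cows breed from ``breeding_age_min`` (default 2) up to
    ``breeding_age_max`` (default 5, i.e. four breeding seasons), after
    which they are culled; the herd is additionally capped at its
    founding size by culling the oldest cows first.
    """

    years: int = 15
    heritability: float = 0.3
    additive_variance: float = 1.0
    founder_cows: int | None = None
    founder_bulls: int | None = None
    dam_replacement_fraction: float = 0.25
    breeding_age_min: int = 2
    breeding_age_max: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.heritability <= 1.0):
            raise ValueError("heritability must be in (0, 1]")
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.additive_variance < 0:
            raise ValueError("additive_variance must be >= 0")
        if not (0.0 < self.dam_replacement_fraction <= 1.0):
            raise ValueError("dam_replacement_fraction must be in (0, 1]")
        for name in ("founder_cows", "founder_bulls"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TargetSpec:
    """Composite breeding goal ``m = sum_t w_t * g_t - w_f * f``.

    By default all gain weight sits on the final year, giving the
    classical ``m = g - w_f * f``.  ``horizon_weights`` maps year
    (1-based) to a non-negative weight for multi-horizon goals.
    """

    inbreeding_weight: float = 50.0
    horizon_weights: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.inbreeding_weight < 0:
            raise ValueError("inbreeding_weight must be >= 0")
        if self.horizon_weights is not None:
            w = list(self.horizon_weights.values())
            if any(v < 0 for v in w) or not any(v > 0 for v in w):
                raise ValueError(
                    "horizon weights must be non-negative with at least one positive"
                )


@dataclass(frozen=True)
class AnimalRecord:
    """One pedigree entry; founders have ``sire_id = dam_id = None``."""

    id: int
    sire_id: int | None
    dam_id: int | None
    sex: str
    birth_year: int
    true_bv: float
    ebv: float | None = None
    inbreeding_coeff: float = 0.0


@dataclass
class SimOutcome:
    """One stochastic realization of the scheme."""

    g: float
    f: float
    m: float
    per_year_g: np.ndarray
    per_year_f: np.ndarray
    final_cohort_ids: list[int] = field(default_factory=list)
    pedigree: list[AnimalRecord] | None = None


def composite_target(outcome: SimOutcome, spec: TargetSpec | None = None) -> float:
    """Evaluate the composite goal for one realization."""
    spec = spec or TargetSpec()
    if spec.horizon_weights is None:
        gain = outcome.g
    else:
        gain = 0.0
        for year, w in spec.horizon_weights.items():
            if not (1 <= year <= len(outcome.per_year_g)):
                raise ValueError(f"horizon year {year} outside simulated range")
            gain += w * float(outcome.per_year_g[year - 1])
    return gain - spec.inbreeding_weight * outcome.f


def mendelian_sample(
    bv_sire,
    bv_dam,
    F_sire,
    F_dam,
    additive_variance: float,
    rng: np.random.Generator,
):
    """Offspring true BV: mid-parent plus a Mendelian-sampling deviation.

    The deviation is Normal with variance ``sigma_a^2 / 2`` shrunk by
    the mean parental inbreeding, ``(1 - (F_s + F_d) / 2)``; fully
    inbred parents transmit no segregation variance.
    """
    if additive_variance < 0:
        raise ValueError("additive_variance must be >= 0")
    bv_sire = np.asarray(bv_sire, dtype=float)
    bv_dam = np.asarray(bv_dam, dtype=float)
    F_sire = np.asarray(F_sire, dtype=float)
    F_dam = np.asarray(F_dam, dtype=float)
    var = additive_variance * (1.0 - 0.5 * (F_sire + F_dam)) / 2.0
    dev = rng.standard_normal(np.broadcast(bv_sire, bv_dam).shape) * np.sqrt(
        np.maximum(var, 0.0)
    )
    out = 0.5 * (bv_sire + bv_dam) + dev
    return out if out.shape else float(out)


def progeny_accuracy(n_daughters: int, heritability: float) -> float:
    """Accuracy of a progeny test with ``n`` daughter phenotypes.

    r = sqrt( (n h^2 / 4) / (1 + (n - 1) h^2 / 4) ); 0 daughters give 0,
    a single daughter with h^2 = 1 gives the classical 0.5, and the
    accuracy tends to 1 as the daughter group grows.
    """
    if n_daughters < 0:
        raise ValueError("n_daughters must be >= 0")
    if n_daughters == 0:
        return 0.0
    q = heritability / 4.0
    return math.sqrt(n_daughters * q / (1.0 + (n_daughters - 1) * q))


def progeny_test_ebv(
    true_bv,
    n_daughters: int,
    heritability: float,
    rng: np.random.Generator,
    genetic_sd: float = 1.0,
):
    """EBV from a daughter group: ``r^2 * bv + r * sqrt(1 - r^2) * sd * z``.

    Built so that corr(EBV, true BV) = r when the candidates' BVs have
    standard deviation ``genetic_sd``.  Returns ``(ebv, r)``.
    """
    r = progeny_accuracy(n_daughters, heritability)
    t = np.asarray(true_bv, dtype=float)
    z = rng.standard_normal(t.shape if t.shape else ())
    ebv = r * r * t + r * math.sqrt(1.0 - r * r) * genetic_sd * z
    return (ebv if np.ndim(ebv) else float(ebv)), r


def _topological_order(pedigree: Sequence[AnimalRecord]) -> list[AnimalRecord]:
    """Kahn's algorithm over parent->offspring edges; raises on cycles."""
    by_id = {a.id: a for a in pedigree}
    if len(by_id) != len(pedigree):
        raise ValueError("duplicate animal ids in pedigree")
    indeg = {a.id: 0 for a in pedigree}
    children: dict[int, list[int]] = {a.id: [] for a in pedigree}
    for a in pedigree:
        for par in (a.sire_id, a.dam_id):
            if par is None:
                continue
            if par not in by_id:
                raise ValueError(f"parent {par} of animal {a.id} not in pedigree")
            indeg[a.id] += 1
            children[par].append(a.id)
    ready = sorted(i for i, d in indeg.items() if d == 0)
    order: list[AnimalRecord] = []
    while ready:
        i = ready.pop(0)
        order.append(by_id[i])
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(order) != len(pedigree):
        raise ValueError("pedigree contains a cycle")
    return order


def pedigree_kinship(
    pedigree: Sequence[AnimalRecord], ids: Iterable[int]
) -> float:
    """Mean pairwise coancestry of a cohort, by the tabular method.

    Builds the full kinship matrix recursively in topological order
    (phi(a, b) = (phi(s_a, b) + phi(d_a, b)) / 2, unknown parents
    contributing 0; phi(a, a) = (1 + phi(s_a, d_a)) / 2) and averages
    over unordered distinct pairs of the cohort.
    """
    order = _topological_order(pedigree)
    pos = {a.id: k for k, a in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for k, a in enumerate(order):
        s = pos[a.sire_id] if a.sire_id is not None else None
        d = pos[a.dam_id] if a.dam_id is not None else None
        row = np.zeros(k)
        if s is not None:
            row += 0.5 * phi[s, :k]
        if d is not None:
            row += 0.5 * phi[d, :k]
        phi[k, :k] = row
        phi[:k, k] = row
        f_self = phi[s, d] if (s is not None and d is not None) else 0.0
        phi[k, k] = 0.5 * (1.0 + f_self)
    cohort = [pos[i] for i in ids]
    if len(cohort) < 2:
        return 0.0
    idx = np.array(cohort)
    sub = phi[np.ix_(idx, idx)]
    m = len(idx)
    return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))


def _select_by_ebv(ebv: np.ndarray, ids: np.ndarray, k: int) -> np.ndarray:
    """Positions of the k highest-EBV candidates, ties to the lower id."""
    order = np.lexsort((ids, -ebv))
    return order[:k]


def simulate_scheme(
    p: Parametrization,
    config: SchemeConfig | None = None,
    seed: int | None = None,
    target: TargetSpec | None = None,
    return_pedigree: bool = False,
) -> SimOutcome:
    """Run one stochastic realization of the scheme for design ``p``.

    Bit-reproducible given ``(p, config, seed)``.  When
    ``return_pedigree`` is set, the full pedigree (every animal ever
    born, with true BV, EBV and inbreeding coefficient) is attached to
    the outcome for external verification.
    """
    config = config or SchemeConfig()
    target = target or TargetSpec()
    if p.x3 > p.x2:
        raise InfeasibleError(f"x3={p.x3} exceeds x2={p.x2}")
    if p.x2 < 1 or p.x3 < 1:
        raise InfeasibleError("x2 and x3 must be >= 1")
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    sigma = math.sqrt(config.additive_variance)
    h2 = config.heritability
    n_cows0 = config.founder_cows if config.founder_cows is not None else p.x1
    n_bulls0 = config.founder_bulls if config.founder_bulls is not None else p.x2
    if n_cows0 < 1 or n_bulls0 < p.x3:
        raise InfeasibleError("founder herd too small for the requested design")
    n_daughters = p.x1 // p.x2
    amin, amax = config.breeding_age_min, config.breeding_age_max

    # --- founders: cows first, then candidate bulls; unrelated, non-inbred
    n0 = n_cows0 + n_bulls0
    bv = rng.normal(0.0, sigma, n0)
    founder_mean = float(bv.mean())
    phi = np.zeros((n0, n0))
    np.fill_diagonal(phi, 0.5)
    ids = np.arange(n0, dtype=np.int64)
    next_id = n0
    # founder cows staggered across the breeding ages so turnover is smooth
    cow_pos = np.arange(n_cows0)
    cow_age = amin + (np.arange(n_cows0) % (amax - amin + 1))
    bull_pos = np.arange(n_cows0, n0)

    pedigree: list[AnimalRecord] | None = None
    if return_pedigree:
        pedigree = [
            AnimalRecord(int(i), None, None, "F" if i < n_cows0 else "M", 0, float(bv[i]))
            for i in range(n0)
        ]

    ebv0, _ = progeny_test_ebv(bv[bull_pos], n_daughters, h2, rng, genetic_sd=sigma)
    ebv0 = np.atleast_1d(ebv0)
    sire_pos = bull_pos[_select_by_ebv(ebv0, ids[bull_pos], p.x3)]
    if pedigree is not None:
        for j, pos_ in enumerate(bull_pos):
            rec = pedigree[pos_]
            pedigree[pos_] = AnimalRecord(
                rec.id, None, None, "M", 0, rec.true_bv, float(ebv0[j]), 0.0
            )

    per_year_g: list[float] = []
    per_year_f: list[float] = []
    final_cohort: list[int] = []

    for year in range(1, config.years + 1):
        dams = cow_pos[(cow_age >= amin) & (cow_age <= amax)]
        if dams.size == 0:
            raise RuntimeError(f"no breeding-age dams available in year {year}")
        n_repl = max(1, round(config.dam_replacement_fraction * cow_pos.size))
        k = p.x2 + n_repl

        s_loc = sire_pos[rng.integers(0, sire_pos.size, k)]
        d_loc = dams[rng.integers(0, dams.size, k)]
        F_off = phi[s_loc, d_loc]
        F_s = 2.0 * phi[s_loc, s_loc] - 1.0
        F_d = 2.0 * phi[d_loc, d_loc] - 1.0
        bv_new = mendelian_sample(bv[s_loc], bv[d_loc], F_s, F_d, config.additive_variance, rng)
        bv_new = np.atleast_1d(bv_new)

        # kinship of newborns vs. live population, then among themselves
        cross = 0.5 * (phi[s_loc] + phi[d_loc])            # (k, n_live)
        nn = 0.5 * (cross[:, s_loc] + cross[:, d_loc])     # (k, k)
        nn[np.diag_indices(k)] = 0.5 * (1.0 + F_off)

        g_year = (float(bv_new.mean()) - founder_mean) / sigma if sigma > 0 else 0.0
        f_year = float((nn.sum() - np.trace(nn)) / (k * (k - 1))) if k > 1 else 0.0
        per_year_g.append(g_year)
        per_year_f.append(f_year)

        new_ids = np.arange(next_id, next_id + k, dtype=np.int64)
        next_id += k
        # first x2 newborns are bull calves, the rest replacement heifers
        bull_slice = np.arange(p.x2)
        heifer_slice = np.arange(p.x2, k)

        ebv_new, _ = progeny_test_ebv(
            bv_new[bull_slice], n_daughters, h2, rng, genetic_sd=sigma
        )
        ebv_new = np.atleast_1d(ebv_new)
        sel = bull_slice[_select_by_ebv(ebv_new, new_ids[bull_slice], p.x3)]

        if pedigree is not None:
            for j in range(k):
                pedigree.append(
                    AnimalRecord(
                        int(new_ids[j]),
                        int(ids[s_loc[j]]),
                        int(ids[d_loc[j]]),
                        "M" if j < p.x2 else "F",
                        year,
                        float(bv_new[j]),
                        float(ebv_new[j]) if j < p.x2 else None,
                        float(F_off[j]),
                    )
                )
        if year == config.years:
            final_cohort = [int(i) for i in new_ids]
            break  # no need to advance state after the last cohort

        # --- herd turnover: age cows, cull old/excess, admit heifers
        cow_age = cow_age + 1
        keep = cow_age <= amax
        kept_cows = cow_pos[keep]
        kept_ages = cow_age[keep]
        # heifers enter at age 1 next year (born this year at age 0)
        new_keep = np.concatenate([heifer_slice, sel])
        n_heifers = heifer_slice.size
        total_cows = kept_cows.size + n_heifers
        if total_cows > n_cows0:
            drop = total_cows - n_cows0
            order = np.argsort(-kept_ages, kind="stable")  # oldest first
            kept_idx = np.sort(order[drop:])
            kept_cows = kept_cows[kept_idx]
            kept_ages = kept_ages[kept_idx]

        old_keep = kept_cows
        n_old = old_keep.size
        n_new = new_keep.size
        n_live = n_old + n_new
        phi_next = np.empty((n_live, n_live))
        phi_next[:n_old, :n_old] = phi[np.ix_(old_keep, old_keep)]
        blk = cross[np.ix_(new_keep, old_keep)]
        phi_next[n_old:, :n_old] = blk
        phi_next[:n_old, n_old:] = blk.T
        phi_next[n_old:, n_old:] = nn[np.ix_(new_keep, new_keep)]
        phi = phi_next
        bv = np.concatenate([bv[old_keep], bv_new[new_keep]])
        ids = np.concatenate([ids[old_keep], new_ids[new_keep]])
        cow_pos = np.concatenate(
            [np.arange(n_old), n_old + np.arange(n_heifers)]
        )
        cow_age = np.concatenate([kept_ages, np.ones(n_heifers, dtype=cow_age.dtype)])
        sire_pos = n_old + n_heifers + np.arange(sel.size)

    outcome = SimOutcome(
        g=per_year_g[-1],
        f=per_year_f[-1],
        m=0.0,
        per_year_g=np.array(per_year_g),
        per_year_f=np.array(per_year_f),
        final_cohort_ids=final_cohort,
        pedigree=pedigree,
    )
    outcome.m = composite_target(outcome, target)
    return outcome


def replicate_seed(global_seed: int, replicate: int) -> int:
    """Stable per-replicate integer seed derived from a global seed."""
    ss = np.random.SeedSequence((int(global_seed), int(replicate)))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_records(
    params: Sequence[Parametrization],
    config: SchemeConfig | None = None,
    global_seed: int = 0,
    target: TargetSpec | None = None,
) -> pd.DataFrame:
    """Simulate each design once; one tidy record per realization."""
    config = config or SchemeConfig()
    target = target or TargetSpec()
    rows = []
    for i, p in enumerate(params):
        s = replicate_seed(global_seed, i)
        out = simulate_scheme(p, config, seed=s, target=target)
        rows.append((i, s, p.x1, p.x2, p.x3, out.g, out.f, out.m))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


@dataclass(frozen=True)
class SimulatorObjective:
    """Adapter exposing the scheme simulator as a stochastic objective."""

    config: SchemeConfig = SchemeConfig()
    target: TargetSpec = TargetSpec()
    budget: BudgetModel = BudgetModel()

    def evaluate(self, params: Sequence[Parametrization], seed: int) -> pd.DataFrame:
        return simulate_records(params, self.config, global_seed=seed, target=self.target)
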