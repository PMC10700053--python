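# Methods

## Design space and budget model

A design is `(x1, x2, x3)`: test daughters, test bulls, selected
sires. The annual budget constraint `c_cow·x1 + c_bull·x2 ≤ B`
(defaults `c_cow = 4,000`, `c_bull = 3,000`, `B = 10,000,000` per
year) omits `x3` deliberately: selected sires are drawn from
already-housed test bulls and add no housing cost. Because more
daughters always mean more accurate progeny tests, any budget not
spent on bulls is spent on daughters; `x1 = ⌊(B − c_bull·x2)/c_cow⌋`
exhausts the budget to within one cow. Sampling draws `x2` and `x3`
discrete-uniform on their inclusive bounds (defaults 100–700 and
3–30) and rejects draws with `x3 > x2`, which preserves uniformity on
the feasible region; grids always use inclusive integer ranges.

## The scheme simulator

The simulator is a deliberately minimal, fully documented yearly
progeny-testing cycle under the infinitesimal model. It is not a
calibrated reproduction of any particular commercial program, and its
absolute `g`/`f` values are properties of this scheme only; the
package's contract is the behaviour of the surrounding
smoothing-and-optimization pipeline, which is independent of scheme
calibration.

* **Genetics.** Founders are unrelated and non-inbred with true
  breeding values `N(0, σ²ₐ)` (default `σ²ₐ = 1`, so gains are in
  initial genetic SD). Offspring BV = mid-parent + Mendelian-sampling
  deviation with variance `σ²ₐ(1 − (F_s + F_d)/2)/2`.
* **Information.** Each candidate bull receives `⌊x1/x2⌋` test
  daughters (remainder discarded); his EBV has the progeny-test
  accuracy `r = √(n h²/4 / (1 + (n−1) h²/4))` (default `h² = 0.3`),
  realized as `r²·BV + r√(1−r²)·σₐ·z`. Test daughters live in
  commercial herds: they inform accuracy but are not simulated as
  individuals and do not enter the pedigree.
* **Population.** The nucleus cow herd (default size: the allocated
  `x1`; configurable smaller for desk-scale runs) breeds from age 2
  through 5; a fraction (default 0.25) of the herd is replaced by
  heifer calves each year, oldest cows culled first so the herd never
  exceeds its founding size. Dams are drawn uniformly at random (the
  decision variables act only on the sire path). Each year the `x3`
  highest-EBV candidate bulls become next year's sires, ties broken by
  lower animal id for determinism.
* **Kinship.** `f` is the mean pairwise coancestry of the newborn
  cohort, propagated exactly by the tabular method over the live
  population only — an ancestor's kinship information is fully
  embedded in its descendants' matrix rows once it stops breeding, so
  memory stays quadratic in herd size, not pedigree size. A standalone
  whole-pedigree implementation exists for verification and matches
  the incremental one to machine precision; both are checked against a
  gene-dropping Monte-Carlo oracle.
* **Reproducibility.** One RNG stream per replicate, seeded by
  hashing `(global_seed, replicate_index)` through numpy's
  `SeedSequence`; runs are bit-reproducible given `(design, config,
  seed)`.

With defaults the scheme yields `g ≈ 4.3` SD and `f ≈ 0.04` after 15
years at the design `(2377, 163, 18)` — plausible magnitudes for a
toy closed nucleus, reported here only as orientation.

## Smoothing

The Nadaraya–Watson estimator uses a product Gaussian kernel
`K(u) = Π_d exp(−u_d²/2)/√(2π)` with per-dimension bandwidths.
Defaults: `h = (30, 1)` over `(x2, x3)` for `g`, divided by 3 for `f`
— the narrower `f` bandwidths avoid bias where kinship changes
sharply at few selected sires. Smoothing operates over the two free
dimensions because `x1` is collinear with `x2`; the pointwise
estimator accepts any dimensionality.

The composite surface is composed **after** smoothing,
`m̂ = ĝ − w·f̂`: with different bandwidths per response this is the
only coherent combination. Direct smoothing of `m` realizations with
the `g` bandwidths is available as an option.

Numerical choices:

* On rectangular integer grids the product kernel separates, so the
  surface is computed as two small matrix products over per-coordinate
  accumulations — algebraically identical to the pointwise estimator
  (verified in tests to 1e-10 relative) but linear instead of
  `grid × samples` cost. This is what makes 100-draw bootstrap
  analyses and multi-seed pipelines desk-scale.
* A grid point whose total kernel mass falls below `10⁻³` of the mass
  expected under uniform sampling is flagged *missing* rather than
  extrapolated; estimates far outside the sampled box rest on a
  handful of distant points and are not trustworthy.
* Duplicate sample locations are kept as separate samples for kernel
  regression (they self-average) but pre-averaged for the
  linear-interpolation baseline, which needs one value per
  triangulation vertex.
* Cross-validated bandwidth selection uses leave-one-out up to 300
  samples and seeded 10-fold above that; ties keep the earliest
  candidate.

The linear baseline (Delaunay triangulation + barycentric
interpolation, `scipy.interpolate.griddata`) exists because it is the
obvious naive alternative: interpolating noisy realizations verbatim
produces a spiky surface whose argmax chases noise. The bootstrap
comparison quantifies this.

## Optimization loop

Per iteration: sample `n_k` designs uniformly in the current box,
simulate, smooth `g` and `f` over the box grid using **all** records
accumulated so far (records outside the box still carry kernel weight
near its boundary and damp edge bias), compose `m̂`, take the
brute-force argmax, detect grid-local maxima (8-neighbourhood), narrow
the box to the smallest rectangle containing the competitive maxima
padded by 50% of its span per side (never less than the current
bandwidth per dimension, so an isolated maximum keeps its unresolved
neighbourhood), and halve the bandwidths. The default simulation
schedule is heavy-first (60,000 / 50,000 / 12,000); tests and the
acceptance script scale it down (e.g. 2,000 / 1,500 / 500).

Open design points resolved as follows:

* **Competitive maxima.** Raw 8-neighbourhood maxima in sparsely
  covered regions are noise ripples; only maxima within 5% of the
  surface range below the global maximum enter box narrowing
  (configurable).
* **Convergence.** The loop stops when the argmax moves at most one
  grid step per dimension between consecutive iterations, or after
  the configured number of iterations.
* **Box rounding.** Padded box edges round outward (floor/ceil), so
  every contributing maximum always stays inside.

## Synthetic objective and evaluation analyses

The synthetic objective stands in for the simulator wherever a known
truth is needed (same `evaluate(params, seed)` interface). The default
is a concave paraboloid composite,
`m*(x2, x3) = 10 − 0.005(x2−400)² − 1.0(x3−15)²`, decomposed into a
hyperbolic inbreeding profile `f* = 0.01 + 0.05/x3` (echoing slower
kinship accumulation with more sires; range ≈ 0.012–0.027) and
`g* = m* + 50·f*`, with Gaussian noise of SD 1.0 on `g` and 0.005 on
`f` (clipped at zero). The curvature-to-noise ratio was fixed once so
that the optimum is genuinely recoverable at the desk-scale simulation
schedule while single realizations remain uninformative (per-step `x3`
signal equals the noise SD); a constructed objective that noise can
never pin down would test nothing. Consequently, passing recovery
tests show the pipeline machinery works under the stated noise model —
they say nothing about how flat or rugged a *real* program's target
surface is, nor about simulator calibration.

* **Bootstrap method comparison** draws subsamples with replacement
  from a record pool (a full-size draw uses the pool verbatim, so the
  trivial self-reference case scores distance zero), smooths each draw
  with every method, and scores each method's argmax on a reference
  surface built from the full pool (kernel regression by default):
  target value at the suggested optimum, and Euclidean `(x2, x3)`
  distance to the reference optimum. The distance is unstandardized;
  a weighted variant is available since the `x2` and `x3` scales
  differ by ~20×. Records are canonically sorted before drawing so
  results are invariant to input ordering.
* **Optimum stability** repeats smooth-and-argmax at several
  simulation counts (fresh synthetic sets, or subsampling a pool
  without replacement) and reports the fraction of optima inside a
  reference region plus a product-Gaussian KDE of optimum locations
  with Scott's-rule bandwidths (`sd · n^(−1/6)`, floored at one grid
  step).

## Problem sizes

Defaults mirror the production-scale setup (60,000-simulation first
iteration, 100×30,000 bootstrap, stability at 1,000–60,000). The test
suite and `scripts/acceptance.py` run everything at desk scale as the
package's own reference configuration: pipeline schedules of
2,000/1,500/500 synthetic realizations over 20 seeds; bootstrap pools
of 5,000 with 50 draws of 2,500; stability at 250/1,000/4,000 with 50
repetitions; scheme-simulator analyses with a 200–500-cow nucleus herd
and 1–15 years, 50–200 replicates. The lattice-separable smoother
makes the synthetic analyses near-instant; the scheme simulator
dominates runtime through its kinship updates (quadratic in herd
size).

## Known limitations

* The simulator omits genomic information, dam-path selection,
  overlapping sire generations, optimum-contribution selection,
  multi-trait goals and economics; `x1` affects nothing but EBV
  accuracy.
* The EBV model applies the founder-variance accuracy formula every
  year, ignoring the Bulmer effect's variance reduction in later
  cohorts; realized accuracies drift slightly below nominal.
* Kernel regression with the wide first-iteration bandwidth is
  biased wherever the target curves strongly (bias ≈ h²·|m''|/2);
  the iterative bandwidth halving removes this near the optimum but
  pointwise surface values from early iterations are systematically
  shrunk toward the local mean.
* Box narrowing is a heuristic; a maximum outside all sampled boxes
  after iteration 1 is unrecoverable by design (no further sampling
  occurs there).
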