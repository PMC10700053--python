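# breedopt

Simulation-based optimization of progeny-testing breeding-program
design. Instead of comparing a handful of hand-picked scenarios,
`breedopt` searches the whole space of feasible designs: it simulates
candidate programs stochastically, smooths the noisy outcomes into an
estimable objective surface by kernel regression, and iteratively
narrows the search onto the most promising region.

## The problem

A closed dairy-type breeding program is described by three integers:

* `x1` — test daughters (females phenotyped to estimate their sires'
  breeding values),
* `x2` — test bulls entering progeny testing each year,
* `x3` — sires truncation-selected from the test bulls.

Housing costs (4,000 per cow-year, 3,000 per bull-year) and an annual
budget of 10,000,000 constrain the design through
`4000·x1 + 3000·x2 ≤ 10,000,000`, with `100 ≤ x2 ≤ 700` and
`3 ≤ x3 ≤ 30`. Since spare budget is always best spent on daughters,
`x1` is determined by `x2`, leaving `(x2, x3)` free.

The breeding goal trades genetic progress against diversity loss:

    m(x) = g(x) − w · f(x),        w = 50 by default,

where `g` is the genetic gain of the newborn cohort after 15 years (in
initial genetic standard deviations) and `f` its mean pairwise
pedigree kinship. A single simulation yields only a noisy realization
`Y` with `E[Y | x] = m(x)`, so `m` is estimated from many simulated
designs by the Nadaraya–Watson kernel regression

    m̂(x) = Σᵢ yᵢ K((x − xᵢ)/h) / Σᵢ K((x − xᵢ)/h),

with a product Gaussian kernel and per-dimension bandwidths
`h = (h₂, h₃) = (30, 1)` for `g` (divided by 3 for `f`). The optimizer
then alternates: sample designs in the current box → simulate → smooth
→ brute-force argmax and local maxima → narrow the box around the
maxima → halve the bandwidths → repeat until the optimum stabilizes.

The package contains:

* `search_space` — budget allocation, feasibility, sampling, grids;
* `simulator` — a stochastic yearly progeny-testing scheme under the
  infinitesimal model with exact pedigree kinship (tabular method);
* `smoothing` — the Nadaraya–Watson estimator, a linear-interpolation
  baseline, and cross-validated bandwidth selection;
* `optimizer` — argmax, grid-local maxima, box narrowing, bandwidth
  schedule, and the full iterative pipeline;
* `evaluation` — bootstrap comparison of smoothing methods and
  optimum-stability-versus-simulation-count analysis, driven by a
  synthetic objective with a known optimum;
* `config` / `io` / `cli` — validated YAML/JSON configuration, CSV
  record persistence, and the `breedopt` command line.

## Worked example

Optimize a noisy synthetic objective whose true maximum sits at
`(x2, x3) = (400, 15)`:

```python
from breedopt import PipelineConfig, run_pipeline
from breedopt.evaluation import SyntheticObjective

objective = SyntheticObjective.quadratic()          # known optimum at (400, 15)
config = PipelineConfig(n_per_iteration=(2000, 1500, 500), max_iterations=3)
report = run_pipeline(objective, config, seed=1)

for it in report.iterations:
    print(f"iter {it.index}: box x2={it.box.x2} x3={it.box.x3} "
          f"h_g={it.h_g} optimum={it.optimum} m_hat={it.optimum_value:.3f}")
print("final:", report.final_optimum, "converged:", report.converged)
```

prints

```
iter 1: box x2=(100, 700) x3=(3, 30) h_g=(30.0, 1.0) optimum=(391, 15) m_hat=4.261
iter 2: box x2=(361, 421) x3=(14, 16) h_g=(15.0, 0.5) optimum=(408, 15) m_hat=8.947
iter 3: box x2=(393, 423) x3=(14, 16) h_g=(7.5, 0.25) optimum=(400, 15) m_hat=9.710
final: Parametrization(x1=2200, x2=400, x3=15) converged: False
```

Iteration 1 surveys the full space with a wide bandwidth and lands near
the optimum; the box narrows around the competitive local maxima, the
bandwidth halves, and by iteration 3 the argmax sits exactly on the
true optimum (the `m̂` values rise across iterations because shrinking
bandwidths remove smoothing bias near the peak). `x1 = 2200` is the
budget-exhausting daughter allocation for `x2 = 400`.

The same loop runs against the real scheme simulator via the CLI:

```sh
breedopt pipeline --config my.yaml --seed 1 --out results/
breedopt simulate --n 500 --seed 2 --out records/
breedopt evaluate --config synthetic.yaml --out eval/
```

Every run writes a `manifest.json` (config digest, seed, versions)
that reproduces its outputs bit-identically.

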