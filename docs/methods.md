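# Methods

## Model and objectives

The data `y_1..y_n` are modelled as independent observations whose
distribution is constant within segments and changes at unknown indices
`τ_1 < ... < τ_k` (segment j contains `y_{τ_{j-1}+1}..y_{τ_j}`). Two loss
families are implemented, both of the form "minus the maximised segment
log-likelihood, dropping data-only terms":

* **Gaussian change in mean**, known variance σ²: pointwise cost
  `γ(y, μ) = (y − μ)² / (2σ²)`; segment cost = RSS about the segment mean
  over 2σ². A term that is linear in segment length and independent of the
  data is dropped — it shifts every segmentation's cost equally and does
  not change the optimum (it does shift `F(t)` by a constant, which is why
  costs from other conventions differ by a data-independent amount).
* **Poisson change in rate**: `γ(y, μ) = μ − y log μ` on `μ ∈ (0, ∞)`;
  segment cost `S − S log(S/m)` for segment sum S and length m, with the
  convention that an all-zero segment costs 0 (the `μ → 0+` limit).

Both satisfy condition **C1** (the segment cost is the minimum over a
shared scalar parameter of a sum of pointwise costs), hence also **C2**
(zero-slack subadditivity across any split), which the two pruning schemes
respectively require. Segment costs are evaluated in O(1) from prefix sums
of `y` and `y²`.

The *penalised* problem minimises total segment cost plus β per
changepoint; the *constrained* problem minimises total cost with exactly k
changepoints for each `k ≤ K`. Minimum segment length is 1 — the
recursions allow `τ = t − 1` — and no option for longer minima is offered,
because the exactness arguments for pruning assume an unrestricted τ.

## Solvers

All six solvers are exact; the pruned ones differ from their unpruned
counterparts only in which candidates they inspect.

* `optimal_partitioning` / `segment_neighbourhood`: the plain O(n²) and
  O(Kn²) recursions.
* `pelt` / `snip`: inequality-based pruning. A candidate is removed the
  step its "cost so far + segment cost to now (+ κ)" exceeds the current
  optimum; under C2 it can never win later. κ defaults to 0 since every
  supported family satisfies C1. The freshly available position t is
  always admitted to the next candidate set: in the penalised rule the
  non-strict inequality admits it automatically (its empty segment costs
  0); the constrained rule is printed with a strict inequality that would
  read as excluding t itself, so t is admitted unconditionally there —
  for earlier candidates strictness only matters at exact cost ties, where
  either choice retains an optimal-cost segmentation (tied *segmentations*
  may differ; costs cannot).
* `fpop` / `pdpa`: functional pruning. Each candidate τ stores its cost
  function of μ in closed coefficient form (Gaussian: a quadratic
  `aμ² + bμ + c` with `a` growing by `1/2σ²` per absorbed point; Poisson:
  `(count, sum, offset)`), plus the interval set where it attains the
  pointwise minimum. Per step: add `γ(y_t, μ)` to every candidate, read
  the optimum off the candidate minima, intersect each optimality set with
  the level set at threshold (current optimum + β, or `C_{k−1,t}` in the
  constrained case), drop candidates with empty sets, and seed the new
  candidate at t on the complement of the level-set union (pruned straight
  away if that complement is empty — possible only on a bounded parameter
  domain, i.e. Poisson).

Tie-breaking is uniform: argmins resolve to the smallest τ (candidates are
kept in insertion order, so the first minimum wins), and interval
boundaries shared by adjacent candidates belong to the smaller τ. Ties are
measure-zero for continuous data; the convention only pins down the output
deterministically.

### Numerical choices

* Gaussian level sets are the roots of a quadratic. A negative
  discriminant means an empty set; an exactly zero discriminant is kept as
  a degenerate single point. No tolerance is injected: a tiny positive
  discriminant produces a near-degenerate interval that the next
  intersection removes naturally.
* Poisson level sets are computed by bisection on each side of the
  minimiser (the function is convex, so each side is monotone), to 1e-10
  relative bracket width, 200 iterations max.
* Candidate sets are unions of closed intervals with ±∞ sentinels;
  intersection is a two-pointer sweep, complement a sort-merge-gaps pass.
* The Gaussian hot loops in `fpop`/`pdpa` use parallel plain-Python lists
  of coefficients rather than the `CandidateCost` objects; the object API
  (`segdp.piecewise`) is the reference implementation, and the test-suite
  replays it step-locked against the production solver.
* Pruned solvers record, per candidate, the last step at which it was
  live (`prune_step`). Because a candidate enters once and never returns,
  stepwise candidate-set inclusion between two solvers is equivalent to an
  elementwise comparison of these arrays — this is what makes the
  dominance verification feasible at n = 10⁴, where storing explicit
  per-step sets for the weakly pruning SNIP would take gigabytes.

## Penalty and noise scale

`β = 2 log n` on a unit-variance scale is the default penalty, the
standard SIC-type choice for a change in mean; `log n` and `3 log n` are
available through the same `"clogn"` syntax. The noise s.d. is estimated
as `median |y_{i+1} − y_i| / (√2 · Φ⁻¹(3/4))`: first differences cancel a
piecewise-constant mean everywhere except at the few changepoints, and
the constant makes the estimator consistent for Gaussian noise. (The
abbreviation MAD is used here in its usual sense of *median* absolute
deviation — of first differences — which is the robust estimator this
literature uses.) The estimate fails loudly when the median absolute
difference is zero, i.e. on signals that are ≥50% locally constant, where
no noise scale is identifiable this way.

## Synthetic data and what the tests show

The generator (`SignalSpec`) draws piecewise-constant Gaussian signals;
its defaults are the benchmark design used for the diagnostics and
recovery checks: n = 100, changepoints at t = 20, 40, 60, 80, means
alternating 0 and 5, σ = 1 (i.e. 5σ shifts), PCG64 generator, replicate r
seeded with `seed + r`. The alternating 0/5 means and unit σ are this
package's choice of a strong-signal design; segment means and σ are
exposed as parameters. The large-n exactness checks scale the same design
up (n = 10⁴, changes every 200 points).

Because the generator produces independent Gaussian noise with exactly
piecewise-constant means, passing tests demonstrate *exactness of the
optimisation* and recovery under the stated conditions — not robustness to
heavy tails, autocorrelation, wavy baselines, or outliers, all of which
real copy-number data exhibit. Exactness claims transfer to real data
(they are properties of the algorithms, not the data); recovery rates and
candidate-count magnitudes do not necessarily.

Brute-force oracles (`brute_force_penalised`, enumeration of all 2^(n−1)
subsets, and `brute_force_constrained`, all k-subsets) are first-class,
size-guarded functions; every solver is tested against them at n = 10,
and the two oracles are tested against each other through the
`min_k [C_{k,n} + βk] = F(n)` identity.

## Problem sizes used in the shipped checks

Enumeration checks use 200 replicates of n = 10 per setting; cross-solver
exactness uses 20 replicates of n = 10⁴ with K = 10; the dominance and
candidate-count experiment uses 1000 replicates of the n = 100 design; the
recovery check uses 500 replicates. The identity check additionally runs
pDPA with K just above the penalised solution's change count (~50 at
n = 10⁴), since the identity minimises over all k.

## Known limitations

* Scalar segment parameters only; the interval machinery does not extend
  to multivariate μ.
* No per-segment length penalties (MDL-style `log(t−s)` terms): they
  break C1, restricting solvers to the inequality-pruned family, and are
  out of scope here.
* No approximate solvers (binary segmentation and relatives) — exactness
  is the point of the package.
* `segment_neighbourhood`/`snip` at n = 10⁴, K = 10 take a few seconds per
  series (they are O(Kn²) worst case in Python/numpy); pDPA and FPOP are
  much faster, consistent with their pruning behaviour.
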