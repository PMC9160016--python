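# Methods

`simplirec` reconstructs 2-simplicial complexes — networks carrying both
pairwise edges and filled three-body triangles — from nothing but a binary
record of spreading dynamics on the unknown structure. This note documents
the models, the estimator, the numerical choices, and what the synthetic
benchmarks do and do not establish.

## The structure and the dynamics

A 2-simplicial complex on `N` nodes is a set of edges (1-simplexes) and
triangles (2-simplexes) satisfying closure: every triangle's three edges
belong to the complex. Its density is summarized by the mean two-body degree
`k1 = 2|E|/N` and mean three-body degree `k2 = 3|T|/N`.

Two binary dynamics produce the `T x N` state matrix `S`:

**Simplicial contagion (SIS with reinforcement).** Nodes are susceptible (0)
or infected (1). A susceptible node `i` with `a` infected neighbors and `b`
incident triangles whose two other members are both infected becomes
infected with probability `1 - (1-beta1)^a (1-beta2)^b`; each channel acts
independently. Infected nodes recover with probability `mu`. The channel
rates are parameterized as `beta1 = alpha/k1`, `beta2 = omega/k2` with the
realized degrees of the simulated complex, which keeps the dynamics near
threshold across densities; a rate above 1 (e.g. `omega=2.4`, `k2=2`)
saturates at probability 1, since a Bernoulli draw against a super-unity
rate is certain. Updates are synchronous: infection and recovery are both
evaluated from the time-`t` snapshot, so a node infected this step cannot
recover within it, and a recovering node cannot be re-infected within it.
(The alternative — letting just-recovered nodes be re-exposed in the same
step — was evaluated and rejected: it drives prevalence above 0.9 at the
benchmark parameters, and the near-constant states carry too little
information for reconstruction.)

With `mu = 1` and near-threshold rates the epidemic flickers and goes
extinct regularly. When `reseed_on_extinction` is enabled (the default in
the reconstruction workflow), the all-zero row is *recorded* and a fresh
`floor(rho0*N)` infected set is seeded at the following row. Recording the
zero row matters: re-seeded infections then follow a row with no active
channel, so the estimator can only attribute them to its noise term.
Overwriting the zero row instead (seeding "in place") was measured to
produce interior-optimum false edges, because the spurious infections
coincide with whichever nodes were active in the dying, low-prevalence
generation.

**Simplicial Ising dynamics.** Spins ±1 under
`H = -J1 Σ_(i,j) S_i S_j - J2 Σ_(i,j,k) S_i S_j S_k`; at each synchronous
step every node flips with probability `1/(1 + exp(delta * dE_i))`, where
`dE_i` is the energy change of flipping `i` in the time-`t` configuration
and `delta` the inverse temperature. An asynchronous single-spin Glauber
variant is provided (`update="asynchronous"`); synchronous is the default
because it matches the row-per-time-step data model. Only the simulator is
in scope; reconstruction from spin data is not implemented.

## The estimator

For each target node `i`, the number of times it leaves the susceptible
state is modeled as a Poisson superposition over candidate channels,
evaluated on the rows where `i` is susceptible:

    E_i(t) = Σ_j  P_{j->i}  P_j^i  Ψ_j(t)
           + Σ_{j<k} P_{jk->i} P_jk^i Ψ_j(t) Ψ_k(t)
           + eps_i

`Ψ_j(t)` is the 0/1 activity of `j` at time `t`; `P_j^i` and `P_jk^i` are
*empirical conditionals* — the observed infection frequency of `i` given `j`
(resp. both `j` and `k`) active — counted directly from consecutive row
pairs; `eps_i` absorbs unexplained events. A conditioning event that never
occurs leaves the channel undefined: its weight is frozen at zero and the
term dropped (never a NaN). The channel weights `P_{j->i}`, `P_{jk->i}` and
`eps_i` are the free parameters; a positive pair weight signals an edge, a
positive triple weight a triangle containing the target.

Because every channel enters the rate linearly, the EM updates are the
standard multiplicative (Richardson–Lucy form) ones: each E-step attributes
every infection event to channels in proportion to their share of the rate
(responsibilities sum to one by construction), and the M-step rescales each
weight by the ratio of attributed events to expected events. The
log-likelihood is non-decreasing across iterations, which the test suite
asserts on the recorded trace.

### Numerical choices

* **Initialization and restarts.** All weights start at 1 (the all-ones
  initialization), plus `n_restarts - 1 = 2` additional uniform-(0,1]
  restarts; the restart with the highest final log-likelihood wins. Restarts
  are iterated as columns of one matrix so the per-iteration cost is a pair
  of BLAS multiplies over the event rows only.
* **Convergence.** Per-parameter relative change below `tol = 1e-6`, with an
  absolute floor of `1e-8` so a weight that is merely decaying toward zero
  does not hold the iteration hostage; at most 500 iterations per restart.
* **Boundary handling.** Multiplicative updates approach the zero boundary
  only geometrically, but the downstream edge rule is a strict positivity
  test, so residual dust is consequential. Two mechanisms produce exact
  zeros: weights below `1e-10` snap to zero (the update keeps them there),
  and a first-order optimality check — run every 25 iterations and at
  termination on weights below `1e-3` — sets a weight to exactly zero when
  the likelihood gradient at zero, with the channel removed from the rate,
  is non-positive. Both are conservative: a channel the likelihood wants is
  never removed by them.
* **Noise floor.** `eps_i` is floored at `1e-12` during iteration so E-step
  denominators stay positive; a target with no infection events at all
  short-circuits to the exact solution (all zeros).
* **Dust clip.** When assembling the complex, weights below `1e-9` count as
  zero.

### Two-step reconstruction

Estimating all `C(N-1, 2)` triple weights per node is both slow and
noisy. The pipeline therefore runs per target node:

1. **First pass** with pair channels only, over all other nodes, giving a
   ranking `P^0_{j->i}`.
2. **Truncation.** Values are sorted descending and split at the maximum of
   the ratio-weighted gap score `(P_l / P_{l+1}) (P_l - P_{l+1})` (ties to
   the smallest index; threshold at the winning gap's midpoint; positions
   with a zero successor are not scored). A second gap search on the values
   strictly below the first threshold yields a smaller, permissive
   threshold, so borderline true neighbors just under the main gap are
   retained. Two safeguards: (a) a proposed cut whose largest discarded
   value is within a factor 2 of the smallest kept value is distrusted —
   this is the signature of a homogeneous cluster, which arises exactly when
   the EM has already zeroed every non-neighbor — and all positives are kept
   instead; (b) the candidate set is capped at the 30 strongest values,
   which binds only in noisy regimes where no neighbor cluster is separable
   and keeps the second pass tractable.
3. **Second pass** restricted to the approximate neighbors (pair channels)
   and all their unordered pairs (triple channels), on the same rows.
4. **Assembly.** An edge `{i,j}` is predicted when either directed weight is
   positive (the disjunctive rule keeps a connection seen clearly from one
   side). A triangle `{i,j,k}` needs at least two of its three directed
   weights to clear their per-target maximum-gap threshold (same guard as
   above); triples with a single vote are rejected as conflicts. Predicted
   triangles whose three edges are not all predicted are dropped — closure
   is enforced by trusting the edge channel, which is the more reliable of
   the two — and logged.

Per-node failures leave that node's channels empty and are reported; they
never abort the run.

## Synthetic generators

* **Random (ERSC):** edges are independent Bernoulli draws with
  `p1 = (k1 - 2 k2) / ((N-1) - 2 k2)`; triangles independent Bernoulli with
  `p2 = 2 k2 / ((N-1)(N-2))` over all triples, their faces merged into the
  edge set. The `p1` correction keeps the realized mean degrees unbiased for
  the targets (verified by a 50-seed Monte-Carlo test at 3 standard errors);
  it requires `k1 > 2 k2` and `N - 1 > 2 k2`. Triangle sampling draws the
  Binomial count and then that many distinct triples — distributionally
  identical to the triple-by-triple draw without the `O(N^3)` loop.
* **Scale-free (SFSC):** a Barabási–Albert backbone (`m` edges per arriving
  node, networkx's star-seed convention, so the backbone has exactly
  `m(N - m)` edges), plus `p2`-triangles; expected
  `k1 = 2m + 2 k2 (1 - 2m/N)`.
* **Small-world (SWSC):** a Watts–Strogatz ring of uniform degree `2m`
  rewired with probability `p`, plus `p2`-triangles.

All generators return validated, closure-true complexes and are
deterministic given the seed.

## Perturbation protocol and experiments

`flip_states` flips `floor(f * #ones)` randomly chosen active entries to 0
and the same number of inactive entries to 1, over the whole matrix,
conserving the total activity exactly. `run_experiment` drives
generate → simulate → (flip) → reconstruct → score over a grid of series
lengths `T` or flip fractions `f`, with per-cell error capture, and returns
a tidy table plus mean±SD summaries. Precision (and hence F1) is defined as
0 for a non-empty truth with an empty prediction; the exact empty-vs-empty
match scores 1.

## Contact-stream builder

Real-world complexes are built from timestamped face-to-face contact
records (20-second resolution, 3-column TSV). Pair weights are total
contact counts over the stream; pairs below the threshold `zeta` are
removed and the rest binarized. Candidate triangles are triples whose three
pairwise contacts all fall within one 5-minute window (windows bin the raw
clock); candidates are ranked by total occurrence count across windows and
the top `keep_frac` (default 50%) retained, including all ties with the
cutoff frequency. Kept triangles missing a surviving edge are dropped for
closure. `zeta` counts raw 20-second contacts, not aggregated episodes.

## What the benchmarks show — and what they do not

The synthetic benchmark is the generators' own output: the reconstruction
is tested on data whose generating process exactly matches the estimator's
assumptions (binary SIS-type dynamics, static structure, synchronous
records, known-to-be-2-simplicial complexes). Passing it demonstrates the
estimator and its thresholds work at realistic sizes and noise levels; it
does not demonstrate robustness to model misspecification — non-SIS
dynamics, time-varying structure, unobserved nodes, or higher-order
simplexes — none of which the generator emulates. The flip protocol probes
i.i.d. measurement noise only.

Problem sizes used in the shipped tests: the full-scale checks run N=200,
T=10,000 complexes (one to five seeds, matching the benchmark conditions);
the qualitative trend checks run N=100 with T in {2000, 4000, 8000}; unit
and property tests run toy instances in seconds. The robustness check at
f=0.3 uses the denser N=200, k1=12, k2=4 complex.

## Known limitations

* Reconstruction from ±1 spin records is out of scope (simulator only).
* The inferred quantities are existence probabilities, not the dynamical
  parameters `beta1`, `beta2`, `mu`; those are treated as unknown nuisances.
* Triangle recovery degrades before edge recovery as `T` shrinks or noise
  grows: triple channels share their events with their two pair channels,
  so their identifiability is intrinsically weaker.
* The candidate cap (30) bounds the per-node second-pass cost; in extremely
  dense or extremely noisy settings it can exclude true neighbors from the
  triple search.
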