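# simplirec

Reconstruction of 2-simplicial complexes — networks with both pairwise
links and three-body "filled triangle" interactions — from binary
time-series data alone.

## The problem

Many spreading and opinion processes are driven not only by pairwise
contacts but by group reinforcement: a susceptible individual exposed to
*two* infected members of a common group is far more likely to adopt than
two independent exposures would suggest. Such systems are modeled on
2-simplicial complexes, where an edge `{i,j}` carries ordinary transmission
and a 2-simplex (triangle) `{i,j,k}` carries the synergistic three-body
channel. The inverse problem — given only a `T x N` matrix `S` of observed
binary node states over time, recover every edge *and* every triangle, with
no knowledge of the dynamical parameters — is what this package solves.

`simplirec` is aimed at researchers in network inference and spreading
dynamics: it bundles the synthetic structure generators, the forward
simulators that produce the data, the reconstruction engine, the scoring
and robustness protocol, and a builder for ground-truth complexes from
face-to-face contact streams.

## The method

For each target node `i`, the count of its transitions out of the
susceptible state is modeled as a Poisson superposition

    E_i(t) = Σ_j P_{j→i} P_j^i Ψ_j(t)
           + Σ_{j<k} P_{jk→i} P_{jk}^i Ψ_j(t) Ψ_k(t) + ε_i

over the times when `i` is susceptible, where `Ψ_j(t)` is the observed 0/1
activity of node `j`, `P_j^i` and `P_{jk}^i` are conditional infection
frequencies counted directly from `S`, and `ε_i` absorbs noise. The channel
weights `Θ = {P_{j→i}, P_{jk→i}, ε_i}` are fitted by expectation
maximization (multiplicative Poisson updates, non-decreasing likelihood,
random restarts). Reconstruction is two-step: a pairs-only EM pass ranks
candidate neighbors, a maximum-gap truncation of the sorted probabilities
extracts an approximate neighborhood, and a second EM pass restricted to
those neighbors and their pairs yields the final weights. Edges are
declared where either directed weight is positive; a triangle needs two of
its three directed weights above their per-target maximum-gap thresholds
and is dropped if its edges are not all predicted (closure). Details and
all numerical choices are in [docs/methods.md](docs/methods.md).

## Worked example

```python
from simplirec import (
    GeneratorParams, ContagionParams, generate_ersc, simulate_contagion,
    reconstruct, score,
)

truth = generate_ersc(GeneratorParams(n_nodes=50, k1_target=6, k2_target=2, seed=11))
print(f"truth: {len(truth.edges)} edges, {len(truth.triangles)} triangles "
      f"(k1={truth.k1:.2f}, k2={truth.k2:.2f})")

params = ContagionParams(alpha=0.8, omega=2.4, mu=1.0, rho0=0.2, T=8000, seed=12)
S = simulate_contagion(truth, params, reseed_on_extinction=True)
print(f"simulated {S.n_steps} steps, prevalence {S.values.mean():.3f}, "
      f"{len(S.meta['reseed_steps'])} reseeds")

rec = reconstruct(S, seed=13)
for mode in ("edges", "triangles"):
    m = score(truth, rec.complex, mode)
    print(f"{mode}: F1={m.f1:.3f} precision={m.precision:.3f} recall={m.recall:.3f}")
```

prints

```
truth: 152 edges, 34 triangles (k1=6.08, k2=2.04)
simulated 8000 steps, prevalence 0.139, 232 reseeds
edges: F1=1.000 precision=1.000 recall=1.000
triangles: F1=1.000 precision=1.000 recall=1.000
```

The generator hits its degree targets in expectation; the contagion runs
near threshold (prevalence ≈ 0.14, with the epidemic re-seeded whenever it
goes extinct); and the two-step reconstruction recovers the edge set and
the triangle set exactly from the binary record alone. At larger sizes and
shorter records recovery is near-exact rather than exact; the test suite
quantifies this.

The same workflow is available from the shell:

```sh
simplirec generate --model ersc --n-nodes 50 --k1 6 --k2 2 --seed 11 --out-prefix truth
simplirec simulate --complex-prefix truth -T 8000 --seed 12 --out states.csv
simplirec reconstruct --states states.csv --out-prefix rec --seed 13
simplirec evaluate --truth-prefix truth --pred-prefix rec
```

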