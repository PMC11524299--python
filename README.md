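# fungraph

Functional mapping of growth QTLs and reconstruction of multilayer genetic
interaction networks from longitudinal trait data.

## The problem

Growth traits — shoot height over a season, stem diameter over years — are
trajectories, not snapshots. `fungraph` implements a two-stage analysis for
genotype–phenotype data of this kind:

1. **Functional mapping.** Each biallelic marker partitions the population
   into genotype classes. The class mean trajectory is a logistic curve
   μ_j(t) = a_j / (1 + b_j e^(−r_j t)) and residuals follow a first-order
   structured antedependence process (SAD(1)): e_t = φ e_{t−1} + ε_t,
   ε_t ~ N(0, ν²), whose covariance has closed-form determinant (ν²ᵀ) and
   tridiagonal inverse. Markers are scored by the likelihood ratio between
   the per-genotype model and a single shared curve; genome-wide
   significance comes from permutation of the individual→trajectory
   assignment. The marker's time-varying genetic effect is its age-varying
   genetic standard deviation
   z_s(τ) = sqrt((1/n) Σ_j n_j (μ_j(τ) − μ̄_s(τ))²).

2. **Functional graphing.** Effect curves of all markers are clustered into
   modules (an EM mixture with Legendre-polynomial mean curves and SAD(1)
   covariance, the number of modules chosen by BIC, recursively refined
   into submodules). Within each module level, every node's effect curve is
   decomposed through a Lotka–Volterra-style ODE

   dz_s/dτ = Q_s(z_s) + Σ_{s′} Q_ss′(z_s′)

   into an *independent* component Q_s (the node's intrinsic dynamics) and
   *dependent* components Q_ss′ contributed by a sparse set of regulators
   chosen by an L1 path with nested-model refinement. The fitted system is
   solved by fourth-order Runge–Kutta inside a nonlinear least-squares
   loop, and the accumulated dependent effects become the signed, weighted,
   directed edges of a multilayer epistasis network, with each reciprocal
   pair classified into one of seven qualitative epistasis types
   (symmetric/asymmetric/directional × positive/negative, plus the
   mixed-sign altruistic/repressive class).

A first-class synthetic-data module plants QTLs, curve families and
interaction systems with known truth, so every stage is testable without
external data.

## Worked example

```bash
fungraph simulate --out demo --seed 3        # 200 trees, 20 markers, one QTL
fungraph run --vcf demo/genotypes.vcf --pheno demo/phenotypes.csv \
             --out demo/results --seed 1
```

The run command prints the manifest summary; on this simulated dataset it
reports

```
"scan":    {"status": "complete", "markers": 20, "fitted": 20,
            "max_lr": 779.54, "threshold": 17.47},
"curves":  {"status": "complete", "curves": 20},
"cluster": {"status": "complete", "leaves": 1},
"network": {"status": "complete", "layers": 1, "edges": 7}
```

The planted QTL (`S1`, first marker) reaches LR ≈ 780 against a 5%
genome-wide permutation threshold of ≈ 17.5 — the locus is unambiguous —
while the 19 phenotype-independent markers stay far below threshold.
`demo/results/scan.tsv` lists per-marker LR, nominal chi-square p-value,
the fitted (a_j, b_j, r_j) per genotype and the shared (φ, ν²);
`curves.csv` holds the effect curves, `tree.json` the module hierarchy and
`edges.tsv` / `network.graphml` the signed interaction network.

The same stages are available as a library:

```python
from fungraph import SimulationSpec, simulate_population, scan, lr_test

geno, trait = simulate_population(SimulationSpec(seed=3))
results = scan(trait, geno, seed=1)
lr, p = lr_test(results[0])
```

## Layout

| module | contents |
| --- | --- |
| `fungraph.growth` | logistic growth curve, time grids |
| `fungraph.sad` | SAD(1) covariance, closed-form determinant/inverse |
| `fungraph.legendre` | Legendre basis, smoothing fits |
| `fungraph.funmap` | likelihood, marker fits, LR scan, permutation threshold, effect curves, plasticity |
| `fungraph.funclust` | curve-mixture EM, BIC selection, module tree |
| `fungraph.ode` | derivative estimation, regulator selection, RK4 node fits, effect decomposition |
| `fungraph.network` | edge weights, epistasis classification, multilayer assembly, GraphML export |
| `fungraph.simulate` | planted QTL populations, curve families, interaction systems |
| `fungraph.io`, `fungraph.pipeline`, `fungraph.cli` | file formats, resumable pipeline, `fungraph` command |

See `docs/methods.md` for the statistical model, its assumptions, all
tunable parameters, and known limitations — including an honest account of
when regulator selection from a single trajectory is and is not
identifiable.
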