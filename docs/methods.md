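# Methods

## Trait model

An individual's trajectory is y_i = (y_i(t_{i1}), …, y_i(t_{iT_i})). Under
genotype class j at a marker the mean vector is the logistic curve
μ_j(t) = a_j / (1 + b_j e^(−r_j t)) evaluated on the individual's own grid
(a: asymptote, b: initial-condition shape, with μ_j(0) = a_j/(1+b_j);
r: relative growth rate, 1/time). Residuals follow the first-order
structured antedependence process

    e_1 = ε_1,   e_t = φ e_{t−1} + ε_t,   ε_t ~ N(0, ν²),

indexed by *position* in the grid rather than raw age, so unequally spaced
and per-individual grids are handled ordinally and the closed forms stay
exact. The covariance factorizes as Σ = L D Lᵀ with L unit lower-triangular
(L[t,s] = φ^{t−s}) and D = ν² I, giving det Σ = ν²ᵀ, a tridiagonal inverse,
and O(T) likelihood evaluation through innovations w_t = e_t − φ e_{t−1}.
φ is unconstrained (|φ| ≥ 1 simply makes the variance grow along the grid);
the optimizer clips it to [−2, 2] for numerical safety. ν² is treated as
age-constant; the antedependence literature also uses per-age innovation
variances, and the parameter type leaves room for that extension.

## Marker fitting and the scan

Both hypotheses (H1: per-class curves; H0: one shared curve) are maximized
by Nelder–Mead simplex over (log a_j, log b_j, log r_j)_j and φ, with ν²
profiled out analytically — for fixed means and φ, its MLE is the mean
squared innovation, which removes one dimension and a source of scaling
problems while leaving the maximum unchanged. Starts come from per-class
least-squares logistic fits (per-age class means; cheap and already close),
plus random restarts in log-space (five by default). Because the pooled H0
fit ignores genotype, one H0 fit is shared by every marker with the same
retained-individual set. If the H1 optimum lands below H0 (nested models
forbid this), H1 is refit from the H0 solution. The LR = 2(logL₁ − logL₀)
is clipped at zero; a pre-clip deficit above 1e−4 marks non-convergence.

Nominal p-values use χ² with df = 3(J−1) — the number of constrained growth
parameters — but are advisory only; the primary genome-wide calibration is
the permutation threshold: B permutations of the individual→trajectory
assignment (trajectories intact), a full rescan per permutation, and the
empirical (1−α) quantile of the B genome-wide maxima. Permutation rescans
reuse the H0 fit (invariant under permutation) and use fewer restarts (the
warm starts make extra restarts redundant); this is a speed choice, not a
statistical one. Genotype classes below `min_class_size` (default 3) are
dropped for that marker and flagged; markers left with fewer than two
classes are excluded.

Effect curves use observed class frequencies n_j/n as weights (not
Hardy–Weinberg expectations). Phenotypic plasticity is control − stress per
individual, so larger values mean growth suffers more under stress;
mismatched grids are linearly interpolated onto the union of ages inside
the overlapping range.

## Functional clustering

Effect curves on a shared grid are modelled by a K-component Gaussian
mixture: component means are Legendre series of order Q (default 4) over
the pooled time range — effect curves are differences of logistics and need
not be logistic themselves, which is why the mean family is nonparametric —
and all components share one SAD(1) covariance. EM alternates
responsibilities, weighted-GLS mean coefficients (through the innovation
transform, so no dense solve is needed), and (φ, ν²) by bounded 1-D search
with ν² profiled. Initialization is k-means on raw curve vectors with five
restarts; the log-likelihood is asserted non-decreasing at every step
(except immediately after an emptied component is re-seeded, at most three
times). Hard assignments take the maximum posterior, ties to the lowest
index.

K minimizes BIC = −2 logL + p log N with p = K(Q+1) + (K−1) + 2 and N the
number of curves — curves are the exchangeable units, so N is not inflated
by grid length. The module tree recursively re-clusters any node above the
leaf-size cap (default 30, small enough for the per-leaf network stage)
until BIC chooses K = 1 (the node stays a leaf, flagged if oversized) or a
depth cap of 6 is reached.

## ODE decomposition and network

Each node's curve obeys dz_s/dτ = Q_s(z_s) + Σ Q_ss′(z_s′) with Q_s a
Legendre series of order K_ind = 3 in the node's own rescaled state and
each Q_ss′ a series of orders 1..K_dep = 3 in the regulator's state,
*anchored* so that Q_ss′ vanishes at the regulator's initial state. The
anchoring resolves a real ambiguity — only the sum of the constant terms of
Q_s and all Q_ss′ is identified — by convention: a regulator contributes
nothing until it departs from where it started. Dependent curves therefore
start at zero with zero slope, and an edge's sign states whether the
regulator's departure accumulates activation or suppression.

Curves are smoothed by a GCV-penalized cubic smoothing spline (an
interpolating not-a-knot spline when the smoothing residual is negligible,
because the penalized fit's natural boundary biases endpoint derivatives);
derivatives and regulator forcing are evaluated analytically from the
spline. A global-polynomial smoother was rejected after ablation: its
ringing on sigmoidal curves destroys derivative accuracy.

Regulator selection works on the *integrated* equation — z(t) − z(0)
regressed on time-integrals (computed on a 4×-refined grid so quadrature
error cannot masquerade as signal) of the candidate basis columns — which
is markedly more noise-robust than regressing the estimated derivative.
The node's own block is unpenalized and projected out exactly
(Frisch–Waugh); an L1 path over the anchored regulator columns (order 1
for selection) supplies the order in which candidates enter; the support
then grows by nested least squares, a candidate being accepted only when
its residual improvement clears an extended-BIC threshold scaled by the
observation-noise variance estimated from the smoothing residual. At most
`d_max` = 5 regulators survive.

The reduced ODE is fit by nonlinear least squares on RK4 trajectories
(4 substeps per observation interval) from the smoothed initial value,
regulator curves held at their smoothed trajectories — a decoupled,
per-node formulation; jointly solving all nodes is unnecessary for
decomposition and intractable at scale. Because the dependent terms do not
involve the target's state, their stage-time values are linear in the
coefficients and are precomputed once per fit. Decomposition integrates
[z, I_s, D_ss′] with one shared RK4 quadrature, so I + Σ D equals the
fitted net curve to roundoff by construction.

Edges are weighted by the time-averaged dependent effect
W = D_ss′(τ_T)/(τ_T − τ₁); the zero threshold ε defaults to 5% of the
layer's maximum |W| and the symmetry tolerance δ to 0.2 (the qualitative
definitions of "same extent" and "no effect" need quantitative defaults;
both are recorded in the network metadata). The altruistic/repressive class
covers both opposite-sign orderings. Networks are built per module-tree
node over its children — module mean curves on coarse layers, member
markers at leaves.

## Synthetic data

`simulate_population` draws genotypes binomially at the stated allele
frequency (ploidy 1 for the two-class default, 2 with a midway heterozygote
for three classes) and phenotypes as the dosage class's logistic mean plus
SAD(1) noise. The default design — n = 200, 8 ages on [1, 12], QTL curves
a = (12, 10), b = (9, 9), r = (0.6, 0.5), φ = 0.3, ν² = 0.25, i.e. an
asymptote gap of four innovation SDs — is the moderate-effect regime in
which a longitudinal mapping study is expected to succeed, and is the
regime the package's detection and recovery figures refer to.

`simulate_effect_system` plants interaction systems *inside the model
family the decomposition fits*: bistable-cubic intrinsic dynamics
Q_s(z) = −k(z−c)(z−m)(z−K) (globally attracting, so trajectories cannot
blow up; nodes start near the unstable middle root and switch up or down at
spread onset times) with anchored-linear couplings w·(z′ − z′(0)),
|w| ∈ [1.5, 3]. Observation noise is Gaussian with SD a fraction (default
2%) of each trajectory's range, clipped at zero. Draws whose trajectories
go non-positive or flat are rejected and redrawn deterministically from
sub-seeds; an unrecoverable configuration raises an error naming the node.
The planted sign of an edge is the sign of its true time-integrated
dependent effect. These curves emulate the smooth, S-shaped, positively
valued effect trajectories of real mapping studies but not their
linkage-disequilibrium structure, nor measurement schedules with only a
handful of ages.

## What the recovery experiments do and do not show

With exact derivatives and the planted system inside the model family,
exhaustive best-subset search identifies every node's true regulator pair
(rank-0 fraction 1.0 in our ablations) — the estimating machinery is
correct. With observation noise at 2% of curve range, however, a single
short trajectory cannot discriminate ~20 correlated smooth candidate
regulators: the same exhaustive oracle — an upper bound on any subset
selector in this formulation — ranks the true pair first for only ~10–25%
of nodes across every planted-system design we tried (noiseless ≈ 0.87, at
0.5% noise ≈ 0.43, at 2% ≈ 0.14). The package's selector operates near
that ceiling; measured over ten 20-node systems at 2% noise it reaches
edge precision ≈ 0.2–0.3 and recall ≈ 0.3–0.4, with sign agreement on
recovered edges ≈ 0.8. Support recovery from one trajectory should therefore be
read as a ranking of candidate regulators, not a reliable reconstruction,
unless noise is well below 1% or external replication constrains the
search. Noise-free, a single strong planted regulator is included in the
selected set in ≈ 95% of systems.

## Numerical choices

- Simplex tolerances: xatol 1e−5, fatol 1e−6, iteration cap 250 per
  dimension; warm starts make these generous.
- Spline smoothing: GCV penalty; noise variance from the smoothing
  residual; near-zero residual switches to interpolation.
- RK4: 4 substeps per observation interval in fits and decomposition
  (6 in the generator); global error is verified fourth-order.
- Least squares: trust-region reflective, 200 function-evaluation cap,
  initialized from the derivative regression on the selected support;
  non-finite trial trajectories are penalized, not fatal.
- Ties and degenerate inputs: flat curves yield zero derivatives and empty
  regulator sets; duplicate ages within an individual are rejected at
  construction; empty EM components are re-seeded at most three times.

## Problem sizes

The test suite and the acceptance script run the full stages at reduced
but statistically meaningful sizes chosen by us: 50 replicate populations
(n = 200, 20 markers) for detection and parameter recovery; one 50-marker
null population with B = 200 permutations and 100 independent null scans
for type-I calibration; 20 replicates of three 50-curve families for
clustering; ten 20-node planted systems for network recovery.

## Known limitations

- One logistic growth law; other growth families (Gompertz, von
  Bertalanffy) are not implemented.
- No kinship or population-structure correction in the scan.
- Regulator selection from a single trajectory is noise-limited (above);
  edge lists at realistic noise are exploratory.
- The epistasis-type thresholds (ε, δ) are conventions, not estimates.
- Chi-square p-values ignore boundary effects in the mixture-free
  parameterization; use the permutation threshold for inference.
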