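"""Synthetic genotype-phenotype and effect-curve generators with known truth.

Three generators cover the three inference stages:

* :func:`simulate_population` — biallelic genotypes plus logistic growth
  trajectories with SAD(1) residuals and planted QTLs (optionally a paired
  stress/control design for plasticity mapping);
* :func:`simulate_curve_families` — effect-curve families with distinct
  temporal shapes, ground-truth labels for clustering;
* :func:`simulate_effect_system` — a sparse planted interaction system in
  the decomposition's own ODE form, integrated by RK4, with the planted
  signed edge list returned as truth.

All randomness flows through one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

from .funmap import EffectCurve, GenotypeMatrix, LongitudinalTrait
from .growth import GrowthParams, TimeGrid, logistic_mean_arr
from .ode import rk4_integrate
from .sad import SADParams

__all__ = [
    "SimulationSpec",
    "simulate_population",
    "simulate_curve_families",
    "simulate_effect_system",
    "PlantedSystem",
]

# default planted QTL: two homozygote curves differing in asymptote and rate,
# residual SD (sqrt nu2 = 0.5) at 25% of the asymptote gap
DEFAULT_QTL_PARAMS = (GrowthParams(a=12.0, b=9.0, r=0.6),
                      GrowthParams(a=10.0, b=9.0, r=0.5))


@dataclass
class SimulationSpec:
    """Study design for a synthetic mapping population.

    Defaults plant one moderate-effect QTL (asymptote gap = 2 trait units,
    four times the residual innovation SD) in an n = 200 population measured
    at 8 ages, the regime in which functional mapping is expected to detect
    the locus reliably.
    """

    n: int = 200
    m: int = 20
    times: NDArray[np.float64] = field(
        default_factory=lambda: np.linspace(1.0, 12.0, 8))
    allele_freq: float = 0.3
    qtl_index: int | None = 0
    qtl_params: tuple[GrowthParams, ...] = DEFAULT_QTL_PARAMS
    baseline: GrowthParams = GrowthParams(a=11.0, b=9.0, r=0.55)
    sad: SADParams = SADParams(phi=0.3, nu2=0.25)
    n_genotype_classes: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.qtl_index is not None and not 0 <= self.qtl_index < self.m:
            raise ValueError("QTL index out of range")
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError("allele frequency must lie in (0, 1)")
        if self.n_genotype_classes not in (2, 3):
            raise ValueError("n_genotype_classes must be 2 or 3")


def _class_params(spec: SimulationSpec) -> list[GrowthParams]:
    """Per-dosage growth parameters; heterozygote midway when J = 3."""
    if spec.qtl_params is None:
        return [spec.baseline] * spec.n_genotype_classes
    p = list(spec.qtl_params)
    if spec.n_genotype_classes == 2:
        if len(p) != 2:
            raise ValueError("need 2 genotype parameter sets for J=2")
        return p
    if len(p) == 3:
        return p
    if len(p) == 2:
        lo, hi = p
        mid = GrowthParams(a=0.5 * (lo.a + hi.a), b=0.5 * (lo.b + hi.b),
                           r=0.5 * (lo.r + hi.r))
        return [lo, mid, hi]
    raise ValueError("need 2 or 3 genotype parameter sets for J=3")


def _sad_noise(rng: np.random.Generator, n: int, T: int, sad: SADParams) -> NDArray:
    eps = rng.normal(0.0, np.sqrt(sad.nu2), size=(n, T))
    e = np.empty_like(eps)
    e[:, 0] = eps[:, 0]
    for t in range(1, T):
        e[:, t] = sad.phi * e[:, t - 1] + eps[:, t]
    return e


def simulate_population(
    spec: SimulationSpec,
    *,
    paired: bool = False,
    stress_a_scale: float = 0.7,
    stress_r_scale: float = 0.85,
) -> tuple[GenotypeMatrix, LongitudinalTrait] | tuple[GenotypeMatrix, LongitudinalTrait, LongitudinalTrait]:
    """Draw genotypes and longitudinal phenotypes with a planted QTL.

    Genotypes are binomial allele-dosage draws at ``allele_freq`` (ploidy 1
    when two genotype classes are requested, 2 otherwise); non-QTL markers
    are phenotype-independent.  Phenotypes follow the dosage class's logistic
    mean at the QTL plus SAD(1) noise.  With ``paired=True`` a second
    (stress) condition is returned for the same individuals, with asymptote
    and rate scaled down and independent noise.
    """
    rng = np.random.default_rng(spec.seed)
    ploidy = 1 if spec.n_genotype_classes == 2 else 2
    codes = rng.binomial(ploidy, spec.allele_freq, size=(spec.m, spec.n))
    geno = GenotypeMatrix(
        marker_ids=[f"S{j + 1}" for j in range(spec.m)],
        individual_ids=[f"ind{i + 1}" for i in range(spec.n)],
        codes=codes.astype(np.int64),
        chrom=["1"] * spec.m,
        pos=[1000 * (j + 1) for j in range(spec.m)],
    )
    params = _class_params(spec)
    T = spec.times.size
    if spec.qtl_index is not None:
        dosage = codes[spec.qtl_index]
    else:
        dosage = np.zeros(spec.n, dtype=int)
        params = [spec.baseline] * (max(dosage) + 1)

    def make_trait(pset: list[GrowthParams]) -> LongitudinalTrait:
        mus = np.vstack([logistic_mean_arr(spec.times, p.a, p.b, p.r)
                         for p in pset])
        Y = mus[dosage] + _sad_noise(rng, spec.n, T, spec.sad)
        grid = TimeGrid(spec.times)
        return LongitudinalTrait(
            ids=list(geno.individual_ids),
            grids=[grid] * spec.n,
            values=[Y[i] for i in range(spec.n)],
        )

    control = make_trait(params)
    if not paired:
        return geno, control
    stress_params = [GrowthParams(a=p.a * stress_a_scale, b=p.b,
                                  r=p.r * stress_r_scale) for p in params]
    stress = make_trait(stress_params)
    return geno, control, stress


# ---------------------------------------------------------------------------
# planted curve families (clustering truth)
# ---------------------------------------------------------------------------

def simulate_curve_families(
    n_families: int = 3,
    curves_per_family: int = 50,
    times: NDArray[np.float64] | None = None,
    noise_frac: float = 0.10,
    seed: int | None = None,
) -> tuple[list[EffectCurve], NDArray[np.int64]]:
    """Effect curves from distinct temporal archetypes, with true labels.

    Archetypes cycle through rising, decaying, peaked, late-rising and flat
    shapes; noise is Gaussian with SD = ``noise_frac`` times the family
    curve's range.  Values are clipped at zero (effect curves are standard
    deviations).
    """
    if times is None:
        times = np.linspace(0.0, 10.0, 20)
    rng = np.random.default_rng(seed)
    u = (times - times[0]) / (times[-1] - times[0])
    archetypes = [
        1.0 + 2.0 / (1.0 + np.exp(-8.0 * (u - 0.45))),      # rising
        0.5 + 2.5 * np.exp(-3.0 * u),                        # decaying
        0.5 + 2.5 * np.exp(-((u - 0.5) ** 2) / 0.02),        # mid peak
        0.8 + 2.2 * u ** 3,                                  # late rise
        1.5 + 0.3 * np.sin(2.0 * np.pi * u),                 # gentle wave
    ]
    if n_families > len(archetypes):
        raise ValueError(f"at most {len(archetypes)} planted families supported")
    grid = TimeGrid(times)
    curves, labels = [], []
    k = 0
    for fam in range(n_families):
        base = archetypes[fam]
        scale = noise_frac * float(np.ptp(base) if np.ptp(base) > 0 else 1.0)
        for _ in range(curves_per_family):
            z = np.maximum(base + rng.normal(0.0, scale, size=times.size), 0.0)
            curves.append(EffectCurve(curve_id=f"C{k + 1}", grid=grid, values=z))
            labels.append(fam)
            k += 1
    return curves, np.asarray(labels, dtype=np.int64)


# ---------------------------------------------------------------------------
# planted interaction system (network truth)
# ---------------------------------------------------------------------------

@dataclass
class PlantedSystem:
    """Ground truth of a simulated interaction system."""

    curves: list[EffectCurve]
    edges: list[tuple[str, str, int]]  # (regulator, target, sign)
    noiseless: NDArray[np.float64]     # (m, T) trajectories before noise

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {(s, t) for s, t, _ in self.edges}


def simulate_effect_system(
    n_nodes: int = 20,
    edges_per_node: int = 2,
    times: NDArray[np.float64] | None = None,
    noise_frac: float = 0.02,
    seed: int | None = None,
    *,
    coupling_range: tuple[float, float] = (1.5, 3.0),
    blowup_bound: float = 80.0,
    max_attempts: int = 40,
) -> PlantedSystem:
    """Integrate a planted sparse interaction system and add observation noise.

    Each node's intrinsic dynamics is a bistable cubic,

        Q_s(z) = -k_s (z - c_s)(z - m_s)(z - K_s),   c_s < m_s < K_s,

    globally attracting (pushed up below c_s, down above K_s, so no
    trajectory can escape), started near the unstable middle root so nodes
    switch to their high or low state at widely varying onset times — a mix
    of rising and falling S-shaped effect trajectories.  Couplings are
    anchored-linear, Q_ss'(z') = w (z' - z'(0)), with signed weights drawn
    from ``coupling_range``, matching the decomposition's model family
    (cubic independent component, anchored dependent components).

    Observation noise is Gaussian with SD = ``noise_frac`` times each
    trajectory's range, clipped at zero.  Parameter draws that produce
    near-zero or blown-up trajectories are rejected and redrawn from a
    deterministic sub-seed sequence; an unrecoverable blow-up raises an
    error naming the offending node.

    The planted sign of an edge is the sign of its true time-integrated
    dependent effect, i.e. whether the regulator's departure from its
    initial state accumulates activation or suppression on the target.
    """
    if times is None:
        times = np.linspace(0.0, 10.0, 50)
    m = n_nodes
    ids = [f"N{j + 1}" for j in range(m)]
    wlo, whi = coupling_range
    ss = np.random.SeedSequence(seed)
    last_bad = None
    for child in ss.spawn(max_attempts):
        rng = np.random.default_rng(child)
        c = rng.uniform(1.5, 2.5, m)
        K = c + rng.uniform(1.5, 3.0, m)
        mid = c + rng.uniform(0.3, 0.6, m) * (K - c)
        k = rng.uniform(2.0, 5.0, m) / ((K - c) * (K - mid))
        rise = rng.random(m) < 0.55
        z0 = np.where(rise, mid + rng.uniform(0.08, 0.45, m) * (K - mid),
                      mid - rng.uniform(0.08, 0.45, m) * (mid - c))
        W = np.zeros((m, m))
        for tgt in range(m):
            n_reg = min(edges_per_node, m - 1)
            regs = rng.choice([j for j in range(m) if j != tgt],
                              size=n_reg, replace=False)
            for src in regs:
                W[tgt, src] = rng.uniform(wlo, whi) * rng.choice([-1.0, 1.0])

        def rhs(ti: float, z: NDArray) -> NDArray:
            return -k * (z - c) * (z - mid) * (z - K) + W @ (z - z0)

        with np.errstate(over="ignore", invalid="ignore"):
            Z = rk4_integrate(rhs, z0, times, substeps=6).T
        if not np.all(np.isfinite(Z)) or np.abs(Z).max() > blowup_bound:
            finite_max = np.nan_to_num(np.abs(Z), nan=np.inf).max(axis=1)
            last_bad = ids[int(np.argmax(finite_max))]
            continue
        if Z.min() < 0.02 or np.min(np.ptp(Z, axis=1)) < 0.1:
            last_bad = ids[int(np.argmin(np.ptp(Z, axis=1)))]
            continue

        # true integrated dependent effects define the planted edge signs
        edges: list[tuple[str, str, int]] = []
        dt = np.gradient(times)
        for tgt in range(m):
            for src in np.nonzero(W[tgt])[0]:
                d_final = float(np.sum(W[tgt, src] * (Z[src] - z0[src]) * dt))
                sign = int(np.sign(d_final)) if d_final != 0 else int(np.sign(W[tgt, src]))
                edges.append((ids[int(src)], ids[tgt], sign))

        grid = TimeGrid(times)
        noise_rng = np.random.default_rng(child.spawn(1)[0])
        curves = []
        for j in range(m):
            scale = noise_frac * max(float(np.ptp(Z[j])), 1e-6)
            z_obs = np.maximum(Z[j] + noise_rng.normal(0.0, scale, times.size), 0.0)
            curves.append(EffectCurve(curve_id=ids[j], grid=grid, values=z_obs))
        return PlantedSystem(curves=curves, edges=edges, noiseless=Z)
    raise RuntimeError(
        f"trajectory blow-up at node {last_bad}: no stable system found in "
        f"{max_attempts} attempts")
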