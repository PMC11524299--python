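"""Per-marker functional mapping of longitudinal growth trajectories.

Each marker partitions the population into J genotype classes.  Under the
full model every class has its own logistic mean curve (a_j, b_j, r_j)
while all classes share one SAD(1) residual covariance (phi, nu2); the
reduced model forces a single curve.  The marker is scored by the
likelihood ratio LR = 2 (logL_1 - logL_0), and genome-wide significance is
calibrated by permutation of the individual-to-trajectory assignment.

The time-varying genetic effect of a marker is summarised by its
age-varying genetic standard deviation

    z_s(tau) = sqrt( (1/n) * sum_j n_j (mu_j(tau) - mu_bar(tau))^2 )

with mu_bar the genotype-frequency-weighted mean curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import optimize, stats

from .growth import GrowthParams, TimeGrid, logistic_mean_arr
from .sad import SADParams, sad1_innovations

__all__ = [
    "LongitudinalTrait",
    "GenotypeVector",
    "GenotypeMatrix",
    "FunMapResult",
    "EffectCurve",
    "group_loglik",
    "fit_marker",
    "lr_test",
    "scan",
    "permutation_threshold",
    "effect_curve",
    "plasticity_trait",
]

logger = logging.getLogger(__name__)

MISSING = -1  # genotype sentinel


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalTrait:
    """Longitudinal phenotypes: one trajectory per individual.

    ``grids[i]`` and ``values[i]`` hold individual ``ids[i]``'s measurement
    ages and trait values; grids may differ between individuals.
    """

    ids: list[str]
    grids: list[TimeGrid]
    values: list[NDArray[np.float64]]

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.grids) == len(self.values)):
            raise ValueError("ids, grids and values must have equal length")
        self.values = [np.asarray(v, dtype=float) for v in self.values]
        for i, (g, v) in enumerate(zip(self.grids, self.values)):
            if len(g) != v.size:
                raise ValueError(
                    f"individual {self.ids[i]}: {v.size} observations on a "
                    f"grid of length {len(g)}"
                )

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *, id_col: str = "id",
                       time_col: str = "time", value_col: str = "value") -> "LongitudinalTrait":
        """Build from a long-format table (one row per observation)."""
        ids, grids, values = [], [], []
        for iid, sub in df.groupby(id_col, sort=True):
            sub = sub.sort_values(time_col)
            ids.append(str(iid))
            grids.append(TimeGrid(sub[time_col].to_numpy(dtype=float)))
            values.append(sub[value_col].to_numpy(dtype=float))
        return cls(ids=ids, grids=grids, values=values)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for iid, g, v in zip(self.ids, self.grids, self.values):
            for t, y in zip(g.times, v):
                rows.append((iid, t, y))
        return pd.DataFrame(rows, columns=["id", "time", "value"])

    def subset(self, indices: Sequence[int]) -> "LongitudinalTrait":
        return LongitudinalTrait(
            ids=[self.ids[i] for i in indices],
            grids=[self.grids[i] for i in indices],
            values=[self.values[i] for i in indices],
        )

    def permuted(self, perm: Sequence[int]) -> "LongitudinalTrait":
        """Reassign trajectories to individuals: individual i gets trajectory perm[i]."""
        return LongitudinalTrait(
            ids=list(self.ids),
            grids=[self.grids[j] for j in perm],
            values=[self.values[j] for j in perm],
        )

    @property
    def pooled_time_range(self) -> tuple[float, float]:
        lo = min(float(g.times[0]) for g in self.grids)
        hi = max(float(g.times[-1]) for g in self.grids)
        return lo, hi


@dataclass
class GenotypeVector:
    """Genotype codes of one biallelic marker across individuals.

    Codes are alt-allele dosages in {0, 1, 2}; missing genotypes carry the
    sentinel ``MISSING`` (-1).
    """

    marker_id: str
    codes: NDArray[np.int64]
    chrom: str = "."
    pos: int = 0

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)

    def observed(self) -> NDArray[np.bool_]:
        return self.codes != MISSING


@dataclass
class GenotypeMatrix:
    """Markers x individuals dosage matrix with marker metadata."""

    marker_ids: list[str]
    individual_ids: list[str]
    codes: NDArray[np.int64]  # (m, n)
    chrom: list[str] = field(default_factory=list)
    pos: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        m, n = self.codes.shape
        if m != len(self.marker_ids) or n != len(self.individual_ids):
            raise ValueError("codes shape does not match id lists")
        if not self.chrom:
            self.chrom = ["."] * m
        if not self.pos:
            self.pos = list(range(1, m + 1))

    @property
    def m(self) -> int:
        return self.codes.shape[0]

    def vector(self, idx: int) -> GenotypeVector:
        return GenotypeVector(
            marker_id=self.marker_ids[idx],
            codes=self.codes[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
        )


@dataclass
class FunMapResult:
    """Maximum-likelihood fit of one marker under both hypotheses."""

    marker_id: str
    class_codes: NDArray[np.int64]      # genotype code of each retained class
    class_sizes: NDArray[np.int64]
    genotype_params: list[GrowthParams]  # per retained class (H1)
    null_params: GrowthParams
    sad: SADParams                       # H1 covariance parameters
    sad_null: SADParams
    loglik_h1: float
    loglik_h0: float
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    @property
    def J(self) -> int:
        return len(self.genotype_params)

    @property
    def lr(self) -> float:
        raw = 2.0 * (self.loglik_h1 - self.loglik_h0)
        return max(raw, 0.0)

    @property
    def lr_deficit(self) -> float:
        """How far below zero the raw LR fell (optimizer noise diagnostic)."""
        raw = 2.0 * (self.loglik_h1 - self.loglik_h0)
        return max(-raw, 0.0)


@dataclass
class EffectCurve:
    """Age-varying genetic standard deviation of a marker (or module mean)."""

    curve_id: str
    grid: TimeGrid
    values: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.grid):
            raise ValueError("effect values do not match grid length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("effect curve contains non-finite values")
        if np.any(self.values < -1e-12):
            raise ValueError("genetic standard deviation cannot be negative")
        self.values = np.maximum(self.values, 0.0)


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

class _GridGroups:
    """Individuals bucketed by identical time grids for vectorized likelihoods."""

    def __init__(self, trait: LongitudinalTrait):
        buckets: dict[tuple, list[int]] = {}
        for i, g in enumerate(trait.grids):
            buckets.setdefault(tuple(g.times), []).append(i)
        self.groups = []
        for times, idx in buckets.items():
            t = np.asarray(times)
            Y = np.vstack([trait.values[i] for i in idx])
            self.groups.append((np.asarray(idx), t, Y))
        self.n_obs = sum(Y.size for _, _, Y in self.groups)

    def restrict(self, keep: NDArray[np.bool_]) -> "_GridGroups":
        out = object.__new__(_GridGroups)
        out.groups = []
        for idx, t, Y in self.groups:
            m = keep[idx]
            if m.any():
                out.groups.append((idx[m], t, Y[m]))
        out.n_obs = sum(Y.size for _, _, Y in out.groups)
        return out


def _partition(groups: _GridGroups, labels: NDArray[np.int64]) -> list[tuple]:
    """(t, Y, class) blocks: one per grid-group x genotype class."""
    blocks = []
    for idx, t, Y in groups.groups:
        lab = labels[idx]
        for j in np.unique(lab):
            blocks.append((t, np.ascontiguousarray(Y[lab == j]), int(j)))
    return blocks


def _residual_ss_blocks(blocks: list[tuple], curves: NDArray[np.float64],
                        phi: float) -> float:
    """Sum of squared SAD(1) innovations over precomputed class blocks."""
    ss = 0.0
    for t, Y, j in blocks:
        a, b, r = curves[j]
        E = Y - a / (1.0 + b * np.exp(-r * t))
        W = E[:, 1:] - phi * E[:, :-1]
        ss += float(np.einsum("ij,ij->", W, W)) + float(E[:, 0] @ E[:, 0])
    return ss


def _residual_ss(groups: _GridGroups, labels: NDArray[np.int64],
                 curves: NDArray[np.float64], phi: float) -> float:
    """Sum of squared SAD(1) innovations; ``curves[j]`` gives class j's
    parameters (a, b, r) and ``labels`` the class of each individual."""
    return _residual_ss_blocks(_partition(groups, labels), curves, phi)


def _profile_loglik_blocks(n_obs: int, blocks: list[tuple],
                           curves: NDArray[np.float64], phi: float) -> tuple[float, float]:
    ss = _residual_ss_blocks(blocks, curves, phi)
    if not np.isfinite(ss) or ss <= 0:
        return -np.inf, np.nan
    nu2 = ss / n_obs
    ll = -0.5 * n_obs * (np.log(2.0 * np.pi * nu2) + 1.0)
    return ll, nu2


def _profile_loglik(groups: _GridGroups, labels: NDArray[np.int64],
                    curves: NDArray[np.float64], phi: float) -> tuple[float, float]:
    """Log-likelihood with nu2 at its conditional MLE; returns (loglik, nu2)."""
    return _profile_loglik_blocks(groups.n_obs, _partition(groups, labels),
                                  curves, phi)


def group_loglik(
    trait: LongitudinalTrait,
    geno: GenotypeVector,
    genotype_params: dict[int, GrowthParams],
    sad: SADParams,
) -> float:
    """Joint log-likelihood of all trajectories under genotype-specific curves.

    Individuals with missing genotype are excluded.  Every observed genotype
    code must have an entry in ``genotype_params``; the SAD(1) covariance is
    shared across classes.
    """
    obs = geno.observed()
    if not obs.any():
        raise ValueError(f"marker {geno.marker_id}: no observed genotypes")
    ll = 0.0
    for i in np.nonzero(obs)[0]:
        code = int(geno.codes[i])
        if code not in genotype_params:
            raise KeyError(
                f"marker {geno.marker_id}: no growth parameters for genotype {code}"
            )
        p = genotype_params[code]
        t = trait.grids[i].times
        e = trait.values[i] - logistic_mean_arr(t, p.a, p.b, p.r)
        w = sad1_innovations(e, sad.phi)
        T = t.size
        ll += -0.5 * (T * np.log(2.0 * np.pi * sad.nu2) + np.sum(w * w) / sad.nu2)
    return float(ll)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _init_logistic(t: NDArray[np.float64], y: NDArray[np.float64]) -> NDArray[np.float64]:
    """Heuristic (a, b, r) start from a pooled point cloud."""
    ymax = float(np.max(y))
    a0 = max(1.05 * ymax, 1e-6)
    t0 = np.min(t)
    y0 = max(float(np.mean(y[t == t0])), 1e-8)
    b0 = max(a0 / y0 - 1.0, 0.05)
    # logit-linearization: log(a0/y - 1) ~ log b - r t
    with np.errstate(divide="ignore", invalid="ignore"):
        lhs = np.log(np.maximum(a0 / np.maximum(y, 1e-8) - 1.0, 1e-8))
    A = np.vstack([np.ones_like(t), -t]).T
    sol, *_ = np.linalg.lstsq(A, lhs, rcond=None)
    r0 = float(sol[1])
    if not np.isfinite(r0) or r0 <= 1e-4:
        r0 = 1.0 / max(np.ptp(t), 1.0)
    return np.array([a0, b0, r0])


def _fit_logistic_ls(t: NDArray[np.float64], y: NDArray[np.float64]) -> NDArray[np.float64]:
    """Least-squares logistic fit of a point cloud (3-parameter simplex).

    Repeated ages are first collapsed to their means — the least-squares
    logistic through per-age means is an excellent warm start at a fraction
    of the cost for large point clouds.
    """
    tu, inv = np.unique(t, return_inverse=True)
    if tu.size < t.size:
        ybar = np.bincount(inv, weights=y) / np.bincount(inv)
        t, y = tu, ybar
    th0 = np.log(_init_logistic(t, y))

    def sse(th):
        a, b, r = np.exp(np.clip(th, -20, 20))
        d = y - logistic_mean_arr(t, a, b, r)
        return float(np.dot(d, d))

    res = optimize.minimize(sse, th0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400})
    return np.exp(np.clip(res.x, -20, 20))


def _pooled_cloud(trait: LongitudinalTrait, indices: NDArray[np.int64]):
    t = np.concatenate([trait.grids[i].times for i in indices])
    y = np.concatenate([trait.values[i] for i in indices])
    return t, y


def _phi_init(groups: _GridGroups, labels, curves) -> float:
    """Lag-1 regression of residuals on their predecessors."""
    num = den = 0.0
    for idx, t, Y in groups.groups:
        lab = labels[idx]
        mu = np.empty_like(Y)
        for j in np.unique(lab):
            a, b, r = curves[j]
            mu[lab == j] = logistic_mean_arr(t, a, b, r)
        E = Y - mu
        num += float(np.sum(E[:, 1:] * E[:, :-1]))
        den += float(np.sum(E[:, :-1] ** 2))
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, -1.5, 1.5))


def _maximize(groups: _GridGroups, labels: NDArray[np.int64], J: int,
              start_curves: NDArray[np.float64], phi0: float,
              n_restarts: int, rng: np.random.Generator,
              maxiter: int | None = None) -> tuple[float, NDArray, SADParams, bool]:
    """Simplex maximization over J logistic curves + phi, nu2 profiled out."""

    blocks = _partition(groups, labels)
    n_obs = groups.n_obs

    def unpack(theta):
        curves = np.exp(np.clip(theta[: 3 * J], -20.0, 20.0)).reshape(J, 3)
        phi = theta[-1]
        phi = -2.0 if phi < -2.0 else (2.0 if phi > 2.0 else float(phi))
        return curves, phi

    def negll(theta):
        curves, phi = unpack(theta)
        ll, _ = _profile_loglik_blocks(n_obs, blocks, curves, phi)
        return -ll if np.isfinite(ll) else 1e12

    base = np.concatenate([np.log(np.maximum(start_curves, 1e-8)).ravel(), [phi0]])
    dim = base.size
    if maxiter is None:
        maxiter = 250 * dim
    best_val, best_theta, ok = np.inf, base, False
    for k in range(max(1, n_restarts)):
        theta0 = base if k == 0 else base + np.concatenate(
            [rng.normal(0.0, 0.15, 3 * J), rng.normal(0.0, 0.2, 1)])
        res = optimize.minimize(negll, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-6,
                                         "maxiter": maxiter, "maxfev": maxiter})
        if res.fun < best_val:
            best_val, best_theta = res.fun, res.x
            ok = ok or bool(res.success) or res.fun < 1e11
    curves, phi = unpack(best_theta)
    ll, nu2 = _profile_loglik(groups, labels, curves, phi)
    return ll, curves, SADParams(phi=phi, nu2=nu2), ok and np.isfinite(ll)


def _fit_null(groups: _GridGroups, trait_t, trait_y, n_restarts, rng,
              maxiter=None) -> tuple[float, GrowthParams, SADParams, bool]:
    labels = np.zeros(max(idx.max() for idx, _, _ in groups.groups) + 1, dtype=np.int64)
    start = _fit_logistic_ls(trait_t, trait_y)[None, :]
    phi0 = _phi_init(groups, labels, start)
    ll, curves, sad, ok = _maximize(groups, labels, 1, start, phi0,
                                    n_restarts, rng, maxiter)
    a, b, r = curves[0]
    return ll, GrowthParams(a=a, b=b, r=r), sad, ok


def fit_marker(
    trait: LongitudinalTrait,
    geno: GenotypeVector,
    *,
    min_class_size: int = 3,
    n_restarts: int = 5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    _groups: _GridGroups | None = None,
    _null_fit: tuple | None = None,
) -> FunMapResult:
    """Maximum-likelihood functional mapping of one marker.

    Fits the full (per-genotype curves) and reduced (single curve) models by
    multi-start Nelder-Mead simplex, with (a, b, r) log-transformed for
    positivity and the innovation variance profiled out analytically.

    Genotype classes smaller than ``min_class_size`` are dropped (their
    individuals are excluded for this marker and the result is flagged);
    fewer than two surviving classes is an error.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    flags: list[str] = []

    obs = geno.observed()
    codes = geno.codes
    uniq, counts = np.unique(codes[obs], return_counts=True)
    keep_codes = uniq[counts >= min_class_size]
    dropped = uniq[counts < min_class_size]
    if dropped.size:
        flags.append(f"dropped_small_classes:{list(map(int, dropped))}")
    if keep_codes.size < 2:
        raise ValueError(
            f"marker {geno.marker_id}: insufficient genotype classes "
            f"(J={keep_codes.size} after filtering)"
        )
    keep = obs & np.isin(codes, keep_codes)
    if (~obs).any():
        flags.append(f"missing_genotypes:{int((~obs).sum())}")

    groups = (_groups or _GridGroups(trait)).restrict(keep)
    J = keep_codes.size
    labels = np.full(codes.size, -1, dtype=np.int64)
    for j, c in enumerate(keep_codes):
        labels[codes == c] = j
    class_sizes = np.array([int(np.sum(keep & (codes == c))) for c in keep_codes])

    # H0: pooled curve (reusable across markers when the kept set is identical)
    t_all = np.concatenate([t[None].repeat(Y.shape[0], 0).ravel()
                            for _, t, Y in groups.groups])
    y_all = np.concatenate([Y.ravel() for _, _, Y in groups.groups])
    if _null_fit is not None:
        ll0, p0, sad0, ok0 = _null_fit
    else:
        ll0, p0, sad0, ok0 = _fit_null(groups, t_all, y_all, n_restarts, rng)

    # H1: per-class curves, warm-started from per-class least squares
    starts = np.empty((J, 3))
    for j, c in enumerate(keep_codes):
        idx = np.nonzero(keep & (codes == c))[0]
        tc, yc = _pooled_cloud(trait, idx)
        starts[j] = _fit_logistic_ls(tc, yc)
    phi0 = _phi_init(groups, labels, starts)
    ll1, curves1, sad1, ok1 = _maximize(groups, labels, J, starts, phi0,
                                        n_restarts, rng)
    # nested models: the pooled optimum is feasible under H1
    if ll1 < ll0:
        ll_fix, curves_fix, sad_fix, _ = _maximize(
            groups, labels, J, np.repeat(p0.as_array()[None, :], J, axis=0),
            sad0.phi, 1, rng)
        if ll_fix > ll1:
            ll1, curves1, sad1 = ll_fix, curves_fix, sad_fix

    converged = bool(ok0 and ok1)
    if not converged:
        flags.append("non_converged")
    return FunMapResult(
        marker_id=geno.marker_id,
        class_codes=keep_codes.astype(np.int64),
        class_sizes=class_sizes,
        genotype_params=[GrowthParams(*c) for c in curves1],
        null_params=p0,
        sad=sad1,
        sad_null=sad0,
        loglik_h1=float(ll1),
        loglik_h0=float(ll0),
        converged=converged,
        flags=flags,
    )


def lr_test(result: FunMapResult) -> tuple[float, float]:
    """LR statistic and nominal chi-square p-value (df = 3*(J-1)).

    The chi-square reference is advisory; permutation thresholds are the
    primary genome-wide calibration.
    """
    lr = result.lr
    df = 3 * (result.J - 1)
    p = float(stats.chi2.sf(lr, df)) if lr > 0 else 1.0
    return lr, p


# ---------------------------------------------------------------------------
# scan + permutation threshold
# ---------------------------------------------------------------------------

def scan(
    trait: LongitudinalTrait,
    genotypes: GenotypeMatrix,
    *,
    min_class_size: int = 3,
    n_restarts: int = 5,
    seed: int | None = None,
    n_jobs: int = 1,
) -> list[FunMapResult | None]:
    """Fit every marker; entries are None where a marker is unfittable
    (insufficient classes) or the optimizer failed outright."""
    rng = np.random.default_rng(seed)
    groups = _GridGroups(trait)
    # the pooled (H0) fit only depends on which individuals are retained;
    # cache it per retained-set so fully observed markers share one fit
    null_cache: dict[bytes, tuple] = {}

    def fit_one(idx: int, child_seed: int) -> FunMapResult | None:
        g = genotypes.vector(idx)
        obs = g.observed()
        uniq, counts = np.unique(g.codes[obs], return_counts=True)
        keepc = uniq[counts >= min_class_size]
        if keepc.size < 2:
            return None
        keep = obs & np.isin(g.codes, keepc)
        key = keep.tobytes()
        if key not in null_cache:
            sub = groups.restrict(keep)
            t_all = np.concatenate([t[None].repeat(Y.shape[0], 0).ravel()
                                    for _, t, Y in sub.groups])
            y_all = np.concatenate([Y.ravel() for _, _, Y in sub.groups])
            null_cache[key] = _fit_null(sub, t_all, y_all, n_restarts,
                                        np.random.default_rng(child_seed))
        try:
            return fit_marker(
                trait, g, min_class_size=min_class_size, n_restarts=n_restarts,
                rng=np.random.default_rng(child_seed ^ 0x5F5F), _groups=groups,
                _null_fit=null_cache[key])
        except ValueError:
            return None

    child_seeds = rng.integers(0, 2**31 - 1, size=genotypes.m)
    if n_jobs != 1:
        from joblib import Parallel, delayed
        # null cache is per-worker; results merged in marker order
        return list(Parallel(n_jobs=n_jobs)(
            delayed(fit_one)(i, int(s)) for i, s in enumerate(child_seeds)))
    return [fit_one(i, int(s)) for i, s in enumerate(child_seeds)]


def max_lr(results: Sequence[FunMapResult | None]) -> float:
    vals = [r.lr for r in results if r is not None and r.converged]
    return max(vals) if vals else 0.0


def permutation_threshold(
    trait: LongitudinalTrait,
    genotypes: GenotypeMatrix,
    B: int,
    alpha: float = 0.05,
    *,
    min_class_size: int = 3,
    n_restarts: int = 2,
    seed: int | None = None,
    n_jobs: int = 1,
) -> tuple[float, NDArray[np.float64]]:
    """Genome-wide LR threshold from permutation of trajectory assignments.

    Each permutation shuffles which individual carries which trajectory
    (trajectories stay intact), reruns the full scan and records the
    genome-wide maximum LR; the threshold is the empirical (1 - alpha)
    quantile of the B maxima.  Returns (threshold, maxima).
    """
    if B < 10:
        raise ValueError(f"at least 10 permutations required, got B={B}")
    if B < 100:
        logger.warning("permutation count B=%d is below the recommended 100", B)
    rng = np.random.default_rng(seed)
    maxima = np.empty(B)
    for b in range(B):
        perm = rng.permutation(trait.n)
        res = scan(trait.permuted(perm), genotypes,
                   min_class_size=min_class_size, n_restarts=n_restarts,
                   seed=int(rng.integers(0, 2**31 - 1)), n_jobs=n_jobs)
        maxima[b] = max_lr(res)
    return float(np.quantile(maxima, 1.0 - alpha)), maxima


# ---------------------------------------------------------------------------
# effect curves + plasticity
# ---------------------------------------------------------------------------

def effect_curve(result: FunMapResult, grid: TimeGrid) -> EffectCurve:
    """Age-varying genetic standard deviation of a fitted marker.

    Uses observed genotype-class frequencies n_j / n as weights.
    """
    n = int(result.class_sizes.sum())
    mus = np.vstack([logistic_mean_arr(grid.times, p.a, p.b, p.r)
                     for p in result.genotype_params])
    w = result.class_sizes / n
    mu_bar = w @ mus
    z = np.sqrt(np.sum(w[:, None] * (mus - mu_bar) ** 2, axis=0))
    return EffectCurve(curve_id=result.marker_id, grid=grid, values=z)


def plasticity_trait(
    stress: LongitudinalTrait, control: LongitudinalTrait
) -> LongitudinalTrait:
    """Phenotypic plasticity: control minus stress trajectory per individual.

    Larger values mean growth suffers more under stress.  Individuals present
    in only one condition are excluded (logged).  Mismatched grids are
    linearly interpolated onto the sorted union of ages inside the overlap of
    the two grids' ranges.
    """
    by_id_s = {i: k for k, i in enumerate(stress.ids)}
    by_id_c = {i: k for k, i in enumerate(control.ids)}
    shared = [i for i in control.ids if i in by_id_s]
    missing = set(control.ids).symmetric_difference(stress.ids)
    for iid in sorted(missing):
        logger.info("plasticity: individual %s present in only one condition, excluded", iid)

    ids, grids, values = [], [], []
    for iid in shared:
        ts = stress.grids[by_id_s[iid]].times
        tc = control.grids[by_id_c[iid]].times
        ys = stress.values[by_id_s[iid]]
        yc = control.values[by_id_c[iid]]
        if ts.size == tc.size and np.allclose(ts, tc):
            t, d = ts, yc - ys
        else:
            lo, hi = max(ts[0], tc[0]), min(ts[-1], tc[-1])
            t = np.unique(np.concatenate([ts, tc]))
            t = t[(t >= lo) & (t <= hi)]
            if t.size < 3:
                logger.info("plasticity: individual %s has <3 overlapping ages, excluded", iid)
                continue
            d = np.interp(t, tc, yc) - np.interp(t, ts, ys)
        ids.append(iid)
        grids.append(TimeGrid(t))
        values.append(d)
    return LongitudinalTrait(ids=ids, grids=grids, values=values)
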