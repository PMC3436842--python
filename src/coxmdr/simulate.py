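"""Synthetic epistasis cohorts and power / type-I-error benchmarks.

The generator emulates a two-locus pure-epistasis disease architecture:
a 3x3 penetrance function f (probability of high-risk status given the
two-locus genotype) with essentially no marginal effects at either locus,
built under Hardy-Weinberg and linkage equilibrium for a target
heritability h2 = sum_g P(g) (f(g) - K)^2 / (K (1 - K)), K the high-risk
prevalence.  Survival times follow a Cox-Weibull model

    lambda(t) = lambda0(t) exp(beta * x + gamma * z),
    Lambda0(t) = (t / scale)^shape,

with x the (hidden) high-risk indicator drawn from the penetrance
function, z a normal covariate, and independent uniform censoring.
Cohorts carry the two causal SNPs at seeded random positions among
independent null SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort
from .mdr import CoxMDR
from .survival import ConvergenceError, DegenerateDataError, fit_cox_single_snp
from .survmdr import SurvMDR

__all__ = [
    "PenetranceModel",
    "SimConfig",
    "hwe_probs",
    "heritability",
    "generate_penetrance",
    "generate_model_grid",
    "simulate_cohort",
    "simulate_null_cohort",
    "PowerEstimate",
    "estimate_power",
    "estimate_type1",
]


def hwe_probs(maf: float) -> np.ndarray:
    """Genotype probabilities (0, 1, 2 minor alleles) under HWE."""
    p = float(maf)
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])


@dataclass
class PenetranceModel:
    """Two-locus penetrance function with its population summaries."""

    f: np.ndarray          # 3x3, rows = locus-1 genotype, cols = locus-2
    maf: float
    prevalence: float
    h2: float

    def joint_probs(self) -> np.ndarray:
        q = hwe_probs(self.maf)
        return np.outer(q, q)


def heritability(f, maf: float):
    """Heritability of the high-risk status scale.

    K = sum_g P(g) f(g);  h2 = sum_g P(g) (f(g) - K)^2 / (K (1 - K)),
    with P(g) the HWE x HWE joint genotype probability.
    Returns (h2, K).
    """
    f = np.asarray(f, dtype=float)
    P = np.outer(hwe_probs(maf), hwe_probs(maf))
    K = float((P * f).sum())
    if K <= 0.0 or K >= 1.0:
        raise DegenerateDataError(f"prevalence K={K} leaves h2 undefined")
    h2 = float((P * (f - K) ** 2).sum() / (K * (1 - K)))
    return h2, K


class PenetranceSearchError(RuntimeError):
    """Raised when no feasible penetrance model is found within max_tries."""


def _zero_marginal_projection(D, q):
    """Weighted double-centering: remove both loci's marginal effects."""
    a = (D * q[None, :]).sum(axis=1)
    b = (D * q[:, None]).sum(axis=0)
    g = float(q @ D @ q)
    return D - a[:, None] - b[None, :] + g


def _marginal_constraints(q):
    """Rows of the linear system forcing zero HWE-weighted marginals."""
    A = []
    for i in range(3):
        row = np.zeros((3, 3))
        row[i, :] = q
        A.append(row.ravel())
    for k in range(3):
        col = np.zeros((3, 3))
        col[:, k] = q
        A.append(col.ravel())
    return np.array(A)


def generate_penetrance(maf: float, h2_target: float, seed=0,
                        tol: float = 0.01, marginal_eps: float = 0.01,
                        max_tries: int = 200, dir_tries: int = 150,
                        prevalence_range=(0.01, 0.5)) -> PenetranceModel:
    """Random search for a pure-epistasis penetrance model.

    Each restart draws a prevalence K uniformly over ``prevalence_range``
    and then searches for a deviation pattern: random 3x3 tables (weighted
    towards rarer genotype cells, where classic pure-epistasis catalogues
    put their extreme penetrances) are projected onto the subspace with
    zero HWE-weighted marginals at both loci and rescaled so the
    heritability lands exactly on target; a draw is accepted when all nine
    penetrances lie in [0, 1].  Near the feasibility frontier (high h2 at
    low K), random directions rarely land inside the box, so the search
    falls back to scaled vertices of the constraint polytope found by
    linear programming with random objectives.  Sampling K first and then
    exhausting directions keeps the accepted prevalence roughly uniform
    over its feasible range instead of concentrating where the feasible
    region is largest.
    """
    from scipy.optimize import linprog

    rng = np.random.default_rng(seed)
    q = hwe_probs(maf)
    P = np.outer(q, q)
    Aeq = _marginal_constraints(q)
    best_dev = np.inf

    def _accept(f):
        nonlocal best_dev
        h2, K_chk = heritability(f, maf)
        m1 = (f * q[None, :]).sum(axis=1)
        m2 = (f * q[:, None]).sum(axis=0)
        mrange = max(np.ptp(m1), np.ptp(m2))
        if abs(h2 - h2_target) <= tol and mrange <= marginal_eps:
            return PenetranceModel(f, maf, K_chk, h2)
        best_dev = min(best_dev, abs(h2 - h2_target))
        return None

    for _ in range(max_tries):
        K = rng.uniform(*prevalence_range)
        v_target = h2_target * K * (1 - K)
        for _ in range(dir_tries):
            D = _zero_marginal_projection(rng.standard_normal((3, 3)) / np.sqrt(P), q)
            v = float((P * D * D).sum())
            if v < 1e-12:
                continue
            f = K + np.sqrt(v_target / v) * D
            if (f >= 0).all() and (f <= 1).all():
                model = _accept(f)
                if model is not None:
                    return model
        # frontier fallback: scaled random vertices of the feasible polytope
        for _ in range(40):
            c = rng.standard_normal(9)
            res = linprog(-c, A_eq=Aeq, b_eq=np.zeros(6),
                          bounds=[(-K, 1 - K)] * 9, method="highs")
            if res.status != 0:
                continue
            d = res.x.reshape(3, 3)
            v = float((P * d * d).sum())
            if v >= v_target > 0:
                model = _accept(K + np.sqrt(v_target / v) * d)
                if model is not None:
                    return model
    raise PenetranceSearchError(
        f"no penetrance model with h2={h2_target} (maf={maf}) within "
        f"{max_tries} restarts; best |h2 - target| achieved: {best_dev:.4g}"
    )


def generate_model_grid(mafs=(0.2, 0.4), h2s=(0.1, 0.2, 0.3, 0.4),
                        models_per_combo: int = 5, seed: int = 0,
                        **kwargs):
    """The benchmark grid: ``models_per_combo`` models for every (maf, h2)
    combination, as a dict {(maf, h2): [PenetranceModel, ...]}."""
    rng = np.random.default_rng(seed)
    grid = {}
    for maf in mafs:
        for h2 in h2s:
            grid[(maf, h2)] = [
                generate_penetrance(maf, h2, seed=int(rng.integers(2**31)),
                                    **kwargs)
                for _ in range(models_per_combo)
            ]
    return grid


@dataclass
class SimConfig:
    """Cox-Weibull cohort simulation settings.

    ``covariate_sd`` defaults to sqrt(0.5): the z ~ N(0, 0.5) covariate is
    read as variance 0.5.
    """

    n_high: int = 200
    n_low: int = 200
    beta: float = 1.0
    gamma: float = 0.0
    covariate_sd: float = float(np.sqrt(0.5))
    weibull_shape: float = 5.0
    weibull_scale: float = 2.0
    censor_upper: float = 4.0
    n_null_snps: int = 8

    def __post_init__(self):
        if min(self.weibull_shape, self.weibull_scale, self.censor_upper) <= 0:
            raise ValueError("Weibull and censoring parameters must be positive")
        if self.n_high < 1 or self.n_low < 1:
            raise ValueError("need at least one subject per risk group")


def _draw_risk_groups(model: PenetranceModel, n_high, n_low, rng,
                      max_draws: int = 2_000_000):
    """Rejection-sample two-locus genotypes and risk status to quota."""
    probs = model.joint_probs().ravel()
    f_flat = model.f.ravel()
    got_high = []
    got_low = []
    drawn = 0
    while (len(got_high) < n_high or len(got_low) < n_low):
        if drawn >= max_draws:
            raise PenetranceSearchError(
                "risk-group quota unreachable (penetrance too extreme): "
                f"{len(got_high)}/{n_high} high, {len(got_low)}/{n_low} low "
                f"after {drawn} draws"
            )
        m = max(4 * (n_high + n_low), 1000)
        cells = rng.choice(9, size=m, p=probs)
        x = rng.random(m) < f_flat[cells]
        drawn += m
        for c in cells[x][: n_high - len(got_high)]:
            got_high.append(c)
        for c in cells[~x][: n_low - len(got_low)]:
            got_low.append(c)
    cells = np.array(got_high + got_low)
    x = np.concatenate([np.ones(n_high, bool), np.zeros(n_low, bool)])
    g1, g2 = cells % 3, cells // 3
    return g1.astype(np.int8), g2.astype(np.int8), x


def simulate_cohort(model: PenetranceModel, config: SimConfig = None,
                    seed: int = 0):
    """Simulate one benchmark cohort.

    Returns (cohort, truth) where truth records the causal SNP column
    indices, the hidden risk indicator x and the generating parameters.
    Survival times use the inverse-transform for Lambda0(t) = (t/scale)^shape:
    T = scale * (-log U / exp(beta x + gamma z))^(1/shape).
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    n = config.n_high + config.n_low
    g1, g2, x = _draw_risk_groups(model, config.n_high, config.n_low, rng)
    null_probs = hwe_probs(model.maf)
    G_null = rng.choice(3, size=(n, config.n_null_snps), p=null_probs)
    n_snps = config.n_null_snps + 2
    causal = rng.choice(n_snps, size=2, replace=False)
    G = np.empty((n, n_snps), dtype=np.int8)
    null_cols = [j for j in range(n_snps) if j not in set(causal.tolist())]
    G[:, null_cols] = G_null
    G[:, causal[0]] = g1
    G[:, causal[1]] = g2

    z = rng.normal(0.0, config.covariate_sd, size=n)
    eta = config.beta * x + config.gamma * z
    u = rng.random(n)
    T = config.weibull_scale * (-np.log(u) / np.exp(eta)) ** (1.0 / config.weibull_shape)
    C = rng.uniform(0.0, config.censor_upper, size=n)
    time = np.minimum(T, C)
    status = (T <= C).astype(np.int8)
    # shuffle so risk groups are not block-ordered
    perm = rng.permutation(n)
    cohort = Cohort(
        ids=np.array([f"s{i:05d}" for i in range(n)]),
        time=time[perm],
        status=status[perm],
        covariates=z[perm, None],
        genotypes=G[perm],
        covariate_names=["z"],
        snp_names=[f"snp{j}" for j in range(n_snps)],
    )
    truth = {
        "causal": tuple(sorted(int(c) for c in causal)),
        "x": x[perm],
        "model": model,
        "config": config,
    }
    return cohort, truth


def simulate_null_cohort(model: PenetranceModel, config: SimConfig = None,
                         seed: int = 0, n_snps: int | None = None):
    """A null cohort: survival still depends on the hidden risk status, but
    the causal genotype columns are removed.

    ``n_snps`` = 8 (default) leaves the 8 null SNPs; 10 appends fresh null
    stand-ins in the causal columns' place so the candidate geometry (45
    pairs) matches the full benchmark.
    """
    config = config or SimConfig()
    cohort, truth = simulate_cohort(model, config, seed)
    if n_snps is None or n_snps == config.n_null_snps:
        out = cohort.drop_snps(truth["causal"])
    elif n_snps == config.n_null_snps + 2:
        rng = np.random.default_rng((int(seed) * 2654435761 + 17) % 2**31)
        G = cohort.genotypes.copy()
        for j in truth["causal"]:
            G[:, j] = rng.choice(3, size=cohort.n, p=hwe_probs(model.maf))
        out = Cohort(cohort.ids, cohort.time, cohort.status, cohort.covariates,
                     G, list(cohort.covariate_names), list(cohort.snp_names))
    else:
        raise ValueError("n_snps must be n_null_snps or n_null_snps + 2")
    truth = dict(truth, causal=None)
    return out, truth


# ----------------------------------------------------------------------
# Power and type-I error.


@dataclass
class PowerEstimate:
    """Monte-Carlo power (or type-I) estimate with its binomial SE."""

    method: str
    power: float
    n_datasets: int
    n_success: int
    n_failed: int = 0
    per_model: list = field(default_factory=list)

    @property
    def se(self) -> float:
        p, n = self.power, self.n_datasets
        return float(np.sqrt(p * (1 - p) / n)) if n else float("nan")


def _success_coxmdr(cohort, truth, adjust, folds, repeats, seed):
    covs = ["z"] if adjust else None
    res = CoxMDR(cohort, k=2, covariates=covs).fit(folds=folds,
                                                   repeats=repeats, seed=seed)
    return tuple(sorted(res.best.snp_indices)) == truth["causal"]


def _success_survmdr(cohort, truth, adjust, folds, repeats, seed):
    res = SurvMDR(cohort, k=2).fit(folds=folds, repeats=repeats, seed=seed)
    return tuple(sorted(res.best.snp_indices)) == truth["causal"]


def _success_coxreg(cohort, truth, adjust, folds, repeats, seed):
    covs = ["z"] if adjust else None
    for j in truth["causal"]:
        if fit_cox_single_snp(cohort, j, covs)["wald_p"] >= 0.05:
            return False
    return True


_METHODS = {
    "coxmdr": _success_coxmdr,
    "survmdr": _success_survmdr,
    "coxreg": _success_coxreg,
}


def estimate_power(method: str, models, n_datasets: int = 100,
                   config: SimConfig = None, adjust: bool = False,
                   seed: int = 0, folds: int = 10,
                   repeats: int = 10) -> PowerEstimate:
    """Monte-Carlo power of a method over a set of penetrance models.

    Success per dataset: for the MDR methods, the causal pair tops the
    two-way ranking; for the univariate Cox screen, both causal SNPs reach
    Wald p < 0.05.  The reported power averages over models (each model
    contributes ``n_datasets`` datasets).  Dataset-level method failures
    are excluded with a warning, never silently.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}")
    config = config or SimConfig()
    success_fn = _METHODS[method]
    rng = np.random.default_rng(seed)
    per_model = []
    total_succ = total_n = total_fail = 0
    for model in models:
        succ = used = 0
        for _ in range(n_datasets):
            ds_seed = int(rng.integers(2**31))
            cohort, truth = simulate_cohort(model, config, ds_seed)
            try:
                ok = success_fn(cohort, truth, adjust, folds, repeats,
                                int(rng.integers(2**31)))
            except (ConvergenceError, DegenerateDataError) as exc:
                total_fail += 1
                warnings.warn(f"{method} failed on one dataset: {exc}")
                continue
            succ += int(ok)
            used += 1
        per_model.append(succ / used if used else float("nan"))
        total_succ += succ
        total_n += used
    power = total_succ / total_n if total_n else float("nan")
    return PowerEstimate(method, power, total_n, total_succ, total_fail,
                         per_model)


def estimate_type1(models, n_null_datasets: int = 800,
                   config: SimConfig = None, seed: int = 0,
                   n_snps: int | None = None, adjust: bool = False,
                   folds: int = 10, repeats: int = 10,
                   designated_pair=(0, 1)) -> PowerEstimate:
    """Type-I error of the Cox-MDR search on null data.

    Null datasets (no SNP associated with survival) are generated by
    cycling over ``models``; the estimate is the fraction of datasets in
    which the pre-designated null pair is returned as the best two-way
    model.  Under exchangeability this is 1 / C(n_snps, 2).
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    designated = tuple(sorted(designated_pair))
    succ = used = failed = 0
    covs = ["z"] if adjust else None
    for i in range(n_null_datasets):
        model = models[i % len(models)]
        cohort, _ = simulate_null_cohort(model, config,
                                         int(rng.integers(2**31)), n_snps)
        try:
            res = CoxMDR(cohort, k=2, covariates=covs).fit(
                folds=folds, repeats=repeats, seed=int(rng.integers(2**31)))
        except (ConvergenceError, DegenerateDataError) as exc:
            failed += 1
            warnings.warn(f"type-I dataset failed: {exc}")
            continue
        succ += int(tuple(sorted(res.best.snp_indices)) == designated)
        used += 1
    rate = succ / used if used else float("nan")
    return PowerEstimate("coxmdr-type1", rate, used, succ, failed)
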