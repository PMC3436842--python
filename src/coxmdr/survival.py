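"""Cox proportional-hazards machinery.

Null-model fitting with Breslow ties and the Breslow baseline cumulative
hazard, martingale residuals, the two-sample log-rank statistic, per-SNP
univariate Cox screening, and Benjamini-Hochberg FDR adjustment.

The martingale residual under the covariate-only (no-SNP) model,

    M_i = delta_i - Lambda0(T_i) * exp(gamma' Z_i),

is the observed-minus-expected event count for subject *i* and is the score
the Cox-MDR classifier thresholds.  The Breslow baseline makes the residuals
sum to zero exactly, which fixes the natural classification threshold at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import Cohort

__all__ = [
    "ConvergenceError",
    "MonotoneLikelihoodError",
    "DegenerateDataError",
    "CoxFit",
    "CoxNullFit",
    "CumulativeHazard",
    "cox_fit",
    "fit_cox_null",
    "logrank",
    "logrank_cells",
    "LogrankResult",
    "fit_cox_single_snp",
    "cox_snp_screen",
    "bh_fdr",
]


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge within the iteration cap."""


class MonotoneLikelihoodError(ConvergenceError):
    """Monotone partial likelihood (perfect separation): no finite MLE."""


class DegenerateDataError(ValueError):
    """Input data cannot support the requested fit or test."""


# ----------------------------------------------------------------------
# Risk-set bookkeeping shared by the fitter and the log-rank statistic.


def _event_groups(time, status):
    """Sort by time and locate tied-time groups.

    Returns (order, first, d_g, n_g): the ascending-time permutation, the
    start index of each unique time group, the number of events per group
    and the at-risk count per group.
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    order = np.argsort(time, kind="stable")
    t = time[order]
    _, first = np.unique(t, return_index=True)
    d_g = np.add.reduceat(status[order].astype(float), first)
    n_g = len(t) - first
    return order, first, d_g, n_g


def _revcumsum(a):
    return np.cumsum(a[::-1], axis=0)[::-1]


# ----------------------------------------------------------------------
# Cox partial-likelihood fitting (Newton-Raphson, Breslow or Efron ties).


@dataclass
class CumulativeHazard:
    """Right-continuous step function Lambda0 with jumps at event times."""

    times: np.ndarray
    jumps: np.ndarray

    def __call__(self, t):
        cum = np.concatenate([[0.0], np.cumsum(self.jumps)])
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        return cum[idx]


@dataclass
class CoxFit:
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    baseline: CumulativeHazard
    n_iter: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald_p(self, j: int = 0) -> float:
        z = self.coef[j] / self.se[j]
        return float(2.0 * stats.norm.sf(abs(z)))


def _breslow_quantities(beta, Xs, es, first, d_g):
    """Log partial likelihood, score and information (Breslow ties)."""
    eta = Xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]
    S0 = _revcumsum(w)[first]
    S1 = _revcumsum(wx)[first]
    S2 = _revcumsum(wxx)[first]
    ev = d_g > 0
    loglik = float(es @ eta - d_g[ev] @ np.log(S0[ev]))
    xbar = S1[ev] / S0[ev][:, None]
    score = (es[:, None] * Xs).sum(axis=0) - d_g[ev] @ xbar
    v = S2[ev] / S0[ev][:, None, None] - xbar[:, :, None] * xbar[:, None, :]
    info = np.einsum("g,gij->ij", d_g[ev], v)
    return loglik, score, info


def _efron_quantities(beta, Xs, es, first, d_g):
    """As above but with Efron's tie correction (loop over event groups)."""
    eta = np.clip(Xs @ beta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]
    cS0, cS1, cS2 = _revcumsum(w), _revcumsum(wx), _revcumsum(wxx)
    n = len(es)
    p = Xs.shape[1]
    loglik = float(es @ eta)
    score = (es[:, None] * Xs).sum(axis=0)
    info = np.zeros((p, p))
    bounds = np.append(first, n)
    for g in range(len(first)):
        d = int(round(d_g[g]))
        if d == 0:
            continue
        lo, hi = bounds[g], bounds[g + 1]
        tied = slice(lo, hi)
        mask = es[tied] > 0
        T0 = w[tied][mask].sum()
        T1 = wx[tied][mask].sum(axis=0)
        T2 = wxx[tied][mask].sum(axis=0)
        for ell in range(d):
            c = ell / d
            D0 = cS0[lo] - c * T0
            D1 = cS1[lo] - c * T1
            D2 = cS2[lo] - c * T2
            loglik -= np.log(D0)
            xbar = D1 / D0
            score -= xbar
            info += D2 / D0 - np.outer(xbar, xbar)
    return loglik, score, info


def cox_fit(
    time,
    status,
    X,
    *,
    ties: str = "breslow",
    max_iter: int = 60,
    tol_score: float = 1e-8,
    tol_loglik: float = 1e-10,
    coef_bound: float = 50.0,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Convergence is declared when the score's max-norm falls below
    ``tol_score`` or the relative log-likelihood change falls below
    ``tol_loglik``.  A coefficient drifting past ``coef_bound`` is taken
    as evidence of a monotone likelihood (perfect separation).
    """
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    n, p = X.shape
    if status.sum() == 0:
        raise DegenerateDataError("no events: Cox regression undefined")
    order, first, d_g, n_g = _event_groups(time, status)
    Xs, es = X[order], status[order]
    quant = _breslow_quantities if ties == "breslow" else _efron_quantities

    beta = np.zeros(p)
    loglik, score, info = quant(beta, Xs, es, first, d_g)
    loglik_null = loglik
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise DegenerateDataError(
                "singular information matrix (constant or collinear predictors)"
            ) from None
        # step-halving line search to keep the likelihood non-decreasing
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, sc_new, info_new = quant(cand, Xs, es, first, d_g)
            if ll_new >= loglik - 1e-12:
                break
            factor /= 2.0
        beta, score, info = cand, sc_new, info_new
        if np.max(np.abs(beta)) > coef_bound:
            raise MonotoneLikelihoodError(
                "monotone partial likelihood: coefficient diverged "
                f"beyond {coef_bound} (perfectly separating predictor?)"
            )
        rel = abs(ll_new - loglik) / (abs(loglik) + 1e-12)
        loglik = ll_new
        if np.max(np.abs(score)) < tol_score or rel < tol_loglik:
            break
    else:
        raise ConvergenceError(
            f"Cox Newton-Raphson did not converge in {max_iter} iterations"
        )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise DegenerateDataError("singular information matrix at optimum") from None
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    # a "converged" fit at the likelihood supremum: large coefficient with an
    # exploding standard error means the partial likelihood is monotone
    if ((np.abs(beta) > 10.0) & (se > 100.0)).any():
        raise MonotoneLikelihoodError(
            "monotone partial likelihood: no finite estimate "
            "(perfectly separating predictor?)"
        )
    baseline = _breslow_baseline(time, status, X, beta, order, first, d_g)
    return CoxFit(beta, cov, loglik, loglik_null, baseline, n_iter)


def _breslow_baseline(time, status, X, beta, order, first, d_g):
    """Breslow estimator: jump d_t / sum_{at risk} exp(eta) at each event time."""
    eta = X @ beta if X.shape[1] else np.zeros(len(time))
    w = np.exp(np.clip(eta, -500, 500))[order]
    S0 = _revcumsum(w)[first]
    t_sorted = np.sort(np.unique(time))
    ev = d_g > 0
    return CumulativeHazard(times=t_sorted[ev], jumps=d_g[ev] / S0[ev])


# ----------------------------------------------------------------------
# Null (no-SNP) model and martingale residuals.


@dataclass
class CoxNullFit:
    """Covariate-only Cox fit used to produce the martingale-residual score."""

    gamma: np.ndarray
    cum_baseline: CumulativeHazard
    residuals: np.ndarray
    loglik: float
    covariate_cols: list

    @property
    def case_status(self) -> np.ndarray:
        """Residual-sign pseudo case status: M_i > 0 is a case."""
        return self.residuals > 0


def fit_cox_null(cohort: Cohort, covariates=None, *, ties: str = "breslow") -> CoxNullFit:
    """Fit the reduced (no-SNP) Cox model and return martingale residuals.

    With no covariates the baseline reduces to the Nelson-Aalen estimator
    and the fit is closed-form.  With covariates at least one event is
    required.
    """
    cols = cohort.covariate_indices(covariates)
    Z = cohort.covariates[:, cols]
    if not np.isfinite(Z).all():
        raise DegenerateDataError("non-finite covariate values")
    if Z.shape[1] == 0:
        order, first, d_g, n_g = _event_groups(cohort.time, cohort.status)
        ev = d_g > 0
        t_sorted = np.sort(np.unique(cohort.time))
        baseline = CumulativeHazard(times=t_sorted[ev], jumps=d_g[ev] / n_g[ev])
        gamma = np.empty(0)
        # log partial likelihood at beta=0 (Breslow): sum_t d_t * -log(n_t)
        loglik = float(-(d_g[ev] * np.log(n_g[ev])).sum())
        eta = np.zeros(cohort.n)
    else:
        if cohort.n_events == 0:
            raise DegenerateDataError(
                "no events: cannot fit covariate-adjusted null model"
            )
        fit = cox_fit(cohort.time, cohort.status, Z, ties=ties)
        gamma, baseline, loglik = fit.coef, fit.baseline, fit.loglik
        eta = Z @ gamma
    residuals = cohort.status - baseline(cohort.time) * np.exp(eta)
    return CoxNullFit(gamma, baseline, residuals, loglik, cols)


# ----------------------------------------------------------------------
# Log-rank statistics.


def logrank_cells(time, status, member):
    """Column-wise two-sample log-rank ingredients: group vs complement.

    ``member`` is an (n, C) indicator matrix; for every column the
    observed-minus-expected event count in the member group and its
    hypergeometric variance are accumulated over the risk-set table.

    Returns (o_minus_e, variance), each of length C.
    """
    member = np.asarray(member, dtype=float)
    if member.ndim == 1:
        member = member[:, None]
    order, first, d_g, n_g = _event_groups(time, status)
    m = member[order]
    es = np.asarray(status)[order].astype(float)
    n_cg = _revcumsum(m)[first]            # at-risk per column per time group
    d_cg = np.add.reduceat(es[:, None] * m, first, axis=0)
    ev = d_g > 0
    d_t, n_t = d_g[ev], n_g[ev].astype(float)
    frac = n_cg[ev] / n_t[:, None]
    o_minus_e = (d_cg[ev] - d_t[:, None] * frac).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vt = np.where(n_t > 1, d_t * (n_t - d_t) / (n_t - 1), 0.0)
    variance = (vt[:, None] * frac * (1.0 - frac)).sum(axis=0)
    return o_minus_e, variance


@dataclass
class LogrankResult:
    observed_minus_expected: float
    variance: float
    chi_square: float
    p_value: float


def logrank(time, status, group) -> LogrankResult:
    """Two-sample log-rank test; the signed O-E gives the risk direction."""
    group = np.asarray(group, dtype=bool)
    status = np.asarray(status)
    if not group.any() or group.all():
        raise DegenerateDataError("log-rank requires two non-empty groups")
    if status.sum() == 0:
        raise DegenerateDataError("log-rank requires at least one event")
    ome, var = logrank_cells(time, status, group)
    ome, var = float(ome[0]), float(var[0])
    chi2 = ome * ome / var if var > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1)) if var > 0 else 1.0
    return LogrankResult(ome, var, chi2, p)


# ----------------------------------------------------------------------
# Univariate per-SNP Cox screen and FDR.


def fit_cox_single_snp(cohort: Cohort, snp, covariates=None, *, ties="breslow"):
    """Additive-coded single-SNP Cox fit, optionally covariate adjusted.

    Subjects missing the genotype are excluded.  Returns a dict with the
    SNP coefficient, its standard error from the observed information and
    the two-sided Wald p-value.
    """
    j = cohort.snp_index(snp)
    g = cohort.genotypes[:, j]
    keep = g != -1
    g = g[keep].astype(float)
    if len(np.unique(g)) < 2:
        raise DegenerateDataError(
            f"SNP {cohort.snp_names[j]!r} has fewer than 2 observed genotypes"
        )
    cols = cohort.covariate_indices(covariates)
    X = np.column_stack([g, cohort.covariates[keep][:, cols]])
    fit = cox_fit(cohort.time[keep], cohort.status[keep], X, ties=ties)
    return {
        "coef": float(fit.coef[0]),
        "se": float(fit.se[0]),
        "wald_p": fit.wald_p(0),
        "n_used": int(keep.sum()),
    }


def bh_fdr(p_values, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    ``m_total`` is the total number of tests performed; p-values not listed
    are assumed larger than every listed one (so only the denominator
    changes).  Adjusted values are returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise DegenerateDataError("p-values must lie in [0, 1]")
    m = len(p) if m_total is None else int(m_total)
    if m < len(p):
        raise DegenerateDataError("m_total smaller than number of p-values")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, len(p) + 1)
    raw = p[order] * m / ranks
    adj = np.minimum.accumulate(raw[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def cox_snp_screen(cohort: Cohort, covariates=None, m_total=None, *, ties="breslow"):
    """Univariate Cox scan over every SNP with BH-FDR adjustment.

    Returns a list of per-SNP dicts (snp, coef, se, p, fdr, note); SNPs
    whose fit fails carry the failure reason in ``note`` and NaN values,
    and are excluded from the FDR adjustment.
    """
    rows = []
    for j, name in enumerate(cohort.snp_names):
        try:
            r = fit_cox_single_snp(cohort, j, covariates, ties=ties)
            rows.append(
                {"snp": name, "coef": r["coef"], "se": r["se"],
                 "p": r["wald_p"], "note": ""}
            )
        except (DegenerateDataError, ConvergenceError) as exc:
            rows.append(
                {"snp": name, "coef": np.nan, "se": np.nan, "p": np.nan,
                 "note": str(exc)}
            )
    ok = [r for r in rows if np.isfinite(r["p"])]
    m = m_total if m_total is not None else len(ok)
    fdr = bh_fdr([r["p"] for r in ok], m) if ok else np.empty(0)
    for r, q in zip(ok, fdr):
        r["fdr"] = float(q)
    for r in rows:
        r.setdefault("fdr", np.nan)
    return rows
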