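"""Cox-MDR: martingale-residual multifactor dimensionality reduction.

The reduction collapses a k-SNP genotype table (3^k cells) into a binary
high/low-risk attribute: a cell is high-risk when the sum of martingale
residuals of the training subjects falling in it is >= 0.  Candidate SNP
combinations are ranked by cross-validated balanced accuracy against the
residual-sign pseudo case status (M_i > 0 = case), and the winning
attribute can be assessed by a permutation test on its Wald statistic in
a covariate-adjusted Cox model.

The heavy lifting is vectorised across candidate combinations: all
C(M, k) cell tables are scored simultaneously per cross-validation fold,
which is what makes the simulation benchmarks tractable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .survival import (
    ConvergenceError,
    CoxNullFit,
    DegenerateDataError,
    cox_fit,
    fit_cox_null,
)

__all__ = [
    "AttributeModel",
    "CVEvaluation",
    "assign_cells",
    "classify_cells",
    "balanced_accuracy",
    "fold_assignments",
    "evaluate_combo",
    "search_best",
    "permutation_pvalue",
    "PermutationResult",
    "CoxMDR",
    "CoxMDRResults",
]


# ----------------------------------------------------------------------
# Cell construction and classification.


def assign_cells(genotypes, snp_indices) -> np.ndarray:
    """Base-3 cell index per subject for a k-SNP combination.

    cell = sum_j g_j * 3**j over the tuple order; a subject missing any
    involved genotype gets -1 and is excluded downstream.
    """
    snp_indices = tuple(int(i) for i in snp_indices)
    if len(set(snp_indices)) != len(snp_indices):
        raise ValueError(f"duplicate SNP indices {snp_indices}")
    G = np.asarray(genotypes)
    if G.ndim == 1:
        G = G[:, None]
    codes = np.zeros(G.shape[0], dtype=np.int64)
    missing = np.zeros(G.shape[0], dtype=bool)
    for j, s in enumerate(snp_indices):
        col = G[:, s]
        missing |= col == -1
        codes += col.astype(np.int64) * 3**j
    codes[missing] = -1
    return codes


def _combo_codes(genotypes, combos) -> np.ndarray:
    """(n, P) cell-code matrix for a list of SNP tuples; -1 = missing."""
    return np.column_stack([assign_cells(genotypes, c) for c in combos])


def classify_cells(residuals, cells, k: int):
    """Label each of the 3^k cells high/low by its residual sum.

    high iff the within-cell sum of training residuals is >= 0; cells
    with no training subjects are labelled low (conservative default).
    Returns (labels, sums, counts) with labels a boolean array of length
    3^k (True = high risk).
    """
    ncells = 3**k
    cells = np.asarray(cells)
    valid = cells >= 0
    sums = np.bincount(cells[valid], weights=np.asarray(residuals, float)[valid],
                       minlength=ncells)
    counts = np.bincount(cells[valid], minlength=ncells)
    labels = (sums >= 0) & (counts > 0)
    return labels, sums, counts


def balanced_accuracy(predicted_high, is_case, *, return_flag: bool = False):
    """Mean of sensitivity and specificity.

    ``predicted_high`` and ``is_case`` are boolean arrays over the same
    subjects.  When one class is absent its term is 0 and the degeneracy
    flag is set; with both classes absent the quantity is undefined.
    """
    pred = np.asarray(predicted_high, dtype=bool)
    case = np.asarray(is_case, dtype=bool)
    npos = int(case.sum())
    nneg = int((~case).sum())
    if npos == 0 and nneg == 0:
        raise DegenerateDataError("balanced accuracy undefined: no subjects")
    sens = float((pred & case).sum() / npos) if npos else 0.0
    spec = float((~pred & ~case).sum() / nneg) if nneg else 0.0
    ba = 0.5 * (sens + spec)
    if return_flag:
        return ba, (npos == 0 or nneg == 0)
    return ba


# ----------------------------------------------------------------------
# Cross-validation scaffolding (shared with the Surv-MDR comparator).


def fold_assignments(n, folds, repeats, seed, stratify=None) -> np.ndarray:
    """Seeded fold ids, shape (repeats, n), stratified round-robin.

    Subjects are shuffled within each stratum and dealt cyclically across
    folds with a counter carried over strata, so fold sizes stay balanced
    and folds = n yields a leave-one-out partition.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"cannot split {n} subjects into {folds} folds")
    rng = np.random.default_rng(seed)
    strata = (np.zeros(n, dtype=int) if stratify is None
              else np.asarray(stratify).astype(int))
    out = np.empty((repeats, n), dtype=np.int32)
    for r in range(repeats):
        counter = 0
        for s in np.unique(strata):
            idx = np.flatnonzero(strata == s)
            idx = rng.permutation(idx)
            out[r, idx] = (np.arange(counter, counter + len(idx))) % folds
            counter += len(idx)
    return out


def _cv_scores(residuals, case, codes, ncells, fold_ids):
    """Vectorised CV of every candidate simultaneously.

    codes: (n, P) cell codes (-1 missing); fold_ids: (R, n).
    Returns train_ba, test_ba arrays of shape (R, F, P) with NaN for
    folds where a candidate had no scorable test subject, and
    fold_best (R, F) -- the training-BA argmax per fold.
    """
    residuals = np.asarray(residuals, dtype=float)
    case = np.asarray(case, dtype=bool)
    n, P = codes.shape
    R = fold_ids.shape[0]
    F = int(fold_ids.max()) + 1
    valid = codes >= 0
    flat = codes + ncells * np.arange(P)[None, :]
    flat = np.where(valid, flat, 0)

    train_ba = np.full((R, F, P), np.nan)
    test_ba = np.full((R, F, P), np.nan)
    fold_best = np.zeros((R, F), dtype=np.int64)
    for r in range(R):
        for f in range(F):
            te = fold_ids[r] == f
            tr = ~te
            labels = _train_labels(residuals, flat, valid, tr, P, ncells)
            pred = labels.ravel()[flat] & valid
            trb = _ba_block(pred[tr], valid[tr], case[tr])
            teb = _ba_block(pred[te], valid[te], case[te])
            train_ba[r, f] = trb
            test_ba[r, f] = teb
            fold_best[r, f] = int(np.argmax(np.where(np.isnan(trb), -np.inf, trb)))
    return train_ba, test_ba, fold_best


def _train_labels(residuals, flat, valid, tr, P, ncells):
    ftr = flat[tr]
    vtr = valid[tr]
    w = np.repeat(residuals[tr], P).reshape(ftr.shape)
    sums = np.bincount(ftr[vtr], weights=w[vtr], minlength=P * ncells)
    counts = np.bincount(ftr[vtr], minlength=P * ncells)
    return ((sums >= 0) & (counts > 0)).reshape(P, ncells)


def _ba_block(pred, valid, case):
    """Balanced accuracy per candidate column over one subject subset."""
    pos = case.astype(float)
    neg = (~case).astype(float)
    predv = (pred & valid).astype(float)
    npredv = (~pred & valid).astype(float)
    TP = pos @ predv
    FN = pos @ npredv
    FP = neg @ predv
    TN = neg @ npredv
    npos = TP + FN
    nneg = FP + TN
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(npos > 0, TP / npos, 0.0)
        spec = np.where(nneg > 0, TN / nneg, 0.0)
    ba = 0.5 * (sens + spec)
    return np.where(npos + nneg > 0, ba, np.nan)


# ----------------------------------------------------------------------
# Public evaluation objects.


@dataclass
class AttributeModel:
    """A k-SNP combination with its high/low cell labelling."""

    snp_indices: tuple
    cell_labels: np.ndarray  # bool, length 3**k, True = high risk
    k: int

    def predict(self, genotypes) -> np.ndarray:
        """High/low attribute per subject; missing genotypes give False
        with the accompanying valid mask from :func:`attribute_with_mask`."""
        codes = assign_cells(genotypes, self.snp_indices)
        ok = codes >= 0
        out = np.zeros(len(codes), dtype=bool)
        out[ok] = self.cell_labels[codes[ok]]
        return out

    def attribute_with_mask(self, genotypes):
        codes = assign_cells(genotypes, self.snp_indices)
        ok = codes >= 0
        out = np.zeros(len(codes), dtype=bool)
        out[ok] = self.cell_labels[codes[ok]]
        return out, ok


@dataclass
class CVEvaluation:
    """Cross-validated scores for one SNP combination."""

    snp_indices: tuple
    train_ba: np.ndarray        # (repeats, folds)
    test_ba: np.ndarray         # (repeats, folds), NaN = unscorable fold
    cv_consistency: int
    folds: int
    repeats: int

    @property
    def mean_train_ba(self) -> float:
        return float(np.nanmean(self.train_ba))

    @property
    def mean_test_ba(self) -> float:
        return float(np.nanmean(self.test_ba))

    @property
    def n_missing_folds(self) -> int:
        return int(np.isnan(self.test_ba).sum())


def _residual_score(cohort: Cohort, covariates) -> CoxNullFit:
    return fit_cox_null(cohort, covariates)


def _evaluate(cohort, combos, folds, repeats, covariates, seed,
              null_fit=None, per_fold_residuals=False):
    """Shared driver: returns (evaluations list, fold_best, null_fit)."""
    k = len(combos[0])
    ncells = 3**k
    codes = _combo_codes(cohort.genotypes, combos)
    fold_ids = fold_assignments(cohort.n, folds, repeats, seed,
                                stratify=cohort.status)
    if per_fold_residuals:
        train_ba, test_ba, fold_best = _cv_scores_per_fold(
            cohort, covariates, codes, ncells, fold_ids)
        if null_fit is None:
            null_fit = _residual_score(cohort, covariates)
    else:
        if null_fit is None:
            null_fit = _residual_score(cohort, covariates)
        train_ba, test_ba, fold_best = _cv_scores(
            null_fit.residuals, null_fit.case_status, codes, ncells, fold_ids)
    evals = []
    for p, combo in enumerate(combos):
        cvc = int((fold_best == p).sum())
        evals.append(CVEvaluation(tuple(combo), train_ba[..., p],
                                  test_ba[..., p], cvc, folds, repeats))
    return evals, null_fit


def _cv_scores_per_fold(cohort, covariates, codes, ncells, fold_ids):
    """Sensitivity mode: refit the null Cox model inside every training fold.

    Training residuals come from the fold fit; test-subject residuals use
    the training baseline and coefficients.
    """
    n, P = codes.shape
    R = fold_ids.shape[0]
    F = int(fold_ids.max()) + 1
    valid = codes >= 0
    flat = np.where(valid, codes + ncells * np.arange(P)[None, :], 0)
    cols = cohort.covariate_indices(covariates)
    Z = cohort.covariates[:, cols]
    train_ba = np.full((R, F, P), np.nan)
    test_ba = np.full((R, F, P), np.nan)
    fold_best = np.zeros((R, F), dtype=np.int64)
    for r in range(R):
        for f in range(F):
            te = fold_ids[r] == f
            tr = ~te
            nf = fit_cox_null(cohort.subset(tr), covariates)
            res = np.empty(n)
            res[tr] = nf.residuals
            eta_te = Z[te] @ nf.gamma if Z.shape[1] else np.zeros(int(te.sum()))
            res[te] = cohort.status[te] - nf.cum_baseline(cohort.time[te]) * np.exp(eta_te)
            case = res > 0
            labels = _train_labels(res, flat, valid, tr, P, ncells)
            pred = labels.ravel()[flat] & valid
            trb = _ba_block(pred[tr], valid[tr], case[tr])
            train_ba[r, f] = trb
            test_ba[r, f] = _ba_block(pred[te], valid[te], case[te])
            fold_best[r, f] = int(np.argmax(np.where(np.isnan(trb), -np.inf, trb)))
    return train_ba, test_ba, fold_best


def evaluate_combo(cohort: Cohort, snp_indices, folds: int = 10,
                   repeats: int = 10, covariates=None, seed: int = 0,
                   per_fold_residuals: bool = False) -> CVEvaluation:
    """Cross-validated balanced accuracy of one k-SNP combination."""
    combo = tuple(cohort.snp_index(s) for s in snp_indices)
    evals, _ = _evaluate(cohort, [combo], folds, repeats, covariates, seed,
                         per_fold_residuals=per_fold_residuals)
    return evals[0]


def _rank_key(ev: CVEvaluation):
    return (-ev.mean_test_ba, -ev.cv_consistency, -ev.mean_train_ba,
            ev.snp_indices)


def search_best(cohort: Cohort, k: int = 2, folds: int = 10, repeats: int = 10,
                covariates=None, seed: int = 0, max_candidates: int = 200_000,
                per_fold_residuals: bool = False):
    """Evaluate every C(M, k) SNP combination and rank them.

    Ranking: mean testing balanced accuracy (descending), ties broken by
    CV consistency, then mean training BA, then lexicographic tuple.
    Returns a ranked list of (AttributeModel, CVEvaluation).
    """
    M = cohort.n_snps
    if M < k:
        raise ValueError(f"need at least k={k} SNPs, have {M}")
    combos = list(itertools.combinations(range(M), k))
    if len(combos) > max_candidates:
        raise ValueError(
            f"{len(combos)} candidate {k}-way combinations exceed the cap "
            f"of {max_candidates}; raise max_candidates explicitly"
        )
    evals, null_fit = _evaluate(cohort, combos, folds, repeats, covariates,
                                seed, per_fold_residuals=per_fold_residuals)
    evals.sort(key=_rank_key)
    out = []
    for ev in evals:
        cells = assign_cells(cohort.genotypes, ev.snp_indices)
        labels, _, _ = classify_cells(null_fit.residuals, cells, k)
        out.append((AttributeModel(ev.snp_indices, labels, k), ev))
    return out


# ----------------------------------------------------------------------
# Permutation p-value for a selected attribute.


@dataclass
class PermutationResult:
    p_value: float
    observed_stat: float
    n_permutations: int
    degenerate: bool = False


def _attribute_wald(time, status, x, Z):
    """Squared Wald statistic of the binary attribute in a Cox model."""
    X = np.column_stack([x.astype(float), Z])
    fit = cox_fit(time, status, X)
    z = fit.coef[0] / fit.se[0]
    return float(z * z)


def permutation_pvalue(cohort: Cohort, snp_indices, covariates=None,
                       B: int = 1000, seed: int = 0) -> PermutationResult:
    """Permutation p-value for a k-SNP attribute.

    The observed statistic is the squared Wald statistic of the high/low
    attribute in a covariate-adjusted Cox model.  Each permutation shuffles
    the phenotype block (time, status, covariates, hence residuals) against
    the genotype rows, re-derives the cell labels and recomputes the
    statistic; p = (1 + #{perm >= obs}) / (B + 1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    combo = tuple(cohort.snp_index(s) for s in snp_indices)
    k = len(combo)
    null_fit = fit_cox_null(cohort, covariates)
    codes = assign_cells(cohort.genotypes, combo)
    ok = codes >= 0
    labels, _, _ = classify_cells(null_fit.residuals, codes, k)
    x = labels[codes[ok]]
    cols = cohort.covariate_indices(covariates)
    Z = cohort.covariates[:, cols]
    if x.all() or not x.any():
        return PermutationResult(1.0, np.nan, B, degenerate=True)
    obs = _attribute_wald(cohort.time[ok], cohort.status[ok], x, Z[ok])
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(B):
        perm = rng.permutation(cohort.n)
        res_p = null_fit.residuals[perm]
        lab_p, _, _ = classify_cells(res_p, codes, k)
        x_p = lab_p[codes[ok]]
        if x_p.all() or not x_p.any():
            stat = 0.0
        else:
            try:
                stat = _attribute_wald(cohort.time[perm][ok],
                                       cohort.status[perm][ok], x_p,
                                       Z[perm][ok])
            except (ConvergenceError, DegenerateDataError):
                stat = np.inf  # conservative: counts against the observed
        if stat >= obs:
            n_ge += 1
    return PermutationResult((1 + n_ge) / (B + 1), obs, B)


# ----------------------------------------------------------------------
# Model / Results front-end.


class CoxMDR:
    """Cox-MDR model: martingale-residual MDR over a survival cohort.

    Parameters
    ----------
    cohort : Cohort
    k : int
        Interaction order (number of SNPs per combination).
    covariates : list of str or int, optional
        Covariate columns of the cohort to adjust the null Cox model for;
        None fits the unadjusted (Nelson-Aalen) null.
    per_fold_residuals : bool
        Recompute the null fit inside each training fold instead of once
        on the full cohort (sensitivity mode).
    """

    def __init__(self, cohort: Cohort, k: int = 2, covariates=None,
                 per_fold_residuals: bool = False):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.cohort = cohort
        self.k = k
        self.covariates = covariates
        self.per_fold_residuals = per_fold_residuals

    def fit(self, folds: int = 10, repeats: int = 10, seed: int = 0,
            max_candidates: int = 200_000) -> "CoxMDRResults":
        ranking = search_best(self.cohort, self.k, folds, repeats,
                              self.covariates, seed, max_candidates,
                              self.per_fold_residuals)
        null_fit = fit_cox_null(self.cohort, self.covariates)
        return CoxMDRResults(self, ranking, null_fit, folds, repeats, seed)


@dataclass
class CoxMDRResults:
    """Ranked Cox-MDR search results."""

    model: CoxMDR
    ranking_: list = field(repr=False)
    null_fit: CoxNullFit = field(repr=False)
    folds: int = 10
    repeats: int = 10
    seed: int = 0

    @property
    def best(self) -> AttributeModel:
        return self.ranking_[0][0]

    @property
    def best_eval(self) -> CVEvaluation:
        return self.ranking_[0][1]

    def ranking(self, top: int | None = None) -> pd.DataFrame:
        rows = []
        names = self.model.cohort.snp_names
        for rank, (attr, ev) in enumerate(self.ranking_[:top], start=1):
            rows.append({
                "rank": rank,
                "snps": ",".join(names[j] for j in attr.snp_indices),
                "train_ba": ev.mean_train_ba,
                "test_ba": ev.mean_test_ba,
                "cv_consistency": ev.cv_consistency,
            })
        return pd.DataFrame(rows)

    def attribute(self, snp_indices=None):
        """Per-subject high/low attribute (and validity mask) of a model;
        defaults to the top-ranked one."""
        attr = self.best if snp_indices is None else self._find(snp_indices)
        return attr.attribute_with_mask(self.model.cohort.genotypes)

    def _find(self, snp_indices) -> AttributeModel:
        combo = tuple(sorted(self.model.cohort.snp_index(s) for s in snp_indices))
        for attr, _ in self.ranking_:
            if tuple(sorted(attr.snp_indices)) == combo:
                return attr
        raise KeyError(f"combination {snp_indices} not in ranking")

    def permutation_pvalue(self, snp_indices=None, B: int = 1000,
                           seed: int = 0) -> PermutationResult:
        attr = self.best if snp_indices is None else self._find(snp_indices)
        return permutation_pvalue(self.model.cohort, attr.snp_indices,
                                  self.model.covariates, B, seed)

    def km_curves(self, snp_indices=None) -> pd.DataFrame:
        """Kaplan-Meier coordinates for the high- vs low-risk groups of an
        attribute, with the two-group log-rank p in the ``logrank_p``
        attribute of the returned frame."""
        from .io import km_table  # local import: avoids a cycle

        attr = self.best if snp_indices is None else self._find(snp_indices)
        co = self.model.cohort
        high, ok = attr.attribute_with_mask(co.genotypes)
        return km_table(co.time[ok], co.status[ok], high[ok])

    def summary(self, top: int = 3) -> str:
        co = self.model.cohort
        lines = [
            "Cox-MDR search results",
            "=" * 60,
            f"subjects: {co.n}   events: {co.n_events}   SNPs: {co.n_snps}",
            f"interaction order k={self.model.k}, "
            f"{self.folds}-fold CV x {self.repeats} repeats (seed {self.seed})",
            f"covariates adjusted: "
            f"{[co.covariate_names[j] for j in self.null_fit.covariate_cols] or 'none'}",
            "-" * 60,
        ]
        df = self.ranking(top)
        lines.append(df.to_string(index=False,
                                  float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)
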