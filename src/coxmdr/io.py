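"""Reading and writing the package's text formats.

Canonical dialect: UTF-8 tab-separated values with "NA" for missing.
Phenotype table: id, time, status, then covariate columns.  Genotype
table: id, then one 0/1/2-coded column per SNP; PLINK ``.raw``
additive-coding exports are accepted as an alternative genotype source.
"""

from __future__ import annotations

import logging
import sys

import numpy as np
import pandas as pd

from .cohort import MISSING, Cohort, CohortError
from .survival import logrank

logger = logging.getLogger("coxmdr")

PLINK_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _read_genotype_table(path) -> pd.DataFrame:
    """Genotype frame indexed by subject id (TSV or PLINK .raw)."""
    with open(path) as fh:
        header = fh.readline().split()
    if header[: len(PLINK_RAW_META)] == PLINK_RAW_META:
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        df = df.set_index(df["IID"].astype(str))
        df = df.drop(columns=PLINK_RAW_META)
    else:
        df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={0: str})
        df = df.set_index(df.columns[0])
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise CohortError(f"duplicated id {dup!r} in genotype file {path}")
    return df


def read_cohort(phenotype_path, genotype_path) -> Cohort:
    """Assemble a :class:`Cohort` from a phenotype and a genotype table.

    Subjects are matched by id (order normalised to the phenotype file);
    unmatched ids on either side are reported.  SNP columns that are
    entirely missing are dropped with a logged warning.
    """
    ph = pd.read_csv(phenotype_path, sep="\t", na_values=["NA"], dtype={0: str})
    ph = ph.set_index(ph.columns[0])
    if ph.index.duplicated().any():
        dup = ph.index[ph.index.duplicated()][0]
        raise CohortError(f"duplicated id {dup!r} in phenotype file")
    if ph.shape[1] < 2:
        raise CohortError("phenotype file needs id, time, status columns")
    gt = _read_genotype_table(genotype_path)

    common = ph.index.intersection(gt.index)
    missing_ph = gt.index.difference(ph.index)
    missing_gt = ph.index.difference(gt.index)
    if len(missing_gt) or len(missing_ph):
        logger.warning(
            "%d phenotype ids without genotypes, %d genotype ids without "
            "phenotypes; keeping the %d matched subjects",
            len(missing_gt), len(missing_ph), len(common),
        )
    if len(common) == 0:
        raise CohortError("no subject ids shared by the two files")
    ph = ph.loc[[i for i in ph.index if i in set(common)]]
    gt = gt.loc[ph.index]

    all_na = [c for c in gt.columns if gt[c].isna().all()]
    if all_na:
        logger.warning("dropping %d all-missing SNP column(s): %s",
                       len(all_na), ", ".join(map(str, all_na[:5])))
        gt = gt.drop(columns=all_na)

    gvals = gt.to_numpy(dtype=float)
    bad = np.isfinite(gvals) & ~np.isin(gvals, (0.0, 1.0, 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise CohortError(
            f"genotype not in {{0,1,2,NA}} for subject {gt.index[i]!r}, "
            f"SNP {gt.columns[j]!r}"
        )
    G = np.where(np.isfinite(gvals), gvals, MISSING).astype(np.int8)

    time = ph.iloc[:, 0].to_numpy(dtype=float)
    status = ph.iloc[:, 1].to_numpy()
    cov = ph.iloc[:, 2:]
    return Cohort(
        ids=ph.index.to_numpy(),
        time=time,
        status=status,
        covariates=cov.to_numpy(dtype=float) if cov.shape[1] else np.empty((len(ph), 0)),
        genotypes=G,
        covariate_names=[str(c) for c in cov.columns],
        snp_names=[str(c) for c in gt.columns],
    )


def write_cohort(cohort: Cohort, phenotype_path, genotype_path) -> None:
    """Write a cohort in the canonical TSV dialect (round-trips exactly)."""
    ph = pd.DataFrame({"id": cohort.ids, "time": cohort.time,
                       "status": cohort.status})
    for j, name in enumerate(cohort.covariate_names):
        ph[name] = cohort.covariates[:, j]
    ph.to_csv(phenotype_path, sep="\t", index=False, na_rep="NA",
              float_format="%.10g")
    gt = pd.DataFrame(cohort.genotypes.astype(object), columns=cohort.snp_names)
    gt = gt.mask(cohort.genotypes == MISSING)
    gt.insert(0, "id", cohort.ids)
    gt.to_csv(genotype_path, sep="\t", index=False, na_rep="NA")


# ----------------------------------------------------------------------
# Report writers.


def write_ranking(results, path, top=None, perm_p=None) -> None:
    """Ranked-model TSV: rank, snps, train/test score columns, CV consistency
    and (optionally) permutation p-values."""
    df = results.ranking(top)
    if perm_p is not None:
        df["perm_p"] = [perm_p.get(s, np.nan) for s in df["snps"]]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_screen(rows, path) -> None:
    """Per-SNP univariate Cox screen TSV (coef, p, FDR)."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.6g", na_rep="NA")


def km_table(time, status, high) -> pd.DataFrame:
    """Kaplan-Meier coordinates (time, survival, n_risk) per risk group.

    The two-group log-rank p-value is stored in ``df.attrs['logrank_p']``.
    """
    from lifelines import KaplanMeierFitter

    frames = []
    for label, mask in (("high", np.asarray(high, bool)),
                        ("low", ~np.asarray(high, bool))):
        if mask.sum() == 0:
            continue
        km = KaplanMeierFitter()
        km.fit(np.asarray(time)[mask], np.asarray(status)[mask])
        ev = km.event_table
        surv = km.survival_function_.iloc[:, 0]
        frames.append(pd.DataFrame({
            "group": label,
            "time": ev.index.to_numpy(dtype=float),
            "survival": surv.to_numpy(dtype=float),
            "n_risk": ev["at_risk"].to_numpy(dtype=int),
        }))
    df = pd.concat(frames, ignore_index=True)
    high = np.asarray(high, bool)
    if high.any() and (~high).any() and np.asarray(status).sum() > 0:
        df.attrs["logrank_p"] = logrank(time, status, high).p_value
    else:
        df.attrs["logrank_p"] = np.nan
    return df


def write_manifest(path, **items) -> None:
    """key=value reproducibility manifest."""
    with open(path, "w") as fh:
        for k, v in items.items():
            fh.write(f"{k}={v}\n")


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(levelname)s] %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
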