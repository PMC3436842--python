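"""Subject-level survival cohort container.

A :class:`Cohort` bundles observed follow-up time, event indicator,
real-valued covariates and additively coded SNP genotypes for a set of
subjects, with the row-consistency and coding invariants every downstream
routine relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for a missing genotype in the integer genotype matrix.
MISSING = -1


class CohortError(ValueError):
    """Raised when cohort data violate a structural invariant."""


@dataclass
class Cohort:
    """Survival cohort with genotypes.

    Parameters
    ----------
    ids : array of str
        Unique subject identifiers.
    time : array of float
        Observed time ``T_i = min(T_i*, C_i*)``; strictly positive.
    status : array of int
        Event indicator ``delta_i``; 1 = event observed, 0 = censored.
    covariates : (n, q) array of float
        Real covariate matrix Z; ``q`` may be zero.
    genotypes : (n, M) array of int
        Minor-allele counts in {0, 1, 2}; :data:`MISSING` marks a
        missing call.
    covariate_names, snp_names : list of str
        Column labels for Z and the genotype matrix.
    """

    ids: np.ndarray
    time: np.ndarray
    status: np.ndarray
    covariates: np.ndarray
    genotypes: np.ndarray
    covariate_names: list[str] = field(default_factory=list)
    snp_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.size == 0:
            self.covariates = np.empty((len(self.time), 0))
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim == 1:
            self.genotypes = self.genotypes[:, None]
        n = len(self.time)
        for name, arr in (
            ("ids", self.ids),
            ("status", self.status),
            ("covariates", self.covariates),
            ("genotypes", self.genotypes),
        ):
            if arr.shape[0] != n:
                raise CohortError(
                    f"{name} has {arr.shape[0]} rows, expected {n}"
                )
        if not self.covariate_names:
            self.covariate_names = [f"z{j}" for j in range(self.covariates.shape[1])]
        if not self.snp_names:
            self.snp_names = [f"snp{j}" for j in range(self.genotypes.shape[1])]
        if len(self.covariate_names) != self.covariates.shape[1]:
            raise CohortError("covariate_names length mismatch")
        if len(self.snp_names) != self.genotypes.shape[1]:
            raise CohortError("snp_names length mismatch")
        if len(np.unique(self.ids)) != n:
            raise CohortError("duplicated subject ids")
        bad = np.where(~(self.time > 0) | ~np.isfinite(self.time))[0]
        if bad.size:
            raise CohortError(
                f"non-positive or non-finite time for subject {self.ids[bad[0]]!r}"
            )
        if not np.isin(self.status, (0, 1)).all():
            bad = np.where(~np.isin(self.status, (0, 1)))[0][0]
            raise CohortError(f"status not in {{0,1}} for subject {self.ids[bad]!r}")
        self.status = self.status.astype(np.int8)
        ok = np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise CohortError(
                f"genotype not in {{0,1,2,NA}} for subject {self.ids[i]!r}, "
                f"SNP {self.snp_names[j]!r}"
            )

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def covariate_indices(self, which) -> list[int]:
        """Resolve covariate names or integer indices to column indices.

        ``None`` selects no covariates, ``"all"`` every column.
        """
        if which is None:
            return []
        if which == "all":
            return list(range(self.covariates.shape[1]))
        out = []
        for w in which:
            if isinstance(w, str):
                try:
                    out.append(self.covariate_names.index(w))
                except ValueError:
                    raise CohortError(f"unknown covariate {w!r}") from None
            else:
                out.append(int(w))
        return out

    def snp_index(self, which) -> int:
        if isinstance(which, str):
            try:
                return self.snp_names.index(which)
            except ValueError:
                raise CohortError(f"unknown SNP {which!r}") from None
        return int(which)

    def subset(self, rows) -> "Cohort":
        """Row-subset by boolean mask or index array."""
        rows = np.asarray(rows)
        return Cohort(
            ids=self.ids[rows],
            time=self.time[rows],
            status=self.status[rows],
            covariates=self.covariates[rows],
            genotypes=self.genotypes[rows],
            covariate_names=list(self.covariate_names),
            snp_names=list(self.snp_names),
        )

    def drop_snps(self, indices) -> "Cohort":
        """Remove genotype columns (e.g. causal SNPs when building nulls)."""
        keep = [j for j in range(self.n_snps) if j not in set(indices)]
        return Cohort(
            ids=self.ids,
            time=self.time,
            status=self.status,
            covariates=self.covariates,
            genotypes=self.genotypes[:, keep],
            covariate_names=list(self.covariate_names),
            snp_names=[self.snp_names[j] for j in keep],
        )
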