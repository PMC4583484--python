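"""Stratum assignment for conditional CMH tests on SNP data.

Conditioning on a set of p SNPs partitions the samples into strata.  The
full genotype cross gives one stratum per distinct genotype tuple (up to
3^p of them), which explodes for large p; the minor-allele-count (MAC) sum
scheme instead groups subjects by the sum of their minor-allele counts over
the conditioning set, capping the number of strata by merging all sums at
or above ``cap - 1`` into the last stratum.  Subjects with a similar allele
burden over the conditioning SNPs are assumed to carry a similar risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cmh import ContingencyTable3D
from .exceptions import ValidationError
from .genotypes import MISSING, GenotypeMatrix

__all__ = ["StrataAssignment", "mac_sum", "assign_strata", "build_table"]

#: Stratum index marking a sample excluded for missingness.
EXCLUDED = -1


@dataclass
class StrataAssignment:
    """Per-sample stratum indices 0..K-1 (EXCLUDED = -1 for dropped samples)."""

    stratum_index: np.ndarray
    K: int
    scheme: str
    conditioning_set: tuple[str, ...]
    cap: int | None = None
    stratum_keys: tuple = ()

    def __post_init__(self) -> None:
        idx = np.asarray(self.stratum_index, dtype=np.int64)
        if idx.ndim != 1:
            raise ValidationError("stratum_index must be 1-D")
        if idx.size and idx.max(initial=-1) >= self.K:
            raise ValidationError("stratum index exceeds K")
        if np.any(idx < EXCLUDED):
            raise ValidationError("stratum indices must be >= -1")
        self.stratum_index = idx


def mac_sum(genos: GenotypeMatrix, snp_set) -> np.ndarray:
    """Per-sample sum of minor-allele counts over ``snp_set``.

    Returns a float vector; samples missing any genotype in the set are NaN
    (excluded from any stratification built on the sum).  An empty set gives
    zero for every sample.
    """
    snp_set = list(snp_set)
    if not snp_set:
        return np.zeros(genos.n_samples)
    cols = genos.codes[:, genos.column_indices(snp_set)]
    sums = cols.sum(axis=1, dtype=np.int64).astype(float)
    sums[(cols == MISSING).any(axis=1)] = np.nan
    return sums


def assign_strata(
    genos: GenotypeMatrix,
    snp_set,
    scheme: str = "mac_sum",
    cap: int = 10,
) -> StrataAssignment:
    """Map each sample to a stratum defined by the conditioning SNP set.

    ``full_cross``: one stratum per distinct observed genotype tuple.
    ``mac_sum``: strata are MAC sums 0, 1, ..., cap-2, with every sum
    >= cap-1 merged into the final stratum.  Unobserved keys produce no
    empty strata; an empty conditioning set yields a single stratum.
    """
    snp_set = tuple(str(s) for s in snp_set)
    if scheme not in ("full_cross", "mac_sum"):
        raise ValidationError(f"unknown stratification scheme {scheme!r}")
    if scheme == "mac_sum" and cap < 2:
        raise ValidationError("cap must be >= 2")

    if not snp_set:
        return StrataAssignment(
            np.zeros(genos.n_samples, dtype=np.int64), 1, scheme, snp_set,
            cap if scheme == "mac_sum" else None, (0,),
        )

    cols = genos.codes[:, genos.column_indices(snp_set)]
    complete = ~(cols == MISSING).any(axis=1)
    index = np.full(genos.n_samples, EXCLUDED, dtype=np.int64)

    if scheme == "full_cross":
        keys, inv = np.unique(cols[complete], axis=0, return_inverse=True)
        index[complete] = inv
        return StrataAssignment(
            index, len(keys), scheme, snp_set, None,
            tuple(map(tuple, keys.tolist())),
        )

    sums = cols[complete].sum(axis=1, dtype=np.int64)
    capped = np.minimum(sums, cap - 1)
    keys, inv = np.unique(capped, return_inverse=True)
    index[complete] = inv
    labels = tuple(
        int(k) if k < cap - 1 else f">={cap - 1}" for k in keys.tolist()
    )
    return StrataAssignment(index, len(keys), scheme, snp_set, cap, labels)


def build_table(
    pheno: np.ndarray,
    target_snp: str,
    strata: StrataAssignment,
    genos: GenotypeMatrix,
    n_trait_levels: int | None = None,
) -> ContingencyTable3D:
    """Cross-tabulate trait x target genotype x stratum into an I x 3 x K table.

    ``pheno`` holds trait level codes 0..I-1 (negative or NaN = missing).
    Samples missing the trait, the target genotype, or excluded by the
    stratification are omitted; the grand total equals the complete cases.
    """
    if target_snp in strata.conditioning_set:
        raise ValidationError(
            f"target SNP {target_snp!r} is in the conditioning set"
        )
    y = np.asarray(pheno, dtype=float)
    if y.shape[0] != genos.n_samples:
        raise ValidationError("phenotype length does not match sample count")
    g = genos.column(target_snp)
    k = strata.stratum_index
    keep = (~np.isnan(y)) & (y >= 0) & (g != MISSING) & (k != EXCLUDED)
    yk = y[keep].astype(np.int64)
    n_i = int(n_trait_levels or (yk.max(initial=0) + 1))
    flat = (yk * 3 + g[keep]) * strata.K + k[keep]
    counts = np.bincount(flat, minlength=n_i * 3 * strata.K).reshape(
        n_i, 3, strata.K
    )
    return ContingencyTable3D(
        counts,
        stratum_labels=strata.stratum_keys,
        col_labels=(0, 1, 2),
    )
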