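"""Genotype matrix container: samples x SNPs minor-allele-count codes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: Sentinel for a missing genotype in the internal int8 coding.
MISSING = np.int8(-1)


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes coded as per-sample minor-allele counts.

    ``codes`` is a samples x SNPs int8 array over {0, 1, 2} with -1 marking a
    missing call.  SNP ids must be unique; positional order of columns is the
    genomic order used by windowed LD pruning.
    """

    codes: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    minor_alleles: list[str] | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.codes)
        if arr.ndim != 2:
            raise ValidationError("codes must be a 2-D samples x SNPs array")
        if np.issubdtype(arr.dtype, np.floating):
            arr = np.where(np.isnan(arr), -1, arr)
        arr = arr.astype(np.int8, copy=False)
        bad = ~np.isin(arr, (-1, 0, 1, 2))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"invalid genotype code {int(np.asarray(self.codes)[i, j])} "
                f"at sample index {i}, SNP index {j}"
            )
        self.codes = arr
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.snp_ids) != arr.shape[1]:
            raise ValidationError("snp_ids length does not match codes")
        if len(self.sample_ids) != arr.shape[0]:
            raise ValidationError("sample_ids length does not match codes")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("snp_ids must be unique")
        if self.minor_alleles is not None and len(self.minor_alleles) != arr.shape[1]:
            raise ValidationError("minor_alleles length does not match codes")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def column_indices(self, snp_ids) -> np.ndarray:
        """Column indices of the given SNP ids, in the given order."""
        try:
            return np.array([self._index[s] for s in snp_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown SNP id {exc.args[0]!r}") from None

    def column(self, snp_id: str) -> np.ndarray:
        if snp_id not in self._index:
            raise KeyError(f"unknown SNP id {snp_id!r}")
        return self.codes[:, self._index[snp_id]]

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        idx = self.column_indices(snp_ids)
        return GenotypeMatrix(
            self.codes[:, idx],
            [self.snp_ids[i] for i in idx],
            list(self.sample_ids),
            None if self.minor_alleles is None
            else [self.minor_alleles[i] for i in idx],
        )

    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def maf(self) -> np.ndarray:
        """Sample minor-allele frequency per SNP, folded to <= 0.5.

        Computed over non-missing calls; NaN for SNPs with no calls.
        """
        obs = self.codes != MISSING
        n_called = obs.sum(axis=0)
        counts = np.where(obs, self.codes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = counts / (2.0 * n_called)
        return np.minimum(freq, 1.0 - freq)

    def call_rate(self) -> np.ndarray:
        return (self.codes != MISSING).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Samples x SNPs DataFrame with pandas NA for missing calls."""
        df = pd.DataFrame(
            self.codes, index=self.sample_ids, columns=self.snp_ids, dtype="Int8"
        )
        return df.mask(df == int(MISSING))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        codes = df.to_numpy(dtype=float, na_value=-1.0)
        return cls(codes, list(df.columns), list(df.index))
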