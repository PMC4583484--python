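"""Marker quality control: MAF / call-rate filtering and windowed LD pruning."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .genotypes import MISSING, GenotypeMatrix

__all__ = ["QCReport", "qc_filter", "ld_prune"]


@dataclass
class QCReport:
    """Bookkeeping of SNPs removed by each QC stage."""

    n_input_snps: int
    n_removed_maf: int = 0
    n_removed_callrate: int = 0
    n_removed_ld: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_output_snps(self) -> int:
        return (
            self.n_input_snps
            - self.n_removed_maf
            - self.n_removed_callrate
            - self.n_removed_ld
        )


def qc_filter(
    genos: GenotypeMatrix,
    maf_min: float = 0.01,
    callrate_min: float = 0.95,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs with folded MAF < ``maf_min`` or call rate < ``callrate_min``.

    Strict inequalities: boundary values are retained.  MAF is computed on
    non-missing calls and folded to <= 0.5.
    """
    for name, v in (("maf_min", maf_min), ("callrate_min", callrate_min)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1]")
    maf = genos.maf()
    call = genos.call_rate()
    low_call = call < callrate_min
    # SNPs with no calls have NaN MAF; they are already caught by call rate.
    low_maf = np.where(np.isnan(maf), False, maf < maf_min) & ~low_call
    keep = ~(low_call | low_maf)
    report = QCReport(
        n_input_snps=genos.n_snps,
        n_removed_maf=int(low_maf.sum()),
        n_removed_callrate=int(low_call.sum()),
        thresholds={"maf_min": maf_min, "callrate_min": callrate_min},
    )
    kept = [s for s, k in zip(genos.snp_ids, keep) if k]
    return genos.subset_snps(kept), report


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of allele counts, complete pairwise cases."""
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(
    genos: GenotypeMatrix,
    r2_max: float = 0.5,
    window: int = 50,
) -> tuple[GenotypeMatrix, QCReport]:
    """Windowed tag-SNP selection: drop the later SNP of any pair with r² > r2_max.

    A window of ``window`` adjacent SNPs (in column/positional order) slides
    one SNP at a time; within each window every surviving pair is checked
    and the positionally later member of an offending pair is removed.
    Strict inequality: pairs at exactly ``r2_max`` are kept.
    """
    if window < 2:
        raise ValidationError("window must be >= 2")
    n = genos.n_snps
    alive = np.ones(n, dtype=bool)
    r2_cache: dict[tuple[int, int], float] = {}

    def r2(a: int, b: int) -> float:
        key = (a, b)
        if key not in r2_cache:
            r2_cache[key] = _pairwise_r2(genos.codes[:, a], genos.codes[:, b])
        return r2_cache[key]

    for start in range(n):
        idx = [j for j in range(start, min(start + window, n)) if alive[j]]
        for pos_a, a in enumerate(idx):
            if not alive[a]:
                continue
            for b in idx[pos_a + 1:]:
                if alive[b] and r2(a, b) > r2_max:
                    alive[b] = False
    report = QCReport(
        n_input_snps=n,
        n_removed_ld=int((~alive).sum()),
        thresholds={"r2_max": r2_max, "window": window},
    )
    kept = [s for s, k in zip(genos.snp_ids, alive) if k]
    return genos.subset_snps(kept), report
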