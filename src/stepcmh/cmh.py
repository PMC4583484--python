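"""Generalized Cochran-Mantel-Haenszel tests for stratified I x J x K tables.

The statistic pools evidence for association between a row variable (trait,
I levels) and a column variable (genotype, J levels) across K strata, under
the null of conditional independence.  Within stratum k the cell counts
``n_k`` follow, conditional on the margins, a multivariate hypergeometric
distribution with mean ``mu_k`` and covariance ``V_k``; the statistic is

    L^2 = T' S^{-1} T,   T = sum_k B_k (n_k - mu_k),   S = sum_k B_k V_k B_k'

where ``B_k`` is the Kronecker product of a row score matrix and a column
score matrix.  Nominal variables use an (L-1) x L contrast; ordinal variables
use a single row of scores.  The combination of score kinds selects the
test: general association (both nominal), mean score (one ordinal), or
correlation (both ordinal).  Under the null, L^2 is asymptotically
chi-square with df equal to the number of rows of B_k, reduced to the rank
of S when S is singular.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateStratumError,
    EmptyStratumError,
    UntestableError,
    ValidationError,
)

__all__ = [
    "ContingencyTable3D",
    "ScoreScheme",
    "CMHResult",
    "make_score_matrix",
    "expected_counts",
    "variance_matrix",
    "cmh_test",
    "GENETIC_MODEL_SCORES",
]

#: Column score vectors realizing the classical single-df genetic models as
#: mean-score tests on minor-allele counts.
GENETIC_MODEL_SCORES = {
    "additive": (0.0, 1.0, 2.0),
    "dominant": (0.0, 1.0, 1.0),
    "recessive": (0.0, 0.0, 1.0),
}


@dataclass(frozen=True)
class ScoreScheme:
    """Weighting of the levels of one table dimension.

    ``kind`` is ``"nominal"`` (an (L-1) x L identity-minus-last contrast) or
    ``"ordinal"`` (a single row of monotone scores).  Ordinal scores must be
    non-decreasing and take at least two distinct values; ties are allowed so
    that dominant/recessive genotype codings such as (0, 1, 1) are valid.
    """

    kind: str
    scores: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("nominal", "ordinal"):
            raise ValidationError(f"unknown score kind {self.kind!r}")
        if self.kind == "ordinal":
            if self.scores is None or len(self.scores) < 2:
                raise ValidationError("ordinal scheme needs >= 2 scores")
            s = np.asarray(self.scores, dtype=float)
            if not np.all(np.isfinite(s)):
                raise ValidationError("ordinal scores must be finite")
            if np.any(np.diff(s) < 0) or s[0] == s[-1]:
                raise ValidationError(
                    "ordinal scores must be non-decreasing with at least "
                    "two distinct values"
                )
            object.__setattr__(self, "scores", tuple(float(x) for x in s))
        elif self.scores is not None:
            raise ValidationError("nominal scheme takes no scores")

    @classmethod
    def nominal(cls) -> "ScoreScheme":
        return cls("nominal")

    @classmethod
    def ordinal(cls, scores: Sequence[float]) -> "ScoreScheme":
        return cls("ordinal", tuple(float(x) for x in scores))

    @classmethod
    def genetic_model(cls, model: str) -> "ScoreScheme":
        """Column scheme for 'additive', 'dominant', 'recessive' or 'codominant'."""
        if model == "codominant":
            return cls.nominal()
        try:
            return cls.ordinal(GENETIC_MODEL_SCORES[model])
        except KeyError:
            raise ValidationError(f"unknown genetic model {model!r}") from None


def make_score_matrix(n_levels: int, scheme: ScoreScheme) -> np.ndarray:
    """Score matrix for one dimension with ``n_levels`` levels.

    Nominal: the (L-1) x L block ``(I | -1)`` whose row r has 1 in column r
    and -1 in the last column.  Ordinal: the 1 x L row of scores.
    """
    if n_levels < 2:
        raise ValidationError("a table dimension needs at least 2 levels")
    if scheme.kind == "nominal":
        mat = np.zeros((n_levels - 1, n_levels))
        mat[:, :-1] = np.eye(n_levels - 1)
        mat[:, -1] = -1.0
        return mat
    if len(scheme.scores) != n_levels:
        raise ValidationError(
            f"ordinal scheme has {len(scheme.scores)} scores "
            f"for {n_levels} levels"
        )
    return np.asarray(scheme.scores, dtype=float).reshape(1, n_levels)


@dataclass
class ContingencyTable3D:
    """I x J x K stratified contingency table of non-negative counts.

    ``counts[i, j, k]`` is the number of subjects at trait level i, genotype
    level j, in stratum k.  Margins are recomputed from the counts on demand.
    """

    counts: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()
    stratum_labels: tuple = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim == 2:  # single-stratum convenience
            arr = arr[:, :, None]
        if arr.ndim != 3:
            raise ValidationError("counts must be an I x J x K array")
        if not np.issubdtype(arr.dtype, np.number) or not np.all(np.isfinite(arr)):
            raise ValidationError("counts must be finite numbers")
        if np.any(arr < 0):
            raise ValidationError("counts must be non-negative")
        if arr.sum() < 1:
            raise ValidationError("table is empty")
        self.counts = arr.astype(np.int64)
        for name, labels, size in (
            ("row_labels", self.row_labels, arr.shape[0]),
            ("col_labels", self.col_labels, arr.shape[1]),
            ("stratum_labels", self.stratum_labels, arr.shape[2]),
        ):
            if labels and len(labels) != size:
                raise ValidationError(f"{name} length does not match counts")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def row_margins(self) -> np.ndarray:
        """n_{i+k}, shape (I, K)."""
        return self.counts.sum(axis=1)

    def col_margins(self) -> np.ndarray:
        """n_{+jk}, shape (J, K)."""
        return self.counts.sum(axis=0)

    def stratum_totals(self) -> np.ndarray:
        """n_{++k}, shape (K,)."""
        return self.counts.sum(axis=(0, 1))


@dataclass
class CMHResult:
    """Outcome of a generalized CMH test."""

    statistic: float
    df: int
    p_value: float
    test_type: str
    n_strata_used: int
    n_strata_dropped: int
    rank_deficient: bool = False

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CMHResult(L2={self.statistic:.6g}, df={self.df}, "
            f"p={self.p_value:.4g}, test={self.test_type!r}, "
            f"strata={self.n_strata_used}"
            + (", rank_deficient" if self.rank_deficient else "")
            + ")"
        )


def expected_counts(stratum: np.ndarray) -> np.ndarray:
    """Null expected counts mu for one I x J stratum, flattened row-major.

    mu_ij = n_{i+} n_{+j} / n; the products of the fixed margins.
    """
    slc = np.asarray(stratum, dtype=float)
    if slc.ndim != 2:
        raise ValidationError("stratum slice must be 2-D")
    n = slc.sum()
    if n < 1:
        raise EmptyStratumError("stratum has zero total")
    return np.outer(slc.sum(axis=1), slc.sum(axis=0)).ravel() / n


def _margin_factor(margin: np.ndarray, n: float) -> np.ndarray:
    """One Kronecker factor of the hypergeometric covariance: diag(m) - m m'/n."""
    return np.diag(margin) - np.outer(margin, margin) / n


def variance_matrix(stratum: np.ndarray) -> np.ndarray:
    """Null covariance of the flattened cell counts of one I x J stratum.

    Under the multivariate hypergeometric law with fixed margins,
    Cov(n_ij, n_i'j') = n_{i+}(w_ii' n - n_{i'+}) n_{+j}(w_jj' n - n_{+j'})
                        / (n^2 (n-1)),
    which factorizes as kron(A_r, A_c)/(n-1) with A_r = diag(r) - r r'/n.
    """
    slc = np.asarray(stratum, dtype=float)
    if slc.ndim != 2:
        raise ValidationError("stratum slice must be 2-D")
    n = slc.sum()
    if n < 2:
        raise DegenerateStratumError("variance undefined for strata with n < 2")
    a_r = _margin_factor(slc.sum(axis=1), n)
    a_c = _margin_factor(slc.sum(axis=0), n)
    return np.kron(a_r, a_c) / (n - 1.0)


def _test_type(row_scheme: ScoreScheme, col_scheme: ScoreScheme) -> str:
    ordinal = (row_scheme.kind == "ordinal") + (col_scheme.kind == "ordinal")
    return ("general", "mean_score", "correlation")[ordinal]


def _accumulate(
    counts: np.ndarray, u_mat: np.ndarray, v_mat: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Accumulate T = sum_k B(n_k - mu_k) and S = sum_k B V_k B' over strata.

    Works on the factorized forms U M V' and kron(U A_r U', V A_c V')/(n-1)
    so no (IJ) x (IJ) matrix is ever built.
    """
    d = u_mat.shape[0] * v_mat.shape[0]
    t_vec = np.zeros(d)
    s_mat = np.zeros((d, d))
    used = dropped = 0
    for k in range(counts.shape[2]):
        slc = counts[:, :, k].astype(float)
        n = slc.sum()
        if n < 2:
            dropped += 1
            continue
        r = slc.sum(axis=1)
        c = slc.sum(axis=0)
        resid = slc - np.outer(r, c) / n
        t_vec += (u_mat @ resid @ v_mat.T).ravel()
        s_mat += np.kron(
            u_mat @ _margin_factor(r, n) @ u_mat.T,
            v_mat @ _margin_factor(c, n) @ v_mat.T,
        ) / (n - 1.0)
        used += 1
    return t_vec, s_mat, used, dropped


def cmh_test(
    table: ContingencyTable3D,
    row_scheme: ScoreScheme | None = None,
    col_scheme: ScoreScheme | None = None,
) -> CMHResult:
    """Generalized CMH test of conditional independence on an I x J x K table.

    Schemes default to nominal on both dimensions (general association).
    Strata with fewer than two subjects carry no information and are dropped.
    When the pooled covariance S is singular the Moore-Penrose inverse is
    used, the degrees of freedom are reduced to rank(S), and the result is
    flagged ``rank_deficient``.
    """
    if not isinstance(table, ContingencyTable3D):
        table = ContingencyTable3D(np.asarray(table))
    row_scheme = row_scheme or ScoreScheme.nominal()
    col_scheme = col_scheme or ScoreScheme.nominal()
    n_i, n_j, _ = table.shape
    u_mat = make_score_matrix(n_i, row_scheme)
    v_mat = make_score_matrix(n_j, col_scheme)

    t_vec, s_mat, used, dropped = _accumulate(table.counts, u_mat, v_mat)
    if used == 0:
        raise UntestableError("all strata are degenerate (n < 2)")

    df_nominal = u_mat.shape[0] * v_mat.shape[0]
    rank = int(np.linalg.matrix_rank(s_mat)) if s_mat.any() else 0
    rank_deficient = rank < df_nominal
    if rank == 0:
        # No variability at all under the fixed margins: nothing to test.
        stat, df, p_value = 0.0, 0, 1.0
    else:
        s_inv = np.linalg.pinv(s_mat) if rank_deficient else np.linalg.inv(s_mat)
        stat = float(t_vec @ s_inv @ t_vec)
        stat = max(stat, 0.0)
        df = rank if rank_deficient else df_nominal
        p_value = float(stats.chi2.sf(stat, df))
    return CMHResult(
        statistic=stat,
        df=df,
        p_value=p_value,
        test_type=_test_type(row_scheme, col_scheme),
        n_strata_used=used,
        n_strata_dropped=dropped,
        rank_deficient=rank_deficient,
    )
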