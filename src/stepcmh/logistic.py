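"""Stepwise logistic-regression baseline for the power comparisons.

Mirrors the stepwise CMH driver but scores each candidate SNP by the
likelihood-ratio test of its two genotype dummies (g == 1, g == 2) added to
a logistic model that already contains dummies for the selected SNPs.  The
fits use an ordinary maximum-likelihood routine; non-convergence or perfect
separation is recorded as p = 1, mimicking the p-value inflation that
sparse genotype cells induce in logistic regression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ValidationError
from .genotypes import MISSING, GenotypeMatrix
from .model import SelectionResult, StepwiseConfig, _TRACE_COLUMNS

__all__ = ["lrt_candidate", "discover_sets_logistic"]


def _dummies(g: np.ndarray) -> np.ndarray:
    """Codominant genotype dummies (n x 2): indicators of g==1 and g==2."""
    return np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])


def _fit_llf(x: np.ndarray, y: np.ndarray) -> float | None:
    """Log-likelihood of a logistic fit, or None on failure/separation."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, x).fit(disp=0, maxiter=50, method="newton")
        except Exception:
            return None
        if not res.mle_retvals.get("converged", False):
            return None
        if not np.isfinite(res.llf):
            return None
        return float(res.llf)


def lrt_candidate(
    y: np.ndarray,
    base: np.ndarray,
    candidate_g: np.ndarray,
    llf_null: float | None = None,
) -> tuple[float, int, float]:
    """LRT p-value for adding one SNP's genotype dummies to a base design.

    Returns ``(statistic, df, p_value)``; failures are reported as p = 1
    with statistic 0.  Constant dummy columns (e.g. no minor homozygotes)
    are dropped, reducing the df accordingly.
    """
    dummies = _dummies(candidate_g)
    keep = dummies.std(axis=0) > 0
    df = int(keep.sum())
    if df == 0:
        return 0.0, 0, 1.0
    if llf_null is None:
        llf_null = _fit_llf(base, y)
    llf_full = _fit_llf(np.hstack([base, dummies[:, keep]]), y)
    if llf_null is None or llf_full is None:
        return 0.0, df, 1.0
    stat = max(2.0 * (llf_full - llf_null), 0.0)
    return stat, df, float(stats.chi2.sf(stat, df))


def _complete_design(
    pheno: np.ndarray, genos: GenotypeMatrix, snps: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complete-case response, base design, and kept-sample mask."""
    cols = (
        genos.codes[:, genos.column_indices(snps)]
        if snps
        else np.empty((genos.n_samples, 0), dtype=np.int8)
    )
    keep = (~np.isnan(pheno)) & (pheno >= 0) & ~(cols == MISSING).any(axis=1)
    y = pheno[keep]
    base = np.ones((keep.sum(), 1))
    for j in range(cols.shape[1]):
        d = _dummies(cols[keep, j])
        base = np.hstack([base, d[:, d.std(axis=0) > 0]])
    return y, base, keep


def _forward_logistic(selected, candidates, pheno, genos, config):
    y, base, keep = _complete_design(pheno, genos, selected)
    llf_null = _fit_llf(base, y)
    best_key, best_snp, best = None, None, None
    for order, snp in enumerate(candidates):
        g = genos.column(snp)[keep]
        ok = g != MISSING
        if ok.all():
            stat, df, p = lrt_candidate(y, base, g, llf_null)
        else:  # candidate brings extra missingness: refit on its own cases
            stat, df, p = lrt_candidate(y[ok], base[ok], g[ok], None)
        key = (p, -stat, order)
        if best_key is None or key < best_key:
            best_key, best_snp, best = key, snp, (stat, df, p)
    if best is not None and best[2] < config.entry_threshold:
        return best_snp, best
    return None, best


def _backward_logistic(selected, pheno, genos, config):
    worst_key, worst_snp, worst = None, None, None
    for order, snp in enumerate(selected):
        rest = [s for s in selected if s != snp]
        y, base, keep = _complete_design(pheno, genos, rest)
        g = genos.column(snp)[keep]
        ok = g != MISSING
        stat, df, p = lrt_candidate(y[ok], base[ok], g[ok], None)
        key = (-p, stat, order)
        if worst_key is None or key < worst_key:
            worst_key, worst_snp, worst = key, snp, (stat, df, p)
    if worst is not None and worst[2] > config.removal_threshold:
        return worst_snp, worst
    return None, worst


def discover_sets_logistic(
    pheno: np.ndarray,
    genos: GenotypeMatrix,
    config: StepwiseConfig | None = None,
) -> SelectionResult:
    """Stepwise logistic selection with the same driver logic as the CMH search.

    Binary traits only (0 = control, 1 = case).
    """
    config = config or StepwiseConfig()
    pheno = np.asarray(pheno, dtype=float)
    observed = pheno[~np.isnan(pheno) & (pheno >= 0)]
    if not set(np.unique(observed)) <= {0.0, 1.0}:
        raise ValidationError("logistic baseline requires a binary 0/1 trait")
    pool = list(genos.snp_ids)
    snp_sets, rows = [], []
    round_no = 0
    while pool:
        round_no += 1
        selected: list[str] = []
        visited = {frozenset()}
        step_no = 0
        while True:
            step_no += 1
            candidates = [s for s in pool if s not in selected]
            added, res = _forward_logistic(
                selected, candidates, pheno, genos, config
            )
            if added is None:
                if res is not None:
                    rows.append((round_no, step_no, "forward", None, res[2],
                                 res[0], res[1], "stop"))
                break
            selected.append(added)
            rows.append((round_no, step_no, "forward", added, res[2], res[0],
                         res[1], "add"))
            state = frozenset(selected)
            if state in visited or len(selected) >= config.max_set_size:
                break
            visited.add(state)
            stop_round = False
            if config.backward_enabled and len(selected) > 1:
                while selected:
                    removed, rres = _backward_logistic(
                        selected, pheno, genos, config
                    )
                    if removed is None:
                        break
                    selected.remove(removed)
                    step_no += 1
                    rows.append((round_no, step_no, "backward", removed,
                                 rres[2], rres[0], rres[1], "remove"))
                    if frozenset(selected) in visited:
                        stop_round = True
                        break
                    visited.add(frozenset(selected))
            if stop_round:
                break
        if not selected:
            break
        snp_sets.append(selected)
        pool = [s for s in pool if s not in selected]
    return SelectionResult(
        snp_sets=snp_sets, trace=pd.DataFrame(rows, columns=_TRACE_COLUMNS)
    )
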