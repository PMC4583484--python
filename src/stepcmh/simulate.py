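"""Case-control GWAS simulation under a multiplicative-odds penetrance model.

Each causal SNP multiplies the baseline disease odds alpha by 1, (1+theta1),
or (1+theta2) for genotype 0, 1, or 2 minor alleles; penetrance is
odds/(1+odds).  On the log-odds scale this is exactly the logistic model
logit P(y=1) = log(alpha) + sum_s beta_s(g_s) with per-genotype coefficients
log(1+theta1) and log(1+theta2).  Causal genotypes are drawn under
Hardy-Weinberg equilibrium and linkage equilibrium; disease status is
Bernoulli(penetrance); retrospective case-control samples are produced by
rejection sampling until the case and control quotas are exactly filled.
Non-causal SNPs are drawn under HWE, independent of the trait.

The default effect sizes theta1 = 0.7 and theta2 = 0.5 and the default
quotas of 1000 cases / 1000 controls are the canonical study conditions
for the power comparisons in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .exceptions import StepCMHError, ValidationError
from .genotypes import GenotypeMatrix

__all__ = [
    "SimulationModel",
    "genotype_factor",
    "hwe_probs",
    "penetrance",
    "solve_alpha",
    "generate_dataset",
    "generate_prospective",
    "generate_ordinal_dataset",
]


def hwe_probs(maf: float) -> np.ndarray:
    """Genotype probabilities ((1-q)^2, 2q(1-q), q^2) for minor-allele count."""
    if not 0.0 < maf <= 0.5:
        raise ValidationError("MAF must be in (0, 0.5]")
    q = float(maf)
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def genotype_factor(g, theta1: float, theta2: float):
    """Odds multiplier 1, 1+theta1, or 1+theta2 for genotype 0, 1, or 2."""
    g_arr = np.asarray(g)
    if not np.isin(g_arr, (0, 1, 2)).all():
        raise ValidationError("genotype codes must be in {0, 1, 2}")
    factors = np.array([1.0, 1.0 + theta1, 1.0 + theta2])
    if np.any(factors <= 0):
        raise ValidationError("1+theta must be positive")
    out = factors[g_arr]
    return float(out) if np.isscalar(g) else out


@dataclass(frozen=True)
class SimulationModel:
    """Parameters of the retrospective case-control generator.

    ``alpha`` is the baseline odds of disease for a subject carrying zero
    minor alleles at every causal locus; when None it is solved so that the
    population prevalence equals ``total_penetrance``.  ``causal_mafs`` has
    one entry per causal SNP.  ``null_maf_law`` is ``("uniform", lo, hi)``
    or ``("fixed", maf)`` and governs the non-causal SNP frequencies.
    """

    causal_mafs: tuple[float, ...] = (0.2, 0.2)
    theta1: float = 0.7
    theta2: float = 0.5
    alpha: float | None = None
    total_penetrance: float = 0.1
    n_cases: int = 1000
    n_controls: int = 1000
    n_null_snps: int = 98
    null_maf_law: tuple = ("uniform", 0.05, 0.5)
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls) < 1:
            raise ValidationError("case/control quotas must be >= 1")
        if not 0.0 < self.total_penetrance < 1.0:
            raise ValidationError("total_penetrance must be in (0, 1)")
        if self.alpha is not None and self.alpha <= 0:
            raise ValidationError("alpha must be positive")
        for q in self.causal_mafs:
            if not 0.0 < q <= 0.5:
                raise ValidationError("causal MAFs must be in (0, 0.5]")
        if min(1 + self.theta1, 1 + self.theta2) <= 0:
            raise ValidationError("1+theta must be positive")

    @property
    def n_causal(self) -> int:
        return len(self.causal_mafs)

    def resolved_alpha(self) -> float:
        """The baseline odds actually used (solving for prevalence if needed)."""
        if self.alpha is not None:
            return self.alpha
        return solve_alpha(
            self.total_penetrance, self.causal_mafs, self.theta1, self.theta2
        )


def penetrance(genotypes, model: SimulationModel, alpha: float | None = None):
    """Disease probability odds/(1+odds) for one multi-locus genotype.

    ``genotypes`` is a length-p vector (or an n x p array, one row per
    subject) of causal-SNP codes.
    """
    a = alpha if alpha is not None else model.resolved_alpha()
    g = np.atleast_2d(np.asarray(genotypes))
    if g.shape[-1] != model.n_causal:
        raise ValidationError("genotype vector length != number of causal SNPs")
    factors = genotype_factor(g, model.theta1, model.theta2)
    odds = a * factors.prod(axis=-1)
    if np.any(odds <= 0):
        raise StepCMHError("non-positive odds under the model")
    out = odds / (1.0 + odds)
    return float(out[0]) if np.asarray(genotypes).ndim == 1 else out


def _prevalence(log_alpha: float, joint_probs, joint_factors) -> float:
    odds = np.exp(log_alpha) * joint_factors
    return float(joint_probs @ (odds / (1.0 + odds)))


def solve_alpha(
    target_penetrance: float,
    mafs,
    theta1: float,
    theta2: float,
    tol: float = 1e-12,
) -> float:
    """Baseline odds alpha giving the requested population prevalence.

    The prevalence E_HWE[odds/(1+odds)] is continuous and strictly
    increasing in alpha, so a bracketed root on log(alpha) always converges.
    With theta1 = theta2 = 0 the closed form target/(1-target) is returned.
    """
    if not 0.0 < target_penetrance < 1.0:
        raise ValidationError("target penetrance must be in (0, 1)")
    if theta1 == 0.0 and theta2 == 0.0:
        return target_penetrance / (1.0 - target_penetrance)
    mafs = tuple(mafs)
    # Joint genotype law over the causal loci (independent under LE).
    probs = np.array([1.0])
    factors = np.array([1.0])
    per_g = np.array([1.0, 1.0 + theta1, 1.0 + theta2])
    for q in mafs:
        probs = np.outer(probs, hwe_probs(q)).ravel()
        factors = np.outer(factors, per_g).ravel()
    lo, hi = -40.0, 40.0
    f = lambda la: _prevalence(la, probs, factors) - target_penetrance
    if f(lo) > 0 or f(hi) < 0:
        raise StepCMHError("no bracket for alpha; target prevalence extreme")
    log_alpha = brentq(f, lo, hi, xtol=tol)
    return float(np.exp(log_alpha))


def _rng(model: SimulationModel, rng) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(model.seed)


def _draw_hwe(rng: np.random.Generator, mafs, n: int) -> np.ndarray:
    """n x len(mafs) genotype draws under HWE, one MAF per column."""
    q = np.asarray(mafs, dtype=float)
    return rng.binomial(1, q, size=(n, q.size)) + rng.binomial(
        1, q, size=(n, q.size)
    )


def _null_mafs(model: SimulationModel, rng: np.random.Generator) -> np.ndarray:
    kind = model.null_maf_law[0]
    if kind == "uniform":
        lo, hi = model.null_maf_law[1:3]
        return rng.uniform(lo, hi, size=model.n_null_snps)
    if kind == "fixed":
        return np.full(model.n_null_snps, float(model.null_maf_law[1]))
    raise ValidationError(f"unknown null MAF law {kind!r}")


def _assemble(
    model: SimulationModel,
    rng: np.random.Generator,
    causal: np.ndarray,
    trait: np.ndarray,
):
    """Attach null SNPs, shuffle SNP positions, and box up the dataset."""
    n = causal.shape[0]
    null_mafs = _null_mafs(model, rng)
    null = _draw_hwe(rng, null_mafs, n) if model.n_null_snps else np.empty(
        (n, 0), dtype=np.int64
    )
    codes = np.hstack([causal, null])
    n_snps = codes.shape[1]
    width = len(str(n_snps))
    ids = [f"snp{i + 1:0{width}d}" for i in range(n_snps)]
    order = rng.permutation(n_snps)
    genos = GenotypeMatrix(
        codes[:, order],
        [ids[i] for i in order],
        [f"s{i + 1}" for i in range(n)],
    )
    causal_ids = [ids[i] for i in range(model.n_causal)]
    truth = {
        "causal_snps": causal_ids,
        "alpha": model.resolved_alpha(),
        "theta1": model.theta1,
        "theta2": model.theta2,
        "causal_mafs": list(model.causal_mafs),
    }
    return genos, trait.astype(float), truth


def generate_dataset(
    model: SimulationModel,
    rng: np.random.Generator | None = None,
    max_attempts: int = 4000,
):
    """Retrospective case-control dataset with exact quotas.

    Population subjects (causal genotypes + Bernoulli(penetrance) status)
    are drawn in batches and kept until ``n_cases`` cases and
    ``n_controls`` controls are accumulated; null SNPs are then drawn for
    the retained subjects only, independent of the trait.  Returns
    ``(GenotypeMatrix, phenotype, truth)`` where truth records the causal
    SNP ids and the model parameters.  Fully reproducible from the seed.
    """
    rng = _rng(model, rng)
    alpha = model.resolved_alpha()
    kept_g, kept_y = [], []
    need_cases, need_controls = model.n_cases, model.n_controls
    batch = max(2048, 4 * (need_cases + need_controls))
    for _ in range(max_attempts):
        g = _draw_hwe(rng, model.causal_mafs, batch)
        p = penetrance(g, model, alpha=alpha)
        y = rng.random(batch) < p
        take_case = np.flatnonzero(y)[:need_cases]
        take_ctrl = np.flatnonzero(~y)[:need_controls]
        take = np.sort(np.concatenate([take_case, take_ctrl]))
        kept_g.append(g[take])
        kept_y.append(y[take])
        need_cases -= take_case.size
        need_controls -= take_ctrl.size
        if need_cases == 0 and need_controls == 0:
            causal = np.vstack(kept_g)
            trait = np.concatenate(kept_y).astype(np.int64)
            return _assemble(model, rng, causal, trait)
    raise StepCMHError(
        "case/control quotas not met; penetrance is too close to 0 or 1"
    )


def generate_prospective(
    model: SimulationModel,
    n_samples: int,
    rng: np.random.Generator | None = None,
    include_null: bool = False,
):
    """Prospective cohort draw (no quotas): genotypes and Bernoulli status.

    Used for prevalence and coefficient-recovery checks; returns
    ``(causal_genotypes, trait)`` arrays, or a full dataset triple when
    ``include_null`` is set.
    """
    rng = _rng(model, rng)
    alpha = model.resolved_alpha()
    g = _draw_hwe(rng, model.causal_mafs, n_samples)
    y = (rng.random(n_samples) < penetrance(g, model, alpha=alpha)).astype(
        np.int64
    )
    if include_null:
        return _assemble(model, rng, g, y)
    return g, y


def generate_ordinal_dataset(
    model: SimulationModel,
    n_samples: int,
    cutpoints,
    rng: np.random.Generator | None = None,
):
    """Ordinal-trait cohort under a proportional-odds extension.

    The linear predictor eta = log(alpha * prod factors) of the binary model
    is reused in a cumulative-logit law P(Y <= m) = expit(c_m - eta) with
    strictly increasing ``cutpoints`` (length I-1); categories are coded
    0..I-1.  This is an extension of the binary generator for ordinal-trait
    testing, not part of the case-control study design.
    """
    cut = np.asarray(cutpoints, dtype=float)
    if cut.ndim != 1 or cut.size < 1 or np.any(np.diff(cut) <= 0):
        raise ValidationError("cutpoints must be strictly increasing, length I-1")
    rng = _rng(model, rng)
    alpha = model.resolved_alpha()
    g = _draw_hwe(rng, model.causal_mafs, n_samples)
    eta = np.log(alpha) + np.log(
        genotype_factor(g, model.theta1, model.theta2)
    ).sum(axis=1)
    cum = expit(cut[None, :] - eta[:, None])  # P(Y <= m), n x (I-1)
    u = rng.random(n_samples)
    y = (u[:, None] > cum).sum(axis=1)
    return g, y.astype(np.int64)
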