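"""Stepwise CMH selection of jointly associated SNP sets.

The procedure alternates a forward step (add the candidate whose CMH
p-value, conditioned on the currently selected SNPs, is smallest and below
the entry threshold) with a backward step (drop the selected SNP whose
p-value conditioned on its co-members is largest and above the removal
threshold), until the forward step adds nothing.  The closed set is removed
from the candidate pool and the procedure restarts from the empty set;
it terminates when a round's first forward step finds no significant SNP.

``StepwiseCMH`` packages the procedure as a model object built from a
phenotype vector and a :class:`~stepcmh.genotypes.GenotypeMatrix`; its
``fit()`` returns a :class:`StepwiseCMHResults` carrying the discovered SNP
sets, the full step trace, and per-SNP conditional test results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cmh import CMHResult, ScoreScheme, cmh_test
from .exceptions import ValidationError
from .genotypes import GenotypeMatrix
from .stratify import assign_strata, build_table

__all__ = [
    "StepwiseConfig",
    "SelectionResult",
    "forward_step",
    "backward_step",
    "discover_sets",
    "StepwiseCMH",
    "StepwiseCMHResults",
]


@dataclass(frozen=True)
class StepwiseConfig:
    """Tuning of the stepwise CMH search.

    entry_threshold / removal_threshold : significance cutoffs for adding
        and dropping SNPs (both 5e-5 by default, the value used for the
        real-data analyses).
    scheme : 'mac_sum' (capped minor-allele-count-sum strata, the default)
        or 'full_cross' (one stratum per genotype tuple).
    cap : maximum number of MAC-sum strata.
    row_scheme / col_scheme : trait and genotype score schemes; nominal on
        both sides gives the general association test for the codominant
        model.
    backward_enabled : whether the backward elimination step runs.
    max_set_size : hard bound on one discovered set (termination guard).
    """

    entry_threshold: float = 5e-5
    removal_threshold: float = 5e-5
    scheme: str = "mac_sum"
    cap: int = 10
    row_scheme: ScoreScheme = field(default_factory=ScoreScheme.nominal)
    col_scheme: ScoreScheme = field(default_factory=ScoreScheme.nominal)
    backward_enabled: bool = True
    max_set_size: int = 30

    def __post_init__(self) -> None:
        for name in ("entry_threshold", "removal_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must be in (0, 1]")
        if self.max_set_size < 1:
            raise ValidationError("max_set_size must be >= 1")


@dataclass
class SelectionResult:
    """Discovered disjoint SNP sets plus the per-step trace."""

    snp_sets: list[list[str]]
    trace: pd.DataFrame

    @property
    def selected(self) -> list[str]:
        """Union of all discovered sets, in discovery order."""
        return [s for snp_set in self.snp_sets for s in snp_set]


_TRACE_COLUMNS = ["round", "step", "kind", "snp", "p_value", "statistic",
                  "df", "action"]


def _conditional_test(
    pheno: np.ndarray,
    genos: GenotypeMatrix,
    target: str,
    conditioning: list[str],
    config: StepwiseConfig,
    n_trait_levels: int,
) -> CMHResult:
    """CMH test of one SNP conditioned on a set (K=1 when the set is empty)."""
    strata = assign_strata(genos, conditioning, config.scheme, config.cap)
    table = build_table(pheno, target, strata, genos, n_trait_levels)
    return cmh_test(table, config.row_scheme, config.col_scheme)


def forward_step(
    selected: list[str],
    candidates: list[str],
    pheno: np.ndarray,
    genos: GenotypeMatrix,
    config: StepwiseConfig,
    n_trait_levels: int | None = None,
) -> tuple[str | None, CMHResult | None]:
    """Test every candidate conditioned on ``selected``; add the best.

    Returns the minimum-p candidate and its result iff that p-value is below
    the entry threshold, else ``(None, best_result_or_None)``.  Ties on
    p-value go to the larger statistic, then to candidate order.
    """
    if set(selected) & set(candidates):
        raise ValidationError("selected and candidate sets overlap")
    n_i = int(n_trait_levels or (int(np.nanmax(pheno)) + 1))
    strata = assign_strata(genos, selected, config.scheme, config.cap)
    best: tuple[float, float, int] | None = None  # (p, -stat, order)
    best_snp, best_res = None, None
    for order, snp in enumerate(candidates):
        table = build_table(pheno, snp, strata, genos, n_i)
        res = cmh_test(table, config.row_scheme, config.col_scheme)
        key = (res.p_value, -res.statistic, order)
        if best is None or key < best:
            best, best_snp, best_res = key, snp, res
    if best_res is not None and best_res.p_value < config.entry_threshold:
        return best_snp, best_res
    return None, best_res


def backward_step(
    selected: list[str],
    pheno: np.ndarray,
    genos: GenotypeMatrix,
    config: StepwiseConfig,
    n_trait_levels: int | None = None,
) -> tuple[str | None, CMHResult | None]:
    """Test each member conditioned on the rest; drop the worst offender.

    At most one SNP — the one with the largest p-value — is removed, and
    only if that p-value exceeds the removal threshold.
    """
    if not selected:
        raise ValidationError("backward step needs a non-empty selected set")
    n_i = int(n_trait_levels or (int(np.nanmax(pheno)) + 1))
    worst: tuple[float, float, int] | None = None
    worst_snp, worst_res = None, None
    for order, snp in enumerate(selected):
        rest = [s for s in selected if s != snp]
        res = _conditional_test(pheno, genos, snp, rest, config, n_i)
        key = (-res.p_value, res.statistic, order)
        if worst is None or key < worst:
            worst, worst_snp, worst_res = key, snp, res
    if worst_res is not None and worst_res.p_value > config.removal_threshold:
        return worst_snp, worst_res
    return None, worst_res


def discover_sets(
    pheno: np.ndarray,
    genos: GenotypeMatrix,
    config: StepwiseConfig | None = None,
) -> SelectionResult:
    """Run the full stepwise procedure, discovering disjoint SNP sets.

    Deterministic given the input SNP order.  A visited-state check and
    ``max_set_size`` guard against forward/backward oscillation.
    """
    config = config or StepwiseConfig()
    n_i = int(np.nanmax(pheno)) + 1
    if n_i < 2:
        raise ValidationError("phenotype needs at least 2 observed levels")
    pool = list(genos.snp_ids)
    snp_sets: list[list[str]] = []
    rows: list[tuple] = []
    round_no = 0
    while pool:
        round_no += 1
        selected: list[str] = []
        visited = {frozenset()}
        step_no = 0
        while True:
            step_no += 1
            candidates = [s for s in pool if s not in selected]
            added, res = forward_step(
                selected, candidates, pheno, genos, config, n_i
            )
            if added is None:
                if res is not None:
                    rows.append((round_no, step_no, "forward", None,
                                 res.p_value, res.statistic, res.df, "stop"))
                break
            selected.append(added)
            rows.append((round_no, step_no, "forward", added, res.p_value,
                         res.statistic, res.df, "add"))
            state = frozenset(selected)
            if state in visited or len(selected) >= config.max_set_size:
                break
            visited.add(state)
            stop_round = False
            if config.backward_enabled and len(selected) > 1:
                while selected:
                    removed, rres = backward_step(
                        selected, pheno, genos, config, n_i
                    )
                    if removed is None:
                        break
                    selected.remove(removed)
                    step_no += 1
                    rows.append((round_no, step_no, "backward", removed,
                                 rres.p_value, rres.statistic, rres.df,
                                 "remove"))
                    if frozenset(selected) in visited:
                        stop_round = True  # oscillation guard
                        break
                    visited.add(frozenset(selected))
            if stop_round:
                break
        if not selected:
            break
        snp_sets.append(selected)
        pool = [s for s in pool if s not in selected]
    trace = pd.DataFrame(rows, columns=_TRACE_COLUMNS)
    return SelectionResult(snp_sets=snp_sets, trace=trace)


class StepwiseCMH:
    """Stepwise CMH model over a phenotype and a genotype matrix.

    Parameters
    ----------
    phenotype : array-like
        Trait level codes 0..I-1 per sample (NaN / negative = missing).
        Binary traits use 0 = control, 1 = case.
    genotypes : GenotypeMatrix
        Minor-allele-count codes per sample x SNP.
    trait_type : {'binary', 'nominal', 'ordinal'}
        Ordinal traits are scored 1..I on the rows (mean-score /
        correlation tests); binary and nominal traits use the nominal
        contrast (general association).
    genetic_model : {'codominant', 'additive', 'dominant', 'recessive'}
        Codominant treats the genotype as a free three-level factor;
        the others are mean-score tests with the standard 0/1/2 codings.
    **config_kwargs
        Remaining :class:`StepwiseConfig` fields (thresholds, scheme, cap,
        backward_enabled, max_set_size).
    """

    def __init__(
        self,
        phenotype,
        genotypes: GenotypeMatrix,
        trait_type: str = "binary",
        genetic_model: str = "codominant",
        **config_kwargs,
    ) -> None:
        pheno = np.asarray(phenotype, dtype=float)
        if pheno.ndim != 1 or pheno.shape[0] != genotypes.n_samples:
            raise ValidationError("phenotype must be 1-D, one code per sample")
        observed = pheno[~np.isnan(pheno) & (pheno >= 0)]
        if observed.size == 0 or np.unique(observed).size < 2:
            raise ValidationError("phenotype needs at least 2 observed levels")
        self.n_trait_levels = int(observed.max()) + 1
        if trait_type == "ordinal":
            row_scheme = ScoreScheme.ordinal(range(1, self.n_trait_levels + 1))
        elif trait_type in ("binary", "nominal"):
            row_scheme = ScoreScheme.nominal()
        else:
            raise ValidationError(f"unknown trait type {trait_type!r}")
        self.phenotype = pheno
        self.genotypes = genotypes
        self.trait_type = trait_type
        self.genetic_model = genetic_model
        self.config = StepwiseConfig(
            row_scheme=row_scheme,
            col_scheme=ScoreScheme.genetic_model(genetic_model),
            **config_kwargs,
        )

    @classmethod
    def from_dataframe(
        cls,
        genotype_frame: pd.DataFrame,
        phenotype: pd.Series,
        **kwargs,
    ) -> "StepwiseCMH":
        """Build from a samples x SNPs DataFrame and an aligned trait Series."""
        pheno = phenotype.reindex(genotype_frame.index)
        return cls(
            pheno.to_numpy(dtype=float, na_value=np.nan),
            GenotypeMatrix.from_frame(genotype_frame),
            **kwargs,
        )

    def fit(self) -> "StepwiseCMHResults":
        """Run the stepwise search and wrap the outcome."""
        selection = discover_sets(self.phenotype, self.genotypes, self.config)
        return StepwiseCMHResults(self, selection)

    def test_snp(self, target: str, conditioning=()) -> CMHResult:
        """One conditional CMH test, outside the stepwise search."""
        return _conditional_test(
            self.phenotype, self.genotypes, target, list(conditioning),
            self.config, self.n_trait_levels,
        )


class StepwiseCMHResults:
    """Fitted stepwise CMH selection: SNP sets, trace, conditional tests."""

    def __init__(self, model: StepwiseCMH, selection: SelectionResult) -> None:
        self.model = model
        self.snp_sets = selection.snp_sets
        self.trace = selection.trace
        self._selection = selection

    @property
    def selected(self) -> list[str]:
        return self._selection.selected

    def conditional_results(self) -> pd.DataFrame:
        """Final test of each selected SNP given its co-members."""
        rows = []
        for set_no, snp_set in enumerate(self.snp_sets, start=1):
            for snp in snp_set:
                rest = [s for s in snp_set if s != snp]
                res = self.model.test_snp(snp, rest)
                rows.append(
                    (set_no, snp, res.statistic, res.df, res.p_value,
                     res.n_strata_used)
                )
        return pd.DataFrame(
            rows,
            columns=["set", "snp", "statistic", "df", "p_value", "n_strata"],
        )

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Stepwise CMH selection",
            "=" * 58,
            f"Samples: {self.model.genotypes.n_samples}   "
            f"SNPs: {self.model.genotypes.n_snps}   "
            f"Trait levels: {self.model.n_trait_levels}",
            f"Trait type: {self.model.trait_type}   "
            f"Genetic model: {self.model.genetic_model}",
            f"Entry/removal thresholds: {cfg.entry_threshold:g} / "
            f"{cfg.removal_threshold:g}",
            f"Stratification: {cfg.scheme}"
            + (f" (cap {cfg.cap})" if cfg.scheme == "mac_sum" else ""),
            "-" * 58,
        ]
        if not self.snp_sets:
            lines.append("No SNP set reached the entry threshold.")
        else:
            table = self.conditional_results()
            for set_no, group in table.groupby("set"):
                lines.append(f"Set {set_no}:")
                for _, r in group.iterrows():
                    lines.append(
                        f"  {r['snp']:<16} L2={r['statistic']:>9.4f}  "
                        f"df={int(r['df'])}  p={r['p_value']:.3e}"
                    )
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<StepwiseCMHResults: {len(self.snp_sets)} set(s), "
            f"{len(self.selected)} SNP(s)>"
        )
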