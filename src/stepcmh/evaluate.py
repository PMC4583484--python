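"""Scoring of selection results against simulation truth, and replicate studies.

Two accuracy measures summarise a method over replicates of a scenario:

* detection probability (Dprob): the mean, over replicates, of the fraction
  of true causal SNPs captured — |selected ∩ truth| / |truth|;
* power: the fraction of replicates in which *all* causal SNPs were
  captured.

Power can never exceed Dprob, since full capture contributes 1 to both.
"Selected" is the union of every discovered set in a replicate; false
positives do not reduce either measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .logistic import discover_sets_logistic
from .model import ScoreScheme, StepwiseConfig, discover_sets
from .simulate import SimulationModel, generate_dataset

__all__ = ["AccuracyMetrics", "score_replicate", "run_study", "plot_study"]

logger = logging.getLogger(__name__)

METHODS = ("stepwise_cmh", "stepwise_logistic")


@dataclass(frozen=True)
class AccuracyMetrics:
    """Dprob/power for one scenario x method cell of a study."""

    dprob: float
    power: float
    n_replicates: int
    scenario: dict | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.power <= self.dprob <= 1.0:
            raise ValidationError(
                "metrics must satisfy 0 <= power <= dprob <= 1"
            )


def score_replicate(selected, truth) -> tuple[float, bool]:
    """Captured fraction and all-captured flag for one replicate.

    ``selected`` is the union of discovered SNP ids; ``truth`` the causal
    ids.  Extra selected SNPs are ignored by both measures.
    """
    truth = set(truth)
    if not truth:
        raise ValidationError("truth set must be non-empty")
    fraction = len(set(selected) & truth) / len(truth)
    return fraction, fraction == 1.0


def _run_method(method: str, pheno, genos, config: StepwiseConfig):
    if method == "stepwise_cmh":
        return discover_sets(pheno, genos, config)
    if method == "stepwise_logistic":
        return discover_sets_logistic(pheno, genos, config)
    raise ValidationError(f"unknown method {method!r}")


def run_study(
    scenarios,
    n_replicates: int,
    methods=METHODS,
    seed: int = 0,
    cap: int = 10,
    total_penetrance: float = 0.1,
    n_cases: int = 1000,
    n_controls: int = 1000,
) -> pd.DataFrame:
    """Replicate study over a scenario grid; returns a tidy metrics table.

    Each scenario is a mapping with keys ``maf`` (shared causal MAF),
    ``n_causal``, ``n_snps`` (total including null SNPs) and ``threshold``
    (entry = removal cutoff).  Every method sees the same replicate
    datasets; per-replicate seeds derive deterministically from ``seed``.
    A method failure on a replicate is logged and counted as zero capture.
    """
    methods = list(methods)
    for m in methods:
        if m not in METHODS:
            raise ValidationError(f"unknown method {m!r}")
    columns = ["maf", "n_causal", "n_snps", "threshold", "method",
               "dprob", "power", "n_replicates"]
    if n_replicates == 0:
        return pd.DataFrame(columns=columns)
    rows = []
    scenarios = list(scenarios)
    scenario_seeds = np.random.SeedSequence(seed).spawn(len(scenarios))
    for s_idx, scen in enumerate(scenarios):
        maf = float(scen["maf"])
        n_causal = int(scen.get("n_causal", 2))
        n_snps = int(scen.get("n_snps", 100))
        threshold = float(scen["threshold"])
        model = SimulationModel(
            causal_mafs=(maf,) * n_causal,
            total_penetrance=total_penetrance,
            n_cases=n_cases,
            n_controls=n_controls,
            n_null_snps=n_snps - n_causal,
        )
        config = StepwiseConfig(
            entry_threshold=threshold,
            removal_threshold=threshold,
            scheme="mac_sum",
            cap=cap,
            row_scheme=ScoreScheme.nominal(),
            col_scheme=ScoreScheme.nominal(),
        )
        fractions = {m: [] for m in methods}
        flags = {m: [] for m in methods}
        children = scenario_seeds[s_idx].spawn(n_replicates)
        for rep, child in enumerate(children):
            rng = np.random.default_rng(child)
            genos, pheno, truth = generate_dataset(model, rng=rng)
            for m in methods:
                try:
                    sel = _run_method(m, pheno, genos, config)
                    frac, flag = score_replicate(
                        sel.selected, truth["causal_snps"]
                    )
                except Exception:
                    logger.exception(
                        "%s failed on replicate %d of scenario %r", m, rep, scen
                    )
                    frac, flag = 0.0, False
                fractions[m].append(frac)
                flags[m].append(flag)
        for m in methods:
            metrics = AccuracyMetrics(
                dprob=float(np.mean(fractions[m])),
                power=float(np.mean(flags[m])),
                n_replicates=n_replicates,
                scenario=dict(scen),
                method=m,
            )
            rows.append(
                (maf, n_causal, n_snps, threshold, m, metrics.dprob,
                 metrics.power, n_replicates)
            )
    return pd.DataFrame(rows, columns=columns)


def plot_study(results: pd.DataFrame, ax=None):
    """Grouped bar chart of Dprob (solid) and power (hatched) per method/MAF."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    methods = list(dict.fromkeys(results["method"]))
    mafs = sorted(results["maf"].unique())
    width = 0.8 / (2 * len(methods))
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for mi, m in enumerate(methods):
        sub = results[results["method"] == m].set_index("maf").loc[mafs]
        x = np.arange(len(mafs)) + (2 * mi) * width
        ax.bar(x, sub["dprob"], width, color=colors[mi % len(colors)],
               label=f"{m} Dprob")
        ax.bar(x + width, sub["power"], width, color=colors[mi % len(colors)],
               hatch="//", alpha=0.6, label=f"{m} power")
    ax.set_xticks(np.arange(len(mafs)) + 0.4 - width / 2)
    ax.set_xticklabels([f"{m:g}" for m in mafs])
    ax.set_xlabel("causal MAF")
    ax.set_ylabel("accuracy")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    return ax
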