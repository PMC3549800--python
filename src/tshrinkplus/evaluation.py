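"""Benchmarking: truth labels, ROC/partial AUC, TP/FP, subsample studies.

The evaluation convention: run a standard t-test on a large design and
call a gene "truly" DE if its Bonferroni-adjusted p-value is below 0.05,
"truly" not DE if its unadjusted p-value exceeds 0.05; everything in
between is ambiguous and excluded from all metrics.  Methods are then run
on repeated small random subsamples and scored by the partial area under
the ROC curve for FPR <= 0.01 (normalized so 1 is a perfect ranking) and
by TP/FP counts at the Bonferroni 0.05 cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CountMatrix
from .de import DEOutcome, METHODS, run_method

__all__ = [
    "define_truth",
    "partial_auc",
    "tp_fp_at_cutoff",
    "subsample_benchmark",
    "BenchmarkReport",
]


def define_truth(full_results: DEOutcome | pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Label genes DE / notDE / ambiguous from a large-design test.

    DE iff Bonferroni-adjusted p < alpha; notDE iff unadjusted p > alpha;
    ambiguous otherwise.
    """
    table = full_results.table if isinstance(full_results, DEOutcome) else full_results
    label = np.where(
        table["p_adjusted"] < alpha,
        "DE",
        np.where(table["p_value"] > alpha, "notDE", "ambiguous"),
    )
    return pd.Series(label, index=table.index, name="label")


def _ranked_labels(results: DEOutcome | pd.DataFrame, truth: pd.Series) -> np.ndarray:
    """Boolean is-DE array in test ranking order, ambiguous genes dropped.

    Ranking is by p-value ascending, ties broken by |statistic| descending
    then gene id — a total order, so the ROC is stepwise.
    """
    table = results.table if isinstance(results, DEOutcome) else results
    truth = truth.reindex(table.index)
    keep = truth.isin(["DE", "notDE"])
    sub = table.loc[keep].copy()
    sub["_abs_stat"] = -sub["statistic"].abs()
    sub["_gene"] = sub.index
    sub = sub.sort_values(["p_value", "_abs_stat", "_gene"], kind="mergesort")
    return (truth.loc[sub.index] == "DE").to_numpy()


def partial_auc(
    results: DEOutcome | pd.DataFrame, truth: pd.Series, fpr_max: float = 0.01
) -> float:
    """Normalized partial area under the ROC for FPR <= ``fpr_max``.

    1.0 means every DE gene ranks ahead of every notDE gene; 0.0 is the
    reverse.  Computed by the trapezoidal rule on the stepwise ROC,
    interpolated at ``fpr_max``, and divided by ``fpr_max``.
    """
    is_de = _ranked_labels(results, truth)
    n_de = int(is_de.sum())
    n_not = int(len(is_de) - n_de)
    if n_de == 0 or n_not == 0:
        raise ValueError("need at least one DE and one notDE gene")
    tpr = np.concatenate([[0.0], np.cumsum(is_de) / n_de])
    fpr = np.concatenate([[0.0], np.cumsum(~is_de) / n_not])
    # integrate TPR dFPR over [0, fpr_max]
    area = 0.0
    for i in range(1, len(fpr)):
        f0, f1 = fpr[i - 1], fpr[i]
        if f1 == f0:
            continue
        if f0 >= fpr_max:
            break
        f_hi = min(f1, fpr_max)
        # stepwise ROC: within a single false-positive step TPR is constant
        t0, t1 = tpr[i - 1], tpr[i]
        frac = (f_hi - f0) / (f1 - f0)
        t_hi = t0 + frac * (t1 - t0)
        area += 0.5 * (t0 + t_hi) * (f_hi - f0)
    return float(area / fpr_max)


def tp_fp_at_cutoff(
    results: DEOutcome | pd.DataFrame, truth: pd.Series, alpha: float = 0.05
) -> tuple[int, int]:
    """True/false positive counts at the adjusted-p cutoff ``alpha``."""
    table = results.table if isinstance(results, DEOutcome) else results
    truth = truth.reindex(table.index)
    passed = table["p_adjusted"] < alpha
    tp = int((passed & (truth == "DE")).sum())
    fp = int((passed & (truth == "notDE")).sum())
    return tp, fp


# threshold-wise ROC averaging grid used in reports
P_GRID = np.logspace(-12, 0, 200)


@dataclass
class BenchmarkReport:
    """Averaged subsample-benchmark metrics, one entry per method."""

    n: int
    replicates: int
    seed: int
    pauc: dict = field(default_factory=dict)  # method -> mean pAUC
    tp: dict = field(default_factory=dict)  # method -> mean TP at cutoff
    fp: dict = field(default_factory=dict)
    lambdas: dict = field(default_factory=dict)  # method -> mean lambda
    roc: dict = field(default_factory=dict)  # method -> (mean FPR, mean TPR) on P_GRID

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "replicates": self.replicates,
            "seed": self.seed,
            "pauc": {k: float(v) for k, v in self.pauc.items()},
            "tp": {k: float(v) for k, v in self.tp.items()},
            "fp": {k: float(v) for k, v in self.fp.items()},
            "lambda": {k: float(v) for k, v in self.lambdas.items()},
            "roc": {
                k: {"fpr": list(map(float, v[0])), "tpr": list(map(float, v[1]))}
                for k, v in self.roc.items()
            },
        }


def _roc_on_grid(results: DEOutcome, truth: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    table = results.table
    truth = truth.reindex(table.index)
    keep = truth.isin(["DE", "notDE"])
    p = table.loc[keep, "p_value"].to_numpy()
    de = (truth.loc[keep] == "DE").to_numpy()
    n_de, n_not = de.sum(), (~de).sum()
    tpr = np.array([(de & (p < c)).sum() / n_de for c in P_GRID])
    fpr = np.array([((~de) & (p < c)).sum() / n_not for c in P_GRID])
    return fpr, tpr


def subsample_benchmark(
    cm: CountMatrix,
    truth: pd.Series,
    methods=METHODS,
    n: int = 4,
    replicates: int = 100,
    seed: int = 0,
    covariate: pd.Series | None = None,
    alpha: float = 0.05,
    fpr_max: float = 0.01,
    span: float = 0.5,
    keep_roc: bool = False,
) -> BenchmarkReport:
    """Repeated random n-vs-n subsample comparison of the test methods.

    Each replicate draws ``n`` samples per group without replacement (all
    methods see the same draw), runs each method, and records pAUC at
    ``fpr_max``, TP/FP at the Bonferroni ``alpha`` cutoff and lambda;
    metrics are averaged over replicates.  A master seed derives one child
    seed per replicate, so reports are bit-reproducible.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    g1, g2 = cm.groups
    s1, s2 = cm.group_samples(g1), cm.group_samples(g2)
    if n > len(s1) or n > len(s2):
        raise ValueError(f"n={n} exceeds a group size ({len(s1)}, {len(s2)})")
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    if "Tshrink+" in methods and covariate is None:
        raise ValueError("Tshrink+ benchmark requires a covariate")

    child_seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)
    acc = {m: {"pauc": [], "tp": [], "fp": [], "lambda": [], "fpr": [], "tpr": []} for m in methods}
    for r in range(replicates):
        rng = np.random.default_rng(int(child_seeds[r]))
        pick = list(rng.choice(s1, n, replace=False)) + list(
            rng.choice(s2, n, replace=False)
        )
        sub = cm.subset_samples(pick)
        for m in methods:
            res = run_method(sub, m, covariate=covariate, span=span)
            acc[m]["pauc"].append(partial_auc(res, truth, fpr_max=fpr_max))
            tp, fp = tp_fp_at_cutoff(res, truth, alpha=alpha)
            acc[m]["tp"].append(tp)
            acc[m]["fp"].append(fp)
            acc[m]["lambda"].append(res.lambda_)
            if keep_roc:
                f, t = _roc_on_grid(res, truth)
                acc[m]["fpr"].append(f)
                acc[m]["tpr"].append(t)

    report = BenchmarkReport(n=n, replicates=replicates, seed=seed)
    for m in methods:
        report.pauc[m] = float(np.mean(acc[m]["pauc"]))
        report.tp[m] = float(np.mean(acc[m]["tp"]))
        report.fp[m] = float(np.mean(acc[m]["fp"]))
        report.lambdas[m] = float(np.mean(acc[m]["lambda"]))
        if keep_roc:
            report.roc[m] = (
                np.mean(acc[m]["fpr"], axis=0),
                np.mean(acc[m]["tpr"], axis=0),
            )
    return report
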