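"""Moderated Wald tests for two-group differential expression.

The per-gene statistic is

    W = (ybar_1 - ybar_2) / sqrt(sigma2_shrink * (1/n1 + 1/n2)),

referred to a Student-t distribution on nu_shrink degrees of freedom
(standard normal when nu_shrink is infinite).  Three method variants share
this statistic and differ only in the variance that enters it:

* ``T``        — the raw pooled sample variance (lambda = 0, df = nu_gene);
                 an ordinary pooled two-sample t-test.
* ``Tshrink``  — variance moderated toward a mean-only common-variance
                 surface.
* ``Tshrink+`` — variance moderated toward a surface that also uses one
                 standardized external covariate (external variance track
                 or gene length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CommonVarianceModel, CountMatrix, GeneMoments, ModerationResult
from .moderation import moderate
from .variance import compute_moments, fit_common_variance

__all__ = ["DEOutcome", "wald_test", "adjust_bonferroni", "adjust_bh", "run_method", "METHODS"]

METHODS = ("T", "Tshrink", "Tshrink+")


@dataclass
class DEOutcome:
    """Per-gene test results plus the run summary downstream tools consume."""

    table: pd.DataFrame  # mean_g1 mean_g2 statistic df_used p_value p_adjusted
    method: str
    lambda_: float
    nu_shrink: float
    n_zero_variance_conflicts: int = 0
    summary_extra: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "method": self.method,
            "lambda": float(self.lambda_),
            "nu_shrink": float(self.nu_shrink) if np.isfinite(self.nu_shrink) else "inf",
            "n_genes": int(len(self.table)),
            "zero_variance_conflicts": int(self.n_zero_variance_conflicts),
            **self.summary_extra,
        }


def wald_test(cm: CountMatrix, moderation: ModerationResult, method: str = "Tshrink") -> DEOutcome:
    """Per-gene moderated Wald test of the two group means.

    Genes with zero moderated variance get statistic 0 / p = 1 when the
    group means coincide, and p = 0 (counted as a warning in the summary)
    when they do not — a nonzero difference with literally zero variance is
    infinitely significant under the model.
    """
    if not moderation.sigma2_shrink.index.equals(cm.gene_ids):
        raise ValueError("moderation gene set does not match the count matrix")
    cm.require_replicates(2)
    g1, g2 = cm.groups
    y1 = cm.counts[cm.group_samples(g1)]
    y2 = cm.counts[cm.group_samples(g2)]
    n1, n2 = y1.shape[1], y2.shape[1]
    mean1 = y1.mean(axis=1).to_numpy(float)
    mean2 = y2.mean(axis=1).to_numpy(float)
    diff = mean1 - mean2
    s2 = moderation.sigma2_shrink.to_numpy(float)
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))

    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, diff / se, 0.0)
    df = moderation.nu_shrink
    if np.isfinite(df):
        p = 2.0 * stats.t.sf(np.abs(stat), df)
    else:
        p = 2.0 * stats.norm.sf(np.abs(stat))

    zero_conflict = (se == 0) & (diff != 0)
    p = np.where(zero_conflict, 0.0, p)
    p = np.where((se == 0) & (diff == 0), 1.0, p)

    table = pd.DataFrame(
        {
            "mean_g1": mean1,
            "mean_g2": mean2,
            "statistic": stat,
            "df_used": df,
            "p_value": p,
        },
        index=cm.gene_ids,
    )
    out = DEOutcome(
        table=table,
        method=method,
        lambda_=moderation.lambda_,
        nu_shrink=df,
        n_zero_variance_conflicts=int(zero_conflict.sum()),
    )
    return adjust_bonferroni(out)


def adjust_bonferroni(outcome: DEOutcome) -> DEOutcome:
    """Bonferroni family-wise adjustment: p_adjusted = min(1, G * p)."""
    g = len(outcome.table)
    outcome.table["p_adjusted"] = np.minimum(1.0, g * outcome.table["p_value"])
    return outcome


def adjust_bh(outcome: DEOutcome) -> DEOutcome:
    """Benjamini-Hochberg FDR adjustment, available behind a flag."""
    from statsmodels.stats.multitest import multipletests

    outcome.table["p_adjusted"] = multipletests(
        outcome.table["p_value"].to_numpy(), method="fdr_bh"
    )[1]
    return outcome


def run_method(
    cm: CountMatrix,
    method: str,
    covariate: pd.Series | None = None,
    span: float = 0.5,
) -> DEOutcome:
    """Run one full test pipeline (moments -> surface -> moderation -> Wald).

    ``method`` is one of ``T``, ``Tshrink``, ``Tshrink+``; the covariate is
    required for Tshrink+ and ignored for the others.  Results keep the
    count matrix's gene order so methods are directly comparable.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    moments = compute_moments(cm)

    if method == "T":
        moderation = ModerationResult(
            lambda_=0.0,
            sigma2_shrink=moments.s2.rename("sigma2_shrink"),
            nu_k=pd.Series(
                float(moments.nu_gene), index=moments.table.index, name="nu_k"
            ),
            nu_shrink=float(moments.nu_gene),
            nu_gene=moments.nu_gene,
        )
        return wald_test(cm, moderation, method="T")

    if method == "Tshrink+":
        if covariate is None:
            raise ValueError("Tshrink+ requires an external covariate")
        model = fit_common_variance(moments, covariate=covariate, span=span)
    else:
        model = fit_common_variance(moments, covariate=None, span=span)
    moderation = moderate(moments, model)
    return wald_test(cm, moderation, method=method)
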