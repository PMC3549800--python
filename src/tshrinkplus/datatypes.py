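"""Core data containers shared by every pipeline stage.

The count matrix follows the standard genes x samples layout: one row per
gene, one column per sample, with a two-group condition design attached.
Counts are integers on input and become non-negative reals after
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "VarianceTrack",
    "GeneMoments",
    "CommonVarianceModel",
    "ModerationResult",
    "validate_annotation",
]


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative counts with condition labels.

    Parameters
    ----------
    counts : DataFrame
        Rows indexed by gene id, columns by sample id; non-negative values.
    conditions : Series
        Maps every sample id to one of exactly two group labels.
    """

    counts: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if not self.counts.columns.is_unique:
            raise ValueError("duplicate sample ids in count matrix")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("count matrix contains non-numeric entries")
        if np.isnan(vals).any():
            raise ValueError("count matrix contains missing values")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )
        self.conditions = pd.Series(self.conditions)
        missing = self.counts.columns.difference(self.conditions.index)
        if len(missing):
            raise ValueError(f"samples without a condition label: {list(missing)}")
        self.conditions = self.conditions.loc[self.counts.columns]
        groups = pd.unique(self.conditions)
        if len(groups) != 2:
            raise ValueError(
                f"expected exactly 2 condition groups, got {list(groups)}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def groups(self) -> tuple:
        """The two group labels, in sorted order (so that relabeling the
        groups swaps the roles of group 1 and group 2)."""
        g = sorted(pd.unique(self.conditions), key=str)
        return (g[0], g[1])

    def group_samples(self, group) -> list:
        return list(self.conditions.index[self.conditions == group])

    def require_replicates(self, min_per_group: int = 2) -> None:
        for g in self.groups:
            n = len(self.group_samples(g))
            if n < min_per_group:
                raise ValueError(
                    f"group {g!r} has {n} samples; need >= {min_per_group}"
                )

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(sample_ids)].copy(),
            self.conditions.loc[list(sample_ids)].copy(),
        )


@dataclass
class VarianceTrack:
    """Gene-wise mean/variance summaries from an external experiment.

    ``table`` is indexed by gene id with columns ``ext_mean``,
    ``ext_variance`` and ``n_replicates``.  These are the raw material for
    the standardized covariates entering the common-variance surface.
    """

    table: pd.DataFrame
    source_label: str = ""

    REQUIRED = ("ext_mean", "ext_variance", "n_replicates")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"variance track missing columns: {missing}")
        if not self.table.index.is_unique:
            raise ValueError("duplicate gene ids in variance track")
        t = self.table
        if (t["ext_variance"] < 0).any():
            raise ValueError("negative external variance")
        if (t["ext_mean"] < 0).any():
            raise ValueError("negative external mean")
        if (t["n_replicates"] < 2).any():
            raise ValueError("external n_replicates must be >= 2")


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene annotation table (index gene_id; length, gc_fraction).

    Lengths are positive base-pair integers; gc_fraction lies in [0, 1].
    """
    for col in ("length", "gc_fraction"):
        if col not in ann.columns:
            raise ValueError(f"annotation missing column {col!r}")
    if not ann.index.is_unique:
        dup = ann.index[ann.index.duplicated()][0]
        raise ValueError(f"duplicate gene id in annotation: {dup!r}")
    if (ann["length"] < 1).any():
        raise ValueError("gene length must be >= 1 bp")
    gc = ann["gc_fraction"]
    if ((gc < 0) | (gc > 1)).any():
        bad = ann.index[(gc < 0) | (gc > 1)][0]
        raise ValueError(f"gc_fraction outside [0, 1] for gene {bad!r}")
    return ann


# moment/moderation containers live here so every stage can share them


@dataclass
class GeneMoments:
    """Per-gene pooled moments: mu_hat (mean over all samples), s2 (pooled
    within-group sample variance) and the shared residual degrees of
    freedom nu_gene = n1 + n2 - 2."""

    table: pd.DataFrame  # columns mu_hat, s2; index gene_id
    nu_gene: int
    n1: int
    n2: int

    @property
    def mu_hat(self) -> pd.Series:
        return self.table["mu_hat"]

    @property
    def s2(self) -> pd.Series:
        return self.table["s2"]


@dataclass
class CommonVarianceModel:
    """Fitted common-variance surface sigma2_common = mu + f(mu, gamma).

    ``sigma2_common`` is floored at mu_hat gene-wise (a count can never be
    less dispersed than Poisson), and ``smoother`` retains enough state to
    predict at new (log-mean, covariate) points.
    """

    sigma2_common: pd.Series
    smoother: object
    span: float
    covariate_name: str | None = None
    log_bias: float = 0.0  # chi-square bias of log s2, removed at back-transform

    def predict(self, mu_hat: np.ndarray, covariate: np.ndarray | None = None) -> np.ndarray:
        mu_hat = np.asarray(mu_hat, dtype=float)
        log_mu = np.log(mu_hat + 0.5)
        if self.covariate_name is None:
            g = np.exp(self.smoother.predict(log_mu) - self.log_bias)
        else:
            cov = np.zeros_like(log_mu) if covariate is None else np.asarray(covariate, float)
            g = np.exp(self.smoother.predict(np.column_stack([log_mu, cov])) - self.log_bias)
        return np.maximum(g, mu_hat)


@dataclass
class ModerationResult:
    """Shrinkage output: lambda, moderated variances and degrees of freedom.

    nu_k is the per-gene Welch-Satterthwaite effective df (np.inf when the
    moderated variance has no finite-df component); nu_shrink is their mean
    and is the single df used for every gene's p-value.
    """

    lambda_: float
    sigma2_shrink: pd.Series
    nu_k: pd.Series
    nu_shrink: float
    nu_gene: int
    n_lambda_genes: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lambda_ <= 1.0):
            raise ValueError(f"lambda outside [0, 1]: {self.lambda_}")
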