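"""Shrinkage of gene-wise variances toward the common-variance surface.

The moderated variance is the convex combination

    sigma2_shrink = lambda * sigma2_common + (1 - lambda) * s2,

where lambda is the ratio of the expected to the average squared error of
the common-variance fit: with ratios r_k = s2_k / sigma2_common_k over K
participating genes,

    lambda = min(1, (2 K / nu_gene) / sum_k (r_k - 1)^2).

Under the working assumption that data standardized by the common variance
are approximately standard normal, each r_k has variance 2 / nu_gene, so
lambda = 1 says the surface fully explains the observed gene variances.

Degrees of freedom of the moderated variance follow Welch-Satterthwaite
with the common-variance component treated as infinitely precise
(nu_common = infinity):

    nu_k = (lambda * sigma2_common_k + (1 - lambda) * s2_k)^2
           / ((1 - lambda)^2 * s2_k^2 / nu_gene).

A single pooled df, nu_shrink = mean of the finite nu_k, is used for every
gene downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CommonVarianceModel, GeneMoments, ModerationResult

__all__ = [
    "lambda_from_ratios",
    "estimate_lambda",
    "moderate_variances",
    "estimate_df",
    "moderate",
]


def lambda_from_ratios(ratios: np.ndarray, nu_gene: int) -> float:
    """Shrinkage coefficient from variance ratios r_k = s2_k / sigma2_common_k.

    lambda = min(1, (2 K / nu_gene) / sum_k (r_k - 1)^2); a zero sum of
    squared deviations (every ratio exactly 1) gives lambda = 1.
    """
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValueError("no ratios supplied")
    denom = float(((r - 1.0) ** 2).sum())
    if denom == 0.0:
        return 1.0
    return min(1.0, (2.0 * r.size / nu_gene) / denom)


def _participating(moments: GeneMoments, model: CommonVarianceModel) -> np.ndarray:
    """Genes entering the lambda sum: positive mean, variance and surface."""
    mu = moments.mu_hat.to_numpy(float)
    s2 = moments.s2.to_numpy(float)
    common = model.sigma2_common.to_numpy(float)
    return (mu > 0) & (s2 > 0) & (common > 0)


def estimate_lambda(moments: GeneMoments, model: CommonVarianceModel) -> float:
    mask = _participating(moments, model)
    k = int(mask.sum())
    if k == 0:
        raise ValueError("no genes participate in lambda estimation")
    r = moments.s2.to_numpy(float)[mask] / model.sigma2_common.to_numpy(float)[mask]
    return lambda_from_ratios(r, moments.nu_gene)


def moderate_variances(
    lambda_: float, moments: GeneMoments, model: CommonVarianceModel
) -> pd.Series:
    if not (0.0 <= lambda_ <= 1.0):
        raise ValueError(f"lambda outside [0, 1]: {lambda_}")
    shrunk = lambda_ * model.sigma2_common + (1.0 - lambda_) * moments.s2
    shrunk.name = "sigma2_shrink"
    return shrunk


def estimate_df(
    lambda_: float, moments: GeneMoments, model: CommonVarianceModel
) -> tuple[pd.Series, float]:
    """Welch-Satterthwaite per-gene df and their pooled mean.

    nu_k is infinite when the finite-df component vanishes (lambda = 1 or
    s2_k = 0); nu_shrink averages the finite nu_k and is infinite only if
    none are.
    """
    if not (0.0 <= lambda_ <= 1.0):
        raise ValueError(f"lambda outside [0, 1]: {lambda_}")
    s2 = moments.s2.to_numpy(float)
    common = model.sigma2_common.to_numpy(float)
    num = (lambda_ * common + (1.0 - lambda_) * s2) ** 2
    den = (1.0 - lambda_) ** 2 * s2**2 / moments.nu_gene
    with np.errstate(divide="ignore", invalid="ignore"):
        nu = np.where(den > 0, num / den, np.inf)
    # a gene with s2 = 0 and sigma2_common = 0 has no variance at all;
    # treat as infinitely-precise zero
    nu = np.where((den == 0) & (num == 0), np.inf, nu)
    nu_k = pd.Series(nu, index=moments.table.index, name="nu_k")
    finite = nu_k[np.isfinite(nu_k)]
    nu_shrink = float(finite.mean()) if len(finite) else float("inf")
    return nu_k, nu_shrink


def moderate(moments: GeneMoments, model: CommonVarianceModel) -> ModerationResult:
    """Full moderation stage: lambda, shrunken variances, pooled df."""
    lambda_ = estimate_lambda(moments, model)
    shrunk = moderate_variances(lambda_, moments, model)
    nu_k, nu_shrink = estimate_df(lambda_, moments, model)
    return ModerationResult(
        lambda_=lambda_,
        sigma2_shrink=shrunk,
        nu_k=nu_k,
        nu_shrink=nu_shrink,
        nu_gene=moments.nu_gene,
        n_lambda_genes=int(_participating(moments, model).sum()),
    )
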