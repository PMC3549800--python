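"""Standardized covariates for the common-variance surface.

External gene-wise variances carry their own strong mean-variance trend;
before entering the surface fit they are standardized so that, at every
level of expression, the covariate has mean zero and variance one.  The
construction is a running location/scale transform on the log scale: a
local regression of log variance on log mean gives the location, a second
local regression of the squared residuals gives the scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import VarianceTrack
from .smoothing import LoessModel

__all__ = ["standardize_external", "length_covariate"]

MIN_COVERAGE = 200
SCALE_FLOOR = 1e-8


def standardize_external(
    track: VarianceTrack,
    genes,
    span: float = 0.5,
    name: str | None = None,
) -> pd.Series:
    """Turn an external variance track into a mean-zero/unit-variance covariate.

    Returns a Series indexed by the requested genes that are covered by the
    track; genes the track does not cover are absent from the result (the
    surface fit treats them as covariate 0, the running mean).  Genes with
    zero external variance receive the minimum covariate value among
    positive-variance genes in their expression decile.

    Raises if the track covers fewer than ``MIN_COVERAGE`` of the requested
    genes — too sparse a track hurts more than it helps.
    """
    genes = pd.Index(genes)
    covered = genes.intersection(track.table.index)
    if len(covered) < MIN_COVERAGE:
        raise ValueError(
            f"external track covers only {len(covered)} of {len(genes)} genes "
            f"(need >= {MIN_COVERAGE}); do not use this track"
        )
    sub = track.table.loc[covered]
    a = np.log(sub["ext_mean"].to_numpy(float) + 0.5)
    var = sub["ext_variance"].to_numpy(float)
    pos = var > 0
    if pos.sum() < MIN_COVERAGE // 2:
        raise ValueError("too few genes with positive external variance")

    v = np.log(var[pos])
    loc = LoessModel(a[pos], v, span=span)
    m_all = loc.predict(a)
    resid = v - m_all[pos]
    scale_fit = LoessModel(a[pos], resid**2, span=span)
    s_all = np.sqrt(np.maximum(scale_fit.predict(a), SCALE_FLOOR))

    z = np.empty(len(covered))
    z[pos] = (v - m_all[pos]) / s_all[pos]

    if (~pos).any():
        # zero-variance genes: informative (ultra-stable), pinned to the
        # stratum minimum rather than -inf
        deciles = np.quantile(a, np.linspace(0, 1, 11))
        stratum = np.clip(np.searchsorted(deciles, a, side="right") - 1, 0, 9)
        for d in range(10):
            in_d = stratum == d
            if not (in_d & ~pos).any():
                continue
            donors = z[in_d & pos]
            if len(donors) == 0:
                donors = z[pos]
            z[in_d & ~pos] = donors.min()

    out = pd.Series(z, index=covered, name=name or track.source_label or "external")
    if not np.isfinite(out.to_numpy()).all():
        raise AssertionError("non-finite standardized covariate values")
    return out


def length_covariate(annotation: pd.DataFrame, genes, name: str = "length") -> pd.Series:
    """Standardized log gene length: (log L - mean log L) / sd(log L).

    Uses the unbiased (n-1) standard deviation.  Longer genes accumulate
    more reads and, at matched mean, different variance behaviour; the
    standardized log length feeds the surface like any other covariate.
    """
    genes = pd.Index(genes)
    missing = genes.difference(annotation.index)
    if len(missing):
        raise ValueError(f"genes missing length annotation: {list(missing[:5])}")
    logl = np.log(annotation.loc[genes, "length"].to_numpy(float))
    sd = logl.std(ddof=1)
    if sd == 0:
        raise ValueError("all gene lengths identical; length covariate undefined")
    return pd.Series((logl - logl.mean()) / sd, index=genes, name=name)
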