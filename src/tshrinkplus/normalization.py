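"""Count normalization: GC-content bias removal and cyclic loess.

Two stages, applied in this order to raw counts:

1. ``gc_normalize`` — against a fixed reference sample, per-gene M-values
   M = log2((y_j + 0.5) / (y_ref + 0.5)) are regressed on GC fraction with
   a robust (Tukey bisquare) straight line, and each non-reference sample
   is rescaled so the average M-value is zero across the GC range.
2. ``cyclic_loess_normalize`` — residual sample-specific trends are removed
   by cyclic loess on log2 counts: every sample pair's M-vs-A trend is
   smoothed and each sample is adjusted by the average of its pairwise
   fitted offsets, iterating to convergence.

Both operations return the adjusted matrix together with a
:class:`NormalizationReport` of fitted coefficients and iteration
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datatypes import CountMatrix, validate_annotation

__all__ = ["NormalizationReport", "gc_normalize", "cyclic_loess_normalize"]

PSEUDOCOUNT = 0.5  # added inside log ratios only; output stays on the count scale
MIN_FIT_GENES = 50


@dataclass
class NormalizationReport:
    """Diagnostics from a normalization pass."""

    gc_lines: dict = field(default_factory=dict)  # sample -> (intercept, slope), first pass
    iterations: int = 0
    max_offsets: list = field(default_factory=list)  # per-iteration max |adjustment|

    def to_dict(self) -> dict:
        return {
            "gc_lines": {s: list(map(float, ab)) for s, ab in self.gc_lines.items()},
            "iterations": self.iterations,
            "max_offsets": [float(v) for v in self.max_offsets],
        }


def _robust_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tukey-bisquare IRLS straight line; returns (intercept, slope)."""
    exog = sm.add_constant(np.asarray(x, float))
    fit = sm.RLM(np.asarray(y, float), exog, M=sm.robust.norms.TukeyBiweight()).fit(
        maxiter=20
    )
    return float(fit.params[0]), float(fit.params[1])


def gc_normalize(
    cm: CountMatrix,
    annotation: pd.DataFrame,
    reference: str,
    tol: float = 1e-3,
    max_passes: int = 10,
) -> tuple[CountMatrix, NormalizationReport]:
    """Remove per-sample GC-content bias relative to a reference sample.

    For each non-reference sample a robust straight line of M on GC
    fraction is fitted over genes detected in the pair (y_ref + y_j > 0)
    and divided out on the count scale (y <- y * 2^-fitted).  Because the
    pseudocount couples the adjustment to the count scale, the fit-adjust
    step is repeated until the refitted line is flat (|intercept| and
    |slope| < ``tol``), which realises the contract that the average
    M-value is zero over the GC range.
    """
    if reference not in cm.sample_ids:
        raise ValueError(f"reference sample {reference!r} not in matrix")
    validate_annotation(annotation)
    missing = cm.gene_ids.difference(annotation.index)
    if len(missing):
        raise ValueError(f"genes missing GC annotation: {list(missing[:5])}")
    gc = annotation.loc[cm.gene_ids, "gc_fraction"].to_numpy(float)

    out = cm.counts.astype(float).copy()
    ref = out[reference].to_numpy()
    report = NormalizationReport()
    for sample in cm.sample_ids:
        if sample == reference:
            continue
        for p in range(max_passes):
            y = out[sample].to_numpy()
            usable = (ref + y) > 0
            if usable.sum() < MIN_FIT_GENES:
                raise ValueError(
                    f"only {int(usable.sum())} genes usable for the GC fit in "
                    f"sample {sample!r}; need >= {MIN_FIT_GENES}"
                )
            m = np.log2((y[usable] + PSEUDOCOUNT) / (ref[usable] + PSEUDOCOUNT))
            a, b = _robust_line(gc[usable], m)
            if p == 0:
                report.gc_lines[sample] = (a, b)
            if abs(a) < tol and abs(b) < tol:
                break
            out[sample] = y * 2.0 ** -(a + b * gc)
    report.iterations = 1
    return CountMatrix(out, cm.conditions.copy()), report


def cyclic_loess_normalize(
    cm: CountMatrix,
    max_iter: int = 5,
    tol: float = 1e-3,
    span: float = 0.4,
) -> tuple[CountMatrix, NormalizationReport]:
    """Remove residual pairwise MA-trends by cyclic loess on log2 counts.

    Each iteration smooths M against A for every sample pair (loess,
    span 0.4, degree 1) and shifts each sample's log2 counts by minus the
    average of its fitted pairwise offsets; iteration stops when the
    largest absolute adjustment drops below ``tol``.  Columns are finally
    rescaled so each column's geometric mean (of count + 0.5) equals the
    grand geometric mean of the input, making the operation
    mean-preserving.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    logy = np.log2(cm.counts.to_numpy(float) + PSEUDOCOUNT)
    n = logy.shape[1]
    grand_mean = logy.mean()
    report = NormalizationReport()
    for it in range(max_iter):
        offsets = np.zeros_like(logy)
        for j, k in combinations(range(n), 2):
            m = logy[:, j] - logy[:, k]
            a = 0.5 * (logy[:, j] + logy[:, k])
            fitted = lowess(m, a, frac=span, it=1, return_sorted=False)
            offsets[:, j] += fitted / 2.0
            offsets[:, k] -= fitted / 2.0
        offsets /= max(n - 1, 1)
        logy = logy - offsets
        report.max_offsets.append(float(np.abs(offsets).max()))
        report.iterations = it + 1
        if report.max_offsets[-1] < tol:
            break
    # mean-preserving rescale on the log scale; iterated to a fixed point
    # because clipping the inverted pseudocount at zero counts nudges the
    # column means of the few near-zero genes
    for _ in range(50):
        logy = logy - logy.mean(axis=0, keepdims=True) + grand_mean
        counts = np.maximum(2.0**logy - PSEUDOCOUNT, 0.0)
        new_logy = np.log2(counts + PSEUDOCOUNT)
        if np.abs(new_logy - logy).max() < 1e-9:
            break
        logy = new_logy
    out = pd.DataFrame(counts, index=cm.gene_ids, columns=cm.sample_ids)
    return CountMatrix(out, cm.conditions.copy()), report
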