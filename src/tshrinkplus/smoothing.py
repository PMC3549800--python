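"""Local regression (loess) in one or two predictors.

Degree-1 weighted least squares in a tricube-weighted nearest-neighbour
window, the smoother used for the common-variance surface and for the
running location/scale standardization of external variance tracks.

Only what the variance machinery needs is implemented: span as a fraction
of points, tricube weights, degree 1, and prediction at arbitrary new
points.  Two-dimensional fits use nearest-neighbour windows under the
Euclidean metric after scaling each coordinate by its standard deviation.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["LoessModel", "loess_fit"]

_CHUNK = 512
_GRID_POINTS = 400


class LoessModel:
    """Fitted local-regression smoother; predicts at new points.

    Parameters
    ----------
    x : (n,) or (n, d) array
        Training predictor(s), d in {1, 2}.
    y : (n,) array
        Training response.
    span : float
        Fraction of training points in each local window, in (0, 1].
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, span: float = 0.5):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if x.ndim != 2 or x.shape[1] not in (1, 2):
            raise ValueError("x must be 1-D or an (n, d) array with d in {1, 2}")
        if x.shape[0] != y.shape[0]:
            raise ValueError("x and y lengths differ")
        if not (0.0 < span <= 1.0):
            raise ValueError(f"span must be in (0, 1], got {span}")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in loess inputs")
        n, d = x.shape
        self.span = float(span)
        self.k = max(min(n, int(np.ceil(span * n))), d + 2)
        if n < d + 2:
            raise ValueError(f"need at least {d + 2} points, got {n}")
        # scale coordinates so nearest-neighbour windows are comparable
        scale = x.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        self._scale = scale
        self._x = x
        self._xs = x / scale
        self._y = y
        # design with intercept; outer products reused for every query chunk
        self._design = np.hstack([np.ones((n, 1)), x])
        p = d + 1
        self._outer = (
            self._design[:, :, None] * self._design[:, None, :]
        ).reshape(n, p * p)
        self._design_y = self._design * y[:, None]

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        x_new = np.asarray(x_new, dtype=float)
        squeeze = x_new.ndim == 1 and self._x.shape[1] == 1
        if x_new.ndim == 1:
            x_new = x_new[:, None]
        if x_new.shape[1] != self._x.shape[1]:
            raise ValueError("query dimensionality differs from training data")
        m, d = x_new.shape
        if d == 1 and m > _GRID_POINTS * 3:
            # exact evaluation on a dense grid, linear interpolation between;
            # the smoother is locally linear so the error is negligible
            lo = min(self._x.min(), x_new.min())
            hi = max(self._x.max(), x_new.max())
            grid = np.linspace(lo, hi, _GRID_POINTS)
            fg = self._predict_exact(grid[:, None])
            res = np.interp(x_new[:, 0], grid, fg)
            return res[0] if squeeze and m == 1 else res
        res = self._predict_exact(x_new)
        return res[0] if squeeze and m == 1 else res

    def _predict_exact(self, x_new: np.ndarray) -> np.ndarray:
        m, d = x_new.shape
        p = d + 1
        out = np.empty(m)
        xs_new = x_new / self._scale
        for lo in range(0, m, _CHUNK):
            hi = min(lo + _CHUNK, m)
            dist = cdist(xs_new[lo:hi], self._xs)
            # bandwidth = distance to k-th nearest training point per query
            h = np.partition(dist, self.k - 1, axis=1)[:, self.k - 1][:, None]
            np.divide(dist, h, out=dist, where=h > 0)
            u = dist
            u[np.broadcast_to(h == 0, u.shape) & (u > 0)] = np.inf
            w = 1.0 - u * u * u
            np.maximum(w, 0.0, out=w)
            w *= w * w
            # ties at the window edge would zero every weight
            w[(w.sum(axis=1) == 0)] = 1.0
            a = (w @ self._outer).reshape(-1, p, p)
            b = w @ self._design_y
            # ridge jitter keeps degenerate windows (all-equal x) solvable
            a += 1e-10 * np.eye(p)
            beta = np.linalg.solve(a, b[:, :, None])[:, :, 0]
            xq = np.hstack([np.ones((hi - lo, 1)), x_new[lo:hi]])
            out[lo:hi] = (xq * beta).sum(axis=1)
        return out


def loess_fit(
    x: np.ndarray, y: np.ndarray, span: float = 0.5, x_new: np.ndarray | None = None
) -> np.ndarray:
    """Fit a loess smoother and return fitted values at ``x_new`` (or ``x``)."""
    model = LoessModel(x, y, span=span)
    return model.predict(x if x_new is None else x_new)
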