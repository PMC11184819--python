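"""Local polynomial regression (loess) used throughout the package.

A single smoother backs three different steps: the feature-vs-count QC
residual, the variance-stabilising trend for highly variable gene
selection, and the cluster-number correction of quality metrics.  All
three use the classic tricube-weighted local fit.
"""

from __future__ import annotations

import numpy as np

__all__ = ["loess_fit"]


def _local_fit(x0: float, x: np.ndarray, y: np.ndarray, q: int, degree: int) -> float:
    d = np.abs(x - x0)
    # q nearest points define the bandwidth
    idx = np.argpartition(d, min(q, d.size) - 1)[:q]
    dmax = d[idx].max()
    if dmax == 0.0:
        return float(np.mean(y[idx]))
    w = (1.0 - (d[idx] / dmax) ** 3) ** 3
    w = np.clip(w, 0.0, None)
    xs = x[idx] - x0  # center at the evaluation point: intercept = fit
    deg = min(degree, max(1, np.unique(xs).size - 1))
    cols = [np.ones_like(xs)]
    for p in range(1, deg + 1):
        cols.append(xs**p)
    A = np.column_stack(cols)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], y[idx] * sw, rcond=None)
    return float(coef[0])


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
    x_eval: np.ndarray | None = None,
) -> np.ndarray:
    """Tricube-weighted local polynomial fit of ``y`` on ``x``.

    Parameters
    ----------
    x, y
        1-D arrays of equal length.
    span
        Fraction of points contributing to each local fit.
    degree
        Local polynomial degree (reduced automatically when the local
        neighbourhood is degenerate).
    x_eval
        Points at which to evaluate the fit; defaults to ``x``.

    Returns
    -------
    Fitted values at ``x_eval``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size == 0:
        raise ValueError("empty input")
    if x_eval is None:
        x_eval = x
    x_eval = np.asarray(x_eval, dtype=float).ravel()
    if x.size == 1:
        return np.full(x_eval.shape, y[0])
    q = max(int(np.ceil(span * x.size)), degree + 1)
    q = min(q, x.size)

    # memoise on unique evaluation points: k-correction evaluates the fit
    # at many repeated cluster counts
    uniq, inv = np.unique(x_eval, return_inverse=True)
    fitted = np.array([_local_fit(x0, x, y, q, degree) for x0 in uniq])
    return fitted[inv]
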