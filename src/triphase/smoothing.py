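"""Locally weighted polynomial regression (loess).

A compact loess in the style of Cleveland's original: for each evaluation
point take the fraction ``span`` of nearest observations, weight them with
the tricube kernel, and fit a weighted polynomial of degree ``degree``.
Gaussian family only (no robustness iterations), which is what soil-moisture
interpolation needs: the sensor readings are smooth, and the hourly grid is
interpolated, not outlier-cleaned.

Defaults (span 0.75, degree 2) match R's ``loess``.
"""

from __future__ import annotations

import numpy as np

from .errors import ImputationError

__all__ = ["loess_fit"]


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    *,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Evaluate a loess smooth of ``y`` on ``x`` at the points ``x_eval``.

    Parameters
    ----------
    x, y
        Observations; ``x`` need not be sorted.
    x_eval
        Points at which the local fits are evaluated.
    span
        Fraction of observations entering each local fit, in (0, 1].
    degree
        Local polynomial degree (0, 1 or 2 are the sensible choices).

    Returns
    -------
    Smoothed values at ``x_eval``.

    Raises
    ------
    ImputationError
        If fewer points are available than a local polynomial of this
        degree needs under this span.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.atleast_1d(np.asarray(x_eval, dtype=float))
    if x.ndim != 1 or x.shape != y.shape:
        raise ImputationError("x and y must be one-dimensional and equal length")
    if not 0 < span <= 1:
        raise ImputationError(f"span must be in (0, 1], got {span}")
    n = x.size
    q = max(int(np.ceil(span * n)), degree + 1)
    if n < degree + 1:
        raise ImputationError(
            f"loess with span {span} and degree {degree} needs at least "
            f"{degree + 1} points, got {n}"
        )
    q = min(q, n)

    out = np.empty(x_eval.shape, dtype=float)
    for j, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        idx = np.argpartition(d, q - 1)[:q]
        dmax = d[idx].max()
        if dmax == 0.0:
            # all selected points coincide with x0
            w = np.ones(q)
        else:
            w = (1.0 - (d[idx] / dmax) ** 3) ** 3
            w = np.clip(w, 0.0, None)
        if w.sum() == 0.0:  # pragma: no cover - dmax>0 leaves the nearest w>0
            w[:] = 1.0
        # centred design for conditioning
        xc = x[idx] - x0
        basis = np.vander(xc, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(basis * sw[:, None], y[idx] * sw, rcond=None)
        out[j] = coef[0]
    return out
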