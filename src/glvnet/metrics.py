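"""Goodness-of-fit metrics shared across the inference and ensemble stages."""

from __future__ import annotations

import numpy as np

from .params import GLVParameters
from .series import AbundanceSeries


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, AbundanceSeries):
        return x.values
    return np.asarray(x, dtype=float)


def smape(x, xhat) -> float:
    """Symmetric mean absolute percentage error, bounded in [0, 1].

    ``(1/NM) sum |x - xhat| / (|x| + |xhat|)`` over all species-time entries;
    a 0/0 entry (both observed and simulated absent) contributes 0.
    """
    a, b = _as_matrix(x), _as_matrix(xhat)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = np.abs(a) + np.abs(b)
    terms = np.where(denom > 0, np.abs(a - b) / np.where(denom > 0, denom, 1.0), 0.0)
    return float(terms.mean())


def adjusted_r2(x, xhat, n_free_params: int) -> float:
    """Pooled coefficient of determination with a small-sample adjustment.

    R^2 = 1 - SSE/SST with SST taken about each species' own mean, pooled over
    all species-time entries; adjusted as 1 - (1 - R^2)(n - 1)/(n - p - 1)
    with n = N*M and p = ``n_free_params``.
    """
    a, b = _as_matrix(x), _as_matrix(xhat)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim == 1:
        a, b = a[None, :], b[None, :]
    n = a.size
    if n <= n_free_params + 1:
        raise ValueError("need n > n_free_params + 1 data values")
    sst = float(np.sum((a - a.mean(axis=1, keepdims=True)) ** 2))
    if sst == 0.0:
        raise ValueError("total variance is zero; R^2 undefined")
    sse = float(np.sum((a - b) ** 2))
    r2 = 1.0 - sse / sst
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - n_free_params - 1))


def parameter_recovery_adjusted_r2(
    true: GLVParameters, estimated: GLVParameters
) -> float:
    """Adjusted R^2 of regressing estimated coefficients on true ones.

    All growth-rate and interaction coefficients are pooled into (true,
    estimated) pairs, an ordinary least-squares line is fit, and its R^2 is
    adjusted with one free parameter.
    """
    from scipy.stats import linregress

    t = np.concatenate([true.alpha, true.beta.ravel()])
    e = np.concatenate([estimated.alpha, estimated.beta.ravel()])
    if t.size != e.size:
        raise ValueError("parameter vectors differ in length")
    fit = linregress(t, e)
    r2 = float(fit.rvalue ** 2)
    n = t.size
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - 2))
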