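"""Standardization, denoising and gradient estimation for abundance series.

Field catch data are gear-dependent, so raw catch-per-unit-effort counts are
first converted to within-gear relative abundance and summed over gears into a
single standardized index per species and year.  Series are then denoised by
classical empirical mode decomposition (EMD): the series is sifted into
intrinsic mode functions (IMFs), each IMF's persistence is measured by a
rescaled-range Hurst exponent, and only IMFs with Hurst >= 0.5 (persistent,
signal-like) are kept along with the residual trend.  Finally, initial
estimates of the log-abundance time-derivatives -- the latent gradients of the
inference stage -- are obtained by analytic differentiation of a cubic spline
through the log data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .series import AbundanceSeries, GearCatchTable

logger = logging.getLogger(__name__)

HURST_SIGNAL_THRESHOLD = 0.5


class ConstantSeriesError(ValueError):
    """The Hurst exponent of a constant series is undefined."""


@dataclass(frozen=True)
class LatentGradients:
    """N x M matrix of d/dt ln x_i(t_k), the latent variables of LGR."""

    g: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.g, dtype=float)
        if g.ndim != 2:
            raise ValueError("gradients must form a 2-D matrix")
        if not np.all(np.isfinite(g)):
            raise ValueError("gradients must be finite")
        object.__setattr__(self, "g", g)


@dataclass(frozen=True)
class IMFDecomposition:
    """Ordered IMFs plus residual trend; IMFs sum with the residual to the input."""

    imfs: tuple[np.ndarray, ...]
    residual: np.ndarray
    hurst: tuple[float, ...]  # per-IMF estimate, NaN when undefined

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out = out + imf
        return out


# ---------------------------------------------------------------------------
# CPUE standardization
# ---------------------------------------------------------------------------

def standardize_cpue(raw: GearCatchTable) -> AbundanceSeries:
    """Convert multi-gear catch counts to a summed relative-abundance index.

    For each gear and time point, species counts are divided by the gear's
    total across species (within-gear relative abundance); the per-gear shares
    are then summed over gears.  A gear-time column whose total is zero is
    skipped for that time with a logged warning and contributes nothing.
    """
    n, m = len(raw.species_ids), raw.times.size
    index = np.zeros((n, m))
    any_positive = np.zeros(m, dtype=bool)
    for gear in raw.gear_ids:
        mat = raw.counts[gear]
        totals = mat.sum(axis=0)
        zero = totals == 0.0
        if np.any(zero):
            logger.warning(
                "gear %r has zero total catch at times %s; skipped there",
                gear, raw.times[zero].tolist(),
            )
        safe = np.where(zero, 1.0, totals)
        shares = np.where(zero[None, :], 0.0, mat / safe[None, :])
        index += shares
        any_positive |= ~zero
    if not np.all(any_positive):
        raise ValueError(
            f"no gear has a positive total at times {raw.times[~any_positive].tolist()}"
        )
    return AbundanceSeries(
        species_ids=raw.species_ids, times=raw.times, values=index,
        site_label=raw.site_label,
    )


# ---------------------------------------------------------------------------
# Empirical mode decomposition
# ---------------------------------------------------------------------------

def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateaus take the midpoint)."""
    d = np.sign(np.diff(x))
    # carry the last nonzero slope through plateaus
    for k in range(1, d.size):
        if d[k] == 0:
            d[k] = d[k - 1]
    turns = np.diff(d)
    maxima = np.where(turns < 0)[0] + 1
    minima = np.where(turns > 0)[0] + 1
    return maxima, minima


def _envelope(t: np.ndarray, x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through the extrema, mirror-extended at the ends."""
    te, xe = t[idx], x[idx]
    # mirror up to two extrema about each boundary so the spline does not
    # diverge at the edges of the record
    k = min(2, te.size)
    t_lo = 2 * t[0] - te[:k][::-1]
    x_lo = xe[:k][::-1]
    t_hi = 2 * t[-1] - te[-k:][::-1]
    x_hi = xe[-k:][::-1]
    tt = np.concatenate([t_lo, te, t_hi])
    xx = np.concatenate([x_lo, xe, x_hi])
    keep = np.concatenate([[True], np.diff(tt) > 0])
    tt, xx = tt[keep], xx[keep]
    if tt.size < 2:
        return np.full_like(x, xx[0] if xx.size else 0.0)
    if tt.size < 4:
        return np.interp(t, tt, xx)
    return CubicSpline(tt, xx)(t)


def emd_decompose(
    series: np.ndarray,
    times: np.ndarray | None = None,
    sd_threshold: float = 0.2,
    max_siftings: int = 10,
    max_imfs: int | None = None,
) -> IMFDecomposition:
    """Classical EMD by envelope-mean sifting.

    Sifting of each mode stops on a Cauchy-type criterion
    ``sum((h_prev - h)^2) / sum(h_prev^2) < sd_threshold`` or after
    ``max_siftings`` passes; extraction stops when the residual has fewer than
    two extrema.  A series with fewer than two extrema yields zero IMFs and the
    series itself as residual.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size < 4:
        raise ValueError("EMD needs at least 4 samples")
    t = np.arange(x.size, dtype=float) if times is None else np.asarray(times, dtype=float)

    imfs: list[np.ndarray] = []
    residual = x.copy()
    limit = max_imfs if max_imfs is not None else x.size
    while len(imfs) < limit:
        maxima, minima = _local_extrema(residual)
        if maxima.size < 1 or minima.size < 1 or maxima.size + minima.size < 2:
            break
        h = residual.copy()
        for _ in range(max_siftings):
            mx, mn = _local_extrema(h)
            if mx.size < 1 or mn.size < 1:
                break
            upper = _envelope(t, h, mx)
            lower = _envelope(t, h, mn)
            mean = 0.5 * (upper + lower)
            h_new = h - mean
            denom = float(np.sum(h ** 2))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_threshold:
                break
        imfs.append(h)
        residual = residual - h
    hurst = tuple(_safe_hurst(imf) for imf in imfs)
    return IMFDecomposition(imfs=tuple(imfs), residual=residual, hurst=hurst)


# ---------------------------------------------------------------------------
# Hurst exponent (rescaled range)
# ---------------------------------------------------------------------------

def hurst_exponent(series: np.ndarray, min_window: int = 8) -> float:
    """Rescaled-range (R/S) estimate of the Hurst exponent.

    Log-spaced window sizes from ``min_window`` to half the record length;
    within each window the range of the cumulative mean-deviation profile is
    divided by the window standard deviation; the exponent is the slope of
    log(R/S) against log(window).  Raises :class:`ConstantSeriesError` for a
    constant input, for which the statistic is undefined.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 16:
        raise ValueError("Hurst estimation needs at least 16 samples")
    if np.ptp(x) == 0.0:
        raise ConstantSeriesError("Hurst exponent undefined for a constant series")
    max_window = x.size // 2
    sizes = np.unique(
        np.round(np.geomspace(min_window, max_window, num=10)).astype(int)
    )
    log_n, log_rs = [], []
    for n in sizes:
        rs_vals = []
        for start in range(0, x.size - n + 1, n):
            w = x[start:start + n]
            dev = w - w.mean()
            profile = np.cumsum(dev)
            r = float(np.ptp(profile))
            s = float(w.std())
            if s > 0 and r > 0:
                rs_vals.append(r / s)
        if rs_vals:
            log_n.append(np.log(n))
            log_rs.append(np.log(np.mean(rs_vals)))
    if len(log_n) < 2:
        raise ConstantSeriesError("too few usable windows for Hurst estimation")
    slope = np.polyfit(log_n, log_rs, 1)[0]
    return float(slope)


def _safe_hurst(series: np.ndarray) -> float:
    try:
        return hurst_exponent(series)
    except (ValueError, ConstantSeriesError):
        return float("nan")


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def smooth_series(x: AbundanceSeries, hurst_threshold: float = HURST_SIGNAL_THRESHOLD) -> AbundanceSeries:
    """Denoise each species' series by Hurst-filtered EMD reconstruction.

    Per species: decompose into IMFs, drop IMFs whose Hurst exponent falls
    below ``hurst_threshold`` (anti-persistent, noise-like oscillations), and
    rebuild from the residual trend plus the surviving IMFs.  The output is
    clipped at zero from below.  Rows too short to decompose pass through
    unchanged.
    """
    out = np.empty_like(x.values)
    for i in range(x.n_species):
        row = x.values[i]
        if row.size < 4 or np.ptp(row) == 0.0:
            out[i] = row
            continue
        dec = emd_decompose(row, times=x.times)
        rebuilt = dec.residual.copy()
        for imf, h in zip(dec.imfs, dec.hurst):
            if np.isnan(h) or h >= hurst_threshold:
                rebuilt += imf
        out[i] = np.clip(rebuilt, 0.0, None)
    return x.with_values(out)


# ---------------------------------------------------------------------------
# Gradient estimation
# ---------------------------------------------------------------------------

def default_floor(values: np.ndarray) -> np.ndarray:
    """Per-species floor: half the smallest positive abundance observed.

    Keeps log transforms finite when relative-abundance data contain zeros.
    Species with no positive observation get a floor of 1 (their log series is
    then constant zero).
    """
    values = np.asarray(values, dtype=float)
    floors = np.empty(values.shape[0])
    for i, row in enumerate(values):
        pos = row[row > 0]
        floors[i] = 0.5 * pos.min() if pos.size else 1.0
    return floors


def estimate_gradients_spline(
    x: AbundanceSeries, floor: float | np.ndarray | None = None
) -> LatentGradients:
    """Initial latent gradients by differentiating a log-abundance spline.

    Fits a cubic spline (not-a-knot boundaries) through ln(max(x, floor)) per
    species and evaluates its analytic derivative at the observation times.
    Boundary gradients extrapolate the end polynomials and are less reliable
    than interior ones.
    """
    if floor is None:
        floors = default_floor(x.values)
    else:
        floors = np.broadcast_to(np.asarray(floor, dtype=float), (x.n_species,))
    if np.any(floors <= 0):
        raise ValueError("floor must be positive")
    g = np.empty_like(x.values)
    for i in range(x.n_species):
        logged = np.log(np.maximum(x.values[i], floors[i]))
        spline = CubicSpline(x.times, logged)  # not-a-knot
        g[i] = spline(x.times, 1)
    return LatentGradients(g=g)


# ---------------------------------------------------------------------------
# Transformer facade
# ---------------------------------------------------------------------------

class CPUEStandardizer(TransformerMixin, BaseEstimator):
    """Stateless transformer from :class:`GearCatchTable` to relative abundance."""

    def fit(self, X: GearCatchTable, y=None):
        return self

    def transform(self, X: GearCatchTable) -> AbundanceSeries:
        return standardize_cpue(X)


class EMDSmoother(TransformerMixin, BaseEstimator):
    """Stateless EMD + Hurst denoising transformer for abundance series."""

    def __init__(self, hurst_threshold: float = HURST_SIGNAL_THRESHOLD):
        self.hurst_threshold = hurst_threshold

    def fit(self, X: AbundanceSeries, y=None):
        return self

    def transform(self, X: AbundanceSeries) -> AbundanceSeries:
        return smooth_series(X, hurst_threshold=self.hurst_threshold)
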