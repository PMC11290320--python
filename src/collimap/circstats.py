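"""Circular statistics: the Moore-Rayleigh test and circular means.

The Moore-Rayleigh test is a rank-weighted extension of the Rayleigh
test for non-uniformity of a sample of vectors (angle, magnitude).  The
magnitudes enter only through their ranks, which makes the statistic
invariant under any monotone rescaling of the magnitudes.  It is used
here pixel-wise to ask whether the response phases of several animals
agree at a given map location.

The null distribution of the statistic is calibrated by seeded Monte
Carlo (uniform independent angles with ranks 1..n), cached per sample
size, rather than read from printed critical-value tables; this handles
arbitrary n and tied magnitudes uniformly.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

TWO_PI = 2.0 * np.pi

_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _validate_sample(angles: np.ndarray, magnitudes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    angles = np.asarray(angles, dtype=float)
    magnitudes = np.asarray(magnitudes, dtype=float)
    if angles.shape != magnitudes.shape:
        raise ValueError("angles and magnitudes must have matching shapes")
    if angles.shape[0] < 2:
        raise ValueError("Moore-Rayleigh test needs n >= 2 vectors")
    if np.any(magnitudes < 0):
        raise ValueError("magnitudes must be non-negative")
    return angles, magnitudes


def moore_rayleigh_stat(angles, magnitudes) -> float:
    """Rank-weighted Rayleigh statistic R* for one vector sample.

    Magnitudes are converted to ranks ``r_i`` (ties receive average
    ranks) and ``R* = hypot(sum r_i cos a_i, sum r_i sin a_i) / n**1.5``.
    """
    angles, magnitudes = _validate_sample(np.atleast_1d(angles), np.atleast_1d(magnitudes))
    return float(_stat_along_axis(angles[:, None], magnitudes[:, None])[0])


def _stat_along_axis(angles: np.ndarray, magnitudes: np.ndarray) -> np.ndarray:
    """Vectorised R* for angle/magnitude arrays of shape (n, ...)."""
    n = angles.shape[0]
    ranks = rankdata(magnitudes, axis=0, method="average")
    s_cos = np.sum(ranks * np.cos(angles), axis=0)
    s_sin = np.sum(ranks * np.sin(angles), axis=0)
    return np.hypot(s_cos, s_sin) / n**1.5


def moore_rayleigh_null(n: int, n_mc: int = 100_000, seed: int = 0) -> np.ndarray:
    """Sorted Monte-Carlo null sample of R* for sample size ``n``.

    Under the null, angles are iid uniform and independent of the
    magnitudes, so the rank vector can be fixed at (1..n) without loss.
    The table is cached per ``(n, n_mc, seed)``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    key = (int(n), int(n_mc), int(seed))
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        ranks = np.arange(1, n + 1, dtype=float)
        # chunked to bound memory for large n_mc
        out = np.empty(n_mc)
        chunk = max(1, int(5e6) // n)
        for start in range(0, n_mc, chunk):
            stop = min(n_mc, start + chunk)
            a = rng.uniform(0.0, TWO_PI, size=(stop - start, n))
            s_cos = (np.cos(a) * ranks).sum(axis=1)
            s_sin = (np.sin(a) * ranks).sum(axis=1)
            out[start:stop] = np.hypot(s_cos, s_sin) / n**1.5
        out.sort()
        _NULL_CACHE[key] = out
    return _NULL_CACHE[key]


def moore_rayleigh_pvalue(r_star, n: int, n_mc: int = 100_000, seed: int = 0):
    """Monte-Carlo p-value(s) for observed R* at sample size ``n``.

    ``p = (1 + #{null R* >= observed}) / (1 + n_mc)``; always in (0, 1].
    Accepts a scalar or an array of statistics (shared null table).
    """
    null = moore_rayleigh_null(n, n_mc=n_mc, seed=seed)
    r = np.asarray(r_star, dtype=float)
    n_ge = n_mc - np.searchsorted(null, r, side="left")
    p = (1.0 + n_ge) / (1.0 + n_mc)
    if np.ndim(r_star) == 0:
        return float(p)
    return p


def moore_rayleigh_test(angles, magnitudes, n_mc: int = 100_000, seed: int = 0) -> tuple[float, float]:
    """Convenience wrapper returning ``(R*, p)`` for one sample."""
    r = moore_rayleigh_stat(angles, magnitudes)
    return r, moore_rayleigh_pvalue(r, n=len(np.atleast_1d(angles)), n_mc=n_mc, seed=seed)


def circular_difference(a, b, period: float = TWO_PI):
    """Smallest absolute difference between cyclic quantities.

    Works element-wise; useful for comparing phase-encoded maps, where
    e.g. positions 0 and span (or orientations 0° and 180°) coincide.
    """
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    return np.minimum(d, period - d)


def circular_mean(angles, weights=None, period: float = TWO_PI,
                  on_degenerate: str = "nan") -> float:
    """Weighted circular mean of angles with an arbitrary period.

    Angles are mapped onto the unit circle via ``2*pi*angle/period``,
    the weighted resultant is formed, and its argument mapped back to
    ``[0, period)``.  Use ``period=180`` (degrees) for orientations.

    A (near-)zero resultant — e.g. two antipodal angles with equal
    weight — has no defined mean; ``on_degenerate`` selects ``"nan"``
    (return NaN) or ``"raise"``.
    """
    angles = np.asarray(angles, dtype=float)
    if weights is None:
        weights = np.ones_like(angles)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != angles.shape:
        raise ValueError("weights shape must match angles")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("at least one weight must be positive")
    z = np.sum(weights * np.exp(1j * TWO_PI * angles / period))
    if np.abs(z) < 1e-9 * wsum:
        if on_degenerate == "raise":
            raise ValueError("circular mean undefined: zero resultant")
        return float("nan")
    return float((np.angle(z) % TWO_PI) * period / TWO_PI)
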