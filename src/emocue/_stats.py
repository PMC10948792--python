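"""Shared statistical primitives.

Product-moment correlation, RMSE, Fisher's r-to-z, bootstrap resampling of
correlations, percentile intervals, and the Hotelling-Williams test for the
difference between two overlapping dependent correlations.  Everything here
is plain numpy/scipy so the higher-level modules stay thin.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import DegenerateDataError

#: Fisher transforms are clamped at |r| = 1 - 1e-7 so perfect-fit raters
#: stay finite.
Z_CLAMP = 1.0 - 1e-7


def pearson_r(x: np.ndarray, y: np.ndarray, *, x_name: str = "x", y_name: str = "y") -> float:
    """Product-moment correlation with explicit degenerate-input errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise DegenerateDataError(f"need at least 3 pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DegenerateDataError("non-finite values in correlation input")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(xc @ xc))
    sy = float(np.sqrt(yc @ yc))
    if sx == 0.0:
        raise DegenerateDataError(f"zero variance in {x_name}")
    if sy == 0.0:
        raise DegenerateDataError(f"zero variance in {y_name}")
    r = float((xc @ yc) / (sx * sy))
    return min(1.0, max(-1.0, r))


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def fisher_z(r, *, clamp: float = Z_CLAMP):
    """Variance-stabilizing atanh transform, clamped near |r| = 1."""
    r = np.clip(np.asarray(r, dtype=float), -clamp, clamp)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def t_from_r(r: float, n: int) -> float:
    """t statistic for H0: rho = 0 with df = n - 2."""
    if n < 3:
        raise DegenerateDataError("need n >= 3")
    if abs(r) >= 1.0:
        return float(np.inf) if r > 0 else float(-np.inf)
    return float(r * np.sqrt((n - 2) / (1.0 - r * r)))


def r_confint_fisher(r: float, n: int, *, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a single correlation."""
    if n < 4:
        raise DegenerateDataError("need n >= 4 for a Fisher-z interval")
    z = fisher_z(r)
    half = stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def bonferroni(p: float, n_tests: int) -> float:
    """Multiply a raw p-value by the family size, capped at 1."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return min(1.0, p * n_tests)


def _row_pearson(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Row-wise correlations of two (b, n) matrices; NaN for constant rows."""
    xs = xs - xs.mean(axis=1, keepdims=True)
    ys = ys - ys.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", xs, ys)
    den = np.sqrt(np.einsum("ij,ij->i", xs, xs) * np.einsum("ij,ij->i", ys, ys))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.clip(r, -1.0, 1.0)


# Cap on elements held per resampling chunk (keeps memory flat for large n).
_CHUNK_ELEMENTS = 2_000_000


def bootstrap_correlations(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """``n_boot`` correlations of paired resamples of (x, y).

    Replicates in which either resampled side is constant are redrawn (their
    count is returned so callers can log the occurrence).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise DegenerateDataError("need at least 3 pairs to bootstrap")
    rows = max(1, _CHUNK_ELEMENTS // n)
    out = np.empty(n_boot)
    filled = 0
    redrawn = 0
    guard = 0
    while filled < n_boot:
        b = min(rows, n_boot - filled)
        idx = rng.integers(0, n, size=(b, n))
        r = _row_pearson(x[idx], y[idx])
        ok = np.isfinite(r)
        k = int(ok.sum())
        redrawn += b - k
        out[filled : filled + k] = r[ok]
        filled += k
        guard += 1
        if guard > 1000 and filled == 0:
            raise DegenerateDataError("bootstrap cannot find a non-degenerate resample")
    return out, redrawn


def bootstrap_correlation_differences(
    x: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Bootstrap distribution of r(x, a) - r(x, b) resampling observations.

    The same resample indices are applied to all three vectors so the two
    correlations in each replicate stay paired.  Degenerate replicates are
    redrawn, as in :func:`bootstrap_correlations`.
    """
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = x.size
    if n < 3:
        raise DegenerateDataError("need at least 3 observations to bootstrap")
    rows = max(1, _CHUNK_ELEMENTS // (2 * n))
    out = np.empty(n_boot)
    filled = 0
    redrawn = 0
    guard = 0
    while filled < n_boot:
        k_rows = min(rows, n_boot - filled)
        idx = rng.integers(0, n, size=(k_rows, n))
        xs = x[idx]
        ra = _row_pearson(xs, a[idx])
        rb = _row_pearson(xs, b[idx])
        delta = ra - rb
        ok = np.isfinite(delta)
        k = int(ok.sum())
        redrawn += k_rows - k
        out[filled : filled + k] = delta[ok]
        filled += k
        guard += 1
        if guard > 1000 and filled == 0:
            raise DegenerateDataError("bootstrap cannot find a non-degenerate resample")
    return out, redrawn


def percentile_ci(samples: np.ndarray, *, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval of a bootstrap distribution."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(samples, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def williams_t(
    r_ae: float, r_be: float, r_ab: float, n: int
) -> tuple[float, float, int, int]:
    """Hotelling-Williams test for two overlapping dependent correlations.

    ``r_ae`` and ``r_be`` are the correlations of models A and B with the
    same empirical vector; ``r_ab`` is the correlation between the models.
    Returns ``(t, p_two_tailed, df_reported, df_conventional)``.  The p-value
    uses the reported df = n - 2 (the convention followed throughout the
    package's reports); the textbook df = n - 3 is returned alongside.
    """
    for name, v in (("r_ae", r_ae), ("r_be", r_be), ("r_ab", r_ab)):
        if not np.isfinite(v) or abs(v) >= 1.0:
            raise DegenerateDataError(f"{name} = {v} has undefined variance (|r| >= 1)")
    if n < 4:
        raise DegenerateDataError("need n >= 4 for the Williams test")
    det = 1.0 - r_ae**2 - r_be**2 - r_ab**2 + 2.0 * r_ae * r_be * r_ab
    rbar = 0.5 * (r_ae + r_be)
    denom = 2.0 * det * (n - 1) / (n - 3) + rbar**2 * (1.0 - r_ab) ** 3
    t = (r_ae - r_be) * np.sqrt((n - 1) * (1.0 + r_ab) / denom)
    df_reported = n - 2
    df_conventional = n - 3
    p = float(2.0 * stats.t.sf(abs(t), df_reported))
    return float(t), min(1.0, p), df_reported, df_conventional
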