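"""Shared correlation helpers with pairwise-complete missing-data handling."""

from __future__ import annotations

import numpy as np

MIN_PAIRED = 10  # minimum paired observations for any reported correlation


def log2_counts(counts: np.ndarray) -> np.ndarray:
    """log2(count + 1) transform applied before all expression correlations."""
    return np.log2(np.asarray(counts, dtype=float) + 1.0)


def pearson_pairwise(x: np.ndarray, y: np.ndarray, min_n: int = MIN_PAIRED) -> float:
    """Pearson r of two vectors using pairwise-complete observations.

    Returns NaN when fewer than ``min_n`` paired finite values remain or
    either vector is constant over the paired subset.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < min_n:
        return float("nan")
    xs, ys = x[mask], y[mask]
    # scale out the magnitudes first so extreme inputs cannot overflow the
    # centering or the sums; Pearson r is scale-invariant
    x_max, y_max = np.abs(xs).max(), np.abs(ys).max()
    if x_max == 0.0 or y_max == 0.0:
        return float("nan")
    xs, ys = xs / x_max, ys / y_max
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    denom = np.sqrt((xs * xs).sum() * (ys * ys).sum())
    if denom == 0.0:
        return float("nan")
    return float((xs * ys).sum() / denom)


def pearson_vector_matrix(
    x: np.ndarray, m: np.ndarray, min_n: int = MIN_PAIRED
) -> np.ndarray:
    """Pearson r of vector ``x`` against every row of matrix ``m``.

    Pairwise-complete per row: each row uses the samples where both the row
    and ``x`` are finite. Rows with fewer than ``min_n`` paired values or
    zero variance give NaN. Vectorized over rows with a masked-array pass.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    valid = np.isfinite(m) & np.isfinite(x)[None, :]
    n = valid.sum(axis=1).astype(float)

    xm = np.where(valid, x[None, :], 0.0)
    mm = np.where(valid, m, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = xm.sum(axis=1) / n
        mean_m = mm.sum(axis=1) / n
        xc = np.where(valid, xm - mean_x[:, None], 0.0)
        mc = np.where(valid, mm - mean_m[:, None], 0.0)
        cov = (xc * mc).sum(axis=1)
        denom = np.sqrt((xc * xc).sum(axis=1) * (mc * mc).sum(axis=1))
        r = cov / denom
    m_max = np.where(valid, m, -np.inf).max(axis=1)
    m_min = np.where(valid, m, np.inf).min(axis=1)
    constant = m_max == m_min
    r[(n < min_n) | (denom == 0.0) | constant | ~np.isfinite(r)] = np.nan
    return r


def pearson_rowwise(
    a: np.ndarray, b: np.ndarray, min_n: int = MIN_PAIRED
) -> np.ndarray:
    """Row-by-row Pearson r between two equally shaped matrices.

    Row i of the result is the pairwise-complete correlation of ``a[i]``
    with ``b[i]`` — e.g. a gene's own CNV against its own expression.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    valid = np.isfinite(a) & np.isfinite(b)
    n = valid.sum(axis=1).astype(float)
    am = np.where(valid, a, 0.0)
    bm = np.where(valid, b, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = am.sum(axis=1) / n
        mean_b = bm.sum(axis=1) / n
        ac = np.where(valid, am - mean_a[:, None], 0.0)
        bc = np.where(valid, bm - mean_b[:, None], 0.0)
        cov = (ac * bc).sum(axis=1)
        denom = np.sqrt((ac * ac).sum(axis=1) * (bc * bc).sum(axis=1))
        r = cov / denom
    constant = np.zeros(len(r), dtype=bool)
    for mat in (a, b):
        hi = np.where(valid, mat, -np.inf).max(axis=1)
        lo = np.where(valid, mat, np.inf).min(axis=1)
        constant |= hi == lo
    r[(n < min_n) | (denom == 0.0) | constant | ~np.isfinite(r)] = np.nan
    return r


def t_statistic(r: np.ndarray, n: np.ndarray | int) -> np.ndarray:
    """Correlation t-statistic t = r * sqrt((n-2) / (1-r^2))."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return r * np.sqrt((n - 2.0) / (1.0 - r * r))
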