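"""Hilbert-Schmidt independence criterion (HSIC) test.

Biased HSIC statistic with Gaussian kernels (bandwidth by the median
heuristic) and a p-value from the two-moment gamma approximation to the
permutation null.  Used both as a standalone independence test and for the
exogeneity checks of the causal-discovery stage.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma

__all__ = ["hsic_test", "hsic_statistic"]


def _median_bandwidth(x: np.ndarray) -> float:
    d = np.abs(x[:, None] - x[None, :])
    med = np.median(d[np.triu_indices_from(d, k=1)])
    return float(med) if med > 0 else 1.0


def _gram(x: np.ndarray, bandwidth: float) -> np.ndarray:
    d2 = (x[:, None] - x[None, :]) ** 2
    return np.exp(-d2 / (2.0 * bandwidth**2))


def hsic_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Biased HSIC estimate ``tr(KHLH) / m**2`` with Gaussian kernels."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    m = len(x)
    k = _gram(x, _median_bandwidth(x))
    l = _gram(y, _median_bandwidth(y))
    h = np.eye(m) - np.ones((m, m)) / m
    kc = h @ k @ h
    return float(np.sum(kc * (h @ l @ h).T) / m**2)


def hsic_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """HSIC independence test with gamma-approximated null.

    Returns ``(statistic, p_value)`` where the statistic is ``m * HSIC_b``.
    A constant input carries no dependence information and yields
    ``(0.0, 1.0)``.

    Raises
    ------
    ValueError
        If the vectors differ in length or are shorter than 20 samples
        (the gamma approximation is unreliable below that).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    m = len(x)
    if m < 20:
        raise ValueError("HSIC test requires at least 20 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0

    k = _gram(x, _median_bandwidth(x))
    l = _gram(y, _median_bandwidth(y))
    h = np.eye(m) - np.ones((m, m)) / m
    kc = h @ k @ h
    lc = h @ l @ h

    test_stat = float(np.sum(kc.T * lc) / m)

    # two-moment gamma approximation to the permutation null
    var_mat = (kc * lc / 6.0) ** 2
    var_hsic = (var_mat.sum() - np.trace(var_mat)) / (m * (m - 1))
    var_hsic = var_hsic * 72.0 * (m - 4) * (m - 5) / (m * (m - 1) * (m - 2) * (m - 3))

    k0 = k - np.diag(np.diag(k))
    l0 = l - np.diag(np.diag(l))
    mu_x = k0.sum() / (m * (m - 1))
    mu_y = l0.sum() / (m * (m - 1))
    mean_hsic = (1.0 + mu_x * mu_y - mu_x - mu_y) / m

    if var_hsic <= 0 or mean_hsic <= 0:
        return test_stat, 1.0
    alpha = mean_hsic**2 / var_hsic
    beta = var_hsic * m / mean_hsic
    p = float(gamma.sf(test_stat, a=alpha, scale=beta))
    return test_stat, p
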