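"""Deterministic multivariate-normal box probabilities for dimension <= 3.

Probabilities are computed by sequential conditioning: the outer integral runs
over the first variable's (truncated) interval against the standard normal
density, and the remaining conditional normal box is evaluated recursively.
The integrands are analytic and rapidly decaying, so Gauss-Legendre quadrature
converges spectrally, giving absolute errors far below 1e-8 at the default
node counts.  No Monte Carlo is involved anywhere, so results are
bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

__all__ = ["mvn_box_prob", "std_box_prob", "UnsupportedDimensionError"]


class UnsupportedDimensionError(ValueError):
    """Raised when a box probability is requested in dimension > 3."""


_NODE_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}

# integration range truncated to +/- _Z_MAX; the discarded normal tail mass
# is below 1e-17
_Z_MAX = 8.5
_LOG_2PI = np.log(2.0 * np.pi)


def _gl_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights mapped to (0, 1), cached per order."""
    if n not in _NODE_CACHE:
        x, w = np.polynomial.legendre.leggauss(n)
        _NODE_CACHE[n] = (0.5 * (x + 1.0), 0.5 * w)
    return _NODE_CACHE[n]


def _box1(lower, upper):
    return ndtr(upper[..., 0]) - ndtr(lower[..., 0])


def _box2(lower, upper, rho: float, n_nodes: int):
    """P(l < X <= u) for standard bivariate normal, batched over leading axes."""
    a = np.clip(lower[..., 0], -_Z_MAX, _Z_MAX)
    b = np.clip(upper[..., 0], -_Z_MAX, _Z_MAX)
    span = np.maximum(b - a, 0.0)
    x, w = _gl_nodes(n_nodes)
    z = a[..., None] + span[..., None] * x
    dens = np.exp(-0.5 * (z * z + _LOG_2PI))
    s = np.sqrt(max(1.0 - rho * rho, 1e-300))
    inner = ndtr((upper[..., 1, None] - rho * z) / s) - ndtr(
        (lower[..., 1, None] - rho * z) / s
    )
    return span * ((dens * inner) @ w)


def _box3(lower, upper, R: np.ndarray, nodes: tuple[int, int]):
    """P(l < X <= u) for standard trivariate normal with correlation R."""
    n1, n2 = nodes
    rho12, rho13, rho23 = R[0, 1], R[0, 2], R[1, 2]
    a = np.clip(lower[..., 0], -_Z_MAX, _Z_MAX)
    b = np.clip(upper[..., 0], -_Z_MAX, _Z_MAX)
    span = np.maximum(b - a, 0.0)
    x, w = _gl_nodes(n1)
    z = a[..., None] + span[..., None] * x
    dens = np.exp(-0.5 * (z * z + _LOG_2PI))

    s2 = np.sqrt(max(1.0 - rho12 * rho12, 1e-300))
    s3 = np.sqrt(max(1.0 - rho13 * rho13, 1e-300))
    r = (rho23 - rho12 * rho13) / (s2 * s3)
    r = float(np.clip(r, -1.0 + 1e-14, 1.0 - 1e-14))

    cond_lower = np.stack(
        [
            (lower[..., 1, None] - rho12 * z) / s2,
            (lower[..., 2, None] - rho13 * z) / s3,
        ],
        axis=-1,
    )
    cond_upper = np.stack(
        [
            (upper[..., 1, None] - rho12 * z) / s2,
            (upper[..., 2, None] - rho13 * z) / s3,
        ],
        axis=-1,
    )
    bvn = _box2(cond_lower, cond_upper, r, n2)
    return span * ((dens * bvn) @ w)


def std_box_prob(
    lower,
    upper,
    R: np.ndarray,
    nodes: tuple[int, int] = (64, 64),
) -> np.ndarray | float:
    """Box probability for a standardized MVN(0, R), batched over rows.

    Parameters
    ----------
    lower, upper
        Arrays of shape ``(d,)`` or ``(m, d)`` with ``-inf``/``+inf`` allowed.
    R
        ``(d, d)`` correlation matrix, ``d <= 3``.
    nodes
        Gauss-Legendre node counts for the (outer, inner) quadrature levels.

    Returns
    -------
    Probability array of shape ``(m,)``, or a scalar for 1-D input.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    scalar = lower.ndim == 1
    lower = np.atleast_2d(lower)
    upper = np.atleast_2d(upper)
    d = R.shape[0]
    if d > 3:
        raise UnsupportedDimensionError(
            f"box probabilities support dimension <= 3, got {d}"
        )
    # bound the (rows x outer x inner) work array to ~1e7 doubles
    chunk = max(1, int(1e7 // (nodes[0] * max(nodes[1], 1))))
    m = lower.shape[0]
    if m > chunk:
        parts = [
            std_box_prob(lower[i : i + chunk], upper[i : i + chunk], R, nodes)
            for i in range(0, m, chunk)
        ]
        return np.concatenate([np.atleast_1d(p) for p in parts])
    if d == 1:
        p = _box1(lower, upper)
    elif d == 2:
        p = _box2(lower, upper, float(R[0, 1]), nodes[0])
    else:
        p = _box3(lower, upper, R, nodes)
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if scalar else p


def mvn_box_prob(lower, upper, mean, cov, nodes: tuple[int, int] = (96, 96)) -> float:
    """P(lower < Z <= upper) for Z ~ MVN(mean, cov), dimension <= 3.

    Deterministic to well below 1e-8 at the default node counts.  Infinite
    bounds are allowed; ``cov`` must be positive definite.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    d = mean.shape[0]
    if d > 3:
        raise UnsupportedDimensionError(
            f"box probabilities support dimension <= 3, got {d}"
        )
    if lower.shape != (d,) or upper.shape != (d,) or cov.shape != (d, d):
        raise ValueError("lower, upper, mean and cov have inconsistent shapes")
    if np.any(lower > upper):
        raise ValueError("lower bound exceeds upper bound")
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    sd = np.sqrt(np.diag(cov))
    R = cov / np.outer(sd, sd)
    np.fill_diagonal(R, 1.0)
    lo = (lower - mean) / sd
    hi = (upper - mean) / sd
    return float(std_box_prob(lo, hi, R, nodes=nodes))
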