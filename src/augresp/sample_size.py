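"""Power and per-arm sample size for a future trial testing a risk
difference, driven by pilot estimates from either analysis route.

The power function is the one-sided normal approximation for a 1:1 design
with Var(RD-hat) = sigma2_tot / n per arm:

    power(n) = Phi( delta * sqrt(n / sigma2_tot) - z_{1-alpha} ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

from .effect_estimation import EffectEstimates

__all__ = [
    "power",
    "required_n",
    "pilot_variance",
    "power_curve",
    "SampleSizeResult",
]


def power(n, delta: float, sigma2_tot: float, alpha: float = 0.05):
    """One-sided normal-approximation power at per-arm size ``n``.

    Accepts scalar or array ``n``.  ``delta = 0`` gives exactly ``alpha``.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 2):
        raise ValueError("per-arm n must be >= 2")
    if sigma2_tot <= 0:
        raise ValueError("sigma2_tot must be > 0")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    z = ndtri(1.0 - alpha)
    out = ndtr(delta * np.sqrt(n / sigma2_tot) - z)
    return float(out) if out.ndim == 0 else out


def required_n(
    delta: float,
    sigma2_tot: float,
    alpha: float = 0.05,
    target_power: float = 0.80,
) -> int:
    """Smallest integer per-arm n with power >= ``target_power``.

    Closed form ceil(sigma2_tot (z_{1-alpha} + z_power)^2 / delta^2),
    then verified (and corrected if needed) by direct power inversion so
    that power(n) >= target > power(n - 1) always holds.
    """
    if delta == 0:
        raise ValueError("delta must be nonzero: no finite n attains the target")
    if not 0.5 < target_power < 1.0:
        raise ValueError("target_power must be in (0.5, 1)")
    if sigma2_tot <= 0:
        raise ValueError("sigma2_tot must be > 0")
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    z_a = ndtri(1.0 - alpha)
    z_p = ndtri(target_power)
    n = max(2, math.ceil(sigma2_tot * (z_a + z_p) ** 2 / delta**2 - 1e-12))
    d = abs(delta)
    # verify by inversion; the closed form can be off by one at ties
    while power(n, d, sigma2_tot, alpha) < target_power:
        n += 1
    while n > 2 and power(n - 1, d, sigma2_tot, alpha) >= target_power:
        n -= 1
    return n


def pilot_variance(
    estimates: EffectEstimates,
    n0: int,
    n1: int,
    route: str | None = None,
) -> float:
    """Per-arm-normalized variance sum sigma2_tot from pilot estimates.

    binary route: sigma2_tot = p0 (1 - p0) + p1 (1 - p1), the exact
    binomial variance law.  augmented route: the pilot RD variance is
    rescaled by the harmonic mean of the pilot arm sizes,
    sigma2_tot = var_rd * 2 / (1/n0 + 1/n1), exact when the per-arm
    variance contributions are equal and an approximation otherwise.
    ``route`` defaults to the estimates' method tag.
    """
    if n0 <= 0 or n1 <= 0:
        raise ValueError("pilot arm sizes must be positive")
    if route is None:
        route = "binary" if estimates.method.startswith("binary") else "augmented"
    if route == "binary":
        p0, p1 = estimates.p0, estimates.p1
        return p0 * (1 - p0) + p1 * (1 - p1)
    if route == "augmented":
        if estimates.var_rd is None or estimates.var_rd <= 0:
            raise ValueError("augmented route requires var_rd > 0")
        return estimates.var_rd * 2.0 / (1.0 / n0 + 1.0 / n1)
    raise ValueError("route must be 'binary' or 'augmented'")


@dataclass
class SampleSizeResult:
    """Power curve and required per-arm sizes for both analysis routes."""

    delta: float
    sigma2_tot_aug: float
    sigma2_tot_bin: float
    alpha: float
    target_power: float
    n_required_aug: int
    n_required_bin: int
    n_grid: np.ndarray
    power_aug: np.ndarray
    power_bin: np.ndarray

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "sigma2_tot_aug": self.sigma2_tot_aug,
            "sigma2_tot_bin": self.sigma2_tot_bin,
            "alpha": self.alpha,
            "target_power": self.target_power,
            "n_required_aug": self.n_required_aug,
            "n_required_bin": self.n_required_bin,
            "power_curve": [
                {"n": int(n), "power_aug": float(pa), "power_bin": float(pb)}
                for n, pa, pb in zip(self.n_grid, self.power_aug, self.power_bin)
            ],
        }


def power_curve(
    delta: float,
    sigma2_tot_aug: float,
    sigma2_tot_bin: float,
    alpha: float = 0.05,
    target_power: float = 0.80,
    n_grid=None,
) -> SampleSizeResult:
    """Tabulated power for both routes plus required per-arm sizes."""
    d = abs(delta)
    n_aug = required_n(d, sigma2_tot_aug, alpha, target_power)
    n_bin = required_n(d, sigma2_tot_bin, alpha, target_power)
    if n_grid is None:
        hi = max(n_aug, n_bin)
        n_grid = np.unique(
            np.linspace(2, math.ceil(1.5 * hi), 60).astype(int)
        )
    else:
        n_grid = np.asarray(n_grid, dtype=int)
        if n_grid.size == 0 or np.any(np.diff(n_grid) <= 0):
            raise ValueError("n_grid must be non-empty and strictly increasing")
    return SampleSizeResult(
        delta=delta,
        sigma2_tot_aug=sigma2_tot_aug,
        sigma2_tot_bin=sigma2_tot_bin,
        alpha=alpha,
        target_power=target_power,
        n_required_aug=n_aug,
        n_required_bin=n_bin,
        n_grid=n_grid,
        power_aug=power(n_grid, d, sigma2_tot_aug, alpha),
        power_bin=power(n_grid, d, sigma2_tot_bin, alpha),
    )
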