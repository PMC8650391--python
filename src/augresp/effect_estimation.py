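"""Treatment effects (log-OR, log-RR, RD) with confidence intervals, for
either analysis route, plus efficiency-reporting arithmetic.

The delta path propagates the fitted model's parameter covariance through
the response-probability map analytically; the bootstrap path resamples
subjects with replacement within arm and refits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

from .latent_model import (
    FitOptions,
    FitResult,
    LatentModelError,
    fit_latent_model,
    response_probability,
    response_probability_gradient,
)
from .trial_data import EndpointSpec, TrialDataset

__all__ = [
    "EffectEstimates",
    "EfficiencyReport",
    "effects_from_probs",
    "probs_from_rd",
    "augmented_effects",
    "efficiency_report",
]


@dataclass
class EffectEstimates:
    """Per-arm response probabilities and treatment effects with CIs.

    ``method`` tags the analysis route (``augmented``, ``binary-unadjusted``
    or ``binary-adjusted``); ``ci_method`` tags the interval construction
    (``delta``, ``bootstrap`` or ``wald``).  ``var_rd`` is the variance of
    the risk-difference estimator and feeds sample-size estimation.
    """

    p0: float
    p1: float
    log_or: float
    log_rr: float
    rd: float
    ci_log_or: tuple[float, float]
    ci_log_rr: tuple[float, float]
    ci_rd: tuple[float, float]
    ci_level: float
    method: str
    ci_method: str
    var_rd: float
    n0: int | None = None
    n1: int | None = None

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)

    @property
    def risk_ratio(self) -> float:
        return math.exp(self.log_rr)

    @property
    def ci_or(self) -> tuple[float, float]:
        return (math.exp(self.ci_log_or[0]), math.exp(self.ci_log_or[1]))

    @property
    def ci_rr(self) -> tuple[float, float]:
        return (math.exp(self.ci_log_rr[0]), math.exp(self.ci_log_rr[1]))

    def ci_width(self, effect: str) -> float:
        lo, hi = {
            "log_or": self.ci_log_or,
            "log_rr": self.ci_log_rr,
            "rd": self.ci_rd,
        }[effect]
        return hi - lo

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "ci_method": self.ci_method,
            "ci_level": self.ci_level,
            "p0": self.p0,
            "p1": self.p1,
            "rd": self.rd,
            "log_or": self.log_or,
            "log_rr": self.log_rr,
            "odds_ratio": self.odds_ratio,
            "risk_ratio": self.risk_ratio,
            "ci_rd": list(self.ci_rd),
            "ci_log_or": list(self.ci_log_or),
            "ci_log_rr": list(self.ci_log_rr),
            "var_rd": self.var_rd,
        }


def effects_from_probs(p0: float, p1: float) -> tuple[float, float, float]:
    """(log_or, log_rr, rd) from per-arm response probabilities.

    Both probabilities must lie strictly inside (0, 1) for the OR and RR to
    exist; the risk difference alone is just ``p1 - p0``.
    """
    if not (0.0 < p0 < 1.0 and 0.0 < p1 < 1.0):
        raise ValueError(
            "odds and risk ratios require probabilities strictly inside "
            f"(0, 1); got p0={p0}, p1={p1} (the risk difference p1 - p0 is "
            "still defined)"
        )
    rd = p1 - p0
    log_rr = math.log(p1 / p0)
    log_or = math.log(p1 / (1 - p1)) - math.log(p0 / (1 - p0))
    return log_or, log_rr, rd


def probs_from_rd(rd: float, p0: float) -> tuple[float, float]:
    """Inverse anchor map: (p0, p0 + rd); exact round-trip partner of
    :func:`effects_from_probs`."""
    return p0, p0 + rd


def _interval(point: float, se: float, ci_level: float) -> tuple[float, float]:
    z = ndtri(0.5 + ci_level / 2.0)
    return (point - z * se, point + z * se)


def augmented_effects(
    fit: FitResult,
    data: TrialDataset,
    spec: EndpointSpec,
    ci_method: str = "delta",
    B: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
    baseline_average: str = "empirical",
    gradient: str = "analytic",
) -> EffectEstimates:
    """Effects from a fitted latent model via marginal standardization.

    delta: the gradient of each effect w.r.t. the unconstrained parameter
    vector (analytic by default, central differences with
    ``gradient='fd'``) is combined with the fit's covariance; intervals are
    symmetric normal on each effect's scale.

    bootstrap: subjects are resampled with replacement within arm, the model
    refit (warm-started at the original MLE) and percentile intervals taken
    over ``B`` replicates; more than 10% failed refits is an error.
    """
    if not fit.converged:
        raise LatentModelError("effect estimation requires a converged fit")
    p0 = response_probability(
        fit.mle, 0, data.baselines, spec, average=baseline_average
    )
    p1 = response_probability(
        fit.mle, 1, data.baselines, spec, average=baseline_average
    )
    log_or, log_rr, rd = effects_from_probs(p0, p1)
    n0 = int(np.sum(data.arm == 0))
    n1 = int(np.sum(data.arm == 1))

    if ci_method == "delta":
        if gradient == "analytic":
            _, g0 = response_probability_gradient(
                fit.mle, 0, data.baselines, spec, average=baseline_average
            )
            _, g1 = response_probability_gradient(
                fit.mle, 1, data.baselines, spec, average=baseline_average
            )
        elif gradient == "fd":
            g0 = _fd_prob_gradient(fit, data, spec, 0, baseline_average)
            g1 = _fd_prob_gradient(fit, data, spec, 1, baseline_average)
        else:
            raise ValueError("gradient must be 'analytic' or 'fd'")
        grads = {
            "rd": g1 - g0,
            "log_rr": g1 / p1 - g0 / p0,
            "log_or": g1 / (p1 * (1 - p1)) - g0 / (p0 * (1 - p0)),
        }
        ses = {
            k: math.sqrt(max(float(g @ fit.vcov @ g), 0.0))
            for k, g in grads.items()
        }
        return EffectEstimates(
            p0=p0,
            p1=p1,
            log_or=log_or,
            log_rr=log_rr,
            rd=rd,
            ci_log_or=_interval(log_or, ses["log_or"], ci_level),
            ci_log_rr=_interval(log_rr, ses["log_rr"], ci_level),
            ci_rd=_interval(rd, ses["rd"], ci_level),
            ci_level=ci_level,
            method="augmented",
            ci_method="delta",
            var_rd=ses["rd"] ** 2,
            n0=n0,
            n1=n1,
        )

    if ci_method != "bootstrap":
        raise ValueError("ci_method must be 'delta' or 'bootstrap'")

    rng = np.random.default_rng(seed)
    idx0 = np.nonzero(data.arm == 0)[0]
    idx1 = np.nonzero(data.arm == 1)[0]
    reps = {"rd": [], "log_rr": [], "log_or": []}
    failures = 0
    opts = FitOptions(x0=fit.theta)
    for _ in range(B):
        take = np.concatenate(
            [rng.choice(idx0, size=len(idx0)), rng.choice(idx1, size=len(idx1))]
        )
        boot = data.subset(take)
        try:
            bfit = fit_latent_model(boot, spec, options=opts)
            bp0 = response_probability(
                bfit.mle, 0, boot.baselines, spec, average=baseline_average
            )
            bp1 = response_probability(
                bfit.mle, 1, boot.baselines, spec, average=baseline_average
            )
            blor, blrr, brd = effects_from_probs(bp0, bp1)
        except (LatentModelError, ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        reps["rd"].append(brd)
        reps["log_rr"].append(blrr)
        reps["log_or"].append(blor)
    if failures > 0.10 * B:
        raise LatentModelError(
            f"{failures}/{B} bootstrap refits failed",
            diagnostics={"failures": failures, "B": B},
        )
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    cis = {
        k: tuple(np.quantile(np.asarray(v), [lo_q, hi_q])) for k, v in reps.items()
    }
    return EffectEstimates(
        p0=p0,
        p1=p1,
        log_or=log_or,
        log_rr=log_rr,
        rd=rd,
        ci_log_or=cis["log_or"],
        ci_log_rr=cis["log_rr"],
        ci_rd=cis["rd"],
        ci_level=ci_level,
        method="augmented",
        ci_method="bootstrap",
        var_rd=float(np.var(np.asarray(reps["rd"]), ddof=1)),
        n0=n0,
        n1=n1,
    )


def _fd_prob_gradient(
    fit: FitResult,
    data: TrialDataset,
    spec: EndpointSpec,
    arm: int,
    baseline_average: str,
    rel_step: float = 1e-5,
) -> np.ndarray:
    """Central-difference gradient of the response probability w.r.t. the
    unconstrained parameter vector (reference route for the analytic one)."""
    from .latent_model import unpack_parameters

    theta = fit.theta
    g = np.empty_like(theta)
    for i in range(len(theta)):
        h = rel_step * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tp[i] += h
        tm = theta.copy()
        tm[i] -= h
        pp = response_probability(
            unpack_parameters(tp, spec), arm, data.baselines, spec,
            average=baseline_average,
        )
        pm = response_probability(
            unpack_parameters(tm, spec), arm, data.baselines, spec,
            average=baseline_average,
        )
        g[i] = (pp - pm) / (2 * h)
    return g


@dataclass
class EfficiencyReport:
    """Relative-efficiency arithmetic on CI widths and sample sizes."""

    width_ratio: float
    ci_width_reduction_pct: float
    sample_size_inflation_pct: float
    implied_n_reduction_from_width_pct: float
    n_reduction_pct: float | None = None

    def to_dict(self) -> dict:
        return {
            "width_ratio": self.width_ratio,
            "ci_width_reduction_pct": self.ci_width_reduction_pct,
            "sample_size_inflation_pct": self.sample_size_inflation_pct,
            "implied_n_reduction_from_width_pct": (
                self.implied_n_reduction_from_width_pct
            ),
            "n_reduction_pct": self.n_reduction_pct,
        }


def efficiency_report(
    width_aug: float,
    width_bin: float,
    n_aug: int | None = None,
    n_bin: int | None = None,
) -> EfficiencyReport:
    """Efficiency summaries comparing the two analysis routes.

    - ``ci_width_reduction_pct`` = 100 (1 - width_aug/width_bin)
    - ``sample_size_inflation_pct`` = 100 / (width_aug/width_bin)
    - ``implied_n_reduction_from_width_pct`` = 100 (1 - (width_aug/width_bin)^2),
      the square-law translation of a CI-width ratio into a sample-size ratio
    - ``n_reduction_pct`` = 100 (1 - n_aug/n_bin) when counts are supplied
    """
    if width_aug <= 0 or width_bin <= 0:
        raise ValueError("CI widths must be positive")
    ratio = width_aug / width_bin
    n_red = None
    if n_aug is not None or n_bin is not None:
        if n_aug is None or n_bin is None:
            raise ValueError("supply both n_aug and n_bin or neither")
        if n_aug <= 0 or n_bin <= 0:
            raise ValueError("sample sizes must be positive")
        n_red = 100.0 * (1.0 - n_aug / n_bin)
    return EfficiencyReport(
        width_ratio=ratio,
        ci_width_reduction_pct=100.0 * (1.0 - ratio),
        sample_size_inflation_pct=100.0 / ratio,
        implied_n_reduction_from_width_pct=100.0 * (1.0 - ratio**2),
        n_reduction_pct=n_red,
    )
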