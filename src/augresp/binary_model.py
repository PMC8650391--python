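"""Standard analysis of the collapsed responder indicator.

The default path is the unadjusted per-arm proportion with Wald intervals on
the log-OR/log-RR scales and the plain scale for the risk difference.  The
adjusted path fits a logistic regression on arm + baselines, recovers
per-arm probabilities by marginal standardization, and uses a stratified
nonparametric bootstrap for intervals.  Zero cells fail loudly rather than
being continuity-corrected.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit, ndtri

from .effect_estimation import EffectEstimates, effects_from_probs
from .trial_data import EndpointSpec, TrialDataset, classify_responders

__all__ = ["binary_effects", "ZeroCellError"]


class ZeroCellError(ValueError):
    """A 2x2 cell is empty; OR/RR are undefined on the unadjusted path."""


def _logit_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Logistic regression MLE by Newton-Raphson (ridge-free, small p)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        W = p * (1 - p)
        grad = X.T @ (y - p)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(X.shape[1]), grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("logistic regression failed (singular design)") from exc
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _marginal_probs(beta: np.ndarray, data: TrialDataset) -> tuple[float, float]:
    n = data.n_subjects
    out = []
    for arm in (0, 1):
        X = np.column_stack(
            [np.ones(n), np.full(n, float(arm)), data.baselines]
        )
        out.append(float(np.mean(expit(X @ beta))))
    return out[0], out[1]


def binary_effects(
    data: TrialDataset,
    spec: EndpointSpec,
    adjust: bool = False,
    ci_level: float = 0.95,
    B: int = 1000,
    seed: int | None = None,
) -> EffectEstimates:
    """Standard binary analysis of the collapsed composite endpoint.

    Unadjusted (default): per-arm responder proportions with Wald intervals;
    OR/RR require all four 2x2 cells non-empty (:class:`ZeroCellError`
    otherwise, recommending the adjusted/bootstrap path).  Adjusted: logistic
    regression on arm + baselines with marginal standardization and
    within-arm bootstrap percentile intervals.
    """
    data.require_both_arms()
    resp = classify_responders(data, spec)
    if resp.sum() == 0 or resp.sum() == len(resp):
        raise ValueError(
            "need at least one responder and one non-responder overall"
        )
    mask1 = data.arm == 1
    n0, n1 = int((~mask1).sum()), int(mask1.sum())
    z = ndtri(0.5 + ci_level / 2.0)

    if not adjust:
        r0, r1 = int(resp[~mask1].sum()), int(resp[mask1].sum())
        cells = {
            "control responders": r0,
            "control non-responders": n0 - r0,
            "treatment responders": r1,
            "treatment non-responders": n1 - r1,
        }
        empty = [k for k, v in cells.items() if v == 0]
        if empty:
            raise ZeroCellError(
                f"empty 2x2 cell(s): {', '.join(empty)}; odds/risk ratios are "
                "undefined without a continuity correction (none is applied) "
                "- consider the adjusted/bootstrap path (adjust=True)"
            )
        p0, p1 = r0 / n0, r1 / n1
        log_or, log_rr, rd = effects_from_probs(p0, p1)
        se_log_or = math.sqrt(
            1 / r1 + 1 / (n1 - r1) + 1 / r0 + 1 / (n0 - r0)
        )
        se_log_rr = math.sqrt(
            (1 - p1) / (n1 * p1) + (1 - p0) / (n0 * p0)
        )
        var_rd = p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0
        se_rd = math.sqrt(var_rd)
        return EffectEstimates(
            p0=p0,
            p1=p1,
            log_or=log_or,
            log_rr=log_rr,
            rd=rd,
            ci_log_or=(log_or - z * se_log_or, log_or + z * se_log_or),
            ci_log_rr=(log_rr - z * se_log_rr, log_rr + z * se_log_rr),
            ci_rd=(rd - z * se_rd, rd + z * se_rd),
            ci_level=ci_level,
            method="binary-unadjusted",
            ci_method="wald",
            var_rd=var_rd,
            n0=n0,
            n1=n1,
        )

    # adjusted path
    n = data.n_subjects
    X = np.column_stack([np.ones(n), data.arm.astype(float), data.baselines])
    beta = _logit_fit(X, resp.astype(float))
    p0, p1 = _marginal_probs(beta, data)
    log_or, log_rr, rd = effects_from_probs(p0, p1)

    rng = np.random.default_rng(seed)
    idx0 = np.nonzero(~mask1)[0]
    idx1 = np.nonzero(mask1)[0]
    reps = {"rd": [], "log_rr": [], "log_or": []}
    failures = 0
    for _ in range(B):
        take = np.concatenate(
            [rng.choice(idx0, size=n0), rng.choice(idx1, size=n1)]
        )
        boot = data.subset(take)
        bresp = classify_responders(boot, spec)
        Xb = np.column_stack(
            [np.ones(n), boot.arm.astype(float), boot.baselines]
        )
        try:
            bb = _logit_fit(Xb, bresp.astype(float))
            bp0, bp1 = _marginal_probs(bb, boot)
            blor, blrr, brd = effects_from_probs(bp0, bp1)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            failures += 1
            continue
        reps["rd"].append(brd)
        reps["log_rr"].append(blrr)
        reps["log_or"].append(blor)
    if failures > 0.10 * B:
        raise ValueError(f"{failures}/{B} bootstrap refits failed")
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
        method="binary-adjusted",
        ci_method="bootstrap",
        var_rd=float(np.var(np.asarray(reps["rd"]), ddof=1)),
        n0=n0,
        n1=n1,
    )
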