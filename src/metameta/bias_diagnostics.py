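"""Publication-bias diagnostics for a set of Fisher-z effect estimates.

The battery mirrors the classical meta-analytic toolbox:

* Rosenthal's classic fail-safe N (how many hidden null studies would be
  needed to push the combined Stouffer Z past the alpha cutoff),
* Orwin's fail-safe N against a user-supplied criterion effect,
* the Begg-Mazumdar rank correlation between effects and their sampling
  variances (Kendall tau over all pairs, with an optional continuity
  correction that shrinks |C - D| by one),
* Egger's regression of the standardized effect on precision, whose
  intercept measures small-study asymmetry, and
* the Duval-Tweedie trim-and-fill, which iteratively trims the most
  extreme studies on the asymmetric side, re-centres, imputes mirrored
  counterparts and reports the adjusted random-effects summary.

All routines operate on :class:`metameta.effects.EffectEstimate` lists;
none of them needs the raw association tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .effects import EffectEstimate
from .errors import ConvergenceError, DomainError
from .meta_engine import cochran_q, pool_fixed, pool_random_dl

Side = Literal["left", "right"]
TrimEstimator = Literal["L0", "R0"]

_MAX_TRIM_ITER = 50


@dataclass(frozen=True)
class BiasReport:
    """Collected publication-bias statistics (fields fill in as computed)."""

    K: int
    fail_safe_n: float | None = None
    alpha_z: float | None = None
    orwin_n: float | None = None
    orwin_criterion: float | None = None
    kendall_tau: float | None = None
    kendall_tau_cc: float | None = None
    egger_intercept: float | None = None
    egger_se: float | None = None
    egger_t: float | None = None
    egger_df: int | None = None
    trimfill_imputed: int | None = None
    trimfill_estimate: float | None = None
    trimfill_ci_lower: float | None = None
    trimfill_ci_upper: float | None = None
    trimfill_Q: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def fail_safe_n_classic(
    estimates: Sequence[EffectEstimate], alpha: float = 0.05
) -> tuple[float, float]:
    """Rosenthal's fail-safe N: ``max(0, (sum Z_i)^2 / z_alpha^2 - K)``."""
    if len(estimates) == 0:
        raise DomainError("fail_safe_n_classic requires at least one estimate")
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must lie in (0, 1), got {alpha!r}")
    z_alpha = float(ndtri(1.0 - alpha / 2.0))
    z_sum = float(sum(e.z_score for e in estimates))
    n = max(0.0, z_sum**2 / z_alpha**2 - len(estimates))
    return n, z_alpha


def fail_safe_n_orwin(estimates: Sequence[EffectEstimate], criterion_effect: float) -> float:
    """Orwin's fail-safe N against a criterion mean effect.

    ``N = max(0, K * (mean_observed - criterion) / criterion)`` where
    mean_observed is the fixed-effect (inverse-variance weighted) mean.
    """
    if len(estimates) == 0:
        raise DomainError("fail_safe_n_orwin requires at least one estimate")
    if not (criterion_effect > 0):
        raise DomainError(f"criterion effect must be > 0, got {criterion_effect!r}")
    mean_observed = pool_fixed(estimates).pooled_z
    return max(0.0, len(estimates) * (mean_observed - criterion_effect) / criterion_effect)


def begg_mazumdar(
    estimates: Sequence[EffectEstimate],
    continuity: bool = False,
    standardized: bool = False,
) -> float:
    """Kendall rank correlation between effect sizes and their variances.

    The plain variant correlates y_i with se_i^2 over all K(K-1)/2 pairs;
    ``standardized=True`` first centres each effect at the fixed-effect
    mean and divides by its standard deviation as in Begg & Mazumdar's
    original refinement.  With ``continuity`` the numerator |C - D| is
    reduced by 1 (sign preserved, floored at 0).
    """
    K = len(estimates)
    if K < 2:
        raise DomainError("begg_mazumdar requires at least two estimates")
    y = np.array([e.fisher_z for e in estimates], dtype=float)
    v = np.array([e.variance for e in estimates], dtype=float)
    if standardized:
        fixed = pool_fixed(estimates)
        sw = float(sum(1.0 / e.variance for e in estimates))
        # variance of (y_i - pooled) under the fixed-effect model
        vstar = v - 1.0 / sw
        vstar = np.clip(vstar, 1e-300, None)
        y = (y - fixed.pooled_z) / np.sqrt(vstar)
    concordant = discordant = 0
    for i in range(K):
        for j in range(i + 1, K):
            s = (y[i] - y[j]) * (v[i] - v[j])
            if s > 0:
                concordant += 1
            elif s < 0:
                discordant += 1
    pairs = K * (K - 1) / 2
    num = concordant - discordant
    if continuity:
        num = math.copysign(max(0.0, abs(num) - 1.0), num)
    return num / pairs


def egger(estimates: Sequence[EffectEstimate]) -> tuple[float, float, float, int]:
    """Egger's regression intercept test for funnel asymmetry.

    OLS of the standardized effect y_i/se_i on the precision 1/se_i;
    returns (intercept, its standard error, t = intercept/se, df = K-2).
    """
    K = len(estimates)
    if K < 3:
        raise DomainError("egger requires at least three estimates (insufficient studies)")
    x = np.array([1.0 / e.se for e in estimates], dtype=float)
    t_resp = np.array([e.z_score for e in estimates], dtype=float)
    xbar = x.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx <= 0:
        raise DomainError("all precisions identical: Egger design matrix is singular")
    slope = float(((x - xbar) * (t_resp - t_resp.mean())).sum() / sxx)
    intercept = float(t_resp.mean() - slope * xbar)
    resid = t_resp - (intercept + slope * x)
    df = K - 2
    s2 = float((resid**2).sum() / df)
    se_intercept = math.sqrt(s2 * (1.0 / K + xbar**2 / sxx))
    return intercept, se_intercept, intercept / se_intercept, df


def _signed_deviations(y: np.ndarray, center: float, side: Side) -> np.ndarray:
    """Deviations oriented so the suspected-excess side is positive."""
    d = y - center
    return d if side == "right" else -d


def _estimate_k0(y: np.ndarray, center: float, side: Side, estimator: TrimEstimator) -> int:
    d = _signed_deviations(y, center, side)
    n = len(d)
    # quantize so float noise cannot break exact ties or signs
    scale = float(np.max(np.abs(d))) or 1.0
    d = np.where(np.abs(d) <= 1e-9 * scale, 0.0, d)
    d = np.round(d / scale, 9) * scale
    order = np.argsort(np.abs(d), kind="stable")
    # midranks keep an exactly symmetric funnel at k0 = 0
    ranks = rankdata(np.abs(d), method="average")
    if estimator == "L0":
        t_n = float(ranks[d > 0].sum())
        k0 = (4.0 * t_n - n * (n + 1)) / (2.0 * n - 1.0)
    elif estimator == "R0":
        # length of the run of positive deviations holding the largest |d| ranks
        gamma = 0
        for idx in order[::-1]:
            if d[idx] > 0:
                gamma += 1
            else:
                break
        k0 = gamma - 1.0
    else:
        raise DomainError(f"unknown trim-and-fill estimator {estimator!r}")
    return max(0, int(round(k0)))


def trim_and_fill(
    estimates: Sequence[EffectEstimate],
    side: Side = "right",
    estimator: TrimEstimator = "L0",
    level: float = 0.95,
) -> tuple[BiasReport, list[EffectEstimate]]:
    """Duval-Tweedie trim-and-fill.

    ``side`` names the side of the funnel holding the *excess* observed
    studies (``right`` under the all-positive entry convention, where
    suppression hides small effects on the left).  The k0 most extreme
    studies on that side are trimmed, the fixed-effect centre is
    re-estimated on the remainder, and the loop repeats until k0
    stabilizes; the trimmed studies are then mirrored about the final
    centre and the adjusted DerSimonian-Laird summary is computed on the
    filled set.  Returns the report and the augmented estimate list
    (imputed units carry source_id suffix ``~fill``).
    """
    K = len(estimates)
    if K < 2:
        raise DomainError("trim_and_fill requires at least two estimates")
    y_all = np.array([e.fisher_z for e in estimates], dtype=float)
    # order along the oriented axis; extreme (most positive) last
    oriented = y_all if side == "right" else -y_all
    order = np.argsort(oriented, kind="stable")
    k0 = 0
    history = []
    for _ in range(_MAX_TRIM_ITER):
        keep_idx = order[: K - k0] if k0 > 0 else order
        kept = [estimates[i] for i in keep_idx]
        center = pool_fixed(kept).pooled_z
        k0_new = _estimate_k0(y_all, center, side, estimator)
        k0_new = min(k0_new, K - 2)  # never trim below two studies
        history.append((k0, center))
        if k0_new == k0:
            break
        k0 = k0_new
    else:
        raise ConvergenceError(
            f"trim_and_fill did not stabilize after {_MAX_TRIM_ITER} iterations",
            state={"history": history, "side": side, "estimator": estimator},
        )
    filled = list(estimates)
    if k0 > 0:
        trimmed_idx = order[K - k0:]
        for i in trimmed_idx:
            src = estimates[i]
            filled.append(
                EffectEstimate(
                    fisher_z=2.0 * center - src.fisher_z,
                    se=src.se,
                    n=src.n,
                    source_id=(src.source_id or f"unit_{i + 1}") + "~fill",
                )
            )
    adjusted = pool_random_dl(filled, level=level)
    report = BiasReport(
        K=K,
        trimfill_imputed=int(k0),
        trimfill_estimate=adjusted.pooled_z,
        trimfill_ci_lower=adjusted.ci_lower,
        trimfill_ci_upper=adjusted.ci_upper,
        trimfill_Q=cochran_q(filled),
    )
    return report, filled


def funnel_data(
    estimates: Sequence[EffectEstimate],
    center: float | None = None,
    imputed_suffix: str = "~fill",
) -> pd.DataFrame:
    """Funnel-plot rows: Fisher z against standard error (se axis inverted).

    ``center`` defaults to the random-effects pooled estimate and is
    recorded on every row as the vertical reference; units whose
    source_id carries ``imputed_suffix`` are flagged as imputed.
    """
    if len(estimates) == 0:
        raise DomainError("funnel_data requires at least one estimate")
    if center is None:
        center = pool_random_dl(estimates).pooled_z
    rows = [
        {
            "label": e.source_id or f"unit_{i + 1}",
            "fisher_z": e.fisher_z,
            "se": e.se,
            "imputed_flag": bool(e.source_id and e.source_id.endswith(imputed_suffix)),
            "center": center,
            "invert_y": True,
        }
        for i, e in enumerate(estimates)
    ]
    return pd.DataFrame(rows)


def bias_battery(
    estimates: Sequence[EffectEstimate],
    alpha: float = 0.05,
    orwin_criterion: float | None = None,
    side: Side = "right",
    estimator: TrimEstimator = "L0",
    level: float = 0.95,
) -> BiasReport:
    """Run every diagnostic that the study count K permits and merge reports."""
    K = len(estimates)
    fsn, alpha_z = fail_safe_n_classic(estimates, alpha=alpha)
    report = BiasReport(K=K, fail_safe_n=fsn, alpha_z=alpha_z)
    if orwin_criterion is not None:
        report = replace(
            report,
            orwin_n=fail_safe_n_orwin(estimates, orwin_criterion),
            orwin_criterion=orwin_criterion,
        )
    if K >= 2:
        report = replace(
            report,
            kendall_tau=begg_mazumdar(estimates, continuity=False),
            kendall_tau_cc=begg_mazumdar(estimates, continuity=True),
        )
        tf_report, _ = trim_and_fill(estimates, side=side, estimator=estimator, level=level)
        report = replace(
            report,
            trimfill_imputed=tf_report.trimfill_imputed,
            trimfill_estimate=tf_report.trimfill_estimate,
            trimfill_ci_lower=tf_report.trimfill_ci_lower,
            trimfill_ci_upper=tf_report.trimfill_ci_upper,
            trimfill_Q=tf_report.trimfill_Q,
        )
    if K >= 3:
        intercept, se, t, df = egger(estimates)
        report = replace(
            report, egger_intercept=intercept, egger_se=se, egger_t=t, egger_df=df
        )
    return report
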