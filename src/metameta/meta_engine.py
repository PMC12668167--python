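"""Fixed- and random-effects pooling on the Fisher-z scale.

The random-effects model uses the DerSimonian-Laird moment estimator of
the between-unit variance tau^2:

    Q   = sum w_i (y_i - ybar_fixed)^2,   w_i = 1/se_i^2
    C   = sum w_i - sum w_i^2 / sum w_i
    tau^2 = max(0, (Q - (K-1)) / C)

after which units are re-weighted by 1/(se_i^2 + tau^2).  Confidence
intervals use the normal quantile (no Knapp-Hartung adjustment), and all
p-values are two-tailed.

A second-level "meta-meta" treats each trait-level meta-analytic summary
as one pseudo-study: by default each group's pooled two-tailed p-value
and total sample size are re-converted through
:func:`metameta.effects.effect_from_p_n` and pooled with the same
DerSimonian-Laird engine (``pseudo_study`` mode); alternatively the
groups' (pooled_z, se) pairs can be pooled directly
(``pooled_estimates`` mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .effects import EffectEstimate, effect_from_p_n
from .errors import DomainError

MetaModel = Literal["fixed", "random"]
MetaMetaMode = Literal["pseudo_study", "pooled_estimates"]


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect with heterogeneity statistics and per-unit weights."""

    model: MetaModel
    K: int
    pooled_z: float
    se: float
    ci_lower: float
    ci_upper: float
    z_stat: float
    p_value: float
    Q: float
    df: int
    tau2: float
    I2: float
    level: float
    weights: tuple[tuple[str, float], ...]  # (source_id, relative weight in %)
    total_n: int | None = None
    mode: str | None = None  # set by meta_meta

    @property
    def weight_pct(self) -> dict[str, float]:
        return dict(self.weights)

    def as_effect(self, source_id: str = "pooled") -> EffectEstimate:
        """The summary as a unit usable in a higher-level pooling."""
        return EffectEstimate(
            fisher_z=self.pooled_z, se=self.se, n=self.total_n, source_id=source_id
        )

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "K": self.K,
            "pooled_z": self.pooled_z,
            "se": self.se,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "z_stat": self.z_stat,
            "p_value": self.p_value,
            "Q": self.Q,
            "df": self.df,
            "tau2": self.tau2,
            "I2": self.I2,
            "level": self.level,
            "weights": {k: v for k, v in self.weights},
            "total_n": self.total_n,
        }
        if self.mode is not None:
            d["mode"] = self.mode
        return d


def _check_estimates(estimates: Sequence[EffectEstimate]) -> None:
    if len(estimates) == 0:
        raise DomainError("cannot pool an empty list of estimates")
    for e in estimates:
        if e.se <= 0:
            raise DomainError(f"standard error must be positive, got {e.se!r}")


def _labels(estimates: Sequence[EffectEstimate]) -> list[str]:
    out = []
    for i, e in enumerate(estimates):
        out.append(e.source_id or f"unit_{i + 1}")
    return out


def _total_n(estimates: Sequence[EffectEstimate]) -> int | None:
    ns = [e.n for e in estimates]
    if any(n is None for n in ns):
        return None
    return int(sum(ns))


def _finish(
    model: MetaModel,
    estimates: Sequence[EffectEstimate],
    y: np.ndarray,
    wstar: np.ndarray,
    Q: float,
    tau2: float,
    level: float,
) -> MetaResult:
    K = len(y)
    df = K - 1
    sw = float(wstar.sum())
    pooled = float(np.dot(wstar, y) / sw)
    se = 1.0 / math.sqrt(sw)
    crit = float(ndtri((1.0 + level) / 2.0))
    z_stat = pooled / se
    p_value = float(2.0 * ndtr(-abs(z_stat)))
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    rel = wstar / sw * 100.0
    weights = tuple(zip(_labels(estimates), (float(w) for w in rel)))
    return MetaResult(
        model=model,
        K=K,
        pooled_z=pooled,
        se=se,
        ci_lower=pooled - crit * se,
        ci_upper=pooled + crit * se,
        z_stat=z_stat,
        p_value=p_value,
        Q=Q,
        df=df,
        tau2=tau2,
        I2=I2,
        level=level,
        weights=weights,
        total_n=_total_n(estimates),
    )


def pool_fixed(estimates: Sequence[EffectEstimate], level: float = 0.95) -> MetaResult:
    """Inverse-variance fixed-effect pooling (the DL backbone)."""
    _check_estimates(estimates)
    if not (0.0 < level < 1.0):
        raise DomainError(f"confidence level must lie in (0, 1), got {level!r}")
    y = np.array([e.fisher_z for e in estimates], dtype=float)
    w = np.array([1.0 / e.variance for e in estimates], dtype=float)
    ybar = float(np.dot(w, y) / w.sum())
    Q = float(np.dot(w, (y - ybar) ** 2))
    return _finish("fixed", estimates, y, w, Q, 0.0, level)


def cochran_q(estimates: Sequence[EffectEstimate]) -> float:
    """Cochran heterogeneity statistic about the fixed-effect mean."""
    _check_estimates(estimates)
    y = np.array([e.fisher_z for e in estimates], dtype=float)
    w = np.array([1.0 / e.variance for e in estimates], dtype=float)
    ybar = float(np.dot(w, y) / w.sum())
    return float(np.dot(w, (y - ybar) ** 2))


def dl_tau2(estimates: Sequence[EffectEstimate]) -> float:
    """DerSimonian-Laird moment estimate of the between-unit variance."""
    _check_estimates(estimates)
    K = len(estimates)
    if K == 1:
        return 0.0
    w = np.array([1.0 / e.variance for e in estimates], dtype=float)
    Q = cochran_q(estimates)
    C = float(w.sum() - (w**2).sum() / w.sum())
    return max(0.0, (Q - (K - 1)) / C)


def pool_random_dl(estimates: Sequence[EffectEstimate], level: float = 0.95) -> MetaResult:
    """DerSimonian-Laird random-effects pooling."""
    _check_estimates(estimates)
    if not (0.0 < level < 1.0):
        raise DomainError(f"confidence level must lie in (0, 1), got {level!r}")
    y = np.array([e.fisher_z for e in estimates], dtype=float)
    tau2 = dl_tau2(estimates)
    Q = cochran_q(estimates)
    wstar = np.array([1.0 / (e.variance + tau2) for e in estimates], dtype=float)
    return _finish("random", estimates, y, wstar, Q, tau2, level)


@dataclass(frozen=True)
class GroupSummary:
    """One trait-level meta-analysis entering the second-level pooling."""

    label: str
    p_value: float
    total_n: int | None = None
    pooled_z: float | None = None
    se: float | None = None

    @classmethod
    def from_meta_result(cls, result: MetaResult, label: str, total_n: int | None = None) -> "GroupSummary":
        return cls(
            label=label,
            p_value=result.p_value,
            total_n=total_n if total_n is not None else result.total_n,
            pooled_z=result.pooled_z,
            se=result.se,
        )


def meta_meta(
    groups: Sequence[GroupSummary],
    mode: MetaMetaMode = "pseudo_study",
    level: float = 0.95,
) -> MetaResult:
    """Second-level pooling over trait-level meta-analytic summaries.

    ``pseudo_study`` (default): each group's (pooled p, total n) pair is
    re-converted to a Fisher-z pseudo-study; ``pooled_estimates``: each
    group's (pooled_z, se) pair is pooled directly.
    """
    if len(groups) == 0:
        raise DomainError("meta_meta requires at least one group")
    if mode == "pseudo_study":
        estimates = []
        for g in groups:
            if g.total_n is None:
                raise DomainError(f"group {g.label!r} is missing total_n (pseudo_study mode)")
            estimates.append(effect_from_p_n(g.p_value, g.total_n, source_id=g.label))
    elif mode == "pooled_estimates":
        estimates = []
        for g in groups:
            if g.pooled_z is None or g.se is None:
                raise DomainError(f"group {g.label!r} is missing (pooled_z, se)")
            estimates.append(
                EffectEstimate(fisher_z=g.pooled_z, se=g.se, n=g.total_n, source_id=g.label)
            )
    else:
        raise DomainError(f"unknown meta-meta mode {mode!r}")
    result = pool_random_dl(estimates, level=level)
    return replace(result, mode=mode)


def forest_data(result: MetaResult, estimates: Sequence[EffectEstimate]) -> pd.DataFrame:
    """Rows for a forest plot: one per unit plus a pooled summary row.

    Columns: label, effect, lower, upper, weight_pct; unit CIs use the
    result's confidence level and the weight column sums to 100 plus the
    summary row's 100.
    """
    crit = float(ndtri((1.0 + result.level) / 2.0))
    wmap = result.weight_pct
    labels = _labels(estimates)
    rows = []
    for label, e in zip(labels, estimates):
        rows.append(
            {
                "label": label,
                "effect": e.fisher_z,
                "lower": e.fisher_z - crit * e.se,
                "upper": e.fisher_z + crit * e.se,
                "weight_pct": wmap.get(label, float("nan")),
                "is_summary": False,
            }
        )
    rows.append(
        {
            "label": f"pooled ({result.model})",
            "effect": result.pooled_z,
            "lower": result.ci_lower,
            "upper": result.ci_upper,
            "weight_pct": 100.0,
            "is_summary": True,
        }
    )
    return pd.DataFrame(rows)
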