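"""Convert GWAS association records into meta-analyzable Fisher-z effects.

A study that reports only a two-tailed p-value and a total sample size n
is entered on the Fisher-z partial-correlation scale: the normal deviate
Z = Phi^-1(1 - p/2) is divided by sqrt(n - 3), giving an effect whose
standard error is the classical 1/sqrt(n - 3) of a z-transformed
correlation.  All effects are entered with positive direction, matching
the convention of reporting GWAS associations as positive signals.

Study selection is two-phase: first every record at or above the
genome-wide significance threshold (default 5e-8) is discarded, then
within each surviving study the single most cautious (largest) remaining
p-value is kept, one pseudo-observation per study.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal

from scipy import stats
from scipy.special import ndtr, ndtri

from .errors import DomainError

logger = logging.getLogger(__name__)

GENOME_WIDE_THRESHOLD = 5e-8

#: p-values of exactly 0 (underflow in source files) are clamped here.
P_UNDERFLOW_FLOOR = 1e-300

VARIANT_CONTEXTS = (
    "intergenic",
    "non_coding_transcript",
    "synonymous",
    "missense",
    "regulatory",
    "other",
)

#: contexts removed when building gene lists (see :mod:`metameta.genelist`).
EXCLUDED_CONTEXTS = frozenset({"intergenic", "non_coding_transcript", "synonymous"})


@dataclass(frozen=True)
class AssociationRecord:
    """One GWAS-catalog-style association row.

    ``effect_text`` (an OR/beta with CI bounds) is carried for provenance
    but never used numerically.
    """

    study_id: str
    trait_id: str
    rsid: str
    mapped_gene: str
    variant_context: str
    p_value: float | None
    sample_size: int | None
    effect_text: str | None = None

    def __post_init__(self):
        if not self.study_id or not self.trait_id:
            raise DomainError("study_id and trait_id must be non-empty")
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise DomainError(
                f"p_value must lie in (0, 1], got {self.p_value!r} "
                f"(study {self.study_id}, {self.rsid})"
            )
        if self.sample_size is not None and self.sample_size < 4:
            raise DomainError(
                f"sample_size must be >= 4 (needed for 1/sqrt(n-3)), got "
                f"{self.sample_size!r} (study {self.study_id})"
            )


@dataclass(frozen=True)
class StudyInput:
    """One pseudo-observation for meta-analysis: (two-tailed p, n, label)."""

    source_id: str
    p_value: float
    n: int
    direction: int = 1  # positive by entry convention

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise DomainError(f"p_value must lie in (0, 1], got {self.p_value!r}")
        if self.n < 4:
            raise DomainError(f"n must be >= 4, got {self.n!r}")
        if self.direction != 1:
            raise DomainError("only positive effect direction is supported")


@dataclass(frozen=True)
class EffectEstimate:
    """A Fisher-z partial-correlation effect with its standard error."""

    fisher_z: float
    se: float
    n: int | None = None
    source_id: str = ""

    def __post_init__(self):
        if not math.isfinite(self.fisher_z):
            raise DomainError(f"non-finite fisher_z: {self.fisher_z!r}")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise DomainError(f"se must be positive and finite, got {self.se!r}")

    @property
    def r(self) -> float:
        """Back-transformed correlation tanh(fisher_z)."""
        return math.tanh(self.fisher_z)

    @property
    def variance(self) -> float:
        return self.se * self.se

    @property
    def z_score(self) -> float:
        """Standardized effect fisher_z / se."""
        return self.fisher_z / self.se


def _clamp_p(p: float) -> float:
    if p == 0.0:
        logger.warning("p-value of 0 clamped to %.0e (underflow)", P_UNDERFLOW_FLOOR)
        return P_UNDERFLOW_FLOOR
    return p


def p_to_z(p: float) -> float:
    """Two-tailed p-value -> nonnegative standard normal deviate.

    Z = Phi^-1(1 - p/2); Z >= 0, and ``z_to_p`` inverts it.
    """
    p = _clamp_p(float(p))
    if not (0.0 < p <= 1.0) or not math.isfinite(p):
        raise DomainError(f"two-tailed p must lie in (0, 1], got {p!r}")
    # isf(p/2) evaluates the upper tail directly and keeps full precision
    # for genome-wide p-values (ndtri(1 - p/2) loses digits below ~1e-15).
    return float(stats.norm.isf(p / 2.0))


def z_to_p(z: float) -> float:
    """Nonnegative deviate -> two-tailed p-value (inverse of :func:`p_to_z`)."""
    if z < 0 or not math.isfinite(z):
        raise DomainError(f"z must be finite and >= 0, got {z!r}")
    return float(2.0 * ndtr(-z))


def effect_from_p_n(
    p: float,
    n: int,
    source_id: str = "",
    method: Literal["normal", "t"] = "normal",
) -> EffectEstimate:
    """Build a Fisher-z effect from a two-tailed p-value and sample size.

    The default ``normal`` method sets fisher_z = Phi^-1(1 - p/2)/sqrt(n-3).
    The ``t`` variant converts p to a t deviate on n-2 degrees of freedom,
    maps it to a correlation r = t/sqrt(t^2 + n - 2) and Fisher-transforms;
    both use se = 1/sqrt(n-3).
    """
    p = _clamp_p(float(p))
    if not math.isfinite(p) or not (0.0 < p <= 1.0):
        raise DomainError(f"two-tailed p must lie in (0, 1], got {p!r}")
    n = int(n)
    if n < 4:
        raise DomainError(f"sample size must be >= 4 for 1/sqrt(n-3), got {n}")
    se = 1.0 / math.sqrt(n - 3)
    if method == "normal":
        fisher_z = p_to_z(p) * se
    elif method == "t":
        t = float(stats.t.isf(p / 2.0, df=n - 2))
        r = t / math.sqrt(t * t + n - 2)
        fisher_z = math.atanh(r)
    else:
        raise DomainError(f"unknown conversion method {method!r}")
    return EffectEstimate(fisher_z=fisher_z, se=se, n=n, source_id=source_id)


def effect_from_study(study: StudyInput, method: Literal["normal", "t"] = "normal") -> EffectEstimate:
    return effect_from_p_n(study.p_value, study.n, source_id=study.source_id, method=method)


def wald_ci(estimate: EffectEstimate, level: float = 0.95) -> tuple[float, float]:
    """Normal-theory confidence interval on the Fisher-z scale."""
    if not (0.0 < level < 1.0):
        raise DomainError(f"confidence level must lie in (0, 1), got {level!r}")
    crit = float(ndtri((1.0 + level) / 2.0))
    return (estimate.fisher_z - crit * estimate.se, estimate.fisher_z + crit * estimate.se)


def select_study_inputs(
    records: Iterable[AssociationRecord],
    threshold: float = GENOME_WIDE_THRESHOLD,
    rule: Literal["largest", "smallest"] = "largest",
) -> list[StudyInput]:
    """Two-phase selection of one (p, n) pseudo-observation per study.

    Phase 1 keeps only records with p strictly below ``threshold`` (records
    missing p or n are excluded).  Phase 2 keeps, within each surviving
    study, the single record with the largest remaining p-value -- the most
    cautious genome-wide-significant signal (``rule="smallest"`` flips this
    for sensitivity analysis).  Ties are broken by lexicographically
    smallest rsid.  Output is sorted by study_id.
    """
    by_study: dict[str, AssociationRecord] = {}
    for rec in records:
        if rec.p_value is None or rec.sample_size is None:
            continue
        if not (rec.p_value < threshold):
            continue
        best = by_study.get(rec.study_id)
        if best is None:
            by_study[rec.study_id] = rec
            continue
        if rule == "largest":
            better_p = rec.p_value > best.p_value
        elif rule == "smallest":
            better_p = rec.p_value < best.p_value
        else:
            raise DomainError(f"unknown selection rule {rule!r}")
        tie = rec.p_value == best.p_value and _rsid_tiebreak(rec.rsid) < _rsid_tiebreak(best.rsid)
        if better_p or tie:
            by_study[rec.study_id] = rec
    if not by_study:
        logger.warning("select_study_inputs: no study survived the p < %g filter", threshold)
    return [
        StudyInput(source_id=sid, p_value=rec.p_value, n=rec.sample_size)
        for sid, rec in sorted(by_study.items())
    ]


def _rsid_tiebreak(rsid: str) -> str:
    return rsid or "~"
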