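"""Similarity-index primitives.

The similarity index ``I_SIM = ES_THEO / ES_OBS`` compares a point-specific
theoretically predicted effect (a mean difference, or a correlation) directly
with an observed effect, deliberately avoiding the observed standard
deviation *s*.  A value of 1 is a perfect match; values inside a *similarity
interval* (SI, default ``[0.80, 1.20]``) count as a preliminary match.

Conventions:

* If prediction and observation point in opposite directions, ``I_SIM`` is
  recorded as 0 (the raw signed ratio is kept as a diagnostic).
* If the observed effect is exactly 0, ``I_SIM`` is undefined.
* A predicted effect of exactly 0 is rejected: the method presupposes a
  nonzero point prediction.

Also provided is Meehl's corroboration index ``Ci = Cl * In`` with
``Cl = 1 - D/S`` (closeness of the observation to the prediction) and
``In = 1 - I/S`` (intolerance, i.e. precision, of the prediction), where
``S`` is the Spielraum: the expected range of observations irrespective of
the theory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

__all__ = [
    "Category",
    "SimilarityInterval",
    "SimilarityVerdict",
    "MeehlComponents",
    "ValidationError",
    "InvalidPredictionError",
    "compute_isim",
    "compute_isim_from_means",
    "compute_isim_correlation",
    "classify_verdict",
    "classify",
    "meehl_corroboration",
]


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class InvalidPredictionError(ValidationError):
    """The theoretical prediction is unusable (zero predicted effect)."""


class Category(str, Enum):
    """Qualitative outcome of comparing a prediction with an observation."""

    MATCH = "match"
    BELOW = "below"
    ABOVE = "above"
    OPPOSITE = "opposite"
    UNDEFINED = "undefined"
    #: ratio computed but not yet compared against a similarity interval
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class SimilarityInterval:
    """Closed acceptance band for ``I_SIM`` values.

    Defaults to ``[0.80, 1.20]``, the band within which roughly 95% of
    repetitions of a well-powered study of a large matched effect fall.
    """

    lower: float = 0.80
    upper: float = 1.20

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValidationError("similarity interval bounds must be finite")
        if not (0.0 < self.lower < 1.0 < self.upper):
            raise ValidationError(
                f"similarity interval must satisfy 0 < lower < 1 < upper, "
                f"got [{self.lower}, {self.upper}]"
            )

    def contains(self, isim: float) -> bool:
        """Closed-interval membership test."""
        return self.lower <= isim <= self.upper


@dataclass(frozen=True)
class SimilarityVerdict:
    """An ``I_SIM`` value together with its qualitative category.

    ``isim`` is ``es_theo / es_obs`` when both effects point the same way,
    0 for opposite-direction observations (with the raw signed ratio kept in
    ``raw_ratio``), and NaN when the observed effect is 0 (undefined).
    """

    isim: float
    es_theo: float
    es_obs: float
    category: Category = Category.UNCLASSIFIED
    raw_ratio: float | None = None

    @property
    def defined(self) -> bool:
        return self.category is not Category.UNDEFINED


@dataclass(frozen=True)
class MeehlComponents:
    """Meehl's corroboration index and its parts.

    All of ``D`` (deviation of the observation from the prediction's
    tolerance interval), ``S`` (Spielraum) and ``I`` (tolerance interval
    width) live on the prediction's measurement scale; the derived
    ``Cl``, ``In`` and ``Ci`` are unitless and lie in ``[0, 1]`` whenever
    ``0 <= D <= S`` and ``0 <= I <= S``.
    """

    deviation_D: float
    spielraum_S: float
    tolerance_I: float
    closeness_Cl: float
    intolerance_In: float
    corroboration_Ci: float


def _require_finite(**values: float) -> None:
    for name, value in values.items():
        if not math.isfinite(value):
            raise ValidationError(f"{name} must be finite, got {value!r}")


def compute_isim(es_theo: float, es_obs: float) -> SimilarityVerdict:
    """Compute the similarity index between a predicted and an observed effect.

    Parameters
    ----------
    es_theo
        Theoretically predicted effect (mean difference on the s = 1 scale).
        Must be nonzero and finite.
    es_obs
        Observed effect on the same scale.

    Returns
    -------
    SimilarityVerdict
        With ``category`` set to ``opposite`` or ``undefined`` when the sign
        or zero rules apply, and ``unclassified`` otherwise; comparison with
        a similarity interval is a separate step (:func:`classify_verdict`).
    """
    _require_finite(es_theo=es_theo, es_obs=es_obs)
    if es_theo == 0:
        raise InvalidPredictionError(
            "a point prediction of exactly zero effect cannot be evaluated"
        )
    if es_obs == 0:
        return SimilarityVerdict(
            isim=math.nan, es_theo=es_theo, es_obs=es_obs, category=Category.UNDEFINED
        )
    ratio = es_theo / es_obs
    if ratio < 0:  # signs disagree
        return SimilarityVerdict(
            isim=0.0,
            es_theo=es_theo,
            es_obs=es_obs,
            category=Category.OPPOSITE,
            raw_ratio=ratio,
        )
    return SimilarityVerdict(isim=ratio, es_theo=es_theo, es_obs=es_obs)


def compute_isim_from_means(m_theo: float, m0: float, m1: float) -> SimilarityVerdict:
    """Similarity index from raw group means.

    ``I_SIM = (m_theo - m0) / (m1 - m0)``: the predicted mean difference over
    the observed one.  Invariant under any affine rescaling
    ``x -> k*x + c`` (``k > 0``) applied to all three means, so observations
    on different measurement scales stay comparable.
    """
    _require_finite(m_theo=m_theo, m0=m0, m1=m1)
    if m_theo == m0:
        raise InvalidPredictionError(
            "predicted mean equals the control mean: zero predicted effect"
        )
    return compute_isim(m_theo - m0, m1 - m0)


def compute_isim_correlation(r_theo: float, r_obs: float) -> SimilarityVerdict:
    """Similarity index between a predicted and an observed correlation.

    The index applies to one predicted correlation against one observed
    correlation at a time (it does not judge whole correlation matrices).
    """
    _require_finite(r_theo=r_theo, r_obs=r_obs)
    for name, r in (("r_theo", r_theo), ("r_obs", r_obs)):
        if not -1.0 <= r <= 1.0:
            raise ValidationError(f"{name} must lie in [-1, 1], got {r}")
    return compute_isim(r_theo, r_obs)


def classify_verdict(
    verdict: SimilarityVerdict, si: SimilarityInterval | None = None
) -> SimilarityVerdict:
    """Fill in the match/below/above category against a similarity interval.

    ``opposite`` and ``undefined`` verdicts pass through unchanged.  Bounds
    are treated as closed: ``isim == lower`` or ``isim == upper`` counts as
    a match.
    """
    si = si or SimilarityInterval()
    if verdict.category in (Category.OPPOSITE, Category.UNDEFINED):
        return verdict
    if si.contains(verdict.isim):
        category = Category.MATCH
    elif verdict.isim < si.lower:
        category = Category.BELOW
    else:
        category = Category.ABOVE
    return replace(verdict, category=category)


def classify(
    es_theo: float, es_obs: float, si: SimilarityInterval | None = None
) -> SimilarityVerdict:
    """Convenience: :func:`compute_isim` followed by :func:`classify_verdict`."""
    return classify_verdict(compute_isim(es_theo, es_obs), si)


def meehl_corroboration(
    deviation_D: float, spielraum_S: float, tolerance_I: float
) -> MeehlComponents:
    """Meehl's corroboration index ``Ci = Cl * In``.

    Parameters
    ----------
    deviation_D
        Deviation of the observed value from the theory's tolerance interval
        (0 if the observation falls inside it).  Must be >= 0.
    spielraum_S
        Expected range of possible observations irrespective of the theory.
        Must be > 0; how to estimate it is left to the caller.
    tolerance_I
        Width of the interval the theory tolerates (raw precision of the
        prediction).  Must be >= 0.
    """
    _require_finite(
        deviation_D=deviation_D, spielraum_S=spielraum_S, tolerance_I=tolerance_I
    )
    if spielraum_S <= 0:
        raise ValidationError(f"Spielraum S must be positive, got {spielraum_S}")
    if deviation_D < 0 or tolerance_I < 0:
        raise ValidationError("deviation D and tolerance I must be non-negative")
    closeness = 1.0 - deviation_D / spielraum_S
    intolerance = 1.0 - tolerance_I / spielraum_S
    return MeehlComponents(
        deviation_D=deviation_D,
        spielraum_S=spielraum_S,
        tolerance_I=tolerance_I,
        closeness_Cl=closeness,
        intolerance_In=intolerance,
        corroboration_Ci=closeness * intolerance,
    )
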