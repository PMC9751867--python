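"""Monte Carlo calibration of the similarity index.

A *study setting* fixes the population means of a two-group design, a
point prediction, and per-group sample sizes.  The engine repeatedly draws
the two observed group means, computes ``I_SIM = (m_theo - m̄0)/(m̄1 - m̄0)``
for each repetition — note that the *sampled* control mean enters the
numerator as well as the denominator — and summarises the resulting
distribution in the ten standard bins together with the similarity-interval
(SI) coverage.

Sampling model (``df_mode="t_nminus1"``, the default): each group mean is

    m̄_g = m_g_pop + pop_sd * T(df = n_g - 1) / sqrt(n_g)

with the two groups independent.  ``normal`` replaces the t kernel by a
standard normal; ``raw_draws`` averages n_g individual t-distributed
observations per group, which is distributionally close to ``t_nminus1``
but noticeably slower.

An analytic quadrature oracle (:func:`analytic_coverage_oracle`) computes
the same SI coverage by integrating over the joint distribution of the two
sampled means, giving an independent check on the engine, and
:func:`find_min_n` searches it for the smallest sample size reaching a
target coverage.
"""

from __future__ import annotations

import hashlib
import logging
import math
import time
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import integrate, stats

from .core import (
    Category,
    SimilarityInterval,
    SimilarityVerdict,
    ValidationError,
)

__all__ = [
    "DF_MODES",
    "BIN_LABELS",
    "BIN_EDGES",
    "SI_BIN_LABELS",
    "TABLE1_EFFECTS",
    "TABLE2_PAIRS",
    "GRID_SAMPLE_SIZES",
    "StudySetting",
    "SimulationConfig",
    "ISimDistribution",
    "NumericalError",
    "draw_observed_means",
    "bin_isim_values",
    "simulate_isim_distribution",
    "analytic_coverage_oracle",
    "replicate_table1",
    "replicate_table2",
    "coverage_gap",
    "find_min_n",
    "UNREACHABLE",
]

logger = logging.getLogger(__name__)

DF_MODES = ("t_nminus1", "normal", "raw_draws")

#: Interior bin edges of the printed ten-bin scheme (left-open, right-closed).
BIN_EDGES = (0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4)
BIN_LABELS = (
    "<=0.6",
    "(0.6,0.7]",
    "(0.7,0.8]",
    "(0.8,0.9]",
    "(0.9,1.0]",
    "(1.0,1.1]",
    "(1.1,1.2]",
    "(1.2,1.3]",
    "(1.3,1.4]",
    ">1.4",
)
#: The four bins spanning the default similarity interval (0.8, 1.2].
SI_BIN_LABELS = ("(0.8,0.9]", "(0.9,1.0]", "(1.0,1.1]", "(1.1,1.2]")

#: Matched-grid effect sizes and per-group sample sizes of the calibration
#: universe (54 settings), and the four over/under-prediction pairs
#: (es_theo, es_pop) of the mismatch grid.
TABLE1_EFFECTS = (0.20, 0.50, 0.80, 1.00, 1.20, 1.40, 1.60, 1.80, 2.00)
GRID_SAMPLE_SIZES = (20, 30, 50, 100, 300, 1000)
TABLE2_PAIRS = ((0.50, 0.20), (0.50, 0.80), (1.00, 0.80), (1.00, 1.20))

#: Sentinel returned by :func:`find_min_n` when no sample size can reach the
#: requested coverage (the limiting coverage of the setting is below target).
UNREACHABLE = None


class NumericalError(RuntimeError):
    """Quadrature failed to converge to a trustworthy value."""


@dataclass(frozen=True)
class StudySetting:
    """One simulated two-group design.

    ``m1_pop - m0_pop`` is the true population effect (ES_POP) and
    ``m_theo - m0_pop`` the predicted effect (ES_THEO); the setting is
    *matched* when the two coincide.  ``pop_sd`` is the per-observation
    scale, so each group mean fluctuates with scale ``pop_sd/sqrt(n_g)``.
    """

    m1_pop: float
    m_theo: float
    n0: int
    n1: int
    m0_pop: float = 0.0
    pop_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("m1_pop", "m_theo", "m0_pop", "pop_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if self.n0 < 2 or self.n1 < 2:
            raise ValidationError("per-group sample sizes must be >= 2")
        if self.pop_sd <= 0:
            raise ValidationError("pop_sd must be positive")

    @property
    def es_pop(self) -> float:
        return self.m1_pop - self.m0_pop

    @property
    def es_theo(self) -> float:
        return self.m_theo - self.m0_pop

    @property
    def matched(self) -> bool:
        return self.m_theo == self.m1_pop

    @staticmethod
    def matched_setting(
        effect: float, n: int, n1: int | None = None, pop_sd: float = 1.0
    ) -> "StudySetting":
        """Matched two-group setting: control mean 0, prediction == truth."""
        return StudySetting(
            m1_pop=effect, m_theo=effect, n0=n, n1=n if n1 is None else n1, pop_sd=pop_sd
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Fully determines one Monte Carlo run given a setting.

    ``reps`` defaults to 10,000 repetitions, the calibration-table scale.
    Per-setting RNG streams are derived from ``seed`` by stable hashing of
    the setting, so any grid row can be regenerated independently.
    """

    reps: int = 10_000
    seed: int = 0
    df_mode: str = "t_nminus1"
    si: SimilarityInterval = field(default_factory=SimilarityInterval)

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValidationError("reps must be >= 1")
        if self.df_mode not in DF_MODES:
            raise ValidationError(f"df_mode must be one of {DF_MODES}")


@dataclass(frozen=True)
class ISimDistribution:
    """Binned Monte Carlo distribution of ``I_SIM`` for one setting.

    Bin percentages are over *defined* repetitions (observed difference
    nonzero); opposite-direction repetitions are recorded as ``I_SIM = 0``
    and therefore land in the ``<=0.6`` bin.  ``si_coverage_percent`` uses
    the closed similarity interval.
    """

    bin_percent: dict[str, float]
    si_coverage_percent: float
    n_opposite: int
    n_undefined: int
    n_reps: int
    setting: StudySetting | None = None
    config: SimulationConfig | None = None


def _setting_rng(seed: int, setting: StudySetting) -> np.random.Generator:
    """Independent, reproducible stream for one grid cell."""
    key = (
        f"{setting.m_theo:.12g}|{setting.m1_pop:.12g}|{setting.m0_pop:.12g}"
        f"|{setting.n0}|{setting.n1}|{setting.pop_sd:.12g}"
    )
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int.from_bytes(digest, "big")])
    )


def _draw_group_means(
    pop_mean: float,
    n: int,
    pop_sd: float,
    rng: np.random.Generator,
    size: int,
    df_mode: str,
) -> np.ndarray:
    scale = pop_sd / math.sqrt(n)
    if df_mode == "t_nminus1":
        if n < 2:
            raise ValidationError("t_nminus1 mode needs n >= 2 (df >= 1)")
        return pop_mean + scale * rng.standard_t(n - 1, size)
    if df_mode == "normal":
        return pop_mean + scale * rng.standard_normal(size)
    if df_mode == "raw_draws":
        draws = rng.standard_t(n - 1, size=(size, n))
        return pop_mean + pop_sd * draws.mean(axis=1)
    raise ValidationError(f"unknown df_mode {df_mode!r}")


def draw_observed_means(
    setting: StudySetting,
    rng: np.random.Generator,
    size: int = 1,
    df_mode: str = "t_nminus1",
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``size`` independent pairs of observed group means."""
    m0 = _draw_group_means(
        setting.m0_pop, setting.n0, setting.pop_sd, rng, size, df_mode
    )
    m1 = _draw_group_means(
        setting.m1_pop, setting.n1, setting.pop_sd, rng, size, df_mode
    )
    return m0, m1


def _isim_values(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised sign/zero rules; returns (isim, opposite mask, undefined mask)."""
    undefined = den == 0
    opposite = (num * den < 0) & ~undefined
    safe_den = np.where(undefined, 1.0, den)
    same = (num * den > 0) & ~undefined
    isim = np.where(same, num / safe_den, 0.0)
    isim[undefined] = np.nan
    return isim, opposite, undefined


def _bin_percent(defined_isim: np.ndarray) -> dict[str, float]:
    idx = np.searchsorted(BIN_EDGES, defined_isim, side="left")
    counts = np.bincount(idx, minlength=len(BIN_LABELS))
    pct = 100.0 * counts / defined_isim.size
    return dict(zip(BIN_LABELS, pct.tolist()))


def _distribution_from_arrays(
    isim: np.ndarray,
    opposite: np.ndarray,
    undefined: np.ndarray,
    si: SimilarityInterval,
    setting: StudySetting | None = None,
    config: SimulationConfig | None = None,
) -> ISimDistribution:
    defined = isim[~undefined]
    if defined.size == 0:
        raise ValidationError("no defined I_SIM values to bin")
    coverage = 100.0 * float(
        np.mean((defined >= si.lower) & (defined <= si.upper))
    )
    return ISimDistribution(
        bin_percent=_bin_percent(defined),
        si_coverage_percent=coverage,
        n_opposite=int(opposite.sum()),
        n_undefined=int(undefined.sum()),
        n_reps=int(isim.size),
        setting=setting,
        config=config,
    )


def bin_isim_values(
    verdicts: Sequence[SimilarityVerdict],
    si: SimilarityInterval | None = None,
) -> ISimDistribution:
    """Bin a sequence of verdicts into the ten printed bins.

    Opposite-direction verdicts (``I_SIM`` recorded as 0) fall into the
    ``<=0.6`` bin; undefined verdicts are excluded from percentages and
    counted separately.
    """
    if len(verdicts) == 0:
        raise ValidationError("cannot bin an empty sequence of verdicts")
    si = si or SimilarityInterval()
    isim = np.array([v.isim for v in verdicts], dtype=float)
    undefined = np.array([v.category is Category.UNDEFINED for v in verdicts])
    opposite = np.array([v.category is Category.OPPOSITE for v in verdicts])
    isim[undefined] = np.nan
    return _distribution_from_arrays(isim, opposite, undefined, si)


def simulate_isim_distribution(
    setting: StudySetting,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ISimDistribution:
    """Monte Carlo distribution of ``I_SIM`` for one setting.

    Each repetition draws both group means and computes
    ``(m_theo - m̄0) / (m̄1 - m̄0)``; sign and zero rules follow
    :func:`simindex.core.compute_isim`.  Deterministic given
    ``(setting, config)``.
    """
    config = config or SimulationConfig()
    if rng is None:
        rng = _setting_rng(config.seed, setting)
    m0, m1 = draw_observed_means(setting, rng, config.reps, config.df_mode)
    isim, opposite, undefined = _isim_values(setting.m_theo - m0, m1 - m0)
    return _distribution_from_arrays(
        isim, opposite, undefined, config.si, setting=setting, config=config
    )


def _mean_kernel(pop_mean: float, n: int, pop_sd: float, df_mode: str):
    """Frozen scipy distribution of one observed group mean."""
    scale = pop_sd / math.sqrt(n)
    if df_mode == "t_nminus1":
        return stats.t(df=n - 1, loc=pop_mean, scale=scale)
    if df_mode == "normal":
        return stats.norm(loc=pop_mean, scale=scale)
    if df_mode == "raw_draws":
        # the mean of n t(df) draws is close to normal with inflated scale
        df = n - 1
        inflate = math.sqrt(df / (df - 2)) if df > 2 else 1.0
        return stats.norm(loc=pop_mean, scale=scale * inflate)
    raise ValidationError(f"unknown df_mode {df_mode!r}")


def analytic_coverage_oracle(
    setting: StudySetting,
    si: SimilarityInterval | None = None,
    df_mode: str = "t_nminus1",
) -> float:
    """P(I_SIM inside the SI) by numerical integration.

    Integrates, over the distribution of the sampled control mean, the
    probability that the observed difference falls where the ratio
    ``(m_theo - m̄0)/(m̄1 - m̄0)`` lands inside the closed interval.  The
    integration variable is the control mean's CDF value, which handles
    heavy-tailed kernels exactly.  Independent of the Monte Carlo engine.
    """
    si = si or SimilarityInterval()
    dist0 = _mean_kernel(setting.m0_pop, setting.n0, setting.pop_sd, df_mode)
    dist1 = _mean_kernel(setting.m1_pop, setting.n1, setting.pop_sd, df_mode)
    lower, upper = si.lower, si.upper
    m_theo = setting.m_theo

    def inner(m0bar: float) -> float:
        if not math.isfinite(m0bar):
            return 0.0
        num = m_theo - m0bar
        if num > 0:
            lo, hi = num / upper, num / lower
        elif num < 0:
            lo, hi = num / lower, num / upper
        else:
            return 0.0
        # observed difference x = m̄1 - m̄0 must lie in [lo, hi]
        return float(dist1.cdf(hi + m0bar) - dist1.cdf(lo + m0bar))

    def integrand(u: float) -> float:
        return inner(float(dist0.ppf(u)))

    breakpoints = sorted(
        {min(max(float(dist0.cdf(x)), 1e-12), 1 - 1e-12) for x in (setting.m0_pop, m_theo)}
    )
    value, abserr = integrate.quad(
        integrand, 0.0, 1.0, points=breakpoints, limit=400
    )
    if not math.isfinite(value) or abserr > 1e-4:
        raise NumericalError(
            f"coverage quadrature did not converge (value={value}, abserr={abserr})"
        )
    return min(max(value, 0.0), 1.0)


def _grid(
    pairs: Iterable[tuple[float, float]],
    config: SimulationConfig,
    sample_sizes: Sequence[int],
) -> list[ISimDistribution]:
    start = time.perf_counter()
    out = []
    for es_theo, es_pop in pairs:
        for n in sample_sizes:
            setting = StudySetting(m1_pop=es_pop, m_theo=es_theo, n0=n, n1=n)
            dist = simulate_isim_distribution(setting, config)
            logger.debug(
                "theo=%.2f pop=%.2f n=%d coverage=%.2f bins=%s",
                es_theo, es_pop, n, dist.si_coverage_percent, dist.bin_percent,
            )
            out.append(dist)
    logger.info(
        "simulated %d settings x %d reps in %.2fs",
        len(out), config.reps, time.perf_counter() - start,
    )
    return out


def replicate_table1(
    config: SimulationConfig | None = None,
    effects: Sequence[float] = TABLE1_EFFECTS,
    sample_sizes: Sequence[int] = GRID_SAMPLE_SIZES,
) -> list[ISimDistribution]:
    """The matched calibration grid: 9 effects x 6 sample sizes (54 settings)."""
    config = config or SimulationConfig()
    return _grid(((e, e) for e in effects), config, sample_sizes)


def replicate_table2(
    config: SimulationConfig | None = None,
    pairs: Sequence[tuple[float, float]] = TABLE2_PAIRS,
    sample_sizes: Sequence[int] = GRID_SAMPLE_SIZES,
) -> list[ISimDistribution]:
    """The mismatch grid: four (es_theo, es_pop) pairs x 6 sample sizes."""
    config = config or SimulationConfig()
    return _grid(pairs, config, sample_sizes)


def coverage_gap(
    theo: float,
    pop: float,
    n: int,
    config: SimulationConfig | None = None,
) -> float:
    """Matched-minus-mismatched SI coverage, in percentage points.

    Runs the matched setting at the population effect and the mismatched
    setting (prediction ``theo`` against truth ``pop``) through the same
    engine and returns the difference of coverages: the margin by which a
    true-positive prediction is easier to detect than a false-positive one.
    """
    if theo <= 0 or pop <= 0:
        raise ValidationError("theo and pop must be positive effects")
    config = config or SimulationConfig()
    matched = simulate_isim_distribution(StudySetting.matched_setting(pop, n), config)
    mismatched = simulate_isim_distribution(
        StudySetting(m1_pop=pop, m_theo=theo, n0=n, n1=n), config
    )
    return matched.si_coverage_percent - mismatched.si_coverage_percent


def _limiting_coverage(ratio: float, si: SimilarityInterval) -> float:
    """Coverage as n -> infinity for a fixed prediction/truth ratio, in %."""
    if si.lower < ratio < si.upper:
        return 100.0
    if ratio == si.lower or ratio == si.upper:
        return 50.0
    return 0.0


def find_min_n(
    theo: float,
    pop: float,
    target_coverage: float,
    si: SimilarityInterval | None = None,
    df_mode: str = "t_nminus1",
    n_max: int = 2_000_000,
) -> int | None:
    """Smallest per-group n whose analytic SI coverage reaches the target.

    Returns :data:`UNREACHABLE` (``None``) when the limiting coverage of the
    prediction/truth ratio is below the target (e.g. any fixed ratio outside
    the SI tends to 0% coverage).  Monotonicity of coverage in n is checked
    on the bracketing path.
    """
    if not (0.0 < target_coverage < 100.0):
        raise ValidationError("target_coverage must be in (0, 100)")
    if theo <= 0 or pop <= 0:
        raise ValidationError("theo and pop must be positive effects")
    si = si or SimilarityInterval()
    if target_coverage >= _limiting_coverage(theo / pop, si):
        return UNREACHABLE

    def coverage(n: int) -> float:
        setting = StudySetting(m1_pop=pop, m_theo=theo, n0=n, n1=n)
        return 100.0 * analytic_coverage_oracle(setting, si, df_mode)

    lo, hi = 2, 2
    prev = coverage(hi)
    while prev < target_coverage:
        lo, hi = hi, hi * 2
        if hi > n_max:
            return UNREACHABLE
        cur = coverage(hi)
        # very heavy-tailed kernels (df <= 3) are legitimately non-monotone
        if cur < prev - 1e-9 and hi >= 8:
            logger.warning(
                "coverage non-monotone on search path at n=%d (%.4f -> %.4f)",
                hi, prev, cur,
            )
        prev = cur
    # smallest n in (lo, hi] with coverage >= target
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if coverage(mid) >= target_coverage:
            hi = mid
        else:
            lo = mid
    return hi
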