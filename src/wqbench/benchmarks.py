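"""Benchmark statistics over normalised principle-score profiles.

Every benchmark in this package is built from the same primitive: the
*normalised profile* of a farm-period, the sum of its four principle scores
each divided by the best value of that principle within a stated pool,

    omega = GF/maxGF + GHo/maxGHo + GHe/maxGHe + AB/maxAB  in [0, 4].

Three benchmark statistics are derived from it:

* ``past_ratio``        -- profile at period t over profile at period t-1,
                           each normalised by its own period's maxima
                           (development relative to the norm group);
* ``best_ratio_percent``-- the profile as a percentage of its ceiling 4
                           (closeness to the sample best);
* ``competitor_sigma``  -- the profile difference to a designated peer,
                           scaled by the pool's profile range (relative
                           position in the sample, in [-1, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import (
    PRINCIPLES,
    DegeneratePoolError,
    FarmPeriodRecord,
    PrincipleExtremes,
    PrincipleScores,
)


@dataclass(frozen=True)
class NormalizedProfile:
    """Sum of the four principle/max ratios, with its components."""

    value: float
    components: tuple[float, float, float, float]
    pool: str = ""


@dataclass(frozen=True)
class PastRatio:
    """Profile at period t divided by the profile at period t-1."""

    value: float
    numerator: NormalizedProfile
    denominator: NormalizedProfile

    @property
    def percent(self) -> float:
        """Ratio expressed in percent, the scale of the fuzzy thresholds."""
        return self.value * 100.0


@dataclass(frozen=True)
class CompetitorSigma:
    """Pairwise profile difference scaled by the pool's profile range.

    Negative values mean the farm performs worse than the competitor.
    """

    value: float
    farm_profile: float
    competitor_profile: float
    pool_max_profile: float
    pool_min_profile: float

    @property
    def percent(self) -> float:
        return self.value * 100.0


def _scores_of(record: FarmPeriodRecord | PrincipleScores) -> PrincipleScores:
    return record.scores if isinstance(record, FarmPeriodRecord) else record


def normalized_profile(
    record: FarmPeriodRecord | PrincipleScores, maxima: PrincipleExtremes
) -> NormalizedProfile:
    """Normalised profile of one record against per-principle maxima.

    Full floating precision is retained; rounding happens only at display.
    """
    scores = _scores_of(record).as_tuple()
    maxs = maxima.maxima.as_tuple()
    components: list[float] = []
    for name, s, m in zip(PRINCIPLES, scores, maxs):
        if m <= 0.0:
            raise ZeroDivisionError(
                f"maximum for principle {name} is {m}; cannot normalise"
            )
        components.append(s / m)
    return NormalizedProfile(
        value=sum(components), components=tuple(components), pool=maxima.pool
    )


def past_ratio(
    record_t: FarmPeriodRecord | PrincipleScores,
    record_tm1: FarmPeriodRecord | PrincipleScores,
    maxima_t: PrincipleExtremes,
    maxima_tm1: PrincipleExtremes,
) -> PastRatio:
    """Development benchmark: current profile over previous-period profile.

    Each period is normalised by the maxima of its own period pool, so the
    statistic measures movement relative to the group, not absolute change.
    """
    num = normalized_profile(record_t, maxima_t)
    den = normalized_profile(record_tm1, maxima_tm1)
    if den.value <= 0.0:
        raise DegeneratePoolError(
            "previous-period profile is zero; past ratio undefined"
        )
    return PastRatio(value=num.value / den.value, numerator=num, denominator=den)


def best_ratio_percent(profile: NormalizedProfile | float) -> float:
    """Profile as a percentage of its theoretical maximum of 4.

    The percentage is taken from the *unrounded* profile: e.g. a profile of
    3.285083 gives 82.13% while the display-rounded 3.29/4 would give 82.25.
    """
    value = profile.value if isinstance(profile, NormalizedProfile) else float(profile)
    if not (0.0 <= value <= 4.0):
        raise ValueError(f"profile value {value} outside [0, 4]")
    return value / 4.0 * 100.0


def sigma_from_profiles(
    farm: float, competitor: float, pool_max: float, pool_min: float
) -> float:
    """Core competitor statistic on already-computed profile sums."""
    if pool_max <= pool_min:
        raise DegeneratePoolError(
            f"pool profile range degenerate: max {pool_max} <= min {pool_min}"
        )
    return (farm - competitor) / (pool_max - pool_min)


def competitor_sigma(
    farm: FarmPeriodRecord | PrincipleScores,
    competitor: FarmPeriodRecord | PrincipleScores,
    maxima: PrincipleExtremes,
    pool_max_profile: NormalizedProfile | float,
    pool_min_profile: NormalizedProfile | float,
) -> CompetitorSigma:
    """Pairwise position benchmark against a designated competitor.

    The min/max profile pool is caller-supplied configuration: the records
    defining the range may span periods and need not coincide with the
    maxima pool.
    """

    def _val(p: NormalizedProfile | float) -> float:
        return p.value if isinstance(p, NormalizedProfile) else float(p)

    farm_p = normalized_profile(farm, maxima).value
    comp_p = normalized_profile(competitor, maxima).value
    hi, lo = _val(pool_max_profile), _val(pool_min_profile)
    return CompetitorSigma(
        value=sigma_from_profiles(farm_p, comp_p, hi, lo),
        farm_profile=farm_p,
        competitor_profile=comp_p,
        pool_max_profile=hi,
        pool_min_profile=lo,
    )
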