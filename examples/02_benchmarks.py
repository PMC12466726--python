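"""Compute the three benchmark statistics for one farm.

Uses the demonstration farm's scores with the per-period normalisation
maxima stated in the worked evaluation, and prints the past-period ratio,
the best-in-sample profile/percentage, and the competitor sigma.
"""

from wqbench import (
    PrincipleExtremes,
    PrincipleScores,
    best_ratio_percent,
    competitor_sigma,
    normalized_profile,
    past_ratio,
)

farm_t = PrincipleScores(51.53, 50.95, 30.80, 33.38)
farm_tm1 = PrincipleScores(46.95, 51.65, 20.30, 36.02)
competitor = PrincipleScores(49.78, 52.29, 34.34, 33.19)
pool_min = PrincipleScores(46.95, 50.95, 20.30, 33.19)
maxima_t = PrincipleExtremes(PrincipleScores(55.01, 52.29, 56.70, 40.18), pool="period t")
maxima_tm1 = PrincipleExtremes(PrincipleScores(57.92, 53.12, 43.29, 44.01), pool="period t-1")

ratio = past_ratio(farm_t, farm_tm1, maxima_t, maxima_tm1)
print(f"past ratio      : {ratio.value:.2f}  ({ratio.percent:.2f}% of the t-1 profile)")
# > 1 means the farm moved closer to the period bests than it was at t-1.

profile = normalized_profile(farm_t, maxima_t)
print(f"best profile    : {profile.value:.4f} of 4  ->  {best_ratio_percent(profile):.2f}%")
# Sum of the four principle/sample-max ratios; 100% would equal the sample best.

sigma = competitor_sigma(
    farm_t,
    competitor,
    maxima_t,
    normalized_profile(maxima_t.maxima, maxima_t),
    normalized_profile(pool_min, maxima_t),
)
print(f"competitor sigma: {sigma.value:+.5f}  ({sigma.percent:+.3f}%)")
# Negative: the farm sits slightly below its competitor within the pool range.
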