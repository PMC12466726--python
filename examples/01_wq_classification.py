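"""Classify farms with the Welfare Quality rule list.

Builds the three-farm, two-period demonstration panel and prints each
farm-period's four principle scores and its WQ category.  The rule list is
threshold-based: e.g. "Enhanced" needs every principle above 20 and at least
two above 55.
"""

from wqbench import FarmPanel, FarmPeriodRecord, PrincipleScores, classify_wq

panel = FarmPanel(
    [
        FarmPeriodRecord("HU", "t-1", PrincipleScores(46.95, 51.65, 20.30, 36.02)),
        FarmPeriodRecord("HU", "t", PrincipleScores(51.53, 50.95, 30.80, 33.38)),
        FarmPeriodRecord("SK", "t-1", PrincipleScores(49.11, 50.19, 43.26, 35.37)),
        FarmPeriodRecord("SK", "t", PrincipleScores(52.45, 51.94, 30.55, 40.19)),
        FarmPeriodRecord("AT", "t-1", PrincipleScores(57.92, 53.12, 43.29, 44.01)),
        FarmPeriodRecord("AT", "t", PrincipleScores(55.01, 51.14, 56.70, 40.18)),
    ],
    period_order=("t-1", "t"),
)

print(f"{'farm':<6}{'period':<8}{'GF':>7}{'GHo':>7}{'GHe':>7}{'AB':>7}  category")
for rec in panel.records:
    gf, gho, ghe, ab = rec.scores.as_tuple()
    category = classify_wq(rec.scores)
    print(
        f"{rec.farm_id:<6}{rec.period_id:<8}{gf:>7.2f}{gho:>7.2f}{ghe:>7.2f}{ab:>7.2f}"
        f"  {category.label}"
    )
# Only the Austrian farm at period t clears the Enhanced bar (all four
# principles above 20 and two -- GF 55.01, GHe 56.70 -- above 55).
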