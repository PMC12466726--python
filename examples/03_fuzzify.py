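"""Fuzzify benchmark values against the expert-elicited category systems.

Each benchmark value (in percent) gets a membership degree in five ordered
categories; the winning category is collapsed to the four-level WQ scale and
mapped to a defuzzified constant for aggregation.
"""

from wqbench import build_preset_system, fuzzify

cases = [
    ("past", 107.0),        # ratio 1.07 expressed in percent
    ("best", 82.13),        # profile 3.2851 as percent of the ceiling 4
    ("competitor", -5.212), # sigma -0.05212 in percent
]

for which, value in cases:
    system = build_preset_system(which)
    res = fuzzify(system, value)
    active = {k: round(v, 4) for k, v in res.memberships.items() if v > 0}
    print(f"{which:<11} @ {value:>8.3f}%  memberships {active}")
    print(
        f"{'':<11}   -> {res.five_level} -> {res.four_level.label}"
        f" -> defuzzified {res.defuzzified:.2f}"
    )
# 107% splits 0.6/0.4 between good and acceptable; the max-membership rule
# picks good, which collapses to Enhanced and defuzzifies to 0.75.
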