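"""Seeded generators for synthetic panels and expert fixtures.

No public dataset of Welfare Quality principle scores exists, so tests and
examples run on generated stand-ins.  Defaults emulate the stated world of
the method's demonstration sample: three commercial dairy herds observed
over two assessment periods, with per-principle score levels and spreads
matching that sample (scores clustered roughly between 20 and 60 on the
0-100 scale, Good Housing nearly flat across herds, Good Health by far the
most variable principle).  Expert fixtures emulate an eight-member panel
rating the 14 non-trivial dimension combinations on the five-point
importance scale, with tunable consensus.

All randomness flows through one ``numpy`` generator per call, seeded by the
caller: identical seeds give identical fixtures.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np

from .choquet import CANONICAL_DIMENSIONS
from .core import FarmPanel, FarmPeriodRecord, PrincipleScores
from .elicitation import (
    DEFAULT_IMPORTANCE_SCALE,
    ExpertImportanceResponse,
    ExpertPanel,
)

#: Per-principle (GF, GHo, GHe, AB) score means and spreads of the default
#: score model, chosen to match the three-herd demonstration sample.
DEFAULT_MEANS = (52.0, 51.5, 37.5, 38.0)
DEFAULT_SDS = (3.5, 1.0, 12.0, 3.5)


def generate_panel(
    n_farms: int = 3,
    n_periods: int = 2,
    seed: int = 0,
    means: Sequence[float] = DEFAULT_MEANS,
    sds: Sequence[float] = DEFAULT_SDS,
) -> FarmPanel:
    """Synthetic farm panel with normally distributed, clipped scores.

    Scores are drawn per principle from ``N(mean, sd)`` and truncated to
    [0, 100].  Farms are ``F01..``; periods ``p01..`` in chronological
    order.
    """
    if n_farms < 1 or n_periods < 1:
        raise ValueError("need at least one farm and one period")
    if len(means) != 4 or len(sds) != 4:
        raise ValueError("means and sds must have four entries (GF, GHo, GHe, AB)")
    rng = np.random.default_rng(seed)
    periods = [f"p{i + 1:02d}" for i in range(n_periods)]
    records = []
    for f in range(n_farms):
        farm = f"F{f + 1:02d}"
        for period in periods:
            raw = rng.normal(loc=means, scale=sds)
            clipped = np.clip(raw, 0.0, 100.0)
            records.append(
                FarmPeriodRecord(farm, period, PrincipleScores(*clipped))
            )
    return FarmPanel(records, period_order=periods)


def generate_importance_panel(
    n_experts: int = 8,
    dims: Sequence[str] = CANONICAL_DIMENSIONS,
    seed: int = 0,
    consensus: float = 0.75,
) -> ExpertPanel:
    """Synthetic importance responses for every proper dimension subset.

    For each subset a consensus label is drawn uniformly; each expert
    answers it with probability ``consensus`` and otherwise drifts to an
    adjacent scale label.
    """
    if not (0.0 <= consensus <= 1.0):
        raise ValueError("consensus must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = list(DEFAULT_IMPORTANCE_SCALE)
    experts = [f"E{i + 1}" for i in range(n_experts)]
    responses = []
    for r in range(1, len(dims)):
        for combo in combinations(dims, r):
            center = int(rng.integers(len(labels)))
            for expert in experts:
                idx = center
                if rng.random() > consensus:
                    idx = int(np.clip(center + rng.choice([-1, 1]), 0, len(labels) - 1))
                responses.append(
                    ExpertImportanceResponse(
                        expert_id=expert,
                        subset=frozenset(combo),
                        label=labels[idx],
                    )
                )
    return ExpertPanel(experts=experts, importance_responses=responses)


def generate_rating_matrix(
    n_raters: int = 8,
    n_items: int = 14,
    seed: int = 0,
    levels: int = 5,
    noise: float = 0.8,
) -> np.ndarray:
    """Likert-style raters x items matrix with a shared latent item order.

    Item "true" importances are uniform on [1, levels]; each rater reports
    them with Gaussian noise, rounded and clipped to the 1..levels codes.
    Smaller ``noise`` means higher concordance.
    """
    rng = np.random.default_rng(seed)
    latent = rng.uniform(1, levels, size=n_items)
    scores = latent[None, :] + rng.normal(0.0, noise, size=(n_raters, n_items))
    return np.clip(np.round(scores), 1, levels).astype(int)
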