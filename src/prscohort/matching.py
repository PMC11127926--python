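"""Proportional control matching.

A large control pool is downsampled so its organ-site composition
matches the case cohort. Integer allocations come from largest-remainder
(Hamilton) apportionment of the requested control total proportionally
to the case counts; sampling within each stratum is then uniform without
replacement and fully determined by the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .io import CohortTable

__all__ = ["MatchPlan", "allocate_strata", "sample_matched_controls"]


@dataclass
class MatchPlan:
    """Per-stratum control allocations: (stratum, case_count, allocated)."""

    strata: list[tuple[str, int, int]]
    total_control: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if sum(a for _, _, a in self.strata) != self.total_control:
            raise ValueError("allocations do not sum to total_control")
        if any(a < 0 for _, _, a in self.strata):
            raise ValueError("negative allocation")
        if any(a > 0 and c == 0 for _, c, a in self.strata):
            raise ValueError("allocation to a stratum with no cases")

    @property
    def allocations(self) -> dict[str, int]:
        return {s: a for s, _, a in self.strata}

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_control": self.total_control,
                "seed": self.seed,
                "strata": [
                    {"stratum": s, "case_count": c, "allocated": a}
                    for s, c, a in self.strata
                ],
            },
            sort_keys=True,
        )


def allocate_strata(case_counts: dict[str, int], total_control: int) -> MatchPlan:
    """Largest-remainder apportionment of controls across strata.

    Each stratum's quota is ``total_control * case_count / total_cases``;
    floors are assigned first and the remaining units go to the largest
    fractional parts, ties broken by lexicographic stratum label.
    """
    if total_control <= 0:
        raise ValueError("total_control must be positive")
    if any(c < 0 for c in case_counts.values()):
        raise ValueError("case counts must be nonnegative")
    total_cases = sum(case_counts.values())
    if total_cases == 0:
        raise ValueError("no cases to match against")

    quotas = {s: total_control * c / total_cases for s, c in case_counts.items()}
    alloc = {s: math.floor(q) for s, q in quotas.items()}
    remaining = total_control - sum(alloc.values())
    by_remainder = sorted(quotas, key=lambda s: (-(quotas[s] - alloc[s]), s))
    for s in by_remainder[:remaining]:
        alloc[s] += 1
    strata = [(s, case_counts[s], alloc[s]) for s in case_counts]
    return MatchPlan(strata=strata, total_control=total_control)


def sample_matched_controls(
    plan: MatchPlan, pool: CohortTable, seed: int
) -> CohortTable:
    """Draw the planned number of controls per stratum, uniformly
    without replacement, reproducibly for a given seed.

    Strata are processed in sorted label order with candidate ids sorted
    before sampling, so the draw depends only on (plan, pool content,
    seed) and not on row order.
    """
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for stratum, _case_count, n_alloc in sorted(plan.strata):
        if n_alloc == 0:
            continue
        ids = sorted(
            pool.df.loc[pool.df["organ_site"] == stratum, "sample_id"].tolist()
        )
        if len(ids) < n_alloc:
            raise ValueError(
                f"stratum {stratum!r}: pool has {len(ids)} controls but "
                f"{n_alloc} requested (shortfall {n_alloc - len(ids)})"
            )
        chosen.extend(rng.choice(ids, size=n_alloc, replace=False).tolist())
    matched = pool.subset(chosen)
    plan.seed = seed
    return matched
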