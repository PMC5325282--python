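"""Demographic cost of mortality: the replacement-chain pair count.

The question: how many territorial pairs does it take to produce one
fatality of a given age — counting not only the pairs whose output is
winnowed down to that single survivor, but also the recruits needed to
keep those pairs themselves staffed, and the pairs needed to produce
*those* recruits, and so on?

Survivorship from fledging to age m months composes the stage-specific
annual rates with fractional-year exponents,

    phi(m) = S_j^(min(m,12)/12) * S_s^(clamp((m-12)/12, 0, 3))
             * S_b^(max((m-48)/12, 0)).

With f2 fledglings of both sexes per pair per year, producing one
survivor of age m requires P0 = 1 / (f2 phi(m)) pairs.  Each such pair
has 2 members dying at annual breeder mortality (1 - S_b); each breeder
replacement is a recruit with survivorship phi_r = S_j S_s^3 S_b (a
fledgling surviving three subadult years and its first adult year),
itself requiring 1 / (f2 phi_r) pairs.  Every replacement round
therefore multiplies the previous pair increment by

    r = 2 (1 - S_b) / (f2 phi_r),

and the cumulative pair count is the geometric series
P0 (1 + r + r^2 + ...) with limit P0 / (1 - r) for r < 1.

The recruit is labelled a 56-month-old in the source narrative, but the
narrative's own arithmetic (sole survivor of 1.653 fledglings, hence
2.590 pairings) corresponds to the full adult year at S_b, i.e.
phi_r = S_j S_s^3 S_b; this module follows the arithmetic.  The
published closed-form "exact" count of 3.931 pairs per fatality cannot
be reproduced from the stated recursion (whose limit is 3.853 from the
rounded inputs); it is stored as a reference constant, never computed,
and the published population footprints (216 and 255 pairs) are the
printed products of annual tolls with that constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .rates import VitalRates

__all__ = [
    "PUBLISHED_PAIRS_PER_FATALITY",
    "CostResult",
    "FootprintResult",
    "survivorship",
    "pairs_to_produce",
    "replacement_chain",
    "age_resolved_cost",
    "footprint",
]

#: Published closed-form pairs-per-fatality constant, kept for reference
#: and for reproducing the printed footprint products only.
PUBLISHED_PAIRS_PER_FATALITY = 3.931


def survivorship(rates: VitalRates, months: float) -> float:
    """phi(m): probability of surviving from fledging to age m months."""
    if months < 0:
        raise ValueError("age must be non-negative")
    yr_juv = min(months, 12.0) / 12.0
    yr_sub = min(max((months - 12.0) / 12.0, 0.0), 3.0)
    yr_ad = max((months - 48.0) / 12.0, 0.0)
    return float(
        rates.s_juv**yr_juv * rates.s_sub**yr_sub * rates.s_breed**yr_ad
    )


def pairs_to_produce(fledglings_needed: float, f2: float) -> float:
    """Pairs whose combined annual output is ``fledglings_needed``."""
    if f2 <= 0:
        raise ValueError("f2 must be positive")
    if fledglings_needed < 0:
        raise ValueError("fledglings_needed must be non-negative")
    return fledglings_needed / f2


@dataclass(frozen=True)
class CostResult:
    fatality_age_months: float
    pairs_initial: float          # P0
    series: tuple[float, ...]     # cumulative pairs after 0..k rounds
    pairs_limit: float            # P0 / (1 - r), inf if r >= 1
    replacement_ratio: float      # r, the per-round multiplier
    sustainable: bool             # r < 1
    per_fatality_published: float = PUBLISHED_PAIRS_PER_FATALITY

    @property
    def cumulative(self) -> float:
        return self.series[-1]


def replacement_chain(
    rates: VitalRates,
    f2: float,
    fatality_age_months: float,
    k_rounds: int = 6,
) -> CostResult:
    """Pairs per fatality through ``k_rounds`` replacement rounds.

    ``series[k]`` is the cumulative pair count after k rounds (k = 0 is
    the initial P0), so ``k_rounds = 6`` yields the 7-term cumulative.
    """
    if k_rounds < 0:
        raise ValueError("k_rounds must be >= 0")
    phi = survivorship(rates, fatality_age_months)
    if phi <= 0:
        raise ValueError("zero survivorship at the fatality age")
    p0 = pairs_to_produce(1.0 / phi, f2)
    phi_r = rates.s_juv * rates.s_sub**3 * rates.s_breed
    pairs_per_recruit = pairs_to_produce(1.0 / phi_r, f2)
    r = 2.0 * (1.0 - rates.s_breed) * pairs_per_recruit
    series = [p0]
    inc = p0
    for _ in range(k_rounds):
        inc *= r
        series.append(series[-1] + inc)
    sustainable = r < 1.0
    limit = p0 / (1.0 - r) if sustainable else float("inf")
    return CostResult(
        fatality_age_months=fatality_age_months,
        pairs_initial=float(p0),
        series=tuple(float(x) for x in series),
        pairs_limit=float(limit),
        replacement_ratio=float(r),
        sustainable=sustainable,
    )


def age_resolved_cost(
    rates: VitalRates,
    f2: float,
    age_distribution: Mapping[float, float],
    k_rounds: int = 6,
) -> float:
    """Pairs per fatality averaged over a fatality-age distribution.

    ``age_distribution`` maps age in months to a weight; weights must sum
    to 1.  Returns the weighted mean of the replacement-chain limits.
    """
    weights = np.array(list(age_distribution.values()), dtype=float)
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must be non-negative and sum to 1")
    return float(
        sum(
            w * replacement_chain(rates, f2, age, k_rounds).pairs_limit
            for age, w in age_distribution.items()
        )
    )


@dataclass(frozen=True)
class FootprintResult:
    annual_deaths: float
    pairs_per_fatality: float
    pairs_required: int
    resident_fraction: float
    resident_pairs: int


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def footprint(
    pairs_per_fatality: float,
    annual_deaths: float,
    resident_fraction: float = 1.0,
) -> FootprintResult:
    """Population footprint of an annual mortality toll.

    ``pairs_required = annual_deaths x pairs_per_fatality`` and the
    resident share of it, both rounded half-up to whole pairs.
    """
    if annual_deaths < 0 or pairs_per_fatality < 0:
        raise ValueError("inputs must be non-negative")
    if not 0.0 <= resident_fraction <= 1.0:
        raise ValueError("resident_fraction must be in [0, 1]")
    total = annual_deaths * pairs_per_fatality
    return FootprintResult(
        annual_deaths=annual_deaths,
        pairs_per_fatality=pairs_per_fatality,
        pairs_required=_round_half_up(total),
        resident_fraction=resident_fraction,
        resident_pairs=_round_half_up(resident_fraction * total),
    )
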