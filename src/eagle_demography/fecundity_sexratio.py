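"""Reproduction metrics, fledgling sex-ratio tests, and female fecundity.

Reproductive rate is measured from annual nest surveys as fledglings per
occupied territory; the across-year summary is the unweighted mean of the
annual rates (not the pooled ratio), with its standard error taken across
years.  Departure of fledgling sex counts from parity is tested with the
likelihood-ratio G-test (no continuity or Williams correction).  The
female-fledgling reproductive rate f — female fledglings per female
territory holder per year, the fertility input of every downstream model
— is the product of the mean annual rate and the female-fledgling
proportion, with a delta-method SE for an independent product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .telemetry_io import NestSurveyRecord

__all__ = [
    "ReproductionSummary",
    "FemaleFecundity",
    "GTestResult",
    "summarize_reproduction",
    "g_test_parity",
    "female_fecundity",
    "subadult_pair_fraction",
    "DEFAULT_P_FEMALE",
]

#: 1 minus the observed aggregate male fledgling proportion (0.64).
DEFAULT_P_FEMALE = 0.36


@dataclass
class ReproductionSummary:
    """Per-year reproduction rates and their across-year summary.

    ``per_year`` has one row per survey year with columns
    ``fledglings_per_pair`` (fledglings / pairs surveyed),
    ``mean_brood_size`` (fledglings / fledged broods; NaN if no brood
    fledged that year) and ``nest_success`` (fledged broods / pairs).
    """

    per_year: pd.DataFrame
    mean_annual_rate: float
    SE: float


def summarize_reproduction(
    surveys: Iterable[NestSurveyRecord],
) -> ReproductionSummary:
    surveys = list(surveys)
    if not surveys:
        raise ValueError("need at least one survey year")
    rows = []
    for s in surveys:
        if s.pairs_surveyed == 0:
            raise ValueError(f"year {s.year}: zero pairs surveyed")
        rows.append(
            {
                "year": s.year,
                "pairs_surveyed": s.pairs_surveyed,
                "fledglings": s.fledglings,
                "fledged_broods": s.fledged_broods,
                "fledglings_per_pair": s.fledglings / s.pairs_surveyed,
                "mean_brood_size": (
                    s.fledglings / s.fledged_broods
                    if s.fledged_broods > 0
                    else float("nan")
                ),
                "nest_success": s.fledged_broods / s.pairs_surveyed,
            }
        )
    per_year = pd.DataFrame(rows).set_index("year")
    rates = per_year["fledglings_per_pair"].to_numpy()
    mean_rate = float(rates.mean())
    se = (
        float(rates.std(ddof=1) / np.sqrt(len(rates)))
        if len(rates) > 1
        else 0.0
    )
    return ReproductionSummary(per_year=per_year, mean_annual_rate=mean_rate,
                               SE=se)


@dataclass(frozen=True)
class GTestResult:
    G: float
    df: int
    p_value: float
    zero_cell: bool = False


def g_test_parity(males: int, females: int) -> GTestResult:
    """Likelihood-ratio test of a 1:1 sex ratio.

    G = 2 sum O ln(O/E) with E = total/2 in each cell, referred to
    chi-square with 1 df.  A zero cell uses the 0 ln 0 = 0 convention and
    is flagged.
    """
    if males < 0 or females < 0:
        raise ValueError("counts must be non-negative")
    total = males + females
    if total == 0:
        raise ValueError("need at least one individual")
    expected = total / 2.0
    G = 0.0
    zero = False
    for obs in (males, females):
        if obs > 0:
            G += 2.0 * obs * np.log(obs / expected)
        else:
            zero = True
    p = float(stats.chi2.sf(G, df=1))
    return GTestResult(G=float(G), df=1, p_value=p, zero_cell=zero)


@dataclass(frozen=True)
class FemaleFecundity:
    f: float
    SE: float


def female_fecundity(
    mean_annual_rate: float,
    p_female: float = DEFAULT_P_FEMALE,
    rate_se: float = 0.0,
    p_female_se: float = 0.0,
) -> FemaleFecundity:
    """f = (fledglings of both sexes per pair) x (female proportion).

    SE by the delta method for a product of independent estimates:
    var(f) = p^2 var(rate) + rate^2 var(p).
    """
    if not 0.0 <= p_female <= 1.0:
        raise ValueError("p_female must be a proportion")
    if mean_annual_rate < 0:
        raise ValueError("mean_annual_rate must be non-negative")
    f = mean_annual_rate * p_female
    var = p_female**2 * rate_se**2 + mean_annual_rate**2 * p_female_se**2
    return FemaleFecundity(f=float(f), SE=float(np.sqrt(var)))


def subadult_pair_fraction(aged_birds: int, subadult_members: int) -> float:
    """Percent of aged pair members that are subadults, to 1 dp."""
    if aged_birds <= 0:
        raise ValueError("no aged birds")
    if subadult_members > aged_birds:
        raise ValueError("more subadults than aged birds")
    return round(100.0 * subadult_members / aged_birds, 1)
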